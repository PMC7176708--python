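"""Synthetic mandibles, phylogenies and diet classes.

Real comparative datasets of this kind consist of lateral-view mandible
outlines digitised from photographs, 12 homologous landmarks, corpus
thickness measurements, muscle attachment descriptors, a dated phylogeny,
and hard/soft diet labels for the extant taxa.  No such data ship with
this package; this module generates datasets with the same statistical
structure so the whole downstream chain (meshing, FEA, stress statistics,
morphometrics, classification) is testable end to end:

* outline shape is controlled by eight interpretable parameters
  (:class:`ShapeParams`) that evolve as multivariate Brownian motion (BM)
  on a simulated pure-birth tree scaled to unit height;
* a binary diet class (H = hard-food eater, S = soft-food eater) is
  assigned to the extant tips as a balanced random split, and hard eaters
  receive a robusticity offset (``diet_effect`` tip standard deviations,
  applied on the natural-log scale so lengths stay positive) on corpus
  height and base thickness;
* "fossil" specimens are extra pendant tips grafted onto the tree with
  diet label ``unknown``; by default they are drawn from the soft regime
  (no robusticity offset), mirroring an unlabeled sample to classify;
* landmark coordinates receive i.i.d. Gaussian digitisation noise.

Everything is a pure function of (tree, parameters, seed).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon

from .errors import GeometryError, InvalidArgumentError

__all__ = [
    "ShapeParams",
    "Phylogeny",
    "Specimen",
    "MuscleSpec",
    "simulate_phylogeny",
    "simulate_specimens",
    "simulate_dataset",
    "outline_from_params",
]

PARAM_NAMES = (
    "corpus_height",
    "corpus_length",
    "ramus_height",
    "gonial_angle",
    "coronoid_height",
    "condyle_offset",
    "symphysis_depth",
    "thickness_base",
)

# Relative BM rates (log-scale tip standard deviation at sigma_bm = 1,
# tree height 1).  Lengths vary ~8%; the gonial angle varies less because
# its biological range is narrow.
REL_SD = {
    "corpus_height": 0.08,
    "corpus_length": 0.08,
    "ramus_height": 0.08,
    "gonial_angle": 0.04,
    "coronoid_height": 0.08,
    "condyle_offset": 0.08,
    "symphysis_depth": 0.08,
    "thickness_base": 0.08,
}

# Landmark order (indices into the 12-landmark configuration).  The
# scheme fixes its own homologous points on the outline:
# 0 infradentale (anterior alveolar margin, incisive bite point)
# 1 gnathion (anterior-inferior symphysis)
# 2 canine alveolar point (canine bite point)
# 3 distal premolar / first molar boundary (premolar bite point)
# 4 centre of M1 (molar bite point)
# 5 posterior end of the alveolar margin
# 6 coronoid process tip
# 7 deepest point of the mandibular notch
# 8 most posterior point of the condyle
# 9 midpoint of the posterior ramus border
# 10 gonion
# 11 midpoint of the inferior corpus border
LANDMARK_NAMES = (
    "infradentale",
    "gnathion",
    "canine_alveolar",
    "premolar_molar_boundary",
    "m1_centre",
    "posterior_alveolar",
    "coronoid_tip",
    "mandibular_notch",
    "condyle_posterior",
    "ramus_posterior_mid",
    "gonion",
    "corpus_base_mid",
)

CONDYLE_LANDMARK = 8
BITE_LANDMARKS = {"IB": 0, "CB": 2, "PB": 3, "MB": 4}


@dataclass(frozen=True)
class ShapeParams:
    """Interpretable mandible outline parameters (mm, degrees).

    Defaults are macaque-like: a 60 mm tooth-row corpus, 45 mm ramus and
    12 mm corpus breadth.
    """

    corpus_height: float = 18.0
    corpus_length: float = 60.0
    ramus_height: float = 45.0
    gonial_angle: float = 120.0
    coronoid_height: float = 50.0
    condyle_offset: float = 8.0
    symphysis_depth: float = 20.0
    thickness_base: float = 12.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if not 90.0 <= self.gonial_angle <= 160.0:
            raise InvalidArgumentError("gonial_angle must be in [90, 160] degrees")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])


@dataclass
class MuscleSpec:
    """One adductor muscle: insertion arc on the outline plus origin.

    ``arc`` is a (start, end) pair of arc-length fractions along the
    outline (counter-clockwise from the infradentale); ``origin`` is the
    area centroid of the cranial attachment in specimen coordinates, and
    ``rel_area`` the muscle's share of total attachment area (the three
    shares sum to 1).
    """

    arc: tuple
    origin: np.ndarray
    rel_area: float


@dataclass
class Specimen:
    """One mandible: outline, landmarks, thickness, muscles, diet label."""

    id: str
    outline: np.ndarray  # (n, 2) mm, counter-clockwise, open (no repeat)
    landmarks: np.ndarray  # (12, 2) mm
    thickness: float  # mm, mean of three breadth measurements
    diet: str  # 'H', 'S' or 'unknown'
    muscles: dict  # name -> MuscleSpec
    params: ShapeParams = None
    generating_regime: str = field(default=None, repr=False)  # latent truth

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (12, 2):
            raise InvalidArgumentError(
                f"specimen {self.id}: exactly 12 landmarks required"
            )
        if not self.thickness > 0:
            raise InvalidArgumentError(f"specimen {self.id}: thickness must be > 0")
        if self.diet not in ("H", "S", "unknown"):
            raise InvalidArgumentError(f"specimen {self.id}: diet must be H/S/unknown")
        if self.muscles:
            total = sum(m.rel_area for m in self.muscles.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidArgumentError(
                    f"specimen {self.id}: muscle relative areas sum to {total}, not 1"
                )

    @property
    def outline_area(self) -> float:
        return Polygon(self.outline).area


class Phylogeny:
    """Rooted tree with strictly positive branch lengths (dendropy-backed)."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise InvalidArgumentError("tip labels must be unique")
        if len(labels) < 3:
            raise InvalidArgumentError("phylogeny must have >= 3 tips")
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None and not (edge.length or 0) > 0:
                raise InvalidArgumentError("all branch lengths must be > 0")

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict:
        """Root-to-node depth for every node."""
        out = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                out[node] = 0.0
            else:
                out[node] = out[parent] + node.edge.length
        return out

    @property
    def height(self) -> float:
        d = self.depths()
        return max(d[leaf] for leaf in self.tree.leaf_node_iter())

    def vcv(self, labels=None) -> tuple:
        """Phylogenetic (Brownian-motion) covariance matrix.

        ``C[i, j]`` is the root-to-MRCA depth of tips i and j (shared
        evolutionary history); the diagonal holds tip depths.  Returns
        ``(C, labels)`` in the requested (default: tree) tip order.
        """
        depths = self.depths()
        leaves = list(self.tree.leaf_node_iter())
        all_labels = [lf.taxon.label for lf in leaves]
        if labels is None:
            labels = all_labels
        index = {lab: i for i, lab in enumerate(labels)}
        missing = [l for l in labels if l not in set(all_labels)]
        if missing:
            raise InvalidArgumentError(f"labels not on tree: {missing}")
        n = len(labels)
        c = np.zeros((n, n))
        # tip sets per node, assigned pair-wise at each internal node
        tipsets = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                tipsets[node] = [index[lab]] if lab in index else []
                if lab in index:
                    c[index[lab], index[lab]] = depths[node]
            else:
                children = node.child_nodes()
                sets = [tipsets[ch] for ch in children]
                for a in range(len(sets)):
                    for b in range(a + 1, len(sets)):
                        if sets[a] and sets[b]:
                            ia = np.asarray(sets[a])
                            ib = np.asarray(sets[b])
                            c[np.ix_(ia, ib)] = depths[node]
                            c[np.ix_(ib, ia)] = depths[node]
                tipsets[node] = [i for s in sets for i in s]
        return c, list(labels)

    def prune_to(self, labels) -> "Phylogeny":
        """New phylogeny retaining only the given tip labels."""
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(list(labels))
        return Phylogeny(tree)


def simulate_phylogeny(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, scaled to unit height.

    Lineages split at rate 1; after the n-th lineage appears the present
    is set one further exponential waiting time later, and all branch
    lengths are divided by the tree height so extant tips sit at depth
    exactly 1.  Reproducible given ``seed``.
    """
    if n_tips < 3:
        raise InvalidArgumentError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)

    # node: [parent, birth_time, end_time, children]
    nodes = {0: [None, 0.0, 0.0, []]}
    nodes[1] = [0, 0.0, None, []]
    nodes[2] = [0, 0.0, None, []]
    nodes[0][3] = [1, 2]
    active = [1, 2]
    nxt = 3
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        nodes[parent][2] = t
        for _ in range(2):
            nodes[nxt] = [parent, t, None, []]
            nodes[parent][3].append(nxt)
            active.append(nxt)
            nxt += 1
    t_end = t + rng.exponential(1.0 / n_tips)
    labels = {}
    tip_counter = [0]
    for nid in active:
        nodes[nid][2] = t_end

    def newick(nid):
        parent, birth, end, children = nodes[nid]
        length = (end - birth) / t_end
        if not children:
            tip_counter[0] += 1
            return f"t{tip_counter[0]}:{length!r}"
        inner = ",".join(newick(ch) for ch in children)
        if parent is None:
            return f"({inner});"
        return f"({inner}):{length!r}"

    return Phylogeny.from_newick(newick(0))


def _graft_fossil_tips(phy: Phylogeny, n_fossils: int, rng) -> Phylogeny:
    """Attach pendant 'fossil' tips at random points of the tree."""
    tree = phy.tree.clone(depth=1)
    tns = tree.taxon_namespace
    for k in range(n_fossils):
        depths = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            depths[node] = 0.0 if parent is None else depths[parent] + node.edge.length
        height = max(depths[lf] for lf in tree.leaf_node_iter())
        edges = [
            e
            for e in tree.preorder_edge_iter()
            if e.tail_node is not None and (e.length or 0) > 0
        ]
        lengths = np.array([e.length for e in edges])
        e = edges[int(rng.choice(len(edges), p=lengths / lengths.sum()))]
        u = float(rng.uniform(0.1, 0.9))
        tail, head = e.tail_node, e.head_node
        orig_len = e.length
        attach_depth = depths[tail] + u * orig_len
        new = dendropy.Node()
        tail.remove_child(head)
        tail.add_child(new)
        new.edge.length = u * orig_len
        new.add_child(head)
        head.edge.length = orig_len * (1.0 - u)
        pendant = float(rng.uniform(0.3, 0.9)) * (height - attach_depth)
        pendant = max(pendant, 0.02 * height)
        leaf = dendropy.Node(taxon=tns.require_taxon(label=f"f{k + 1}"))
        new.add_child(leaf)
        leaf.edge.length = pendant
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Outline construction


def _anchors(p: ShapeParams) -> np.ndarray:
    """~20 anchor points of the outline, counter-clockwise from infradentale."""
    l, hc, hr = p.corpus_length, p.corpus_height, p.ramus_height
    hk, gamma = p.coronoid_height, np.deg2rad(p.gonial_angle)
    off, sd = p.condyle_offset, p.symphysis_depth

    cond_x = -0.22 * l - off
    cot = np.cos(gamma) / np.sin(gamma)
    # the gonial angle places the gonion: more obtuse angles carry it
    # further under the corpus (capped so the corpus base keeps room)
    gx = min(cond_x - (hr + hc) * cot, 0.45 * l)
    gn_x = 0.95 * l  # gnathion

    def bottom(u):  # inferior corpus border, gonion -> gnathion
        x = gx + u * (gn_x - gx)
        return (x, -(hc + (sd - hc) * u**2))

    # posterior ramus border bulges backwards between condyle and gonion
    mid_post = (cond_x + 0.08 * l, 0.35 * hr)
    notch_y = 0.55 * min(hk, hr)
    return np.array(
        [
            (l, 0.0),  # 0 infradentale
            (0.85 * l, 0.0),  # 1 canine
            (0.68 * l, 0.0),  # 2 premolar middle
            (0.52 * l, 0.0),  # 3 premolar/molar boundary
            (0.40 * l, 0.0),  # 4 M1 centre
            (0.22 * l, 0.0),  # 5 posterior alveolar
            (0.12 * l, 0.30 * hk),  # 6 anterior ramus border, low
            (0.06 * l, 0.70 * hk),  # 7 anterior ramus border, high
            (0.02 * l, hk),  # 8 coronoid tip
            (-0.10 * l, notch_y),  # 9 mandibular notch
            (-0.20 * l, 0.85 * hr),  # 10 condyle neck
            (cond_x, hr),  # 11 condyle, most posterior
            mid_post,  # 12 posterior ramus midpoint
            (gx, -hc),  # 13 gonion
            bottom(0.30),  # 14
            bottom(0.55),  # 15 corpus base midpoint
            bottom(0.80),  # 16
            (gn_x, -sd),  # 17 gnathion
            (1.02 * l, -0.5 * sd),  # 18 symphysis anterior
        ]
    )


# anchor indices of the 12 landmarks, in LANDMARK_NAMES order
_LM_ANCHORS = (0, 17, 1, 3, 4, 5, 8, 9, 11, 12, 13, 15)

# muscle insertion arcs as (start_anchor, end_anchor) along the outline
_MUSCLE_ARCS = {"temporalis": (7, 9), "masseter": (12, 13), "pterygoid": (13, 14)}
DEFAULT_REL_AREAS = {"masseter": 0.50, "temporalis": 0.375, "pterygoid": 0.125}


def outline_from_params(
    params: ShapeParams, points_per_segment: int = 10
) -> tuple:
    """Deterministic smooth closed outline and 12 landmarks from parameters.

    A periodic cubic spline is drawn through the anchor points; the outline
    polygon samples the spline with the anchors themselves among its
    vertices, so every landmark lies exactly on the outline.  Returns
    ``(outline (n, 2), landmarks (12, 2), anchor_fractions (19,))`` where
    ``anchor_fractions`` gives each anchor's arc-length fraction along the
    outline (used to locate muscle insertion arcs).

    Raises :class:`GeometryError` when the resulting polygon
    self-intersects.
    """
    anchors = _anchors(params)
    closed = np.vstack([anchors, anchors[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t_anchor = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(t_anchor, closed, bc_type="periodic")
    ts = []
    for i in range(len(anchors)):
        ts.append(
            np.linspace(t_anchor[i], t_anchor[i + 1], points_per_segment, endpoint=False)
        )
    ts = np.concatenate(ts)
    outline = spline(ts)
    poly = Polygon(outline)
    if (not poly.is_valid) or poly.area <= 0:
        raise GeometryError("outline from these parameters self-intersects")
    landmarks = anchors[list(_LM_ANCHORS)]

    # arc-length fraction of each anchor vertex along the sampled outline
    ring = np.vstack([outline, outline[:1]])
    arclen = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(ring, axis=0), axis=1))]
    )
    anchor_vertex = np.arange(len(anchors)) * points_per_segment
    fractions = arclen[anchor_vertex] / arclen[-1]
    return outline, landmarks, fractions


def _muscle_specs(params: ShapeParams, fractions: np.ndarray, rel_areas=None) -> dict:
    l, hr, hk = params.corpus_length, params.ramus_height, params.coronoid_height
    origins = {
        "temporalis": np.array([-0.09 * l, 1.8 * hk]),
        "masseter": np.array([0.15 * l, 1.3 * hr]),
        "pterygoid": np.array([0.35 * l, 0.9 * hr]),
    }
    rel = dict(DEFAULT_REL_AREAS if rel_areas is None else rel_areas)
    return {
        name: MuscleSpec(
            arc=(float(fractions[a0]), float(fractions[a1])),
            origin=origins[name],
            rel_area=rel[name],
        )
        for name, (a0, a1) in _MUSCLE_ARCS.items()
    }


def make_specimen(
    spec_id: str,
    params: ShapeParams,
    diet: str = "unknown",
    noise_sd: float = 0.0,
    rng=None,
    generating_regime: str = None,
) -> Specimen:
    """Build a full Specimen (outline, landmarks, muscles) from parameters."""
    outline, landmarks, fractions = outline_from_params(params)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        landmarks = landmarks + rng.normal(0.0, noise_sd, size=landmarks.shape)
        thk = params.thickness_base + rng.normal(0.0, noise_sd, size=3)
        thickness = float(np.mean(np.abs(thk)))
    else:
        if rng is not None:  # keep the stream position independent of noise_sd
            pass
        thickness = params.thickness_base
    return Specimen(
        id=spec_id,
        outline=outline,
        landmarks=landmarks,
        thickness=thickness,
        diet=diet,
        muscles=_muscle_specs(params, fractions),
        params=params,
        generating_regime=generating_regime,
    )


def _bm_params(
    tree: Phylogeny,
    labels: list,
    base: ShapeParams,
    sigma_bm: float,
    rng,
) -> dict:
    """Multivariate BM draw of log-shape-parameters for every tip."""
    c, labels = tree.vcv(labels)
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(len(labels)))
    logs = {}
    base_arr = np.log(base.as_array())
    z = rng.standard_normal((len(labels), len(PARAM_NAMES)))
    dev = chol @ z  # correlated across tips, independent across traits
    for j, name in enumerate(PARAM_NAMES):
        logs[name] = base_arr[j] + sigma_bm * REL_SD[name] * dev[:, j]
    return {lab: {n: logs[n][i] for n in PARAM_NAMES} for i, lab in enumerate(labels)}


def _params_from_logs(logd: dict) -> ShapeParams:
    vals = {n: float(np.exp(logd[n])) for n in PARAM_NAMES}
    # keep the gonial angle inside its anatomical range
    vals["gonial_angle"] = float(np.clip(vals["gonial_angle"], 95.0, 150.0))
    return ShapeParams(**vals)


def simulate_specimens(
    tree: Phylogeny,
    diet_effect: float = 3.0,
    sigma_bm: float = 1.0,
    noise_sd: float = 0.1,
    n_fossils: int = 0,
    seed: int = 0,
    base: ShapeParams = None,
    fossil_regime: str = "S",
) -> list:
    """Simulate specimens on a tree (see module docstring for the model).

    Returns a list of Specimen: one per extant tip (diet H or S, balanced
    split) followed by ``n_fossils`` fossils (diet ``unknown``) grafted as
    extra pendant branches.  ``diet_effect`` is the robusticity offset for
    hard eaters in units of the marginal BM tip standard deviation;
    ``fossil_regime`` ('S' or 'H') chooses which regime generates the
    fossils.
    """
    if not sigma_bm > 0:
        raise InvalidArgumentError("sigma_bm must be > 0")
    if diet_effect < 0 or noise_sd < 0:
        raise InvalidArgumentError("diet_effect and noise_sd must be >= 0")
    if fossil_regime not in ("S", "H"):
        raise InvalidArgumentError("fossil_regime must be 'S' or 'H'")
    specimens, _ = simulate_dataset(
        tree,
        diet_effect=diet_effect,
        sigma_bm=sigma_bm,
        noise_sd=noise_sd,
        n_fossils=n_fossils,
        seed=seed,
        base=base,
        fossil_regime=fossil_regime,
    )
    return specimens


def simulate_dataset(
    tree: Phylogeny,
    diet_effect: float = 3.0,
    sigma_bm: float = 1.0,
    noise_sd: float = 0.1,
    n_fossils: int = 12,
    seed: int = 0,
    base: ShapeParams = None,
    fossil_regime: str = "S",
) -> tuple:
    """Like :func:`simulate_specimens` but also returns the grafted tree.

    Returns ``(specimens, full_tree)`` where ``full_tree`` carries both the
    extant and the fossil tips (needed for phylogenetic statistics over the
    complete sample).
    """
    if not sigma_bm > 0:
        raise InvalidArgumentError("sigma_bm must be > 0")
    base = base or ShapeParams()
    rng = np.random.default_rng(seed)
    extant = list(tree.tip_labels)
    full = _graft_fossil_tips(tree, n_fossils, rng) if n_fossils > 0 else tree
    labels = extant + [f"f{k + 1}" for k in range(n_fossils)]
    logs = _bm_params(full, labels, base, sigma_bm, rng)

    # balanced diet split over extant tips
    n_ext = len(extant)
    order = rng.permutation(n_ext)
    hard = set(np.asarray(extant, dtype=object)[order[: n_ext // 2]])
    offset_h = diet_effect * sigma_bm  # x REL_SD per parameter below

    specimens = []
    for lab in extant:
        logd = dict(logs[lab])
        diet = "H" if lab in hard else "S"
        if diet == "H":
            logd["corpus_height"] += offset_h * REL_SD["corpus_height"]
            logd["thickness_base"] += offset_h * REL_SD["thickness_base"]
        specimens.append(
            make_specimen(
                lab,
                _params_from_logs(logd),
                diet=diet,
                noise_sd=noise_sd,
                rng=rng,
                generating_regime=diet,
            )
        )
    for k in range(n_fossils):
        lab = f"f{k + 1}"
        logd = dict(logs[lab])
        if fossil_regime == "H":
            logd["corpus_height"] += offset_h * REL_SD["corpus_height"]
            logd["thickness_base"] += offset_h * REL_SD["thickness_base"]
        specimens.append(
            make_specimen(
                lab,
                _params_from_logs(logd),
                diet="unknown",
                noise_sd=noise_sd,
                rng=rng,
                generating_regime=fossil_regime,
            )
        )
    return specimens, full
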