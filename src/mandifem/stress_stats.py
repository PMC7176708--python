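"""Area-weighted stress percentiles and permutational group tests.

A stress field is summarised per specimen by the 25th, 50th, 75th and
95th percentiles (M25-M95) of the element von Mises stresses.  Because
even a quasi-ideal mesh is not perfectly uniform, elements are weighted
by their areas: the percentile is taken on the area-weighted empirical
distribution, which makes the statistic independent of local mesh
density.  With four bite scenarios this yields 16 variables per
specimen.

Group differences (e.g. hard- vs soft-food eaters) are assessed with
pairwise one-way PERMANOVA on Euclidean distances (Anderson's pseudo-F,
permutation p-values) with a Holm correction across pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "PERCENTILES",
    "StressSummary",
    "weighted_percentile",
    "summarize_specimen",
    "permanova",
    "permanova_pairwise",
    "holm_adjust",
]

PERCENTILES = (25, 50, 75, 95)


def weighted_percentile(values, weights, p) -> float:
    """Weighted lower percentile (step ECDF) of element values.

    Returns the smallest value whose cumulative normalised weight reaches
    ``p``/100 — i.e. the standard lower quantile of the distribution that
    puts mass ``w_i / sum(w)`` on ``x_i``.  With equal weights this
    coincides with the unweighted lower quantile.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise InvalidArgumentError("empty input")
    if values.shape != weights.shape:
        raise InvalidArgumentError("values and weights must have the same length")
    if np.any(weights <= 0):
        raise InvalidArgumentError("weights must be > 0")
    if not 0 < p < 100:
        raise InvalidArgumentError("p must be in (0, 100)")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    idx = int(np.searchsorted(cw, p / 100.0 - 1e-12))
    return float(v[min(idx, v.size - 1)])


@dataclass
class StressSummary:
    """Per-specimen stress percentiles: 4 scenarios x M25/M50/M75/M95."""

    specimen_id: str
    values: dict  # e.g. {"IB_M25": ..., ..., "MB_M95": ...}

    @staticmethod
    def columns(scenarios=("IB", "CB", "PB", "MB")) -> list:
        return [f"{s}_M{p}" for s in scenarios for p in PERCENTILES]

    def as_array(self, scenarios=("IB", "CB", "PB", "MB")) -> np.ndarray:
        return np.array([self.values[c] for c in self.columns(scenarios)])


def summarize_specimen(fields: dict, mesh, specimen_id: str = "") -> StressSummary:
    """Area-weighted M25-M95 for each solved bite scenario.

    ``fields`` maps scenario name -> :class:`~mandifem.fem.StressField`,
    all solved on ``mesh``.  Missing scenarios raise
    :class:`InvalidArgumentError`; within each scenario the percentiles
    are monotone by construction.
    """
    required = ("IB", "CB", "PB", "MB")
    missing = [s for s in required if s not in fields]
    if missing:
        raise InvalidArgumentError(f"missing scenarios: {missing}")
    values = {}
    for s in required:
        vm = fields[s].element_vm
        if vm.shape[0] != mesh.n_elements:
            raise InvalidArgumentError(f"scenario {s}: field does not match mesh")
        for p in PERCENTILES:
            values[f"{s}_M{p}"] = weighted_percentile(vm, mesh.element_areas, p)
    return StressSummary(specimen_id=specimen_id, values=values)


def _pseudo_f(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Anderson's one-way PERMANOVA pseudo-F for stacked group masks.

    ``d2`` is the (N, N) squared-distance matrix; ``masks`` has shape
    (n_perm, n_groups, N) of booleans; ``sizes`` the group sizes.
    """
    n = d2.shape[0]
    a = sizes.size
    ss_t = d2.sum() / (2.0 * n)
    m = masks.astype(float)
    within = np.einsum("pgi,ij,pgj->pg", m, d2, m) / 2.0
    ss_w = (within / sizes[None, :]).sum(axis=1)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def permanova(
    x: np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
    return_null: bool = False,
):
    """One-way PERMANOVA on Euclidean distances.

    Partitions the total sum of squared Euclidean distances into among-
    and within-group components (Anderson's pseudo-F) and assesses it by
    permuting group labels: ``p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)``.

    Returns ``(pseudo_f, p_value)``; with ``return_null=True`` also the
    permuted statistics.
    """
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2 or np.any(counts < 2):
        raise InvalidArgumentError(">=2 groups of size >=2 required")
    sq = np.sum(x**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    np.fill_diagonal(d2, 0.0)

    obs_masks = np.stack([groups == g for g in levels])[None]
    f_obs = float(_pseudo_f(d2, obs_masks, counts)[0])

    rng = np.random.default_rng(seed)
    n = groups.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_labels = groups[perm_idx]  # (n_perm, N)
    masks = np.stack([perm_labels == g for g in levels], axis=1)
    f_perm = _pseudo_f(d2, masks, counts)
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
    if return_null:
        return f_obs, float(p), f_perm
    return f_obs, float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values.

    Sort ascending, multiply the i-th smallest by (m - i), enforce the
    running maximum, cap at 1, and return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidArgumentError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def permanova_pairwise(
    x: np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise PERMANOVA between all group pairs, Holm-corrected.

    Returns a DataFrame with one row per pair: ``group_a``, ``group_b``,
    ``pseudo_f``, ``p_raw``, ``p_holm``.
    """
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise InvalidArgumentError("need at least two groups")
    rows = []
    seed_seq = np.random.SeedSequence(seed).generate_state(
        len(list(itertools.combinations(levels, 2)))
    )
    for k, (ga, gb) in enumerate(itertools.combinations(levels, 2)):
        sel = (groups == ga) | (groups == gb)
        f, p = permanova(
            x[sel], groups[sel], n_perm=n_perm, seed=int(seed_seq[k] % 2**31)
        )
        rows.append({"group_a": ga, "group_b": gb, "pseudo_f": f, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    return table
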