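"""Bite-scenario load cases: constraints, muscle forces, force scaling.

Each specimen is analysed under four biting scenarios that differ only in
the bite point along the tooth row:

* IB — incisive bite, at the alveolar margin of the incisor;
* CB — canine bite, at the centre of the canine;
* PB — premolar bite, between the most distal premolar and M1;
* MB — molar bite, at the centre of M1.

The condyle node (most posterior point of the condyle) is fully fixed,
standing in for the contact with the mandibular fossa; the bite node is
fixed only perpendicular to the occlusal plane (models are oriented with
the occlusal plane along x), which produces the bite reaction force.

The total muscle force is distributed between masseter, temporalis and
pterygoid in proportion to their relative attachment areas, each muscle
pulling from its insertion-arc centroid toward its origin centroid.
Between specimens of different size the total force is rescaled
quasi-homothetically (``F ∝ sqrt(area) x thickness`` relative to a
reference specimen at 1 N) so that stress fields of geometrically similar
jaws are directly comparable regardless of absolute size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .errors import InvalidArgumentError, MappingError
from .synth import BITE_LANDMARKS, CONDYLE_LANDMARK, Specimen

__all__ = [
    "SCENARIOS",
    "ForceScaling",
    "LoadCase",
    "scale_total_force",
    "distribute_muscle_forces",
    "build_load_case",
    "reference_from_specimen",
]

SCENARIOS = ("IB", "CB", "PB", "MB")


@dataclass(frozen=True)
class ForceScaling:
    """Reference model for quasi-homothetic force scaling.

    The reference specimen (the analogue of the 1 N H. sapiens model)
    receives exactly ``reference_force``; every other specimen receives
    ``F = F_ref * sqrt(S / S_ref) * (t / t_ref)`` with S the lateral
    outline area and t the corpus thickness.
    """

    reference_area: float  # mm^2
    reference_thickness: float  # mm
    reference_force: float = 1.0  # N

    def __post_init__(self) -> None:
        if min(self.reference_area, self.reference_thickness, self.reference_force) <= 0:
            raise InvalidArgumentError("reference quantities must be > 0")


@dataclass
class LoadCase:
    """One bite scenario mapped onto a mesh."""

    scenario: str
    condyle_node: int
    bite_node: int
    muscle_forces: list  # [(node index, np.ndarray force vector N), ...]

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InvalidArgumentError(f"scenario must be one of {SCENARIOS}")
        if self.condyle_node == self.bite_node:
            raise InvalidArgumentError("condyle and bite node coincide (mesh too coarse)")

    @property
    def total_force(self) -> np.ndarray:
        return np.sum([v for _, v in self.muscle_forces], axis=0)


def reference_from_specimen(specimen: Specimen, force: float = 1.0) -> ForceScaling:
    """Force-scaling reference built from a specimen's area and thickness."""
    return ForceScaling(
        reference_area=specimen.outline_area,
        reference_thickness=specimen.thickness,
        reference_force=force,
    )


def scale_total_force(spec_area: float, spec_thickness: float, ref: ForceScaling) -> float:
    """Quasi-homothetically scaled total muscle force (N).

    Nominal stress goes as F / (length x thickness); matching stress
    between geometrically similar models of in-plane scale lambda and
    thickness ratio mu therefore requires F ∝ lambda * mu =
    sqrt(S / S_ref) * (t / t_ref).
    """
    if spec_area <= 0 or spec_thickness <= 0:
        raise InvalidArgumentError("specimen area and thickness must be > 0")
    return (
        ref.reference_force
        * float(np.sqrt(spec_area / ref.reference_area))
        * (spec_thickness / ref.reference_thickness)
    )


def _boundary_fractions(specimen: Specimen, mesh) -> tuple:
    """Boundary node indices and their arc-length fractions on the outline."""
    ring = shapely.LinearRing(np.vstack([specimen.outline, specimen.outline[:1]]))
    bidx = mesh.boundary_node_indices()
    pts = mesh.nodes[bidx]
    frac = np.array(
        [ring.project(shapely.Point(p)) for p in pts]
    ) / ring.length
    return bidx, frac


def distribute_muscle_forces(
    specimen: Specimen, mesh, total_force: float
) -> list:
    """Nodal muscle forces for one specimen on one mesh.

    Muscle ``m`` receives magnitude ``total_force * rel_area_m``, split
    equally across the mesh boundary nodes lying on its insertion arc;
    the common direction is the unit vector from the insertion-arc
    centroid toward the muscle's origin centroid.  Raises
    :class:`MappingError` when an insertion arc contains no boundary node.
    """
    if total_force <= 0:
        raise InvalidArgumentError("total_force must be > 0")
    bidx, frac = _boundary_fractions(specimen, mesh)
    out = []
    for name, spec in specimen.muscles.items():
        t0, t1 = spec.arc
        if t0 <= t1:
            mask = (frac >= t0) & (frac <= t1)
        else:  # arc wraps around the outline start
            mask = (frac >= t0) | (frac <= t1)
        nodes = bidx[mask]
        if nodes.size == 0:
            raise MappingError(
                f"insertion arc of {name} ({t0:.3f}-{t1:.3f}) maps to no boundary node"
            )
        centroid = mesh.nodes[nodes].mean(axis=0)
        direction = np.asarray(spec.origin, dtype=float) - centroid
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise MappingError(f"muscle {name}: origin coincides with insertion centroid")
        direction /= norm
        magnitude = total_force * spec.rel_area
        per_node = direction * (magnitude / nodes.size)
        out.extend((int(n), per_node.copy()) for n in nodes)
    return out


def build_load_case(
    specimen: Specimen, mesh, scenario: str, ref: ForceScaling
) -> LoadCase:
    """Assemble the full load case for one bite scenario.

    Constraint nodes are the mesh nodes nearest the condyle landmark and
    the scenario's bite-point landmark; a bite landmark farther than one
    element size from any boundary node raises :class:`MappingError`.
    """
    if scenario not in SCENARIOS:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    elem_size = float(np.sqrt(np.mean(mesh.element_areas)))
    bidx = mesh.boundary_node_indices()
    bpts = mesh.nodes[bidx]

    def nearest_boundary(point, what):
        d = np.linalg.norm(bpts - point, axis=1)
        k = int(np.argmin(d))
        if d[k] > elem_size:
            raise MappingError(
                f"{what} landmark is {d[k]:.2f} mm from the nearest boundary "
                f"node (> element size {elem_size:.2f} mm)"
            )
        return int(bidx[k])

    condyle = nearest_boundary(specimen.landmarks[CONDYLE_LANDMARK], "condyle")
    bite = nearest_boundary(specimen.landmarks[BITE_LANDMARKS[scenario]], f"{scenario} bite")
    total = scale_total_force(specimen.outline_area, specimen.thickness, ref)
    muscle_forces = distribute_muscle_forces(specimen, mesh, total)
    return LoadCase(
        scenario=scenario,
        condyle_node=condyle,
        bite_node=bite,
        muscle_forces=muscle_forces,
    )
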