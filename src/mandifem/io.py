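"""File formats: TPS landmarks, CSV tables, Newick trees, legacy VTK.

The TPS dialect is the common landmark-file format: ``LM=<k>`` followed
by one ``x y`` line per landmark, then ``ID=<name>`` and an optional
``SCALE=<s>`` applied multiplicatively to the coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError
from .loads import LoadCase
from .synth import MuscleSpec, Phylogeny, Specimen

__all__ = [
    "read_tps",
    "write_tps",
    "read_tree",
    "write_tree",
    "write_dataset",
    "read_dataset",
    "write_vtk",
    "load_case_to_json",
    "load_case_from_json",
]

MUSCLE_NAMES = ("masseter", "temporalis", "pterygoid")


def read_tps(path, expected_landmarks: int = 12) -> dict:
    """Read a TPS file into ``{specimen_id: (k, 2) array}`` (scale applied)."""
    text = Path(path).read_text()
    out: dict = {}
    lm_count = None
    points: list = []
    spec_id = None
    scale = None

    def flush(line_no):
        nonlocal lm_count, points, spec_id, scale
        if lm_count is None:
            return
        if spec_id is None:
            raise FormatError(f"{path}: block ending near line {line_no} has no ID=")
        if len(points) != lm_count:
            raise FormatError(
                f"{path}: specimen {spec_id!r} declares LM={lm_count} but has "
                f"{len(points)} points"
            )
        if expected_landmarks is not None and lm_count != expected_landmarks:
            raise FormatError(
                f"{path}: specimen {spec_id!r} has LM={lm_count}, "
                f"expected {expected_landmarks}"
            )
        if spec_id in out:
            raise FormatError(f"{path}: duplicate ID {spec_id!r}")
        arr = np.asarray(points, dtype=float)
        if scale is not None:
            arr = arr * scale
        out[spec_id] = arr
        lm_count, points, spec_id, scale = None, [], None, None

    for line_no, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush(line_no)
            lm_count = int(line[3:])
        elif upper.startswith("ID="):
            spec_id = line[3:].strip()
        elif upper.startswith("SCALE="):
            scale = float(line[6:])
        elif upper.startswith(("IMAGE=", "CURVES=", "POINTS=")):
            continue
        else:
            try:
                x, y = line.split()[:2]
                points.append((float(x), float(y)))
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: cannot parse {line!r}") from exc
    flush(line_no="EOF")
    if not out:
        raise FormatError(f"{path}: no specimens found")
    return out


def write_tps(path, landmarks: dict) -> None:
    """Write ``{specimen_id: (k, 2) array}`` as a TPS file."""
    lines = []
    for spec_id, arr in landmarks.items():
        arr = np.asarray(arr, dtype=float)
        lines.append(f"LM={arr.shape[0]}")
        for x, y in arr:
            lines.append(f"{float(x)!r} {float(y)!r}")
        lines.append(f"ID={spec_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path).read_text())


def write_tree(path, tree: Phylogeny) -> None:
    Path(path).write_text(tree.newick() + "\n")


def write_dataset(specimens, tree: Phylogeny, outdir) -> None:
    """Write a dataset as plain-text files.

    ``landmarks.tps`` (12 landmarks), ``specimens.csv`` (thickness, diet,
    muscle arcs / origins / relative areas), ``outlines.csv`` (long-format
    vertex list) and ``tree.nwk``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tps(outdir / "landmarks.tps", {s.id: s.landmarks for s in specimens})
    rows = []
    for s in specimens:
        row = {"id": s.id, "thickness": s.thickness, "diet": s.diet}
        for m in MUSCLE_NAMES:
            spec = s.muscles[m]
            row[f"{m}_arc_start"] = spec.arc[0]
            row[f"{m}_arc_end"] = spec.arc[1]
            row[f"{m}_origin_x"] = spec.origin[0]
            row[f"{m}_origin_y"] = spec.origin[1]
            row[f"{m}_rel_area"] = spec.rel_area
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "specimens.csv", index=False)
    out_rows = []
    for s in specimens:
        for k, (x, y) in enumerate(s.outline):
            out_rows.append({"id": s.id, "vertex": k, "x": x, "y": y})
    pd.DataFrame(out_rows).to_csv(outdir / "outlines.csv", index=False)
    if tree is not None:
        write_tree(outdir / "tree.nwk", tree)


def read_dataset(indir) -> tuple:
    """Read a dataset written by :func:`write_dataset`.

    Returns ``(specimens, tree)``; ``tree`` is None when no ``tree.nwk``
    is present (phylogenetic stages are then skipped downstream).
    """
    indir = Path(indir)
    landmarks = read_tps(indir / "landmarks.tps")
    meta = pd.read_csv(indir / "specimens.csv").set_index("id")
    outlines = pd.read_csv(indir / "outlines.csv")
    specimens = []
    for spec_id, lm in landmarks.items():
        if spec_id not in meta.index:
            raise FormatError(f"specimen {spec_id!r} missing from specimens.csv")
        row = meta.loc[spec_id]
        o = outlines[outlines["id"] == spec_id].sort_values("vertex")
        if o.empty:
            raise FormatError(f"specimen {spec_id!r} missing from outlines.csv")
        muscles = {
            m: MuscleSpec(
                arc=(float(row[f"{m}_arc_start"]), float(row[f"{m}_arc_end"])),
                origin=np.array(
                    [float(row[f"{m}_origin_x"]), float(row[f"{m}_origin_y"])]
                ),
                rel_area=float(row[f"{m}_rel_area"]),
            )
            for m in MUSCLE_NAMES
        }
        specimens.append(
            Specimen(
                id=spec_id,
                outline=o[["x", "y"]].to_numpy(),
                landmarks=lm,
                thickness=float(row["thickness"]),
                diet=str(row["diet"]),
                muscles=muscles,
            )
        )
    tree_path = indir / "tree.nwk"
    tree = read_tree(tree_path) if tree_path.exists() else None
    return specimens, tree


def write_vtk(path, mesh, cell_data: dict = None, point_data: dict = None) -> None:
    """Write a QUAD8 mesh as a legacy ASCII VTK unstructured grid.

    Cell type 23 (quadratic quad); ``cell_data`` maps names to per-element
    scalars (e.g. ``von_mises``), ``point_data`` to per-node 2-vectors
    (e.g. ``displacement``).
    """
    nn, ne = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 2.0",
        "mandifem QUAD8 mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {nn} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{float(x)!r} {float(y)!r} 0.0")
    lines.append(f"CELLS {ne} {ne * 9}")
    for el in mesh.elements:
        lines.append("8 " + " ".join(str(int(i)) for i in el))
    lines.append(f"CELL_TYPES {ne}")
    lines.extend(["23"] * ne)
    if cell_data:
        lines.append(f"CELL_DATA {ne}")
        for name, values in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{float(v)!r}" for v in values)
    if point_data:
        lines.append(f"POINT_DATA {nn}")
        for name, values in point_data.items():
            lines.append(f"VECTORS {name} double")
            for vx, vy in values:
                lines.append(f"{float(vx)!r} {float(vy)!r} 0.0")
    Path(path).write_text("\n".join(lines) + "\n")


def load_case_to_json(load_case: LoadCase) -> str:
    """Serialise a load case (scenario, nodes, vectors) for audit."""
    return json.dumps(
        {
            "scenario": load_case.scenario,
            "condyle_node": int(load_case.condyle_node),
            "bite_node": int(load_case.bite_node),
            "muscle_forces": [
                {"node": int(n), "force": [float(v[0]), float(v[1])]}
                for n, v in load_case.muscle_forces
            ],
        },
        indent=2,
    )


def load_case_from_json(text: str) -> LoadCase:
    d = json.loads(text)
    try:
        return LoadCase(
            scenario=d["scenario"],
            condyle_node=d["condyle_node"],
            bite_node=d["bite_node"],
            muscle_forces=[
                (m["node"], np.asarray(m["force"], dtype=float))
                for m in d["muscle_forces"]
            ],
        )
    except KeyError as exc:
        raise FormatError(f"load-case JSON missing key {exc}") from exc
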