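"""Mesh one mandible and solve the four bite scenarios.

Builds the default synthetic mandible, meshes it with quasi-uniform
QUAD8 elements, applies the condyle/bite constraints and the muscle
forces (masseter 50%, temporalis 37.5%, pterygoid 12.5% of a 1 N total,
this being the force-scaling reference specimen), solves the
plane-stress problem and prints the area-weighted stress percentiles.
Writes the incisive-bite solution as a legacy VTK file for ParaView.
"""

from mandifem import (
    BONE,
    ShapeParams,
    build_load_case,
    generate_mesh,
    mesh_uniformity,
    reference_from_specimen,
    solve_case,
    summarize_specimen,
)
from mandifem.io import write_vtk
from mandifem.synth import make_specimen

specimen = make_specimen("demo", ShapeParams())
mesh = generate_mesh(specimen.outline, target_elem_size=1.0, seed=0)
u = mesh_uniformity(mesh)
print(f"mesh: {u['n_elements']} QUAD8 elements, area CV {u['cv_area']:.3f} "
      "(quasi-ideal: uniform element sizes keep stress statistics unbiased)")

ref = reference_from_specimen(specimen)  # this specimen gets F = 1 N
fields = {}
for scenario in ("IB", "CB", "PB", "MB"):
    lc = build_load_case(specimen, mesh, scenario, ref)
    fields[scenario] = solve_case(mesh, BONE, specimen.thickness, lc)

summary = summarize_specimen(fields, mesh, "demo")
print("\narea-weighted von Mises percentiles (MPa):")
print("scenario   M25      M50      M75      M95")
for s in ("IB", "CB", "PB", "MB"):
    vals = [summary.values[f"{s}_M{p}"] for p in (25, 50, 75, 95)]
    print(f"  {s}    " + "  ".join(f"{v:.5f}" for v in vals))
print("-> anterior bites (IB) load the long corpus lever arm hardest; lower")
print("   percentiles mean a stiffer jaw for the same scaled muscle force.")

write_vtk(
    "demo_ib.vtk",
    mesh,
    cell_data={"von_mises": fields["IB"].element_vm},
    point_data={"displacement": fields["IB"].nodal_displacements},
)
print("wrote demo_ib.vtk")
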