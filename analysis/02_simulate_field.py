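"""Minimize the confined polar-fluid free energy and map its phases.

On the fitted tissue shape (rescaled to units of R0), solves the
heterogeneous-anchoring problem (tangential at the ExE cap,
perpendicular at the VE cap) in the surface-dominated regime, locates
the topological defects, and scans the (xi/R0, lambda/R0) plane for
the global order P and the defect content.  Writes
results/field_reference.npz, results/defects.csv and
results/phase_diagram.csv.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
from epialign import geometry as G  # noqa: E402
from epialign import polar_field as PF  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

geom_um = (G.CapGeometry.load(OUT / "geometry.json")
           if (OUT / "geometry.json").exists()
           else G.CapGeometry(1.0, 0.2, 1.1, 0.5).scaled(23.0))
gn = geom_um.scaled(1.0 / geom_um.R0)
print(f"geometry: R0 = {geom_um.R0:.2f} um; simulating in units of R0")

params = PF.MaterialParams(xi_rel=0.2, lambda_rel=5.0, K=1e-2)
sol = PF.minimize(gn, params, PF.AnchoringSpec(), resolution=0.05)
parts = PF.free_energy(sol)
ds = PF.detect_defects(sol)
sol.save(OUT / "field_reference.npz")

print(f"reference solve (xi/R0={params.xi_rel}, lambda/R0={params.lambda_rel}, "
      f"K={params.K}): converged={sol.converged}, "
      f"residual={sol.residual:.1e}")
print(f"  F/F0 = {parts.total:.4f} (bulk {parts.bulk:.3f}, distortion "
      f"{parts.distortion:.3f}, surface {parts.surface:.3f})")
print(f"  global order P = {sol.P:.4f}")
print(f"  defects: {[(round(x, 3), round(z, 3), w) for x, z, w in ds.defects]}"
      f" -> total charge {ds.total_charge:+d}")

rows = [{"x": x, "z": z, "winding": w} for x, z, w in ds.defects]
pd.DataFrame(rows, columns=["x", "z", "winding"]).to_csv(
    OUT / "defects.csv", index=False)

# uniform-anchoring counterpart and defect displacement
uni = PF.minimize(gn, params, PF.UNIFORM_NORMAL, resolution=0.05)
pos_het = PF.defect_position(sol, gn)
pos_uni = PF.defect_position(uni, gn)
print(f"  defect axial position (z - L/2)/L: heterogeneous {pos_het:+.3f}, "
      f"uniform perpendicular {pos_uni:+.3f} "
      "(positive = toward the ExE cap)")

print("scanning the (xi/R0, lambda/R0) plane ...")
df = PF.phase_diagram(gn, np.geomspace(0.1, 1.0, 6),
                      np.geomspace(0.1, 20.0, 7))
df.to_csv(OUT / "phase_diagram.csv", index=False)
containing = df[df.total_charge > 0]
print(f"  {len(containing)}/{len(df)} grid points are defect-containing "
      "(total charge +1 state)")
print(f"  P ranges from {df.P.min():.3f} (weak anchoring) to "
      f"{df.P.max():.3f} (surface-dominated)")
print(f"wrote {OUT / 'field_reference.npz'}, {OUT / 'defects.csv'}, "
      f"{OUT / 'phase_diagram.csv'}")
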