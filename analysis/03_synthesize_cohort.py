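"""Generate the synthetic embryo cohort used by the measurement stages.

Renders a cohort of label volumes whose cell orientations follow the
reference polar-order field (late-stage-like conditions: 60 cells,
orientation concentration kappa = 20, voxel 0.8 um), plus the axis
annotations a human would click.  Volumes go to scratch/ (regenerable
binary data); the manifest and per-embryo ground truth go to results/.
"""

import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from epialign import synthetic as S  # noqa: E402
from cohort_utils import (ANNOTATION_JITTER, FIELD_PARAMS, N_EMBRYOS,  # noqa: E402
                          SEED, SHAPE_JITTER, make_cohort)

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort"
OUT.mkdir(exist_ok=True)
SCRATCH.mkdir(parents=True, exist_ok=True)

geom_um = S.default_geometry()
template = S.SyntheticSpec(geometry=geom_um, seed=SEED)
cohort = make_cohort()

manifest = {"seed": SEED, "n_embryos": N_EMBRYOS,
            "shape_jitter": SHAPE_JITTER,
            "annotation_jitter_um": ANNOTATION_JITTER,
            "n_cells": template.n_cells,
            "angular_noise_kappa": template.angular_noise_kappa,
            "eta_range": list(template.eta_range),
            "voxel_size_um": template.voxel_size,
            "field_params": {"xi_rel": FIELD_PARAMS[0],
                             "lambda_rel": FIELD_PARAMS[1], "K": 1e-2},
            "geometry_um": geom_um.to_dict(), "embryos": []}

for k, (vol, ann, truth) in enumerate(cohort):
    vol.to_tiff(SCRATCH / f"embryo_{k}.tif")
    ann.save(SCRATCH / f"embryo_{k}_annotations.json")
    truth.save(OUT / f"cohort_truth_{k}.json")
    manifest["embryos"].append({
        "tiff": str(SCRATCH / f"embryo_{k}.tif"),
        "annotations": str(SCRATCH / f"embryo_{k}_annotations.json"),
        "n_labels": int(len(vol.labels())),
        "shape": list(vol.voxels.shape)})
    print(f"embryo {k}: {len(vol.labels())} cells rendered into "
          f"{vol.voxels.shape} voxels at {vol.voxel_size} um, "
          f"mean ground-truth eta {truth.eta.mean():.3f}")

with open(OUT / "cohort_manifest.json", "w") as fh:
    json.dump(manifest, fh, indent=1)
print(f"wrote {N_EMBRYOS} embryos under {SCRATCH} and the manifest to "
      f"{OUT / 'cohort_manifest.json'}")
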