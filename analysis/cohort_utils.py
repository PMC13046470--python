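"""Shared cohort access for the numbered analysis steps.

Loads the rendered cohort from scratch/ when present, otherwise
regenerates it deterministically from the manifest conditions.
"""

import json
import pathlib
import sys

ROOT = pathlib.Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

SEED = 11
N_EMBRYOS = 4
SHAPE_JITTER = 0.04        # relative log-normal cap-parameter jitter
ANNOTATION_JITTER = 0.5    # um
FIELD_PARAMS = (0.2, 5.0)  # (xi/R0, lambda/R0) of the generating field


def make_cohort():
    from epialign import polar_field as PF
    from epialign import synthetic as S

    geom_um = S.default_geometry()
    field = PF.minimize(geom_um.scaled(1.0 / geom_um.R0),
                        PF.MaterialParams(*FIELD_PARAMS))
    template = S.SyntheticSpec(geometry=geom_um, seed=SEED)
    return S.field_driven_cohort(field, N_EMBRYOS, template,
                                 shape_jitter=SHAPE_JITTER,
                                 annotation_jitter=ANNOTATION_JITTER)


def load_cohort():
    from epialign import orientation as O

    out = ROOT / "results"
    scratch = ROOT / "scratch" / "cohort"
    mf = out / "cohort_manifest.json"
    if mf.exists():
        meta = json.load(open(mf))
        if all((scratch / f"embryo_{k}.tif").exists()
               for k in range(meta["n_embryos"])):
            loaded = []
            for k in range(meta["n_embryos"]):
                vol = O.LabelVolume.from_tiff(scratch / f"embryo_{k}.tif",
                                              meta["voxel_size_um"])
                ann = O.AxisAnnotation.load(
                    scratch / f"embryo_{k}_annotations.json")
                loaded.append((vol, ann, None))
            return loaded
    return make_cohort()
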