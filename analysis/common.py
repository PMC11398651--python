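"""Shared study conditions for the numbered analysis drivers.

Desk-scale version of the study: 4-slice 64x64 volumes, 2/7/7 sequences per
phase, observer Dice target 0.79, 7:32 grade fractions. The drivers default
to 12 patients so each script finishes in well under a minute; pass a larger
cohort (e.g. 39) for the full-size run.
"""

from pathlib import Path

from dcect_radiomics.phantom import PhantomSpec

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

N_PATIENTS = 12
GRADE_FRACTIONS = (7 / 39, 32 / 39)
SEED = 17


def study_spec(**kw):
    base = dict(grid_shape=(4, 64, 64), lesion_radii=(10.0, 9.0, 9.0),
                n_nce=2, n_lap=7, n_pvp=7,
                baseline_jitter_sd=6.0, amplitude_jitter_sd=0.2,
                radii_jitter_frac=0.15)
    base.update(kw)
    return PhantomSpec(**base)
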