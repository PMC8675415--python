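"""Published reference estimates for sex differences in subcortical volumes.

These are the per-region Cohen's d values (positive = male mean larger) and
log-transformed male/female variance ratios reported by a large multi-cohort
lifespan mega-analysis of healthy subjects for the 14 subcortical volumes
(7 structures x 2 hemispheres).  They serve two purposes here: as realistic
default effect-size targets for the synthetic cohort generator, and as the
printed reference table whose summaries (e.g. the mean subcortical d of 0.7)
the acceptance script recomputes.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["subcortical_reference", "mean_subcortical_d"]

_SUBCORTICAL = [
    # measure_id, cohens_d, log_vr
    ("lh_thalamus_vol", 0.840, 0.237),
    ("rh_thalamus_vol", 0.918, 0.357),
    ("lh_caudate_vol", 0.609, 0.150),
    ("rh_caudate_vol", 0.625, 0.147),
    ("lh_putamen_vol", 0.757, 0.197),
    ("rh_putamen_vol", 0.786, 0.220),
    ("lh_pallidum_vol", 0.768, 0.317),
    ("rh_pallidum_vol", 0.793, 0.339),
    ("lh_hippocampus_vol", 0.673, 0.173),
    ("rh_hippocampus_vol", 0.669, 0.232),
    ("lh_amygdala_vol", 0.765, 0.154),
    ("rh_amygdala_vol", 0.790, 0.216),
    ("lh_accumbens_vol", 0.414, 0.168),
    ("rh_accumbens_vol", 0.454, 0.119),
]


def subcortical_reference() -> pd.DataFrame:
    """Reference Cohen's d and log variance ratio for the 14 subcortical volumes."""
    return pd.DataFrame(_SUBCORTICAL, columns=["measure_id", "cohens_d", "log_vr"])


def mean_subcortical_d() -> float:
    """Mean of the 14 reference subcortical Cohen's d values."""
    return float(subcortical_reference()["cohens_d"].mean())
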