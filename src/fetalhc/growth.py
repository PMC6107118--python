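"""Synthetic fetal growth-curve table.

Published reference charts (HC and BPD percentiles against gestational age)
are licensed tables that users supply as CSV.  For self-contained testing
and simulation this module generates a *synthetic* chart with the same
qualitative shape as clinical references: median HC rises smoothly from
about 39 mm at 9 weeks to about 345 mm at term, with decelerating growth;
BPD tracks a fixed fraction of HC; the P3/P97 envelopes sit at +-7%.
It is a stand-in with realistic magnitudes, not a clinical chart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import GrowthCurveTable

__all__ = ["synthetic_growth_curve", "median_hc_at"]

# quadratic median HC model in gestational weeks, anchored at
# (9 w, 39 mm), (20 w, 175 mm), (40 w, 345 mm)
_C0, _C1, _C2 = -94.66879, 15.97507, -0.124633
_BPD_FRACTION = 0.285
_ENVELOPE = 0.07


def median_hc_at(ga_days: float | np.ndarray) -> np.ndarray:
    """Median (P50) head circumference in mm at a gestational age in days."""
    w = np.asarray(ga_days, dtype=float) / 7.0
    return _C0 + _C1 * w + _C2 * w * w


def synthetic_growth_curve(ga_start: int = 63, ga_stop: int = 294, step: int = 7) -> GrowthCurveTable:
    """Build the synthetic chart on a weekly grid of gestational ages (days)."""
    ga = np.arange(ga_start, ga_stop + 1, step, dtype=float)
    hc50 = median_hc_at(ga)
    bpd50 = _BPD_FRACTION * hc50
    table = pd.DataFrame(
        {
            "ga_days": ga,
            "hc_p3": (1 - _ENVELOPE) * hc50,
            "hc_p50": hc50,
            "hc_p97": (1 + _ENVELOPE) * hc50,
            "bpd_p3": (1 - _ENVELOPE) * bpd50,
            "bpd_p50": bpd50,
            "bpd_p97": (1 + _ENVELOPE) * bpd50,
        }
    )
    return GrowthCurveTable(table)
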