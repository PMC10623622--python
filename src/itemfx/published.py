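"""Published SWLS latent-moment estimates used as worked-example inputs.

These are reported estimates from a large Dutch probability panel (LISS;
N = 2,543 complete cases) in which the five-item Satisfaction with Life
Scale was modeled with a multi-state item-effects model over two
three-wave periods (2008-2010 and 2011-2013).  They serve as realistic
input magnitudes for the synthetic-data generator and as inputs to the
reference-switch worked examples; they are *data*, not quantities this
package estimates from raw panel files.

Layout of each table: latent order eta1, eta2, eta3 followed by the
item-effect variables in ascending item order (the reference item has
none).  Correlations are the upper/lower symmetric matrix implied by the
printed triangle.
"""

from __future__ import annotations

import numpy as np

from .latent_moments import LatentMomentTable, table_from_published

__all__ = [
    "N_COMPLETE",
    "SWLS_REF3_2008_2010",
    "SWLS_REF3_2011_2013",
    "SWLS_REF5_2008_2010",
    "SWLS_REF5_2011_2013",
    "MODEL_FIT_STATS",
    "reference3_table",
    "reference5_table",
]

N_COMPLETE = 2543


def _sym(rows):
    a = np.array(rows, dtype=float)
    return np.where(np.isnan(a), a.T, a)


# ---- reference item 3: latents (eta1, eta2, eta3, d1, d2, d4, d5) -----

SWLS_REF3_2008_2010 = {
    "reference_item": 3,
    "means": [5.565, 5.548, 5.516, -0.461, -0.330, -0.277, -0.990],
    "sds": [0.977, 0.977, 0.997, 0.389, 0.400, 0.562, 0.889],
    "corr": _sym([
        [1.000, 0.754, 0.698, 0.021, 0.066, -0.135, 0.002],
        [np.nan, 1.000, 0.785, 0.030, 0.035, -0.199, -0.018],
        [np.nan, np.nan, 1.000, 0.069, 0.085, -0.200, -0.014],
        [np.nan, np.nan, np.nan, 1.000, 0.626, 0.317, 0.316],
        [np.nan, np.nan, np.nan, np.nan, 1.000, 0.227, 0.111],
        [np.nan, np.nan, np.nan, np.nan, np.nan, 1.000, 0.457],
        [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.000],
    ]),
}

SWLS_REF3_2011_2013 = {
    "reference_item": 3,
    "means": [5.505, 5.500, 5.484, -0.460, -0.320, -0.214, -0.898],
    "sds": [0.997, 0.998, 1.032, 0.436, 0.406, 0.532, 0.902],
    "corr": _sym([
        [1.000, 0.763, 0.737, 0.062, 0.082, -0.161, 0.005],
        [np.nan, 1.000, 0.786, 0.078, 0.103, -0.156, 0.015],
        [np.nan, np.nan, 1.000, 0.041, 0.103, -0.191, 0.008],
        [np.nan, np.nan, np.nan, 1.000, 0.691, 0.254, 0.331],
        [np.nan, np.nan, np.nan, np.nan, 1.000, 0.131, 0.143],
        [np.nan, np.nan, np.nan, np.nan, np.nan, 1.000, 0.431],
        [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.000],
    ]),
}

# ---- reference item 5: latents (eta1, eta2, eta3, d1, d2, d3, d4) -----

SWLS_REF5_2008_2010 = {
    "reference_item": 5,
    "means": [4.576, 4.558, 4.527, 0.529, 0.660, 0.990, 0.712],
    "sds": [1.322, 1.309, 1.327, 0.850, 0.934, 0.889, 0.806],
    "corr": _sym([
        [1.000, 0.865, 0.832, -0.601, -0.589, -0.674, -0.599],
        [np.nan, 1.000, 0.880, -0.588, -0.590, -0.666, -0.622],
        [np.nan, np.nan, 1.000, -0.569, -0.569, -0.660, -0.619],
        [np.nan, np.nan, np.nan, 1.000, 0.931, 0.901, 0.762],
        [np.nan, np.nan, np.nan, np.nan, 1.000, 0.905, 0.762],
        [np.nan, np.nan, np.nan, np.nan, np.nan, 1.000, 0.784],
        [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.000],
    ]),
}

SWLS_REF5_2011_2013 = {
    "reference_item": 5,
    "means": [4.607, 4.602, 4.586, 0.438, 0.577, 0.898, 0.683],
    "sds": [1.348, 1.355, 1.376, 0.862, 0.935, 0.902, 0.826],
    "corr": _sym([
        [1.000, 0.871, 0.854, -0.569, -0.581, -0.673, -0.625],
        [np.nan, 1.000, 0.882, -0.568, -0.578, -0.677, -0.628],
        [np.nan, np.nan, 1.000, -0.567, -0.564, -0.661, -0.633],
        [np.nan, np.nan, np.nan, 1.000, 0.935, 0.879, 0.752],
        [np.nan, np.nan, np.nan, np.nan, 1.000, 0.903, 0.754],
        [np.nan, np.nan, np.nan, np.nan, np.nan, 1.000, 0.814],
        [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.000],
    ]),
}

# Published model-test statistics per period (complete cases, N = 2,543):
# chi-square and degrees of freedom of the multi-state model without
# ("states_only") and with ("item_effects") item-effect variables.
MODEL_FIT_STATS = {
    "2008-2010": {"states_only": (3315.0, 103), "item_effects": (479.0, 85)},
    "2011-2013": {"states_only": (3374.0, 103), "item_effects": (584.0, 85)},
}


def _make_table(d: dict) -> LatentMomentTable:
    return table_from_published(
        means=d["means"], sds=d["sds"], corr=d["corr"],
        reference_item=d["reference_item"], n_occasions=3,
    )


def reference3_table(period: str = "2008-2010") -> LatentMomentTable:
    """Published latent moments under reference item 3 for one period."""
    src = {"2008-2010": SWLS_REF3_2008_2010,
           "2011-2013": SWLS_REF3_2011_2013}[period]
    return _make_table(src)


def reference5_table(period: str = "2008-2010") -> LatentMomentTable:
    """Published latent moments under reference item 5 for one period."""
    src = {"2008-2010": SWLS_REF5_2008_2010,
           "2011-2013": SWLS_REF5_2011_2013}[period]
    return _make_table(src)
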