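"""Published NESI 2008-2009 summary estimates used as worked-example inputs.

These are the headline subgroup EFR initiation rates and fitted piecewise
incarceration rates from Scotland's Needle Exchange Surveillance Initiative
(2008-2009, ~2,500 injector respondents).  The synthetic-cohort generator
is calibrated against them, and the worked examples evaluate the
replacement-rate model directly on them.
"""

from __future__ import annotations

from .incarceration_model import IncarcerationRates
from .replacement_model import EFRLookupTable

__all__ = [
    "NESI_EFR_POOLED",
    "NESI_INCARCERATION_OVERALL",
    "NESI_INCARCERATION_BY_SEX",
    "NESI_CESSATION_SCENARIOS",
]

# pooled per-annum EFR initiation rates by career bin (0-5 / 6-10 / >=11)
# and incarceration history
NESI_EFR_POOLED = EFRLookupTable(
    strata={
        "pooled": {
            "never": (0.46, 0.22, 0.11),
            "ever": (0.26, 0.22, 0.21),
        }
    }
)

# fitted per-annum first-incarceration probabilities (p1, p2, p3)
NESI_INCARCERATION_OVERALL = IncarcerationRates(0.14, 0.05, 0.04)
NESI_INCARCERATION_BY_SEX = {
    "F": IncarcerationRates(0.07, 0.06, 0.04),
    "M": IncarcerationRates(0.19, 0.05, 0.03),
}

# commonly assumed per-annum cessation rates, with the immediate quit rate
# initially set equal to the cessation rate
NESI_CESSATION_SCENARIOS = (0.05, 0.10, 0.15)
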