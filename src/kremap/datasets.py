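"""Published aggregate tables shipped as package data.

Stage-at-diagnosis distributions for the Indiana State Cancer Registry
cohort of adults diagnosed with female breast, colorectal, or lung cancer,
2010-2019, as printed in the cohort characteristics table of the published
statewide hotspot analysis.  Only aggregated printed counts are included —
no record-level registry data.
"""

from __future__ import annotations

__all__ = ["INDIANA_STAGE_DISTRIBUTION", "INDIANA_SITE_TOTALS"]

#: Printed stage-at-diagnosis counts per cancer site (AJCC stage at
#: diagnosis, resolved pathology-first).  Each site's counts sum to the
#: printed site N.
INDIANA_STAGE_DISTRIBUTION: dict[str, dict[str, int]] = {
    "breast": {"0": 9478, "I": 25130, "II": 13124, "III": 4348, "IV": 2823},
    "colorectal": {"0": 1877, "I": 6394, "II": 6737, "III": 7461, "IV": 6125},
    "lung": {"0": 87, "I": 10807, "II": 4351, "III": 10973, "IV": 24058},
}

#: Printed analytic-cohort size per site.
INDIANA_SITE_TOTALS: dict[str, int] = {"breast": 54903, "colorectal": 28594, "lung": 50276}
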