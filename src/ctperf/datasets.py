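"""Reference canine cohort measurements bundled with the package.

Fourteen anesthetized dogs imaged prone with four breath-hold CT scans each
(end-expiration, midinspiration and end-inspiration before contrast, plus a
postcontrast end-inspiratory scan): seven subjects with normal lungs (C1–C7)
and seven with diseased lungs (D1–D7).  The tables carry body weight, the
segmented total lung volume of each scan, and the per-subject coefficient of
variation (CoV) of the resulting perfusion maps.  They serve as inputs for
the cohort-level arithmetic (volume differences, group means, group t-test)
and as realistic defaults for the phantom generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["canine_lung_volumes", "canine_perfusion_cov", "GROUPS"]

GROUPS = ("normal", "diseased")

_VOLUME_ROWS = [
    # subject, group, weight_kg, end_exp_pre, mid_ins_pre, end_ins_pre, end_ins_post
    ("C1", "normal", 42.5, 2217, 3193, 3532, 3888),
    ("C2", "normal", 13.1, 302, 468, 514, 481),
    ("C3", "normal", 25.5, 963, 1610, 1732, 1671),
    ("C4", "normal", 22.0, 1592, 1847, 2059, 2029),
    ("C5", "normal", 34.4, 2090, 2524, 3075, 3085),
    ("C6", "normal", 36.4, 1534, 2330, 2422, 2316),
    ("C7", "normal", 24.4, 792, 1084, 1137, 1032),
    ("D1", "diseased", 40.4, 920, 1296, 1764, 2046),
    ("D2", "diseased", 13.7, 906, 1212, 1202, 1295),
    ("D3", "diseased", 33.6, 1533, 2035, 2294, 2247),
    ("D4", "diseased", 13.5, 616, 726, 824, 801),
    ("D5", "diseased", 23.0, 1468, 1677, 1959, 1847),
    ("D6", "diseased", 26.6, 1489, 1922, 2060, 2184),
    ("D7", "diseased", 21.2, 968, 1076, 1171, 1169),
]

_COV_ROWS = [
    ("C1", "normal", 1.48), ("C2", "normal", 1.14), ("C3", "normal", 1.35),
    ("C4", "normal", 2.44), ("C5", "normal", 1.73), ("C6", "normal", 1.66),
    ("C7", "normal", 1.34),
    ("D1", "diseased", 1.22), ("D2", "diseased", 2.36), ("D3", "diseased", 2.02),
    ("D4", "diseased", 2.10), ("D5", "diseased", 2.06), ("D6", "diseased", 1.97),
    ("D7", "diseased", 2.67),
]


def canine_lung_volumes() -> pd.DataFrame:
    """Per-subject lung volumes (cm³) of the four breath-hold scans."""
    return pd.DataFrame(
        _VOLUME_ROWS,
        columns=["subject", "group", "weight_kg",
                 "end_exp_pre_cm3", "mid_ins_pre_cm3",
                 "end_ins_pre_cm3", "end_ins_post_cm3"],
    )


def canine_perfusion_cov() -> pd.DataFrame:
    """Per-subject CoV of HU enhancement over the lung mask."""
    return pd.DataFrame(_COV_ROWS, columns=["subject", "group", "cov"])
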