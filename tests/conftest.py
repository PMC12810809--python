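"""Shared fixtures: published characteristics table re-entered as a cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from doifusion.synthetic import COHORT_COLUMNS

# Published patient-characteristics counts by CLNM stratum
# (node-negative n=26, node-positive n=20; marginals per variable).
_TABLE1_COUNTS = {
    "clnm_negative": {
        "c_t": {"T1": 6, "T2": 11, "T3": 6, "T4": 3},
        "c_n": {"N0": 19, "N1": 3, "N2": 3, "N3": 1},
        "c_stage": {"I": 6, "II": 7, "III": 8, "IV": 5},
    },
    "clnm_positive": {
        "c_t": {"T1": 2, "T2": 5, "T3": 10, "T4": 3},
        "c_n": {"N0": 12, "N1": 2, "N2": 5, "N3": 1},
        "c_stage": {"I": 2, "II": 6, "III": 5, "IV": 7},
    },
}

# variable -> level -> (total_pct, neg_pct, pos_pct) as printed
TABLE1_EXPECTED_PCT = {
    "c_t": {
        "T1": (17.4, 23.1, 10.0),
        "T2": (34.8, 42.3, 25.0),
        "T3": (34.8, 23.1, 50.0),
        "T4": (13.0, 11.5, 15.0),
    },
    "c_n": {
        "N0": (67.4, 73.1, 60.0),
        "N1": (10.9, 11.5, 10.0),
        "N2": (17.4, 11.5, 25.0),
        "N3": (4.3, 3.8, 5.0),
    },
    "c_stage": {
        "I": (17.4, 23.1, 10.0),
        "II": (28.3, 26.9, 30.0),
        "III": (28.3, 30.8, 25.0),
        "IV": (26.1, 19.2, 35.0),
    },
}


def _expand(counts: dict) -> list:
    out = []
    for level, k in counts.items():
        out.extend([level] * k)
    return out


@pytest.fixture(scope="session")
def table1_cohort() -> pd.DataFrame:
    """46-patient cohort whose categorical marginals match the published
    characteristics table (joint distribution is arbitrary)."""
    frames = []
    for stratum, clnm in (("clnm_negative", 0), ("clnm_positive", 1)):
        spec = _TABLE1_COUNTS[stratum]
        n = sum(spec["c_t"].values())
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{stratum[5]}{i}" for i in range(n)],
                    "p_doi_mm": 5.0,
                    "us_doi_mm": np.nan,
                    "mr_doi_mm": np.nan,
                    "clnm": clnm,
                    "c_t": _expand(spec["c_t"]),
                    "c_n": _expand(spec["c_n"]),
                    "c_stage": _expand(spec["c_stage"]),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df[list(COHORT_COLUMNS)]
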