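"""Demographics of the nine-patient postmortem cohort behind the
default class profiles.

Ages (years) at initial diagnosis and at autopsy for the nine pediatric
brain-tumor patients whose specimens anchor the reference group
statistics. Summary statistics use the population SD convention (÷ n),
which is how the cohort's reported ages aggregate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cohort_table", "cohort_summary"]

_PATIENTS = [
    # (patient, age_at_diagnosis, age_at_autopsy, sex)
    ("WU-1", 9, 9, "F"),
    ("WU-2", 11, 14, "M"),
    ("WU-3", 11, 12, "F"),
    ("WU-4", 7, 16, "M"),
    ("WU-5", 10, 10, "M"),
    ("WU-6", 13, 14, "M"),
    ("WU-7", 4, 7, "F"),
    ("WU-8", 17, 18, "M"),
    ("WU-9", 15, 18, "F"),
]


def cohort_table() -> pd.DataFrame:
    return pd.DataFrame(
        _PATIENTS, columns=["patient", "age_at_diagnosis", "age_at_autopsy", "sex"]
    )


def cohort_summary(ddof: int = 0) -> dict[str, float]:
    """Mean and SD of the cohort ages (population convention by default)."""
    t = cohort_table()
    diag = t["age_at_diagnosis"].to_numpy(float)
    autop = t["age_at_autopsy"].to_numpy(float)
    return {
        "n": len(t),
        "mean_age_at_diagnosis": float(diag.mean()),
        "sd_age_at_diagnosis": float(np.std(diag, ddof=ddof)),
        "mean_age_at_autopsy": float(autop.mean()),
        "sd_age_at_autopsy": float(np.std(autop, ddof=ddof)),
    }
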