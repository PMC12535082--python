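"""Small bundled reference tables.

:func:`published_subtype_comparison` carries the between-group summary
statistics reported by a published adolescent NSSI subtyping study that
applied this method to 881 patients (two K-means groups of 560 and 321):
per selected edge, each group's mean and SD of the perturbation z-scores,
the reported Welch t, and the reported pooled Cohen's d.  Because Welch t
and pooled Cohen's d are functions of summary statistics alone, the table
lets the package's arithmetic be checked against printed values without
the (non-public) raw data.
"""

from __future__ import annotations

import pandas as pd

GROUP_SIZES = (560, 321)

_ROWS = [
    # edge, mean_1, sd_1, mean_2, sd_2, reported t, reported p, reported d
    ("Openness-SDS", -0.11, 0.94, 0.20, 1.07, -4.28, "<0.01", -0.31),
    ("Conscientiousness-Extraversion", -0.39, 0.93, 0.68, 0.72, -19.09, "<0.01", -1.25),
    ("Cohesion-Extraversion", -0.46, 0.86, 0.80, 0.67, -24.00, "<0.01", -1.57),
    ("Cohesion-Conscientiousness", -0.44, 0.90, 0.77, 0.62, -23.56, "<0.01", -1.50),
    ("Organization-Expressiveness", -0.19, 0.94, 0.34, 1.01, -7.72, "<0.01", -0.55),
    ("Active Recreational-Intellectual Culture", -0.12, 1.02, 0.21, 0.92, -5.00, "<0.01", -0.34),
    ("Control-Intellectual Culture", -0.13, 1.02, 0.22, 0.93, -5.21, "<0.01", -0.36),
    ("Control-Organization", 0.01, 0.93, -0.01, 1.11, 0.22, "0.83", 0.02),
]


def published_subtype_comparison() -> pd.DataFrame:
    """Eight selected edges with per-group summary statistics (n1=560, n2=321)."""
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "edge", "mean_1", "sd_1", "mean_2", "sd_2",
            "reported_t", "reported_p", "reported_d",
        ],
    )
    df["n_1"] = GROUP_SIZES[0]
    df["n_2"] = GROUP_SIZES[1]
    return df
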