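"""Small bundled reference datasets.

``treatment_recognition()`` returns the per-subject test-set recognition
percentages (eight subjects x four preprocessing treatments, QDA classifier)
reported by a published 15-gesture sEMG decoding study.  They are the
worked-example input for the statistical validation stage (one-way ANOVA +
Duncan's multiple range test): the four treatments are compared as groups
with eight subject replicates each.

Note the study's printed column average for "only normalization" (94.01)
disagrees with the mean of its own printed column entries (94.055); the
recomputed value is authoritative here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TREATMENT_LABELS", "treatment_recognition",
           "PRINTED_COLUMN_AVERAGES"]

#: Treatment codes: A = normalization + SFS, B = normalization only,
#: C = SFS only, D = no preprocessing.
TREATMENT_LABELS = {
    "A": "normalization and SFS",
    "B": "only normalization",
    "C": "only with SFS",
    "D": "without any processing",
}

# subjects 1..8 (rows) x treatments (columns D, C, B, A as published)
_TABLE = np.array([
    # D      C      B      A
    [65.97, 96.53, 96.68, 98.27],
    [88.82, 95.38, 96.37, 97.76],
    [59.06, 91.80, 87.57, 91.87],
    [71.41, 92.26, 92.32, 93.93],
    [73.89, 97.06, 97.48, 98.94],
    [72.09, 95.47, 96.92, 97.44],
    [65.46, 95.35, 96.06, 97.06],
    [47.36, 94.01, 89.04, 93.98],
])

#: Column averages as printed in the source table (B is inconsistent with
#: its own column, which recomputes to 94.055).
PRINTED_COLUMN_AVERAGES = {"D": 68.01, "C": 94.73, "B": 94.01, "A": 96.16}


def treatment_recognition() -> dict[str, np.ndarray]:
    """Per-treatment arrays of the eight subjects' QDA TST recognition (%)."""
    cols = ("D", "C", "B", "A")
    return {t: _TABLE[:, i].copy() for i, t in enumerate(cols)}
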