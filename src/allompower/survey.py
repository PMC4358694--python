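"""Literature-survey sample-size summaries and Kolmogorov-Smirnov comparisons.

A :class:`SurveyTable` records one row per published intraspecific sample:
the study, species, whether the taxon is an invertebrate or a vertebrate,
whether it is extant or extinct, and the sample size n.  Groups are
summarised (N, min, max, mean, median, proportion with n <= 10) and compared
pairwise with the two-sided two-sample KS test, which is sensitive to the
whole shape of the sample-size distribution rather than location alone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("invertebrate", "vertebrate")
STATUSES = ("extant", "extinct")
REQUIRED_COLUMNS = ("study", "species", "group", "status", "n")

#: The four standard pairwise comparisons: label, (group, status), (group, status).
STANDARD_PAIRINGS = (
    ("invertebrate: extant vs extinct", ("invertebrate", "extant"), ("invertebrate", "extinct")),
    ("vertebrate: extant vs extinct", ("vertebrate", "extant"), ("vertebrate", "extinct")),
    ("extant: vertebrate vs invertebrate", ("vertebrate", "extant"), ("invertebrate", "extant")),
    ("extinct: vertebrate vs invertebrate", ("vertebrate", "extinct"), ("invertebrate", "extinct")),
)


class SurveyTable:
    """Validated table of published intraspecific sample sizes.

    Samples, not studies, are the unit: a study comparing several species
    contributes one row per species, and duplicate study/species labels are
    preserved.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"survey table is missing columns {missing}")
        data = data.reset_index(drop=True)
        for row, g in data["group"].items():
            if g not in GROUPS:
                raise ValidationError(
                    f"row {row}: unknown group {g!r}; expected one of {GROUPS}"
                )
        for row, s in data["status"].items():
            if s not in STATUSES:
                raise ValidationError(
                    f"row {row}: unknown status {s!r}; expected one of {STATUSES}"
                )
        n = pd.to_numeric(data["n"], errors="coerce")
        bad = n.isna() | (n < 1) | (n != n.round())
        if bad.any():
            row = bad.idxmax()
            raise ValidationError(
                f"row {row}: sample size must be a positive integer, "
                f"got {data.at[row, 'n']!r}"
            )
        data = data.assign(n=n.astype(int))
        self._data = data

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    def __len__(self) -> int:
        return len(self._data)

    def group_n(self, group: str | None = None, status: str | None = None) -> np.ndarray:
        """Sample sizes of one (group, status) cell (either filter optional)."""
        sel = self._data
        if group is not None:
            sel = sel[sel["group"] == group]
        if status is not None:
            sel = sel[sel["status"] == status]
        return sel["n"].to_numpy()

    def to_csv(self, path) -> None:
        self._data.to_csv(path, index=False)


def read_survey_csv(path) -> SurveyTable:
    """Read and validate a survey CSV (columns study, species, group, status, n)."""
    return SurveyTable(pd.read_csv(path, dtype={"study": str, "species": str}))


def summarize_groups(table: SurveyTable) -> pd.DataFrame:
    """Per-(group, status) sample-size summary.

    Columns: group, status, N, min, max, mean, median, prop_n_le_10.  The
    median of an even-N group is the midpoint of the two central order
    statistics; the proportion uses n <= 10 inclusively.  Absent groups are
    omitted with a logged warning.
    """
    rows = []
    for group in GROUPS:
        for status in STATUSES:
            n = table.group_n(group, status)
            if n.size == 0:
                logger.warning("survey group (%s, %s) is empty; omitted", group, status)
                continue
            rows.append(
                {
                    "group": group,
                    "status": status,
                    "N": int(n.size),
                    "min": int(n.min()),
                    "max": int(n.max()),
                    "mean": float(n.mean()),
                    "median": float(np.median(n)),
                    "prop_n_le_10": float((n <= 10).mean()),
                }
            )
    return pd.DataFrame(rows)


def ks_compare(a, b) -> tuple:
    """Two-sided two-sample KS test: (D, asymptotic p).

    D is the supremum distance between the two empirical CDFs; the p-value
    uses the asymptotic two-sided KS distribution at the effective size
    N_a N_b / (N_a + N_b), which is the appropriate choice for heavily tied
    integer sample sizes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_significance(p: float) -> str:
    """Significance band for survey comparisons: *** p<0.001, * p<0.05."""
    if p < 1e-3:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def compare_standard_pairs(table: SurveyTable) -> pd.DataFrame:
    """Run the four standard group comparisons; skip pairs with an empty side."""
    rows = []
    for label, (g1, s1), (g2, s2) in STANDARD_PAIRINGS:
        a = table.group_n(g1, s1)
        b = table.group_n(g2, s2)
        if a.size == 0 or b.size == 0:
            logger.warning("comparison %r skipped: empty group", label)
            continue
        d, p = ks_compare(a, b)
        rows.append(
            {
                "comparison": label,
                "D": d,
                "p_value": p,
                "significance": ks_significance(p),
            }
        )
    return pd.DataFrame(rows)
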