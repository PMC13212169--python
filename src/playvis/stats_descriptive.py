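"""Frequency tables and association tests for playground observations.

Cross-tabulations of observed children (activity or play type against
gender x year-group strata), Pearson chi-square tests without continuity
correction, Cramér's V effect sizes, and Haberman adjusted standardized
residuals (approximately standard normal under independence; |r| > 1.96
flags over-/under-represented cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ContingencyTable:
    counts: pd.DataFrame  # rows x columns, integer counts

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class AssociationTestResult:
    chi2: float
    df: int
    p: float
    cramers_v: float
    residuals: pd.DataFrame  # adjusted standardized residuals per cell
    n: int

    def flagged(self, threshold: float = 1.96) -> pd.DataFrame:
        """Cells over- (+) or under- (-) represented beyond the threshold."""
        return self.residuals.where(self.residuals.abs() > threshold)

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "cramers_v": self.cramers_v,
            "n": self.n,
        }


def tabulate(records, row_attr: str, col_attr: str) -> ContingencyTable:
    """Complete cross-tabulation (including zero cells) of two attributes.

    ``records`` may be a list of objects with the attributes or a
    DataFrame with the columns.  Records where either attribute is
    missing (None/NaN) are dropped.
    """
    if isinstance(records, pd.DataFrame):
        df = records[[row_attr, col_attr]].copy()
    else:
        df = pd.DataFrame(
            {
                row_attr: [getattr(r, row_attr) for r in records],
                col_attr: [getattr(r, col_attr) for r in records],
            }
        )
    df = df.dropna()
    table = pd.crosstab(df[row_attr], df[col_attr], dropna=False)
    return ContingencyTable(table)


def cramers_v(chi2: float, n: int, k: int) -> float:
    """Cramér's V = sqrt(chi2 / (n * k)) with k = min(r-1, c-1)."""
    if chi2 < 0 or n < 1 or k < 1:
        raise ValueError("need chi2 >= 0, n >= 1, k >= 1")
    return float(np.sqrt(chi2 / (n * k)))


def chi_square_test(table: ContingencyTable) -> AssociationTestResult:
    """Pearson chi-square test of independence with effect size and
    Haberman adjusted standardized residuals.

    residual_ij = (O - E) / sqrt(E (1 - rowshare_i)(1 - colshare_j)).
    Raises when any expected count is zero (statistic undefined).
    """
    O = table.counts.to_numpy(dtype=float)
    n = O.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    rowsum = O.sum(axis=1, keepdims=True)
    colsum = O.sum(axis=0, keepdims=True)
    E = rowsum @ colsum / n
    if (E == 0).any():
        raise ValueError("expected count of zero; chi-square statistic undefined")
    chi2, p, df, _ = sps.chi2_contingency(O, correction=False)
    k = min(O.shape[0] - 1, O.shape[1] - 1)
    v = cramers_v(chi2, int(n), k)
    with np.errstate(invalid="ignore"):
        resid = (O - E) / np.sqrt(E * (1 - rowsum / n) * (1 - colsum / n))
    residuals = pd.DataFrame(resid, index=table.counts.index, columns=table.counts.columns)
    return AssociationTestResult(float(chi2), int(df), float(p), v, residuals, int(n))


# ---------------------------------------------------------------------------
# Published two-school reference summaries
# ---------------------------------------------------------------------------
# Printed descriptive frequencies and test statistics from the two-school
# London playground observation campaign this pipeline was designed
# around.  They serve as consistency inputs: the effect sizes and shares
# they imply can be recomputed with the functions above.  The raw
# per-child records behind them are not public.

REFERENCE_SUMMARIES: dict = {
    "school_a": {
        "n": 1245,
        "gender": {"male": 633, "female": 612},
        "year_group": {"Y3/4": 636, "Y5/6": 609},
        "activity": {"other": 96, "conversation": 119, "play": 1030},
        "activity_shares_printed": {"other": 7.7, "conversation": 9.6, "play": 82.7},
        "areas": {
            "basketball": 35,
            "climbing frame": 289,
            "football": 164,
            "hockey": 193,
            "tennis": 152,
            "undesignated": 412,
        },
        "undesignated_share_printed": 33.1,
        # activity x (gender x year): 3 x 4 table -> df 6, k = 2
        "activity_test": {"chi2": 105.95, "df": 6, "n": 1245, "k": 2, "v_printed": 0.21},
        # play type x (gender x year): 8 x 4 table -> df 21, k = 3;
        # n is the number of play observations
        "play_type_test": {"chi2": 311.25, "df": 21, "n": 1030, "k": 3, "v_printed": 0.32},
        "vmd_range_printed": (1.09, 3.0),
        "vmd_mean_printed": 1.22,
    },
    "school_b": {
        "n": 1640,
        "gender": {"male": 805, "female": 835},
        "year_group": {"Y3/4": 841, "Y5/6": 799},
        "activity": {"other": 113, "conversation": 338, "play": 1189},
        "activity_shares_printed": {"other": 6.9, "conversation": 20.6, "play": 72.5},
        "areas": {
            "kingball": 178,
            "climbing frame": 460,
            "lower playground": 102,
            "silent zone": 109,
            "treehouse": 79,
            "undesignated": 712,
        },
        "undesignated_share_printed": 43.4,
        "activity_test": {"chi2": 75.62, "df": 6, "n": 1640, "k": 2, "v_printed": 0.15},
        "play_type_test": {"chi2": 206.46, "df": 21, "n": 1189, "k": 3, "v_printed": 0.24},
        "vmd_range_printed": (1.63, 4.05),
        "vmd_mean_printed": 2.23,
    },
}


def reference_effect_sizes() -> pd.DataFrame:
    """Recompute Cramér's V from the published chi-square statistics.

    One row per (school, test) with the recomputed V next to the printed
    value — a closed-form consistency check of the published effect sizes.
    """
    rows = []
    for school, ref in REFERENCE_SUMMARIES.items():
        for test in ("activity_test", "play_type_test"):
            t = ref[test]
            rows.append(
                {
                    "school": school,
                    "test": test.replace("_test", ""),
                    "chi2": t["chi2"],
                    "n": t["n"],
                    "k": t["k"],
                    "v_recomputed": cramers_v(t["chi2"], t["n"], t["k"]),
                    "v_printed": t["v_printed"],
                }
            )
    return pd.DataFrame(rows)


def reference_shares() -> pd.DataFrame:
    """Recompute activity and area percentage shares from the published
    frequency tables, next to the printed percentages (1 dp)."""
    rows = []
    for school, ref in REFERENCE_SUMMARIES.items():
        n = ref["n"]
        for act, freq in ref["activity"].items():
            rows.append(
                {
                    "school": school,
                    "quantity": f"activity_share[{act}]",
                    "share_recomputed": 100.0 * freq / n,
                    "share_printed": ref["activity_shares_printed"][act],
                }
            )
        rows.append(
            {
                "school": school,
                "quantity": "area_share[undesignated]",
                "share_recomputed": 100.0 * ref["areas"]["undesignated"] / n,
                "share_printed": ref["undesignated_share_printed"],
            }
        )
    return pd.DataFrame(rows)
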