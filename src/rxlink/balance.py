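"""Covariate balance between fillers and non-fillers.

The standardized mean difference (SMD) is the scale-free group-difference
measure used throughout: |m1 - m2| / sqrt((s1^2 + s2^2) / 2) for continuous
covariates, the pooled-proportion-variance analogue for binary ones, and a
Mahalanobis-type form for multicategory covariates (the proportion-
difference vector over K-1 categories against the averaged multinomial
covariance).  An SMD above 0.10 conventionally flags imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IMBALANCE_THRESHOLD",
    "smd_continuous",
    "smd_binary",
    "smd_multicategory",
    "balance_table",
    "SmdReport",
]

IMBALANCE_THRESHOLD = 0.10


def smd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def smd_binary(x1: int, n1: int, x2: int, n2: int) -> float:
    """SMD for a binary covariate from group counts.

    p = x/n per group; |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2).
    The degenerate 0/0 case (identical all-or-nothing groups) returns 0.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n, n > 0")
    p1, p2 = x1 / n1, x2 / n2
    var = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    diff = abs(p1 - p2)
    if var == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return diff / np.sqrt(var)


def smd_multicategory(counts1, counts2) -> float:
    """Mahalanobis-type SMD for a K-category covariate from group counts.

    Dropping the last category, T is the K-1 vector of proportion
    differences and S the average of the two multinomial covariance
    matrices: diagonal (p1k(1-p1k) + p2k(1-p2k))/2, off-diagonal
    -(p1k p1l + p2k p2l)/2.  Returns sqrt(T' S^-1 T), via pseudo-inverse
    when S is singular.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1 or len(c1) < 2:
        raise ValueError("count vectors must share a length K >= 2")
    if c1.sum() <= 0 or c2.sum() <= 0:
        raise ValueError("each group must have a positive total")
    p1 = c1 / c1.sum()
    p2 = c2 / c2.sum()
    k = len(p1) - 1
    t = (p1 - p2)[:k]
    s = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                s[i, j] = (p1[i] * (1 - p1[i]) + p2[i] * (1 - p2[i])) / 2.0
            else:
                s[i, j] = -(p1[i] * p1[j] + p2[i] * p2[j]) / 2.0
    if np.allclose(t, 0.0):
        return 0.0
    try:
        sol = np.linalg.solve(s, t)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(s) @ t
    val = float(t @ sol)
    return float(np.sqrt(max(val, 0.0)))


@dataclass
class SmdReport:
    rows: pd.DataFrame  # name, type, summaries, smd, imbalance_flag

    def flagged(self) -> list[str]:
        return list(self.rows.loc[self.rows["imbalance_flag"], "covariate"])

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


CONTINUOUS = ["age", "bmi", "adi_state_rank", "n_rx_at_index", "n_rx_in_year"]
BINARY = [
    ("sex", "Female"),
    ("provider_type", "Physician"),
    ("dx_depression", True),
    ("dx_anxiety", True),
    ("dx_adhd", True),
    ("dx_headache", True),
    ("ssri", True),
    ("wcv_prior_year", True),
    ("wcv_index_year", True),
    ("outpatient_prior_year", True),
    ("inpatient_prior_year", True),
    ("ed_prior_year", True),
]
MULTICATEGORY = ["race_ethnicity", "payer", "prescriber_specialty", "clinic_type", "phq9_severity"]


def _median_iqr(s: pd.Series) -> str:
    s = s.dropna()
    if not len(s):
        return "n/a"
    return f"{s.median():g} ({s.quantile(0.25):g}-{s.quantile(0.75):g})"


def balance_table(rows: pd.DataFrame, group_col: str = "fill_status") -> SmdReport:
    """Per-covariate SMDs between the two fill-status groups.

    Continuous covariates are compared on means/SDs (and summarised as
    median (IQR) for display); binary and multicategory covariates on
    counts.  Rows with missing values for a covariate are dropped for that
    covariate only.
    """
    g1 = rows[rows[group_col].astype(bool)]
    g2 = rows[~rows[group_col].astype(bool)]
    if not len(g1) or not len(g2):
        raise ValueError("both fill-status groups must be nonempty")

    out = []

    def add(name, ctype, s1, s2, smd):
        out.append(
            {
                "covariate": name,
                "type": ctype,
                "group1_summary": s1,
                "group2_summary": s2,
                "smd": round(float(smd), 3),
                "imbalance_flag": float(smd) > IMBALANCE_THRESHOLD,
            }
        )

    for name in CONTINUOUS:
        a = g1[name].astype(float).dropna()
        b = g2[name].astype(float).dropna()
        sd1, sd2 = a.std(ddof=1), b.std(ddof=1)
        if sd1 > 0 and sd2 > 0:
            smd = smd_continuous(a.mean(), sd1, b.mean(), sd2)
        else:
            smd = 0.0 if np.isclose(a.mean(), b.mean()) else float("inf")
        add(name, "continuous", _median_iqr(a), _median_iqr(b), smd)

    for name, level in BINARY:
        x1 = int((g1[name] == level).sum())
        x2 = int((g2[name] == level).sum())
        smd = smd_binary(x1, len(g1), x2, len(g2))
        add(
            name,
            "binary",
            f"{x1} ({100 * x1 / len(g1):.1f})",
            f"{x2} ({100 * x2 / len(g2):.1f})",
            smd,
        )

    for name in MULTICATEGORY:
        levels = sorted(set(rows[name].astype(str)))
        if len(levels) < 2:
            add(name, "multicategory", "single level", "single level", 0.0)
            continue
        c1 = [int((g1[name].astype(str) == lv).sum()) for lv in levels]
        c2 = [int((g2[name].astype(str) == lv).sum()) for lv in levels]
        smd = smd_multicategory(c1, c2)
        add(
            name,
            "multicategory",
            "/".join(str(c) for c in c1),
            "/".join(str(c) for c in c2),
            smd,
        )

    return SmdReport(rows=pd.DataFrame(out))
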