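"""Two-group comparison statistics and significance annotation.

Classical (pooled-variance) Student's t-test by default, with Welch and
paired variants; results carry mean ± SEM per group (SEM = SD/√n, n = number
of animals) and the conventional star annotation with strict thresholds
*p < 0.05, **p < 0.01, ***p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "students_t", "star_annotation", "comparison_table"]


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float
    stars: str
    test: str = "student"

    def format(self) -> str:
        return (f"{self.label_a}: {self.mean_a:.4g} ± {self.sem_a:.3g} (n={self.n_a})  vs  "
                f"{self.label_b}: {self.mean_b:.4g} ± {self.sem_b:.3g} (n={self.n_b})  "
                f"t={self.t:.3f}, df={self.df:g}, p={self.p:.4g} [{self.stars}]")


def star_annotation(p: float) -> str:
    """Map a two-sided p-value to its star annotation (strict thresholds)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def students_t(group_a: Sequence[float], group_b: Sequence[float],
               labels: tuple[str, str] = ("A", "B"),
               equal_var: bool = True, paired: bool = False) -> GroupComparison:
    """Two-sample t-test with mean ± SEM summaries and star annotation.

    Default is the classical pooled-variance unpaired Student's test with
    df = n_a + n_b − 2; ``equal_var=False`` selects Welch, ``paired=True``
    the paired test (requires equal n).  Two identical constant groups give
    t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    zero_var = np.var(a) == 0.0 and np.var(b) == 0.0
    if zero_var and np.mean(a) == np.mean(b) and not paired:
        # zero pooled variance with equal means: no evidence either way
        df = float(a.size + b.size - 2)
        return GroupComparison(
            label_a=labels[0], label_b=labels[1], n_a=int(a.size), n_b=int(b.size),
            mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
            sem_a=0.0, sem_b=0.0, t=0.0, df=df, p=1.0, stars="ns",
            test="student" if equal_var else "welch")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        res = sps.ttest_rel(a, b)
        df = float(a.size - 1)
        test = "paired"
    elif equal_var:
        res = sps.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
        test = "student"
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
        test = "welch"

    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance
        t, p = 0.0, 1.0
    return GroupComparison(
        label_a=labels[0], label_b=labels[1], n_a=int(a.size), n_b=int(b.size),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        sem_a=float(np.std(a, ddof=1) / np.sqrt(a.size)),
        sem_b=float(np.std(b, ddof=1) / np.sqrt(b.size)),
        t=t, df=df, p=p, stars=star_annotation(p), test=test)


def comparison_table(comparisons: Sequence[GroupComparison],
                     names: Sequence[str] | None = None) -> pd.DataFrame:
    """Assemble comparisons into a tidy results table."""
    rows = []
    for i, c in enumerate(comparisons):
        rows.append({
            "comparison": names[i] if names is not None else f"{c.label_a}_vs_{c.label_b}",
            "group_a": c.label_a, "group_b": c.label_b,
            "n_a": c.n_a, "n_b": c.n_b,
            "mean_a": c.mean_a, "sem_a": c.sem_a,
            "mean_b": c.mean_b, "sem_b": c.sem_b,
            "t": c.t, "df": c.df, "p": c.p, "stars": c.stars, "test": c.test,
        })
    return pd.DataFrame(rows)
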