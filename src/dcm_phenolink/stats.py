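"""Group comparison: the unpaired Student's t-test used for all readouts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups"]


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    alpha: float
    significant: bool


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test (pooled-variance Student by default, Welch by flag).

    Both groups need n >= 2 finite values. When both groups have zero
    variance, p is 1 if the means are equal and 0 otherwise (the
    degenerate limit of the statistic).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain only finite values")

    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        equal = a.mean() == b.mean()
        t = 0.0 if equal else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if equal else 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return GroupComparison(
        label_a=labels[0],
        label_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )
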