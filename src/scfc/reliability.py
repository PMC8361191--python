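"""Test-retest and out-of-sample agreement statistics.

Agreement between two sets of paired region-wise values (e.g. group-mean
coupling from a test visit vs a retest visit) is summarized two ways:
a Bland-Altman analysis — the bias d-bar (mean of paired differences)
with 95% limits of agreement d-bar +/- 1.96 * S_d, where S_d is the
sample SD (n-1 denominator) of the differences — and a Pearson
correlation with a one-sided permutation p-value.

The difference direction is second argument minus first (retest minus
test, replication minus original); pass ``direction=-1`` to flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netstats import correlation_with_permutation


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float  # bias d-bar
    sd_of_differences: float  # S_d, n-1 denominator
    loa_lower: float
    loa_upper: float
    n: int

    @property
    def loa_half_width(self) -> float:
        return 1.96 * self.sd_of_differences


def bland_altman(a, b, direction: int = 1) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement for paired values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and the same length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = direction * (b - a)
    dbar = float(d.mean())
    s_d = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=dbar,
        sd_of_differences=s_d,
        loa_lower=dbar - 1.96 * s_d,
        loa_upper=dbar + 1.96 * s_d,
        n=a.size,
    )


def agreement_correlation(
    a, b, n_perm: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """Pearson correlation between paired vectors with one-sided permutation p."""
    return correlation_with_permutation(a, b, n_perm=n_perm, seed=seed)
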