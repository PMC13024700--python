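"""Variably methylated region (VMR) calling.

Per-window inter-individual variance of the weighted methylation level
is ranked in descending order; the VMR/non-VMR threshold is the maximum
inflection point of the ranked curve, located as the rank-normalized
point of greatest perpendicular distance from the chord joining the
curve's endpoints (the knee). This presumes a biphasic variance
distribution: a large low-variance bulk and a smaller high-variance
tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationMatrix

__all__ = ["VarianceProfile", "window_variance", "variance_threshold", "call_vmrs"]

_DEGENERATE_DIST = 1e-12


@dataclass
class VarianceProfile:
    """Per-window variance with (optional) descending ranking and threshold."""

    frame: pd.DataFrame  # index window_id; columns chrom, start, end, v
    group: str
    threshold_value: float | None = None
    threshold_rank: int | None = None
    ranked: bool = field(default=False)

    @property
    def v(self) -> pd.Series:
        return self.frame["v"]

    def rank_order(self) -> pd.Index:
        """Window ids in descending-variance order (ties stable in window id)."""
        order = np.lexsort((self.frame.index.to_numpy(), -self.v.to_numpy(float)))
        return self.frame.index[order]


def window_variance(matrix: MethylationMatrix, group: str) -> VarianceProfile:
    """Unbiased (n-1) variance of per-sample methylation levels, one group.

    Computed on the proportion scale, so units are proportion^2; every
    matrix window contributes (the matrix invariant guarantees full
    coverage).
    """
    samples = matrix.samples_in(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} needs >= 2 individuals")
    m = matrix.m[samples]
    v = m.var(axis=1, ddof=1)
    frame = matrix.windows.copy()
    frame["v"] = v
    return VarianceProfile(frame=frame, group=group)


def variance_threshold(profile: VarianceProfile) -> float:
    """Locate the variance cut-off at the ranked curve's maximum inflection.

    Variances are sorted descending; rank and variance are each
    min-max-normalized to [0, 1], making the cut scale-free, and the
    threshold is the variance at the rank of maximum perpendicular
    distance below the chord from the first point to the last. Ties go
    to the higher-variance rank (fewer VMRs). Mutates and returns the
    profile's threshold; raises if all variances are equal.
    """
    v = profile.v.to_numpy(float)
    if len(np.unique(v)) < 3:
        raise ValueError("need >= 3 distinct variance values to locate a threshold")
    order = np.lexsort((profile.frame.index.to_numpy(), -v))
    vs = v[order]
    n = len(vs)
    x = np.arange(n) / (n - 1)
    y = (vs - vs[-1]) / (vs[0] - vs[-1])
    # chord runs from (0, 1) to (1, 0): y = 1 - x
    dist = (1.0 - x - y) / np.sqrt(2.0)
    k = int(np.argmax(dist))
    if dist[k] <= _DEGENERATE_DIST:
        warnings.warn(
            "ranked variance curve is (near-)linear; knee is degenerate and the "
            "tie-break rank was used",
            RuntimeWarning,
            stacklevel=2,
        )
    profile.threshold_rank = k
    profile.threshold_value = float(vs[k])
    profile.frame = profile.frame.copy()
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    profile.frame["rank"] = ranks
    profile.ranked = True
    return profile.threshold_value


def call_vmrs(profile: VarianceProfile) -> tuple[pd.Index, pd.Index]:
    """Partition the window universe into (VMR, non-VMR) at the threshold.

    A window is a VMR iff its variance is strictly above the threshold
    value; the window sitting at the knee itself is not. An empty VMR
    set (threshold at or above the maximum) is allowed with a warning.
    """
    if profile.threshold_value is None:
        raise ValueError("run variance_threshold first")
    tau = profile.threshold_value
    is_vmr = profile.v > tau
    profile.frame["is_vmr"] = is_vmr
    vmr = profile.frame.index[is_vmr]
    non_vmr = profile.frame.index[~is_vmr]
    if len(vmr) == 0:
        warnings.warn("threshold at or above maximum variance: empty VMR set",
                      RuntimeWarning, stacklevel=2)
    return vmr, non_vmr
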