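"""Per-window two-group differential methylation testing.

Each window is tested with a binomial logistic regression of per-sample
(methylated, total) counts on a group indicator. With a single binary
covariate the maximum-likelihood fit is closed-form — the fitted
proportions are the per-group pooled (coverage-weighted) methylation
levels — so the 1-df likelihood-ratio chi-square is computed vectorized
across all windows. P-values are Benjamini–Hochberg adjusted and
windows with q below the threshold are called DMRs.

No overdispersion correction is applied: the test is exactly the plain
logistic-regression DMR test, which is well calibrated under binomial
sampling and anticonservative when counts are overdispersed across
individuals (see the methods note).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .io import MethylationMatrix

__all__ = ["dmr_test", "adjust_fdr", "call_dmrs", "rank_by_change"]


def _binom_loglik(meth: np.ndarray, total: np.ndarray, p: np.ndarray) -> np.ndarray:
    # xlogy handles the 0*log(0) boundary (separation) terms exactly
    return xlogy(meth, p) + xlogy(total - meth, 1.0 - p)


def dmr_test(
    matrix: MethylationMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Likelihood-ratio test of group on methylation, one row per window.

    Returns a frame indexed by window id with the window coordinates,
    both groups' pooled methylation levels, ``meth_diff`` (group B minus
    group A pooled level, in percentage points), ``meth_diff_mean`` (the
    same contrast on mean-of-sample-proportions), the LRT statistic and
    its chi-square(1) p-value. Complete separation (0% vs 100%) is not
    an error: the boundary deviance is finite and used as-is.
    """
    sa = matrix.samples_in(group_a)
    sb = matrix.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 samples per group")
    meth_a = matrix.meth[sa].sum(axis=1).to_numpy(float)
    tot_a = matrix.total[sa].sum(axis=1).to_numpy(float)
    meth_b = matrix.meth[sb].sum(axis=1).to_numpy(float)
    tot_b = matrix.total[sb].sum(axis=1).to_numpy(float)

    p_a = meth_a / tot_a
    p_b = meth_b / tot_b
    p_0 = (meth_a + meth_b) / (tot_a + tot_b)

    ll_full = _binom_loglik(meth_a, tot_a, p_a) + _binom_loglik(meth_b, tot_b, p_b)
    ll_null = _binom_loglik(meth_a + meth_b, tot_a + tot_b, p_0)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    p = np.where(lrt == 0.0, 1.0, p)

    m = matrix.m
    out = matrix.windows.copy()
    out["m_a"] = p_a
    out["m_b"] = p_b
    out["meth_diff"] = 100.0 * (p_b - p_a)
    out["meth_diff_mean"] = 100.0 * (
        m[sb].mean(axis=1).to_numpy() - m[sa].mean(axis=1).to_numpy()
    )
    out["lrt"] = lrt
    out["p"] = p
    return out


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in ranked p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(records: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Attach q-values and the DMR flag (q < threshold) to test results."""
    out = records.copy()
    out["q"] = adjust_fdr(out["p"].to_numpy())
    out["is_dmr"] = out["q"] < q_threshold
    return out


def rank_by_change(records: pd.DataFrame) -> pd.DataFrame:
    """Order windows by methylation change, largest gain first.

    Ties in ``meth_diff`` are broken by genomic coordinate so the
    ranking is a deterministic total order regardless of input order.
    """
    return records.sort_values(
        ["meth_diff", "chrom", "start"],
        ascending=[False, True, True],
        kind="mergesort",
    )
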