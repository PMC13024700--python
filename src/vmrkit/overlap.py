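"""Region-set overlap statistics and ranked-list enrichment.

Two overlap framings are exposed, matching how window-based methylome
studies mix them: (i) set overlap of window ids drawn from a common
window universe, scored against the independence null E = nA*nB/N with
Fisher's exact test; and (ii) >=1-bp interval intersection between a
region set and an external BED track. A GSEA-style running enrichment
score localizes a member set (e.g. VMRs) within a ranked window list
(e.g. by methylation change), with permutation p-values and a
two-extremes statistic for membership piling up at both ends of the
ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "OverlapTest",
    "EnrichmentCurve",
    "expected_overlap",
    "fold_vs_expected",
    "signed_fold",
    "fisher_overlap",
    "overlap_test",
    "overlap_with_track",
    "gsea_enrichment",
    "feature_distribution",
]


def expected_overlap(n_a: int, n_b: int, n_universe: int) -> float:
    """Expected shared elements of two sets under independence: nA*nB/N."""
    if n_universe <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("set sizes must lie in [0, N]")
    return n_a * n_b / n_universe


def fold_vs_expected(observed: float, expected: float, round_to: int | None = None) -> float:
    """Observed/expected overlap ratio, optionally rounded."""
    if expected <= 0:
        raise ValueError("expected overlap must be positive for a fold")
    fold = observed / expected
    return round(fold, round_to) if round_to is not None else fold


def signed_fold(frac_a: float, frac_b: float, round_to: int | None = None) -> float:
    """Signed enrichment/depletion convention for two percentages.

    Ratios >= 1 are returned positive (fold enrichment of a over b);
    ratios < 1 as the negative reciprocal (fold depletion). A zero
    denominator yields the infinite-enrichment sentinel; a zero
    numerator infinite depletion.
    """
    if frac_a < 0 or frac_b < 0:
        raise ValueError("fractions must be non-negative")
    if frac_b == 0:
        return math.inf
    if frac_a == 0:
        return -math.inf
    r = frac_a / frac_b
    fold = r if r >= 1 else -1.0 / r
    return round(fold, round_to) if round_to is not None else fold


def fisher_overlap(
    observed: int, n_a: int, n_b: int, n_universe: int, sided: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test of a 2x2 overlap table, computed in log space.

    Returns ``(p, log10_p)``; ``log10_p`` remains informative when p
    underflows. ``sided`` is ``"greater"`` (enrichment tail) or
    ``"two-sided"`` (sum of table probabilities no larger than the
    observed table's).
    """
    cells = (
        observed,
        n_a - observed,
        n_b - observed,
        n_universe - n_a - n_b + observed,
    )
    if any(c < 0 for c in cells):
        raise ValueError(f"inconsistent 2x2 table from O={observed}, "
                         f"nA={n_a}, nB={n_b}, N={n_universe}")
    hg = stats.hypergeom(n_universe, n_a, n_b)
    if sided == "greater":
        log_p = hg.logsf(observed - 1)
    elif sided == "two-sided":
        lo = max(0, n_a + n_b - n_universe)
        hi = min(n_a, n_b)
        support = np.arange(lo, hi + 1)
        logpmf = hg.logpmf(support)
        obs_logpmf = hg.logpmf(observed)
        log_p = logsumexp(logpmf[logpmf <= obs_logpmf + 1e-9])
        log_p = min(log_p, 0.0)
    else:
        raise ValueError("sided must be 'greater' or 'two-sided'")
    return float(np.exp(log_p)), float(log_p / np.log(10.0))


@dataclass(frozen=True)
class OverlapTest:
    """Observed vs independence-expected overlap of two sets in a universe."""

    n_universe: int
    n_a: int
    n_b: int
    observed: int
    expected: float
    fold: float  # signed: positive O/E enrichment, negative E/O depletion
    p: float
    log10_p: float

    def as_dict(self) -> dict:
        return {
            "N": self.n_universe, "n_a": self.n_a, "n_b": self.n_b,
            "observed": self.observed, "expected": self.expected,
            "fold": self.fold, "p": self.p, "log10_p": self.log10_p,
        }


def overlap_test(set_a, set_b, universe, sided: str = "greater") -> OverlapTest:
    """Score the overlap of two window-id sets from a shared universe."""
    universe = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    observed = len(a & b)
    expected = expected_overlap(len(a), len(b), len(universe))
    if observed >= expected:
        fold = observed / expected if expected > 0 else math.inf
    else:
        fold = -expected / observed if observed > 0 else -math.inf
    p, log10_p = fisher_overlap(observed, len(a), len(b), len(universe), sided=sided)
    return OverlapTest(len(universe), len(a), len(b), observed, expected, fold, p, log10_p)


def _forest(track: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in track.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].to_numpy(), sub["end"].to_numpy())
        )
    return trees


def overlap_with_track(regions: pd.DataFrame, track: pd.DataFrame) -> tuple[int, float]:
    """Count regions intersecting a BED track by >= 1 bp (half-open).

    Returns ``(count, percentage)`` where percentage = 100 * count / |regions|.
    """
    if regions.empty:
        raise ValueError("empty region set")
    trees = _forest(track)
    hits = 0
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            hits += 1
    return hits, 100.0 * hits / len(regions)


@dataclass
class EnrichmentCurve:
    """Running enrichment of a member set along a ranked list."""

    ranked_ids: np.ndarray
    member_flags: np.ndarray
    running: np.ndarray  # length n+1, starts and ends at 0
    es: float
    es_rank: int
    p_es: float
    leading_edge: np.ndarray
    extreme_k: int
    extreme_observed: int
    extreme_fraction: float
    p_extremes: float
    n_perm: int


def _running_sum(member: np.ndarray) -> np.ndarray:
    n_hit = int(member.sum())
    n_miss = len(member) - n_hit
    inc = np.where(member, 1.0 / n_hit, -1.0 / n_miss)
    out = np.empty(len(member) + 1)
    out[0] = 0.0
    np.cumsum(inc, out=out[1:])
    return out


def gsea_enrichment(
    ranked_ids,
    members,
    n_perm: int = 1000,
    seed: int = 0,
    extreme_frac: float = 0.05,
) -> EnrichmentCurve:
    """Classic (unweighted) running enrichment score with permutation p.

    The running sum gains 1/|hits| on each member and loses 1/|misses|
    on each non-member down the ranking; ES is its extreme deviation
    from zero. Because methylation-change rankings put interesting
    windows at *both* ends, a two-extremes statistic is also computed:
    the fraction of members falling in the top-k or bottom-k ranks
    (k = ``extreme_frac`` of the list per end), with an empirical
    p-value from the same membership permutations as the ES p-value.
    """
    ranked_ids = np.asarray(ranked_ids)
    member_set = set(members)
    if not member_set:
        raise ValueError("member set is empty")
    if not member_set <= set(ranked_ids.tolist()):
        raise ValueError("members must be a subset of the ranked universe")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked_ids)
    member = np.fromiter((w in member_set for w in ranked_ids), bool, count=n)
    n_hit = int(member.sum())
    if n_hit == n:
        raise ValueError("member set equals the universe")

    running = _running_sum(member)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    es_rank = peak - 1 if peak > 0 else 0

    k = max(1, int(round(extreme_frac * n)))
    in_extremes = np.zeros(n, bool)
    in_extremes[:k] = True
    in_extremes[-k:] = True
    obs_extreme = int(member[in_extremes].sum())

    rng = np.random.default_rng(seed)
    hits_es = 0
    hits_ext = 0
    for _ in range(n_perm):
        perm = member[rng.permutation(n)]
        run = _running_sum(perm)
        if np.max(np.abs(run)) >= abs(es):
            hits_es += 1
        if int(perm[in_extremes].sum()) >= obs_extreme:
            hits_ext += 1
    p_es = (1 + hits_es) / (n_perm + 1)
    p_ext = (1 + hits_ext) / (n_perm + 1)

    if es >= 0:
        leading = ranked_ids[:peak][member[:peak]]
    else:
        leading = ranked_ids[peak:][member[peak:]]

    return EnrichmentCurve(
        ranked_ids=ranked_ids,
        member_flags=member,
        running=running,
        es=es,
        es_rank=es_rank,
        p_es=p_es,
        leading_edge=leading,
        extreme_k=k,
        extreme_observed=obs_extreme,
        extreme_fraction=obs_extreme / n_hit,
        p_extremes=p_ext,
        n_perm=n_perm,
    )


def feature_distribution(
    regions: pd.DataFrame,
    annotation: pd.DataFrame,
    fallback_label: str | None = "intergenic",
    priority: list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of regions intersecting each annotation label.

    ``annotation`` is a labelled BED (chrom/start/end/name). Two
    assignments are reported per label: ``frac_multi`` counts a region
    under every label it touches (fractions may sum above 1) and
    ``frac_exclusive`` assigns each region to its single
    highest-priority label (priority defaults to the order labels first
    appear in the annotation). Regions touching nothing fall back to
    ``fallback_label`` when one is enabled.
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    if "name" not in annotation.columns:
        raise ValueError("annotation needs a label ('name') column")
    labels = list(dict.fromkeys(annotation["name"]))
    if priority is None:
        priority = labels
    rank = {lab: i for i, lab in enumerate(priority)}

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotation.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub["name"])
        )

    multi = {lab: 0 for lab in labels}
    exclusive = {lab: 0 for lab in labels}
    if fallback_label is not None:
        multi.setdefault(fallback_label, 0)
        exclusive.setdefault(fallback_label, 0)
    n = len(regions)
    if n == 0:
        raise ValueError("empty region set")
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        tree = trees.get(chrom)
        hit_labels = {iv.data for iv in tree.overlap(start, end)} if tree else set()
        if not hit_labels:
            if fallback_label is not None:
                multi[fallback_label] += 1
                exclusive[fallback_label] += 1
            continue
        for lab in hit_labels:
            multi[lab] += 1
        best = min(hit_labels, key=lambda lab: rank.get(lab, len(rank)))
        exclusive[best] += 1

    out = pd.DataFrame(
        {
            "label": list(multi),
            "n_multi": [multi[lab] for lab in multi],
            "frac_multi": [multi[lab] / n for lab in multi],
            "n_exclusive": [exclusive[lab] for lab in multi],
            "frac_exclusive": [exclusive[lab] / n for lab in multi],
        }
    )
    return out.set_index("label")
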