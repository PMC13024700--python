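"""Synthetic RRBS-like methylome generator with ground-truth labels.

Emulates the statistical structure that window-based sperm-methylome
analysis assumes: a strongly bimodal baseline (the bulk of 100-bp
windows essentially fully unmethylated or fully methylated),
beta-binomial overdispersion across individuals, a small subset of
high-dispersion variably methylated windows (VMRs), skewed per-CpG
coverage, and a two-group design in which the group effect is an
inflation of across-individual dispersion in VMR windows.

The group effect is one knob — a multiplicative dispersion inflation f.
Because single-cell methylation is binary and bounded, inflating the
across-cell variance of an initially extreme region necessarily drags
its population mean toward 50%; the generator realizes this by
displacing the stressed group's window mean along the path toward 0.5
by a fraction ``coupling * (1 - 1/f)`` of the remaining distance. At
f = 1 the two groups are exchangeable; at a baseline mean of 0.5 the
displacement vanishes and only the variance grows; at extreme baselines
the mean moves toward 0.5 — so any differential methylation a
downstream test detects is the emergent consequence of variance
inflation, not an independently injected effect.

VMR baseline means are drawn away from the hard 0/1 boundary (a region
whose methylation varies across individuals cannot have its mean pinned
at an extreme); a small "poised" VMR fraction does sit near the
boundary and only becomes detectably variable once dispersion is
inflated, so the number of callable VMRs grows in the stressed group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageModel",
    "SimulatedMethylome",
    "generate_truth",
    "generate_null_truth",
    "simulate_counts",
    "write_cytosine_reports",
]

# beta parameters cannot be formed at exactly 0/1; proportions are clipped
_EPS = 1e-6


@dataclass(frozen=True)
class CoverageModel:
    """Negative-binomial per-CpG read coverage.

    ``dispersion`` is the gamma shape of the NB mixing distribution:
    variance = mean + mean**2 / dispersion, so smaller values give the
    heavier right tail typical of RRBS libraries.
    """

    mean_coverage: float = 30.0
    dispersion: float = 5.0
    n_cpg_per_window: int = 5

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.dispersion <= 0:
            raise ValueError("coverage dispersion must be > 0")
        if self.n_cpg_per_window < 1:
            raise ValueError("n_cpg_per_window must be >= 1")


def _bimodal(rng: np.random.Generator, hyper: np.ndarray, a: float, b: float) -> np.ndarray:
    """Mirror-symmetric beta mixture: Beta(a, b) hypo mode, Beta(b, a) hyper."""
    n = len(hyper)
    return np.where(hyper, rng.beta(b, a, size=n), rng.beta(a, b, size=n))


def generate_truth(
    n_windows: int,
    frac_vmr: float = 0.1,
    seed: int = 0,
    *,
    base_dispersion: tuple[float, float] = (0.01, 0.02),
    dispersion_contrast: float | tuple[float, float] = (2.5, 10.0),
    inflation_factor: float = 1.0,
    bulk_mean_beta: tuple[float, float] = (0.01, 20.0),
    vmr_mean_beta: tuple[float, float] = (2.5, 10.0),
    poised_mean_beta: tuple[float, float] = (0.3, 12.0),
    poised_frac: float = 0.1,
    chrom: str = "chrS",
    window_size: int = 100,
) -> pd.DataFrame:
    """Draw a ground-truth table of disjoint, sorted 100-bp windows.

    Bulk (non-VMR) baseline means come from an equal mixture of
    Beta(0.01, 20) and its mirror — nearly all mass within a percent of
    0 or 1, the strongly bimodal profile of sperm RRBS windows. VMR
    means come from the mirrored Beta(2.5, 10) mixture (hypo- or
    hypermethylated but not boundary-pinned), except for a ``poised_frac``
    minority drawn from the extreme Beta(0.3, 12) mixture: windows that
    look like bulk at baseline and surface as variable only under
    stress. Per-window beta-binomial dispersion rho is uniform on
    ``base_dispersion``; VMR windows have rho multiplied by
    ``dispersion_contrast`` (a scalar, or a (lo, hi) range sampled per
    window), so every VMR is strictly more dispersed than every non-VMR
    under the defaults. ``inflation_factor`` (>= 1) is the extra
    dispersion multiplier the stressed/aged group will apply on top of
    ``group_effect``; at the default 1.0 the truth is group-neutral.

    Set ``base_dispersion=(0, 0)`` for a dispersion-free methylome.
    """
    if not isinstance(n_windows, (int, np.integer)) or n_windows <= 0:
        raise ValueError("n_windows must be a positive integer")
    if n_windows < 10:
        raise ValueError("n_windows must be >= 10")
    if not 0 < frac_vmr < 1:
        raise ValueError("frac_vmr must lie strictly between 0 and 1")
    if inflation_factor < 1:
        raise ValueError("inflation_factor must be >= 1")
    if not 0 <= poised_frac <= 1:
        raise ValueError("poised_frac must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_vmr = int(round(n_windows * frac_vmr))

    hyper = rng.random(n_windows) < 0.5
    baseline = _bimodal(rng, hyper, *bulk_mean_beta)
    vmr_means = _bimodal(rng, hyper, *vmr_mean_beta)
    poised_means = _bimodal(rng, hyper, *poised_mean_beta)
    poised = rng.random(n_windows) < poised_frac
    vmr_means = np.where(poised, poised_means, vmr_means)

    is_vmr = np.zeros(n_windows, dtype=bool)
    is_vmr[rng.choice(n_windows, size=n_vmr, replace=False)] = True
    baseline = np.where(is_vmr, vmr_means, baseline)

    lo, hi = base_dispersion
    if not (0 <= lo <= hi < 1):
        raise ValueError("base_dispersion must satisfy 0 <= lo <= hi < 1")
    rho = rng.uniform(lo, hi, size=n_windows) if hi > lo else np.full(n_windows, float(lo))
    if np.iterable(dispersion_contrast):
        c_lo, c_hi = dispersion_contrast
        contrast = rng.uniform(c_lo, c_hi, size=n_windows)
    else:
        contrast = np.full(n_windows, float(dispersion_contrast))
    if (contrast < 1).any():
        raise ValueError("dispersion_contrast must be >= 1")
    rho = np.where(is_vmr, np.minimum(rho * contrast, 0.999), rho)

    starts = np.arange(n_windows, dtype=np.int64) * window_size
    return pd.DataFrame(
        {
            "window_id": np.arange(n_windows, dtype=np.int64),
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "baseline_mean": baseline,
            "dispersion": rho,
            "is_vmr": is_vmr,
            "inflation_factor": np.where(is_vmr, float(inflation_factor), 1.0),
        }
    )


def generate_null_truth(
    n_windows: int,
    seed: int = 0,
    mean_range: tuple[float, float] = (0.1, 0.9),
    chrom: str = "chrS",
    window_size: int = 100,
) -> pd.DataFrame:
    """Truth table for type-I-error calibration: no VMRs, zero dispersion.

    Means are uniform on ``mean_range`` (kept away from 0/1 so the
    chi-square reference distribution of the window-level test applies;
    at boundary means the discrete counts make the test conservative),
    and counts are purely binomial, the sampling model under which the
    logistic-regression DMR test is exactly calibrated.
    """
    if n_windows < 10:
        raise ValueError("n_windows must be >= 10")
    rng = np.random.default_rng(seed)
    starts = np.arange(n_windows, dtype=np.int64) * window_size
    return pd.DataFrame(
        {
            "window_id": np.arange(n_windows, dtype=np.int64),
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "baseline_mean": rng.uniform(*mean_range, size=n_windows),
            "dispersion": 0.0,
            "is_vmr": False,
            "inflation_factor": 1.0,
        }
    )


@dataclass
class SimulatedMethylome:
    """Per-site counts for two groups of individuals plus the truth table.

    ``cov_site`` and ``meth_site`` have shape (windows, cpgs, samples);
    window-level counts are their sums over the CpG axis.
    """

    truth: pd.DataFrame
    samples: list[str]
    groups: pd.Series  # sample -> group label
    cov_site: np.ndarray
    meth_site: np.ndarray
    cpg_positions: np.ndarray  # (windows, cpgs), 1-based
    window_size: int = 100
    seed: int | None = field(default=None)

    @property
    def total(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cov_site.sum(axis=1),
            index=self.truth["window_id"].to_numpy(),
            columns=self.samples,
        )

    @property
    def meth(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.meth_site.sum(axis=1),
            index=self.truth["window_id"].to_numpy(),
            columns=self.samples,
        )

    def site_frame(self, sample: str) -> pd.DataFrame:
        """Cytosine-report-shaped table (all-plus strand) for one sample."""
        j = self.samples.index(sample)
        w, c, _ = self.cov_site.shape
        cov = self.cov_site[:, :, j].ravel()
        meth = self.meth_site[:, :, j].ravel()
        return pd.DataFrame(
            {
                "chrom": np.repeat(self.truth["chrom"].to_numpy(), c),
                "pos": self.cpg_positions.ravel(),
                "strand": "+",
                "n_meth": meth,
                "n_unmeth": cov - meth,
            }
        )

    def to_matrix(self):
        """Assemble window counts into a cross-sample matrix (no filtering)."""
        from .io import MethylationMatrix

        windows = self.truth.set_index("window_id")[["chrom", "start", "end"]]
        return MethylationMatrix(
            windows=windows.copy(),
            meth=self.meth.astype(np.int64),
            total=self.total.astype(np.int64),
            groups=self.groups.copy(),
        )


def _window_proportions(
    rng: np.random.Generator, mean: np.ndarray, rho: np.ndarray, n_samples: int
) -> np.ndarray:
    """Per-(window, sample) methylation proportions, beta-distributed.

    Windows with rho = 0 get their mean deterministically (binomial-only
    noise downstream).
    """
    n_w = len(mean)
    m = np.clip(mean, _EPS, 1 - _EPS)[:, None]
    disp = rho[:, None] > 0
    inv = np.where(disp, 1.0 / np.maximum(rho[:, None], 1e-12) - 1.0, 1.0)
    draws = rng.beta(
        np.broadcast_to(m * inv, (n_w, n_samples)),
        np.broadcast_to((1 - m) * inv, (n_w, n_samples)),
    )
    return np.where(disp, draws, np.broadcast_to(m, (n_w, n_samples)))


def simulate_counts(
    truth: pd.DataFrame,
    n_per_group: int = 8,
    coverage: CoverageModel | None = None,
    group_effect: float = 1.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("young", "old"),
    coupling: float = 0.5,
) -> SimulatedMethylome:
    """Simulate (methylated, total) counts for two groups of individuals.

    Group A draws each window's proportion from a beta with the truth's
    baseline mean and dispersion. In VMR windows group B uses dispersion
    ``rho * inflation_factor * group_effect`` (clamped below 1 with a
    warning) and a mean displaced toward 0.5 by the fraction
    ``coupling * (1 - 1/f)`` of the remaining distance, where f is the
    total dispersion inflation — the bounded-cell-state consequence of
    variance inflation. Non-VMR windows are identical in distribution
    across groups, and f = 1 makes the groups exchangeable. Each sample
    draws one window-level proportion (shared by the window's CpGs) and
    per-CpG negative-binomial coverage; methylated counts are binomial
    given both.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if group_effect < 0:
        raise ValueError("group_effect must be >= 0")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    coverage = coverage or CoverageModel()

    rng = np.random.default_rng(seed)
    n_w = len(truth)
    n_cpg = coverage.n_cpg_per_window
    name_a, name_b = group_names
    samples = [f"{name_a}_{i + 1}" for i in range(n_per_group)] + [
        f"{name_b}_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        [name_a] * n_per_group + [name_b] * n_per_group, index=samples, name="group"
    )

    is_vmr = truth["is_vmr"].to_numpy(bool)
    mean_a = truth["baseline_mean"].to_numpy(float)
    rho_a = truth["dispersion"].to_numpy(float)
    f = truth["inflation_factor"].to_numpy(float) * group_effect
    rho_b_raw = np.where(is_vmr, rho_a * f, rho_a)
    rho_b = np.minimum(rho_b_raw, 0.999)
    if (rho_b_raw >= 1).any():
        warnings.warn(
            f"dispersion inflation pushed rho >= 1 in {(rho_b_raw >= 1).sum()} "
            "windows; clamped to 0.999",
            RuntimeWarning,
            stacklevel=2,
        )
    shift = np.where(is_vmr & (f > 1), coupling * (1.0 - 1.0 / np.maximum(f, 1.0)), 0.0)
    mean_b = mean_a + shift * (0.5 - mean_a)

    p_a = _window_proportions(rng, mean_a, rho_a, n_per_group)
    p_b = _window_proportions(rng, mean_b, rho_b, n_per_group)
    p = np.concatenate([p_a, p_b], axis=1)  # (W, 2n)

    nb_p = coverage.dispersion / (coverage.dispersion + coverage.mean_coverage)
    cov = rng.negative_binomial(
        coverage.dispersion, nb_p, size=(n_w, n_cpg, 2 * n_per_group)
    )
    meth = rng.binomial(cov, np.clip(p, 0.0, 1.0)[:, None, :])

    starts = truth["start"].to_numpy()
    window_size = int(truth["end"].iloc[0] - truth["start"].iloc[0]) if n_w else 100
    offsets = (np.arange(n_cpg) * window_size) // n_cpg + 1
    positions = (starts[:, None] + offsets[None, :]) if n_w else np.empty((0, n_cpg), np.int64)

    return SimulatedMethylome(
        truth=truth.reset_index(drop=True),
        samples=samples,
        groups=groups,
        cov_site=cov,
        meth_site=meth,
        cpg_positions=positions,
        window_size=window_size,
        seed=seed,
    )


def write_cytosine_reports(sim: SimulatedMethylome, directory) -> list[str]:
    """Write one Bismark-style cytosine report per sample (CpG context only).

    Columns: chrom, 1-based position, strand, count methylated,
    count unmethylated, context, trinucleotide. Round-trips losslessly
    through :func:`vmrkit.io.read_cytosine_report`.
    """
    from pathlib import Path

    if not sim.samples:
        raise ValueError("no samples to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample in sim.samples:
        frame = sim.site_frame(sample)
        out = directory / f"{sample}.CpG_report.txt"
        frame = frame.assign(context="CG", tri="CGG")
        frame.to_csv(out, sep="\t", header=False, index=False)
        paths.append(str(out))
    return paths
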