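"""Stochastic variance-inflation model of methylation shift.

Methylation of a CpG in a single cell is binary, so a genomic region's
methylation level in an individual is the average of Bernoulli states
across cells. When stress or aging inflates the across-cell variance of
an initially extreme region (near 0% or 100%), the cell-level parameter
can only move toward 0.5 — Bernoulli variance p(1-p) is maximized there
— which drags the region average toward 50%. The model therefore bounds
the expected shift obtainable from pure variance inflation at 50
percentage points, versus 100 for a coordinated change in which every
cell switches state.

Two modes:

* ``variance`` — each cell's Bernoulli parameter moves from the initial
  mean m0 toward 0.5 exactly far enough to achieve a requested
  across-cell variance (capped at 0.25);
* ``coordinated`` — all cells shift deterministically toward the
  opposite extreme by a step in [0, 1] (step 1 = every cell switches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShiftModelConfig",
    "ShiftModelResult",
    "shifted_parameter",
    "expected_shift",
    "analytic_max_shift",
    "simulate_shift",
    "asymmetry_stat",
]

_MODES = ("variance", "coordinated")


@dataclass(frozen=True)
class ShiftModelConfig:
    """Settings for one region's cell-population simulation.

    ``variance_target`` is the across-cell Bernoulli variance after
    stress (variance mode; at most 0.25); ``step`` is the fraction of
    the distance to the opposite extreme travelled in coordinated mode.
    """

    m0: float
    n_cells: int = 10_000
    n_individuals: int = 8
    variance_target: float = 0.25
    step: float = 1.0
    mode: str = "variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m0 <= 1.0:
            raise ValueError("m0 must lie in [0, 1]")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.mode == "variance" and not 0.0 <= self.variance_target <= 0.25:
            raise ValueError("variance_target must lie in [0, 0.25] "
                             "(Bernoulli variance cap)")
        if self.mode == "coordinated" and not 0.0 <= self.step <= 1.0:
            raise ValueError("step must lie in [0, 1]")
        if self.n_cells < 1 or self.n_individuals < 1:
            raise ValueError("n_cells and n_individuals must be >= 1")


@dataclass(frozen=True)
class ShiftModelResult:
    """Per-individual means before/after stress and the population shift."""

    before_means: np.ndarray
    after_means: np.ndarray
    delta_pp: float  # population mean shift, percentage points
    expected_delta_pp: float
    var_before: float  # across-cell Bernoulli parameter variance
    var_after: float
    p_after: float


def shifted_parameter(m0: float, mode: str, variance_target: float = 0.25,
                      step: float = 1.0) -> float:
    """Post-stress cell-level Bernoulli parameter p'.

    Variance mode moves p' from m0 toward 0.5 until p'(1-p') reaches
    the target (never past 0.5, never backwards if the target is below
    the starting variance). Coordinated mode moves toward the opposite
    extreme: p' = m0 + step * (extreme - m0), extreme = 1 for m0 <= 0.5.
    """
    if mode == "variance":
        root = np.sqrt(max(0.25 - variance_target, 0.0))
        if m0 <= 0.5:
            return float(np.clip(0.5 - root, m0, 0.5))
        return float(np.clip(0.5 + root, 0.5, m0))
    if mode == "coordinated":
        extreme = 1.0 if m0 <= 0.5 else 0.0
        return float(m0 + step * (extreme - m0))
    raise ValueError(f"mode must be one of {_MODES}")


def expected_shift(m0: float, mode: str, variance_target: float = 0.25,
                   step: float = 1.0) -> float:
    """Expected shift of the region-average methylation, percentage points."""
    return 100.0 * (shifted_parameter(m0, mode, variance_target, step) - m0)


def analytic_max_shift(mode: str) -> float:
    """Maximum expected shift in percentage points: 50 (variance) or 100 (coordinated).

    The variance-mode bound is the distance from an extreme start (0 or
    1) to 0.5, reached when across-cell variance is maxed out; the
    coordinated bound is the full sweep when every cell switches state.
    """
    if mode == "variance":
        return 50.0
    if mode == "coordinated":
        return 100.0
    raise ValueError(f"mode must be one of {_MODES}")


def simulate_shift(config: ShiftModelConfig) -> ShiftModelResult:
    """Simulate cell populations before and after stress.

    Each of ``n_individuals`` individuals carries ``n_cells`` cells;
    before-states are Bernoulli(m0) and after-states Bernoulli(p') with
    p' from :func:`shifted_parameter`. The reported shift is the change
    in the across-individual mean of per-individual averages.
    """
    rng = np.random.default_rng(config.seed)
    p_after = shifted_parameter(config.m0, config.mode, config.variance_target,
                                config.step)
    shape = (config.n_individuals, config.n_cells)
    before = rng.random(shape) < config.m0
    after = rng.random(shape) < p_after
    before_means = before.mean(axis=1)
    after_means = after.mean(axis=1)
    return ShiftModelResult(
        before_means=before_means,
        after_means=after_means,
        delta_pp=100.0 * float(after_means.mean() - before_means.mean()),
        expected_delta_pp=100.0 * (p_after - config.m0),
        var_before=config.m0 * (1.0 - config.m0),
        var_after=p_after * (1.0 - p_after),
        p_after=p_after,
    )


def asymmetry_stat(young_means, old_means) -> dict:
    """Directional asymmetry of methylation change between paired states.

    Returns the fraction of regions whose change points toward 0.5 from
    the young value — sign(old - young) == sign(0.5 - young) among
    regions that changed (NaN when none did) — and the least-squares
    slope of old on young. A slope below 1 with a high fraction is the
    signature of variance-driven drift: hypomethylated regions gain,
    hypermethylated regions lose.
    """
    young = np.asarray(young_means, dtype=float)
    old = np.asarray(old_means, dtype=float)
    if young.shape != old.shape:
        raise ValueError("paired vectors must have equal length")
    if ((young < 0) | (young > 1) | (old < 0) | (old > 1)).any():
        raise ValueError("methylation levels must lie in [0, 1]")
    delta = old - young
    moved = delta != 0.0
    if moved.any():
        toward_mid = np.sign(delta[moved]) == np.sign(0.5 - young[moved])
        fraction = float(toward_mid.mean())
    else:
        fraction = float("nan")
    if np.ptp(young) == 0:
        slope = float("nan")
    else:
        slope = float(np.polyfit(young, old, deg=1)[0])
    return {"fraction_toward_mid": fraction, "slope": slope,
            "n": int(young.size), "n_changed": int(moved.sum())}
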