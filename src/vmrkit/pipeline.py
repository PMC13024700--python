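"""End-to-end orchestration: simulate -> tile/filter -> VMR -> DMR -> enrichment.

A run is fully described by a YAML config; every stochastic stage has
its own seed, all outputs are plain text (TSV/BED/JSON), and a
provenance manifest records the config, seeds and output hashes so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dmr import call_dmrs, dmr_test, rank_by_change
from .io import (
    MethylationMatrix,
    build_matrix,
    filter_coverage,
    filter_sites,
    normalize_coverage,
    read_cytosine_report,
    tile_windows,
    write_bed,
)
from .overlap import gsea_enrichment, overlap_test
from .shift_model import ShiftModelConfig, analytic_max_shift, simulate_shift
from .synthetic import CoverageModel, generate_truth, simulate_counts, write_cytosine_reports
from .vmr import call_vmrs, variance_threshold, window_variance

__all__ = ["RunConfig", "run_pipeline", "matrix_from_reports"]

log = logging.getLogger("vmrkit")


@dataclass
class RunConfig:
    """Validated run configuration; defaults mirror the standard pipeline
    (100-bp windows, 10x minimum coverage, 99.9th-percentile cap, q < 0.05)."""

    outdir: str = "vmrkit_run"
    window_size: int = 100
    min_coverage: int = 10
    upper_percentile: float = 99.9
    q_threshold: float = 0.05
    group_a: str = "young"
    group_b: str = "old"
    # simulate stage
    n_windows: int = 2000
    frac_vmr: float = 0.1
    n_per_group: int = 8
    group_effect: float = 1.0
    sim_seed: int = 1
    coverage: CoverageModel = field(default_factory=CoverageModel)
    write_reports: bool = False
    # optional real input: directory of cytosine reports + group map
    input_reports: dict[str, str] | None = None  # sample -> path
    input_groups: dict[str, str] | None = None  # sample -> group
    # enrichment stage
    n_perm: int = 1000
    gsea_seed: int = 7
    extreme_frac: float = 0.05
    # shift-model stage
    shift_seed: int = 3
    shift_n_cells: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        sections = {
            "windows": {"window_size", "min_coverage", "upper_percentile"},
            "dmr": {"q_threshold"},
            "groups": {"a", "b"},
            "simulate": {
                "n_windows", "frac_vmr", "n_per_group", "group_effect",
                "seed", "coverage", "write_reports",
            },
            "input": {"reports", "groups"},
            "gsea": {"n_perm", "seed", "extreme_frac"},
            "shift_model": {"seed", "n_cells"},
        }
        unknown = set(raw) - set(sections) - {"outdir"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg.outdir = raw.get("outdir", cfg.outdir)
        for section, keys in sections.items():
            sub = raw.get(section, {}) or {}
            bad = set(sub) - keys
            if bad:
                raise ValueError(f"unknown keys in '{section}': {sorted(bad)}")
        w = raw.get("windows", {}) or {}
        cfg.window_size = int(w.get("window_size", cfg.window_size))
        cfg.min_coverage = int(w.get("min_coverage", cfg.min_coverage))
        cfg.upper_percentile = float(w.get("upper_percentile", cfg.upper_percentile))
        cfg.q_threshold = float((raw.get("dmr", {}) or {}).get("q_threshold", cfg.q_threshold))
        g = raw.get("groups", {}) or {}
        cfg.group_a = g.get("a", cfg.group_a)
        cfg.group_b = g.get("b", cfg.group_b)
        s = raw.get("simulate", {}) or {}
        cfg.n_windows = int(s.get("n_windows", cfg.n_windows))
        cfg.frac_vmr = float(s.get("frac_vmr", cfg.frac_vmr))
        cfg.n_per_group = int(s.get("n_per_group", cfg.n_per_group))
        cfg.group_effect = float(s.get("group_effect", cfg.group_effect))
        cfg.sim_seed = int(s.get("seed", cfg.sim_seed))
        cfg.write_reports = bool(s.get("write_reports", cfg.write_reports))
        if "coverage" in s:
            cfg.coverage = CoverageModel(**s["coverage"])
        inp = raw.get("input", {}) or {}
        cfg.input_reports = inp.get("reports")
        cfg.input_groups = inp.get("groups")
        if cfg.input_reports is not None:
            if cfg.input_groups is None:
                raise ValueError("input.groups is required with input.reports")
            for sample, p in cfg.input_reports.items():
                if not Path(p).exists():
                    raise ValueError(f"input report for {sample!r} not found: {p}")
        e = raw.get("gsea", {}) or {}
        cfg.n_perm = int(e.get("n_perm", cfg.n_perm))
        cfg.gsea_seed = int(e.get("seed", cfg.gsea_seed))
        cfg.extreme_frac = float(e.get("extreme_frac", cfg.extreme_frac))
        sm = raw.get("shift_model", {}) or {}
        cfg.shift_seed = int(sm.get("seed", cfg.shift_seed))
        cfg.shift_n_cells = int(sm.get("n_cells", cfg.shift_n_cells))
        if cfg.window_size <= 0 or cfg.min_coverage < 0:
            raise ValueError("window_size must be positive and min_coverage >= 0")
        if not 0 < cfg.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        return cfg


def matrix_from_reports(
    reports: dict[str, str],
    groups: dict[str, str],
    window_size: int = 100,
    min_coverage: int = 10,
    upper_percentile: float = 99.9,
) -> MethylationMatrix:
    """Read cytosine reports, filter sites, tile, and intersect the universe."""
    counts = {}
    for sample, path in reports.items():
        rec = read_cytosine_report(path)
        rec = filter_sites(rec, min_cov=min_coverage, upper_percentile=upper_percentile)
        counts[sample] = tile_windows(rec, window_size=window_size)
    matrix = build_matrix(counts, groups)
    return filter_coverage(matrix, min_cov=min_coverage, upper_percentile=None)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order and write a provenance manifest.

    Returns the manifest dict; all artifacts land under ``config.outdir``.
    """
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "vmrkit", "version": __version__, "stages": {}}
    state = outdir / "STATE"
    state.write_text("running\n")

    try:
        # --- stage 1: counts ------------------------------------------------
        if config.input_reports:
            log.info("reading %d cytosine reports", len(config.input_reports))
            matrix = matrix_from_reports(
                config.input_reports, config.input_groups,
                window_size=config.window_size,
                min_coverage=config.min_coverage,
                upper_percentile=config.upper_percentile,
            )
            truth = None
        else:
            log.info("simulating methylome (%d windows, seed %d)",
                     config.n_windows, config.sim_seed)
            truth = generate_truth(
                config.n_windows, config.frac_vmr, seed=config.sim_seed,
                window_size=config.window_size,
            )
            sim = simulate_counts(
                truth, n_per_group=config.n_per_group, coverage=config.coverage,
                group_effect=config.group_effect, seed=config.sim_seed,
                group_names=(config.group_a, config.group_b),
            )
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            if config.write_reports:
                report_dir = outdir / "reports"
                paths = write_cytosine_reports(sim, report_dir)
                matrix = matrix_from_reports(
                    {Path(p).name.split(".")[0]: p for p in paths},
                    sim.groups.to_dict(),
                    window_size=config.window_size,
                    min_coverage=config.min_coverage,
                    upper_percentile=config.upper_percentile,
                )
            else:
                matrix = filter_coverage(
                    sim.to_matrix(), min_cov=config.min_coverage,
                    upper_percentile=config.upper_percentile,
                )
        matrix = normalize_coverage(matrix)
        matrix.to_tsv(outdir / "matrix.tsv")
        manifest["stages"]["matrix"] = {
            "n_windows": matrix.n_windows, "samples": matrix.samples,
        }

        # --- stage 2: VMRs per group ---------------------------------------
        vmr_sets = {}
        for group in (config.group_a, config.group_b):
            profile = window_variance(matrix, group)
            variance_threshold(profile)
            vmr, _ = call_vmrs(profile)
            vmr_sets[group] = vmr
            vt = profile.frame.sort_values("rank")
            vt.to_csv(outdir / f"variance_{group}.tsv", sep="\t",
                      index_label="window_id")
            bed = matrix.windows.loc[vmr].copy()
            bed["score_src"] = profile.v.loc[vmr]
            write_bed(bed.assign(name=[f"vmr_{i}" for i in vmr]),
                      outdir / f"vmr_{group}.bed", score="score_src")
            manifest["stages"][f"vmr_{group}"] = {
                "n_vmr": int(len(vmr)),
                "threshold": profile.threshold_value,
                "threshold_rank": profile.threshold_rank,
            }
            log.info("group %s: %d VMRs (tau=%.3g)", group, len(vmr),
                     profile.threshold_value)

        # --- stage 3: DMRs -------------------------------------------------
        records = call_dmrs(
            dmr_test(matrix, config.group_a, config.group_b),
            q_threshold=config.q_threshold,
        )
        records.to_csv(outdir / "dmr.tsv", sep="\t", index_label="window_id")
        dmr_ids = records.index[records["is_dmr"]]
        if len(dmr_ids):
            write_bed(
                matrix.windows.loc[dmr_ids].assign(
                    name=[f"dmr_{i}" for i in dmr_ids]),
                outdir / "dmr.bed",
            )
        manifest["stages"]["dmr"] = {"n_dmr": int(len(dmr_ids)),
                                     "q_threshold": config.q_threshold}
        log.info("%d DMRs at q < %g", len(dmr_ids), config.q_threshold)

        # --- stage 4: overlap + GSEA ---------------------------------------
        universe = matrix.windows.index
        ov = overlap_test(vmr_sets[config.group_a], vmr_sets[config.group_b],
                          universe)
        ranked = rank_by_change(records)
        curve = gsea_enrichment(
            ranked.index.to_numpy(), vmr_sets[config.group_a],
            n_perm=config.n_perm, seed=config.gsea_seed,
            extreme_frac=config.extreme_frac,
        )
        pd.DataFrame({
            "rank": np.arange(len(curve.running)),
            "running": curve.running,
        }).to_csv(outdir / "gsea_running.tsv", sep="\t", index=False)
        enrich = {
            "vmr_overlap": ov.as_dict(),
            "gsea": {
                "es": curve.es, "p_es": curve.p_es,
                "extreme_k": curve.extreme_k,
                "extreme_observed": curve.extreme_observed,
                "extreme_fraction": curve.extreme_fraction,
                "p_extremes": curve.p_extremes,
                "n_perm": curve.n_perm,
            },
        }
        (outdir / "enrichment.json").write_text(json.dumps(enrich, indent=2) + "\n")
        manifest["stages"]["enrichment"] = enrich

        # --- stage 5: shift model ------------------------------------------
        shift = {}
        for mode, m0 in (("variance", 0.0), ("coordinated", 0.0)):
            res = simulate_shift(ShiftModelConfig(
                m0=m0, mode=mode, n_cells=config.shift_n_cells,
                seed=config.shift_seed,
            ))
            shift[mode] = {
                "delta_pp": res.delta_pp,
                "expected_delta_pp": res.expected_delta_pp,
                "analytic_max": analytic_max_shift(mode),
            }
        (outdir / "shift_model.json").write_text(json.dumps(shift, indent=2) + "\n")
        manifest["stages"]["shift_model"] = shift

        # --- manifest ------------------------------------------------------
        manifest["config"] = {
            k: (asdict(v) if isinstance(v, CoverageModel) else v)
            for k, v in asdict(config).items()
        }
        artifacts = sorted(
            p for pat in ("*.tsv", "*.bed", "*.json") for p in outdir.glob(pat)
            if p.name != "manifest.json"
        )
        manifest["outputs"] = {p.name: _sha256(p) for p in artifacts}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True) + "\n")
        state.write_text("ok\n")
        log.info("pipeline finished in %.1f s", time.monotonic() - t0)
        return manifest
    except Exception:
        state.write_text("failed\n")
        raise
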