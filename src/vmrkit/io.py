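"""Reading per-CpG bisulfite counts, tiling windows, and the cross-sample matrix.

Coordinate conventions: cytosine reports and coverage files are 1-based
(Bismark); everything internal and every BED written is 0-based
half-open. A CpG at 1-based position p lands in the 100-bp tile
[((p-1)//100)*100, ((p-1)//100)*100 + 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "MethylationMatrix",
    "read_cytosine_report",
    "merge_cpg_dyads",
    "filter_sites",
    "tile_windows",
    "build_matrix",
    "filter_coverage",
    "normalize_coverage",
    "read_bed",
    "write_bed",
]

_REPORT_COLS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]
_COVERAGE_COLS = ["chrom", "pos", "end", "pct", "n_meth", "n_unmeth"]
_RECORD_COLS = ["chrom", "pos", "strand", "n_meth", "n_unmeth"]


class ParseError(ValueError):
    """Malformed row in a counts file; carries the 1-based line number."""


def read_cytosine_report(path) -> pd.DataFrame:
    """Parse a Bismark cytosine report (7 columns) or coverage file (6 columns).

    The dialect is auto-detected from the column count of the first data
    line. Cytosine-report rows outside CpG context are dropped; coverage
    files carry no strand, so '+' is recorded. Output is sorted by
    (chrom, pos).
    """
    path = Path(path)
    with open(path) as fh:
        first = None
        for line in fh:
            if line.strip():
                first = line
                break
    if first is None:
        return pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in zip(_RECORD_COLS, [str, np.int64, str, np.int64, np.int64])}
        )
    ncol = len(first.rstrip("\n").split("\t"))
    if ncol == 7:
        names, dialect = _REPORT_COLS, "report"
    elif ncol == 6:
        names, dialect = _COVERAGE_COLS, "coverage"
    else:
        raise ParseError(f"{path}: line 1: expected 6 or 7 tab-separated columns, got {ncol}")

    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
        for col in ("pos", "n_meth", "n_unmeth"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    except (ValueError, TypeError):
        _locate_bad_line(path, ncol)
        raise
    if dialect == "report":
        df = df[df["context"] == "CG"]
    else:
        df = df.assign(strand="+")
    if (df[["n_meth", "n_unmeth"]] < 0).any().any():
        raise ParseError(f"{path}: negative counts")
    df = df[_RECORD_COLS].sort_values(["chrom", "pos"], kind="mergesort")
    return df.reset_index(drop=True)


def _locate_bad_line(path: Path, ncol: int) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ParseError(f"{path}: line {i}: expected {ncol} columns, got {len(fields)}")
            try:
                int(fields[1]), int(fields[4]), int(fields[5] if ncol == 6 else fields[4])
                if ncol == 7:
                    int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}: line {i}: non-numeric count field") from None


def merge_cpg_dyads(records: pd.DataFrame) -> pd.DataFrame:
    """Sum counts of a '+' CpG at p with its '−' partner at p+1 (destranding).

    Off by default throughout the package; merged records keep the
    plus-strand coordinate.
    """
    rec = records.copy()
    minus = rec["strand"] == "-"
    rec.loc[minus, "pos"] = rec.loc[minus, "pos"] - 1
    out = (
        rec.groupby(["chrom", "pos"], as_index=False)[["n_meth", "n_unmeth"]]
        .sum()
        .assign(strand="+")
    )
    return out[_RECORD_COLS].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def filter_sites(
    records: pd.DataFrame, min_cov: int = 10, upper_percentile: float = 99.9
) -> pd.DataFrame:
    """Drop CpG sites below ``min_cov`` or above this sample's coverage percentile."""
    cov = records["n_meth"] + records["n_unmeth"]
    keep = cov >= min_cov
    if len(records) and upper_percentile is not None:
        cap = np.percentile(cov.to_numpy(), upper_percentile)
        keep &= cov <= cap
    return records[keep].reset_index(drop=True)


def tile_windows(records: pd.DataFrame, window_size: int = 100) -> pd.DataFrame:
    """Sum per-CpG counts into non-overlapping genomic tiles.

    Returns one row per covered window with chrom, 0-based start/end and
    the summed (n_meth, n_total); the weighted methylation level of a
    window is n_meth / n_total. Total counts are conserved exactly.
    """
    if records.empty:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str)}
            | {c: pd.Series(dtype=np.int64) for c in ["start", "end", "n_meth", "n_total"]}
        )
    rec = records.assign(
        start=((records["pos"] - 1) // window_size) * window_size,
        n_total=records["n_meth"] + records["n_unmeth"],
    )
    out = rec.groupby(["chrom", "start"], as_index=False)[["n_meth", "n_total"]].sum()
    out["end"] = out["start"] + window_size
    out = out[["chrom", "start", "end", "n_meth", "n_total"]]
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


@dataclass
class MethylationMatrix:
    """Windows x samples table of (methylated, total) counts with group labels.

    Every retained window is covered in every sample (intersection
    universe), mirroring how overlapping-region universes are defined
    when two sample sets are compared.
    """

    windows: pd.DataFrame  # index window_id; columns chrom, start, end
    meth: pd.DataFrame  # index window_id; columns samples
    total: pd.DataFrame
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if list(self.meth.columns) != list(self.total.columns):
            raise ValueError("meth/total sample columns differ")
        if not self.meth.index.equals(self.total.index) or not self.meth.index.equals(
            self.windows.index
        ):
            raise ValueError("window indices differ across components")
        missing = [s for s in self.meth.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def m(self) -> pd.DataFrame:
        """Weighted methylation level per (window, sample)."""
        return self.meth / self.total

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def samples_in(self, group: str) -> list[str]:
        out = [s for s in self.samples if self.groups[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    def check_invariants(self, min_coverage: int = 1) -> None:
        if (self.total < min_coverage).any().any():
            raise AssertionError("cell below minimum coverage")
        if ((self.meth > self.total) | (self.meth < 0)).any().any():
            raise AssertionError("methylated counts outside [0, total]")

    def subset(self, window_ids) -> "MethylationMatrix":
        idx = pd.Index(window_ids)
        return MethylationMatrix(
            windows=self.windows.loc[idx],
            meth=self.meth.loc[idx],
            total=self.total.loc[idx],
            groups=self.groups,
        )

    # --- plain-text persistence -------------------------------------------

    def to_tsv(self, path) -> None:
        path = Path(path)
        wide = self.windows.copy()
        for s in self.samples:
            wide[f"{s}.meth"] = self.meth[s]
            wide[f"{s}.total"] = self.total[s]
        with open(path, "w") as fh:
            labels = "\t".join(f"{s}={self.groups[s]}" for s in self.samples)
            fh.write(f"#groups\t{labels}\n")
            wide.to_csv(fh, sep="\t", index_label="window_id")

    @classmethod
    def from_tsv(cls, path) -> "MethylationMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#groups"):
                raise ParseError(f"{path}: missing #groups header line")
            pairs = [tok.split("=", 1) for tok in header.rstrip("\n").split("\t")[1:]]
            groups = pd.Series({s: g for s, g in pairs}, name="group")
            body = pd.read_csv(fh, sep="\t", index_col="window_id")
        samples = list(groups.index)
        meth = body[[f"{s}.meth" for s in samples]].copy()
        meth.columns = samples
        total = body[[f"{s}.total" for s in samples]].copy()
        total.columns = samples
        return cls(
            windows=body[["chrom", "start", "end"]],
            meth=meth.astype(np.int64),
            total=total.astype(np.int64),
            groups=groups,
        )


def build_matrix(
    window_counts: dict[str, pd.DataFrame], groups: dict[str, str]
) -> MethylationMatrix:
    """Assemble per-sample tiled counts into the intersection-universe matrix.

    ``window_counts`` maps sample name to a :func:`tile_windows` frame.
    Only windows covered in every sample are retained.
    """
    if not window_counts:
        raise ValueError("no samples supplied")
    frames = {}
    for sample, df in window_counts.items():
        frames[sample] = df.set_index(["chrom", "start", "end"])[["n_meth", "n_total"]]
    common = None
    for df in frames.values():
        common = df.index if common is None else common.intersection(df.index)
    if common.empty:
        raise ValueError("no window is covered in all samples")
    windows = pd.DataFrame(list(common), columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], kind="mergesort"
    )
    windows.index = pd.RangeIndex(len(windows), name="window_id")
    key = pd.MultiIndex.from_frame(windows)
    samples = list(window_counts)
    meth = pd.DataFrame(
        {s: frames[s]["n_meth"].reindex(key).to_numpy() for s in samples},
        index=windows.index,
    )
    total = pd.DataFrame(
        {s: frames[s]["n_total"].reindex(key).to_numpy() for s in samples},
        index=windows.index,
    )
    return MethylationMatrix(
        windows=windows,
        meth=meth.astype(np.int64),
        total=total.astype(np.int64),
        groups=pd.Series(groups, name="group").loc[samples],
    )


def filter_coverage(
    matrix: MethylationMatrix, min_cov: int = 10, upper_percentile: float = 99.9
) -> MethylationMatrix:
    """Remove low- and extreme-coverage cells, then re-intersect the universe.

    A cell is dropped when its total is below ``min_cov`` or above the
    per-sample coverage percentile (guards against PCR-duplicated or
    repetitive pileups); any window no longer covered in every sample is
    dropped entirely. Raises if nothing survives.
    """
    total = matrix.total
    keep = total >= min_cov
    if upper_percentile is not None:
        caps = total.apply(lambda col: np.percentile(col.to_numpy(), upper_percentile))
        keep &= total.le(caps, axis=1)
    rows = keep.all(axis=1)
    if not rows.any():
        raise ValueError("coverage filtering removed every window")
    idx = matrix.windows.index[rows]
    return matrix.subset(idx)


def normalize_coverage(matrix: MethylationMatrix) -> MethylationMatrix:
    """Scale each sample's counts to the median of per-sample median coverages.

    Counts are rounded to the nearest integer (ties to even) with
    methylated counts re-derived from the sample's methylation level so
    0 <= m <= 1 survives rounding and m moves by less than 1/total per cell.
    """
    if len(matrix.samples) < 2:
        raise ValueError("normalization needs >= 2 samples")
    medians = matrix.total.median(axis=0)
    if (medians <= 0).any():
        raise ValueError("zero median coverage in at least one sample")
    target = float(np.median(medians.to_numpy()))
    factors = target / medians
    m = matrix.m
    new_total = np.rint(matrix.total * factors).clip(lower=1).astype(np.int64)
    new_meth = np.rint(m * new_total).clip(lower=0).astype(np.int64)
    new_meth = new_meth.where(new_meth <= new_total, new_total)
    return MethylationMatrix(
        windows=matrix.windows.copy(),
        meth=new_meth,
        total=new_total,
        groups=matrix.groups,
    )


# --- BED ------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read BED3-6 into chrom/start/end(/name/score/strand), 0-based half-open."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: interval with end <= start")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path, score: str | None = None) -> None:
    """Write BED6; missing name/score/strand columns are filled with defaults."""
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"region_{i}" for i in range(len(out))]
    if score is not None:
        out["score"] = np.minimum(np.asarray(out[score], dtype=float) * 1000, 1000).astype(int)
    elif "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )
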