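"""DMR calling: threshold seeding, iterative edge extension, annotation.

A DMR starts from any window with exact-test p below the seed threshold
(default 1e-05).  Its edges are then extended: any tested window with
p below the extension threshold (default 0.1) lying within 1000 bp of
the current span is absorbed, and the process repeats until no such
window remains — equivalently, extension-qualified windows chain into
single-linkage clusters whenever consecutive ones are separated by at
most the neighbourhood distance, and a DMR is the span of any cluster
containing at least one seed.  Distances are edge-to-edge, so an
immediately adjacent window (gap 0) always qualifies.  Windows removed
by the depth filter carry no p value: they cannot trigger or block
extension but are spanned when flanked.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeIndex

DEFAULT_P_SEED = 1e-5
DEFAULT_P_EXTEND = 0.1
DEFAULT_NEIGHBORHOOD_BP = 1000


class DmrError(ValueError):
    pass


@dataclass(frozen=True)
class DMR:
    """A called differential methylation region (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    n_significant_windows: int
    min_p: float
    fdr_at_min: float
    log2fc: float  # from the minimum-p window; positive = hypermethylated in cases
    cpg_count: int | None = None
    cpg_per_100bp: float | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise DmrError(f"empty DMR span {self.chromosome}:{self.start}-{self.end}")
        if self.n_significant_windows < 1:
            raise DmrError("a DMR must contain at least one significant window")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"

    def overlaps(self, other: "DMR") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


def _check_sorted(df: pd.DataFrame) -> None:
    prev: tuple[str, int] | None = None
    seen: set[str] = set()
    last_chrom = None
    for chrom, start in zip(df["chromosome"], df["start"]):
        if chrom != last_chrom:
            if chrom in seen:
                raise DmrError("results are not sorted by chromosome and position")
            seen.add(chrom)
            last_chrom = chrom
            prev = None
        if prev is not None and start < prev:
            raise DmrError("results are not sorted by chromosome and position")
        prev = start


def call_dmrs(
    results: pd.DataFrame,
    p_seed: float = DEFAULT_P_SEED,
    p_extend: float = DEFAULT_P_EXTEND,
    neighborhood_bp: int = DEFAULT_NEIGHBORHOOD_BP,
) -> list[DMR]:
    """Call DMRs from sorted per-window test results.

    ``results`` needs columns chromosome, start, end, p_value, log2fc
    (``fdr`` used when present), sorted by chromosome then start, and
    may contain only the depth-filtered (tested) windows.
    """
    for thr, name in ((p_seed, "p_seed"), (p_extend, "p_extend")):
        if not (0 < thr < 1):
            raise DmrError(f"{name} must be in (0, 1), got {thr}")
    if p_seed > p_extend:
        raise DmrError("p_seed must not exceed p_extend")
    if neighborhood_bp < 0:
        raise DmrError("neighborhood_bp must be >= 0")
    _check_sorted(results)

    has_fdr = "fdr" in results.columns
    dmrs: list[DMR] = []
    for chrom, sub in results.groupby("chromosome", sort=False):
        ext = sub[sub["p_value"] < p_extend]
        if ext.empty:
            continue
        starts = ext["start"].to_numpy()
        ends = ext["end"].to_numpy()
        # single-linkage chaining of extension-qualified windows
        breaks = np.flatnonzero(starts[1:] - ends[:-1] > neighborhood_bp)
        cluster_bounds = zip(
            np.concatenate(([0], breaks + 1)),
            np.concatenate((breaks + 1, [len(ext)])),
        )
        for lo, hi in cluster_bounds:
            cluster = ext.iloc[lo:hi]
            seeds = cluster[cluster["p_value"] < p_seed]
            if seeds.empty:
                continue
            best = cluster.loc[cluster["p_value"].idxmin()]
            dmrs.append(
                DMR(
                    chromosome=str(chrom),
                    start=int(cluster["start"].iloc[0]),
                    end=int(cluster["end"].iloc[-1]),
                    n_significant_windows=int(len(seeds)),
                    min_p=float(best["p_value"]),
                    fdr_at_min=float(best["fdr"]) if has_fdr else float("nan"),
                    log2fc=float(best["log2fc"]),
                )
            )
    # clusters are separated by > neighborhood_bp, but merge defensively
    return _merge_overlapping(dmrs)


def _merge_overlapping(dmrs: list[DMR]) -> list[DMR]:
    merged: list[DMR] = []
    for dmr in sorted(dmrs, key=lambda d: (d.chromosome, d.start)):
        if merged and merged[-1].chromosome == dmr.chromosome and dmr.start <= merged[-1].end:
            prev = merged[-1]
            keep_prev = prev.min_p <= dmr.min_p
            merged[-1] = replace(
                prev,
                end=max(prev.end, dmr.end),
                n_significant_windows=prev.n_significant_windows
                + dmr.n_significant_windows,
                min_p=min(prev.min_p, dmr.min_p),
                fdr_at_min=prev.fdr_at_min if keep_prev else dmr.fdr_at_min,
                log2fc=prev.log2fc if keep_prev else dmr.log2fc,
            )
        else:
            merged.append(dmr)
    return merged


def annotate_dmr(dmr: DMR, genome: GenomeIndex) -> DMR:
    """Fill CpG count and density from the reference sequence.

    A CG dinucleotide straddling the right edge counts when its C lies
    inside the span.
    """
    count = genome.cpg_count(dmr.chromosome, dmr.start, dmr.end)
    return replace(
        dmr,
        cpg_count=count,
        cpg_per_100bp=100.0 * count / dmr.length_bp,
    )


def annotate_dmrs(dmrs: Sequence[DMR], genome: GenomeIndex) -> list[DMR]:
    return [annotate_dmr(d, genome) for d in dmrs]


def threshold_table(
    results: pd.DataFrame,
    thresholds: Sequence[float],
    p_extend: float = DEFAULT_P_EXTEND,
    neighborhood_bp: int = DEFAULT_NEIGHBORHOOD_BP,
) -> pd.DataFrame:
    """DMR counts at a ladder of seed thresholds.

    For each threshold the caller is re-run with that seed p; the table
    reports all DMRs and those containing at least two significant
    windows (the "multiple window" DMRs).
    """
    rows = []
    for t in thresholds:
        if not (0 < t < 1):
            raise DmrError(f"threshold must be in (0, 1), got {t}")
        called = call_dmrs(
            results, p_seed=t, p_extend=max(t, p_extend), neighborhood_bp=neighborhood_bp
        )
        rows.append(
            {
                "threshold": t,
                "all_window": len(called),
                "multiple_window": sum(
                    1 for d in called if d.n_significant_windows >= 2
                ),
            }
        )
    return pd.DataFrame(rows)


def window_histogram(dmrs: Sequence[DMR]) -> pd.Series:
    """DMR counts keyed by number of significant windows."""
    counts = pd.Series([d.n_significant_windows for d in dmrs], dtype=int)
    return counts.value_counts().sort_index()


def size_histogram(dmrs: Sequence[DMR]) -> pd.Series:
    """DMR counts by length class: '1kb', '2kb', '>=3kb'."""
    def classify(length: int) -> str:
        if length <= 1000:
            return "1kb"
        if length <= 2000:
            return "2kb"
        return ">=3kb"

    hist = pd.Series([classify(d.length_bp) for d in dmrs])
    return hist.value_counts().reindex(["1kb", "2kb", ">=3kb"], fill_value=0)


def per_chromosome_counts(dmrs: Sequence[DMR]) -> pd.Series:
    return pd.Series([d.chromosome for d in dmrs]).value_counts().sort_index()


# --------------------------------------------------------------------- I/O

_BED_COLUMNS = [
    "chromosome", "start", "end", "name", "score", "strand",
    "n_significant_windows", "log2fc", "cpg_count", "cpg_per_100bp", "fdr",
]


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    rows = []
    for d in dmrs:
        score = int(round(min(-10.0 * np.log10(max(d.min_p, 1e-300)), 1000)))
        rows.append(
            {
                "chromosome": d.chromosome,
                "start": d.start,
                "end": d.end,
                "name": d.name,
                "score": score,
                "strand": ".",
                "n_significant_windows": d.n_significant_windows,
                "log2fc": d.log2fc,
                "cpg_count": -1 if d.cpg_count is None else d.cpg_count,
                "cpg_per_100bp": float("nan")
                if d.cpg_per_100bp is None
                else d.cpg_per_100bp,
                "fdr": d.fdr_at_min,
                "min_p": d.min_p,
                "length_bp": d.length_bp,
            }
        )
    return pd.DataFrame(rows, columns=_BED_COLUMNS + ["min_p", "length_bp"])


def write_dmr_bed(dmrs: Sequence[DMR], path: str | Path) -> None:
    """BED6+ with extra columns; a #header names every column."""
    df = dmrs_to_frame(dmrs)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_dmr_bed(path: str | Path) -> list[DMR]:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise DmrError(f"{path}: missing #header line naming columns")
    columns = header[1:].rstrip("\n").split("\t")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=columns)
    missing = {"chromosome", "start", "end", "min_p", "log2fc"} - set(columns)
    if missing:
        raise DmrError(f"{path}: missing columns {sorted(missing)}")
    dmrs = []
    for r in df.itertuples():
        cpg = int(r.cpg_count) if "cpg_count" in columns else -1
        dmrs.append(
            DMR(
                chromosome=str(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                n_significant_windows=int(getattr(r, "n_significant_windows", 1)),
                min_p=float(r.min_p),
                fdr_at_min=float(getattr(r, "fdr", float("nan"))),
                log2fc=float(r.log2fc),
                cpg_count=None if cpg < 0 else cpg,
                cpg_per_100bp=None
                if cpg < 0
                else float(getattr(r, "cpg_per_100bp")),
            )
        )
    return dmrs


def write_dmr_tsv(dmrs: Sequence[DMR], path: str | Path) -> None:
    """Flat table mirroring the per-DMR report layout."""
    df = dmrs_to_frame(dmrs)[
        ["name", "chromosome", "start", "length_bp", "log2fc",
         "min_p", "fdr", "n_significant_windows", "cpg_count", "cpg_per_100bp"]
    ]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
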