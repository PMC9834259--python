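"""Genome tiling, deduplicated read counting, and the depth filter.

The unit of analysis is a 1000 bp genomic window.  Reads are counted per
(window, sample) after removing PCR duplicates — records sharing a
chromosome, 5' alignment coordinate, and strand within one sample — and
each retained read is assigned to the single window containing its
midpoint.  Library sizes are the per-sample deduplicated totals over the
whole genome, fixed *before* any window filtering so that normalization
reflects sequencing effort rather than the analysis subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeIndex

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 1000


class WindowError(ValueError):
    pass


class DesignError(ValueError):
    """A sample in the data is missing from the design table."""


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """A tile of the reference genome, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    index: int  # ordinal within its chromosome

    def __post_init__(self):
        if self.end <= self.start:
            raise WindowError(f"empty window {self.chromosome}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


def tile_genome(
    genome: GenomeIndex, window_size: int = DEFAULT_WINDOW_SIZE
) -> list[GenomicWindow]:
    """Tile every chromosome into consecutive ``window_size`` bp windows.

    The final window of each chromosome is truncated at the chromosome end,
    so the union of windows covers every base exactly once.
    """
    if window_size < 1:
        raise WindowError(f"window_size must be >= 1, got {window_size}")
    tiles: list[GenomicWindow] = []
    for name, length in genome.chromosomes:
        n_full, rest = divmod(length, window_size)
        for i in range(n_full):
            tiles.append(
                GenomicWindow(name, i * window_size, (i + 1) * window_size, i)
            )
        if rest:
            tiles.append(
                GenomicWindow(name, n_full * window_size, length, n_full)
            )
    return tiles


@dataclass
class CountMatrix:
    """Deduplicated read counts per (window, sample), plus design metadata.

    ``library_sizes`` are the column sums over *all* windows before any
    filtering; ``filter_windows`` preserves them.
    """

    windows: list[GenomicWindow]
    samples: list[str]
    counts: np.ndarray  # shape (n_windows, n_samples), integer
    library_sizes: np.ndarray  # shape (n_samples,)
    design: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise WindowError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.windows)} windows x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise WindowError("negative counts")
        missing = [s for s in self.samples if s not in self.design]
        if missing:
            raise DesignError(f"samples missing from design: {missing}")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.design[s] == group]

    def group_columns(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.design[s] == group]
        )

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.design[s], None)
        return list(seen)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chromosome": [w.chromosome for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "index": [w.index for w in self.windows],
            }
        )
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        return df

    def write_tsv(self, path: str | Path) -> None:
        """Write counts as TSV; library sizes and design ride in # headers."""
        with open(path, "w") as fh:
            libs = "\t".join(
                f"{s}={int(l)}" for s, l in zip(self.samples, self.library_sizes)
            )
            groups = "\t".join(f"{s}={self.design[s]}" for s in self.samples)
            fh.write(f"#library_sizes\t{libs}\n")
            fh.write(f"#design\t{groups}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        libs: dict[str, int] = {}
        design: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                tag, *fields = line.rstrip("\n").split("\t")
                pairs = dict(f.split("=", 1) for f in fields)
                if tag == "#library_sizes":
                    libs = {k: int(v) for k, v in pairs.items()}
                elif tag == "#design":
                    design = pairs
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"chromosome", "start", "end", "index"}
        missing = required - set(df.columns)
        if missing:
            raise WindowError(f"count TSV missing columns: {sorted(missing)}")
        samples = [c for c in df.columns if c not in required]
        windows = [
            GenomicWindow(r.chromosome, int(r.start), int(r.end), int(r.index))
            for r in df.itertuples()
        ]
        counts = df[samples].to_numpy(dtype=np.int64)
        if not libs:
            libs = {s: int(c) for s, c in zip(samples, counts.sum(axis=0))}
        return cls(
            windows=windows,
            samples=samples,
            counts=counts,
            library_sizes=np.array([libs[s] for s in samples], dtype=np.int64),
            design=design,
        )


def write_windows_bed(windows: Sequence[GenomicWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chromosome}\t{w.start}\t{w.end}\t{w.name}\n")


def _window_lookup(
    windows: Sequence[GenomicWindow],
) -> tuple[dict[str, tuple[int, int, int]], dict[tuple[str, int], int]]:
    """Validate the per-chromosome tiling and build midpoint -> row lookup.

    Returns per-chromosome (window_size, n_windows, chrom_span) and a map
    from (chromosome, window ordinal) to matrix row.
    """
    per_chrom: dict[str, list[GenomicWindow]] = {}
    row_of: dict[tuple[str, int], int] = {}
    for row, w in enumerate(windows):
        per_chrom.setdefault(w.chromosome, []).append(w)
        row_of[(w.chromosome, w.index)] = row
    meta: dict[str, tuple[int, int, int]] = {}
    for chrom, ws in per_chrom.items():
        ws = sorted(ws, key=lambda w: w.start)
        size = ws[0].length
        for i, w in enumerate(ws):
            contiguous = w.index == i and w.start == i * size
            full = w.length == size or (i == len(ws) - 1 and w.length < size)
            if not (contiguous and full):
                raise WindowError(
                    f"windows on {chrom} are not a contiguous tiling at {w.name}"
                )
        meta[chrom] = (size, len(ws), ws[-1].end)
    return meta, row_of


def count_reads(
    sam_paths: Mapping[str, str | Path],
    windows: Sequence[GenomicWindow],
    design: Mapping[str, str],
) -> CountMatrix:
    """Count deduplicated reads per window per sample from SAM files.

    Parameters
    ----------
    sam_paths
        Mapping of sample id to SAM file path (one alignment file per
        sample).  Every sample must appear in ``design``.
    windows
        The full genome tiling (``tile_genome`` output).
    design
        Sample id -> group label.

    Unmapped records are dropped.  Duplicates — identical (chromosome,
    5' alignment coordinate, strand) within a sample — are collapsed to a
    single read.  Each retained read is assigned to the window containing
    its alignment midpoint.  Reads on chromosomes absent from the tiling
    are skipped with a warning and counted in the log.
    """
    samples = list(sam_paths)
    absent = [s for s in samples if s not in design]
    if absent:
        raise DesignError(f"samples missing from design table: {absent}")
    meta, row_of = _window_lookup(windows)

    counts = np.zeros((len(windows), len(samples)), dtype=np.int64)
    library_sizes = np.zeros(len(samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        seen: set[tuple[str, int, bool]] = set()
        n_unknown = 0
        with pysam.AlignmentFile(str(sam_paths[sample]), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                chrom = rec.reference_name
                if chrom not in meta:
                    n_unknown += 1
                    continue
                five_prime = rec.reference_end if rec.is_reverse else rec.reference_start
                key = (chrom, five_prime, rec.is_reverse)
                if key in seen:
                    continue
                seen.add(key)
                size, n_win, span = meta[chrom]
                mid = (rec.reference_start + rec.reference_end) // 2
                ordinal = min(mid // size, n_win - 1)
                counts[row_of[(chrom, ordinal)], j] += 1
                library_sizes[j] += 1
        if n_unknown:
            msg = (
                f"sample {sample}: skipped {n_unknown} reads on chromosomes "
                "absent from the window tiling"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
    return CountMatrix(
        windows=list(windows),
        samples=samples,
        counts=counts,
        library_sizes=library_sizes,
        design=dict(design),
    )


def filter_windows(matrix: CountMatrix, min_avg_depth: float = 10.0) -> CountMatrix:
    """Retain windows whose mean raw count across all samples meets the cutoff.

    Cases and controls are pooled for the mean; library sizes are left
    untouched (they were fixed pre-filter).  Idempotent.
    """
    if matrix.n_windows == 0:
        raise WindowError("empty count matrix")
    keep = matrix.counts.mean(axis=1) >= min_avg_depth
    if not keep.any():
        raise WindowError(
            f"no window has mean depth >= {min_avg_depth}; "
            "lower min_avg_depth or increase coverage"
        )
    return replace(
        matrix,
        windows=[w for w, k in zip(matrix.windows, keep) if k],
        counts=matrix.counts[keep],
    )
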