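"""Synthetic MeDIP-seq data with known spiked differential regions.

The generator produces a toy reference genome whose CpG dinucleotides
are planted at a controlled background density (the low-density "CpG
desert" regime of roughly 1-3 CpG per 100 bp where methylation
differences are typically found), then draws per-window read counts
from a negative binomial whose mean is proportional to local CpG
content — MeDIP pulls down methylated CpGs, so windows with more CpGs
attract proportionally more reads — times a per-sample library-size
factor.  Differential regions of one or two 1000 bp windows are spiked
into the case group with a signed log2 fold change, in a configurable
mix of hyper- and hypomethylated directions, and recorded as ground
truth so recovery can be scored downstream.  Counts can additionally be
realized as aligned ~50 bp single-end SAM records, optionally with
exact positional PCR duplicates, such that deduplicated recounting
reproduces the count matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .genome import GenomeIndex
from .windows import CountMatrix, GenomicWindow, tile_genome

DEFAULT_READ_LENGTH = 50


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the field."""


class PlacementError(RuntimeError):
    """Spiked regions or reads cannot be placed under the constraints."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic MeDIP experiment.

    Defaults are a desk-scale rendition of a two-group MeDIP-seq cohort:
    a couple of hundred-kilobase chromosomes instead of GRCh38, eight
    samples per group instead of ~15, and a mean of 30 deduplicated
    reads per 1000 bp window instead of tens of millions of reads per
    sample — enough depth that the 10-read average filter keeps the bulk
    of the genome.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 300_000
    background_cpg_per_100bp: float = 2.0
    n_case_samples: int = 8
    n_control_samples: int = 8
    mean_depth_per_window: float = 30.0
    dispersion: float = 0.1
    library_size_factors: Sequence[float] | None = None  # drawn lognormal if None
    n_spiked_regions: int = 20
    spike_length_bp: int | Sequence[int] = (1000, 2000)
    spike_log2fc_magnitude: float = 2.0
    fraction_up: float = 0.5
    rng_seed: int = 0
    window_size: int = 1000
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self):
        def positive_int(name: str, minimum: int = 1):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < minimum:
                raise ConfigError(f"{name} must be an integer >= {minimum}, got {v!r}")

        for name in (
            "n_chromosomes",
            "chromosome_length",
            "n_case_samples",
            "n_control_samples",
            "window_size",
            "read_length",
        ):
            positive_int(name)
        if self.n_spiked_regions < 0:
            raise ConfigError(f"n_spiked_regions must be >= 0, got {self.n_spiked_regions}")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion must be >= 0, got {self.dispersion}")
        if not (0 <= self.fraction_up <= 1):
            raise ConfigError(f"fraction_up must be in [0, 1], got {self.fraction_up}")
        if self.background_cpg_per_100bp <= 0 or self.background_cpg_per_100bp > 50:
            raise ConfigError(
                f"background_cpg_per_100bp must be in (0, 50], got {self.background_cpg_per_100bp}"
            )
        if self.mean_depth_per_window <= 0:
            raise ConfigError(
                f"mean_depth_per_window must be > 0, got {self.mean_depth_per_window}"
            )
        if self.spike_log2fc_magnitude <= 0:
            raise ConfigError(
                f"spike_log2fc_magnitude must be > 0, got {self.spike_log2fc_magnitude}"
            )
        lengths = self.spike_lengths
        if any(l < 1 or l % self.window_size for l in lengths):
            raise ConfigError(
                f"spike_length_bp must be positive multiples of window_size, got {lengths}"
            )
        if self.library_size_factors is not None:
            lf = list(self.library_size_factors)
            if len(lf) != self.n_samples or any(f <= 0 for f in lf):
                raise ConfigError(
                    "library_size_factors must list one positive factor per sample"
                )

    @property
    def spike_lengths(self) -> tuple[int, ...]:
        if isinstance(self.spike_length_bp, (int, np.integer)):
            return (int(self.spike_length_bp),)
        return tuple(int(l) for l in self.spike_length_bp)

    @property
    def n_samples(self) -> int:
        return self.n_case_samples + self.n_control_samples

    @property
    def sample_ids(self) -> list[str]:
        return [f"case_{i + 1}" for i in range(self.n_case_samples)] + [
            f"control_{i + 1}" for i in range(self.n_control_samples)
        ]

    @property
    def design(self) -> dict[str, str]:
        return {
            s: ("case" if s.startswith("case") else "control") for s in self.sample_ids
        }


@dataclass
class SyntheticTruth:
    """The spiked differential regions; positive log2fc = hyper in cases."""

    regions: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        self.regions = sorted(self.regions, key=lambda r: (r[0], r[1]))
        prev_end: dict[str, int] = {}
        for chrom, start, end, _ in self.regions:
            if end <= start or start < 0:
                raise ConfigError(f"invalid truth region {chrom}:{start}-{end}")
            if start < prev_end.get(chrom, 0):
                raise ConfigError("truth regions overlap")
            prev_end[chrom] = end

    def __len__(self) -> int:
        return len(self.regions)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[str, int, int, float]]:
        return [
            r for r in self.regions if r[0] == chrom and r[1] < end and start < r[2]
        ]

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, start, end, lfc) in enumerate(self.regions, 1):
                fh.write(f"{chrom}\t{start}\t{end}\tspike_{i}\t{lfc:.6g}\n")

    @classmethod
    def read_bed(cls, path: str | Path) -> "SyntheticTruth":
        regions = []
        with open(path) as fh:
            for line in fh:
                chrom, start, end, _name, lfc = line.rstrip("\n").split("\t")
                regions.append((chrom, int(start), int(end), float(lfc)))
        return cls(regions)


_STREAMS = {"genome": 0, "counts": 1, "reads": 2}


def _chromosome_rngs(config: SimulationConfig, stream: str) -> list[np.random.Generator]:
    """Independent per-chromosome RNG sub-streams from the run seed."""
    root = np.random.SeedSequence(config.rng_seed, spawn_key=(_STREAMS[stream],))
    return [np.random.default_rng(child) for child in root.spawn(config.n_chromosomes)]


def generate_genome(config: SimulationConfig) -> GenomeIndex:
    """Random genome with CpG dinucleotides planted at the target density.

    CG sites are planted explicitly and the remaining positions are
    filled so that no further CG pair arises (a G is never drawn right
    after a C), hence the realized CpG count equals the planted count
    and concentrates tightly around ``background_cpg_per_100bp``.
    """
    seqs: dict[str, str] = {}
    rate = config.background_cpg_per_100bp / 100.0
    for c, rng in enumerate(_chromosome_rngs(config, "genome")):
        length = config.chromosome_length
        n_sites = rng.binomial(max(length - 1, 1), rate)
        # candidate C positions on an even grid, thinned to n_sites, so
        # planted CGs never abut
        candidates = np.arange(0, length - 1, 2)
        n_sites = min(n_sites, len(candidates))
        sites = rng.choice(candidates, size=n_sites, replace=False)
        planted = np.zeros(length, dtype=np.uint8)  # 1 = planted C, 2 = planted G
        planted[sites] = 1
        planted[sites + 1] = 2

        # Fill the rest iid over ACGT, then repeatedly resample the G of
        # any spontaneous (non-planted) C-G pair from {A,C,T}; each pass
        # shrinks the spontaneous count ~12-fold, so a handful suffice.
        codes = rng.integers(0, 4, size=length).astype(np.uint8)  # A C G T
        free = planted == 0
        C, G = 1, 2
        codes[planted == 1] = C
        codes[planted == 2] = G
        for _ in range(64):
            bad = (codes[:-1] == C) & (codes[1:] == G) & free[1:]
            idx = np.flatnonzero(bad) + 1
            if idx.size == 0:
                break
            repl = rng.integers(0, 3, size=idx.size).astype(np.uint8)
            repl[repl == G] = 3  # map {0,1,2} -> {A,C,T}
            codes[idx] = repl
        else:  # pragma: no cover - astronomically unlikely
            raise PlacementError("could not eliminate spontaneous CG pairs")
        seqs[f"chr{c + 1}"] = codes.tobytes().translate(
            bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")
        ).decode("ascii")
    return GenomeIndex(seqs)


def _place_spikes(
    config: SimulationConfig,
    windows_per_chrom: dict[str, int],
    rng: np.random.Generator,
) -> list[tuple[str, int, int, float]]:
    """Window-aligned, non-overlapping spikes separated by >= 3 windows."""
    if config.n_spiked_regions == 0:
        return []
    lengths_w = [l // config.window_size for l in config.spike_lengths]
    gap_w = 3

    n = config.n_spiked_regions
    n_up = int(round(config.fraction_up * n))
    signs = np.array([1.0] * n_up + [-1.0] * (n - n_up))
    rng.shuffle(signs)
    chosen_lengths = rng.choice(lengths_w, size=n)

    chroms = list(windows_per_chrom)
    capacity = {c: windows_per_chrom[c] for c in chroms}
    # greedy sequential placement with randomized per-chromosome budget
    quota = rng.multinomial(n, np.ones(len(chroms)) / len(chroms))
    regions: list[tuple[str, int, int, float]] = []
    k = 0
    for chrom, q in zip(chroms, quota):
        if q == 0:
            continue
        lens = chosen_lengths[k : k + q]
        total_needed = int(lens.sum()) + gap_w * (q - 1)
        free = capacity[chrom] - 1 - total_needed  # reserve last (maybe partial) window
        if free < 0:
            raise PlacementError(
                f"cannot place {q} spiked regions on {chrom}: needs "
                f"{total_needed} windows, has {capacity[chrom] - 1}"
            )
        # distribute the slack uniformly among q+1 gaps
        cuts = np.sort(rng.integers(0, free + 1, size=q))
        pos_w = 0
        prev_cut = 0
        for i in range(q):
            pos_w += cuts[i] - prev_cut
            prev_cut = cuts[i]
            start = int(pos_w) * config.window_size
            end = start + int(lens[i]) * config.window_size
            regions.append(
                (chrom, start, end, float(signs[k + i]) * config.spike_log2fc_magnitude)
            )
            pos_w += int(lens[i]) + gap_w
        k += q
    return regions


def simulate_counts(
    genome: GenomeIndex, config: SimulationConfig
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw the per-(window, sample) NB count matrix and its ground truth.

    Window w, sample s: ``count ~ NB(mu_w * lib_s * effect_ws, phi)``
    with ``mu_w = depth_scale * (cpg_w + 1)`` — the +1 floor keeps
    zero-CpG windows at nonzero background, as MeDIP input is — and
    ``effect_ws = 2**log2fc`` for case samples inside a spiked region,
    1 elsewhere.  ``depth_scale`` is set so the average mu over windows
    equals ``mean_depth_per_window``.
    """
    windows = tile_genome(genome, config.window_size)
    cpg = np.array(
        [genome.cpg_count(w.chromosome, w.start, w.end) for w in windows], dtype=float
    )
    depth_scale = config.mean_depth_per_window / float(np.mean(cpg + 1.0))
    mu_w = depth_scale * (cpg + 1.0)

    rng = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=(1,))
    )
    windows_per_chrom: dict[str, int] = {}
    for w in windows:
        windows_per_chrom[w.chromosome] = windows_per_chrom.get(w.chromosome, 0) + 1
    truth = SyntheticTruth(_place_spikes(config, windows_per_chrom, rng))

    if config.library_size_factors is not None:
        lib_factors = np.asarray(config.library_size_factors, dtype=float)
    else:
        lib_factors = np.exp(rng.normal(0.0, 0.15, size=config.n_samples))

    samples = config.sample_ids
    n_case = config.n_case_samples
    effect = np.ones((len(windows), config.n_samples))
    for chrom, start, end, lfc in truth.regions:
        rows = [
            i
            for i, w in enumerate(windows)
            if w.chromosome == chrom and w.start < end and start < w.end
        ]
        effect[np.ix_(rows, range(n_case))] = 2.0 ** lfc

    mean = mu_w[:, None] * lib_factors[None, :] * effect
    if config.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam)
    counts = counts.astype(np.int64)

    matrix = CountMatrix(
        windows=windows,
        samples=samples,
        counts=counts,
        library_sizes=counts.sum(axis=0),
        design=config.design,
    )
    return matrix, truth


def emit_sam(
    matrix: CountMatrix,
    genome: GenomeIndex,
    duplicate_rate: float = 0.0,
    out_dir: str | Path = ".",
    rng_seed: int = 0,
) -> dict[str, Path]:
    """Realize the count matrix as one aligned SAM file per sample.

    Each counted read becomes a ~50 bp single-end record placed uniformly
    at random inside its window, on a random strand, with distinct
    (position, strand) within a (window, sample) so that deduplicated
    recounting reproduces the matrix exactly.  ``duplicate_rate`` is the
    expected number of exact positional duplicates emitted per read
    (Bernoulli per read for rates below one), mimicking PCR duplication.

    Returns a mapping of sample id to SAM path.
    """
    if not (0 <= duplicate_rate < 1):
        raise ConfigError(f"duplicate_rate must be in [0, 1), got {duplicate_rate}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    read_len_cfg = DEFAULT_READ_LENGTH
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.chromosomes],
    }
    ref_ids = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(2,)))

    paths: dict[str, Path] = {}
    for j, sample in enumerate(matrix.samples):
        path = out_dir / f"{sample}.sam"
        paths[sample] = path
        serial = 0
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for i, w in enumerate(matrix.windows):
                n_reads = int(matrix.counts[i, j])
                if n_reads == 0:
                    continue
                read_len = min(read_len_cfg, w.length)
                n_offsets = w.length - read_len + 1
                n_slots = 2 * n_offsets
                if n_reads > n_slots:
                    raise PlacementError(
                        f"window {w.name} needs {n_reads} distinct read "
                        f"placements but has only {n_slots}"
                    )
                slots = rng.choice(n_slots, size=n_reads, replace=False)
                dup = rng.random(n_reads) < duplicate_rate
                for slot, extra in zip(slots, dup):
                    offset, reverse = divmod(int(slot), 2)
                    start = w.start + offset
                    seq = genome.fetch(w.chromosome, start, start + read_len)
                    for _copy in range(1 + int(extra)):
                        serial += 1
                        rec = pysam.AlignedSegment()
                        rec.query_name = f"{sample}.r{serial}"
                        rec.flag = 16 if reverse else 0
                        rec.reference_id = ref_ids[w.chromosome]
                        rec.reference_start = start
                        rec.mapping_quality = 60
                        rec.cigartuples = [(0, read_len)]
                        rec.query_sequence = seq
                        sam.write(rec)
    return paths


def write_design_tsv(design: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in design.items():
            fh.write(f"{sample}\t{group}\n")


def read_design_tsv(path: str | Path) -> dict[str, str]:
    design: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "group"]:
            raise ConfigError(
                f"design TSV must have columns sample_id, group; got {header}"
            )
        for line in fh:
            if not line.strip():
                continue
            sample, group = line.rstrip("\n").split("\t")[:2]
            design[sample] = group
    return design


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Flat key: value record of the simulation conditions."""
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}: {value}\n")
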