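"""End-to-end orchestration: count -> filter -> normalize -> test -> call.

``run_pipeline`` wires the stages together from file inputs, logs each
stage with record counts and timing, and writes a JSON manifest of
inputs, parameters, versions, and output checksums so a rerun with the
same inputs can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .compare import associate_genes, associations_to_frame, read_genes_gff3
from .dmr import (
    annotate_dmrs,
    call_dmrs,
    per_chromosome_counts,
    threshold_table,
    write_dmr_bed,
    write_dmr_tsv,
)
from .genome import GenomeIndex
from .simulate import read_design_tsv
from .stats import (
    estimate_common_dispersion,
    exact_test,
    tmm_factors,
    write_results_tsv,
)
from .windows import CountMatrix, count_reads, filter_windows, tile_genome

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, parameters, and flags for a full DMR analysis run."""

    genome_fasta: str = ""
    sam_paths: dict[str, str] = field(default_factory=dict)  # sample -> SAM
    counts_tsv: str = ""  # alternative to sam_paths
    design_tsv: str = ""
    gff3: str = ""
    out_dir: str = "dmr_out"

    window_size: int = 1000
    min_avg_depth: float = 10.0
    p_seed: float = 1e-5
    p_extend: float = 0.1
    neighborhood_bp: int = 1000
    p_relaxed: float = 0.05
    gene_max_distance: int = 10_000
    case_group: str = ""
    control_group: str = ""
    rng_seed: int = 0
    keep_intermediates: bool = True
    plot: bool = False

    def validate(self) -> None:
        for name in ("p_seed", "p_extend", "p_relaxed"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise PipelineError(f"config: {name} must be in (0, 1), got {v}")
        if not self.genome_fasta:
            raise PipelineError("config: genome_fasta is required")
        if not self.sam_paths and not self.counts_tsv:
            raise PipelineError("config: provide sam_paths or counts_tsv")
        for label, path in self._input_paths():
            if not Path(path).exists():
                raise PipelineError(f"config: {label} file not found: {path}")

    def _input_paths(self) -> list[tuple[str, str]]:
        paths = [("genome_fasta", self.genome_fasta)]
        paths += [(f"sam[{s}]", p) for s, p in self.sam_paths.items()]
        for label in ("counts_tsv", "design_tsv", "gff3"):
            if getattr(self, label):
                paths.append((label, getattr(self, label)))
        return paths

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a flat key: value config file; kwargs override file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: count (or load counts) -> depth filter -> TMM -> common
    dispersion -> exact test + FDR -> DMR calling -> CpG annotation ->
    optional gene association.  Outputs land in ``config.out_dir``;
    reruns with identical inputs produce byte-identical TSV/BED files.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "medipdmr",
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("sam_paths",)
        },
        "inputs": {label: str(p) for label, p in config._input_paths()},
        "seed": config.rng_seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name: str, fn):
        t0 = time.monotonic()
        try:
            result = fn()
        except Exception as e:
            raise PipelineError(f"stage {name!r} failed: {e}") from e
        dt = time.monotonic() - t0
        logger.info("stage %s done in %.2fs", name, dt)
        return result

    genome = stage("load_genome", lambda: GenomeIndex.from_fasta(config.genome_fasta))
    manifest["stages"]["load_genome"] = {"chromosomes": len(genome.chromosomes)}

    if config.counts_tsv:
        matrix = stage("load_counts", lambda: CountMatrix.read_tsv(config.counts_tsv))
    else:
        design = stage("load_design", lambda: read_design_tsv(config.design_tsv))
        windows = tile_genome(genome, config.window_size)
        matrix = stage(
            "count", lambda: count_reads(config.sam_paths, windows, design)
        )
    manifest["stages"]["count"] = {
        "windows": matrix.n_windows,
        "samples": matrix.n_samples,
        "library_sizes": {
            s: int(l) for s, l in zip(matrix.samples, matrix.library_sizes)
        },
    }

    filtered = stage(
        "filter", lambda: filter_windows(matrix, config.min_avg_depth)
    )
    manifest["stages"]["filter"] = {"windows_kept": filtered.n_windows}

    factors = stage("tmm", lambda: tmm_factors(filtered))
    manifest["stages"]["tmm"] = {
        "factors": {
            s: round(float(f), 6) for s, f in zip(factors.samples, factors.factors)
        }
    }

    case = config.case_group or None
    control = config.control_group or None
    disp = stage(
        "dispersion",
        lambda: estimate_common_dispersion(filtered, factors, case, control),
    )
    manifest["stages"]["dispersion"] = {"phi": round(disp.phi, 6), "method": disp.method}

    results = stage(
        "exact_test",
        lambda: exact_test(filtered, factors, disp, case, control),
    )
    manifest["stages"]["exact_test"] = {
        "windows_tested": len(results),
        "windows_p_below_seed": int((results["p_value"] < config.p_seed).sum()),
    }

    dmrs = stage(
        "call_dmrs",
        lambda: annotate_dmrs(
            call_dmrs(
                results,
                p_seed=config.p_seed,
                p_extend=config.p_extend,
                neighborhood_bp=config.neighborhood_bp,
            ),
            genome,
        ),
    )
    manifest["stages"]["call_dmrs"] = {"dmrs": len(dmrs)}

    outputs: dict[str, Path] = {}
    if config.keep_intermediates:
        filtered.write_tsv(out / "counts_filtered.tsv")
        outputs["counts_filtered"] = out / "counts_filtered.tsv"
    write_results_tsv(results, out / "window_results.tsv")
    outputs["window_results"] = out / "window_results.tsv"
    write_dmr_bed(dmrs, out / "dmrs.bed")
    outputs["dmrs_bed"] = out / "dmrs.bed"
    write_dmr_tsv(dmrs, out / "dmrs.tsv")
    outputs["dmrs_tsv"] = out / "dmrs.tsv"

    ladder = [1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7]
    table = stage(
        "threshold_table",
        lambda: threshold_table(
            results, ladder, config.p_extend, config.neighborhood_bp
        ),
    )
    table.to_csv(out / "threshold_table.tsv", sep="\t", index=False)
    outputs["threshold_table"] = out / "threshold_table.tsv"

    per_chromosome_counts(dmrs).rename("n_dmrs").to_csv(
        out / "dmrs_per_chromosome.tsv", sep="\t"
    )
    outputs["dmrs_per_chromosome"] = out / "dmrs_per_chromosome.tsv"

    if config.gff3:
        genes = stage("load_genes", lambda: read_genes_gff3(config.gff3))
        assocs = stage(
            "associate_genes",
            lambda: associate_genes(dmrs, genes, config.gene_max_distance),
        )
        manifest["stages"]["associate_genes"] = {
            "genes": len(genes),
            "associations": len(assocs),
        }
        associations_to_frame(assocs).to_csv(
            out / "gene_associations.tsv", sep="\t", index=False
        )
        outputs["gene_associations"] = out / "gene_associations.tsv"

    manifest["outputs"] = {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
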