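"""Cross-comparison analyses over called DMR sets.

Covers gene association within a promoter-scale distance (default
10 kb, capturing proximal and distal promoters), Venn-style overlap
between the DMR sets of different group comparisons, the "extended"
overlap of a strict DMR set against another comparison re-called at a
relaxed seed threshold (p < 0.05), and principal-component analysis of
per-sample RPKM over DMR windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dmr import DMR, call_dmrs
from .windows import CountMatrix, GenomicWindow

logger = logging.getLogger(__name__)

DEFAULT_GENE_MAX_DISTANCE = 10_000
DEFAULT_P_RELAXED = 0.05


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene span from an annotation file (0-based half-open)."""

    gene_id: str
    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise CompareError(f"gene {self.gene_id} has empty span")


@dataclass(frozen=True)
class DmrGeneAssociation:
    dmr_name: str
    gene_id: str
    symbol: str
    distance_bp: int  # 0 when overlapping


def read_genes_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene-type features from GFF3, converting to 0-based half-open."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        symbol = feat.attributes.get("Name", [gene_id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chromosome=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return genes


def interval_gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Edge-to-edge gap between half-open intervals; 0 when they overlap."""
    if start1 < end2 and start2 < end1:
        return 0
    return max(start2 - end1, start1 - end2)


def associate_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_GENE_MAX_DISTANCE,
) -> list[DmrGeneAssociation]:
    """All (DMR, gene) pairs within ``max_distance`` bp (inclusive).

    Distance is measured to the annotated gene body.  A DMR may hit
    several genes and a gene several DMRs.  Chromosomes present in one
    input but not the other are logged and skipped.
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    unmatched = {d.chromosome for d in dmrs} - set(genes_by_chrom)
    if unmatched:
        logger.info("no genes on chromosomes: %s", sorted(unmatched))
    out = []
    for d in dmrs:
        for g in genes_by_chrom.get(d.chromosome, []):
            gap = interval_gap(d.start, d.end, g.start, g.end)
            if gap <= max_distance:
                out.append(
                    DmrGeneAssociation(
                        dmr_name=d.name,
                        gene_id=g.gene_id,
                        symbol=g.symbol,
                        distance_bp=gap,
                    )
                )
    return out


def associations_to_frame(assocs: Sequence[DmrGeneAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dmr": a.dmr_name,
                "gene_id": a.gene_id,
                "symbol": a.symbol,
                "distance_bp": a.distance_bp,
            }
            for a in assocs
        ],
        columns=["dmr", "gene_id", "symbol", "distance_bp"],
    )


# ------------------------------------------------------------------- Venn


@dataclass
class OverlapReport:
    """Overlap structure of 2-4 named DMR sets.

    ``membership[name]`` counts, for each DMR of set ``name``, the
    sorted tuple of set names (including its own) whose DMRs it overlaps
    by at least one base — the Venn region it falls in, from that set's
    perspective.  ``pairwise[(a, b)]`` is the number of DMRs of ``a``
    overlapping any DMR of ``b``.
    """

    set_sizes: dict[str, int]
    membership: dict[str, dict[tuple[str, ...], int]]
    pairwise: dict[tuple[str, str], int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, regions in self.membership.items():
            for region, count in sorted(regions.items()):
                rows.append(
                    {"set": name, "region": "&".join(region), "count": count}
                )
        return pd.DataFrame(rows, columns=["set", "region", "count"])

    def to_dict(self) -> dict:
        return {
            "set_sizes": self.set_sizes,
            "membership": {
                name: {"&".join(k): v for k, v in regions.items()}
                for name, regions in self.membership.items()
            },
            "pairwise": {f"{a}|{b}": v for (a, b), v in self.pairwise.items()},
        }


def _overlaps_any(dmr: DMR, others: Sequence[DMR]) -> bool:
    return any(dmr.overlaps(o) for o in others)


def venn_overlap(dmr_sets: Mapping[str, Sequence[DMR]]) -> OverlapReport:
    """Venn region membership of each DMR across 2-4 named sets."""
    names = list(dmr_sets)
    if not (2 <= len(names) <= 4):
        raise CompareError(f"venn_overlap supports 2-4 sets, got {len(names)}")
    membership: dict[str, dict[tuple[str, ...], int]] = {n: {} for n in names}
    for name in names:
        for dmr in dmr_sets[name]:
            region = tuple(
                sorted(
                    [name]
                    + [
                        other
                        for other in names
                        if other != name and _overlaps_any(dmr, dmr_sets[other])
                    ]
                )
            )
            membership[name][region] = membership[name].get(region, 0) + 1
    pairwise = {
        (a, b): sum(1 for d in dmr_sets[a] if _overlaps_any(d, dmr_sets[b]))
        for a, b in combinations(names, 2)
    } | {
        (b, a): sum(1 for d in dmr_sets[b] if _overlaps_any(d, dmr_sets[a]))
        for a, b in combinations(names, 2)
    }
    return OverlapReport(
        set_sizes={n: len(dmr_sets[n]) for n in names},
        membership=membership,
        pairwise=pairwise,
    )


def extended_overlap(
    strict_dmrs: Sequence[DMR],
    relaxed_results: pd.DataFrame,
    p_relaxed: float = DEFAULT_P_RELAXED,
    p_extend: float = 0.1,
    neighborhood_bp: int = 1000,
) -> tuple[int, float]:
    """Overlap of a strict DMR set with another comparison at a relaxed seed.

    The comparison's window results are re-called as DMRs with
    ``p_seed = p_relaxed`` (same extension rule) and each strict DMR is
    checked for >= 1 bp overlap.  Returns (count, percentage of the
    strict set).
    """
    if not strict_dmrs:
        warnings.warn("extended_overlap: empty strict DMR set; reporting 0%")
        return 0, 0.0
    relaxed = call_dmrs(
        relaxed_results,
        p_seed=p_relaxed,
        p_extend=max(p_relaxed, p_extend),
        neighborhood_bp=neighborhood_bp,
    )
    count = sum(1 for d in strict_dmrs if _overlaps_any(d, relaxed))
    return count, 100.0 * count / len(strict_dmrs)


# -------------------------------------------------------------- RPKM + PCA


def rpkm_matrix(
    matrix: CountMatrix, windows: Sequence[GenomicWindow] | None = None
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, windows x samples.

    ``RPKM(w, s) = count / (length_kb(w) * library_size(s) / 1e6)`` with
    raw (pre-normalization) library sizes.  ``windows`` restricts to a
    subset (e.g. DMR windows); default all.
    """
    if (matrix.library_sizes <= 0).any():
        raise CompareError("zero library size")
    if windows is None:
        rows = np.arange(matrix.n_windows)
        selected = matrix.windows
    else:
        row_of = {w: i for i, w in enumerate(matrix.windows)}
        try:
            rows = np.array([row_of[w] for w in windows])
        except KeyError as e:
            raise CompareError(f"window {e.args[0]} not in the count matrix") from e
        selected = list(windows)
    lengths_kb = np.array([w.length for w in selected]) / 1000.0
    denom = lengths_kb[:, None] * (matrix.library_sizes[None, :] / 1e6)
    rpkm = matrix.counts[rows] / denom
    return pd.DataFrame(
        rpkm, index=[w.name for w in selected], columns=matrix.samples
    )


def dmr_windows(matrix: CountMatrix, dmrs: Sequence[DMR]) -> list[GenomicWindow]:
    """The matrix windows falling inside any DMR span."""
    return [
        w
        for w in matrix.windows
        if any(
            w.chromosome == d.chromosome and w.start < d.end and d.start < w.end
            for d in dmrs
        )
    ]


def dmr_pca(rpkm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal components of samples in DMR-window RPKM space.

    Samples are observations, windows features; features are centered
    but not scaled.  Component signs are fixed by making each
    component's largest-magnitude loading positive.  Degenerate input
    (all samples identical) yields zero scores and zero explained
    variance.

    Returns (scores DataFrame with columns PC1, PC2 indexed by sample,
    explained-variance fractions of the two components).
    """
    if rpkm.shape[1] < 3:
        raise CompareError("PCA needs at least 3 samples")
    if rpkm.shape[0] < 2:
        raise CompareError("PCA needs at least 2 windows")
    x = rpkm.to_numpy().T  # samples x windows
    centered = x - x.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        scores = pd.DataFrame(
            np.zeros((x.shape[0], 2)), index=rpkm.columns, columns=["PC1", "PC2"]
        )
        return scores, np.zeros(2)
    n_comp = min(2, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    transformed = pca.fit_transform(x)
    scores_arr = np.zeros((x.shape[0], 2))
    evr = np.zeros(2)
    for k in range(n_comp):
        comp = pca.components_[k]
        sign = 1.0 if comp[np.argmax(np.abs(comp))] >= 0 else -1.0
        scores_arr[:, k] = sign * transformed[:, k]
        evr[k] = pca.explained_variance_ratio_[k]
    scores = pd.DataFrame(scores_arr, index=rpkm.columns, columns=["PC1", "PC2"])
    return scores, evr


def plot_pca(
    scores: pd.DataFrame,
    design: Mapping[str, str],
    evr: np.ndarray,
    path: str | Path,
) -> None:  # pragma: no cover - optional plotting
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group in sorted(set(design.values())):
        sel = [s for s in scores.index if design[s] == group]
        ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"], label=group)
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
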