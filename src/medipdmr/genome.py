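"""Reference genome access: named sequences, slices, and CpG counting.

MeDIP-seq enrichment tracks methylated cytosines, which in mammalian
genomes occur almost exclusively at CpG dinucleotides, so the CpG content
of a region is the natural covariate for both simulated coverage and DMR
annotation.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class GenomeError(ValueError):
    """Raised for out-of-bounds or unknown-chromosome access."""


class GenomeIndex:
    """In-memory genome: ordered chromosomes with sequence slice access.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to sequence string (upper-case ACGTN).
        Insertion order defines chromosome order.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise GenomeError("genome has no chromosomes")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise GenomeError(f"chromosome {name!r} has zero length")
            if name in self._seqs:
                raise GenomeError(f"duplicate chromosome name {name!r}")
            self._seqs[name] = str(seq).upper()

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        """Ordered (name, length) pairs."""
        return [(name, len(seq)) for name, seq in self._seqs.items()]

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        self._check(name)
        return len(self._seqs[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def _check(self, name: str) -> None:
        if name not in self._seqs:
            raise GenomeError(f"unknown chromosome {name!r}")

    def fetch(self, name: str, start: int, end: int) -> str:
        """Sequence of the half-open interval [start, end)."""
        self._check(name)
        seq = self._seqs[name]
        if start < 0 or end > len(seq) or end < start:
            raise GenomeError(
                f"span {name}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    def cpg_count(self, name: str, start: int, end: int) -> int:
        """Number of CG dinucleotides whose C lies in [start, end).

        A CG straddling the right boundary counts (its C is inside); one
        straddling the left boundary does not.
        """
        self._check(name)
        chrom_len = len(self._seqs[name])
        if start < 0 or end > chrom_len or end < start:
            raise GenomeError(f"span {name}:{start}-{end} out of bounds")
        window = self._seqs[name][start : min(end + 1, chrom_len)]
        span = end - start
        count = 0
        pos = window.find("CG")
        while 0 <= pos < span:
            count += 1
            pos = window.find("CG", pos + 1)
        return count

    def cpg_density_per_100bp(self, name: str, start: int, end: int) -> float:
        span = end - start
        if span <= 0:
            raise GenomeError("empty span has no CpG density")
        return 100.0 * self.cpg_count(name, start, end) / span

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise GenomeError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        """Write all chromosomes as FASTA wrapped at 60 columns."""
        records: Iterable[SeqRecord] = (
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()
        )
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")
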