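"""Genome, annotation and conserved-element I/O.

This module is the coordinate substrate for the rest of the package: GTF
exon records are converted to 0-based half-open intervals at the boundary,
introns are derived as the gaps between consecutive exons of a transcript,
and sequence extraction is strand-aware (reverse complement on the minus
strand). Conserved elements (e.g. phastConsElements) are held as a merged,
strandless interval set and queried for per-interval coverage fractions.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_STRANDS = ("+", "-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """A transcript as an ordered exon chain.

    Exons are stored in transcript 5'->3' order: ascending genomic
    coordinate on the plus strand, descending on the minus strand.
    """

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id} spans chroms/strands")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id} has overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class GeneModelSet:
    """Transcripts grouped by gene."""

    genes: dict[str, list[Transcript]] = field(default_factory=dict)

    def add(self, t: Transcript) -> None:
        self.genes.setdefault(t.gene_id, []).append(t)

    def transcripts(self) -> Iterator[Transcript]:
        for tlist in self.genes.values():
            yield from tlist

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModelSet):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for g in self.genes:
            a = sorted(self.genes[g], key=lambda t: t.id)
            b = sorted(other.genes[g], key=lambda t: t.id)
            if a != b:
                return False
        return True


class SequenceStore:
    """In-memory chrom -> sequence map with strand-aware extraction."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceStore":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                s = self.sequences[chrom]
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        return extract_sequence(iv, self)


def extract_sequence(iv: GenomicInterval, store: SequenceStore) -> str:
    """Strand-aware sequence of ``iv``: reverse complement on minus.

    Raises ``KeyError`` for an unknown chromosome and ``ValueError`` when
    the interval exceeds the chromosome bounds.
    """
    seq = store.sequences[iv.chrom]
    if iv.end > len(seq):
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chrom "
            f"length {len(seq)}"
        )
    sub = seq[iv.start : iv.end]
    return reverse_complement(sub) if iv.strand == "-" else sub


class IntervalSet:
    """Per-chromosome sorted, merged, strandless intervals (BED-style)."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        self._starts: dict[str, list[int]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self._by_chrom[chrom] = _merge(ivs)
        self._reindex()

    def _reindex(self) -> None:
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self._by_chrom.items()}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in pairs:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls(by_chrom)

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        """Read BED3+; score/name/strand columns are ignored."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed BED line {lineno}")
                pairs.append((parts[0], int(parts[1]), int(parts[2])))
        return cls.from_pairs(pairs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._by_chrom):
                for s, e in self._by_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._by_chrom.get(chrom, []))

    def intersect(self, iv: GenomicInterval) -> list[tuple[int, int]]:
        """Merged overlaps of ``iv`` with the set, in ascending order."""
        ivs = self._by_chrom.get(iv.chrom, [])
        starts = self._starts.get(iv.chrom, [])
        out = []
        # first element that could overlap: the one before the insertion point
        idx = max(0, bisect_right(starts, iv.start) - 1)
        for s, e in ivs[idx:]:
            if s >= iv.end:
                break
            lo, hi = max(s, iv.start), min(e, iv.end)
            if lo < hi:
                out.append((lo, hi))
        return out


def _merge(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coverage_fraction(iv: GenomicInterval, elems: IntervalSet) -> float:
    """Fraction of bases of ``iv`` covered by the (merged) element set."""
    covered = sum(hi - lo for lo, hi in elems.intersect(iv))
    return covered / len(iv)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_models(gtf_path: str | Path) -> GeneModelSet:
    """Parse a GTF into transcripts grouped by gene.

    Only ``exon`` features are used. GTF 1-based closed coordinates are
    converted to 0-based half-open. Exons of each transcript are ordered
    5'->3' in transcript orientation.
    """
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    gene_of_tid: dict[str, str] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{gtf_path}: malformed GTF line {lineno}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature != "exon":
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ValueError(
                    f"{gtf_path}: bad exon on line {lineno}: {exc}"
                ) from exc
            a = _parse_gtf_attributes(attrs)
            if "gene_id" not in a or "transcript_id" not in a:
                raise ValueError(
                    f"{gtf_path}: line {lineno} lacks gene_id/transcript_id"
                )
            tid = a["transcript_id"]
            exons_by_tid.setdefault(tid, []).append(iv)
            gene_of_tid[tid] = a["gene_id"]

    models = GeneModelSet()
    for tid, exons in exons_by_tid.items():
        if not exons:
            log.warning("transcript %s has zero exons; excluded", tid)
            continue
        strand = exons[0].strand
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        models.add(Transcript(id=tid, gene_id=gene_of_tid[tid], exons=tuple(exons)))
    return models


def write_gtf(models: GeneModelSet, path: str | Path, source: str = "mxefold") -> None:
    """Write exon records in Ensembl-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for gene_id in sorted(models.genes):
            for t in sorted(models.genes[gene_id], key=lambda t: t.id):
                for e in t.exons:
                    attrs = f'gene_id "{gene_id}"; transcript_id "{t.id}";'
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t."
                        f"\t{e.strand}\t.\t{attrs}\n"
                    )


def derive_introns(t: Transcript) -> list[GenomicInterval]:
    """Gaps between consecutive exons, in transcript 5'->3' order.

    A single-exon transcript yields an empty list.
    """
    introns = []
    for a, b in zip(t.exons, t.exons[1:]):
        if t.strand == "+":
            introns.append(GenomicInterval(t.chrom, a.end, b.start, "+"))
        else:
            introns.append(GenomicInterval(t.chrom, b.end, a.start, "-"))
    return introns
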