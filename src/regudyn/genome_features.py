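"""Gene-structure comparison and annotation filters.

Covers intron-chain based equivalence between transcript model sets
(long-read models vs an existing annotation), short-read splice-junction
support binning, the primary+supplement merge of two model sets, and the
lncRNA retention filter (length / homology / coding potential).
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .models import Junction, TranscriptModel, TranscriptModelSet


class ComparisonClass(str, Enum):
    EXACT_MATCH = "exact_match"
    NOVEL_ISOFORM = "novel_isoform"
    NOVEL_LOCUS = "novel_locus"
    OTHER = "other"


def intron_chain(t: TranscriptModel) -> tuple[Junction, ...]:
    return t.intron_chain()


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total overlapping exonic bases between two transcripts."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel) -> float:
    ov = _exonic_overlap(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.spliced_length, ov / b.spliced_length)


class _ExonIndex:
    """Per (chrom, strand) sorted exon lists for fast overlap candidate lookup."""

    def __init__(self, models: TranscriptModelSet):
        import bisect

        self._bisect = bisect
        self.by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        self.max_len: dict[tuple[str, str], int] = {}
        for t in models:
            key = (t.chrom, t.strand)
            lst = self.by_key.setdefault(key, [])
            for s, e in t.exons:
                lst.append((s, e, t.transcript_id))
                self.max_len[key] = max(self.max_len.get(key, 0), e - s)
        for lst in self.by_key.values():
            lst.sort()

    def overlapping(self, chrom: str, strand: str, start: int, end: int) -> set[str]:
        key = (chrom, strand)
        lst = self.by_key.get(key)
        if not lst:
            return set()
        lo = self._bisect.bisect_left(lst, (start - self.max_len[key], -1, ""))
        hits = set()
        for s, e, tid in lst[lo:]:
            if s >= end:
                break
            if e > start:
                hits.add(tid)
        return hits


def _overlapping_transcripts(
    index: _ExonIndex, t: TranscriptModel, strand: str
) -> set[str]:
    hits: set[str] = set()
    for s, e in t.exons:
        hits |= index.overlapping(t.chrom, strand, s, e)
    return hits


def compare_model_sets(
    query: TranscriptModelSet,
    reference: TranscriptModelSet,
    single_exon_min_overlap: float = 0.8,
) -> tuple[dict[str, ComparisonClass], Counter]:
    """Classify every query transcript against a reference annotation.

    * ``exact_match`` — a same-strand reference transcript shares the full
      intron chain (multi-exon), or, for single-exon queries, a single-exon
      same-strand reference reciprocally overlaps by
      ``single_exon_min_overlap``.
    * ``novel_isoform`` — same-strand exonic overlap with a reference
      transcript, but no chain match.
    * ``novel_locus`` — no exonic overlap with any reference transcript on
      either strand.
    * ``other`` — remaining cases (opposite-strand overlap only).
    """
    q_chroms = {t.chrom for t in query}
    r_chroms = {t.chrom for t in reference}
    if q_chroms and r_chroms and not (q_chroms & r_chroms):
        raise ValueError(
            "no shared chromosome names between query and reference; "
            "are these the same assembly?"
        )

    ref_chains: dict[tuple, list[str]] = {}
    for t in reference:
        chain = tuple((j.donor, j.acceptor) for j in t.intron_chain())
        if chain:
            ref_chains.setdefault((t.chrom, t.strand, chain), []).append(t.transcript_id)

    same = _ExonIndex(reference)
    flipped = {"+": "-", "-": "+"}

    classes: dict[str, ComparisonClass] = {}
    for t in query:
        chain = tuple((j.donor, j.acceptor) for j in t.intron_chain())
        same_hits = _overlapping_transcripts(same, t, t.strand)
        if chain:
            if (t.chrom, t.strand, chain) in ref_chains:
                classes[t.transcript_id] = ComparisonClass.EXACT_MATCH
                continue
        else:
            match = any(
                len(reference.transcripts[rid].exons) == 1
                and _reciprocal_overlap(t, reference.transcripts[rid])
                >= single_exon_min_overlap
                for rid in same_hits
            )
            if match:
                classes[t.transcript_id] = ComparisonClass.EXACT_MATCH
                continue
        if same_hits:
            classes[t.transcript_id] = ComparisonClass.NOVEL_ISOFORM
        elif _overlapping_transcripts(same, t, flipped[t.strand]):
            classes[t.transcript_id] = ComparisonClass.OTHER
        else:
            classes[t.transcript_id] = ComparisonClass.NOVEL_LOCUS

    return classes, Counter(classes.values())


JUNCTION_BINS = ("0", "1-500", ">500")


def classify_junction_support(
    junctions: list[Junction], support: dict[tuple[str, int, int], int]
) -> tuple[dict[Junction, str], dict[str, float]]:
    """Bin junctions by short-read support: none, 1-500, or over 500 reads.

    ``support`` maps (chrom, donor, acceptor) to a read count; junctions
    missing from the table count as unsupported.
    """
    bins: dict[Junction, str] = {}
    for j in junctions:
        n = support.get((j.chrom, j.donor, j.acceptor), 0)
        if n < 0:
            raise ValueError(f"negative support count for {j}")
        bins[j] = "0" if n == 0 else ("1-500" if n <= 500 else ">500")
    total = len(junctions)
    counts = Counter(bins.values())
    proportions = {b: (counts.get(b, 0) / total if total else 0.0) for b in JUNCTION_BINS}
    return bins, proportions


@dataclass
class MergeResult:
    merged: TranscriptModelSet
    gene_provenance: dict[str, str]  # gene id -> "primary" | "supplement"


def merge_model_sets(
    primary: TranscriptModelSet, supplement: TranscriptModelSet
) -> MergeResult:
    """Union of two model sets with the primary set taking precedence.

    All primary models are kept. A supplement gene is added only if none of
    its transcripts has same-strand exonic overlap with any primary model.
    """
    merged = TranscriptModelSet(gene_source=dict(primary.gene_source))
    provenance: dict[str, str] = {}
    for t in primary:
        merged.add(t)
        provenance[t.gene_id] = "primary"

    index = _ExonIndex(primary)
    for gid, ts in supplement.genes().items():
        if any(_overlapping_transcripts(index, t, t.strand) for t in ts):
            continue
        provenance[gid] = "supplement"
        for t in ts:
            tid = t.transcript_id
            if tid in merged:
                warnings.warn(f"duplicate transcript id {tid}; suffixing")
                tid = tid + ".supp"
            merged.add(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=t.chrom,
                    strand=t.strand,
                    exons=list(t.exons),
                    source=t.source,
                )
            )
            merged.gene_source.setdefault(gid, supplement.gene_source.get(gid, "."))
    return MergeResult(merged=merged, gene_provenance=provenance)


def filter_lncrna(
    transcripts: TranscriptModelSet,
    coding_potential: dict[str, float],
    homology_flags: dict[str, bool],
    min_length: int = 200,
    coding_cutoff: float = 0.5,
) -> set[str]:
    """Retain long noncoding RNA candidates.

    A transcript is kept iff its spliced length is at least ``min_length``
    nucleotides, it is not flagged as homologous to a known coding gene, and
    its coding-potential score is below ``coding_cutoff``. Transcripts with
    a missing score are excluded with a warning.
    """
    kept: set[str] = set()
    for t in transcripts:
        tid = t.transcript_id
        if tid not in coding_potential:
            warnings.warn(f"{tid}: no coding-potential score; excluded")
            continue
        score = coding_potential[tid]
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"{tid}: coding-potential score {score} outside [0,1]")
        if (
            t.spliced_length >= min_length
            and not homology_flags.get(tid, False)
            and score < coding_cutoff
        ):
            kept.add(tid)
    return kept
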