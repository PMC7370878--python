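"""Core domain objects: transcript models, splice junctions, stage matrices.

All genomic coordinates are 0-based half-open internally; the GFF3 layer
converts at the boundary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Junction:
    """An intron span: ``donor`` is the first intronic base, ``acceptor`` the
    first base of the downstream exon (half-open [donor, acceptor))."""

    chrom: str
    strand: str
    donor: int
    acceptor: int

    def __post_init__(self) -> None:
        if self.acceptor <= self.donor:
            raise ValueError(
                f"junction acceptor must exceed donor: {self.donor}..{self.acceptor}"
            )


@dataclass
class TranscriptModel:
    """A transcript: ordered, disjoint exons on one chromosome and strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    source: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = sorted(tuple(e) for e in self.exons)
        if exons != [tuple(e) for e in self.exons]:
            warnings.warn(f"{self.transcript_id}: exons were unsorted; sorting")
        for start, end in exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty exon [{start},{end})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (5' end)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def intron_chain(self) -> tuple[Junction, ...]:
        """Ordered introns; empty for single-exon transcripts."""
        return tuple(
            Junction(self.chrom, self.strand, e0, s1)
            for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )


@dataclass
class TranscriptModelSet:
    """A collection of transcripts grouped into genes."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    gene_source: dict[str, str] = field(default_factory=dict)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self:
            seen.setdefault(t.gene_id, None)
        return list(seen)

    def genes(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for t in self:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def gene_span(self, gene_id: str) -> tuple[str, str, int, int]:
        """(chrom, strand, start, end) covering all transcripts of a gene."""
        ts = [t for t in self if t.gene_id == gene_id]
        if not ts:
            raise KeyError(gene_id)
        return (
            ts[0].chrom,
            ts[0].strand,
            min(t.start for t in ts),
            max(t.end for t in ts),
        )

    def transcript_to_gene(self) -> dict[str, str]:
        return {t.transcript_id: t.gene_id for t in self}


class StageMatrix:
    """Entities x ordered developmental stages of non-negative values.

    A thin wrapper over a pandas DataFrame that pins down orientation
    (rows = entities, columns = stages in developmental order) and the
    TSV dialect used throughout the package (first column = entity id,
    header = stage labels).
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any() or data.index.duplicated().any():
            raise ValueError("duplicate entity ids or stage labels")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("stage matrix contains non-finite values")
        self.data = data.astype(float)

    @property
    def entities(self) -> list[str]:
        return list(self.data.index)

    @property
    def stages(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StageMatrix) and self.data.equals(other.data)

    def subset(self, entities: Iterable[str]) -> "StageMatrix":
        return StageMatrix(self.data.loc[list(entities)])

    def to_tsv(self, path) -> None:
        self.data.rename_axis("id").to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path) -> "StageMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)


def check_replicates(rep1: StageMatrix, rep2: StageMatrix) -> None:
    """Raise unless the two replicates cover identical entities and stages."""
    if rep1.entities != rep2.entities or rep1.stages != rep2.stages:
        raise ValueError("replicates disagree on entities or stage labels")


def replicate_mean(rep1: StageMatrix, rep2: StageMatrix) -> StageMatrix:
    check_replicates(rep1, rep2)
    return StageMatrix((rep1.data + rep2.data) / 2.0)
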