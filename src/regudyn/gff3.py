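"""Minimal GFF3 reader/writer for the gene/mRNA/exon hierarchy.

Only the three feature levels used by this package are interpreted; other
feature types are ignored. GFF3 columns 4/5 are 1-based inclusive and are
converted to 0-based half-open on read (and back on write).
"""
from __future__ import annotations

import warnings
from typing import TextIO

from .models import TranscriptModel, TranscriptModelSet


class Gff3ParseError(ValueError):
    pass


def _attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


_TRANSCRIPT_TYPES = {"mRNA", "transcript", "lnc_RNA", "ncRNA"}


def read_gff3(path) -> TranscriptModelSet:
    """Parse a GFF3 file into a :class:`TranscriptModelSet`.

    Raises :class:`Gff3ParseError` (with the offending line number) for exons
    whose parent transcript is never defined; unsorted exons are sorted with
    a warning.
    """
    gene_source: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # id -> chrom,strand,gene,source
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    orphan_lines: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3ParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, source, ftype, start, end, _score, strand, _phase, attr = cols
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise Gff3ParseError(f"line {lineno}: non-integer coordinates") from exc
            if end0 <= start0:
                raise Gff3ParseError(f"line {lineno}: empty interval {start}..{end}")
            attrs = _attributes(attr)
            if ftype == "gene":
                gene_source[attrs.get("ID", "")] = source
            elif ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID")
                if tid is None:
                    raise Gff3ParseError(f"line {lineno}: transcript without ID")
                tx_meta[tid] = (chrom, strand, attrs.get("Parent", tid), source)
                tx_exons.setdefault(tid, [])
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise Gff3ParseError(f"line {lineno}: exon without Parent")
                tx_exons.setdefault(parent, []).append((start0, end0))
                orphan_lines.setdefault(parent, lineno)

    out = TranscriptModelSet(gene_source=gene_source)
    for tid, exons in tx_exons.items():
        if tid not in tx_meta:
            raise Gff3ParseError(
                f"line {orphan_lines[tid]}: exon references undefined transcript {tid!r}"
            )
        chrom, strand, gene, source = tx_meta[tid]
        if not exons:
            raise Gff3ParseError(f"transcript {tid!r} has no exons")
        if exons != sorted(exons):
            warnings.warn(f"{tid}: exons out of order in GFF3; sorted")
        out.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=sorted(exons),
                source=source,
            )
        )
    return out


def _write_feature(fh: TextIO, chrom, source, ftype, start0, end0, strand, attrs) -> None:
    attr = ";".join(f"{k}={v}" for k, v in attrs)
    fh.write(
        f"{chrom}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr}\n"
    )


def write_gff3(models: TranscriptModelSet, path) -> None:
    """Write a model set; output is deterministic (sorted by position/id)."""
    genes = models.genes()
    order = sorted(
        genes,
        key=lambda g: (genes[g][0].chrom, min(t.start for t in genes[g]), g),
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in order:
            ts = sorted(genes[gid], key=lambda t: (t.start, t.transcript_id))
            chrom, strand = ts[0].chrom, ts[0].strand
            g_start = min(t.start for t in ts)
            g_end = max(t.end for t in ts)
            source = models.gene_source.get(gid, ts[0].source)
            _write_feature(fh, chrom, source, "gene", g_start, g_end, strand, [("ID", gid)])
            for t in ts:
                _write_feature(
                    fh, chrom, t.source, "mRNA", t.start, t.end, strand,
                    [("ID", t.transcript_id), ("Parent", gid)],
                )
                for i, (s, e) in enumerate(t.exons, start=1):
                    _write_feature(
                        fh, chrom, t.source, "exon", s, e, strand,
                        [("ID", f"{t.transcript_id}.exon{i}"), ("Parent", t.transcript_id)],
                    )
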