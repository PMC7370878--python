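"""Predominant-isoform switching across developmental stages.

A gene's predominant isoform at a stage is the isoform contributing more
than 60% of the gene's summed isoform TPM; a gene "switches" when the
predominant isoform changes between two stages where predominance is
defined.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import StageMatrix


@dataclass(frozen=True)
class SwitchEvent:
    gene_id: str
    isoform_from: str
    isoform_to: str
    stage_from: str  # last stage where isoform_from is predominant
    stage_to: str  # first stage where isoform_to is predominant

    def __post_init__(self) -> None:
        if self.isoform_from == self.isoform_to:
            raise ValueError("a switch needs two distinct isoforms")


def _gene_groups(matrix: StageMatrix, gene_map: dict[str, str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for tid in matrix.entities:
        if tid not in gene_map:
            raise ValueError(f"transcript {tid!r} has no gene mapping")
        groups.setdefault(gene_map[tid], []).append(tid)
    return groups


def multi_isoform_filter(
    matrix: StageMatrix, gene_map: dict[str, str], min_tpm: float = 1.0
) -> tuple[list[str], dict[str, list[str]]]:
    """Genes with at least two expressed isoforms.

    An isoform counts as expressed iff it reaches ``min_tpm`` (inclusive) at
    one or more stages. Returns the retained gene ids and the expressed
    isoforms per retained gene.
    """
    groups = _gene_groups(matrix, gene_map)
    genes: list[str] = []
    expressed: dict[str, list[str]] = {}
    for gid, tids in groups.items():
        exp = [t for t in tids if matrix.data.loc[t].max() >= min_tpm]
        if len(exp) >= 2:
            genes.append(gid)
            expressed[gid] = exp
    return genes, expressed


def isoform_fractions(
    matrix: StageMatrix, gene_map: dict[str, str], gene_floor: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage isoform fractions of gene TPM.

    Returns (fractions, gene_tpm). Fractions are NaN at stages where the
    gene's summed TPM does not exceed ``gene_floor`` (undefined rather than
    0/0 artifacts).
    """
    groups = _gene_groups(matrix, gene_map)
    gene_tpm = pd.DataFrame(
        {gid: matrix.data.loc[tids].sum(axis=0) for gid, tids in groups.items()}
    ).T
    gene_tpm = gene_tpm[matrix.stages]
    denom = gene_tpm.reindex([gene_map[t] for t in matrix.entities])
    denom.index = matrix.entities
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = matrix.data / denom.where(denom > gene_floor)
    return frac, gene_tpm


def predominant_isoform(
    fractions: pd.DataFrame,
    gene_tpm: pd.DataFrame,
    gene_map: dict[str, str],
    threshold: float = 0.6,
    gene_floor: float = 1.0,
) -> pd.DataFrame:
    """Per gene and stage, the isoform whose fraction strictly exceeds
    ``threshold``, or None.

    Predominance is only called at stages where the gene's total TPM is at
    least ``gene_floor``. With ``threshold > 0.5`` at most one isoform can
    qualify per stage.
    """
    by_gene: dict[str, list[str]] = {}
    for tid in fractions.index:
        by_gene.setdefault(gene_map[tid], []).append(tid)
    rows = {}
    for gid, tids in by_gene.items():
        sub = fractions.loc[tids]
        calls = []
        for stage in fractions.columns:
            col = sub[stage]
            if gene_tpm.loc[gid, stage] < gene_floor or col.isna().all():
                calls.append(None)
                continue
            top = col.idxmax()
            calls.append(top if col.loc[top] > threshold else None)
        rows[gid] = calls
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(fractions.columns))


def detect_switches(predominant: pd.DataFrame) -> tuple[list[SwitchEvent], list[str]]:
    """Switch events from per-stage predominant-isoform series.

    Stages without a defined predominant isoform are bridged: an event is
    emitted for each change between consecutive *defined* calls, so
    A, none, B yields A->B while A, none, A yields nothing.
    """
    events: list[SwitchEvent] = []
    switching: list[str] = []
    for gid, row in predominant.iterrows():
        defined = [(stage, iso) for stage, iso in row.items() if iso is not None]
        gene_events = [
            SwitchEvent(gid, prev_iso, iso, prev_stage, stage)
            for (prev_stage, prev_iso), (stage, iso) in zip(defined, defined[1:])
            if iso != prev_iso
        ]
        events.extend(gene_events)
        if gene_events:
            switching.append(gid)
    return events, switching


def find_switching_genes(
    matrix: StageMatrix,
    gene_map: dict[str, str],
    min_tpm: float = 1.0,
    threshold: float = 0.6,
    gene_floor: float = 1.0,
) -> tuple[list[SwitchEvent], list[str], list[str]]:
    """End-to-end switching detection on a transcript TPM matrix.

    Returns (events, switching gene ids, multi-isoform gene ids considered).
    """
    genes, expressed = multi_isoform_filter(matrix, gene_map, min_tpm=min_tpm)
    keep = [t for g in genes for t in expressed[g]]
    sub = matrix.subset(keep)
    frac, gene_tpm = isoform_fractions(sub, gene_map)
    calls = predominant_isoform(
        frac, gene_tpm, gene_map, threshold=threshold, gene_floor=gene_floor
    )
    events, switching = detect_switches(calls)
    return events, switching, genes


def events_table(events: list[SwitchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": e.gene_id,
                "isoform_from": e.isoform_from,
                "isoform_to": e.isoform_to,
                "stage_from": e.stage_from,
                "stage_to": e.stage_to,
            }
            for e in events
        ],
        columns=["gene", "isoform_from", "isoform_to", "stage_from", "stage_to"],
    )
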