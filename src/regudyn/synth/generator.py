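"""Synthetic multi-omics dataset generator with planted, labelled structure.

Emulates the shapes of a developmental multi-omics study: a genome
annotation (GFF3), transcript/gene TPM matrices over ~10 embryonic stages
in two replicates, accessible elements with per-stage accessibility coupled
to their genes through four planted cis-regulatory logic types, a
conservation track, position weight matrices with planted binding
instances, and per-base Tn5 cut-site tracks with planted footprints.

Determinism: one master seed is split into fixed per-submodule streams, so
adding a later generator stage never perturbs earlier draws.
"""
from __future__ import annotations

import json

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..bedio import Interval, write_bed
from ..models import StageMatrix, TranscriptModel, TranscriptModelSet
from ..pwm import PWM, BASES, normalize_pwm, write_pwm_file
from .config import ConfigError, SyntheticConfig, TruthLabels

# fixed stream indices of the master seed
_S_ANNOT, _S_TYPES, _S_EXPR, _S_ACC, _S_CONS, _S_MOTIF, _S_CUTS, _S_DECOY = range(8)


def _stream(config: SyntheticConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[index])


# ---------------------------------------------------------------------------
# expression archetypes

def _zrow(c: np.ndarray) -> np.ndarray:
    sd = c.std(ddof=1)
    return (c - c.mean()) / (sd if sd > 0 else 1.0)


def _curve_pool(n_stages: int) -> np.ndarray:
    """Smooth candidate profiles: bumps/valleys over a peak x width grid
    plus rising/falling ramps with varying onset and steepness."""
    t = np.arange(n_stages, dtype=float)
    curves = []
    for p in np.linspace(0, n_stages - 1, 2 * n_stages - 1):
        for w in (0.7, 1.1, 1.7, 2.5):
            b = np.exp(-((t - p) ** 2) / (2 * w**2))
            curves.append(b)
            curves.append(-b)
    # ramp onsets stop early enough that every curve still varies over the
    # first n_stages-1 stages (the ATAC-covered prefix)
    for o in np.linspace(-1, n_stages - 4, 2 * n_stages):
        for length in (2.0, 4.0):
            r = np.clip((t - o) / length, 0.0, 1.0)
            curves.append(r)
            curves.append(-r)
    # quantize so sub-resolution tail differences become exact ties; rank
    # structure then survives any later monotone transform bit-for-bit
    return np.round(np.array(curves), 8)


def archetypes(n_clusters: int, n_stages: int) -> np.ndarray:
    """Cluster archetype profiles on the z-scale (rows mean 0, sd 1).

    Archetypes are chosen from a pool of smooth developmental shapes
    (bumps, valleys, ramps) by deterministic greedy farthest-point
    selection in the space the clustering actually operates in (z-scored
    exponentiated profiles). This maximizes the minimal pairwise archetype
    distance, keeping all clusters mutually separable at realistic noise —
    a naive peak-stage grid of bumps over ~10 stages is not.
    """
    pool = _curve_pool(n_stages)
    if n_clusters > len(pool):
        raise ValueError(f"n_clusters={n_clusters} exceeds archetype pool size")
    # separability is judged after the TPM backtransform + z-score the
    # clustering pipeline applies
    zed = np.array([_zrow(np.exp(_zrow(c))) for c in pool])
    chosen = [0]
    d = ((zed - zed[0]) ** 2).sum(axis=1)
    for _ in range(n_clusters - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, ((zed - zed[nxt]) ** 2).sum(axis=1))
    return np.array([_zrow(pool[i]) for i in chosen])


# ---------------------------------------------------------------------------
# annotation

@dataclass
class GeneLocus:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    n_isoforms: int


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[TranscriptModelSet, dict[str, int]]:
    """Gene models on >=2 chromosomes with non-overlapping loci.

    Multi-isoform genes (an ``isoform_rate`` fraction) carry 2-4 isoforms
    that share the first and last exon and differ by skipped internal
    exons.
    """
    rng = _stream(config, _S_ANNOT)
    n_chroms = max(2, 1 + config.n_genes // 300)
    models = TranscriptModelSet()
    cursors = {f"chr{i + 1}": 10_000 for i in range(n_chroms)}
    chrom_names = sorted(cursors)

    n_multi = int(round(config.isoform_rate * config.n_genes))
    multi_flags = np.zeros(config.n_genes, dtype=bool)
    multi_flags[rng.choice(config.n_genes, size=n_multi, replace=False)] = True

    for g in range(config.n_genes):
        gid = f"g{g:05d}"
        chrom = chrom_names[g % n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 9))
        if not multi_flags[g] and rng.random() < 0.1:
            n_exons = 1
        exon_lens = rng.integers(80, 400, size=n_exons)
        intron_lens = rng.integers(200, 1500, size=max(0, n_exons - 1))
        start = cursors[chrom]
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            if i < n_exons - 1:
                pos += int(el) + int(intron_lens[i])
            else:
                pos += int(el)
        n_iso = int(rng.integers(2, 5)) if multi_flags[g] else 1
        chains: list[tuple[tuple[int, int], ...]] = []
        for k in range(n_iso):
            if k == 0 or n_exons < 3:
                chain = tuple(exons)
            else:
                internal = list(range(1, n_exons - 1))
                chain = None
                for _ in range(10):
                    n_drop = int(rng.integers(1, len(internal) + 1))
                    drop = set(rng.choice(internal, size=n_drop, replace=False))
                    cand = tuple(e for i, e in enumerate(exons) if i not in drop)
                    if cand not in chains:
                        chain = cand
                        break
                if chain is None:
                    continue
            if chain in chains:
                continue
            chains.append(chain)
        for k, chain in enumerate(chains):
            models.add(
                TranscriptModel(
                    transcript_id=f"{gid}.t{k + 1}",
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=list(chain),
                    source="synthetic",
                )
            )
        models.gene_source[gid] = "synthetic"
        # spacing exceeds twice the maximal distal-element reach (~3.5 kb),
        # so elements never collide across loci and nearest-gene is unambiguous
        cursors[chrom] = pos + int(rng.integers(8000, 14000))

    genome = {c: int(cursors[c] + 10_000) for c in chrom_names}
    return models, genome


# ---------------------------------------------------------------------------
# gene regulatory types and expression

def assign_gene_types(config: SyntheticConfig, gene_ids: list[str]) -> dict[str, str]:
    """Draw one cis-logic type per gene from the configured mix; mass not
    covered by the mix falls to 'null' (uncoupled elements)."""
    rng = _stream(config, _S_TYPES)
    types = ["sync", "repression", "enh_switch", "early_open", "null"]
    probs = np.array([config.cislogic_mix.get(t, 0.0) for t in types])
    probs[-1] += 1.0 - probs.sum()
    draws = rng.choice(len(types), size=len(gene_ids), p=probs)
    return {gid: types[d] for gid, d in zip(gene_ids, draws)}


_ISOFORM_FRACTIONS = {
    2: (0.8, 0.2),
    3: (0.7, 0.2, 0.1),
    4: (0.65, 0.2, 0.1, 0.05),
}

_RAMP_LEN = 3
_RAMP_AMP = 2.5


def _ramp(n: int, onset: float, length: float = _RAMP_LEN) -> np.ndarray:
    t = np.arange(n, dtype=float)
    return np.clip((t - onset) / length, 0.0, 1.0)


def _bimodal_shapes(n: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(n, dtype=float)
    f1 = np.exp(-((t - 1.5) ** 2) / (2 * 1.2**2))
    f2 = np.exp(-((t - (n - 2.5)) ** 2) / (2 * 1.2**2))
    return f1, f2


@dataclass
class ExpressionData:
    tx_rep1: StageMatrix
    tx_rep2: StageMatrix
    gene_rep1: StageMatrix
    gene_rep2: StageMatrix
    gene_profiles: pd.DataFrame  # noise-free gene TPM, genes x RNA stages
    gene_map: dict[str, str]  # transcript -> gene
    truth: TruthLabels
    gene_types: dict[str, str] = field(default_factory=dict)
    mu_g: dict[str, float] = field(default_factory=dict)
    early_onset: dict[str, int] = field(default_factory=dict)
    pioneer_gene: str | None = None


def generate_expression(
    models: TranscriptModelSet, config: SyntheticConfig
) -> ExpressionData:
    """Transcript- and gene-level TPM matrices in two replicates, plus
    planted truth (cluster labels, switch events).

    Gene profiles are type-aware: archetype bumps for sync/repression/null
    genes (cluster label = archetype id), a bimodal early+late double bump
    for enhancer-switching genes, and a monotone ramp for early-opening
    genes (cluster label -1 for both bespoke shapes). TPM backtransform is
    exp(zscale*z + mu_g) with a lognormal per-gene log-mean, which cancels
    exactly under per-gene z-scoring. Replicates differ only by noise.
    """
    rng = _stream(config, _S_EXPR)
    genes = models.genes()
    gene_ids = sorted(genes)
    gene_types = assign_gene_types(config, gene_ids)
    arch = archetypes(config.n_clusters, config.n_stages)
    n = config.n_stages
    stages = config.rna_stages

    truth = TruthLabels(early_shift=config.early_shift)
    truth.cluster_peak_stage = {
        str(c): int(np.argmax(arch[c])) for c in range(config.n_clusters)
    }

    clusters = rng.integers(0, config.n_clusters, size=len(gene_ids))
    mu = rng.lognormal(mean=np.log(3.4), sigma=0.25, size=len(gene_ids))
    onsets = rng.integers(config.early_shift, max(config.early_shift + 1, n - _RAMP_LEN - 1),
                          size=len(gene_ids))

    # the pioneer TF gene: an archetype gene forced onto the archetype
    # highest at the pioneer stage, with a high expression floor
    pioneer_stage_idx = min(2, len(config.atac_stages) - 1)
    pioneer_gene: str | None = None
    best_cluster = int(np.argmax(arch[:, pioneer_stage_idx]))
    mu_map: dict[str, float] = {gid: float(mu[i]) for i, gid in enumerate(gene_ids)}
    for i, gid in enumerate(gene_ids):
        if gene_types[gid] in ("sync", "repression", "null"):
            pioneer_gene = gid
            clusters[i] = best_cluster
            mu_map[gid] = float(np.log(40.0))
            break

    # isoform fractions and switches (decided before profiles so switch
    # genes can get an expression floor keeping predominance defined)
    multi = [gid for gid in gene_ids if len(genes[gid]) >= 2]
    truth.multi_isoform_genes = multi
    switch_flags = rng.random(len(multi)) < config.switch_rate
    switch_stages = rng.integers(3, max(4, n - 2), size=len(multi))
    fractions: dict[str, np.ndarray] = {}  # transcript -> per-stage fraction
    for gid in gene_ids:
        tids = sorted(t.transcript_id for t in genes[gid])
        truth.gene_switch[gid] = False
        if len(tids) == 1:
            fractions[tids[0]] = np.ones(n)
            continue
        base = np.array(_ISOFORM_FRACTIONS[min(len(tids), 4)][: len(tids)])
        base = base / base.sum()
        frac = np.tile(base[:, None], (1, n)).astype(float)
        j = multi.index(gid)
        if switch_flags[j]:
            sw = int(switch_stages[j])
            mu_map[gid] = max(mu_map[gid], float(np.log(20.0)))
            frac[0, sw:], frac[1, sw:] = base[1], base[0]
            truth.gene_switch[gid] = True
            truth.switch_detail[gid] = {
                "stage_index": sw,
                "stage": stages[sw],
                "isoform_from": tids[0],
                "isoform_to": tids[1],
            }
        for tid, fr in zip(tids, frac):
            fractions[tid] = fr

    f1_shape, f2_shape = _bimodal_shapes(n)
    gene_profiles: dict[str, np.ndarray] = {}
    onset_map: dict[str, int] = {}
    for i, gid in enumerate(gene_ids):
        gtype = gene_types[gid]
        if gtype == "enh_switch":
            profile = (f1_shape + f2_shape) * np.exp(mu_map[gid])
            truth.gene_cluster[gid] = -1
        elif gtype == "early_open":
            onset_map[gid] = int(onsets[i])
            profile = np.exp(
                config.zscale * _RAMP_AMP * _ramp(n, onsets[i]) + mu_map[gid]
            )
            truth.gene_cluster[gid] = -1
        else:
            profile = np.exp(config.zscale * arch[clusters[i]] + mu_map[gid])
            truth.gene_cluster[gid] = int(clusters[i])
        truth.gene_type[gid] = gtype
        gene_profiles[gid] = profile

    # assemble matrices with per-transcript noise
    tx_ids = sorted(t.transcript_id for t in models)
    gene_of = models.transcript_to_gene()
    reps = []
    for _ in range(2):
        rows = np.empty((len(tx_ids), n))
        for r_i, tid in enumerate(tx_ids):
            gid = gene_of[tid]
            eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
            rows[r_i] = gene_profiles[gid] * fractions[tid] * np.exp(config.zscale * eps)
        reps.append(pd.DataFrame(rows, index=tx_ids, columns=stages))

    gene_reps = []
    for rep in reps:
        g = rep.groupby([gene_of[t] for t in rep.index]).sum()
        gene_reps.append(g.loc[gene_ids])

    return ExpressionData(
        tx_rep1=StageMatrix(reps[0]),
        tx_rep2=StageMatrix(reps[1]),
        gene_rep1=StageMatrix(gene_reps[0]),
        gene_rep2=StageMatrix(gene_reps[1]),
        gene_profiles=pd.DataFrame(gene_profiles).T.set_axis(stages, axis=1),
        gene_map=gene_of,
        truth=truth,
        gene_types=gene_types,
        mu_g=mu_map,
        early_onset=onset_map,
        pioneer_gene=pioneer_gene,
    )


# ---------------------------------------------------------------------------
# accessibility, conservation, motifs, cut sites

@dataclass
class SynthElement:
    element_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    etype: str
    profile: np.ndarray  # noise-free accessibility over ATAC stages


@dataclass
class AccessibilityData:
    elements: list[SynthElement]
    acc_rep1: StageMatrix
    acc_rep2: StageMatrix
    stage_peaks: dict[str, list[Interval]]
    constrained: list[Interval]
    cut_runs: dict[str, list[tuple[str, int, int, float]]]  # stage -> bedGraph runs
    sequences: dict[str, str]
    pwms: list[PWM]
    raw_pfms: dict[str, np.ndarray]
    genome: dict[str, int]
    truth: TruthLabels


def _place_elements(
    rng: np.random.Generator, locus: GeneLocus, n_elements: int, lengths: list[int]
) -> list[tuple[int, int]]:
    """Non-overlapping element intervals: promoter first, then gene body,
    then distal positions on the upstream side."""
    out: list[tuple[int, int]] = []
    tss = locus.tss
    upstream = -1 if locus.strand == "+" else 1  # direction away from the gene
    for i in range(n_elements):
        length = lengths[i]
        if i == 0:  # promoter, straddling the TSS
            start = tss - length // 2
        elif i == 1:  # gene body
            mid = (locus.start + locus.end) // 2
            start = mid - length // 2
            if abs(mid - tss) < length + 200:  # short gene: push distal instead
                start = tss + upstream * (1400 + 300 * i)
        else:  # distal, 1.4-2.4 kb beyond the TSS
            start = tss + upstream * int(1400 + 300 * i + rng.integers(0, 200))
            if upstream == -1:
                start -= length
        start = max(0, start)
        # enforce >=60 bp separation from previously placed elements,
        # repeating until stable (a push can create a new clash)
        moved = True
        guard = 0
        while moved and guard < 20:
            moved = False
            guard += 1
            for s, e in out:
                if start < e + 60 and s - 60 < start + length:
                    start = e + 60 + int(rng.integers(0, 50))
                    moved = True
        out.append((start, start + length))
    return out


def generate_accessibility(
    models: TranscriptModelSet,
    expression: ExpressionData,
    config: SyntheticConfig,
    genome: dict[str, int] | None = None,
) -> AccessibilityData:
    """Accessible elements with planted cis-logic coupling, per-stage peak
    calls, conservation track, PWMs with planted instances, and cut-site
    tracks with planted pioneer footprints."""
    if genome is None:
        _, genome = generate_annotation(config)
    rng = _stream(config, _S_ACC)
    n_atac = len(config.atac_stages)
    atac_stages = config.atac_stages
    truth = expression.truth
    gene_types = expression.gene_types
    arch = archetypes(config.n_clusters, config.n_stages)

    loci: dict[str, GeneLocus] = {}
    for gid in sorted(models.genes()):
        chrom, strand, start, end = models.gene_span(gid)
        tss = start if strand == "+" else end - 1
        loci[gid] = GeneLocus(gid, chrom, strand, start, end, tss, 0)

    f1_shape, f2_shape = _bimodal_shapes(config.n_stages)
    specs: list[SynthElement] = []
    for gid in sorted(loci):
        locus = loci[gid]
        gtype = gene_types[gid]
        if gtype == "enh_switch":
            n_el = 2
        elif gtype == "early_open":
            # promoter plus >=1 early-shifted element
            n_el = 2 + int(rng.integers(0, 2))
        elif gtype == "null":
            n_el = 1 + int(rng.integers(0, 2))
        else:
            n_el = 1 + int(rng.integers(0, 4))
        lengths = [600 if gtype == "null" else int(rng.integers(250, 450))
                   for _ in range(n_el)]
        positions = _place_elements(rng, locus, n_el, lengths)
        mu_e = rng.normal(np.log(30.0), 0.4, size=n_el)
        for i, (start, end) in enumerate(positions):
            if gtype == "sync":
                z = arch[truth.gene_cluster[gid]][:n_atac]
                profile = np.exp(config.zscale * z + mu_e[i])
            elif gtype == "repression":
                z = arch[truth.gene_cluster[gid]][:n_atac]
                profile = np.exp(-config.zscale * z + mu_e[i])
            elif gtype == "enh_switch":
                shape = (f1_shape if i == 0 else f2_shape)[:n_atac]
                profile = shape * np.exp(mu_e[i])
            elif gtype == "early_open":
                # the promoter tracks the gene (synchronized); the other
                # elements are the gene ramp shifted earlier by early_shift
                onset = expression.early_onset[gid]
                if i > 0:
                    onset -= config.early_shift
                profile = np.exp(
                    config.zscale * _RAMP_AMP * _ramp(n_atac, onset) + mu_e[i]
                )
            else:  # null: flat, uncoupled
                profile = np.full(n_atac, np.exp(mu_e[i]))
            etype = gtype
            if gtype == "early_open" and i == 0:
                etype = "sync"
            specs.append(
                SynthElement("", gid, locus.chrom, start, end, etype, profile)
            )

    specs.sort(key=lambda s: (s.chrom, s.start))
    for i, s in enumerate(specs):
        s.element_id = f"e{i}"
        truth.element_type[s.element_id] = s.etype
        truth.element_gene[s.element_id] = s.gene_id
        if s.etype == "enh_switch":
            truth.enh_switch_pairs.setdefault(s.gene_id, []).append(s.element_id)

    # ---- motifs, sequences, pioneer accessibility boost -------------------
    mrng = _stream(config, _S_MOTIF)
    pwms: list[PWM] = []
    raw_pfms: dict[str, np.ndarray] = {}
    motif_ids = [f"M{i}" for i in range(config.n_motifs)]
    consensi: dict[str, str] = {}
    for mid in motif_ids:
        cons = "".join(BASES[i] for i in mrng.integers(0, 4, size=config.motif_length))
        consensi[mid] = cons
        raw = np.full((config.motif_length, 4), 0.02)
        for p, b in enumerate(cons):
            raw[p, BASES.index(b)] = 0.94
        raw_pfms[mid] = raw
        pwms.append(normalize_pwm(mid, f"TF_{mid}", raw))

    pioneer_stage_idx = min(2, n_atac - 1)
    null_elements = [s for s in specs if s.etype == "null"]
    n_pioneer_el = min(20, max(1, len(null_elements)))
    arch_genes = sorted(
        gid for gid, c in truth.gene_cluster.items() if c >= 0
    )
    pioneer_set = set(config.pioneer_ids)
    truth.motif_pioneer = {mid: mid in pioneer_set for mid in motif_ids}
    for k, mid in enumerate(motif_ids):
        truth.motif_tf[mid] = arch_genes[k % len(arch_genes)] if arch_genes else ""
    pioneer_gene = expression.pioneer_gene
    for mid in config.pioneer_ids:
        if pioneer_gene is not None:
            truth.motif_tf[mid] = pioneer_gene
        truth.pioneer_stage[mid] = atac_stages[pioneer_stage_idx]

    planted: dict[str, list[tuple[str, int]]] = {mid: [] for mid in motif_ids}
    srng = _stream(config, _S_CUTS)
    sequences: dict[str, str] = {}
    for s in specs:
        length = s.end - s.start
        seq = "".join(BASES[i] for i in srng.integers(0, 4, size=length))
        sequences[s.element_id] = seq

    def plant(mid: str, element: SynthElement, offset: int) -> None:
        seq = sequences[element.element_id]
        cons = consensi[mid]
        sequences[element.element_id] = (
            seq[:offset] + cons + seq[offset + len(cons):]
        )
        planted[mid].append((element.element_id, offset))

    for k, mid in enumerate(motif_ids):
        if mid in pioneer_set:
            targets = null_elements[:n_pioneer_el]
        else:
            pool = [s for s in specs if s.etype != "null"]
            n_t = max(5, len(pool) // 10)
            idx = mrng.choice(len(pool), size=min(n_t, len(pool)), replace=False)
            targets = [pool[i] for i in sorted(idx)]
        for el in targets:
            # motif-indexed offsets keep instances of different motifs in the
            # same element from overwriting each other
            length = el.end - el.start
            offset = (
                (length - config.motif_length) // 2
                + (k - config.n_motifs // 2) * (config.motif_length + 4)
            )
            offset = int(np.clip(offset, 0, length - config.motif_length))
            plant(mid, el, offset)
    truth.motif_elements = {
        mid: [eid for eid, _ in planted[mid]] for mid in motif_ids
    }

    # pioneer-bound elements get an accessibility burst at the pioneer stage
    pioneer_eids = {
        eid for mid in config.pioneer_ids for eid, _ in planted[mid]
    }
    for s in specs:
        if s.element_id in pioneer_eids:
            s.profile = s.profile.copy()
            s.profile[pioneer_stage_idx] *= config.pioneer_acc_boost

    # ---- accessibility matrices (2 replicates) ----------------------------
    eids = [s.element_id for s in specs]
    acc_reps = []
    for _ in range(2):
        rows = np.empty((len(specs), n_atac))
        for i, s in enumerate(specs):
            eps = rng.normal(0.0, config.noise_sd, size=n_atac) if config.noise_sd > 0 else 0.0
            rows[i] = s.profile * np.exp(config.zscale * eps)
        acc_reps.append(pd.DataFrame(rows, index=eids, columns=atac_stages))

    # ---- per-stage peak calls (true peaks + sub-threshold decoys) ---------
    prng = _stream(config, _S_DECOY)
    stage_peaks: dict[str, list[Interval]] = {st: [] for st in atac_stages}
    for s in specs:
        open_at = s.profile >= 0.5 * s.profile.max()
        for j, st in enumerate(atac_stages):
            if open_at[j]:
                q = float(prng.uniform(8.0, 60.0))
                stage_peaks[st].append(
                    Interval(s.chrom, s.start, s.end, name=f"{s.element_id}:{st}", score=q)
                )
    occupied: dict[str, list[tuple[int, int]]] = {}
    for s in specs:
        occupied.setdefault(s.chrom, []).append((s.start, s.end))
    for iv_list in occupied.values():
        iv_list.sort()

    def clashes(chrom: str, start: int, end: int, margin: int = 2) -> bool:
        for s0, e0 in occupied.get(chrom, []):
            if start < e0 + margin and s0 - margin < end:
                return True
        return False

    n_decoys = max(3, len(specs) // 5)
    chroms = sorted(genome)
    made = 0
    tries = 0
    while made < n_decoys and tries < 50 * n_decoys:
        tries += 1
        chrom = chroms[int(prng.integers(0, len(chroms)))]
        length = int(prng.integers(150, 400))
        start = int(prng.integers(0, max(1, genome[chrom] - length)))
        if clashes(chrom, start, start + length):
            continue
        st = atac_stages[int(prng.integers(0, n_atac))]
        stage_peaks[st].append(
            Interval(chrom, start, start + length, name=f"decoy{made}",
                     score=float(prng.uniform(1.0, 6.5)))
        )
        made += 1

    # ---- conservation track ----------------------------------------------
    crng = _stream(config, _S_CONS)
    constrained: list[Interval] = []
    conserved_draw = crng.random(len(specs)) < config.conserved_fraction_fg
    for s, hit in zip(specs, conserved_draw):
        truth.element_conserved[s.element_id] = bool(hit)
        if hit:
            length = s.end - s.start
            cs = s.start + length // 4
            constrained.append(
                Interval(s.chrom, cs, cs + length // 2, name=f"cr_{s.element_id}",
                         score=0.0, rs=float(crng.uniform(20.0, 500.0)))
            )
    # background regions tuned so a random element-length interval overlaps
    # the track with probability ~conserved_fraction_bg
    if config.conserved_fraction_bg > 0:
        med_len = int(np.median([s.end - s.start for s in specs])) if specs else 300
        region_len = 300
        rate = -np.log(1.0 - config.conserved_fraction_bg) / (med_len + region_len)
        cons_occ = {
            chrom: sorted(
                [(s.start, s.end) for s in specs if s.chrom == chrom]
            )
            for chrom in chroms
        }
        bg_count = 0
        for chrom in chroms:
            n_bg = int(round(rate * genome[chrom]))
            placed = 0
            tries = 0
            taken = list(cons_occ.get(chrom, []))
            while placed < n_bg and tries < 50 * n_bg:
                tries += 1
                start = int(crng.integers(0, max(1, genome[chrom] - region_len)))
                end = start + region_len
                if any(start < e0 + 1 and s0 - 1 < end for s0, e0 in taken):
                    continue
                taken.append((start, end))
                constrained.append(
                    Interval(chrom, start, end, name=f"bg{bg_count}",
                             score=0.0, rs=float(crng.uniform(1.0, 50.0)))
                )
                bg_count += 1
                placed += 1

    # ---- cut-site tracks with planted footprints --------------------------
    cut_runs: dict[str, list[tuple[str, int, int, float]]] = {}
    c0 = config.cut_baseline
    by_eid = {s.element_id: s for s in specs}
    for j, st in enumerate(atac_stages):
        runs: list[tuple[str, int, int, float]] = []
        for s in specs:
            # piecewise-constant per-base density over the element
            density = np.full(s.end - s.start, c0)
            for mid in motif_ids:
                is_pioneer = mid in pioneer_set
                for eid, offset in planted[mid]:
                    if eid != s.element_id:
                        continue
                    core = slice(offset, offset + config.motif_length)
                    if is_pioneer and j == pioneer_stage_idx:
                        lo = max(0, offset - 200)
                        hi = min(len(density), offset + config.motif_length + 200)
                        density[lo:hi] *= config.pioneer_flank_boost
                        density[core] = c0 * config.pioneer_core_factor
                    else:
                        density[core] *= 0.5
            # run-length encode
            change = np.flatnonzero(np.diff(density)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [density.size]])
            for a, b in zip(starts, ends):
                runs.append((s.chrom, s.start + int(a), s.start + int(b),
                             float(density[a])))
        runs.sort()
        cut_runs[st] = runs

    return AccessibilityData(
        elements=specs,
        acc_rep1=StageMatrix(acc_reps[0]),
        acc_rep2=StageMatrix(acc_reps[1]),
        stage_peaks=stage_peaks,
        constrained=sorted(constrained, key=lambda r: (r.chrom, r.start)),
        cut_runs=cut_runs,
        sequences=sequences,
        pwms=pwms,
        raw_pfms=raw_pfms,
        genome=genome,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# dataset assembly on disk

def generate_dataset(config: SyntheticConfig, outdir) -> Path:
    """Generate and write the full dataset; returns the output directory.

    Files: annotation.gff3, genome.tsv, expr_{tx,gene}_rep{1,2}.tsv,
    peaks_<stage>.bed, acc_rep{1,2}.tsv, conserved.bed,
    cutsites_<stage>.bedGraph, elements.fa, motifs/<id>.txt, truth.json,
    manifest.json.
    """
    from ..gff3 import write_gff3

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    models, genome = generate_annotation(config)
    expr = generate_expression(models, config)
    acc = generate_accessibility(models, expr, config, genome=genome)

    write_gff3(models, out / "annotation.gff3")
    with open(out / "genome.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in sorted(genome):
            fh.write(f"{chrom}\t{genome[chrom]}\n")
    expr.tx_rep1.to_tsv(out / "expr_tx_rep1.tsv")
    expr.tx_rep2.to_tsv(out / "expr_tx_rep2.tsv")
    expr.gene_rep1.to_tsv(out / "expr_gene_rep1.tsv")
    expr.gene_rep2.to_tsv(out / "expr_gene_rep2.tsv")
    acc.acc_rep1.to_tsv(out / "acc_rep1.tsv")
    acc.acc_rep2.to_tsv(out / "acc_rep2.tsv")
    for st, peaks in acc.stage_peaks.items():
        write_bed(sorted(peaks, key=lambda p: (p.chrom, p.start)),
                  out / f"peaks_{st}.bed")
    write_bed(acc.constrained, out / "conserved.bed")
    for st, runs in acc.cut_runs.items():
        with open(out / f"cutsites_{st}.bedGraph", "w") as fh:
            for chrom, s, e, v in runs:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    with open(out / "elements.fa", "w") as fh:
        for eid in sorted(acc.sequences, key=lambda e: int(e[1:])):
            fh.write(f">{eid}\n{acc.sequences[eid]}\n")
    motif_dir = out / "motifs"
    motif_dir.mkdir(exist_ok=True)
    for pwm in acc.pwms:
        write_pwm_file(pwm, motif_dir / f"{pwm.motif_id}.txt",
                       raw=acc.raw_pfms[pwm.motif_id])
    acc.truth.save(out / "truth.json")
    with open(out / "tf_map.tsv", "w") as fh:
        fh.write("motif\ttf_gene\n")
        for mid in sorted(acc.truth.motif_tf, key=lambda m: int(m[1:])):
            fh.write(f"{mid}\t{acc.truth.motif_tf[mid]}\n")
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "rna_stages": config.rna_stages,
        "atac_stages": config.atac_stages,
        "stage_map": config.stage_map,
        "n_transcripts": len(models),
        "n_genes": len(models.gene_ids),
        "n_elements": len(acc.elements),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
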