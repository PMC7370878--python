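"""Accessible-element atlas: q-value filtering and cross-stage merging of
peaks, nearest-gene assignment, genomic categorization, accessibility
variability, and the conservation enrichment test against length-matched
random intervals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bedio import Interval
from .models import StageMatrix, TranscriptModelSet

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "gene_body", "downstream", "distal_intergenic")


@dataclass
class Element:
    """A merged accessible interval with its annotations."""

    element_id: str
    chrom: str
    start: int
    end: int
    max_neglog_q: float
    stages: tuple[str, ...] = ()
    nearest_gene: str | None = None
    distance: int | None = None
    category: str | None = None
    conserved: bool | None = None
    conserved_ratio: float | None = None
    rs_score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, name=self.element_id)


def filter_and_merge_peaks(
    stage_peaks: dict[str, list[Interval]], min_neglog_q: float = 7.0
) -> list[Element]:
    """Drop peaks with -log10(q) <= ``min_neglog_q`` (strict filter), then
    merge surviving peaks across all stages by single-linkage overlap.

    Each merged element records the stages that contributed peaks and the
    maximum score among them. Elements are returned sorted by position and
    named e0, e1, ... in that order.
    """
    kept: list[tuple[str, int, int, float, str]] = []
    for stage, peaks in stage_peaks.items():
        for p in peaks:
            if p.score > min_neglog_q:
                kept.append((p.chrom, p.start, p.end, p.score, stage))
    kept.sort()
    elements: list[Element] = []
    current: list | None = None
    cur_stages: set[str] = set()
    for chrom, start, end, score, stage in kept:
        if current is not None and chrom == current[0] and start < current[2]:
            current[2] = max(current[2], end)
            current[3] = max(current[3], score)
            cur_stages.add(stage)
        else:
            if current is not None:
                elements.append(
                    Element("", current[0], current[1], current[2], current[3],
                            stages=tuple(sorted(cur_stages)))
                )
            current = [chrom, start, end, score]
            cur_stages = {stage}
    if current is not None:
        elements.append(
            Element("", current[0], current[1], current[2], current[3],
                    stages=tuple(sorted(cur_stages)))
        )
    for i, el in enumerate(elements):
        el.element_id = f"e{i}"
    return elements


@dataclass
class _GeneIndex:
    gene_ids: list[str]
    chrom: list[str]
    strand: list[str]
    start: np.ndarray
    end: np.ndarray
    tss: np.ndarray

    @classmethod
    def build(cls, models: TranscriptModelSet) -> "_GeneIndex":
        gids, chroms, strands, starts, ends, tsss = [], [], [], [], [], []
        for gid, ts in models.genes().items():
            gids.append(gid)
            chroms.append(ts[0].chrom)
            strands.append(ts[0].strand)
            start = min(t.start for t in ts)
            end = max(t.end for t in ts)
            starts.append(start)
            ends.append(end)
            tsss.append(start if ts[0].strand == "+" else end - 1)
        return cls(gids, chroms, strands, np.asarray(starts), np.asarray(ends),
                   np.asarray(tsss))


def _gene_distance(el: Element, start: int, end: int) -> int:
    """bp gap between element and a gene span; 0 when they overlap."""
    if el.start < end and start < el.end:
        return 0
    return start - el.end + 1 if start >= el.end else el.start - end + 1


def assign_nearest_gene(
    elements: list[Element], models: TranscriptModelSet
) -> list[Element]:
    """Attach the closest gene (by gene-span distance) to each element.

    Ties by distance are broken by the nearer strand-aware TSS, then by
    lexicographic gene id. Elements on chromosomes without genes stay
    unassigned.
    """
    index = _GeneIndex.build(models)
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(index.chrom):
        by_chrom.setdefault(c, []).append(i)
    for el in elements:
        idxs = by_chrom.get(el.chrom)
        if not idxs:
            el.nearest_gene = None
            el.distance = None
            continue
        center = (el.start + el.end - 1) / 2
        best = min(
            idxs,
            key=lambda i: (
                _gene_distance(el, index.start[i], index.end[i]),
                abs(index.tss[i] - center),
                index.gene_ids[i],
            ),
        )
        el.nearest_gene = index.gene_ids[best]
        el.distance = _gene_distance(el, index.start[best], index.end[best])
    return elements


def categorize_elements(
    elements: list[Element],
    models: TranscriptModelSet,
    promoter_window: tuple[int, int] = (-1000, 500),
    downstream_window: int = 1000,
) -> list[Element]:
    """Assign each element one genomic category relative to its nearest gene.

    Precedence: promoter (overlapping the strand-aware TSS window) >
    gene_body (overlapping the gene span) > downstream (within
    ``downstream_window`` past the 3' end) > distal_intergenic.
    """
    spans = {gid: models.gene_span(gid) for gid in models.gene_ids}
    up, down = promoter_window
    for el in elements:
        if el.nearest_gene is None:
            el.category = "distal_intergenic"
            continue
        chrom, strand, gstart, gend = spans[el.nearest_gene]
        if strand == "+":
            tss = gstart
            pstart, pend = tss + up, tss + down + 1
            dstart, dend = gend, gend + downstream_window
        else:
            tss = gend - 1
            pstart, pend = tss - down, tss - up + 1
            dstart, dend = gstart - downstream_window, gstart
        if el.start < pend and pstart < el.end:
            el.category = "promoter"
        elif el.start < gend and gstart < el.end:
            el.category = "gene_body"
        elif el.start < dend and dstart < el.end:
            el.category = "downstream"
        else:
            el.category = "distal_intergenic"
    return elements


def accessibility_variability(
    matrix: StageMatrix, pseudocount: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-element max/min fold change across stages, with strict >2x and
    >5x variability flags.

    Values are expected to be library-size normalized (see the pipeline's
    normalization step); a pseudocount guards against zero minima.
    """
    x = matrix.values
    if (x < 0).any():
        raise ValueError("accessibility values must be non-negative")
    fold = (x.max(axis=1) + pseudocount) / (x.min(axis=1) + pseudocount)
    return fold, fold > 2.0, fold > 5.0


def normalize_accessibility(matrix: StageMatrix) -> StageMatrix:
    """Scale each stage column so its total over elements equals the mean
    stage total (counts-per-mean-library over elements)."""
    import pandas as pd

    totals = matrix.data.sum(axis=0)
    scale = totals.mean() / totals
    return StageMatrix(matrix.data * scale)


class _Track:
    """Sorted, disjoint constrained regions per chromosome with prefix
    coverage sums, supporting O(log n) overlap queries."""

    def __init__(self, regions: list[Interval]):
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.rs: dict[str, np.ndarray] = {}
        self.prefix: dict[str, np.ndarray] = {}
        per: dict[str, list[Interval]] = {}
        for r in regions:
            per.setdefault(r.chrom, []).append(r)
        for chrom, rr in per.items():
            rr.sort(key=lambda r: r.start)
            for a, b in zip(rr, rr[1:]):
                if b.start < a.end:
                    raise ValueError("constrained regions must be disjoint per chromosome")
            self.starts[chrom] = np.array([r.start for r in rr])
            self.ends[chrom] = np.array([r.end for r in rr])
            self.rs[chrom] = np.array(
                [r.rs if r.rs is not None else np.nan for r in rr]
            )
            lengths = self.ends[chrom] - self.starts[chrom]
            self.prefix[chrom] = np.concatenate([[0], np.cumsum(lengths)])

    def overlap_stats(
        self, chrom: str, start: np.ndarray, end: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(overlapped bases, max RS or nan) for each query interval."""
        n = len(start)
        if chrom not in self.starts:
            return np.zeros(n), np.full(n, np.nan)
        s, e, pre = self.starts[chrom], self.ends[chrom], self.prefix[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        bases = np.zeros(n)
        maxrs = np.full(n, np.nan)
        for i in range(n):
            if hi[i] <= lo[i]:
                continue
            full = pre[hi[i]] - pre[lo[i]]
            # trim the flanking partial overlaps
            full -= max(0, start[i] - s[lo[i]])
            full -= max(0, e[hi[i] - 1] - end[i])
            bases[i] = full
            seg = self.rs[chrom][lo[i]: hi[i]]
            if not np.isnan(seg).all():
                maxrs[i] = np.nanmax(seg)
        return bases, maxrs


def conservation_overlap(
    elements: list[Element], constrained: list[Interval]
) -> list[Element]:
    """Flag elements overlapping constrained regions as conserved; record
    the overlapped-base ratio and the max RS score over overlapped regions."""
    track = _Track(constrained)
    by_chrom: dict[str, list[Element]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    for chrom, els in by_chrom.items():
        starts = np.array([e.start for e in els])
        ends = np.array([e.end for e in els])
        bases, maxrs = track.overlap_stats(chrom, starts, ends)
        for el, b, r in zip(els, bases, maxrs):
            el.conserved = bool(b > 0)
            el.conserved_ratio = float(b / el.length)
            el.rs_score = None if np.isnan(r) else float(r)
    return elements


def sample_length_matched(
    lengths: np.ndarray,
    genome_lengths: dict[str, int],
    n: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Random genomic intervals with lengths drawn (with replacement) from
    the observed length distribution; chromosomes chosen weighted by size.

    Intervals that would run past a chromosome end are rejected and
    redrawn (logged at debug level).
    """
    chroms = sorted(genome_lengths)
    sizes = np.array([genome_lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out: list[tuple[str, int, int]] = []
    n_reject = 0
    while len(out) < n:
        need = n - len(out)
        ls = rng.choice(lengths, size=need, replace=True)
        cs = rng.choice(len(chroms), size=need, p=probs)
        starts = np.floor(rng.random(need) * sizes[cs]).astype(int)
        for length, ci, start in zip(ls, cs, starts):
            if start + length > sizes[ci]:
                n_reject += 1
                continue
            out.append((chroms[ci], int(start), int(start + length)))
    if n_reject:
        logger.debug("rejected %d intervals running past chromosome ends", n_reject)
    return out


@dataclass
class ConservationTest:
    observed_ratios: np.ndarray
    null_ratios: np.ndarray  # pooled over repeats
    null_conserved_fraction: np.ndarray  # per repeat
    observed_conserved_fraction: float
    ks_statistic: float
    p_value: float
    n_repeats: int = 0


def length_matched_null_test(
    elements: list[Element],
    genome_lengths: dict[str, int],
    constrained: list[Interval],
    n_repeats: int = 200,
    seed: int = 0,
) -> ConservationTest:
    """Compare element conserved ratios against length-matched random
    intervals.

    Each repeat samples ``len(elements)`` intervals uniformly over the
    genome with lengths resampled from the observed distribution, records
    their conserved-base ratios and conserved fraction, and finally a
    two-sample two-sided KS test compares the observed ratio distribution
    to the pooled null ratios.
    """
    elements = conservation_overlap(elements, constrained)
    observed = np.array([el.conserved_ratio for el in elements])
    track = _Track(constrained)
    lengths = np.array([el.length for el in elements])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null_pool: list[np.ndarray] = []
    null_fracs = np.zeros(n_repeats)
    for rep in range(n_repeats):
        sampled = sample_length_matched(lengths, genome_lengths, len(elements), rng)
        ratios = np.zeros(len(sampled))
        per: dict[str, list[int]] = {}
        for i, (chrom, _, _) in enumerate(sampled):
            per.setdefault(chrom, []).append(i)
        for chrom, idxs in per.items():
            ss = np.array([sampled[i][1] for i in idxs])
            ee = np.array([sampled[i][2] for i in idxs])
            bases, _ = track.overlap_stats(chrom, ss, ee)
            ratios[idxs] = bases / (ee - ss)
        null_pool.append(ratios)
        null_fracs[rep] = (ratios > 0).mean()
    pooled = np.concatenate(null_pool)
    ks = stats.ks_2samp(observed, pooled, alternative="two-sided", method="asymp")
    return ConservationTest(
        observed_ratios=observed,
        null_ratios=pooled,
        null_conserved_fraction=null_fracs,
        observed_conserved_fraction=float((observed > 0).mean()),
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        n_repeats=n_repeats,
    )


def elements_table(elements: list[Element]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "element": el.element_id,
                "chrom": el.chrom,
                "start": el.start,
                "end": el.end,
                "max_neglog_q": el.max_neglog_q,
                "nearest_gene": el.nearest_gene,
                "distance": el.distance,
                "category": el.category,
                "conserved": el.conserved,
                "conserved_ratio": el.conserved_ratio,
                "rs_score": el.rs_score,
            }
            for el in elements
        ]
    )
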