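"""Trans-regulatory logic: motif scanning, accessibility deviation scores,
chromatin opening index, footprint aggregation, and pioneer-TF calling.

A pioneer TF engages closed chromatin and opens it for other factors.
Operationally a TF is called a pioneer at a stage when it jointly shows
(i) a high chromatin opening index (log2 enrichment of Tn5 cut density
flanking its bound motifs over the accessible-compartment background),
(ii) a high motif accessibility deviation z-score against matched
background element sets, and (iii) expression above a TPM floor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pwm import PWM, BASES

_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based within the scanned sequence
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in seq.upper()], dtype=int)


def _scan_one_strand(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every window start; NaN where the window has an N."""
    L = lom.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for off in range(L):
        window_codes = codes[off: off + n]
        invalid = window_codes < 0
        bad |= invalid
        safe = np.where(invalid, 0, window_codes)
        scores += lom[off, safe]
    scores[bad] = np.nan
    return scores


def log_odds_matrix(pwm: PWM, background: np.ndarray | None = None) -> np.ndarray:
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, float)
    return np.log2(pwm.matrix / background[None, :])


def scan_motifs(
    sequences: dict[str, str],
    pwm: PWM,
    background: np.ndarray | None = None,
    score_fraction: float = 0.8,
) -> list[MotifHit]:
    """Scan both strands of each sequence for PWM matches.

    A window is a hit when its log-odds score reaches ``score_fraction``
    of the PWM's maximum attainable score. Windows containing N are
    skipped; sequences shorter than the motif yield no hits. Hit positions
    are 0-based starts on the forward strand.
    """
    lom_fwd = log_odds_matrix(pwm, background)
    lom_rev = log_odds_matrix(pwm.reverse_complement(), background)
    threshold = score_fraction * lom_fwd.max(axis=1).sum()
    hits: list[MotifHit] = []
    for sid in sorted(sequences):
        codes = _encode(sequences[sid])
        for strand, lom in (("+", lom_fwd), ("-", lom_rev)):
            scores = _scan_one_strand(codes, lom)
            for pos in np.flatnonzero(~np.isnan(scores) & (scores >= threshold)):
                hits.append(MotifHit(sid, int(pos), strand, float(scores[pos])))
    return hits


@dataclass
class DeviationResult:
    z: pd.DataFrame  # motifs x stages; NaN where undefined
    raw: pd.DataFrame  # observed fractional deviations y


def _raw_deviation(X: np.ndarray, member: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Fractional deviation y_s = (o_s - e_s)/e_s for one element set."""
    o = X[member].sum(axis=0)
    e = weights[member].sum() / weights.sum() * X.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = (o - e) / e
    y[e == 0] = np.nan
    return y


def motif_deviation(
    counts: pd.DataFrame,
    hit_indicator: pd.DataFrame,
    n_background: int = 50,
    seed: int = 0,
    n_bins: int = 10,
) -> DeviationResult:
    """Background-corrected motif accessibility deviations.

    ``counts`` is elements x stages accessibility; ``hit_indicator`` is a
    boolean elements x motifs membership matrix. For each motif the
    observed fractional deviation per stage is compared against
    ``n_background`` element sets matched on mean-accessibility deciles,
    giving z = (y - mean(y_bg)) / sd(y_bg). Deviations are NaN where the
    expectation is zero or the background spread vanishes.
    """
    if not counts.index.equals(hit_indicator.index):
        raise ValueError("counts and hit indicator must share element ids")
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("accessibility counts must be non-negative")
    a = X.mean(axis=1)
    # decile bins of mean accessibility; each element belongs to one bin
    edges = np.quantile(a, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, a, side="right")
    members_by_bin = {b: np.flatnonzero(bins == b) for b in range(n_bins)}

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z_rows, y_rows = [], []
    for motif in hit_indicator.columns:
        member = hit_indicator[motif].to_numpy(dtype=bool)
        y = _raw_deviation(X, member, a)
        bg_ys = np.empty((n_background, X.shape[1]))
        motif_bins = bins[member]
        # matched elements are drawn from the same decile excluding the
        # motif's own elements; in a small element universe the hit set can
        # dominate its decile, which would otherwise contaminate the null
        pools = {}
        for b in set(motif_bins):
            non_self = members_by_bin[b][~member[members_by_bin[b]]]
            pools[b] = non_self if non_self.size else members_by_bin[b]
        for b in range(n_background):
            sampled = np.array(
                [rng.choice(pools[bin_]) for bin_ in motif_bins], dtype=int
            )
            mask = np.zeros(X.shape[0], dtype=bool)
            mask[sampled] = True
            bg_ys[b] = _raw_deviation(X, mask, a)
        mu = np.nanmean(bg_ys, axis=0)
        sd = np.nanstd(bg_ys, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (y - mu) / sd
        z[sd == 0] = np.nan
        z_rows.append(z)
        y_rows.append(y)
    stages = list(counts.columns)
    motifs = list(hit_indicator.columns)
    return DeviationResult(
        z=pd.DataFrame(z_rows, index=motifs, columns=stages),
        raw=pd.DataFrame(y_rows, index=motifs, columns=stages),
    )


def track_background_density(
    track: dict[str, np.ndarray], intervals: list[tuple[str, int, int]] | None = None
) -> float:
    """Mean per-base cut density over the given intervals (the accessible
    compartment), or over all defined track positions when none given."""
    total = 0.0
    bases = 0
    if intervals is None:
        for arr in track.values():
            total += float(arr.sum())
            bases += arr.size
    else:
        for chrom, start, end in intervals:
            arr = track.get(chrom)
            if arr is None:
                continue
            end = min(end, arr.size)
            if end > start:
                total += float(arr[start:end].sum())
                bases += end - start
    return total / bases if bases else 0.0


def opening_index(
    track: dict[str, np.ndarray],
    hit_positions: list[tuple[str, int]],
    motif_length: int,
    background_density: float,
    flank: int = 200,
    min_hits: int = 10,
) -> float | None:
    """Chromatin opening index: log2 of the cut density in ±``flank``
    around hit centers (core excluded) over the background density.

    ``hit_positions`` are (chrom, motif start) in genomic coordinates.
    Flank densities are pooled over hits before taking the log. Returns
    None when there are fewer than ``min_hits`` hits or the background
    density is zero.
    """
    if len(hit_positions) < min_hits or background_density <= 0:
        return None
    total = 0.0
    bases = 0
    for chrom, start in hit_positions:
        arr = track.get(chrom)
        if arr is None:
            continue
        core_start, core_end = start, start + motif_length
        for s, e in ((core_start - flank, core_start), (core_end, core_end + flank)):
            s, e = max(0, s), min(arr.size, e)
            if e > s:
                total += float(arr[s:e].sum())
                bases += e - s
    if bases == 0:
        return None
    ratio = (total / bases) / background_density
    if ratio <= 0:
        return None
    return float(np.log2(ratio))


def footprint_profile(
    track: dict[str, np.ndarray],
    hits: list[tuple[str, int, str]],
    motif_length: int,
    flank: int = 100,
) -> np.ndarray:
    """Aggregate per-position cut counts centered on motif hits.

    ``hits`` are (chrom, motif start, strand) in genomic coordinates; minus
    strand profiles are reversed so position 0 is always the 5' flank edge.
    Returns a vector of length motif + 2*flank.
    """
    if not hits:
        raise ValueError("footprint aggregation needs at least one hit")
    width = motif_length + 2 * flank
    profile = np.zeros(width)
    for chrom, start, strand in hits:
        arr = track.get(chrom)
        if arr is None:
            continue
        lo = start - flank
        window = np.zeros(width)
        s, e = max(0, lo), min(arr.size, lo + width)
        if e > s:
            window[s - lo: e - lo] = arr[s:e]
        profile += window[::-1] if strand == "-" else window
    return profile


PIONEER_THRESHOLDS = {"opening": 2.5, "deviation": 10.0, "tpm": 5.0}


def call_pioneer_tfs(
    scores: pd.DataFrame,
    opening_min: float = 2.5,
    deviation_min: float = 10.0,
    tpm_min: float = 5.0,
) -> pd.DataFrame:
    """Pioneer calls from a long-format (tf, stage, opening, deviation_z,
    tpm) table: pioneer iff all three scores are present and strictly
    exceed their thresholds."""
    required = {"tf", "stage", "opening", "deviation_z", "tpm"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    out = scores.copy()
    present = out[["opening", "deviation_z", "tpm"]].notna().all(axis=1)
    out["pioneer"] = (
        present
        & (out["opening"] > opening_min)
        & (out["deviation_z"] > deviation_min)
        & (out["tpm"] > tpm_min)
    )
    return out


def tf_activity_summary(
    deviation_z: pd.DataFrame, expression: pd.DataFrame
) -> pd.DataFrame:
    """Long-format join of per-TF per-stage deviation z and expression TPM
    for dot-plot export. Missing cells are kept and flagged rather than
    imputed."""
    z_long = deviation_z.rename_axis("tf").reset_index().melt(
        id_vars="tf", var_name="stage", value_name="deviation_z"
    )
    e_long = expression.rename_axis("tf").reset_index().melt(
        id_vars="tf", var_name="stage", value_name="tpm"
    )
    merged = z_long.merge(e_long, on=["tf", "stage"], how="outer")
    merged["complete"] = merged[["deviation_z", "tpm"]].notna().all(axis=1)
    return merged.sort_values(["tf", "stage"]).reset_index(drop=True)
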