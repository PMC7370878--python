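"""Cis-regulatory logic between accessible elements and their nearest genes.

Four relationship types are called from paired accessibility/expression
profiles over shared developmental stages:

* synchronization — element accessibility tracks gene expression
  (Spearman rho > 0.8);
* repression — accessibility and expression are mutually exclusive
  (rho < -0.8);
* enhancer switching — an anti-correlated element pair whose joint linear
  fit explains the gene's expression (overall-regression F-test p < 0.1);
* early opening — for genes with gradually increasing, promoter-coupled
  expression, an element reaching half-maximal accessibility strictly
  before the gene reaches half-maximal expression.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CisCall:
    element_ids: tuple[str, ...]
    gene_id: str
    call_type: str  # synchronization | repression | enhancer_switching | early_opening | unclassified
    statistic: float | None
    stages_used: tuple[str, ...]


def align_stages(
    expression_stages: list[str],
    accessibility_stages: list[str],
    stage_map: dict[str, str],
    min_shared: int = 5,
) -> list[tuple[str, str]]:
    """Pair accessibility stages with expression stages through an injective
    stage map, preserving accessibility stage order.

    Returns (accessibility stage, expression stage) pairs. Raises if the map
    is not injective; a result with fewer than ``min_shared`` pairs signals
    that correlation calls should be skipped (callers warn per element).
    """
    values = [stage_map[s] for s in accessibility_stages if s in stage_map]
    if len(set(values)) != len(values):
        raise ValueError("stage map must be injective")
    pairs = [
        (s, stage_map[s])
        for s in accessibility_stages
        if s in stage_map and stage_map[s] in expression_stages
    ]
    if len(pairs) < min_shared:
        warnings.warn(
            f"only {len(pairs)} shared stages (<{min_shared}); correlation calls skipped"
        )
    return pairs


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def classify_sync_repression(
    element_profile: np.ndarray,
    gene_profile: np.ndarray,
    element_id: str,
    gene_id: str,
    stages: tuple[str, ...],
    hi: float = 0.8,
    lo: float = -0.8,
) -> CisCall:
    """Rank-correlation call: synchronization if rho > hi, repression if
    rho < lo, otherwise unclassified (zero-variance profiles are flagged
    unclassified with a NaN statistic)."""
    rho = _spearman(np.asarray(element_profile, float), np.asarray(gene_profile, float))
    if np.isnan(rho):
        call = "unclassified"
    elif rho > hi:
        call = "synchronization"
    elif rho < lo:
        call = "repression"
    else:
        call = "unclassified"
    return CisCall((element_id,), gene_id, call, rho, stages)


def _ols_overall_f_pvalue(y: np.ndarray, X: np.ndarray) -> float:
    """p-value of the overall F-test for y ~ X + intercept."""
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    df_model, df_resid = p, n - p - 1
    if df_resid <= 0 or ss_tot == 0:
        return np.nan
    if ss_res <= 1e-12 * ss_tot:
        return 0.0
    f = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
    return float(stats.f.sf(f, df_model, df_resid))


def enhancer_switch_pairs(
    element_profiles: dict[str, np.ndarray],
    gene_profile: np.ndarray,
    gene_id: str,
    stages: tuple[str, ...],
    neg_corr_cutoff: float = 0.0,
    f_test_cutoff: float = 0.1,
) -> list[CisCall]:
    """Enhancer-switching calls among a gene's elements.

    Candidate pairs are unordered element pairs whose accessibility profiles
    are negatively rank-correlated (rho < ``neg_corr_cutoff``); each
    candidate is retained when the ordinary least-squares fit of the gene's
    expression on the two accessibility profiles (plus intercept) passes the
    overall F-test at ``f_test_cutoff``. Collinear pairs are skipped with a
    warning.
    """
    ids = sorted(element_profiles)
    y = np.asarray(gene_profile, float)
    calls: list[CisCall] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            rho = _spearman(element_profiles[a], element_profiles[b])
            if np.isnan(rho) or rho >= neg_corr_cutoff:
                continue
            X = np.column_stack([element_profiles[a], element_profiles[b]])
            try:
                p = _ols_overall_f_pvalue(y, X)
            except np.linalg.LinAlgError:
                warnings.warn(f"collinear element pair ({a},{b}) skipped for {gene_id}")
                continue
            if not np.isnan(p) and p < f_test_cutoff:
                calls.append(CisCall((a, b), gene_id, "enhancer_switching", p, stages))
    return calls


def half_max_stage(profile: np.ndarray) -> int | None:
    """First stage index where the profile reaches at least half its
    maximum (inclusive); None for all-zero profiles."""
    x = np.asarray(profile, float)
    if x.max() <= 0:
        return None
    return int(np.argmax(x >= 0.5 * x.max()))


def gradual_increase_filter(
    promoter_profile: np.ndarray,
    gene_profile: np.ndarray,
    null_rhos: np.ndarray,
    rho_min: float = 0.7,
    p_max: float = 0.1,
) -> tuple[bool, float, float]:
    """Keep a gene when its promoter accessibility tracks its expression
    more tightly than random promoter-gene pairings.

    Returns (retained, observed rho, empirical p) where the empirical
    p-value is (1 + #{null rho >= observed}) / (1 + N).
    """
    rho = _spearman(np.asarray(promoter_profile, float), np.asarray(gene_profile, float))
    if np.isnan(rho):
        return False, np.nan, np.nan
    null_rhos = np.asarray(null_rhos, float)
    null_rhos = null_rhos[~np.isnan(null_rhos)]
    p = (1.0 + (null_rhos >= rho).sum()) / (1.0 + null_rhos.size)
    return bool(rho > rho_min and p <= p_max), rho, float(p)


def null_promoter_rhos(
    promoter_profiles: list[np.ndarray],
    gene_profiles: list[np.ndarray],
    n_pairs: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Spearman correlations of randomly re-paired promoter-gene profiles,
    the empirical null for :func:`gradual_increase_filter`."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_p, n_g = len(promoter_profiles), len(gene_profiles)
    pi = rng.integers(0, n_p, size=n_pairs)
    gi = rng.integers(0, n_g, size=n_pairs)
    return np.array(
        [_spearman(promoter_profiles[i], gene_profiles[j]) for i, j in zip(pi, gi)]
    )


def early_opening_calls(
    element_profiles: dict[str, np.ndarray],
    gene_profile: np.ndarray,
    gene_id: str,
    stages: tuple[str, ...],
) -> list[CisCall]:
    """Early-opening calls for one (retained) gene: an element is called
    when its half-max stage strictly precedes the gene's. Pairs with an
    undefined half-max are skipped."""
    g_half = half_max_stage(gene_profile)
    if g_half is None:
        return []
    calls = []
    for eid, prof in element_profiles.items():
        e_half = half_max_stage(prof)
        if e_half is None:
            continue
        if e_half < g_half:
            calls.append(CisCall((eid,), gene_id, "early_opening",
                                 float(g_half - e_half), stages))
    return calls


def early_opening_grid(
    gene_half: dict[str, int], element_half: dict[str, tuple[str, int]], n_stages: int
) -> np.ndarray:
    """Count grid of (gene half-max stage x element half-max stage) over
    (gene, element) pairs; ``element_half`` maps element id to
    (gene id, half-max stage)."""
    grid = np.zeros((n_stages, n_stages), dtype=int)
    for _, (gid, e_half) in element_half.items():
        if gid in gene_half:
            grid[gene_half[gid], e_half] += 1
    return grid
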