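"""Stage-wise expression dynamics: expressed-gene filtering, z-score
standardization, fuzzy c-means clustering, and adjustable membership
assignment.

The clustering follows the classic fuzzy c-means alternating updates
(memberships from inverse distance ratios, centers from membership-weighted
means), the soft analogue of k-means used for time-course expression
profiles, where a gene may genuinely belong to several similar clusters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import StageMatrix, check_replicates


def expressed_filter(
    rep1: StageMatrix, rep2: StageMatrix, min_tpm: float = 1.0
) -> list[str]:
    """Entities reaching ``min_tpm`` at the same stage in both replicates."""
    check_replicates(rep1, rep2)
    both = (rep1.values >= min_tpm) & (rep2.values >= min_tpm)
    keep = both.any(axis=1)
    return [e for e, k in zip(rep1.entities, keep) if k]


def zscore(matrix: StageMatrix) -> StageMatrix:
    """Per-entity standardization across stages (sample sd, ddof=1).

    Constant rows cannot be standardized and become all-zero with a warning.
    """
    x = matrix.values
    if x.shape[1] < 2:
        raise ValueError("z-scoring needs at least two stages")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant row(s) set to zero in z-scoring")
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    z[flat, :] = 0.0
    return StageMatrix(pd.DataFrame(z, index=matrix.entities, columns=matrix.stages))


@dataclass
class FuzzyClustering:
    """Result of fuzzy c-means: centers (k x stages), memberships U
    (entities x k, rows summing to 1), and the objective trace of the
    winning restart."""

    centers: np.ndarray
    memberships: pd.DataFrame
    fuzzifier: float
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    stage_labels: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def hard_labels(self) -> pd.Series:
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index,
            name="cluster",
        )


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    # squared distances entities x k
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    u = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = d2 ** (-power)
    inv[~np.isfinite(inv)] = 0.0
    rows_zero = zero.any(axis=1)
    u[~rows_zero] = inv[~rows_zero] / inv[~rows_zero].sum(axis=1, keepdims=True)
    if rows_zero.any():
        # coincident point/center: full membership to (the first) coincident center
        u[rows_zero] = 0.0
        first = np.argmax(zero[rows_zero], axis=1)
        u[np.flatnonzero(rows_zero), first] = 1.0
    return u


def _fcm_objective(x, centers, u, m) -> float:
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((u**m) * d2).sum())


def _init_centers(x: np.ndarray, k: int, seed_state: int) -> np.ndarray:
    """Initial fuzzy centers from one converged hard k-means fit
    (greedy k-means++ seeding); the fuzzy updates then soften the
    partition."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=1, random_state=seed_state).fit(x)
    return km.cluster_centers_.astype(float)


def fuzzy_cmeans(
    matrix: StageMatrix,
    k: int = 30,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 20,
) -> FuzzyClustering:
    """Fuzzy c-means on z-scaled profiles; best of ``n_restarts`` by
    objective, deterministic under a fixed seed.

    Each restart starts from a converged hard k-means solution (see
    :func:`_init_centers`), which the fuzzy updates then soften. The
    objective sum_ij u_ij^m ||x_j - c_i||^2 is non-increasing across the
    alternating updates and iteration stops when its change falls below
    ``tol`` (relative to the current value).
    """
    x = matrix.values
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be below the number of entities ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")

    best: tuple[float, FuzzyClustering] | None = None
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    for ss in streams:
        centers = _init_centers(x, k, int(ss.generate_state(1)[0] % (2**31)))
        trace = []
        converged = False
        u = _fcm_memberships(x, centers, m)
        for _ in range(max_iter):
            um = u**m
            centers = (um.T @ x) / um.sum(axis=0)[:, None]
            u = _fcm_memberships(x, centers, m)
            obj = _fcm_objective(x, centers, u, m)
            trace.append(obj)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < tol * max(trace[-1], 1.0):
                converged = True
                break
        result = FuzzyClustering(
            centers=centers,
            memberships=pd.DataFrame(
                u, index=matrix.entities, columns=[f"c{i}" for i in range(k)]
            ),
            fuzzifier=m,
            objective_trace=np.asarray(trace),
            n_iter=len(trace),
            converged=converged,
            stage_labels=matrix.stages,
        )
        key = trace[-1]
        if best is None or key < best[0]:
            best = (key, result)
    assert best is not None
    return best[1]


@dataclass
class MembershipAssignment:
    clusters: dict[str, list[int]]  # entity -> clusters above cutoff
    n_zero: int
    n_single: int
    n_multi: int

    @property
    def fractions(self) -> tuple[float, float, float]:
        total = self.n_zero + self.n_single + self.n_multi
        if total == 0:
            return (0.0, 0.0, 0.0)
        return (self.n_zero / total, self.n_single / total, self.n_multi / total)


def assign_memberships(
    clustering: FuzzyClustering, cutoff: float = 0.3
) -> MembershipAssignment:
    """Clusters with membership strictly above ``cutoff`` per entity, and the
    unassigned / single / multi-assigned breakdown."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"membership cutoff must lie in (0,1), got {cutoff}")
    u = clustering.memberships.to_numpy()
    out: dict[str, list[int]] = {}
    n0 = n1 = n2 = 0
    for entity, row in zip(clustering.memberships.index, u):
        hits = list(np.flatnonzero(row > cutoff))
        out[entity] = [int(h) for h in hits]
        if len(hits) == 0:
            n0 += 1
        elif len(hits) == 1:
            n1 += 1
        else:
            n2 += 1
    return MembershipAssignment(clusters=out, n_zero=n0, n_single=n1, n_multi=n2)


def order_clusters_by_peak_stage(clustering: FuzzyClustering) -> list[int]:
    """Cluster indices sorted by the stage where the center peaks; ties keep
    the original cluster index order."""
    peaks = np.argmax(clustering.centers, axis=1)
    return sorted(range(clustering.k), key=lambda i: (peaks[i], i))
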