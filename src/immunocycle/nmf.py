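"""Subtype discovery by consensus NMF with cophenetic rank selection.

The immunogram matrix (signed enrichment axes) is made nonnegative by a
lossless "posneg" split, factorized with Brunet-style multiplicative updates
minimizing the generalized Kullback-Leibler divergence D(X || WH), and
clustered by the argmax factor of H.  Many random restarts yield a consensus
co-clustering matrix; the cophenetic correlation of that matrix against its
average-linkage dendrogram measures clustering stability and selects the
number of clusters k over a searched range (ties break toward smaller k).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

_EPS = 1e-12

__all__ = [
    "FactorizationResult",
    "ConsensusResult",
    "SubtypeAssignment",
    "nonnegativize",
    "nmf_brunet",
    "consensus_cluster",
    "select_rank",
    "composition_tables",
]


@dataclass
class FactorizationResult:
    W: np.ndarray  # features x k
    H: np.ndarray  # k x samples
    divergence_trace: np.ndarray  # KL after each update
    n_updates: int
    converged: bool
    seed: int | None

    @property
    def labels(self) -> np.ndarray:
        """Hard sample assignment: argmax factor of H (ties -> lowest index).

        H rows are weighted by their W column mass first, which removes the
        arbitrary restart-dependent diagonal rescaling of the factor pair
        (WH is invariant under it, raw argmax is not).
        """
        scale = self.W.sum(axis=0)
        return (scale[:, None] * self.H).argmax(axis=0)


@dataclass
class ConsensusResult:
    consensus: np.ndarray  # samples x samples, in [0, 1]
    cophenetic: float
    k: int
    n_restarts: int


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # sample -> cluster id in 1..k
    k: int
    per_k_cophenetic: dict[int, float]
    consensus: pd.DataFrame = field(repr=False, default=None)


def nonnegativize(ig: pd.DataFrame) -> pd.DataFrame:
    """Posneg split: each signed axis becomes two nonnegative features.

    Axis x maps to rows "x+" = max(x, 0) and "x-" = max(-x, 0), so the
    original value is recoverable as (x+) - (x-).  Output is feature x sample.
    """
    vals = ig.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("immunogram matrix contains non-finite values")
    rows, names = [], []
    for j, axis in enumerate(ig.columns):
        rows.append(np.maximum(vals[:, j], 0.0))
        names.append(f"{axis}+")
        rows.append(np.maximum(-vals[:, j], 0.0))
        names.append(f"{axis}-")
    return pd.DataFrame(np.vstack(rows), index=names, columns=ig.index)


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(X||WH); x log x terms vanish at x = 0."""
    pos = X > 0
    d = float(WH.sum() - X.sum())
    d += float((X[pos] * np.log(X[pos] / WH[pos])).sum())
    return d


def nmf_brunet(
    X: np.ndarray,
    k: int,
    max_updates: int = 2000,
    tol: float = 1e-9,
    seed: int | None = None,
    stable_checks: int = 40,
    check_interval: int = 10,
    n_inits: int = 3,
    burn_in: int = 40,
) -> FactorizationResult:
    """Multiplicative-update NMF minimizing generalized KL divergence.

    Each call draws ``n_inits`` random starting points, burns each in for
    ``burn_in`` updates and continues only the one with the lowest divergence
    — a cheap guard against shallow local basins.  It then stops when the
    sample connectivity (argmax-of-H labels) has been unchanged for
    ``stable_checks`` consecutive checks (one check every ``check_interval``
    updates), when the relative divergence improvement per update falls below
    ``tol``, or at ``max_updates``.  Stopping on connectivity keeps restarts
    init-dependent, which is what gives the consensus matrix its
    discriminating power across k.  All-zero rows are dropped with a warning
    (their W rows are returned as zeros).
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be nonnegative")
    row_ok = X.sum(axis=1) > 0
    if not row_ok.all():
        warnings.warn(f"dropping {int((~row_ok).sum())} all-zero rows from NMF input")
    Xr = X[row_ok]
    n_feat, n_samp = Xr.shape
    if not 2 <= k < min(n_feat, n_samp):
        raise ValueError(f"k={k} must satisfy 2 <= k < min(dim)={min(n_feat, n_samp)}")

    rng = np.random.default_rng(seed)

    def _burned(W, H):
        for _ in range(burn_in):
            R = Xr / (W @ H + _EPS)
            H *= (W.T @ R) / (W.sum(axis=0)[:, None] + _EPS)
            R = Xr / (W @ H + _EPS)
            W *= (R @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        return _kl_divergence(Xr, W @ H), W, H

    candidates = [
        _burned(rng.uniform(0.0, 1.0, size=(n_feat, k)),
                rng.uniform(0.0, 1.0, size=(k, n_samp)))
        for _ in range(max(1, n_inits))
    ]
    _, W, H = min(candidates, key=lambda c: c[0])

    trace = np.empty(max_updates)
    prev_labels = H.argmax(axis=0)
    prev_kl = _kl_divergence(Xr, W @ H)
    stable = 0
    converged = False
    n_updates = 0
    for it in range(max_updates):
        R = Xr / (W @ H + _EPS)
        H *= (W.T @ R) / (W.sum(axis=0)[:, None] + _EPS)
        R = Xr / (W @ H + _EPS)
        W *= (R @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        kl = _kl_divergence(Xr, W @ H)
        trace[it] = kl
        n_updates = it + 1
        rel = abs(prev_kl - kl) / max(abs(prev_kl), _EPS)
        prev_kl = kl
        if (it + 1) % check_interval == 0:
            labels = H.argmax(axis=0)
            stable = stable + 1 if np.array_equal(labels, prev_labels) else 0
            prev_labels = labels
            if stable >= stable_checks:
                converged = True
                break
        if rel < tol:
            converged = True
            break

    W_full = np.zeros((X.shape[0], k))
    W_full[row_ok] = W
    return FactorizationResult(W_full, H, trace[:n_updates], n_updates, converged, seed)


def consensus_cluster(
    X: np.ndarray,
    k: int,
    n_restarts: int = 200,
    seed: int | None = None,
    max_updates: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Consensus co-clustering over random NMF restarts.

    consensus[i, j] is the fraction of restarts in which samples i and j share
    an argmax factor; the cophenetic coefficient is the Pearson correlation
    between (1 - consensus) distances and the cophenetic distances of their
    average-linkage dendrogram.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2")
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    C = np.zeros((n, n))
    for ss in seeds:
        child = int(ss.generate_state(1)[0] % (2**31))
        res = nmf_brunet(X, k, max_updates=max_updates, tol=tol, seed=child)
        lab = res.labels
        C += lab[:, None] == lab[None, :]
    C /= n_restarts
    np.fill_diagonal(C, 1.0)
    return ConsensusResult(C, _cophenetic(C), k, n_restarts)


def _cophenetic(consensus: np.ndarray) -> float:
    d = 1.0 - consensus
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    cond = squareform(d, checks=False)
    if cond.std() == 0.0:
        # degenerate: every pair always (or never) co-clusters; no structure
        return 0.0
    Z = average(cond)
    c, _ = cophenet(Z, cond)
    return float(c)


def select_rank(
    X: np.ndarray,
    k_range=range(2, 8),
    n_restarts: int = 200,
    seed: int | None = None,
    sample_ids=None,
    max_updates: int = 2000,
) -> SubtypeAssignment:
    """Choose k in ``k_range`` maximizing the cophenetic coefficient.

    Ties break toward smaller k.  Final labels come from cutting the
    average-linkage dendrogram of the chosen consensus matrix at k clusters.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if max(ks) >= n:
        raise ValueError("max(k_range) must be < number of samples")
    children = np.random.SeedSequence(seed).spawn(len(ks))
    per_k: dict[int, float] = {}
    results: dict[int, ConsensusResult] = {}
    for k, ss in zip(ks, children):
        child = int(ss.generate_state(1)[0] % (2**31))
        res = consensus_cluster(X, k, n_restarts=n_restarts, seed=child,
                                max_updates=max_updates)
        per_k[k] = res.cophenetic
        results[k] = res
        log.info("k=%d cophenetic=%.4f", k, res.cophenetic)
    best_k = max(ks, key=lambda k: (per_k[k], -k))
    cons = results[best_k].consensus
    d = 1.0 - cons
    np.fill_diagonal(d, 0.0)
    labels = fcluster(average(squareform(d, checks=False)), t=best_k, criterion="maxclust")
    idx = sample_ids if sample_ids is not None else pd.RangeIndex(n)
    cons_df = pd.DataFrame(cons, index=idx, columns=idx)
    return SubtypeAssignment(pd.Series(labels, index=idx, name="subtype"),
                             best_k, per_k, cons_df)


def composition_tables(
    labels: pd.Series, sample_meta: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Subtype composition within each cancer type and each stage.

    Returns tables indexed by stratum (cancer type or stage) with one column
    per cluster; each row sums to 1.
    """
    labels = pd.Series(labels)
    unknown = labels.index.difference(sample_meta.index)
    if len(unknown):
        raise ValueError(f"{len(unknown)} labeled samples missing from metadata")
    meta = sample_meta.loc[labels.index]
    out = {}
    for col in ("cancer_type", "stage"):
        if col in meta.columns:
            tab = pd.crosstab(meta[col], labels)
            out[col] = tab.div(tab.sum(axis=1), axis=0)
    if not out:
        raise ValueError("metadata has neither 'cancer_type' nor 'stage'")
    return out
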