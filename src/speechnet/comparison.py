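"""Permutation network comparison test and global network distances.

The network comparison test (NCT) asks whether two groups share one
network structure: it re-estimates both group networks under random
reassignments of subjects to groups and compares the observed statistics

- M: maximum absolute edge-weight difference (structure invariance), and
- S: absolute difference in global strength (sum of |edge weights|)

against their permutation distributions. Per-edge differences get raw
permutation p-values, Bonferroni-adjusted over the tested edge set (the
edges nonzero in at least one observed group network). All p-values use
the add-one convention (1 + exceedances) / (1 + permutations), so they
are never zero.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpeechNetError
from .ggm import NetworkModel
from .stability import _fit_weights

logger = logging.getLogger(__name__)

__all__ = ["NctResult", "global_strength", "frobenius_distance",
           "bonferroni_adjust", "nct"]


def global_strength(net: NetworkModel) -> float:
    """Sum of absolute edge weights over the upper triangle."""
    iu, ju = np.triu_indices(net.p, k=1)
    return float(np.abs(net.weights[iu, ju]).sum())


def frobenius_distance(net_a: NetworkModel, net_b: NetworkModel) -> float:
    """Frobenius distance over upper-triangle edge weights."""
    if list(net_a.nodes) != list(net_b.nodes):
        raise SpeechNetError("networks must share one node set in one order")
    iu, ju = np.triu_indices(net_a.p, k=1)
    diff = net_a.weights[iu, ju] - net_b.weights[iu, ju]
    return float(np.sqrt(np.sum(diff**2)))


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: adjusted p = min(1, p * m), order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise SpeechNetError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise SpeechNetError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


@dataclass
class NctResult:
    """Observed NCT statistics, permutation p-values, and edgewise tests."""

    nodes: list[str]
    M_observed: float
    p_M: float
    S_observed: float
    p_S: float
    tested_edges: list[tuple[int, int]]
    edge_p_raw: np.ndarray
    edge_p_adjusted: np.ndarray
    nperm: int
    seed: int | None
    weights_a: np.ndarray | None = None
    weights_b: np.ndarray | None = None
    n_redraws: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_M", "p_S"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise SpeechNetError(f"{name}={v} outside (0, 1]")
        if self.M_observed < 0 or self.S_observed < 0:
            raise SpeechNetError("observed statistics must be nonnegative")
        self.edge_p_raw = np.asarray(self.edge_p_raw, dtype=float)
        self.edge_p_adjusted = np.asarray(self.edge_p_adjusted, dtype=float)
        if np.any(self.edge_p_adjusted + 1e-12 < self.edge_p_raw):
            raise SpeechNetError("adjusted p-values must be >= raw p-values")

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "nodes": self.nodes,
            "M_observed": self.M_observed,
            "p_M": self.p_M,
            "S_observed": self.S_observed,
            "p_S": self.p_S,
            "nperm": self.nperm,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
            "tested_edges": [list(e) for e in self.tested_edges],
            "edge_p_raw": self.edge_p_raw.tolist(),
            "edge_p_adjusted": self.edge_p_adjusted.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    def edgewise_table(self) -> pd.DataFrame:
        rows = []
        for (i, j), pr, pa in zip(self.tested_edges, self.edge_p_raw,
                                  self.edge_p_adjusted):
            rows.append({
                "node_a": self.nodes[i], "node_b": self.nodes[j],
                "p_raw": pr, "p_bonferroni": pa,
            })
        return pd.DataFrame(rows)


def _as_array(X) -> np.ndarray:
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if np.isnan(arr).any():
        raise SpeechNetError("NCT input must be complete (no missing cells)")
    return arr


def nct(
    X_a,
    X_b,
    nperm: int = 1000,
    gamma: float = 0.5,
    seed: int | None = None,
    nlambda: int = 100,
    lambda_min_ratio: float = 0.01,
    nodes: list[str] | None = None,
) -> NctResult:
    """Permutation network comparison test between two subject groups.

    Both observed group networks are estimated with EBICglasso (unpruned:
    pruning inside the permutation loop would be computationally and
    statistically incoherent). The pooled rows are canonicalized by
    lexicographic sort before permuting, which makes the test exactly
    invariant to swapping the group labels.
    """
    A = _as_array(X_a)
    B = _as_array(X_b)
    if A.shape[1] != B.shape[1]:
        raise SpeechNetError("both groups must share the same variables")
    p = A.shape[1]
    if isinstance(X_a, pd.DataFrame):
        node_names = [str(c) for c in X_a.columns]
    else:
        node_names = nodes or [f"v{i}" for i in range(p)]
    for X, tag in ((A, "A"), (B, "B")):
        if X.shape[0] < p:
            logger.warning("group %s has n=%d < p=%d variables", tag,
                           X.shape[0], p)

    W_a = _fit_weights(A, gamma, nlambda, lambda_min_ratio)
    W_b = _fit_weights(B, gamma, nlambda, lambda_min_ratio)
    iu, ju = np.triu_indices(p, k=1)
    diff_obs = np.abs(W_a[iu, ju] - W_b[iu, ju])
    M_obs = float(diff_obs.max())
    S_obs = float(abs(np.abs(W_a[iu, ju]).sum() - np.abs(W_b[iu, ju]).sum()))

    tested_mask = (W_a[iu, ju] != 0.0) | (W_b[iu, ju] != 0.0)
    tested_idx = np.flatnonzero(tested_mask)
    tested_edges = [(int(iu[k]), int(ju[k])) for k in tested_idx]

    # canonical pooled ordering: invariant to which group came first
    pooled = np.vstack([A, B])
    order = np.lexsort(pooled.T[::-1])
    pooled = pooled[order]
    n_first = min(A.shape[0], B.shape[0])
    N = pooled.shape[0]

    rng = np.random.default_rng(seed)
    M_perm = np.empty(nperm)
    S_perm = np.empty(nperm)
    edge_exceed = np.zeros(len(tested_idx))
    n_redraws = 0
    done = 0
    attempts = 0
    while done < nperm:
        if attempts >= 10 * nperm:
            raise SpeechNetError("too many degenerate permutations")
        attempts += 1
        perm = rng.permutation(N)
        Xa_p = pooled[perm[:n_first]]
        Xb_p = pooled[perm[n_first:]]
        if (np.any(Xa_p.std(axis=0, ddof=1) == 0)
                or np.any(Xb_p.std(axis=0, ddof=1) == 0)):
            n_redraws += 1
            logger.info("redrawing permutation %d: zero-variance column", done)
            continue
        Wa_p = _fit_weights(Xa_p, gamma, nlambda, lambda_min_ratio)
        Wb_p = _fit_weights(Xb_p, gamma, nlambda, lambda_min_ratio)
        d = np.abs(Wa_p[iu, ju] - Wb_p[iu, ju])
        M_perm[done] = d.max()
        S_perm[done] = abs(np.abs(Wa_p[iu, ju]).sum() - np.abs(Wb_p[iu, ju]).sum())
        edge_exceed += d[tested_idx] >= diff_obs[tested_idx]
        done += 1

    p_M = (1.0 + np.sum(M_perm >= M_obs)) / (1.0 + nperm)
    p_S = (1.0 + np.sum(S_perm >= S_obs)) / (1.0 + nperm)
    edge_p_raw = (1.0 + edge_exceed) / (1.0 + nperm)
    edge_p_adj = bonferroni_adjust(edge_p_raw, m=len(tested_idx)) \
        if len(tested_idx) else np.array([])

    return NctResult(
        nodes=node_names,
        M_observed=M_obs, p_M=float(p_M),
        S_observed=S_obs, p_S=float(p_S),
        tested_edges=tested_edges,
        edge_p_raw=edge_p_raw,
        edge_p_adjusted=edge_p_adj,
        nperm=nperm, seed=seed,
        weights_a=W_a, weights_b=W_b,
        n_redraws=n_redraws,
        metadata={"gamma": gamma, "nlambda": nlambda,
                  "lambda_min_ratio": lambda_min_ratio,
                  "bonferroni_m": len(tested_idx)},
    )
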