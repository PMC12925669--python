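"""Sparse Gaussian graphical model estimation with EBIC model selection.

The feature matrix is z-standardized, turned into a Pearson correlation
matrix, and fed to a graphical lasso over a log-spaced penalty path; the
penalty is selected by the Extended Bayesian Information Criterion

    EBIC(lambda) = -2 L + E log n + 4 E gamma log p,

with L the Gaussian log-likelihood of the estimated precision matrix,
E its number of nonzero upper-triangle off-diagonals, and gamma the
sparsity preference (0.5 here, the standard choice for psychological and
behavioral data). The selected precision matrix Theta is reported as a
partial-correlation network, rho_ij = -theta_ij / sqrt(theta_ii theta_jj).
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _glasso
from .errors import ConvergenceError, SpeechNetError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationInput",
    "NetworkModel",
    "zscore_columns",
    "pearson_correlation",
    "glasso_fit",
    "ebic_score",
    "precision_to_partial",
    "ebicglasso_select",
    "network_from_features",
]

#: ridge added to a PSD-but-singular correlation matrix before fitting
PSD_RIDGE = 1e-8


@dataclass
class CorrelationInput:
    """A correlation matrix plus the effective sample size behind it."""

    S: np.ndarray
    n: int
    names: list[str]
    domains: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = self.S.shape[0]
        if self.S.ndim != 2 or self.S.shape[1] != p or p < 2:
            raise SpeechNetError("correlation matrix must be square with p >= 2")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise SpeechNetError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-8):
            raise SpeechNetError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.S) > 1 + 1e-10):
            raise SpeechNetError("correlation entries must lie in [-1, 1]")
        if len(self.names) != p:
            raise SpeechNetError("need one name per variable")
        if self.n <= p:
            warnings.warn(
                f"effective sample size n={self.n} not larger than p={p}; "
                "estimates may be unstable",
                stacklevel=2,
            )


@dataclass
class NetworkModel:
    """A partial-correlation network with its estimation metadata."""

    weights: np.ndarray  # p x p partial correlations, zero diagonal
    nodes: list[str]
    domains: dict[str, str]
    n: int
    gamma: float
    lambda_selected: float | None = None
    lambda_grid: np.ndarray | None = None
    ebic_path: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        p = W.shape[0]
        if W.ndim != 2 or W.shape[1] != p:
            raise SpeechNetError("weight matrix must be square")
        if len(self.nodes) != p:
            raise SpeechNetError("need one node name per row")
        if not np.allclose(W, W.T, atol=1e-8):
            raise SpeechNetError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0.0):
            raise SpeechNetError("weight matrix diagonal must be exactly zero")
        if np.any(np.abs(W) >= 1.0):
            raise SpeechNetError("partial correlations must satisfy |rho| < 1")
        self.weights = W

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Nonzero upper-triangle edges as (node_a, node_b, weight)."""
        iu, ju = np.triu_indices(self.p, k=1)
        out = []
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0.0:
                out.append((self.nodes[i], self.nodes[j], float(w)))
        return out

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "nodes": self.nodes,
            "domains": self.domains,
            "n": int(self.n),
            "gamma": self.gamma,
            "lambda_selected": self.lambda_selected,
            "lambda_grid": None if self.lambda_grid is None else list(self.lambda_grid),
            "ebic_path": None if self.ebic_path is None else list(self.ebic_path),
            "weights": self.weights.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "NetworkModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            weights=np.array(d["weights"]),
            nodes=d["nodes"],
            domains=d["domains"],
            n=d["n"],
            gamma=d["gamma"],
            lambda_selected=d["lambda_selected"],
            lambda_grid=None if d["lambda_grid"] is None else np.array(d["lambda_grid"]),
            ebic_path=None if d["ebic_path"] is None else np.array(d["ebic_path"]),
            metadata=d.get("metadata", {}),
        )

    def write_edge_list(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b, w in self.edge_list():
                fh.write(f"{a}\t{b}\t{w:.6g}\n")


def zscore_columns(X: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Standardize each column to mean 0 and sample SD 1 (ddof=1)."""
    arr = np.asarray(X, dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        if isinstance(X, pd.DataFrame):
            bad = list(X.columns[np.flatnonzero(sd == 0)])
        else:
            bad = list(np.flatnonzero(sd == 0))
        raise SpeechNetError(f"zero-variance column(s): {bad}")
    Z = (arr - mu) / sd
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z


def pearson_correlation(
    X: pd.DataFrame | np.ndarray,
    missing_policy: str = "listwise",
    repair: bool = False,
    domains: dict[str, str] | None = None,
) -> CorrelationInput:
    """Pearson correlation matrix with explicit missing-data handling.

    ``listwise`` drops any row with a missing value (n = rows kept);
    ``pairwise`` uses all available pairs (n = minimum pairwise count) and
    checks positive definiteness, repairing by a small ridge only when
    ``repair=True``.
    """
    df = pd.DataFrame(X).astype(float)
    names = [str(c) for c in df.columns]
    if missing_policy == "listwise":
        kept = df.dropna(axis=0, how="any")
        dropped = len(df) - len(kept)
        if dropped:
            logger.info("listwise deletion dropped %d of %d subjects",
                        dropped, len(df))
        if len(kept) < 3:
            raise SpeechNetError(
                f"need >=3 complete rows, found {len(kept)}"
            )
        S = np.corrcoef(kept.to_numpy(), rowvar=False)
        n = len(kept)
    elif missing_policy == "pairwise":
        S = df.corr(method="pearson").to_numpy()
        notna = df.notna().to_numpy().astype(int)
        pair_n = notna.T @ notna
        n = int(pair_n[np.triu_indices_from(pair_n, k=1)].min())
        if n < 3:
            raise SpeechNetError("fewer than 3 complete pairs for some variable pair")
        min_eig = float(np.linalg.eigvalsh(S).min())
        if min_eig <= 0:
            if not repair:
                raise SpeechNetError(
                    f"pairwise correlation matrix is not positive definite "
                    f"(min eigenvalue {min_eig:.2e}); rerun with repair=True"
                )
            S = _nearest_pd_ridge(S)
    else:
        raise SpeechNetError(f"unknown missing_policy {missing_policy!r}")
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return CorrelationInput(S=S, n=n, names=names, domains=domains)


def _nearest_pd_ridge(S: np.ndarray) -> np.ndarray:
    """Inflate the diagonal just enough to restore positive definiteness."""
    min_eig = float(np.linalg.eigvalsh(S).min())
    ridge = abs(min_eig) + PSD_RIDGE
    warnings.warn(f"adding ridge {ridge:.2e} to restore positive definiteness",
                  stacklevel=3)
    S = S + ridge * np.eye(S.shape[0])
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _ensure_pd(S: np.ndarray) -> np.ndarray:
    min_eig = float(np.linalg.eigvalsh(S).min())
    if min_eig > PSD_RIDGE:
        return S
    if min_eig < -1e-6:
        raise SpeechNetError(
            f"input matrix is far from positive semidefinite (min eig {min_eig:.2e})"
        )
    warnings.warn(
        f"input matrix is singular (min eig {min_eig:.2e}); adding ridge {PSD_RIDGE:g}",
        stacklevel=3,
    )
    return S + PSD_RIDGE * np.eye(S.shape[0])


def glasso_fit(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 10000,
) -> np.ndarray:
    """L1-penalized precision estimation at one penalty value.

    Maximizes ``log det Theta - tr(S Theta) - lam * sum_{i!=j} |theta_ij|``
    (diagonal unpenalized) by block coordinate descent.
    """
    if lam < 0:
        raise SpeechNetError("penalty must be nonnegative")
    S = _ensure_pd(np.asarray(S, dtype=float))
    Theta, n_iter, ok = _glasso.glasso_single(S, lam, tol=tol, max_iter=max_iter)
    if not ok:
        raise ConvergenceError(
            f"glasso did not converge within {max_iter} iterations", n_iter=n_iter
        )
    return Theta


def ebic_score(Theta: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a precision matrix against a correlation matrix."""
    Theta = np.asarray(Theta, dtype=float)
    S = np.asarray(S, dtype=float)
    try:
        L = np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError as exc:
        raise SpeechNetError("precision matrix must be positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    tr = float(np.sum(S * Theta))
    p = Theta.shape[0]
    E = int(np.count_nonzero(np.triu(Theta, k=1)))
    loglik = 0.5 * n * (logdet - tr)
    return -2.0 * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def precision_to_partial(Theta: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -theta_ij / sqrt(theta_ii theta_jj)."""
    Theta = np.asarray(Theta, dtype=float)
    d = np.sqrt(np.diag(Theta))
    W = -Theta / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return W


def ebicglasso_select(
    S_input: CorrelationInput | np.ndarray,
    n: int | None = None,
    gamma: float = 0.5,
    nlambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 10000,
    nodes: list[str] | None = None,
    domains: dict[str, str] | None = None,
) -> NetworkModel:
    """EBICglasso: fit the penalty path, select by EBIC, return the network.

    Ties in EBIC are broken toward the larger penalty (the sparser model).
    """
    if isinstance(S_input, CorrelationInput):
        ci = S_input
    else:
        if n is None:
            raise SpeechNetError("n is required when passing a bare matrix")
        p = np.asarray(S_input).shape[0]
        names = nodes if nodes is not None else [f"v{i}" for i in range(p)]
        ci = CorrelationInput(S=np.asarray(S_input), n=n, names=names,
                              domains=domains)
    S = _ensure_pd(ci.S)
    lambdas = _glasso.make_lambda_grid(S, nlambda=nlambda,
                                       lambda_min_ratio=lambda_min_ratio)
    thetas, ebics, converged = _glasso.ebic_glasso_path(
        np.ascontiguousarray(S), float(ci.n), float(gamma),
        np.ascontiguousarray(lambdas, dtype=np.float64), float(tol), int(max_iter)
    )
    if not np.any(converged):
        raise ConvergenceError("no penalty value converged on this input")
    # argmin with ties toward larger lambda: grid is descending, so the
    # first index attaining the minimum is the sparser model
    best = int(np.argmin(ebics))
    ties = np.flatnonzero(ebics == ebics[best])
    if len(ties) > 1:
        logger.info("EBIC tie among %d penalties; keeping the sparser model",
                    len(ties))
    W = precision_to_partial(thetas[best])
    dom = ci.domains if ci.domains is not None else (domains or {})
    return NetworkModel(
        weights=W,
        nodes=list(ci.names),
        domains=dom if dom else {nm: "linguistic" for nm in ci.names},
        n=ci.n,
        gamma=gamma,
        lambda_selected=float(lambdas[best]),
        lambda_grid=lambdas,
        ebic_path=np.asarray(ebics),
        metadata={"nlambda": int(nlambda), "lambda_min_ratio": lambda_min_ratio},
    )


def network_from_features(
    fm: FeatureMatrix,
    gamma: float = 0.5,
    missing_policy: str = "listwise",
    exclude_domains: tuple[str, ...] = (),
    subjects=None,
    **select_kwargs,
) -> NetworkModel:
    """Feature matrix -> z-scores -> correlations -> EBICglasso network."""
    sub = fm.select(subjects=subjects, exclude_domains=exclude_domains)
    complete = sub.values.dropna(axis=0, how="any") if missing_policy == "listwise" else sub.values
    Z = zscore_columns(complete)
    ci = pearson_correlation(Z, missing_policy=missing_policy,
                             domains=sub.domains)
    return ebicglasso_select(ci, gamma=gamma, **select_kwargs)
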