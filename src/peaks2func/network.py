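"""Debiased sparse partial correlation (DSPC) network inference.

For a sample x feature matrix, a sparse precision matrix is estimated
by the graphical lasso on the empirical correlation matrix, then
de-biased with the de-sparsified estimator

    T = Theta + Theta' - Theta' Sigma Theta,

whose off-diagonal entries are asymptotically normal with variance
(T_ii T_jj + T_ij^2) / n.  Partial correlations are
rho_ij = -T_ij / sqrt(T_ii T_jj); each feature pair gets a two-sided
p-value and a Benjamini-Hochberg q-value, yielding an association
network applicable to both targeted and untargeted feature tables
(annotated or not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso

from .errors import DataError

LAMBDA_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5)


@dataclass
class DSPCNetwork:
    """Edge list of partial correlations with p- and q-values.

    ``edges`` holds the pairs passing the FDR threshold; ``all_edges``
    is the full table over every feature pair.  Pairs are stored with
    i < j (undirected, no self-loops).
    """

    nodes: list[str]
    edges: pd.DataFrame
    all_edges: pd.DataFrame
    lambda_: float
    n_samples: int
    fdr_alpha: float

    def to_frame(self) -> pd.DataFrame:
        return self.edges


def _prepare_matrix(
    X: np.ndarray,
    feature_ids: list[str],
    log_transform: bool,
    max_missing_fraction: float = 0.2,
) -> tuple[np.ndarray, list[str]]:
    """Drop overly missing features, impute the rest, transform, standardize."""
    X = np.asarray(X, dtype=float)
    miss_frac = np.isnan(X).mean(axis=0)
    keep = miss_frac <= max_missing_fraction
    if not keep.all():
        dropped = [feature_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropped {len(dropped)} features with > {max_missing_fraction:.0%} "
            f"missing values: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=3,
        )
    X = X[:, keep]
    ids = [feature_ids[j] for j in np.flatnonzero(keep)]
    for j in range(X.shape[1]):
        col = X[:, j]
        nan = np.isnan(col)
        if nan.any():
            observed = col[~nan]
            col[nan] = observed.min() / 2.0  # half-minimum imputation
    if log_transform:
        if np.any(X < 0):
            raise DataError("log transform requires non-negative intensities")
        X = np.log1p(X)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = ids[int(np.flatnonzero(sd == 0)[0])]
        raise DataError(f"feature {bad!r} is constant; remove it before network analysis")
    return (X - X.mean(axis=0)) / sd, ids


SHRINKAGE_LADDER = (0.0, 0.05, 0.1, 0.2, 0.4)


def _glasso(S: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Graphical lasso precision estimate, tolerant of ill-conditioned input.

    With far fewer samples than features the empirical correlation
    matrix is rank-deficient and the coordinate-descent solver can hit
    non-SPD iterates.  In that case the target is shrunk toward the
    identity, (1-eps) S + eps I, stepping up eps until the solver
    succeeds; the shrunk matrix is then used consistently downstream
    (including de-biasing).  Returns (theta, S_used).
    """
    last_err: Exception | None = None
    for eps in SHRINKAGE_LADDER:
        S_used = (1.0 - eps) * S + eps * np.eye(S.shape[0]) if eps else S
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # near-converged dual gaps are fine
                _, theta = graphical_lasso(S_used, alpha=float(lam), max_iter=500)
            if eps:
                warnings.warn(
                    f"correlation matrix shrunk toward identity (eps={eps}) to "
                    "stabilize the graphical lasso; estimates are conservative",
                    stacklevel=3,
                )
            return theta, S_used
        except FloatingPointError as err:
            last_err = err
    raise DataError(
        f"graphical lasso failed even with shrinkage: {last_err}"
    )


def _ebic(theta: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a Gaussian graphical model fit."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    loglik = n / 2.0 * (logdet - np.trace(S @ theta))
    n_edges = int(np.count_nonzero(np.triu(theta, k=1)))
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def select_lambda(S: np.ndarray, n: int, grid=LAMBDA_GRID) -> float:
    """Pick the graphical-lasso penalty minimizing the extended BIC."""
    best, best_score = grid[0], np.inf
    for lam in grid:
        try:
            theta, _ = _glasso(S, lam)
        except Exception:
            continue
        score = _ebic(theta, S, n)
        if score < best_score:
            best, best_score = lam, score
    return best


def dspc(
    X: np.ndarray,
    feature_ids: list[str] | None = None,
    lam: float | None = None,
    fdr_alpha: float = 0.05,
    log_transform: bool = False,
) -> DSPCNetwork:
    """Debiased sparse partial correlation network over a feature table.

    ``X`` is samples x features.  Features are column-standardized
    internally (after optional log transform and half-minimum
    imputation of sparse missingness).  ``lam`` is the graphical-lasso
    penalty; None selects it from a small grid by extended BIC, and
    ``lam = 0`` (only valid when features < samples) reduces to the
    dense inverse-covariance estimate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be a 2-D samples x features matrix")
    n, p = X.shape
    if n < 10:
        raise DataError(f"need at least 10 samples, got {n}")
    if feature_ids is None:
        feature_ids = [f"F{j + 1}" for j in range(p)]
    Z, ids = _prepare_matrix(X, list(feature_ids), log_transform)
    n, p = Z.shape
    S = np.corrcoef(Z, rowvar=False)
    S = np.atleast_2d(S)

    if lam is None:
        lam = select_lambda(S, n)
    if lam == 0:
        if p >= n:
            raise DataError(
                "lambda = 0 requires fewer features than samples; use regularization"
            )
        theta = np.linalg.inv(S)
    else:
        theta, S = _glasso(S, float(lam))

    T = theta + theta.T - theta.T @ S @ theta
    d = np.sqrt(np.diag(T))
    denom = np.outer(d, d)
    rho = np.clip(-T / denom, -1.0, 1.0)
    var = (np.outer(np.diag(T), np.diag(T)) + T**2) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = T / np.sqrt(var)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    iu, ju = np.triu_indices(p, k=1)
    pv = pvals[iu, ju]
    qv = stats.false_discovery_control(pv, method="bh")
    table = pd.DataFrame(
        {
            "node1": [ids[i] for i in iu],
            "node2": [ids[j] for j in ju],
            "pcor": rho[iu, ju],
            "p_value": pv,
            "q_value": qv,
        }
    )
    table = table.sort_values(
        ["q_value", "p_value", "node1", "node2"], kind="stable"
    ).reset_index(drop=True)
    edges = table[table["q_value"] <= fdr_alpha].reset_index(drop=True)
    return DSPCNetwork(
        nodes=ids,
        edges=edges,
        all_edges=table,
        lambda_=float(lam),
        n_samples=n,
        fdr_alpha=fdr_alpha,
    )


def degree_table(net: DSPCNetwork, q_threshold: float | None = None) -> pd.DataFrame:
    """Per-node degree counts among edges at or below a q-value threshold.

    Ordered by degree descending, then node id — the ordering used for
    sizing nodes in network displays.
    """
    thr = net.fdr_alpha if q_threshold is None else q_threshold
    sel = net.all_edges[net.all_edges["q_value"] <= thr]
    counts = {node: 0 for node in net.nodes}
    for _, row in sel.iterrows():
        counts[row["node1"]] += 1
        counts[row["node2"]] += 1
    frame = pd.DataFrame(
        {"node": list(counts.keys()), "degree": list(counts.values())}
    )
    return frame.sort_values(
        ["degree", "node"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
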