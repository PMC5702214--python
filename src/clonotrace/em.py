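"""Clonal inference on the binary genotype matrix.

The cells x assays 0/1 matrix is modelled as a finite mixture of
multivariate Bernoulli distributions: a cell in clone k carries assay j
with probability theta[k, j], independently across assays, and clones mix
with weights pi. Parameters are fit by expectation-maximization with
Jeffreys (0.5/0.5) pseudocount smoothing of theta, random restarts plus a
hierarchical-clustering anchor initialization, and the number of clusters
is estimated beforehand by average-linkage hierarchical clustering under
Hamming distance with a silhouette cut.

After fitting, assays are grouped into mutation clusters by their
presence pattern across clusters (theta thresholded at 0.5): the all-ones
pattern is the ancestral cluster, the all-zeros pattern collects poorly
performing assays, and clusters of cells whose profile matches the
elementwise union of two other clusters are flagged as doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp
from sklearn.metrics import silhouette_score

DEFAULT_K_MAX = 8
DEFAULT_N_RESTARTS = 20
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_SMOOTH_A = 0.5
DEFAULT_SMOOTH_B = 0.5
DEFAULT_PRESENT_THRESHOLD = 0.5
DEFAULT_DOUBLET_TOLERANCE = 0.15
MIN_SILHOUETTE = 0.1

ANCESTRAL_LABEL = "ancestral"
POOR_LABEL = "poor"


@dataclass
class MixtureModel:
    """Fitted multivariate-Bernoulli mixture.

    pi : (K,) mixing weights; theta : (K, J) per-cluster presence
    probabilities; gamma : (n, K) responsibilities; loglik_trace : the
    per-iteration objective of the best restart. With pseudocount
    smoothing the EM objective is the data log-likelihood plus the Beta
    prior term on theta (MAP-EM); that penalized objective is what EM
    provably never decreases, so that is what the trace records.
    ``data_loglik`` is the plain observed-data log-likelihood at the
    final parameters.
    """

    K: int
    pi: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    seed: int | None = None
    data_loglik: float = float("nan")

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment: argmax responsibility per cell."""
        return self.gamma.argmax(axis=1)


def _as_array(matrix) -> tuple[np.ndarray, np.ndarray | None]:
    if hasattr(matrix, "X"):
        mask = matrix.mask if getattr(matrix, "mask", None) is not None else None
        return np.asarray(matrix.X, dtype=float), (
            np.asarray(mask, dtype=float) if mask is not None else None
        )
    return np.asarray(matrix, dtype=float), None


def hierarchical_labels(X: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage Hamming clustering cut into k groups (labels 0..k-1)."""
    Z = linkage(X, method="average", metric="hamming")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def estimate_k(
    matrix,
    k_max: int = DEFAULT_K_MAX,
    min_silhouette: float = MIN_SILHOUETTE,
) -> int:
    """Estimate the number of clones by hierarchical clustering.

    Cuts the average-linkage Hamming dendrogram at every k in 2..k_max and
    returns the k with the best mean silhouette width; if no cut reaches
    ``min_silhouette`` (e.g. a single homogeneous population) returns 1.
    """
    X, _ = _as_array(matrix)
    n = X.shape[0]
    if n < 2:
        return 1
    if np.all(X == X[0]):
        return 1
    Z = linkage(X, method="average", metric="hamming")
    best_k, best_s = 1, min_silhouette
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels, metric="hamming")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def _log_bernoulli(X, W, log_t, log_1mt):
    # (n,K) matrix of per-cluster data log-likelihoods; W weights out masked
    # entries (W=1 observed). X and W are (n,J), log_t/log_1mt are (K,J).
    return (W * X) @ log_t.T + (W * (1.0 - X)) @ log_1mt.T


def _em_once(X, W, gamma0, a, b, tol, max_iter):
    n = X.shape[0]
    gamma = gamma0
    trace: list[float] = []
    converged = False
    data_ll = float("nan")
    with np.errstate(divide="ignore"):
        for _ in range(max_iter):
            # M-step from current responsibilities (MAP under Beta(1+a,1+b))
            nk = gamma.sum(axis=0)
            pi = nk / n
            wk = gamma.T @ (W * X)  # (K,J) weighted presence sums
            denom = gamma.T @ W  # (K,J) weighted coverage sums
            log_t = np.log(theta := (wk + a) / (denom + a + b))
            log_1mt = np.log1p(-theta)
            # E-step
            log_pi = np.log(np.clip(pi, 1e-300, None))
            log_p = log_pi + _log_bernoulli(X, W, log_t, log_1mt)
            norm = logsumexp(log_p, axis=1)
            data_ll = float(norm.sum())
            # objective EM monotonically improves: loglik + theta prior term
            trace.append(data_ll + float(a * log_t.sum() + b * log_1mt.sum()))
            gamma = np.exp(log_p - norm[:, None])
            if len(trace) > 1:
                prev = trace[-2]
                if abs(trace[-1] - prev) <= tol * max(abs(prev), 1.0):
                    converged = True
                    break
    return pi, theta, gamma, trace, converged, data_ll


def fit_bernoulli_mixture(
    matrix,
    K: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    smooth_a: float = DEFAULT_SMOOTH_A,
    smooth_b: float = DEFAULT_SMOOTH_B,
    use_mask: bool = False,
) -> MixtureModel:
    """Fit a K-component Bernoulli mixture by EM.

    Initialization: ``n_restarts`` Dirichlet-random responsibility matrices
    plus one deterministic anchor from the hierarchical-clustering cut; the
    restart with the highest final log-likelihood wins. theta is smoothed
    with pseudocounts (``smooth_a``, ``smooth_b``) so it stays inside (0,1)
    and log-likelihoods remain finite. With ``use_mask`` the matrix's
    no-data entries are skipped in both the E- and M-steps; by default they
    are treated as observed zeros.

    K = 1 needs no iteration: theta is the smoothed column mean.
    """
    X, mask = _as_array(matrix)
    n, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of cells n={n}")
    W = (1.0 - mask) if (use_mask and mask is not None) else np.ones_like(X)

    if K == 1:
        theta = ((W * X).sum(axis=0) + smooth_a) / (
            W.sum(axis=0) + smooth_a + smooth_b
        )
        theta = theta[None, :]
        log_t, log_1mt = np.log(theta), np.log1p(-theta)
        ll = float(_log_bernoulli(X, W, log_t, log_1mt).sum())
        obj = ll + float(smooth_a * log_t.sum() + smooth_b * log_1mt.sum())
        return MixtureModel(
            1, np.ones(1), theta, np.ones((n, 1)), [obj], True, seed, ll
        )

    rng = np.random.default_rng(seed)
    inits = [rng.dirichlet(np.ones(K), size=n) for _ in range(n_restarts)]
    try:
        hard = hierarchical_labels(X, K)
        anchor = np.zeros((n, K))
        anchor[np.arange(n), hard] = 1.0
        inits.append(anchor)
    except Exception:  # degenerate matrices (e.g. all-identical rows)
        pass

    best = None
    for gamma0 in inits:
        fit = _em_once(X, W, gamma0, smooth_a, smooth_b, tol, max_iter)
        if best is None or fit[3][-1] > best[3][-1]:
            best = fit
    pi, theta, gamma, trace, converged, data_ll = best
    return MixtureModel(K, pi, theta, gamma, trace, converged, seed, data_ll)


def derive_mutation_clusters(
    model: MixtureModel,
    assay_ids: Sequence[str] | None = None,
    present_threshold: float = DEFAULT_PRESENT_THRESHOLD,
    clusters: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Group assays by their presence pattern across clusters.

    Each assay's theta column is thresholded (>= ``present_threshold``) over
    ``clusters`` (default: all K) into a 0/1 pattern. Pattern all-ones is
    the ancestral mutation cluster; all-zeros collects poor assays; a
    single-cluster pattern is that clone's specific cluster; any other
    pattern is labelled ``shared-<pattern>``.

    Returns a frame ``assay_id, pattern, label`` in assay order.
    """
    ks = list(clusters) if clusters is not None else list(range(model.K))
    patterns = (model.theta[ks, :] >= present_threshold).astype(int)
    J = model.theta.shape[1]
    ids = list(assay_ids) if assay_ids is not None else [str(j) for j in range(J)]
    rows = []
    for j in range(J):
        pat = tuple(int(v) for v in patterns[:, j])
        if all(pat):
            label = ANCESTRAL_LABEL
        elif not any(pat):
            label = POOR_LABEL
        elif sum(pat) == 1:
            label = f"clone-{ks[pat.index(1)]}-specific"
        else:
            label = "shared-" + "".join(map(str, pat))
        rows.append((ids[j], "".join(map(str, pat)), label))
    return pd.DataFrame(rows, columns=["assay_id", "pattern", "label"])


def flag_doublet_clusters(
    model: MixtureModel,
    tolerance: float = DEFAULT_DOUBLET_TOLERANCE,
) -> list[int]:
    """Flag clusters whose profile is the union of two other clusters.

    A doublet chamber holds two cells, so its genotype profile is close to
    the elementwise maximum of two clones' theta rows. Cluster d is flagged
    when mean_j |theta[d, j] - max(theta[a, j], theta[b, j])| < tolerance
    for some pair a != b of other clusters, and d is not itself within
    tolerance of any single other cluster (a cluster duplicating one clone
    is a K-selection matter, not a doublet). Needs K >= 3 to be expressible.
    """
    K = model.K
    if K < 3:
        return []
    flagged = []
    for d in range(K):
        others = [k for k in range(K) if k != d]
        near_single = any(
            np.mean(np.abs(model.theta[d] - model.theta[a])) < tolerance
            for a in others
        )
        if near_single:
            continue
        for a, b in combinations(others, 2):
            union = np.maximum(model.theta[a], model.theta[b])
            if np.mean(np.abs(model.theta[d] - union)) < tolerance:
                flagged.append(d)
                break
    return flagged
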