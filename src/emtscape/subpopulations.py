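"""Gaussian mixture subpopulations in E-M score space.

Samples are clustered on their (E, M) score pairs with axis-aligned
(diagonal-covariance) Gaussian mixtures.  Six covariance structures are
supported, named by the model-based-clustering convention where the three
letters describe volume, shape and orientation (orientation is always ``I``,
the identity, i.e. axis-aligned):

======  =======================================  variance parameters (d dims)
EII     one spherical variance shared by all     1
VII     per-component spherical variance         K
EEI     one diagonal shared by all               d
VEI     shared shape, per-component volume       K + (d - 1)
EVI     shared volume, per-component shape       1 + K (d - 1)
VVI     free diagonal per component              K d
======  =======================================  ======================

Model selection uses BIC = -2 loglik + n_params log(n), lower is better.
The mixture with five components typically wins on cancer-cohort geometry,
and its components receive semantic EMT labels: E (epithelial pole),
M (mesenchymal pole), I0 (low-E-low-M), I1 (high-E-high-M hybrid) and I2
(M-adjacent intermediate).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

__all__ = [
    "STRUCTURES",
    "DEFAULT_STRUCTURES",
    "MixtureModel",
    "ClusterAssignment",
    "fit_gmm",
    "select_model",
    "assign_clusters",
    "label_semantic",
    "compare_structures",
]

STRUCTURES = ("EII", "VII", "EEI", "VEI", "EVI", "VVI")
#: default selection set: unequal-volume shape models (VEI, VVI) are excluded
#: because they trade a small BIC gain for markedly less certain assignments.
DEFAULT_STRUCTURES = ("EII", "VII", "EEI", "EVI")

_EPS = 1e-12


@dataclass
class MixtureModel:
    """A fitted diagonal-family Gaussian mixture in d dimensions."""

    K: int
    structure: str
    weights: np.ndarray           # (K,)
    means: np.ndarray             # (K, d)
    variances: np.ndarray         # (K, d) diagonal entries
    loglik: float
    n_obs: int
    n_iter: int = 0
    converged: bool = True
    semantic: dict[int, str] | None = None

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_params(self) -> int:
        return _n_params(self.K, self.d, self.structure)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    def log_responsibilities(self, points: np.ndarray) -> np.ndarray:
        lp = _log_component_density(np.asarray(points, float), self.means, self.variances)
        lp = lp + np.log(self.weights)[None, :]
        return lp - logsumexp(lp, axis=1, keepdims=True)

    def posterior(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self.log_responsibilities(points))

    def to_json(self, path: str | Path | None = None) -> str:
        rec = {
            "K": self.K,
            "structure": self.structure,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "semantic": self.semantic,
        }
        text = json.dumps(rec, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MixtureModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        rec = json.loads(text)
        sem = rec.get("semantic")
        return cls(
            K=rec["K"],
            structure=rec["structure"],
            weights=np.asarray(rec["weights"], float),
            means=np.asarray(rec["means"], float),
            variances=np.asarray(rec["variances"], float),
            loglik=rec["loglik"],
            n_obs=rec["n_obs"],
            semantic={int(k): v for k, v in sem.items()} if sem else None,
        )


@dataclass
class ClusterAssignment:
    """Hard labels, posteriors and per-sample uncertainty for a fitted model."""

    labels: np.ndarray            # (n,) component indices
    posteriors: np.ndarray        # (n, K)
    sample_ids: list[str] | None = None
    semantic: dict[int, str] | None = None

    @property
    def uncertainty(self) -> np.ndarray:
        return 1.0 - self.posteriors.max(axis=1)

    def semantic_labels(self) -> np.ndarray:
        if self.semantic is None:
            raise ValueError("no semantic mapping attached")
        return np.asarray([self.semantic[int(k)] for k in self.labels])

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids is not None else range(len(self.labels))
        df = pd.DataFrame(
            {"cluster": self.labels, "uncertainty": self.uncertainty}, index=idx
        )
        if self.semantic is not None:
            df["semantic"] = self.semantic_labels()
        for k in range(self.posteriors.shape[1]):
            df[f"p{k}"] = self.posteriors[:, k]
        return df


def _n_params(K: int, d: int, structure: str) -> int:
    var = {
        "EII": 1,
        "VII": K,
        "EEI": d,
        "VEI": K + (d - 1),
        "EVI": 1 + K * (d - 1),
        "VVI": K * d,
    }[structure]
    return (K - 1) + K * d + var


def _log_component_density(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    # X: (n, d); means/variances: (K, d) -> (n, K)
    diff2 = (X[:, None, :] - means[None, :, :]) ** 2
    return -0.5 * (
        np.log(2 * np.pi * variances)[None, :, :] + diff2 / variances[None, :, :]
    ).sum(axis=2)


def _m_step_variances(W: np.ndarray, nk: np.ndarray, n: int, structure: str) -> np.ndarray:
    """Structure-constrained variance update.

    ``W[k, j] = sum_i resp_ik (x_ij - mu_kj)^2``; returns (K, d) diagonals.
    """
    K, d = W.shape
    W = np.maximum(W, 0.0)
    if structure == "VVI":
        return W / nk[:, None]
    if structure == "EEI":
        return np.tile(W.sum(axis=0) / n, (K, 1))
    if structure == "EII":
        return np.full((K, d), W.sum() / (n * d))
    if structure == "VII":
        return np.tile((W.sum(axis=1) / (nk * d))[:, None], (1, d))
    if structure == "EVI":
        # Sigma_k = lambda * B_k with det(B_k) = 1
        geo = np.exp(np.log(np.maximum(W, _EPS)).mean(axis=1))       # (K,) (prod W)^{1/d}
        B = W / geo[:, None]
        lam = geo.sum() / n
        return lam * np.maximum(B, _EPS)
    if structure == "VEI":
        # Sigma_k = lambda_k * B with det(B) = 1; alternate closed-form updates
        lam = np.ones(K)
        B = np.ones(d)
        for _ in range(10):
            Bn = (W / lam[:, None]).sum(axis=0)
            Bn = np.maximum(Bn, _EPS)
            B = Bn / np.exp(np.log(Bn).mean())
            lam_new = (W / B[None, :]).sum(axis=1) / (nk * d)
            if np.allclose(lam_new, lam, rtol=1e-10):
                lam = lam_new
                break
            lam = lam_new
        return lam[:, None] * B[None, :]
    raise ValueError(f"unknown covariance structure {structure!r}")


def _init_responsibilities(
    X: np.ndarray, K: int, init: str, seed: int | None,
    ward_tree: np.ndarray | None = None,
) -> np.ndarray:
    n = X.shape[0]
    if K == 1:
        return np.ones((n, 1))
    if init == "ward":
        Z = ward_tree if ward_tree is not None else linkage(X, method="ward")
        hard = fcluster(Z, t=K, criterion="maxclust") - 1
    elif init == "kmeans":
        from sklearn.cluster import KMeans

        hard = KMeans(n_clusters=K, n_init=5, random_state=seed).fit_predict(X)
    else:
        raise ValueError(f"unknown init {init!r}")
    resp = np.zeros((n, K))
    resp[np.arange(n), hard] = 1.0
    return resp


def fit_gmm(
    points: np.ndarray,
    K: int,
    structure: str = "EII",
    init: str = "ward",
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    max_restarts: int = 1,
    ward_tree: np.ndarray | None = None,
) -> MixtureModel:
    """Fit a K-component diagonal mixture by EM.

    Initialisation is a Ward hierarchical partition cut at K (deterministic);
    ``init="kmeans"`` with an explicit seed is the fallback.  EM stops when
    the log-likelihood improves by less than ``tol`` or after ``max_iter``
    iterations.  A component collapsing below variance 1e-12 triggers a
    k-means restart; after ``max_restarts`` failed attempts an error is
    raised.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be n x d")
    n, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 5 * K:
        raise ValueError(f"need n >= 5K points (n={n}, K={K})")
    if structure not in STRUCTURES:
        raise ValueError(f"unknown covariance structure {structure!r}")

    attempt_init = init
    attempt_seed = seed
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        try:
            return _fit_em(
                X, K, structure, attempt_init, attempt_seed, max_iter, tol,
                ward_tree=ward_tree if attempt_init == "ward" else None,
            )
        except _DegenerateComponent as err:
            last_err = err
            attempt_init = "kmeans"
            attempt_seed = (0 if seed is None else seed) + attempt + 1
            logger.warning("GMM restart %d for K=%d %s: %s", attempt + 1, K, structure, err)
    raise RuntimeError(f"GMM fit failed after {max_restarts} restarts: {last_err}")


class _DegenerateComponent(RuntimeError):
    pass


def _fit_em(
    X: np.ndarray, K: int, structure: str, init: str, seed: int | None,
    max_iter: int, tol: float, ward_tree: np.ndarray | None = None,
) -> MixtureModel:
    n, d = X.shape
    resp = _init_responsibilities(X, K, init, seed, ward_tree=ward_tree)
    loglik = -np.inf
    means = np.zeros((K, d))
    variances = np.ones((K, d))
    weights = np.full(K, 1.0 / K)
    converged = False
    it = 0
    prev_gain: float | None = None
    log2pi = np.log(2 * np.pi)
    cols = [X[:, j:j + 1] for j in range(d)]                   # n x 1 views per dim
    for it in range(1, max_iter + 1):
        # M step
        nk = resp.sum(axis=0)
        if (nk < _EPS).any():
            raise _DegenerateComponent("empty component")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        diff2 = [(c - means[None, :, j]) ** 2 for j, c in enumerate(cols)]  # d of (n, K)
        W = np.column_stack([(resp * d2).sum(axis=0) for d2 in diff2])      # (K, d)
        variances = _m_step_variances(W, nk, n, structure)
        if (variances < _EPS).any():
            raise _DegenerateComponent("variance collapsed below 1e-12")
        # E step (density at the just-updated means reuses diff2)
        lp = np.log(weights)[None, :] - 0.5 * (
            d * log2pi + np.log(variances).sum(axis=1)[None, :]
        )
        for j, d2 in enumerate(diff2):
            lp = lp - 0.5 * d2 / variances[None, :, j]
        lp_max = lp.max(axis=1)
        norm = lp_max + np.log(np.exp(lp - lp_max[:, None]).sum(axis=1))
        new_loglik = float(norm.sum())
        resp = np.exp(lp - norm[:, None])
        if np.isfinite(loglik):
            gain = new_loglik - loglik
            scale = tol * (1.0 + abs(new_loglik))
            if gain < scale:
                loglik = new_loglik
                converged = True
                break
            # Aitken acceleration: the EM gain sequence is asymptotically
            # geometric, so project the remaining total improvement and stop
            # once it falls below tolerance
            if prev_gain is not None and 0.0 < gain < prev_gain:
                rate = gain / prev_gain
                if gain * rate / (1.0 - rate) < scale:
                    loglik = new_loglik
                    converged = True
                    break
            prev_gain = gain
        loglik = new_loglik
    return MixtureModel(
        K=K, structure=structure, weights=weights, means=means,
        variances=variances, loglik=loglik, n_obs=n, n_iter=it, converged=converged,
    )


def select_model(
    points: np.ndarray,
    K_range: Sequence[int] = range(1, 10),
    structures: Sequence[str] = DEFAULT_STRUCTURES,
    init: str = "ward",
    seed: int | None = 0,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit all (K, structure) candidates and pick the minimum-BIC model.

    Returns ``(best_model, bic_table)``; the table has K as rows and
    structures as columns, with NaN for candidates that failed to fit.
    """
    table = pd.DataFrame(index=list(K_range), columns=list(structures), dtype=float)
    best: MixtureModel | None = None
    pts = np.asarray(points, dtype=float)
    tree = linkage(pts, method="ward") if init == "ward" else None
    for K in K_range:
        for structure in structures:
            try:
                model = fit_gmm(pts, K, structure, init=init, seed=seed, ward_tree=tree)
            except Exception as err:  # recorded as missing, not fatal
                logger.warning("candidate K=%d %s failed: %s", K, structure, err)
                continue
            table.loc[K, structure] = model.bic
            if best is None or model.bic < best.bic:
                best = model
    if best is None:
        raise RuntimeError("no mixture candidate could be fitted")
    return best, table


def assign_clusters(
    model: MixtureModel,
    points: np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Hard labels (argmax posterior) and uncertainties (1 - max posterior)."""
    X = np.asarray(points, dtype=float)
    if X.shape[1] != model.d:
        raise ValueError("points dimensionality does not match model")
    post = model.posterior(X)
    return ClusterAssignment(
        labels=post.argmax(axis=1),
        posteriors=post,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        semantic=model.semantic,
    )


def label_semantic(model: MixtureModel) -> dict[int, str]:
    """Attach EMT semantics to the components of a K in {4, 5} model.

    E is the component maximising (mu_E - mu_M), M the one maximising
    (mu_M - mu_E).  Of the remaining components, I0 has the lowest and I1 the
    highest mu_E + mu_M; with K = 5 the leftover (M-adjacent) intermediate is
    I2.  The mapping is stored on the model and returned.
    """
    if model.K not in (4, 5):
        raise ValueError(
            "semantic EMT labels are defined for K in {4, 5}; use integer labels otherwise"
        )
    if model.d != 2:
        raise ValueError("semantic labels require 2-D (E, M) score space")
    mu = model.means
    diff = mu[:, 0] - mu[:, 1]
    total = mu[:, 0] + mu[:, 1]
    e_idx = int(diff.argmax())
    m_idx = int(diff.argmin())
    if e_idx == m_idx:
        raise ValueError("degenerate geometry: E and M poles coincide")
    rest = [k for k in range(model.K) if k not in (e_idx, m_idx)]
    i0 = min(rest, key=lambda k: total[k])
    i1 = max(rest, key=lambda k: total[k])
    mapping = {e_idx: "E", m_idx: "M", i0: "I0", i1: "I1"}
    for k in rest:
        if k not in (i0, i1):
            mapping[k] = "I2"
    model.semantic = mapping
    return mapping


def compare_structures(
    assignments: Mapping[str, ClusterAssignment] | Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Pairwise adjusted Rand agreement between assignments on the same samples.

    Returns a square DataFrame; ``mean_agreement`` per structure is its row
    mean excluding the diagonal.
    """
    labels: dict[str, np.ndarray] = {}
    for name, a in assignments.items():
        arr = a.labels if isinstance(a, ClusterAssignment) else np.asarray(a)
        labels[name] = arr
    names = list(labels)
    if len(names) < 2:
        raise ValueError("need >= 2 assignments to compare")
    n = {len(v) for v in labels.values()}
    if len(n) != 1:
        raise ValueError("assignments cover different sample sets")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                ari = adjusted_rand_score(labels[a], labels[b])
                out.iloc[i, j] = out.iloc[j, i] = ari
    return out
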