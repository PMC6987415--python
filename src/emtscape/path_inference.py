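"""EMT paths through E-M score space.

A cohort's samples are summarised three ways:

* a quadrant census over the four sign-quadrants of (E, M) score space
  (hybrid high-E-high-M, terminal-E, terminal-M, characterless low-E-low-M);
* rotated coordinates ``u = (E - M)/sqrt(2)`` (progression along the
  hypothetical linear EMT axis, positive toward the E pole) and
  ``v = (E + M)/sqrt(2)`` (deviation toward the hybrid corner);
* minimal cluster paths: ordered sequences of adjacent mixture components
  from the extreme E component to the extreme M component using the fewest
  clusters, each fitted with a segmented model of deviation on progression.

Cluster adjacency defaults to the Gabriel graph on component means: two
components are adjacent when no third mean falls inside the disc whose
diameter joins them.  This captures "neighbouring regions" robustly; a
symmetrised k-nearest-neighbour graph is available as an alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .scoring import ScoreTable
from .segmented import SegmentedFit, davies_test, pseudo_score_test, select_n_breakpoints
from .subpopulations import ClusterAssignment, MixtureModel

logger = logging.getLogger(__name__)

__all__ = [
    "QuadrantCensus",
    "EMTPath",
    "quadrant_census",
    "rotate_coordinates",
    "cluster_adjacency",
    "enumerate_min_paths",
    "fit_emt_path",
    "plot_paths",
]

QUADRANTS = ("high-E-high-M", "high-E-low-M", "low-E-high-M", "low-E-low-M")


@dataclass
class QuadrantCensus:
    """Sample counts per sign-quadrant of the E-M plane.

    A score of exactly 0 counts as "low" (closed-left convention).
    """

    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n
        return {q: c / n for q, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "fraction": self.fractions}
        ).loc[list(QUADRANTS)]


@dataclass
class EMTPath:
    """One minimal cluster path from E to M with its segmented fit."""

    cluster_sequence: list[str]
    member_samples: list
    fit: SegmentedFit
    davies_p: float
    pseudo_score_p: float

    def to_dict(self) -> dict:
        return {
            "cluster_sequence": self.cluster_sequence,
            "n_samples": len(self.member_samples),
            "davies_p": self.davies_p,
            "pseudo_score_p": self.pseudo_score_p,
            "fit": self.fit.to_dict(),
        }


def quadrant_census(scores: ScoreTable | pd.DataFrame, e_col: str = "E", m_col: str = "M") -> QuadrantCensus:
    """Count samples per quadrant of the (E, M) score plane."""
    df = scores.scores if isinstance(scores, ScoreTable) else scores
    for col in (e_col, m_col):
        if col not in df.columns:
            raise ValueError(f"score column {col!r} not present")
    e = df[e_col].to_numpy(dtype=float)
    m = df[m_col].to_numpy(dtype=float)
    high_e = e > 0
    high_m = m > 0
    counts = {
        "high-E-high-M": int((high_e & high_m).sum()),
        "high-E-low-M": int((high_e & ~high_m).sum()),
        "low-E-high-M": int((~high_e & high_m).sum()),
        "low-E-low-M": int((~high_e & ~high_m).sum()),
    }
    return QuadrantCensus(counts)


def rotate_coordinates(e, m) -> tuple[np.ndarray, np.ndarray]:
    """Rotate (E, M) scores onto progression/deviation axes.

    ``u = (E - M) / sqrt(2)`` projects onto the slope -1 line through the
    origin (the hypothetical linear EMT axis), positive toward the E pole;
    ``v = (E + M) / sqrt(2)`` is the orthogonal deviation, positive toward
    the hybrid high-E-high-M corner.  The map is an isometry.
    """
    e = np.asarray(e, dtype=float)
    m = np.asarray(m, dtype=float)
    if not (np.isfinite(e).all() and np.isfinite(m).all()):
        raise ValueError("scores must be finite")
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    return (e - m) * inv_sqrt2, (e + m) * inv_sqrt2


def _gabriel_edges(means: np.ndarray) -> list[tuple[int, int]]:
    K = means.shape[0]
    edges = []
    for a in range(K):
        for b in range(a + 1, K):
            mid = (means[a] + means[b]) / 2.0
            r2 = ((means[a] - means[b]) ** 2).sum() / 4.0
            blocked = False
            for c in range(K):
                if c in (a, b):
                    continue
                if ((means[c] - mid) ** 2).sum() < r2:
                    blocked = True
                    break
            if not blocked:
                edges.append((a, b))
    return edges


def _knn_edges(means: np.ndarray, k: int) -> list[tuple[int, int]]:
    K = means.shape[0]
    d = np.sqrt(((means[:, None, :] - means[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    edges = set()
    for a in range(K):
        for b in np.argsort(d[a])[:k]:
            edges.add((min(a, int(b)), max(a, int(b))))
    return sorted(edges)


def cluster_adjacency(
    model: MixtureModel, method: str = "gabriel", k: int = 2
) -> nx.Graph:
    """Adjacency graph over mixture components (nodes are component indices)."""
    means = model.means
    if method == "gabriel":
        edges = _gabriel_edges(means)
    elif method == "knn":
        edges = _knn_edges(means, k)
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    g = nx.Graph()
    g.add_nodes_from(range(model.K))
    g.add_edges_from(edges)
    return g


def enumerate_min_paths(
    model: MixtureModel, method: str = "gabriel", k: int = 2
) -> list[list[str]]:
    """All shortest cluster sequences from the E pole to the M pole.

    Loops and backtracking are excluded by construction (shortest paths).
    Returns sequences of semantic labels, each starting at E and ending at M.
    """
    if model.semantic is None:
        raise ValueError("model needs semantic labels; call label_semantic first")
    inv = {v: k_ for k_, v in model.semantic.items()}
    graph = cluster_adjacency(model, method=method, k=k)
    try:
        paths = list(nx.all_shortest_paths(graph, inv["E"], inv["M"]))
    except nx.NetworkXNoPath:
        raise ValueError(
            "E and M components are disconnected in the adjacency graph; "
            "try a larger neighbour count (method='knn', k>2)"
        )
    sequences = [[model.semantic[c] for c in p] for p in paths]
    return sorted(sequences)


def fit_emt_path(
    sequence: list[str],
    scores: ScoreTable | pd.DataFrame,
    assignment: ClusterAssignment,
    e_col: str = "E",
    m_col: str = "M",
    max_breaks: int = 4,
    min_samples: int = 20,
) -> EMTPath:
    """Fit a segmented deviation-vs-progression model along one cluster path.

    Samples hard-assigned (by the mixture) to clusters on the sequence are
    rotated to (u, v) and ``v ~ u`` is fit with 1..max_breaks breakpoints,
    the best chosen by adjusted R^2.  Davies and pseudo-score breakpoint
    tests are attached.
    """
    df = scores.scores if isinstance(scores, ScoreTable) else scores
    sem = assignment.semantic_labels()
    on_path = np.isin(sem, sequence)
    if int(on_path.sum()) < min_samples:
        raise ValueError(f"path {sequence} has < {min_samples} member samples")
    sub = df.loc[on_path]
    u, v = rotate_coordinates(sub[e_col].to_numpy(), sub[m_col].to_numpy())
    fit, _ = select_n_breakpoints(u, v, max_breaks=max_breaks)
    return EMTPath(
        cluster_sequence=list(sequence),
        member_samples=sub.index.tolist(),
        fit=fit,
        davies_p=davies_test(u, v),
        pseudo_score_p=pseudo_score_test(u, v, n_breakpoints=max(1, fit.n_breakpoints)),
    )


def fit_all_samples(
    scores: ScoreTable | pd.DataFrame,
    e_col: str = "E",
    m_col: str = "M",
    max_breaks: int = 4,
) -> SegmentedFit:
    """Single segmented model over every sample, for path-vs-all comparison."""
    df = scores.scores if isinstance(scores, ScoreTable) else scores
    u, v = rotate_coordinates(df[e_col].to_numpy(), df[m_col].to_numpy())
    fit, _ = select_n_breakpoints(u, v, max_breaks=max_breaks)
    return fit


def plot_paths(
    scores: ScoreTable | pd.DataFrame,
    assignment: ClusterAssignment | None = None,
    paths: list[EMTPath] | None = None,
    e_col: str = "E",
    m_col: str = "M",
    ax=None,
):
    """Scatter of samples in E-M space with optional path-model overlay."""
    import matplotlib.pyplot as plt

    df = scores.scores if isinstance(scores, ScoreTable) else scores
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    colors = {"E": "tab:orange", "I0": "pink", "I1": "purple", "I2": "tab:blue", "M": "green"}
    if assignment is not None and assignment.semantic is not None:
        sem = assignment.semantic_labels()
        for lab in sorted(set(sem)):
            sel = sem == lab
            ax.scatter(df[e_col][sel], df[m_col][sel], s=6, alpha=0.6,
                       color=colors.get(lab, "gray"), label=lab)
        ax.legend(title="cluster", fontsize=8)
    else:
        ax.scatter(df[e_col], df[m_col], s=6, alpha=0.6, color="gray")
    if paths:
        inv_sqrt2 = 1.0 / np.sqrt(2.0)
        for path in paths:
            ugrid = np.linspace(path.fit.x.min(), path.fit.x.max(), 200)
            vgrid = path.fit.predict(ugrid)
            # back-rotate (u, v) -> (E, M)
            ax.plot((ugrid + vgrid) * inv_sqrt2, (vgrid - ugrid) * inv_sqrt2,
                    lw=2, label="-".join(path.cluster_sequence))
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("E score")
    ax.set_ylabel("M score")
    return ax
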