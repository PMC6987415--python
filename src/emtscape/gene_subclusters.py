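"""Semi-supervised subclustering of E- and M-genes by regulatory circuit.

Gene profiles from a combinatorial perturbation panel (e.g. TGF-beta x ZEB1
up/down-regulation in epithelial cells) are z-scored per gene and tiled onto
a 10 x 10 self-organizing map.  Each map node is then classified E or M by
majority vote of the annotated signature genes it contains (a 1-nearest-node
vote fills annotation-free nodes), and the nodes of each class are cut into
subclusters by Ward hierarchical clustering with the elbow criterion on
within-cluster sums of squares.  Genes inherit the subcluster of their node,
yielding subclusters such as E1..E3 / M1..M3 that group genes by the logic
of their TGF-beta / ZEB1 regulation.  Subclusters can finally be scored over
a time course like any other gene set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .genesets import GeneSet, GeneSetCollection
from .scoring import ExpressionMatrix, ScoreTable, WalkParams, score_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SOMGrid",
    "GeneSubcluster",
    "train_som",
    "classify_nodes",
    "subcluster_nodes",
    "score_subclusters",
]


@dataclass
class SOMGrid:
    """A trained self-organizing map over gene profiles.

    ``codebooks`` is (rows*cols, n_conditions); ``bmu`` maps each gene to its
    best-matching node (flat index).  ``quantization_errors`` records the mean
    gene-to-BMU distance after each epoch.
    """

    shape: tuple[int, int]
    codebooks: np.ndarray
    bmu: np.ndarray
    gene_ids: list[str]
    quantization_errors: list[float]
    seed: int
    epochs: int

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    def node_position(self, idx: int) -> tuple[int, int]:
        return divmod(idx, self.shape[1])

    def genes_in_node(self, idx: int) -> list[str]:
        return [g for g, b in zip(self.gene_ids, self.bmu) if b == idx]


@dataclass
class GeneSubcluster:
    """A named subcluster of same-class (E or M) genes."""

    name: str
    class_label: str
    member_nodes: list[int]
    member_genes: list[str]

    @property
    def size(self) -> int:
        return len(self.member_genes)

    def as_gene_set(self) -> GeneSet:
        return GeneSet(self.name, frozenset(self.member_genes), f"{self.class_label} subcluster")


def _grid_coords(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def condition_profiles(matrix: ExpressionMatrix, by: str = "condition") -> pd.DataFrame:
    """Gene x condition log2 profiles, averaging replicate columns.

    Replicate averaging (columns sharing a ``by`` metadata value) cuts
    per-condition noise before SOM training; genes keep one column per
    distinct condition.
    """
    if matrix.sample_meta is None or by not in matrix.sample_meta:
        raise ValueError(f"sample metadata with a {by!r} column is required")
    log2 = np.log2(matrix.values + 1.0)
    return log2.T.groupby(matrix.sample_meta[by]).mean().T


def train_som(
    profiles: pd.DataFrame | np.ndarray,
    shape: tuple[int, int] = (10, 10),
    epochs: int = 100,
    seed: int = 0,
    standardize: bool = True,
) -> SOMGrid:
    """Train a batch SOM on gene x condition profiles.

    Profiles are z-scored per gene across conditions (constant-profile genes
    are an error, listed by name).  Codebooks are initialised from a seeded
    random sample of genes and updated in batch with a Gaussian neighbourhood
    whose radius decays linearly from half the grid width to 0.5 over
    ``epochs``.  Deterministic under a fixed seed.
    """
    if isinstance(profiles, pd.DataFrame):
        gene_ids = profiles.index.tolist()
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        gene_ids = [f"g{i}" for i in range(X.shape[0])]
    if X.shape[1] < 2:
        raise ValueError("need >= 2 conditions")
    if standardize:
        sd = X.std(axis=1, ddof=0)
        constant = sd <= 0
        if constant.any():
            bad = [gene_ids[i] for i in np.flatnonzero(constant)[:10]]
            raise ValueError(f"constant-profile genes cannot be standardized: {bad}")
        X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    rng = np.random.default_rng(seed)
    coords = _grid_coords(shape)
    n_nodes = coords.shape[0]
    init_idx = rng.choice(X.shape[0], size=n_nodes, replace=X.shape[0] < n_nodes)
    codebooks = X[init_idx] + 1e-6 * rng.standard_normal((n_nodes, X.shape[1]))

    radius0 = max(shape) / 2.0
    grid_d2 = cdist(coords, coords, "sqeuclidean")
    qerrs: list[float] = []
    bmu = np.zeros(X.shape[0], dtype=int)
    for epoch in range(epochs):
        radius = max(radius0 * (1.0 - epoch / epochs), 0.5)
        d = cdist(X, codebooks, "sqeuclidean")
        bmu = d.argmin(axis=1)
        qerrs.append(float(np.sqrt(d[np.arange(X.shape[0]), bmu]).mean()))
        h = np.exp(-grid_d2[:, bmu] / (2.0 * radius * radius))   # nodes x genes
        denom = h.sum(axis=1, keepdims=True)
        updated = (h @ X) / np.where(denom > 0, denom, 1.0)
        codebooks = np.where(denom > 0, updated, codebooks)
    d = cdist(X, codebooks, "sqeuclidean")
    bmu = d.argmin(axis=1)
    qerrs.append(float(np.sqrt(d[np.arange(X.shape[0]), bmu]).mean()))
    return SOMGrid(
        shape=shape, codebooks=codebooks, bmu=bmu, gene_ids=gene_ids,
        quantization_errors=qerrs, seed=seed, epochs=epochs,
    )


def classify_nodes(
    grid: SOMGrid, e_set: GeneSet, m_set: GeneSet
) -> pd.DataFrame:
    """Label every map node E or M from its annotated member genes.

    Per node, annotated E and M members are counted and the majority class
    wins (the winning ratio is reported).  Nodes with no annotated members,
    and tied nodes, take the majority among the nearest labelled nodes on
    the grid (1-NN in grid distance); a residual tie goes to the class with
    more labelled nodes overall.
    """
    counts = np.zeros((grid.n_nodes, 2), dtype=int)   # columns: E, M
    for gene, node in zip(grid.gene_ids, grid.bmu):
        if gene in e_set:
            counts[node, 0] += 1
        if gene in m_set:
            counts[node, 1] += 1
    if counts.sum() == 0:
        raise ValueError("no annotated E or M genes map onto the grid")

    labels = np.array(["unlabeled"] * grid.n_nodes, dtype=object)
    labels[counts[:, 0] > counts[:, 1]] = "E"
    labels[counts[:, 1] > counts[:, 0]] = "M"

    coords = _grid_coords(grid.shape)
    decided = np.flatnonzero(labels != "unlabeled")
    undecided = np.flatnonzero(labels == "unlabeled")
    n_e_nodes = int((labels == "E").sum())
    n_m_nodes = int((labels == "M").sum())
    fallback = "E" if n_e_nodes >= n_m_nodes else "M"
    resolved = labels.copy()
    for node in undecided:
        d = np.sqrt(((coords[decided] - coords[node]) ** 2).sum(axis=1))
        nearest = decided[d == d.min()]
        votes = pd.Series(labels[nearest]).value_counts()
        if len(votes) == 1 or votes.iloc[0] > votes.iloc[1]:
            resolved[node] = votes.index[0]
        else:
            resolved[node] = fallback
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, counts.max(axis=1) / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "label": resolved,
            "n_e_genes": counts[:, 0],
            "n_m_genes": counts[:, 1],
            "majority_ratio": ratio,
            "imputed": labels == "unlabeled",
        },
        index=pd.RangeIndex(grid.n_nodes, name="node"),
    )


def _elbow_k(wss: np.ndarray) -> int:
    """Elbow of the WSS scree: largest second difference on log scale.

    The log scale measures relative curvature, so a huge first drop does not
    mask a later, proportionally sharper elbow.  Ties resolve to smaller k.
    """
    if wss[0] <= 1e-12:
        return 1
    if wss.size < 3:
        return 1
    logw = np.log(np.maximum(wss, 1e-12 * wss[0]))
    second = logw[:-2] - 2 * logw[1:-1] + logw[2:]  # index i -> k = i + 2
    return int(np.argmax(second)) + 2


def subcluster_nodes(
    grid: SOMGrid,
    node_labels: pd.DataFrame,
    class_label: str,
    k_max: int = 8,
    k: int | None = None,
) -> list[GeneSubcluster]:
    """Ward-cluster the codebooks of one class's nodes into gene subclusters.

    The number of subclusters is chosen by the elbow criterion on the
    within-cluster SSE over k = 1..k_max unless ``k`` is given; the SSE is
    weighted by node occupancy (gene count) so that sparsely populated
    interpolating nodes do not dominate the scree, and empty nodes are left
    out of the clustering entirely (they carry no genes).  Gene membership
    is inherited from nodes; subclusters are named ``E1.. / M1..`` in order
    of their earliest node index.
    """
    in_class = node_labels.index[node_labels["label"] == class_label].to_numpy()
    if in_class.size == 0:
        raise ValueError(f"no nodes labelled {class_label!r}")
    occ_all = np.array([len(grid.genes_in_node(int(n))) for n in in_class])
    nodes = in_class[occ_all > 0] if (occ_all > 0).any() else in_class
    occ = occ_all[occ_all > 0] if (occ_all > 0).any() else np.ones_like(occ_all)
    if nodes.size == 1:
        warnings.warn(f"single {class_label} node: one trivial subcluster", RuntimeWarning)
        return [
            GeneSubcluster(
                f"{class_label}1", class_label, [int(nodes[0])], grid.genes_in_node(int(nodes[0]))
            )
        ]
    cb = grid.codebooks[nodes]
    Z = linkage(cb, method="ward")
    k_hi = min(k_max, nodes.size)
    if k is None:
        wss = np.empty(k_hi)
        for kk in range(1, k_hi + 1):
            memb = fcluster(Z, t=kk, criterion="maxclust")
            total = 0.0
            for c in np.unique(memb):
                sel = memb == c
                w = occ[sel].astype(float)
                mu = (cb[sel] * w[:, None]).sum(axis=0) / w.sum()
                total += float((w[:, None] * (cb[sel] - mu) ** 2).sum())
            wss[kk - 1] = total
        k = _elbow_k(wss)
    memb = fcluster(Z, t=k, criterion="maxclust")
    # name subclusters deterministically by their earliest node index
    order = sorted(np.unique(memb), key=lambda c: nodes[memb == c].min())
    out = []
    for rank, c in enumerate(order, start=1):
        node_list = [int(v) for v in nodes[memb == c]]
        genes = [g for nd in node_list for g in grid.genes_in_node(nd)]
        out.append(GeneSubcluster(f"{class_label}{rank}", class_label, node_list, genes))
    return out


def score_subclusters(
    matrix: ExpressionMatrix,
    subclusters: list[GeneSubcluster],
    params: WalkParams = WalkParams(),
) -> ScoreTable:
    """Enrichment-score each subcluster per sample (delegates to scoring)."""
    sets = GeneSetCollection.from_sets(
        sc.as_gene_set() for sc in subclusters if sc.size > 0
    )
    return score_matrix(matrix, sets, params=params)


def membership_table(subclusters: list[GeneSubcluster]) -> pd.DataFrame:
    """Long-format (gene, class, subcluster) table for export."""
    rows = [
        {"gene": g, "class": sc.class_label, "subcluster": sc.name}
        for sc in subclusters
        for g in sorted(sc.member_genes)
    ]
    return pd.DataFrame(rows)
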