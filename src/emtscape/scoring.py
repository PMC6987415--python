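"""Single-sample gene-set enrichment scores in the E-M plane.

The score of a gene set in one sample is computed by the kernel-ECDF /
Kolmogorov-Smirnov random-walk statistic popularised by gene set variation
analysis:

1. For every gene, a cumulative density of its expression is estimated across
   the whole cohort with a Gaussian kernel of bandwidth ``sd / 4``, giving a
   per-gene, per-sample statistic ``z`` that is monotone in expression.
2. Within each sample, genes are ranked by decreasing ``z`` and the rank ``r``
   is folded into the symmetric rank statistic ``|p/2 - r|`` so that extreme
   up- and down-regulation both carry large weight.
3. A weighted Kolmogorov-Smirnov random walk over the ranked gene list steps
   up by the (tau-powered) symmetric rank weight at in-set genes and down by
   ``1/(p - m)`` elsewhere; the enrichment score is the signed combination of
   the walk's largest positive and negative excursions, which lies in [-1, 1].

Scores are cohort-relative: adding samples changes the kernel ECDF and hence
every sample's score.  Cohorts must therefore be scored as the analysis
intends to compare them (e.g. a time course is scored on its own).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ScoreTable",
    "WalkParams",
    "expression_statistic",
    "symmetric_rank",
    "random_walk_es",
    "score_matrix",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    ``values`` is a DataFrame indexed by unique gene identifiers with unique
    sample identifiers as columns.  ``sample_meta`` (optional) is indexed by
    sample id and may carry ``cohort``, ``time_days``, ``subtype``,
    ``condition`` or any other annotation.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if v.shape[0] < 2:
            raise ValueError("expression matrix needs >= 2 genes")
        if v.shape[1] < 1:
            raise ValueError("expression matrix needs >= 1 sample")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.sample_meta is not None:
            missing = v.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing samples: {list(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[v.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @classmethod
    def read_delimited(
        cls,
        path: str | Path,
        sep: str = "\t",
        meta_path: str | Path | None = None,
    ) -> "ExpressionMatrix":
        """Read a gene x sample matrix (first column gene id, header = samples)."""
        values = pd.read_csv(path, sep=sep, index_col=0)
        meta = pd.read_csv(meta_path, sep=sep, index_col=0) if meta_path else None
        return cls(values, meta)

    def write_delimited(self, path: str | Path, sep: str = "\t") -> None:
        self.values.to_csv(path, sep=sep, index_label="gene")


@dataclass
class ScoreTable:
    """Samples x named enrichment scores, each value in [-1, 1].

    ``provenance`` maps score name -> (gene-set name, effective set size after
    dropping genes absent from the matrix).
    """

    scores: pd.DataFrame
    provenance: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1 - 1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise ValueError("enrichment scores must lie in [-1, 1]")

    def __getitem__(self, name: str) -> pd.Series:
        return self.scores[name]

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    def write_delimited(self, path: str | Path, sep: str = "\t") -> None:
        self.scores.to_csv(path, sep=sep, index_label="sample")

    @classmethod
    def read_delimited(cls, path: str | Path, sep: str = "\t") -> "ScoreTable":
        return cls(pd.read_csv(path, sep=sep, index_col=0))


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the random-walk statistic.

    tau
        Exponent on the symmetric rank weight (default 1).
    es_mode
        ``max_diff``: es = max(0, max nu) + min(0, min nu); ``max_abs``: the
        signed extremum of largest magnitude.
    kernel
        ``gaussian`` kernel-ECDF (bandwidth sd / bandwidth_divisor),
        ``none`` for rank-only ECDF, ``poisson`` reserved for count input.
    log_transform
        Apply log2(x + 1) before kernel estimation; appropriate for
        linear-scale abundance (RSEM / FPKM) input.
    """

    tau: float = 1.0
    es_mode: str = "max_diff"
    kernel: str = "gaussian"
    bandwidth_divisor: float = 4.0
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.es_mode not in ("max_diff", "max_abs"):
            raise ValueError(f"unknown es_mode {self.es_mode!r}")
        if self.kernel not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.bandwidth_divisor <= 0:
            raise ValueError("bandwidth_divisor must be > 0")


def expression_statistic(
    values: np.ndarray | pd.DataFrame,
    kernel: str = "gaussian",
    bandwidth_divisor: float = 4.0,
    block_size: int | None = None,
) -> np.ndarray:
    """Kernel-estimated cumulative expression statistic, genes x samples.

    For gene ``i`` and sample ``j`` under the Gaussian kernel::

        z_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i),   h_i = sd_i / divisor

    which is strictly increasing in ``x_ij`` for fixed ``i``.  Genes with zero
    variance get the constant ``z = 0.5`` (middle of the distribution) and are
    logged.  ``kernel="none"`` uses the within-gene empirical CDF (average
    ranks for ties) instead, making downstream scores purely rank-based.
    """
    X = np.asarray(values, dtype=float)
    p, n = X.shape
    if kernel == "poisson":
        raise NotImplementedError(
            "Poisson kernel is reserved for raw count input; use gaussian or none"
        )
    if kernel == "none":
        from scipy.stats import rankdata

        return rankdata(X, axis=1) / n
    if n < 2:
        raise ValueError("cohort scoring requires >=2 samples")
    sd = X.std(axis=1, ddof=1)
    h = sd / bandwidth_divisor
    degenerate = h <= 0
    if degenerate.any():
        logger.warning("%d zero-variance genes set to z = 0.5", int(degenerate.sum()))
    z = np.full((p, n), 0.5)
    ok = np.flatnonzero(~degenerate)
    if block_size is None:
        # keep the (block, n, n) temporary around ~32 MB
        block_size = max(1, int(4e6 / max(n * n, 1)))
    for start in range(0, ok.size, block_size):
        idx = ok[start : start + block_size]
        xb = X[idx]                                    # b x n
        hb = h[idx][:, None, None]
        z[idx] = ndtr((xb[:, :, None] - xb[:, None, :]) / hb).mean(axis=2)
    return z


def symmetric_rank(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample decreasing-z gene ranks folded around the middle rank.

    Returns ``(r_tilde, ordering)`` where ``ordering[:, j]`` lists gene
    indices of sample ``j`` by decreasing ``z`` (ties broken by input gene
    order for determinism) and ``r_tilde[i, j] = |p/2 - r_ij|`` with
    ``r_ij`` the 1-based rank of gene ``i`` in sample ``j``.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("expression statistic contains non-finite values")
    p, n = z.shape
    ordering = np.argsort(-z, axis=0, kind="stable")    # p x n gene indices
    ranks = np.empty_like(ordering)
    rows = np.arange(1, p + 1)[:, None]
    np.put_along_axis(ranks, ordering, np.broadcast_to(rows, (p, n)), axis=0)
    r_tilde = np.abs(p / 2.0 - ranks)
    return r_tilde, ordering


def random_walk_es(
    ordering: np.ndarray,
    r_tilde_sample: np.ndarray,
    set_mask: np.ndarray,
    params: WalkParams = WalkParams(),
) -> tuple[float, np.ndarray]:
    """Weighted KS random walk for one sample and one gene set.

    Parameters
    ----------
    ordering
        Gene indices of this sample sorted by decreasing ``z`` (length p).
    r_tilde_sample
        Symmetric rank statistic of this sample, indexed by gene (length p).
    set_mask
        Boolean gene membership, indexed by gene (length p), with
        ``1 <= m < p`` members.

    Returns the enrichment score and the full walk ``nu`` (length p, with
    ``nu[p-1] == 0`` by construction of the normalisation).
    """
    ordering = np.asarray(ordering)
    mask = np.asarray(set_mask, dtype=bool)
    p = ordering.size
    m = int(mask.sum())
    if m == 0 or m >= p:
        raise ValueError("gene set must have 1 <= m < p members in the matrix")
    in_set = mask[ordering]
    w = np.where(in_set, np.asarray(r_tilde_sample, float)[ordering] ** params.tau, 0.0)
    w_total = w.sum()
    if w_total <= 0:
        raise ValueError("degenerate set weights: all in-set symmetric ranks are zero")
    nu = np.cumsum(w) / w_total - np.cumsum(~in_set) / (p - m)
    es = _walk_to_es(nu[None, :], params.es_mode)[0]
    return float(es), nu


def _walk_to_es(nu: np.ndarray, es_mode: str) -> np.ndarray:
    """Collapse walks (rows) to enrichment scores."""
    top = np.maximum(nu.max(axis=1), 0.0)
    bottom = np.minimum(nu.min(axis=1), 0.0)
    if es_mode == "max_diff":
        return top + bottom
    return np.where(top >= -bottom, top, bottom)


def score_matrix(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    params: WalkParams = WalkParams(),
    restrict_to_matrix: bool = True,
) -> ScoreTable:
    """Score every sample of ``matrix`` for every gene set in ``sets``.

    Genes in a set but absent from the matrix are dropped with a logged
    count; a set matching fewer than 2 matrix genes is an error.  Returns a
    :class:`ScoreTable` with one column per set.
    """
    X = matrix.values.to_numpy(dtype=float)
    if params.log_transform:
        if (X < 0).any():
            raise ValueError(
                "negative values with log_transform=True; pass log_transform=False "
                "for pre-transformed input"
            )
        X = np.log2(X + 1.0)
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    p, n = X.shape

    masks: dict[str, np.ndarray] = {}
    provenance: dict[str, tuple[str, int]] = {}
    for gs in sets:
        hit = [gene_index[g] for g in gs.genes if g in gene_index]
        dropped = gs.size - len(hit)
        if dropped and restrict_to_matrix:
            logger.info("set %s: dropped %d/%d genes absent from matrix", gs.name, dropped, gs.size)
        if len(hit) < 2:
            raise ValueError(f"gene set {gs.name!r} matches < 2 genes in the matrix")
        if len(hit) >= p:
            raise ValueError(f"gene set {gs.name!r} covers every matrix gene")
        mask = np.zeros(p, dtype=bool)
        mask[hit] = True
        masks[gs.name] = mask
        provenance[gs.name] = (gs.name, len(hit))

    z = expression_statistic(X, kernel=params.kernel, bandwidth_divisor=params.bandwidth_divisor)
    r_tilde, ordering = symmetric_rank(z)

    # walk all samples at once per set: reorder weights by each sample's ordering
    r_ord = np.take_along_axis(r_tilde, ordering, axis=0) ** params.tau   # p x n
    scores = np.empty((n, len(masks)))
    for s_idx, (name, mask) in enumerate(masks.items()):
        in_set = mask[ordering]                                           # p x n
        w = np.where(in_set, r_ord, 0.0)
        w_total = w.sum(axis=0)
        if (w_total <= 0).any():
            raise ValueError(f"degenerate set weights for set {name!r}")
        m = int(mask.sum())
        nu = np.cumsum(w, axis=0) / w_total - np.cumsum(~in_set, axis=0) / (p - m)
        scores[:, s_idx] = _walk_to_es(nu.T, params.es_mode)
    table = pd.DataFrame(scores, index=matrix.sample_ids, columns=list(masks))
    return ScoreTable(table, provenance)
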