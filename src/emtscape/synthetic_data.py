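"""Synthetic transcriptomes with the statistical structure the pipeline assumes.

Three generators emit gene x sample expression matrices on a linear
(RSEM/FPKM-like) scale together with their generating truth:

* cohorts whose samples carry latent (E-activity, M-activity) pairs drawn
  from a mixture of clusters arranged along a nonlinear EMT path, plus an
  optional non-epithelial outgroup far below every cluster;
* induction time courses whose latent activities follow a piecewise-linear
  triphasic trajectory with breakpoints at 2.5 and 10 days;
* combinatorial TGF-beta x ZEB1 perturbation panels in which six gene
  subclusters respond through distinct logic gates (OR / AND / single-input /
  incoherent feed-forward).

Signature genes load linearly on their latent activity on log2 scale
(positive loadings), background genes are latent-independent, and Gaussian
log-scale noise (default sd 0.3) is added before exponentiating.  Scores are
cohort-relative, so truth is kept in latent units and recovery is judged on
orderings and structure, not absolute score values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genesets import GeneSet, GeneSetCollection
from .scoring import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PathSpec",
    "GateSpec",
    "GateModel",
    "PiecewiseTrajectory",
    "SyntheticTruth",
    "default_path_spec",
    "default_gate_model",
    "default_trajectory",
    "signature_sets",
    "generate_cohort",
    "generate_outgroup",
    "generate_timecourse",
    "generate_perturbation_panel",
    "generate_gate_timecourse",
    "pool_matrices",
]

# latent (E, M) cluster centers mimicking the five-state cancer-cohort
# geometry: epithelial pole, low-low intermediate, hybrid high-high
# intermediate, M-adjacent intermediate, mesenchymal pole
_FIVE_STATE_CENTERS = {
    "E": (0.45, -0.35),
    "I0": (-0.15, -0.30),
    "I1": (0.30, 0.25),
    "I2": (-0.05, 0.35),
    "M": (-0.50, 0.55),
}


@dataclass(frozen=True)
class PathSpec:
    """Mixture of latent (E, M) clusters along an EMT path."""

    centers: dict[str, tuple[float, float]]
    weights: dict[str, float]
    spread: float = 0.09
    path_truth: tuple[tuple[str, ...], ...] = (
        ("E", "I0", "I2", "M"),
        ("E", "I1", "I2", "M"),
    )

    def __post_init__(self) -> None:
        if set(self.centers) != set(self.weights):
            raise ValueError("centers and weights must name the same clusters")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total})")
        pts = list(self.centers.values())
        if len({tuple(p) for p in pts}) != len(pts):
            raise ValueError("cluster centers must be distinct")

    def sample_latent(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw n latent (e, m) pairs; returns (points, cluster labels)."""
        names = list(self.centers)
        probs = np.array([self.weights[c] for c in names])
        idx = rng.choice(len(names), size=n, p=probs)
        centers = np.array([self.centers[c] for c in names])
        pts = centers[idx] + rng.normal(0.0, self.spread, size=(n, 2))
        return pts, np.array(names, dtype=object)[idx]


def default_path_spec() -> PathSpec:
    return PathSpec(
        centers=dict(_FIVE_STATE_CENTERS),
        weights={"E": 0.30, "I0": 0.15, "I1": 0.22, "I2": 0.13, "M": 0.20},
    )


@dataclass
class SyntheticTruth:
    """Generating truth emitted alongside a synthetic matrix."""

    latent: pd.DataFrame                  # per-sample latent activities (+ cluster/time)
    gene_class: pd.Series                 # per-gene: E / M / background
    seed: int
    subcluster: pd.Series | None = None   # per-gene subcluster (gate-model panels)

    def write(self, prefix: str) -> None:
        self.latent.to_csv(f"{prefix}_latent.tsv", sep="\t", index_label="sample")
        frame = self.gene_class.to_frame("class")
        if self.subcluster is not None:
            frame["subcluster"] = self.subcluster
        frame.to_csv(f"{prefix}_genes.tsv", sep="\t", index_label="gene")


def signature_sets(n_e_genes: int = 150, n_m_genes: int = 120) -> GeneSetCollection:
    """The E/M gene-set collection matching the generators' gene naming."""
    e = GeneSet("E", frozenset(f"EG{i:04d}" for i in range(n_e_genes)), "synthetic E signature")
    m = GeneSet("M", frozenset(f"MG{i:04d}" for i in range(n_m_genes)), "synthetic M signature")
    return GeneSetCollection.from_sets([e, m])


def _gene_params(n_e: int, n_m: int, n_bg: int, seed: int):
    """Deterministic per-gene baselines and loadings shared across generators.

    Derived from the seed alone so that cohort and outgroup matrices built
    with the same seed and gene counts share identical gene models and can
    be pooled column-wise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 7919]))
    p = n_e + n_m + n_bg
    baseline = rng.uniform(4.0, 8.0, size=p)
    loading = rng.uniform(1.5, 3.0, size=p)       # positive: monotone in latent
    names = (
        [f"EG{i:04d}" for i in range(n_e)]
        + [f"MG{i:04d}" for i in range(n_m)]
        + [f"BG{i:04d}" for i in range(n_bg)]
    )
    classes = ["E"] * n_e + ["M"] * n_m + ["background"] * n_bg
    return names, classes, baseline, loading


def _latent_to_matrix(
    latent: np.ndarray,
    sample_ids: list[str],
    n_e: int,
    n_m: int,
    n_bg: int,
    seed: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    names, classes, baseline, loading = _gene_params(n_e, n_m, n_bg, seed)
    n = latent.shape[0]
    p = len(names)
    signal = np.zeros((p, n))
    signal[:n_e] = np.outer(loading[:n_e], latent[:, 0])
    signal[n_e : n_e + n_m] = np.outer(loading[n_e : n_e + n_m], latent[:, 1])
    log2_expr = baseline[:, None] + signal + rng.normal(0.0, noise_sd, size=(p, n))
    values = pd.DataFrame(
        np.maximum(np.exp2(log2_expr) - 1.0, 0.0), index=names, columns=sample_ids
    )
    return values, pd.Series(classes, index=names, name="class")


def generate_cohort(
    spec: PathSpec | None = None,
    n_samples: int = 1200,
    n_e_genes: int = 150,
    n_m_genes: int = 120,
    n_background: int = 200,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Cohort whose samples lie on a mixture of clusters along an EMT path."""
    spec = spec or default_path_spec()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 1]))
    latent, clusters = spec.sample_latent(n_samples, rng)
    ids = [f"S{i:05d}" for i in range(n_samples)]
    values, gene_class = _latent_to_matrix(
        latent, ids, n_e_genes, n_m_genes, n_background, seed, noise_sd, rng
    )
    meta = pd.DataFrame({"cohort": "synthetic", "true_cluster": clusters}, index=ids)
    truth = SyntheticTruth(
        latent=pd.DataFrame(
            {"e_activity": latent[:, 0], "m_activity": latent[:, 1], "cluster": clusters},
            index=ids,
        ),
        gene_class=gene_class,
        seed=seed,
    )
    return ExpressionMatrix(values, meta), truth


def generate_outgroup(
    n: int = 173,
    seed: int = 0,
    center: tuple[float, float] = (-1.3, -1.1),
    spread: float = 0.08,
    n_e_genes: int = 150,
    n_m_genes: int = 120,
    n_background: int = 200,
    noise_sd: float = 0.3,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Non-epithelial-lineage surrogate far below every cohort cluster.

    Shares gene parameters with :func:`generate_cohort` for the same seed
    and gene counts, so the matrices can be pooled and scored jointly.
    Scoring an outgroup alone is meaningless (no E/M contrast within it);
    it exists to anchor the extreme low-E-low-M corner of a pooled cohort.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 2]))
    latent = np.asarray(center, float) + rng.normal(0.0, spread, size=(n, 2))
    ids = [f"O{i:05d}" for i in range(n)]
    values, gene_class = _latent_to_matrix(
        latent, ids, n_e_genes, n_m_genes, n_background, seed, noise_sd, rng
    )
    meta = pd.DataFrame({"cohort": "outgroup", "true_cluster": "outgroup"}, index=ids)
    truth = SyntheticTruth(
        latent=pd.DataFrame(
            {"e_activity": latent[:, 0], "m_activity": latent[:, 1], "cluster": "outgroup"},
            index=ids,
        ),
        gene_class=gene_class,
        seed=seed,
    )
    return ExpressionMatrix(values, meta), truth


def pool_matrices(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two matrices over identical gene sets."""
    if list(a.gene_ids) != list(b.gene_ids):
        raise ValueError("matrices must share an identical gene index to pool")
    values = pd.concat([a.values, b.values], axis=1)
    metas = [m for m in (a.sample_meta, b.sample_meta) if m is not None]
    meta = pd.concat(metas) if len(metas) == 2 else None
    return ExpressionMatrix(values, meta)


@dataclass(frozen=True)
class PiecewiseTrajectory:
    """Piecewise-linear latent (e(t), m(t)) with two shared breakpoints."""

    breakpoints: tuple[float, float] = (2.5, 10.0)
    e_start: float = 0.5
    e_slopes: tuple[float, float, float] = (0.02, -0.01, -0.08)
    m_start: float = -0.5
    m_slopes: tuple[float, float, float] = (0.1, 0.02, 0.05)

    def _eval(self, t: np.ndarray, start: float, slopes: tuple[float, ...]) -> np.ndarray:
        b1, b2 = self.breakpoints
        out = start + slopes[0] * np.minimum(t, b1)
        out = out + slopes[1] * np.clip(t - b1, 0.0, b2 - b1)
        out = out + slopes[2] * np.maximum(t - b2, 0.0)
        return out

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return np.column_stack(
            [self._eval(t, self.e_start, self.e_slopes), self._eval(t, self.m_start, self.m_slopes)]
        )


def default_trajectory() -> PiecewiseTrajectory:
    return PiecewiseTrajectory()


DEFAULT_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 12.0, 16.0, 21.0)


def generate_timecourse(
    trajectory: PiecewiseTrajectory | None = None,
    times: tuple[float, ...] = DEFAULT_TIMES,
    replicates: int = 3,
    latent_noise_sd: float = 0.02,
    n_e_genes: int = 150,
    n_m_genes: int = 120,
    n_background: int = 200,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Induction time course with piecewise-linear latent E/M activity."""
    if len(times) < 2:
        raise ValueError("need >= 2 time points")
    trajectory = trajectory or default_trajectory()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 3]))
    t_all = np.repeat(np.asarray(times, float), replicates)
    latent = trajectory.evaluate(t_all) + rng.normal(0.0, latent_noise_sd, size=(t_all.size, 2))
    ids = [f"T{t:05.1f}_r{r}" for t in times for r in range(replicates)]
    values, gene_class = _latent_to_matrix(
        latent, ids, n_e_genes, n_m_genes, n_background, seed, noise_sd, rng
    )
    meta = pd.DataFrame({"cohort": "timecourse", "time_days": t_all}, index=ids)
    truth = SyntheticTruth(
        latent=pd.DataFrame(
            {"e_activity": latent[:, 0], "m_activity": latent[:, 1], "time_days": t_all},
            index=ids,
        ),
        gene_class=gene_class,
        seed=seed,
    )
    return ExpressionMatrix(values, meta), truth


@dataclass(frozen=True)
class GateSpec:
    """Regulatory logic of one gene subcluster.

    ``gate`` is one of ``or``, ``and``, ``single``, ``ffl-incoherent``.
    ``sign`` is the direction of the fully-active response; ``single_tgfb``
    scales the response to TGF-beta alone for AND gates (reduced when in
    (0, 1), opposite-signed when negative).
    """

    name: str
    class_label: str
    regulators: tuple[str, ...]
    gate: str
    sign: float
    single_tgfb: float = 0.0
    effect: float = 1.0

    def response(self, tgfb: float, zeb1: float) -> float:
        """Mean log2-scale response at continuous regulator levels in [0, 1]."""
        t, z = float(tgfb), float(zeb1)
        if self.gate == "or":
            r = self.sign * max(t if "TGFB" in self.regulators else 0.0,
                                z if "ZEB1" in self.regulators else 0.0)
        elif self.gate == "and":
            r = self.sign * t * z + self.single_tgfb * t * (1.0 - z)
        elif self.gate == "single":
            level = t if self.regulators == ("TGFB",) else z
            r = self.sign * level
        elif self.gate == "ffl-incoherent":
            # TGF-beta activates through a ZEB1-independent arm whose output
            # ZEB1 suppresses when present; ZEB1 also represses directly
            r = t * (1.0 - z) - z
        else:
            raise ValueError(f"unknown gate {self.gate!r}")
        return self.effect * r


@dataclass(frozen=True)
class GateModel:
    """The six-subcluster TGF-beta / ZEB1 logic-gate model."""

    subclusters: tuple[GateSpec, ...]
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for sc in self.subclusters:
            if not sc.regulators:
                raise ValueError(f"subcluster {sc.name} has no regulators")
        e2 = next((sc for sc in self.subclusters if sc.name == "E2"), None)
        if e2 is not None and e2.gate != "ffl-incoherent":
            raise ValueError("E2 must be configured as an incoherent feed-forward loop")

    def get(self, name: str) -> GateSpec:
        for sc in self.subclusters:
            if sc.name == name:
                return sc
        raise KeyError(name)


def default_gate_model() -> GateModel:
    """Default wiring: OR/AND/single/iFFL circuits for E1-E3 and M1-M3.

    E-genes are net-repressed and M-genes net-activated during EMT; the AND
    gates respond to TGF-beta alone with a reduced (M1) or opposite-signed
    (E3) effect, and E2's TGF-beta activation is suppressed whenever ZEB1 is
    present.
    """
    return GateModel(
        subclusters=(
            GateSpec("E1", "E", ("TGFB", "ZEB1"), "or", sign=-1.0),
            GateSpec("E2", "E", ("TGFB", "ZEB1"), "ffl-incoherent", sign=+1.0),
            GateSpec("E3", "E", ("TGFB", "ZEB1"), "and", sign=-1.0, single_tgfb=+0.5),
            GateSpec("M1", "M", ("TGFB", "ZEB1"), "and", sign=+1.0, single_tgfb=+0.5),
            GateSpec("M2", "M", ("TGFB", "ZEB1"), "or", sign=+1.0),
            GateSpec("M3", "M", ("ZEB1",), "single", sign=+1.0),
        )
    )


FACTORIAL_CONDITIONS = ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0))


def generate_perturbation_panel(
    gates: GateModel | None = None,
    conditions: tuple[tuple[float, float], ...] = FACTORIAL_CONDITIONS,
    genes_per_subcluster: int = 40,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """2x2-factorial (or richer) TGF-beta x ZEB1 perturbation panel.

    Every condition is a (TGFB level, ZEB1 level) pair; the 2x2 factorial
    must be covered.  Gene log2 expression = baseline + subcluster gate
    response + noise, emitted on linear scale.
    """
    gates = gates or default_gate_model()
    for cond in conditions:
        if len(cond) != 2:
            raise ValueError(f"condition {cond} must provide both regulator levels")
    required = {(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)}
    if not required.issubset({(float(a), float(b)) for a, b in conditions}):
        raise ValueError("conditions must include the full 2x2 factorial")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 4]))

    gene_names, gene_cls, gene_sub = [], [], []
    for sc in gates.subclusters:
        for i in range(genes_per_subcluster):
            gene_names.append(f"{sc.name}G{i:03d}")
            gene_cls.append(sc.class_label)
            gene_sub.append(sc.name)
    p = len(gene_names)
    baseline = rng.uniform(4.0, 8.0, size=p)

    cols, col_ids, meta_rows = [], [], []
    for t_level, z_level in conditions:
        resp = np.array(
            [gates.get(sub).response(t_level, z_level) for sub in gene_sub]
        )
        for r in range(replicates):
            log2_expr = baseline + resp + rng.normal(0.0, gates.noise_sd, size=p)
            cols.append(np.maximum(np.exp2(log2_expr) - 1.0, 0.0))
            col_ids.append(f"T{t_level:g}_Z{z_level:g}_r{r}")
            meta_rows.append({"condition": f"T{t_level:g}_Z{z_level:g}",
                              "tgfb": t_level, "zeb1": z_level})
    values = pd.DataFrame(np.column_stack(cols), index=gene_names, columns=col_ids)
    meta = pd.DataFrame(meta_rows, index=col_ids)
    truth = SyntheticTruth(
        latent=pd.DataFrame(meta, index=col_ids),
        gene_class=pd.Series(gene_cls, index=gene_names, name="class"),
        seed=seed,
        subcluster=pd.Series(gene_sub, index=gene_names, name="subcluster"),
    )
    return ExpressionMatrix(values, meta), truth


def _regulator_dynamics(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """TGF-beta saturates early; ZEB1 rises during the intermediate phase."""
    t = np.asarray(times, float)
    tgfb = np.clip(t / 2.5, 0.0, 1.0)
    zeb1 = np.clip((t - 5.0) / 7.0, 0.0, 1.0)
    return tgfb, zeb1


def generate_gate_timecourse(
    gates: GateModel | None = None,
    times: tuple[float, ...] = DEFAULT_TIMES,
    replicates: int = 3,
    genes_per_subcluster: int = 40,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Time course in which the gate model is driven by EMT-like regulator
    dynamics (TGF-beta ramps up by day 2.5, ZEB1 between days 5 and 12).

    The incoherent-feed-forward E2 subcluster therefore pulses: activated
    early by TGF-beta, then suppressed once ZEB1 accumulates.
    """
    gates = gates or default_gate_model()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 5]))
    gene_names, gene_cls, gene_sub = [], [], []
    for sc in gates.subclusters:
        for i in range(genes_per_subcluster):
            gene_names.append(f"{sc.name}G{i:03d}")
            gene_cls.append(sc.class_label)
            gene_sub.append(sc.name)
    p = len(gene_names)
    baseline = rng.uniform(4.0, 8.0, size=p)
    # latent-independent background keeps within-sample ranks informative
    n_bg = 2 * genes_per_subcluster
    bg_names = [f"BGG{i:03d}" for i in range(n_bg)]
    bg_baseline = rng.uniform(4.0, 8.0, size=n_bg)

    tgfb, zeb1 = _regulator_dynamics(np.asarray(times))
    cols, col_ids, meta_rows = [], [], []
    for j, t in enumerate(times):
        resp = np.array([gates.get(sub).response(tgfb[j], zeb1[j]) for sub in gene_sub])
        for r in range(replicates):
            log2_expr = np.concatenate(
                [
                    baseline + resp + rng.normal(0.0, gates.noise_sd, size=p),
                    bg_baseline + rng.normal(0.0, gates.noise_sd, size=n_bg),
                ]
            )
            cols.append(np.maximum(np.exp2(log2_expr) - 1.0, 0.0))
            col_ids.append(f"T{t:05.1f}_r{r}")
            meta_rows.append({"time_days": float(t), "tgfb": tgfb[j], "zeb1": zeb1[j]})
    all_names = gene_names + bg_names
    values = pd.DataFrame(np.column_stack(cols), index=all_names, columns=col_ids)
    meta = pd.DataFrame(meta_rows, index=col_ids)
    truth = SyntheticTruth(
        latent=pd.DataFrame(meta, index=col_ids),
        gene_class=pd.Series(
            gene_cls + ["background"] * n_bg, index=all_names, name="class"
        ),
        seed=seed,
        subcluster=pd.Series(
            gene_sub + ["background"] * n_bg, index=all_names, name="subcluster"
        ),
    )
    return ExpressionMatrix(values, meta), truth
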