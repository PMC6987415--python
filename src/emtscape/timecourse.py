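"""Triphasic models of induction time courses in E-M score space.

TGF-beta induction of EMT in epithelial cells proceeds in phases: an early
rise of the mesenchymal program, a middle plateau traversing the hybrid
high-E-high-M region, and a late collapse of the epithelial program.  Both
scores as functions of time (days) are modelled with two-breakpoint
segmented regressions initialised at 2.5 and 10 days, and compared against
one-breakpoint alternatives by adjusted R^2.  The first E-score breakpoint
is the least certain; "bound" models pin it at the endpoints of its
score-inversion confidence interval and refit everything else, bracketing
the modelled trajectory.  Mapping the modelled (E(t), M(t)) curve through a
cohort mixture model yields per-time posterior probabilities over the
semantic EMT states.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import ScoreTable
from .segmented import SegmentedFit, breakpoint_ci, fit_segmented, pseudo_score_test
from .subpopulations import MixtureModel

logger = logging.getLogger(__name__)

__all__ = ["TimecourseModel", "fit_timecourse", "bound_models", "trajectory_cluster_probs"]

DEFAULT_PSI0 = (2.5, 10.0)


@dataclass
class TimecourseModel:
    """Segmented E(t) and M(t) fits plus the model-comparison table."""

    e_fit: SegmentedFit
    m_fit: SegmentedFit
    comparison: pd.DataFrame
    bounds: dict[str, SegmentedFit] = field(default_factory=dict)

    @property
    def time_range(self) -> tuple[float, float]:
        return float(self.e_fit.x.min()), float(self.e_fit.x.max())

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return np.column_stack([self.e_fit.predict(t), self.m_fit.predict(t)])


def fit_timecourse(
    times: np.ndarray,
    scores: ScoreTable | pd.DataFrame,
    e_col: str = "E",
    m_col: str = "M",
    psi0: tuple[float, float] = DEFAULT_PSI0,
) -> TimecourseModel:
    """Fit two-breakpoint E(t) and M(t) models to an induction time course.

    All replicate points enter the regression individually (no
    pre-averaging).  The two breakpoints are initialised at ``psi0``
    (defaults 2.5 and 10 days); one-breakpoint comparison fits (initialised
    at the median time) are recorded with their adjusted R^2.
    """
    t = np.asarray(times, dtype=float)
    df = scores.scores if isinstance(scores, ScoreTable) else scores
    if len(t) != len(df):
        raise ValueError("times and scores must align")
    n_distinct = np.unique(t).size
    if n_distinct < 6:
        raise ValueError("need >= 6 distinct time points")
    lo, hi = t.min(), t.max()
    psi_init = np.clip(np.asarray(psi0, float), lo + 1e-9, hi - 1e-9)

    fits: dict[str, SegmentedFit] = {}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for name, col in (("E", e_col), ("M", m_col)):
            y = df[col].to_numpy(dtype=float)
            two = fit_segmented(t, y, psi_init)
            one = fit_segmented(t, y, [float(np.median(t))])
            seg_p = pseudo_score_test(t, y, n_breakpoints=2)
            fits[name] = two
            rows.append(
                {
                    "score": name,
                    "adj_r2_two_breaks": two.adjusted_r2,
                    "adj_r2_one_break": one.adjusted_r2,
                    "segmentation_p": seg_p,
                    "two_breaks_supported": bool(
                        two.n_breakpoints == 2
                        and two.adjusted_r2 > one.adjusted_r2
                        and seg_p < 0.05
                    ),
                }
            )
    comparison = pd.DataFrame(rows).set_index("score")
    return TimecourseModel(e_fit=fits["E"], m_fit=fits["M"], comparison=comparison)


def bound_models(
    model: TimecourseModel, level: float = 0.95
) -> dict[str, SegmentedFit]:
    """Lower/upper variants of the E(t) fit with the first breakpoint pinned.

    The first E breakpoint's score-inversion confidence interval endpoints
    are used as fixed breakpoints; the remaining breakpoint and slopes are
    re-estimated.  Endpoints outside the sampled time range are clamped with
    a warning.  Results are stored on ``model.bounds`` and returned.
    """
    e_fit = model.e_fit
    if e_fit.n_breakpoints == 0:
        raise ValueError("E fit has no breakpoints to bound")
    if e_fit.breakpoint_cis is None:
        breakpoint_ci(e_fit, level=level)
    ci_lo, ci_hi, _ = e_fit.breakpoint_cis[0]
    t = e_fit.x
    lo, hi = float(t.min()), float(t.max())
    out: dict[str, SegmentedFit] = {}
    remaining = e_fit.breakpoints[1:]
    for name, endpoint in (("lower", ci_lo), ("upper", ci_hi)):
        pinned = endpoint
        if not (lo <= pinned <= hi):
            pinned = float(np.clip(pinned, lo, hi))
            warnings.warn(
                f"CI endpoint {endpoint:.3g} outside time range; clamped to {pinned:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
        # a pinned breakpoint exactly at the boundary adds no hinge support;
        # nudge inside by a hair so the design stays well posed
        pinned = float(np.clip(pinned, lo + 1e-9, hi - 1e-9))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if remaining.size:
                refit = fit_segmented(t, e_fit.y, psi0=remaining, fixed_psi=[pinned])
            else:
                refit = fit_segmented(t, e_fit.y, psi0=[], fixed_psi=[pinned])
        out[name] = refit
    model.bounds = out
    return out


def trajectory_cluster_probs(
    model: TimecourseModel,
    gmm: MixtureModel,
    times_grid: np.ndarray,
    allow_extrapolation: bool = False,
) -> pd.DataFrame:
    """Posterior probability of each EMT state along the modelled trajectory.

    Evaluates (E(t), M(t)) on ``times_grid`` and returns the cohort mixture
    model's posterior over components, with columns renamed to semantic
    labels when available.  Rows sum to 1.
    """
    if gmm.d != 2:
        raise ValueError("mixture model must be 2-D over (E, M)")
    t = np.asarray(times_grid, dtype=float)
    lo, hi = model.time_range
    if not allow_extrapolation and ((t < lo) | (t > hi)).any():
        raise ValueError(
            f"times outside the fitted range [{lo:g}, {hi:g}]; "
            "pass allow_extrapolation=True to evaluate anyway"
        )
    points = model.predict(t)
    post = gmm.posterior(points)
    if gmm.semantic is not None:
        cols = [gmm.semantic[k] for k in range(gmm.K)]
    else:
        cols = [f"component_{k}" for k in range(gmm.K)]
    return pd.DataFrame(post, index=pd.Index(t, name="time_days"), columns=cols)
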