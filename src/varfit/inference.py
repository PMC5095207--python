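"""Model validation, selection and maximum-likelihood estimation.

Given a polynomial steady-state model and a noisy observation of its
outputs, the goodness-of-fit statistic is the global minimum d² of the
weighted squared distance between the model variety and the data variety.
Under the null (data generated by the model with Gaussian errors of known
variance) the distribution of the weighted d² is dominated by a chi-squared
with m degrees of freedom, m the number of observed outputs, so comparing
d² to the upper-α quantile gives a conservative compatibility test.
Selection ranks compatible candidate models by d² (optionally with an
AIC-style penalty), and estimation returns the minimizing (â, x̂, ẑ) — the
maximum-likelihood parameter / hidden-state / de-noised-output estimates.

Reporting convention: when all observed error variances are equal (σ²
common), d² is reported as the plain squared distance and the threshold as
p_α = σ²·χ²_{m,α} — the two scalings a reader sees in worked examples;
with heterogeneous variances d² is the weighted statistic Σ(zᵢ-yᵢ)²/σᵢ²
and p_α the raw quantile.  The accept/reject decision is identical either
way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .geometry import (
    CodimensionError,
    DistanceResult,
    IntersectionResult,
    build_joint_critical_system,
    intersect_varieties,
    min_distance,
    _real_critical_candidates,
    _point_estimates,
)
from .polysys import DataPoint, ModelSpec, bind_known
from .tracker import TrackConfig, total_degree_solve

__all__ = [
    "FitReport",
    "SelectionReport",
    "chi2_threshold",
    "validate",
    "select",
    "estimate",
    "joint_distance",
]

COMPATIBLE = "compatible"
INCOMPATIBLE = "incompatible"
POSSIBLY = "possibly"

MORE_DATA_GUIDANCE = (
    "multiple models intersect the data variety; measuring more variables "
    "can reduce the dimension of the model varieties and make the data "
    "informative enough for selection"
)
NO_MODEL_MESSAGE = "no model adequately fits the data"


@dataclass
class FitReport:
    """Result of fitting one model against one data point (or several)."""

    d2: float | None
    d2_weighted: float | None
    p_alpha: float | None
    alpha: float | None
    decision: str
    estimates: list[dict]
    intersection: IntersectionResult | None
    dof: int
    sigma_ref2: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def exact_fit(self) -> bool:
        return self.d2 is not None and self.d2 == 0.0


@dataclass
class SelectionReport:
    reports: dict[str, FitReport]
    ranking: list[str]
    selected: str | None
    indeterminate: bool
    message: str | None = None


def chi2_threshold(m: int, alpha: float, sigma2: float = 1.0) -> float:
    """Rescaled upper-α quantile of χ² with m degrees of freedom.

    Returns ``sigma2 × χ²_{m, α}``; with a common error variance σ² this is
    the threshold against which the plain squared distance is compared.
    """
    if m < 1:
        raise ValueError("degrees of freedom m must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie strictly between 0 and 1, got {alpha}")
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    return float(sigma2 * stats.chi2.isf(alpha, df=m))


# ---------------------------------------------------------------------------
# Algorithm 1: validation
# ---------------------------------------------------------------------------

def _intersection_estimates(model: ModelSpec, inter: IntersectionResult) -> list[dict]:
    """Exact-fit estimates (â, x̂, ẑ) from real intersection points."""
    bound = bind_known(model)
    from ._batcheval import BatchEvaluator

    gev = BatchEvaluator(bound.g)
    out = []
    for p in inter.real_points:
        z = np.real(gev.values(np.asarray(p, dtype=complex)[None, :])[0])
        na = len(bound.params)
        out.append(
            {
                "params": dict(zip(bound.params, np.real(p[:na]).tolist())),
                "states": dict(zip(bound.states, np.real(p[na:]).tolist())),
                "outputs": dict(zip(bound.outputs, z.tolist())),
            }
        )
    return out


def validate(
    model: ModelSpec,
    data: DataPoint,
    alpha: float = 0.1,
    nonneg: bool = False,
    config: TrackConfig | None = None,
) -> FitReport:
    """Chi-squared model validation against one data point.

    Follows the validation algorithm: if the model and data varieties
    intersect in a real point the model is compatible with d² = 0; a
    positive-dimensional intersection yields the guarded answer
    ``possibly`` (real points on positive-dimensional components are not
    certified here); otherwise the global minimum d² is computed and
    compared to p_α with m = number of observed outputs.
    """
    config = config or TrackConfig()
    m_obs = data.n_observed
    sigma_ref2 = data.common_variance() or 1.0
    p_alpha = chi2_threshold(m_obs, alpha, sigma_ref2)
    inter = intersect_varieties(model, data, config)

    diagnostics = {
        "seed": config.seed,
        "intersection_kind": inter.kind,
        "intersection_dimension": inter.dimension,
        "ambient_dim": inter.ambient_dim,
        "dim_data": inter.dim_data,
        "nonneg": nonneg,
    }

    if inter.kind == "positive_dimensional":
        # heuristic branch: witness points exist but real membership of the
        # positive-dimensional component is not certified
        return FitReport(
            d2=0.0,
            d2_weighted=0.0,
            p_alpha=p_alpha,
            alpha=alpha,
            decision=POSSIBLY,
            estimates=[],
            intersection=inter,
            dof=m_obs,
            sigma_ref2=sigma_ref2,
            diagnostics=diagnostics,
        )

    real_inter = inter.real_points
    if nonneg:
        real_inter = [p for p in real_inter if np.all(np.real(p) >= -1e-7)]
    if inter.kind == "zero_dimensional" and real_inter:
        inter_f = IntersectionResult(**{**inter.__dict__, "real_points": real_inter})
        return FitReport(
            d2=0.0,
            d2_weighted=0.0,
            p_alpha=p_alpha,
            alpha=alpha,
            decision=COMPATIBLE,
            estimates=_intersection_estimates(model, inter_f),
            intersection=inter_f,
            dof=m_obs,
            sigma_ref2=sigma_ref2,
            diagnostics=diagnostics,
        )

    # empty (or real-point-free) intersection: minimize the distance
    dist = min_distance(model, data, config, nonneg=nonneg)
    diagnostics["n_real_criticals"] = dist.n_real_criticals
    diagnostics["path_accounting"] = _accounting(dist)
    if dist.possibly_degenerate and dist.d2 is None:
        decision = POSSIBLY
    elif dist.d2 is None:
        decision = POSSIBLY
        diagnostics["warning"] = dist.warning
    else:
        decision = (
            COMPATIBLE if dist.d2_weighted <= chi2_threshold(m_obs, alpha, 1.0)
            else INCOMPATIBLE
        )
    if dist.possibly_degenerate:
        diagnostics["possibly_degenerate"] = True
    return FitReport(
        d2=dist.d2,
        d2_weighted=dist.d2_weighted,
        p_alpha=p_alpha,
        alpha=alpha,
        decision=decision,
        estimates=dist.argmins,
        intersection=inter,
        dof=m_obs,
        sigma_ref2=sigma_ref2,
        diagnostics=diagnostics,
    )


def _accounting(dist: DistanceResult) -> dict:
    s = dist.solutions
    if s is None:
        return {}
    return {
        "paths": s.n_paths,
        "converged": s.n_converged_paths,
        "diverged": s.n_diverged,
        "failed": s.n_failed,
    }


# ---------------------------------------------------------------------------
# Algorithm 2: selection
# ---------------------------------------------------------------------------

def select(
    models: dict[str, ModelSpec] | Sequence[ModelSpec],
    data: DataPoint | Sequence[DataPoint],
    alpha: float | None = 0.1,
    penalty: str | None = None,
    nonneg: bool = False,
    config: TrackConfig | None = None,
) -> SelectionReport:
    """Choose among competing models by minimal (optionally penalized) d².

    With a significance level α, models rejected at that level are excluded
    first; with ``alpha=None`` the rejection step is skipped and all models
    are ranked by fit alone.  If two or more surviving models intersect the
    data variety exactly (d² = 0) the data cannot discriminate and the
    report is flagged indeterminate.  ``penalty='aic'`` ranks by
    d² + 2·(#free parameters).  Ties break toward fewer free parameters,
    then declared order.
    """
    if not isinstance(models, dict):
        models = {f"M{i + 1}": m for i, m in enumerate(models)}
    if len(models) < 2:
        raise ValueError("selection needs at least two candidate models")
    config = config or TrackConfig()
    alpha_eff = alpha if alpha is not None else 0.05

    def _fit(m: ModelSpec) -> FitReport:
        if isinstance(data, DataPoint):
            return validate(m, data, alpha_eff, nonneg, config)
        return joint_distance(
            m, list(data), nonneg=nonneg, config=config, alpha=alpha_eff
        )

    reports = {name: _fit(m) for name, m in models.items()}

    exact = [n for n, r in reports.items() if r.decision in (COMPATIBLE, POSSIBLY) and
             (r.exact_fit or r.decision == POSSIBLY)]
    if len(exact) >= 2:
        return SelectionReport(
            reports=reports,
            ranking=[],
            selected=None,
            indeterminate=True,
            message=MORE_DATA_GUIDANCE,
        )

    order = {n: i for i, n in enumerate(models)}

    def _score(name: str) -> tuple:
        r = reports[name]
        pen = 2.0 * len(models[name].free_params) if penalty == "aic" else 0.0
        d2w = r.d2_weighted if r.d2_weighted is not None else np.inf
        return (d2w + pen, len(models[name].free_params), order[name])

    if alpha is None:
        surviving = list(reports)
    else:
        surviving = [n for n, r in reports.items() if r.decision != INCOMPATIBLE]
    ranking = sorted(surviving, key=_score)
    if not ranking:
        return SelectionReport(
            reports=reports,
            ranking=[],
            selected=None,
            indeterminate=False,
            message=NO_MODEL_MESSAGE,
        )
    return SelectionReport(
        reports=reports,
        ranking=ranking,
        selected=ranking[0],
        indeterminate=False,
    )


# ---------------------------------------------------------------------------
# Algorithm 3: estimation
# ---------------------------------------------------------------------------

def estimate(
    model: ModelSpec,
    data: DataPoint | Sequence[DataPoint],
    nonneg: bool = False,
    config: TrackConfig | None = None,
) -> FitReport:
    """Maximum-likelihood estimation of parameters and hidden variables.

    As validation but without an α decision: returns every global argmin
    (â, x̂, ẑ) together with d².  A nonempty real intersection yields
    exact-fit estimates (possibly several); a positive-dimensional
    intersection means the model is non-identifiable from this data and is
    flagged as such.
    """
    config = config or TrackConfig()
    if not isinstance(data, DataPoint):
        data = list(data)
        if len(data) == 1:
            data = data[0]
    if isinstance(data, list):
        return joint_distance(model, data, nonneg=nonneg, config=config)

    bound = bind_known(model)
    if not bound.params and bound.n_states == 0:
        raise ValueError("estimation needs at least one unknown parameter or state")

    inter = intersect_varieties(model, data, config)
    sigma_ref2 = data.common_variance() or 1.0
    diagnostics = {"seed": config.seed, "intersection_kind": inter.kind}
    if inter.kind == "positive_dimensional":
        diagnostics["non_identifiable"] = True
        return FitReport(
            d2=0.0,
            d2_weighted=0.0,
            p_alpha=None,
            alpha=None,
            decision=POSSIBLY,
            estimates=[],
            intersection=inter,
            dof=data.n_observed,
            sigma_ref2=sigma_ref2,
            diagnostics=diagnostics,
        )
    real_inter = inter.real_points
    if nonneg:
        real_inter = [p for p in real_inter if np.all(np.real(p) >= -1e-7)]
    if inter.kind == "zero_dimensional" and real_inter:
        inter_f = IntersectionResult(**{**inter.__dict__, "real_points": real_inter})
        return FitReport(
            d2=0.0,
            d2_weighted=0.0,
            p_alpha=None,
            alpha=None,
            decision=COMPATIBLE,
            estimates=_intersection_estimates(model, inter_f),
            intersection=inter_f,
            dof=data.n_observed,
            sigma_ref2=sigma_ref2,
            diagnostics=diagnostics,
        )
    dist = min_distance(model, data, config, nonneg=nonneg)
    diagnostics["n_real_criticals"] = dist.n_real_criticals
    diagnostics["path_accounting"] = _accounting(dist)
    if dist.possibly_degenerate:
        diagnostics["non_identifiable"] = True
    decision = COMPATIBLE if dist.d2 is not None else POSSIBLY
    return FitReport(
        d2=dist.d2,
        d2_weighted=dist.d2_weighted,
        p_alpha=None,
        alpha=None,
        decision=decision,
        estimates=dist.argmins,
        intersection=inter,
        dof=data.n_observed,
        sigma_ref2=sigma_ref2,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# joint distance over multiple data points
# ---------------------------------------------------------------------------

def joint_distance(
    model: ModelSpec,
    data_points: Sequence[DataPoint],
    nonneg: bool = False,
    config: TrackConfig | None = None,
    alpha: float | None = None,
) -> FitReport:
    """Joint weighted squared distance to several data points at once.

    One critical system with shared parameters ``a`` and per-point hidden
    states/outputs; the statistic sums the per-point distances and the
    chi-squared threshold uses ``Σ_j m_j`` degrees of freedom.
    """
    data_points = list(data_points)
    if len(data_points) < 2:
        raise ValueError("joint distance needs at least two data points")
    config = config or TrackConfig()
    cs = build_joint_critical_system(model, data_points, seed=config.seed)
    sols = total_degree_solve(cs.system, config)
    cands, degenerate = _real_critical_candidates(cs, sols, config)
    if nonneg:
        na, nx = len(cs.avars), len(cs.xvars)
        cands = [(p, v) for (p, v) in cands if np.all(np.real(p[: na + nx]) >= -1e-7)]

    dof = sum(dp.n_observed for dp in data_points)
    all_s2 = [dp.variances[i] for dp in data_points for i in dp.observed]
    sigma_ref2 = all_s2[0] if all(s == all_s2[0] for s in all_s2) else 1.0
    p_alpha = chi2_threshold(dof, alpha, sigma_ref2) if alpha is not None else None

    diagnostics = {
        "seed": config.seed,
        "n_points": len(data_points),
        "path_accounting": {
            "paths": sols.n_paths,
            "converged": sols.n_converged_paths,
            "diverged": sols.n_diverged,
            "failed": sols.n_failed,
        },
    }
    if not cands:
        return FitReport(
            d2=None, d2_weighted=None, p_alpha=p_alpha, alpha=alpha,
            decision=POSSIBLY, estimates=[], intersection=None, dof=dof,
            sigma_ref2=sigma_ref2, diagnostics={**diagnostics, "warning": "no real critical point"},
        )
    vals = np.array([v for _, v in cands])
    vmin = float(vals.min())
    att = [cands[i][0] for i in np.nonzero(vals <= vmin + 1e-8 * (1 + vmin))[0]]
    decision = COMPATIBLE
    if alpha is not None:
        decision = (
            COMPATIBLE if vmin <= chi2_threshold(dof, alpha, 1.0) else INCOMPATIBLE
        )
    if degenerate:
        diagnostics["possibly_degenerate"] = True
    return FitReport(
        d2=vmin * sigma_ref2,
        d2_weighted=vmin,
        p_alpha=p_alpha,
        alpha=alpha,
        decision=decision,
        estimates=[_point_estimates(cs, p) for p in att],
        intersection=None,
        dof=dof,
        sigma_ref2=sigma_ref2,
        diagnostics=diagnostics,
    )
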