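"""Profile likelihoods, likelihood-based confidence intervals, identifiability.

For each free parameter theta_i the profile likelihood

    chi2_PL(theta_i) = min over theta_{j != i} of chi2(theta)

is traced by scanning theta_i outward from the estimate in both directions
with adaptive steps, re-optimizing all remaining parameters at every grid
point (warm-started from the neighboring point).  The likelihood-based
confidence interval at level 1 - alpha is the set of theta_i whose profile
stays within Delta_alpha = Q(chi2_df, 1 - alpha) of the global minimum
(df = 1 for point-wise intervals).

Classification follows the shape of the profile:

* both threshold crossings found             -> identifiable (finite CI);
* a minimum but a missing crossing on one or
  both sides                                 -> practically non-identifiable
  (infinite bound on that side; more or better data can resolve it);
* a flat profile with no minimum at all      -> structurally non-identifiable
  (exact parameter compensation; more data of the same kind cannot help).

The design-level score is the mean CI width across parameters (A-optimality);
it is infinite as soon as any single parameter is non-identifiable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .estimate import (
    CHI2_CAP,
    DCMProblem,
    FitResult,
    ResidualProblem,
    fit,
    fit_problem,
    perturb_start,
)
from .model import DCMModel, DesignSpec, ParameterVector
from .simulate import SimulatedDataset, simulate_dataset

__all__ = [
    "CIStatus",
    "ProfileCurve",
    "ConfidenceInterval",
    "ProfileSettings",
    "IdentifiabilityReport",
    "chi2_threshold",
    "profile_curve",
    "profile_parameter",
    "extract_ci",
    "mean_ci",
    "assess_model",
]


class CIStatus(str, enum.Enum):
    IDENTIFIABLE = "identifiable"
    PRACTICAL_LOWER = "practically-non-identifiable-lower"
    PRACTICAL_UPPER = "practically-non-identifiable-upper"
    PRACTICAL_BOTH = "practically-non-identifiable-both"
    STRUCTURAL = "structurally-non-identifiable"
    UNDETERMINED = "undetermined"


@dataclass
class ProfileCurve:
    """Scanned profile of one parameter around the estimate."""

    param_index: int
    theta_grid: np.ndarray
    chi2_pl: np.ndarray
    chi2_hat: float
    capped: np.ndarray          # True where the point hit the divergence cap
    center_index: int = 0       # position of theta_hat_i in the grid


@dataclass
class ConfidenceInterval:
    lower: float
    upper: float
    alpha: float
    status: CIStatus
    contains_zero: bool

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class ProfileSettings:
    """Tunables of the profile scan.

    The initial step is ``max(step_floor, step_frac * |theta_hat_i|)``; it
    grows by ``growth`` whenever a step raised chi2 by less than
    ``slow_frac * Delta_alpha``.  A step that raised chi2 by more than
    ``fast_frac * Delta_alpha`` is rejected and retried at half size (down to
    ``min_step_frac`` of the initial step), so the grid near the threshold
    crossing stays fine enough for accurate interpolation.  Each direction
    stops after the profile exceeds the threshold by
    ``overshoot_frac * Delta_alpha`` (so the crossing is bracketed), after
    ``max_steps`` accepted points, or at the divergence cap.
    """

    alpha: float = 0.05
    df: int = 1
    max_steps: int = 100
    step_floor: float = 0.01
    step_frac: float = 0.05
    growth: float = 1.5
    shrink: float = 0.5
    slow_frac: float = 0.1
    fast_frac: float = 1.0 / 3.0
    min_step_frac: float = 1e-3
    overshoot_frac: float = 0.5
    flatness_frac: float = 0.01
    inner_gtol: float = 1e-8
    inner_xtol: float = 1e-10
    inner_max_nfev: int = 1000
    fit_restarts: int = 5
    start_perturbation: float = 0.1


def chi2_threshold(alpha: float, df: int) -> float:
    """Threshold Delta_alpha: the (1 - alpha) quantile of chi2 with ``df`` dof.

    With alpha = 0.05 and df = 1 this is the conventional 3.841 used for
    point-wise 95% likelihood-ratio confidence intervals.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


class _FixedParamProblem:
    """View of a problem with parameter ``i`` clamped to a fixed value."""

    def __init__(self, problem: ResidualProblem, i: int, value: float):
        self._problem = problem
        self._i = i
        self._value = value
        self.n_params = problem.n_params - 1

    def residuals(self, x: np.ndarray) -> np.ndarray:
        full = np.insert(np.asarray(x, dtype=float), self._i, self._value)
        return self._problem.residuals(full)


def _reoptimize(
    problem: ResidualProblem,
    i: int,
    value: float,
    warm: np.ndarray,
    settings: ProfileSettings,
) -> tuple[float, np.ndarray, bool]:
    """Min chi2 over all parameters but ``i``; returns (chi2, argmin, ok)."""
    if problem.n_params == 1:
        r = problem.residuals(np.array([value]))
        return float(r @ r), np.empty(0), True
    sub = _FixedParamProblem(problem, i, value)
    try:
        res = fit_problem(
            sub,
            warm,
            gtol=settings.inner_gtol,
            xtol=settings.inner_xtol,
            max_nfev=settings.inner_max_nfev,
        )
    except Exception:
        return CHI2_CAP, warm, False
    return res.chi2_min, np.asarray(res.theta_hat), True


def profile_curve(
    problem: ResidualProblem,
    theta_hat: np.ndarray,
    chi2_hat: float,
    i: int,
    settings: ProfileSettings | None = None,
) -> ProfileCurve:
    """Adaptive bidirectional profile scan of parameter ``i`` (generic core)."""
    settings = settings or ProfileSettings()
    delta = chi2_threshold(settings.alpha, settings.df)
    stop_excess = delta * (1.0 + settings.overshoot_frac)
    theta_hat = np.asarray(theta_hat, dtype=float)
    center = float(theta_hat[i])
    step0 = max(settings.step_floor, settings.step_frac * abs(center))
    warm0 = np.delete(theta_hat, i)

    min_step = step0 * settings.min_step_frac
    sides: dict[int, list[tuple[float, float, bool]]] = {}
    for direction in (1, -1):
        points: list[tuple[float, float, bool]] = []
        value, step, warm, prev = center, step0, warm0.copy(), chi2_hat
        evals_left = 4 * settings.max_steps
        while len(points) < settings.max_steps and evals_left > 0:
            candidate = value + direction * step
            chi2, argmin, ok = _reoptimize(problem, i, candidate, warm, settings)
            evals_left -= 1
            capped = (not ok) or chi2 >= CHI2_CAP / 2 or not math.isfinite(chi2)
            rise = (CHI2_CAP if capped else chi2) - prev
            if rise > delta * settings.fast_frac and step > min_step:
                step = max(step * settings.shrink, min_step)
                continue  # reject the step: resolve the crossing region finer
            if capped:
                chi2 = CHI2_CAP
                warm = warm0.copy()   # fall back to the global estimate
            else:
                warm = argmin
            value = candidate
            points.append((value, chi2, capped))
            if chi2 - chi2_hat > stop_excess:
                break
            if rise < delta * settings.slow_frac:
                step *= settings.growth
            prev = chi2
        sides[direction] = points

    left = sides[-1][::-1]
    right = sides[1]
    grid = [p[0] for p in left] + [center] + [p[0] for p in right]
    vals = [p[1] for p in left] + [chi2_hat] + [p[1] for p in right]
    caps = [p[2] for p in left] + [False] + [p[2] for p in right]
    return ProfileCurve(
        param_index=i,
        theta_grid=np.array(grid),
        chi2_pl=np.array(vals),
        chi2_hat=chi2_hat,
        capped=np.array(caps, dtype=bool),
        center_index=len(left),
    )


def profile_parameter(
    i: int,
    fit_result: FitResult,
    model: DCMModel,
    data: SimulatedDataset,
    settings: ProfileSettings | None = None,
) -> ProfileCurve:
    """Profile likelihood of one model parameter given a converged fit."""
    if not fit_result.converged:
        raise ValueError("profiling requires a converged fit")
    problem = DCMProblem.from_dataset(model, data)
    return profile_curve(problem, fit_result.x, fit_result.chi2_min, i, settings)


def extract_ci(
    curve: ProfileCurve,
    delta: float,
    flatness_frac: float = 0.01,
    alpha: float = 0.05,
) -> ConfidenceInterval:
    """Locate the threshold crossings of a profile and classify the parameter.

    Bounds come from linear interpolation between the grid points bracketing
    the crossing of ``chi2_hat + delta``.  Divergence-capped points are not
    genuine crossings: the profile "suddenly jumps" there because the
    trajectory explodes, not because the data exclude the value with the
    stated confidence, so a side whose only exceedance is capped keeps an
    infinite bound.  A side with no crossing has an infinite bound; if
    neither side crosses and the total chi2 variation over the whole scanned
    (non-capped) range stays below ``flatness_frac * delta``, the profile is
    flat and the parameter is structurally non-identifiable.
    """
    if len(curve.theta_grid) == 0:
        raise ValueError("profile curve is empty")
    level = curve.chi2_hat + delta
    grid, vals, capped = curve.theta_grid, curve.chi2_pl, curve.capped
    c = min(curve.center_index, len(grid) - 1)

    def cross(indices) -> float | None:
        prev = c
        for j in indices:
            if capped[j]:
                continue
            if vals[j] > level:
                y0, y1 = vals[prev], vals[j]
                if y1 == y0:
                    return float(grid[j])
                t = (level - y0) / (y1 - y0)
                return float(grid[prev] + t * (grid[j] - grid[prev]))
            prev = j
        return None

    upper = cross(range(c + 1, len(grid)))
    lower = cross(range(c - 1, -1, -1))

    if upper is None and lower is None:
        finite_vals = vals[~capped]
        variation = float(finite_vals.max() - finite_vals.min())
        if variation < flatness_frac * delta:
            status = CIStatus.STRUCTURAL
        else:
            status = CIStatus.PRACTICAL_BOTH
        lo, hi = -np.inf, np.inf
    elif lower is None:
        status, lo, hi = CIStatus.PRACTICAL_LOWER, -np.inf, upper
    elif upper is None:
        status, lo, hi = CIStatus.PRACTICAL_UPPER, lower, np.inf
    else:
        status, lo, hi = CIStatus.IDENTIFIABLE, lower, upper
    return ConfidenceInterval(
        lower=lo,
        upper=hi,
        alpha=alpha,
        status=status,
        contains_zero=bool(lo <= 0.0 <= hi),
    )


def mean_ci(cis: list[ConfidenceInterval]) -> float:
    """Mean CI width (A-optimality); infinite if any bound is infinite."""
    if not cis:
        raise ValueError("mean CI of an empty parameter set is undefined")
    widths = [ci.width for ci in cis]
    if any(not math.isfinite(w) for w in widths):
        return math.inf
    return float(np.mean(widths))


@dataclass
class IdentifiabilityReport:
    """Everything the assessment of one model under one design produced."""

    fit: FitResult
    curves: list[ProfileCurve]
    cis: list[ConfidenceInterval]
    mci: float
    design: DesignSpec
    snr: float
    seed: int | None
    labels: list[str] = field(default_factory=list)
    true_values: np.ndarray | None = None
    alpha: float = 0.05
    diagnostic: str | None = None

    @property
    def n_identifiable(self) -> int:
        return sum(ci.status == CIStatus.IDENTIFIABLE for ci in self.cis)

    def statuses(self) -> list[str]:
        return [ci.status.value for ci in self.cis]


def _profile_all(problem, fit_result, n, settings, n_jobs):
    def one(i):
        return profile_curve(problem, fit_result.x, fit_result.chi2_min, i, settings)

    if n_jobs and n_jobs != 1:
        from joblib import Parallel, delayed

        return list(Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(n)))
    return [one(i) for i in range(n)]


def assess_model(
    model: DCMModel,
    params: ParameterVector | np.ndarray,
    design: DesignSpec,
    snr: float,
    seed: int | None,
    settings: ProfileSettings | None = None,
    n_jobs: int = 1,
) -> IdentifiabilityReport:
    """End-to-end assessment: simulate, fit, profile every parameter.

    Reproducible under ``seed``: the same seed yields bit-identical data,
    start values, and (profiles carry no randomness) an identical report.
    Profiles of distinct parameters are independent and may run in parallel
    without changing the result.
    """
    settings = settings or ProfileSettings()
    if not isinstance(params, ParameterVector):
        params = ParameterVector(params, model.index_map())
    data = simulate_dataset(model, design, snr, seed, params)
    start_seed = None if seed is None else (seed + 10007) % (2**31)
    start = perturb_start(params, settings.start_perturbation, start_seed)
    fit_result = fit(
        model, data, start, restarts=settings.fit_restarts, seed=start_seed
    )
    labels = model.parameter_labels()
    if not fit_result.converged:
        n = model.n_free
        cis = [
            ConfidenceInterval(-np.inf, np.inf, settings.alpha,
                               CIStatus.UNDETERMINED, True)
            for _ in range(n)
        ]
        return IdentifiabilityReport(
            fit=fit_result, curves=[], cis=cis, mci=math.inf, design=design,
            snr=snr, seed=seed, labels=labels, true_values=params.values.copy(),
            alpha=settings.alpha,
            diagnostic="fit did not converge after restarts: " + fit_result.message,
        )
    problem = DCMProblem.from_dataset(model, data)
    curves = _profile_all(problem, fit_result, model.n_free, settings, n_jobs)
    delta = chi2_threshold(settings.alpha, settings.df)
    cis = [
        extract_ci(cv, delta, settings.flatness_frac, settings.alpha)
        for cv in curves
    ]
    return IdentifiabilityReport(
        fit=fit_result,
        curves=curves,
        cis=cis,
        mci=mean_ci(cis),
        design=design,
        snr=snr,
        seed=seed,
        labels=labels,
        true_values=params.values.copy(),
        alpha=settings.alpha,
    )
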