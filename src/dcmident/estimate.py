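"""Weighted least-squares / maximum-likelihood estimation of model parameters.

The objective is the weighted sum of squared residuals

    chi2(theta) = sum_i sum_k (Y_i(t_k) - Yhat_i(t_k, theta))^2 / sigma_i^2,

which for Gaussian measurement noise with known per-region SDs equals
``const - 2 log L(theta)``, so its minimizer is the maximum-likelihood
estimate.  Note the squared sigma in the denominator: it is forced by the
Gaussian likelihood (exponent ``(Y - Yhat)^2 / sigma^2``) and by the
``chi2 = const - 2 log L`` identity.

Minimization uses Levenberg-Marquardt on the weighted residual vector with
forward finite-difference Jacobians.  Parameter regimes where the trajectory
diverges return a capped objective; if the optimizer lands there, the fit is
restarted with sign-flipped off-diagonal A entries (self-connections keep
their sign — they are the inhibitory terms that prevent run-away excitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy.optimize import least_squares

from .hrf import HRFKernel, canonical_hrf
from .model import (
    DCMModel,
    DesignSpec,
    ParameterVector,
    compile_design,
    integrate_compiled,
    observe_compiled,
)
from .simulate import SimulatedDataset

__all__ = [
    "CHI2_CAP",
    "FitResult",
    "ResidualProblem",
    "DCMProblem",
    "chi_squared",
    "fit",
    "fit_problem",
    "perturb_start",
]

#: chi-squared value reported for divergent parameter regimes.
CHI2_CAP = 1e12


class ResidualProblem(Protocol):
    """Anything exposing a weighted residual vector of a parameter vector."""

    n_params: int

    def residuals(self, theta: np.ndarray) -> np.ndarray: ...


@dataclass
class FitResult:
    theta_hat: ParameterVector | np.ndarray
    chi2_min: float
    n_restarts: int = 0
    converged: bool = False
    diverged_during_fit: bool = False
    message: str = ""
    trace: list = field(default_factory=list)

    @property
    def x(self) -> np.ndarray:
        return (
            self.theta_hat.values
            if isinstance(self.theta_hat, ParameterVector)
            else self.theta_hat
        )


class DCMProblem:
    """Weighted-residual problem tying a model structure to observed data.

    Precompiles the constant-input segment structure of the design and the
    HRF kernel so that repeated objective evaluations only integrate and
    convolve.
    """

    def __init__(
        self,
        model: DCMModel,
        design: DesignSpec,
        y_obs: np.ndarray,
        sigma: np.ndarray,
        kernel: HRFKernel | None = None,
        sample_offset: int = 0,
    ):
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("all per-region noise SDs must be positive")
        self.model = model
        self.design = design
        self.y_obs = np.asarray(y_obs, dtype=float)
        self.sigma = sigma
        self.kernel = kernel or canonical_hrf(design.microtime_step)
        self.sample_offset = sample_offset
        self._compiled = compile_design(design)
        self._weights = 1.0 / sigma[:, None]
        self.n_params = model.n_free
        self._n_res = self.y_obs.size
        self._cap_residuals = np.full(self._n_res, np.sqrt(CHI2_CAP / self._n_res))

    @classmethod
    def from_dataset(
        cls, model: DCMModel, data: SimulatedDataset, **kw
    ) -> "DCMProblem":
        return cls(model, data.design, data.y_obs, data.sigma, **kw)

    def predict(self, theta: np.ndarray) -> np.ndarray | None:
        """Model BOLD for theta, or None on divergence."""
        A, B, C = self.model.unpack(theta)
        traj = integrate_compiled(A, B, C, self._compiled, np.zeros(A.shape[0]))
        if traj.diverged:
            return None
        return observe_compiled(
            traj.z,
            self.kernel.values,
            self._compiled.ts,
            self.design.n_slices,
            self.design.n_volumes,
            self.sample_offset,
        )

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)):
            raise ValueError("parameter vector must be finite")
        y_model = self.predict(theta)
        if y_model is None:
            return self._cap_residuals
        return ((self.y_obs - y_model) * self._weights).ravel()

    def chi2(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)


def chi_squared(
    params: ParameterVector | np.ndarray,
    model: DCMModel,
    data: SimulatedDataset,
    **kw,
) -> float:
    """Weighted sum of squared residuals; ``CHI2_CAP`` on divergence."""
    problem = DCMProblem.from_dataset(model, data, **kw)
    theta = params.values if isinstance(params, ParameterVector) else params
    return problem.chi2(theta)


def fit_problem(
    problem: ResidualProblem,
    x0: np.ndarray,
    gtol: float = 1e-8,
    xtol: float = 1e-10,
    max_nfev: int | None = None,
    diff_step: float = 1e-6,
) -> FitResult:
    """One Levenberg-Marquardt run on a generic weighted-residual problem."""
    res = least_squares(
        problem.residuals,
        np.asarray(x0, dtype=float),
        method="lm",
        gtol=gtol,
        xtol=xtol,
        diff_step=diff_step,
        max_nfev=max_nfev,
    )
    chi2 = float(2.0 * res.cost)
    return FitResult(
        theta_hat=res.x,
        chi2_min=chi2,
        converged=bool(res.status > 0 and chi2 < CHI2_CAP / 2),
        diverged_during_fit=bool(chi2 >= CHI2_CAP / 2),
        message=res.message,
    )


def _offdiagonal_a_positions(index_map) -> np.ndarray:
    return np.array(
        [
            j
            for j, entry in enumerate(index_map)
            if entry[0] == "A" and entry[1] != entry[2]
        ],
        dtype=int,
    )


def fit(
    model: DCMModel,
    data: SimulatedDataset,
    start: ParameterVector | np.ndarray,
    gtol: float = 1e-8,
    xtol: float = 1e-10,
    max_iter: int = 500,
    restarts: int = 5,
    seed: int | None = 0,
    kernel: HRFKernel | None = None,
) -> FitResult:
    """Estimate all free parameters of ``model`` from a dataset.

    On divergence the fit is retried (up to ``restarts`` times) with
    sign-flipped off-diagonal A entries: the first retry flips all of them, later
    ones a random subset.  Exhausting the budget yields ``converged=False``,
    never an exception.
    """
    index_map = model.index_map()
    x0 = np.asarray(
        start.values if isinstance(start, ParameterVector) else start,
        dtype=float,
    ).copy()
    if x0.shape != (model.n_free,):
        raise ValueError(f"start vector must have length {model.n_free}")
    problem = DCMProblem.from_dataset(model, data, kernel=kernel)
    max_nfev = max_iter * (model.n_free + 1)
    rng = np.random.default_rng(seed)
    off = _offdiagonal_a_positions(index_map)
    result = None
    for attempt in range(restarts + 1):
        result = fit_problem(problem, x0, gtol=gtol, xtol=xtol, max_nfev=max_nfev)
        result.n_restarts = attempt
        if not result.diverged_during_fit:
            break
        if len(off) == 0:
            break
        flip = off if attempt == 0 else off[rng.random(len(off)) < 0.5]
        x0 = x0.copy()
        x0[flip] = -x0[flip]
    result.theta_hat = ParameterVector(np.asarray(result.theta_hat), index_map)
    if result.diverged_during_fit:
        result.converged = False
        result.message += " (restart budget exhausted in a divergent regime)"
    return result


def perturb_start(
    params: ParameterVector, magnitude: float, seed: int | None
) -> ParameterVector:
    """Shift every free parameter by +/- ``magnitude`` with random signs.

    This is the default start-value policy for simulated data: the known
    generating values, slightly displaced so the optimizer does not begin at
    the optimum.
    """
    if magnitude < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=len(params))
    return params.with_values(params.values + signs * magnitude)
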