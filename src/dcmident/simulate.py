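"""Synthetic BOLD data generation with SNR-calibrated Gaussian noise.

The deterministic model is integrated on the microtime grid, convolved with
the canonical HRF, and sampled once per TR.  Per region, independent Gaussian
noise with standard deviation ``sd(signal)/SNR`` is then added — the SNR is
defined as the ratio of signal SD to noise SD, the usual fMRI convention.
Noise is independent across regions and time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hrf import HRFKernel, canonical_hrf
from .model import DCMModel, DesignSpec, ParameterVector, integrate_neuronal, observe_bold

__all__ = [
    "SimulatedDataset",
    "DivergenceError",
    "simulate_clean",
    "add_noise",
    "simulate_dataset",
]

#: Effective SNR used for the noise-free limit (snr = inf): observations are
#: kept exactly clean while the per-region sigma passed downstream is tiny.
_NOISE_FREE_SNR = 1e6


class DivergenceError(RuntimeError):
    """The deterministic trajectory left the divergence bound."""


@dataclass
class SimulatedDataset:
    """A simulated multi-region BOLD session with known noise levels."""

    design: DesignSpec
    y_clean: np.ndarray  # (m, n_volumes)
    y_obs: np.ndarray
    sigma: np.ndarray    # per-region noise SD
    snr: float
    seed: int | None
    true_params: ParameterVector | None = None
    region_names: tuple[str, ...] | None = None

    @property
    def n_regions(self) -> int:
        return self.y_obs.shape[0]


def simulate_clean(
    model: DCMModel,
    design: DesignSpec,
    params: ParameterVector | np.ndarray | None = None,
    kernel: HRFKernel | None = None,
    sample_offset: int = 0,
) -> np.ndarray:
    """Noise-free BOLD: integrate the neuronal ODE, convolve, sample per TR.

    Raises :class:`DivergenceError` if the trajectory diverges, so that noise
    can never be added to a divergent signal.
    """
    if params is not None:
        model = model.with_theta(params)
    traj = integrate_neuronal(model, design)
    if traj.diverged:
        raise DivergenceError(
            "neuronal trajectory diverged; check connection strengths "
            "(inhibitory self-connections may be too weak)"
        )
    if kernel is None:
        kernel = canonical_hrf(design.microtime_step)
    return observe_bold(traj, kernel, design, sample_offset)


def add_noise(
    y_clean: np.ndarray, snr: float, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Add per-region Gaussian noise with sigma_i = sd(y_clean_i) / snr.

    ``snr = inf`` is the noise-free flag: returns the clean signal and zero
    sigmas.  A region with zero signal variance has no defined sigma and is
    rejected.
    """
    y_clean = np.asarray(y_clean, dtype=float)
    if not snr > 0:
        raise ValueError("snr must be positive (or infinite for noise-free)")
    if np.isinf(snr):
        return y_clean.copy(), np.zeros(y_clean.shape[0])
    sd = y_clean.std(axis=1)
    if np.any(sd == 0):
        flat = [i for i, s in enumerate(sd) if s == 0]
        raise ValueError(
            f"region(s) {flat} have zero signal variance, so the noise SD is "
            "undefined; route a driving or modulatory input into them"
        )
    sigma = sd / snr
    rng = np.random.default_rng(seed)
    y_obs = y_clean + rng.normal(0.0, sigma[:, None], size=y_clean.shape)
    return y_obs, sigma


def simulate_dataset(
    model: DCMModel,
    design: DesignSpec,
    snr: float,
    seed: int | None,
    params: ParameterVector | np.ndarray | None = None,
    kernel: HRFKernel | None = None,
    sample_offset: int = 0,
) -> SimulatedDataset:
    """Full generator: clean signal plus calibrated noise, reproducible by seed.

    In the noise-free limit (``snr = inf``) observations equal the clean
    signal and the sigmas passed to estimation are a tiny fraction
    (``1/1e6``) of the per-region signal SD, keeping the weighted objective
    well defined.
    """
    if params is None:
        params = model.pack()
    elif not isinstance(params, ParameterVector):
        params = ParameterVector(params, model.index_map())
    y_clean = simulate_clean(model, design, params, kernel, sample_offset)
    if np.isinf(snr):
        y_obs = y_clean.copy()
        sd = y_clean.std(axis=1)
        if np.any(sd == 0):
            raise ValueError(
                "a region has zero signal variance; route an input into it"
            )
        sigma = sd / _NOISE_FREE_SNR
    else:
        y_obs, sigma = add_noise(y_clean, snr, seed)
    return SimulatedDataset(
        design=design,
        y_clean=y_clean,
        y_obs=y_obs,
        sigma=sigma,
        snr=snr,
        seed=seed,
        true_params=params,
        region_names=tuple(model.region_names),
    )
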