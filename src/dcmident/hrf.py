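"""Gamma densities and the canonical hemodynamic response kernel.

The canonical HRF is the difference of two gamma probability densities,

    HRF(t) = Gpdf(6, 1, t) - (1/6) Gpdf(16, 1, t),

with a peak delay of 6 s, an undershoot delay of 16 s and a one-to-six
peak-to-undershoot ratio.  ``l`` is treated as a *rate*, i.e. the density is
proportional to ``l**h * t**(h-1) * exp(-l*t)``; with ``l = 1`` (the canonical
kernel) the rate/scale distinction is moot, but the convention matters for
user-supplied kernels and is fixed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFKernel", "gamma_pdf", "canonical_hrf", "export_kernel"]

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT = 32.0  # seconds


@dataclass(frozen=True)
class HRFKernel:
    """A kernel sampled on [0, support) with fixed step; values[0] is t = 0."""

    step: float
    values: np.ndarray
    support: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.step


def gamma_pdf(h: float, l: float, t) -> np.ndarray:
    """Gamma density with shape ``h`` and rate ``l``; zero for t < 0."""
    if h <= 0 or l <= 0:
        raise ValueError("gamma shape and rate must be positive")
    return stats.gamma.pdf(np.asarray(t, dtype=float), a=h, scale=1.0 / l)


def canonical_hrf(step: float, support: float = DEFAULT_SUPPORT) -> HRFKernel:
    """Canonical double-gamma HRF sampled at ``step`` over ``[0, support)``.

    ``step`` must lie in (0, 1] s and ``support`` must be at least 24 s; a
    support below ~32 s clips part of the undershoot and only triggers a
    logged warning.
    """
    if not 0 < step <= 1.0:
        raise ValueError("kernel step must lie in (0, 1] seconds")
    if support < 24.0:
        raise ValueError("kernel support must be at least 24 s")
    if support < 32.0:
        logger.warning(
            "HRF support %.1f s clips part of the undershoot (peak at 16 s)",
            support,
        )
    t = np.arange(0.0, support, step)
    values = gamma_pdf(6.0, 1.0, t) - gamma_pdf(16.0, 1.0, t) / 6.0
    return HRFKernel(step=step, values=values, support=support)


def export_kernel(kernel: HRFKernel, path) -> None:
    """Write the kernel as two-column (time, value) plain text."""
    np.savetxt(
        path,
        np.column_stack([kernel.times(), kernel.values]),
        header="time_s value",
    )
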