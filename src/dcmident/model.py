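"""Bilinear neuronal network model, acquisition design, and forward simulation.

The neuronal state of ``m`` brain regions evolves under the deterministic
bilinear ODE

    dZ/dt = (A + sum_i u_i(t) B(i)) Z + C u(t),

where ``A`` holds the fixed (condition-averaged) effective connections in Hz,
each ``B(i)`` the change in coupling induced by modulatory input ``i``, and
``C`` the gains of driving inputs.  Inputs are piecewise-constant boxcar (or
single-bin "stick") functions, so within every interval of constant input the
system is linear time-invariant and is propagated exactly with a matrix
exponential / eigendecomposition, with interval boundaries placed at every
input change point.  The BOLD observation is the causal convolution of the
neuronal states with a hemodynamic response kernel, sampled once per TR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "DCMModel",
    "ParameterVector",
    "DesignSpec",
    "Stimulus",
    "Trajectory",
    "DimensionError",
    "neuronal_derivative",
    "integrate_neuronal",
    "observe_bold",
    "DIVERGENCE_BOUND",
]

#: States with magnitude beyond this bound flag the trajectory as divergent.
DIVERGENCE_BOUND = 1e6

# Tolerance (in units of the microtime step) used when snapping stimulus
# change points onto the sampling grid.
_GRID_EPS = 1e-9


class DimensionError(ValueError):
    """Shape mismatch between a state/input vector and a model matrix."""


def _as_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ParameterVector:
    """Ordered free parameters of a model.

    The packing order is fixed: nonzero entries of ``A`` in row-major order,
    then each ``B(i)`` in input order (row-major within each), then ``C``
    row-major.  ``index_map`` holds one entry per position: ``("A", row, col)``,
    ``("B", input_index, row, col)`` or ``("C", row, col)``.
    """

    values: np.ndarray
    index_map: tuple[tuple, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) != len(self.index_map):
            raise DimensionError(
                "parameter values and index map must have equal length"
            )

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values) -> "ParameterVector":
        return ParameterVector(np.asarray(values, dtype=float), self.index_map)


@dataclass
class DCMModel:
    """Structure masks and parameter values of a bilinear network model.

    Masks are binary; values are zero wherever the mask is zero.  The
    diagonal of ``a_mask`` is all ones: inhibitory self-connections are always
    part of the model.  The nonlinear (second-order) modulation term is not
    represented.
    """

    region_names: list[str]
    a_mask: np.ndarray
    a_values: np.ndarray
    b_masks: np.ndarray  # (n_inputs, m, m)
    b_values: np.ndarray
    c_mask: np.ndarray  # (m, n_inputs)
    c_values: np.ndarray
    input_names: list[str]
    _a_idx: tuple = field(init=False, repr=False, compare=False)
    _b_idx: list = field(init=False, repr=False, compare=False)
    _c_idx: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        m = len(self.region_names)
        if m < 1:
            raise DimensionError("a model needs at least one region")
        self.a_mask = _as_matrix(self.a_mask, "a_mask")
        self.a_values = _as_matrix(self.a_values, "a_values")
        self.b_masks = np.asarray(self.b_masks, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.c_mask = _as_matrix(self.c_mask, "c_mask")
        self.c_values = _as_matrix(self.c_values, "c_values")
        n_in = len(self.input_names)
        if self.b_masks.size == 0:
            self.b_masks = np.zeros((n_in, m, m))
        if self.b_values.size == 0:
            self.b_values = np.zeros((n_in, m, m))
        if self.a_mask.shape != (m, m):
            raise DimensionError(f"A mask must be {m}x{m}, got {self.a_mask.shape}")
        if self.a_values.shape != (m, m):
            raise DimensionError(f"A values must be {m}x{m}")
        if self.b_masks.shape != (n_in, m, m) or self.b_values.shape != (n_in, m, m):
            raise DimensionError(
                f"B masks/values must be {n_in}x{m}x{m}, got "
                f"{self.b_masks.shape}/{self.b_values.shape}"
            )
        if self.c_mask.shape != (m, n_in) or self.c_values.shape != (m, n_in):
            raise DimensionError(f"C mask/values must be {m}x{n_in}")
        for name, mask in (
            ("A", self.a_mask),
            ("B", self.b_masks),
            ("C", self.c_mask),
        ):
            if not np.isin(mask, (0.0, 1.0)).all():
                raise ValueError(f"{name} mask entries must be binary")
        if not np.all(np.diag(self.a_mask) == 1):
            raise ValueError("diagonal of the A mask must be all ones "
                             "(self-connections are always modeled)")
        for name, mask, vals in (
            ("A", self.a_mask, self.a_values),
            ("B", self.b_masks, self.b_values),
            ("C", self.c_mask, self.c_values),
        ):
            if np.any((mask == 0) & (vals != 0)):
                raise ValueError(f"{name} values must be zero where the mask is zero")
        self._a_idx = np.nonzero(self.a_mask)
        self._b_idx = [np.nonzero(bm) for bm in self.b_masks]
        self._c_idx = np.nonzero(self.c_mask)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_free(self) -> int:
        n = len(self._a_idx[0]) + len(self._c_idx[0])
        return n + sum(len(ix[0]) for ix in self._b_idx)

    # -- parameter packing -------------------------------------------------
    def index_map(self) -> tuple[tuple, ...]:
        entries: list[tuple] = []
        entries += [("A", int(r), int(c)) for r, c in zip(*self._a_idx)]
        for i, ix in enumerate(self._b_idx):
            entries += [("B", i, int(r), int(c)) for r, c in zip(*ix)]
        entries += [("C", int(r), int(c)) for r, c in zip(*self._c_idx)]
        return tuple(entries)

    def pack(self) -> ParameterVector:
        """Collect the current matrix values into a flat parameter vector."""
        parts = [self.a_values[self._a_idx]]
        parts += [self.b_values[i][ix] for i, ix in enumerate(self._b_idx)]
        parts.append(self.c_values[self._c_idx])
        return ParameterVector(np.concatenate(parts), self.index_map())

    def unpack(self, theta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Scatter a flat parameter vector into full (A, B, C) matrices."""
        theta = np.asarray(
            theta.values if isinstance(theta, ParameterVector) else theta,
            dtype=float,
        )
        if theta.shape != (self.n_free,):
            raise DimensionError(
                f"expected {self.n_free} free parameters, got {theta.shape}"
            )
        m, n_in = self.n_regions, self.n_inputs
        A = np.zeros((m, m))
        B = np.zeros((n_in, m, m))
        C = np.zeros((m, n_in))
        pos = len(self._a_idx[0])
        A[self._a_idx] = theta[:pos]
        for i, ix in enumerate(self._b_idx):
            k = len(ix[0])
            B[i][ix] = theta[pos:pos + k]
            pos += k
        C[self._c_idx] = theta[pos:]
        return A, B, C

    def with_theta(self, theta) -> "DCMModel":
        """Return a copy of the model carrying the given parameter values."""
        A, B, C = self.unpack(theta)
        return dataclasses.replace(self, a_values=A, b_values=B, c_values=C)

    def parameter_labels(self) -> list[str]:
        """Human-readable labels, e.g. ``"V1→V5"`` or ``"Motion: V1→V5"``."""
        labels = []
        for entry in self.index_map():
            if entry[0] == "A":
                _, r, c = entry
                labels.append(f"{self.region_names[c]}→{self.region_names[r]}")
            elif entry[0] == "B":
                _, i, r, c = entry
                labels.append(
                    f"{self.input_names[i]}: "
                    f"{self.region_names[c]}→{self.region_names[r]}"
                )
            else:
                _, r, c = entry
                labels.append(f"{self.input_names[c]}→{self.region_names[r]}")
        return labels


@dataclass(frozen=True)
class Stimulus:
    """One boxcar: active on the half-open interval [onset, onset+duration)."""

    onset: float
    duration: float
    amplitude: float = 1.0


@dataclass
class DesignSpec:
    """Acquisition timing and the per-input stimulus trains.

    ``stimuli`` holds one list of :class:`Stimulus` per input, aligned with
    the model's input order.  The neuronal ODE is integrated on the microtime
    grid with step ``ts = tr / n_slices``; the session covers
    ``[0, tr * n_volumes)``.
    """

    tr: float
    n_slices: int
    n_volumes: int
    stimuli: tuple[tuple[Stimulus, ...], ...] = ()
    input_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        self.stimuli = tuple(
            tuple(
                s if isinstance(s, Stimulus) else Stimulus(*s) for s in train
            )
            for train in self.stimuli
        )
        T = self.duration
        for train in self.stimuli:
            for s in train:
                if s.onset < 0:
                    raise ValueError(f"stimulus onset {s.onset} < 0")
                if s.duration < 0:
                    raise ValueError("stimulus duration must be >= 0")
                if s.onset + s.duration > T + 1e-9 * max(T, 1.0):
                    raise ValueError(
                        f"stimulus [{s.onset}, {s.onset + s.duration}) extends "
                        f"past the session end {T}"
                    )

    @property
    def microtime_step(self) -> float:
        return self.tr / self.n_slices

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.tr * self.n_volumes

    @property
    def n_inputs(self) -> int:
        return len(self.stimuli)

    @property
    def n_microtime(self) -> int:
        return self.n_volumes * self.n_slices

    def times(self) -> np.ndarray:
        return np.arange(self.n_microtime) * self.microtime_step

    def input_values(self, t: float) -> np.ndarray:
        """Input amplitudes at time ``t`` (half-open boxcar convention)."""
        u = np.zeros(self.n_inputs)
        for i, train in enumerate(self.stimuli):
            for s in train:
                if s.onset <= t < s.onset + s.duration:
                    u[i] += s.amplitude
        return u

    def sample_inputs(self) -> np.ndarray:
        """Inputs sampled on the microtime grid, shape (n_inputs, n_microtime)."""
        U = np.zeros((self.n_inputs, self.n_microtime))
        ts = self.microtime_step
        for i, train in enumerate(self.stimuli):
            for s in train:
                k0 = int(np.ceil(s.onset / ts - _GRID_EPS))
                k1 = int(np.ceil((s.onset + s.duration) / ts - _GRID_EPS))
                U[i, k0:min(k1, self.n_microtime)] += s.amplitude
        return U


@dataclass
class Trajectory:
    """Neuronal states on the microtime grid.

    If the integration left the divergence bound, ``diverged`` is set and
    ``times``/``z`` are truncated at the last finite, in-bound sample.
    """

    times: np.ndarray
    z: np.ndarray
    diverged: bool = False

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# State equation
# ---------------------------------------------------------------------------

def neuronal_derivative(z, u, model: DCMModel) -> np.ndarray:
    """Right-hand side (A + Σ u_i B(i)) z + C u of the bilinear state equation."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    m, n_in = model.n_regions, model.n_inputs
    if z.shape != (m,):
        raise DimensionError(
            f"state vector has shape {z.shape} but A is {m}x{m}"
        )
    if u.shape != (n_in,):
        raise DimensionError(
            f"input vector has shape {u.shape} but C is {m}x{n_in}"
        )
    M = model.a_values.copy()
    if n_in:
        M += np.tensordot(u, model.b_values, axes=1)
    return M @ z + (model.c_values @ u if n_in else np.zeros(m))


# ---------------------------------------------------------------------------
# Piecewise-exact integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    k0: int            # index of first microtime sample inside the segment
    n_samples: int
    taus: np.ndarray   # offsets from segment start; last entry = segment length
    u: np.ndarray
    key: bytes


@dataclass(frozen=True)
class CompiledDesign:
    """Constant-input segments of a design, precomputed for fast integration."""

    segments: tuple[_Segment, ...]
    n_microtime: int
    ts: float


def compile_design(design: DesignSpec) -> CompiledDesign:
    ts = design.microtime_step
    T = design.duration
    events = {0.0, T}
    for train in design.stimuli:
        for s in train:
            if s.onset < T:
                events.add(round(s.onset, 12))
                events.add(round(min(s.onset + s.duration, T), 12))
    bps = sorted(events)
    segments = []
    N = design.n_microtime
    for t0, t1 in zip(bps[:-1], bps[1:]):
        if t1 - t0 <= 1e-12:
            continue
        u = design.input_values((t0 + t1) / 2.0)
        k0 = int(np.ceil(t0 / ts - _GRID_EPS))
        k1 = min(int(np.ceil(t1 / ts - _GRID_EPS)), N)
        k0 = min(k0, k1)
        taus = np.append(np.arange(k0, k1) * ts - t0, t1 - t0)
        segments.append(_Segment(k0, k1 - k0, taus, u, u.tobytes()))
    return CompiledDesign(tuple(segments), N, ts)


def _propagate_stepwise(M, c, z0, taus):
    """Augmented-matrix-exponential fallback for defective/singular systems."""
    m = M.shape[0]
    Maug = np.zeros((m + 1, m + 1))
    Maug[:m, :m] = M
    Maug[:m, m] = c
    out = np.empty((m, len(taus)))
    zaug = np.append(z0, 1.0)
    prev = 0.0
    for j, t in enumerate(taus):
        dt = t - prev
        if dt > 0:
            with np.errstate(over="ignore", invalid="ignore"):
                zaug = scipy.linalg.expm(Maug * dt) @ zaug
        out[:, j] = zaug[:m]
        prev = t
    return out


def _decompose(M, c):
    """Eigendecomposition (w, V, V^-1, p) of dz/dt = M z + c, or None.

    Returns None when M is defective or (with nonzero forcing) singular, in
    which case the caller falls back to stepwise matrix exponentials.
    """
    try:
        w, V = np.linalg.eig(M)
        if not np.all(np.isfinite(V)) or np.linalg.cond(V) > 1e10:
            return None
        Vinv = np.linalg.inv(V)
        if np.any(c):
            p = np.linalg.solve(M, c)
            if not np.all(np.isfinite(p)) or np.abs(p).max() > 1e12:
                return None
        else:
            p = np.zeros(len(c), dtype=complex)
        return w, V, Vinv, p
    except np.linalg.LinAlgError:
        return None


def _propagate_segment(decomp, M, c, z0, taus):
    """States of dz/dt = M z + c at offsets ``taus`` from initial state ``z0``."""
    if decomp is None:
        return _propagate_stepwise(M, c, z0, taus)
    w, V, Vinv, p = decomp
    y0 = Vinv @ (z0 + p)
    with np.errstate(over="ignore", invalid="ignore"):
        ew = np.exp(np.multiply.outer(w, taus))
        Z = np.real(V @ (ew * y0[:, None])) - np.real(p)[:, None]
    return Z


def integrate_compiled(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    compiled: CompiledDesign,
    init: np.ndarray,
    divergence_bound: float = DIVERGENCE_BOUND,
) -> Trajectory:
    """Integrate the bilinear ODE over precompiled constant-input segments."""
    m = A.shape[0]
    n_in = B.shape[0] if B.ndim == 3 else 0
    N = compiled.n_microtime
    z = np.zeros((m, N))
    state = np.asarray(init, dtype=float).copy()
    times = np.arange(N) * compiled.ts
    cache: dict[bytes, tuple] = {}
    for seg in compiled.segments:
        if seg.key in cache:
            M, c, decomp = cache[seg.key]
        else:
            M = A + np.tensordot(seg.u, B, axes=1) if n_in else A
            c = C @ seg.u if n_in else np.zeros(m)
            decomp = _decompose(M, c)
            cache[seg.key] = (M, c, decomp)
        Z = _propagate_segment(decomp, M, c, state, seg.taus)
        if seg.n_samples:
            z[:, seg.k0:seg.k0 + seg.n_samples] = Z[:, :seg.n_samples]
        state = Z[:, -1]
        with np.errstate(invalid="ignore"):
            bad = ~np.isfinite(Z) | (np.abs(Z) > divergence_bound)
        if bad.any():
            sample_bad = bad[:, :seg.n_samples].any(axis=0)
            first_bad = (
                int(np.argmax(sample_bad)) if sample_bad.any() else seg.n_samples
            )
            stop = seg.k0 + first_bad
            return Trajectory(times[:stop], z[:, :stop], diverged=True)
    return Trajectory(times, z, diverged=False)


def integrate_neuronal(
    model: DCMModel,
    design: DesignSpec,
    init=None,
    divergence_bound: float = DIVERGENCE_BOUND,
) -> Trajectory:
    """Neuronal trajectory of the model under the given design.

    The session is split into bins wherever an input changes; within each bin
    the frozen linear system is solved exactly, so the result carries no
    time-stepping error beyond floating point.  The baseline initial condition
    is Z(0) = 0.  Divergence is reported in the trajectory, never raised.
    """
    if design.n_inputs != model.n_inputs:
        raise DimensionError(
            f"design provides {design.n_inputs} stimulus trains but the model "
            f"has {model.n_inputs} inputs"
        )
    if init is None:
        init = np.zeros(model.n_regions)
    init = np.asarray(init, dtype=float)
    if init.shape != (model.n_regions,):
        raise DimensionError("initial state has the wrong length for A")
    if not np.all(np.isfinite(init)):
        raise ValueError("initial state must be finite")
    compiled = compile_design(design)
    return integrate_compiled(
        model.a_values, model.b_values, model.c_values, compiled, init,
        divergence_bound,
    )


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def observe_compiled(
    z: np.ndarray,
    kernel_values: np.ndarray,
    ts: float,
    n_slices: int,
    n_volumes: int,
    sample_offset: int = 0,
) -> np.ndarray:
    """Convolve microtime states with a kernel and sample once per TR."""
    from scipy.signal import fftconvolve

    y = fftconvolve(z, kernel_values[None, :], mode="full", axes=1)
    y = y[:, :z.shape[1]] * ts
    idx = sample_offset + np.arange(n_volumes) * n_slices
    return y[:, idx]


def observe_bold(
    traj: Trajectory,
    hrf_kernel,
    design: DesignSpec,
    sample_offset: int = 0,
) -> np.ndarray:
    """BOLD observations: causal convolution of ``traj`` with the HRF kernel.

    The convolution is the Riemann-sum approximation of the continuous
    convolution integral (hence the ``ts`` scaling) and is linear in the
    neuronal states.  One sample per TR is taken at microtime bin
    ``sample_offset`` of each TR period (default: the first bin).
    """
    ts = design.microtime_step
    if abs(hrf_kernel.step - ts) > 1e-9 * max(ts, 1.0):
        raise DimensionError(
            f"kernel step {hrf_kernel.step} does not match the microtime step {ts}"
        )
    if traj.diverged or traj.z.shape[1] != design.n_microtime:
        raise ValueError(
            "trajectory is divergent/truncated; BOLD observations are undefined"
        )
    if not 0 <= sample_offset < design.n_slices:
        raise ValueError("sample_offset must lie in [0, n_slices)")
    return observe_compiled(
        traj.z, hrf_kernel.values, ts, design.n_slices, design.n_volumes,
        sample_offset,
    )
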