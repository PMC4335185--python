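"""Design variants and identifiability sweeps over TR, session, epoch and SNR.

Each variant changes one acquisition axis at a time relative to a base
design, mirroring how experimental designs are compared in practice:

* ``vary_tr``      — new repetition time; the *session length* is held fixed
  (volume count rescaled, rounding down), stimuli keep their absolute timing;
* ``vary_session`` — new volume count; stimuli past the new end are dropped,
  an extended session repeats the base stimulus pattern cyclically;
* ``vary_epoch``   — every stimulus keeps its onset but gets a new duration,
  so stimulus count and onset spacing stay fixed while "on" time changes.

``run_sweep`` assesses every variant x replicate-seed combination and returns
a tidy table with the mean-CI (A-optimality) score and per-parameter statuses.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DCMModel, DesignSpec, ParameterVector, Stimulus
from .profile_likelihood import ProfileSettings, assess_model

__all__ = [
    "SweepSpec",
    "vary_tr",
    "vary_session",
    "vary_epoch",
    "run_sweep",
]


def _clip_stimuli(
    stimuli: tuple[tuple[Stimulus, ...], ...], end: float
) -> tuple[tuple[Stimulus, ...], ...]:
    """Drop stimuli starting at/after ``end``; clip ones straddling it."""
    out = []
    for train in stimuli:
        kept = []
        for s in train:
            if s.onset >= end:
                continue
            duration = min(s.duration, end - s.onset)
            kept.append(Stimulus(s.onset, duration, s.amplitude))
        out.append(tuple(kept))
    return tuple(out)


def vary_tr(design: DesignSpec, new_tr: float) -> DesignSpec:
    """Change TR, preserving session length to the nearest (lower) volume.

    Slices per volume are kept, so the microtime step scales with TR.
    Stimulus trains are unchanged in absolute time apart from clipping at the
    (at most one TR shorter) new session end.
    """
    if new_tr <= 0:
        raise ValueError("new_tr must be positive")
    n_volumes = int(math.floor(design.duration / new_tr + 1e-9))
    new = dataclasses.replace(
        design,
        tr=new_tr,
        n_volumes=n_volumes,
        stimuli=_clip_stimuli(design.stimuli, new_tr * n_volumes),
    )
    return new


def vary_session(design: DesignSpec, n_volumes: int) -> DesignSpec:
    """Change the number of volumes at fixed TR.

    Shortening drops (or clips) stimuli beyond the new session end; extending
    repeats the base stimulus pattern with its original onset spacing, i.e.
    each train is shifted by whole multiples of the base session length.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    T_old = design.duration
    T_new = design.tr * n_volumes
    stimuli = design.stimuli
    if T_new > T_old:
        extended = []
        for train in stimuli:
            new_train = list(train)
            k = 1
            while k * T_old < T_new:
                for s in train:
                    onset = s.onset + k * T_old
                    if onset < T_new:
                        new_train.append(Stimulus(onset, s.duration, s.amplitude))
                k += 1
            extended.append(tuple(new_train))
        stimuli = tuple(extended)
    return dataclasses.replace(
        design,
        n_volumes=n_volumes,
        stimuli=_clip_stimuli(stimuli, T_new),
    )


def vary_epoch(design: DesignSpec, epoch_s: float) -> DesignSpec:
    """Set every stimulus duration to ``epoch_s``, keeping all onsets.

    The number of stimuli and the distance between onsets are untouched;
    only the "on" length changes.  An epoch longer than the smallest onset
    spacing of any input would make epochs overlap and is rejected.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    for i, train in enumerate(design.stimuli):
        onsets = np.sort([s.onset for s in train])
        if len(onsets) > 1:
            spacing = float(np.diff(onsets).min())
            if epoch_s > spacing + 1e-9:
                raise ValueError(
                    f"epoch {epoch_s} s exceeds the minimum onset spacing "
                    f"{spacing} s of input {i}; epochs would overlap"
                )
    stimuli = tuple(
        tuple(Stimulus(s.onset, epoch_s, s.amplitude) for s in train)
        for train in design.stimuli
    )
    return dataclasses.replace(
        design, stimuli=_clip_stimuli(stimuli, design.duration)
    )


@dataclass
class SweepSpec:
    """Axes of a design sweep.  Each listed value varies one axis alone."""

    base_design: DesignSpec
    tr_values: list[float] = field(default_factory=list)
    n_volume_values: list[int] = field(default_factory=list)
    epoch_durations: list[float] = field(default_factory=list)
    snr_values: list[float] = field(default_factory=list)
    base_snr: float = 10.0
    replicate_seeds: list[int] = field(default_factory=lambda: [0])

    def variants(self) -> list[tuple[str, float, DesignSpec, float]]:
        """(axis, value, design, snr) for the base plus every single-axis change."""
        base = self.base_design
        out: list[tuple[str, float, DesignSpec, float]] = [
            ("base", float("nan"), base, self.base_snr)
        ]
        out += [("tr", v, vary_tr(base, v), self.base_snr) for v in self.tr_values]
        out += [
            ("volumes", v, vary_session(base, int(v)), self.base_snr)
            for v in self.n_volume_values
        ]
        out += [
            ("epoch", v, vary_epoch(base, v), self.base_snr)
            for v in self.epoch_durations
        ]
        out += [("snr", v, base, v) for v in self.snr_values]
        return out


def run_sweep(
    model: DCMModel,
    params: ParameterVector | np.ndarray,
    sweep: SweepSpec,
    settings: ProfileSettings | None = None,
    base_seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Assess every variant under every replicate seed.

    The seed of each run is ``base_seed + 1000 * variant_index +
    replicate_index`` (always a different noise realization, logged per row).
    A failing variant is recorded in its row; the sweep continues.
    """
    rows = []
    variants = sweep.variants()
    for vi, (axis, value, design, snr) in enumerate(variants):
        for ri, rep_seed in enumerate(sweep.replicate_seeds):
            seed = (base_seed + 1000 * vi + rep_seed) % (2**31)
            row = {
                "axis": axis,
                "value": value,
                "tr": design.tr,
                "n_volumes": design.n_volumes,
                "snr": snr,
                "replicate": ri,
                "seed": seed,
            }
            try:
                report = assess_model(
                    model, params, design, snr, seed, settings, n_jobs=n_jobs
                )
                row.update(
                    mci=report.mci,
                    n_identifiable=report.n_identifiable,
                    n_params=len(report.cis),
                    statuses=";".join(report.statuses()),
                    converged=report.fit.converged,
                    error="",
                )
            except Exception as exc:  # keep sweeping; record the failure
                row.update(
                    mci=float("nan"),
                    n_identifiable=0,
                    n_params=model.n_free,
                    statuses="",
                    converged=False,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)
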