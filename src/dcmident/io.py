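"""Configuration, dataset and report I/O, plus SPM-style ``DCM.mat`` import.

The native configuration is plain structured text (YAML; JSON is a subset)
with the schema documented in ``docs/config_schema.md``:

.. code-block:: yaml

    regions: [V1, V5, SPC]
    inputs: [Photic, Motion, Attention]
    a: {mask: [[...]], values: [[...]]}
    b:
      - {input: Motion, mask: [[...]], values: [[...]]}
    c: {mask: [[...]], values: [[...]]}
    design:
      tr: 3.22
      n_slices: 32
      n_volumes: 360
      stimuli:
        Photic: {start: 0.0, spacing: 64.4, duration: 32.2, count: 18}
        Motion: [[64.4, 32.2], [193.2, 32.2]]
    snr: 10
    seed: 0

Stimulus trains are either explicit ``[onset, duration(, amplitude)]`` lists
or a generating rule ``{start, spacing, duration, count}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .model import DCMModel, DesignSpec, ParameterVector, Stimulus
from .simulate import SimulatedDataset

__all__ = [
    "ConfigError",
    "load_config",
    "model_from_config",
    "design_from_config",
    "config_from_model",
    "save_config",
    "save_dataset",
    "load_dataset",
    "import_dcm_mat",
    "export_dcm_mat",
    "report_to_dict",
    "save_report",
]


class ConfigError(ValueError):
    """A configuration file is missing or malforms a required key."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ConfigError(f"missing required config key '{key}'")
    return cfg[key]


def _mask_values(block, name: str, shape) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(block, dict) or "mask" not in block:
        raise ConfigError(f"'{name}' must be a mapping with a 'mask' entry")
    mask = np.asarray(block["mask"], dtype=float)
    if mask.shape != shape:
        raise ConfigError(f"'{name}.mask' must have shape {shape}, got {mask.shape}")
    values = np.asarray(block.get("values", np.zeros(shape)), dtype=float)
    if values.shape != shape:
        raise ConfigError(f"'{name}.values' must have shape {shape}")
    return mask, values


def model_from_config(cfg: dict) -> DCMModel:
    regions = list(_require(cfg, "regions"))
    inputs = list(cfg.get("inputs", []))
    m, n_in = len(regions), len(inputs)
    a_mask, a_values = _mask_values(_require(cfg, "a"), "a", (m, m))
    b_masks = np.zeros((n_in, m, m))
    b_values = np.zeros((n_in, m, m))
    for block in cfg.get("b", []) or []:
        name = block.get("input")
        if name not in inputs:
            raise ConfigError(f"'b' block references unknown input '{name}'")
        i = inputs.index(name)
        b_masks[i], b_values[i] = _mask_values(block, f"b[{name}]", (m, m))
    c_mask, c_values = _mask_values(_require(cfg, "c"), "c", (m, n_in))
    return DCMModel(
        region_names=regions,
        a_mask=a_mask, a_values=a_values,
        b_masks=b_masks, b_values=b_values,
        c_mask=c_mask, c_values=c_values,
        input_names=inputs,
    )


def _train_from_config(spec, name: str) -> tuple[Stimulus, ...]:
    if isinstance(spec, dict):
        for key in ("start", "spacing", "duration", "count"):
            if key not in spec:
                raise ConfigError(f"stimulus rule for '{name}' is missing '{key}'")
        amp = float(spec.get("amplitude", 1.0))
        return tuple(
            Stimulus(spec["start"] + k * spec["spacing"], spec["duration"], amp)
            for k in range(int(spec["count"]))
        )
    return tuple(Stimulus(*entry) for entry in spec)


def design_from_config(cfg: dict, input_names=None) -> DesignSpec:
    dcfg = _require(cfg, "design")
    for key in ("tr", "n_slices", "n_volumes"):
        if key not in dcfg:
            raise ConfigError(f"missing required design key '{key}'")
    names = input_names if input_names is not None else list(cfg.get("inputs", []))
    stim_cfg = dcfg.get("stimuli", {}) or {}
    for name in stim_cfg:
        if name not in names:
            raise ConfigError(f"stimuli reference unknown input '{name}'")
    stimuli = tuple(
        _train_from_config(stim_cfg.get(name, []), name) for name in names
    )
    return DesignSpec(
        tr=float(dcfg["tr"]),
        n_slices=int(dcfg["n_slices"]),
        n_volumes=int(dcfg["n_volumes"]),
        stimuli=stimuli,
        input_names=tuple(names),
    )


def config_from_model(
    model: DCMModel, design: DesignSpec | None = None,
    snr: float | None = None, seed: int | None = None,
) -> dict:
    cfg: dict = {
        "regions": list(model.region_names),
        "inputs": list(model.input_names),
        "a": {"mask": model.a_mask.tolist(), "values": model.a_values.tolist()},
        "b": [
            {
                "input": model.input_names[i],
                "mask": model.b_masks[i].tolist(),
                "values": model.b_values[i].tolist(),
            }
            for i in range(model.n_inputs)
            if model.b_masks[i].any()
        ],
        "c": {"mask": model.c_mask.tolist(), "values": model.c_values.tolist()},
    }
    if design is not None:
        cfg["design"] = {
            "tr": design.tr,
            "n_slices": design.n_slices,
            "n_volumes": design.n_volumes,
            "stimuli": {
                name: [[s.onset, s.duration, s.amplitude] for s in train]
                for name, train in zip(model.input_names, design.stimuli)
            },
        }
    if snr is not None:
        cfg["snr"] = snr
    if seed is not None:
        cfg["seed"] = seed
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Datasets: plain tabular text plus a JSON sidecar
# ---------------------------------------------------------------------------

def save_dataset(ds: SimulatedDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = ds.region_names or tuple(
        f"region{i}" for i in range(ds.n_regions)
    )
    header = "\t".join(names)
    np.savetxt(out / "bold.tsv", ds.y_obs.T, delimiter="\t",
               header=header, comments="")
    np.savetxt(out / "bold_clean.tsv", ds.y_clean.T, delimiter="\t",
               header=header, comments="")
    meta = {
        "regions": list(names),
        "sigma": ds.sigma.tolist(),
        "snr": None if np.isinf(ds.snr) else ds.snr,
        "seed": ds.seed,
        "design": {
            "tr": ds.design.tr,
            "n_slices": ds.design.n_slices,
            "n_volumes": ds.design.n_volumes,
            "input_names": list(ds.design.input_names or []),
            "stimuli": [
                [[s.onset, s.duration, s.amplitude] for s in train]
                for train in ds.design.stimuli
            ],
        },
        "true_params": None
        if ds.true_params is None
        else {
            "values": ds.true_params.values.tolist(),
            "index_map": [list(e) for e in ds.true_params.index_map],
        },
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_dataset(in_dir) -> SimulatedDataset:
    src = Path(in_dir)
    with open(src / "meta.json") as fh:
        meta = json.load(fh)
    y_obs = np.loadtxt(src / "bold.tsv", delimiter="\t", skiprows=1).T
    clean_path = src / "bold_clean.tsv"
    y_clean = (
        np.loadtxt(clean_path, delimiter="\t", skiprows=1).T
        if clean_path.exists()
        else y_obs.copy()
    )
    d = meta["design"]
    design = DesignSpec(
        tr=d["tr"], n_slices=d["n_slices"], n_volumes=d["n_volumes"],
        stimuli=tuple(tuple(Stimulus(*s) for s in train) for train in d["stimuli"]),
        input_names=tuple(d.get("input_names", [])) or None,
    )
    tp = meta.get("true_params")
    true_params = (
        ParameterVector(
            np.asarray(tp["values"]),
            tuple(tuple(e) for e in tp["index_map"]),
        )
        if tp
        else None
    )
    snr = meta.get("snr")
    return SimulatedDataset(
        design=design,
        y_clean=y_clean,
        y_obs=y_obs,
        sigma=np.asarray(meta["sigma"], dtype=float),
        snr=float("inf") if snr is None else snr,
        seed=meta.get("seed"),
        true_params=true_params,
        region_names=tuple(meta["regions"]),
    )


# ---------------------------------------------------------------------------
# SPM-style DCM.mat containers (best effort, read-only plus a round-trip
# exporter used for interchange and testing)
# ---------------------------------------------------------------------------

def _field(obj, name: str, context: str):
    if isinstance(obj, dict):
        if name not in obj:
            raise ConfigError(f"DCM.mat import: missing field '{context}.{name}'")
        return obj[name]
    if not hasattr(obj, name):
        raise ConfigError(f"DCM.mat import: missing field '{context}.{name}'")
    return getattr(obj, name)


def _runs_to_stimuli(u: np.ndarray, dt: float) -> tuple[Stimulus, ...]:
    """Turn one sampled input column into boxcar (onset, duration, amplitude)s."""
    u = np.asarray(u, dtype=float).ravel()
    stimuli = []
    start = None
    amp = 0.0
    for k, v in enumerate(np.append(u, 0.0)):
        if start is None and v != 0:
            start, amp = k, v
        elif start is not None and v != amp:
            stimuli.append(Stimulus(start * dt, (k - start) * dt, amp))
            start = None if v == 0 else k
            amp = v
    return tuple(stimuli)


def import_dcm_mat(path) -> tuple[DCMModel, ParameterVector, DesignSpec]:
    """Read structure, estimates, input timing and TR from an SPM DCM file.

    Masks come from the ``a``/``b``/``c`` structure fields, values from the
    ``Ep`` estimates when present (zeros otherwise), and the design from the
    microtime input trains ``U.u``/``U.dt`` together with ``Y.dt`` (the TR)
    and ``v`` (volumes).  Missing fields raise a :class:`ConfigError` naming
    the field; there is never a partial silent import.
    """
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    if "DCM" not in mat:
        raise ConfigError("DCM.mat import: missing top-level field 'DCM'")
    dcm = mat["DCM"]
    a = np.atleast_2d(_field(dcm, "a", "DCM"))
    b = np.atleast_3d(_field(dcm, "b", "DCM"))
    c = np.atleast_2d(_field(dcm, "c", "DCM"))
    m = a.shape[0]
    if b.shape[:2] == (m, m):  # SPM stores b as (m, m, n_inputs)
        b = np.moveaxis(b, -1, 0)
    n_in = b.shape[0]
    if c.shape == (n_in, m) and c.shape != (m, n_in):
        c = c.T
    U = _field(dcm, "U", "DCM")
    u = np.atleast_2d(_field(U, "u", "DCM.U"))
    dt = float(_field(U, "dt", "DCM.U"))
    if u.shape[0] == n_in and u.shape[1] != n_in:
        u = u.T
    try:
        names = [str(n) for n in np.atleast_1d(_field(U, "name", "DCM.U"))]
    except ConfigError:
        names = [f"input{i + 1}" for i in range(n_in)]
    Y = _field(dcm, "Y", "DCM")
    tr = float(_field(Y, "dt", "DCM.Y"))
    n_volumes = int(_field(dcm, "v", "DCM"))
    try:
        ep = _field(dcm, "Ep", "DCM")
        ea = np.atleast_2d(_field(ep, "A", "DCM.Ep"))
        eb = np.atleast_3d(_field(ep, "B", "DCM.Ep"))
        if eb.shape[:2] == (m, m):
            eb = np.moveaxis(eb, -1, 0)
        ec = np.atleast_2d(_field(ep, "C", "DCM.Ep"))
        if ec.shape == (n_in, m) and ec.shape != (m, n_in):
            ec = ec.T
    except ConfigError:
        ea, eb, ec = np.zeros((m, m)), np.zeros((n_in, m, m)), np.zeros((m, n_in))
    a_mask = (a != 0).astype(float)
    np.fill_diagonal(a_mask, 1.0)
    b_masks = (b != 0).astype(float)
    c_mask = (c != 0).astype(float)
    model = DCMModel(
        region_names=[f"region{i + 1}" for i in range(m)],
        a_mask=a_mask, a_values=ea * a_mask,
        b_masks=b_masks, b_values=eb * b_masks,
        c_mask=c_mask, c_values=ec * c_mask,
        input_names=names,
    )
    n_slices = max(1, int(round(tr / dt)))
    design = DesignSpec(
        tr=tr,
        n_slices=n_slices,
        n_volumes=n_volumes,
        stimuli=tuple(_runs_to_stimuli(u[:, i], dt) for i in range(n_in)),
        input_names=tuple(names),
    )
    return model, model.pack(), design


def export_dcm_mat(
    path, model: DCMModel, params: ParameterVector | None, design: DesignSpec
) -> None:
    """Write an SPM-style DCM container for interchange/round-tripping."""
    from scipy.io import savemat

    if params is not None:
        model = model.with_theta(params)
    dt = design.microtime_step
    u = design.sample_inputs().T  # (n_microtime, n_inputs)
    dcm = {
        "a": model.a_mask,
        "b": np.moveaxis(model.b_masks, 0, -1),
        "c": model.c_mask,
        "Ep": {
            "A": model.a_values,
            "B": np.moveaxis(model.b_values, 0, -1),
            "C": model.c_values,
        },
        "U": {"u": u, "dt": dt, "name": np.array(model.input_names, dtype=object)},
        "Y": {"dt": design.tr},
        "v": design.n_volumes,
    }
    savemat(path, {"DCM": dcm})


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def report_to_dict(report) -> dict:
    def num(x):
        return None if x is None or not np.isfinite(x) else float(x)

    return {
        "alpha": report.alpha,
        "snr": None if np.isinf(report.snr) else report.snr,
        "seed": report.seed,
        "mci": num(report.mci),
        "mci_is_infinite": not np.isfinite(report.mci),
        "diagnostic": report.diagnostic,
        "fit": {
            "theta_hat": report.fit.x.tolist(),
            "chi2_min": report.fit.chi2_min,
            "converged": report.fit.converged,
            "n_restarts": report.fit.n_restarts,
        },
        "design": {
            "tr": report.design.tr,
            "n_slices": report.design.n_slices,
            "n_volumes": report.design.n_volumes,
        },
        "labels": list(report.labels),
        "true_values": None
        if report.true_values is None
        else report.true_values.tolist(),
        "cis": [
            {
                "label": lbl,
                "lower": num(ci.lower),
                "upper": num(ci.upper),
                "status": ci.status.value,
                "contains_zero": ci.contains_zero,
            }
            for lbl, ci in zip(report.labels, report.cis)
        ],
        "curves": [
            {
                "param_index": cv.param_index,
                "theta": cv.theta_grid.tolist(),
                "chi2_pl": cv.chi2_pl.tolist(),
                "chi2_hat": cv.chi2_hat,
                "capped": cv.capped.astype(int).tolist(),
                "center_index": cv.center_index,
            }
            for cv in report.curves
        ],
    }


def save_report(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
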