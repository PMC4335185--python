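"""Rendering of identifiability reports: profile panels, CI table, summary."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io import save_report

__all__ = ["render_report", "ci_table"]


def ci_table(report) -> pd.DataFrame:
    rows = []
    for lbl, ci in zip(report.labels, report.cis):
        rows.append(
            {
                "parameter": lbl,
                "lower": ci.lower,
                "upper": ci.upper,
                "width": ci.width,
                "status": ci.status.value,
                "contains_zero": ci.contains_zero,
            }
        )
    return pd.DataFrame(rows)


def _plot_profiles(report, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .profile_likelihood import chi2_threshold

    n = len(report.curves)
    if n == 0:
        return
    ncols = min(5, n)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    delta = chi2_threshold(report.alpha, 1)
    for k, curve in enumerate(report.curves):
        ax = axes[k // ncols][k % ncols]
        keep = ~curve.capped
        ax.plot(curve.theta_grid[keep], curve.chi2_pl[keep], "b-", lw=1.2)
        ax.axhline(curve.chi2_hat + delta, color="r", lw=1.0)
        if report.true_values is not None:
            ax.axvline(report.true_values[k], color="g", lw=1.0)
        ax.set_title(report.labels[k], fontsize=9)
        finite = curve.chi2_pl[keep]
        if finite.size:
            lo = curve.chi2_hat
            hi = max(curve.chi2_hat + 2.5 * delta, finite.min() + 2.5 * delta)
            ax.set_ylim(lo - 0.2 * delta, hi)
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.suptitle(_mci_line(report.mci))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _mci_line(mci: float) -> str:
    return "mCI = inf" if not np.isfinite(mci) else f"mCI = {mci:.4g}"


def render_report(report, out_dir) -> list[Path]:
    """Write profile plots, per-parameter CSVs, a CI table and a summary.

    All outputs are deterministic functions of the report.  Returns the list
    of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    table = ci_table(report)
    table_path = out / "confidence_intervals.csv"
    table.to_csv(table_path, index=False)
    written.append(table_path)

    for curve, lbl in zip(report.curves, report.labels):
        safe = lbl.replace("→", "_to_").replace(":", "").replace(" ", "")
        p = out / f"profile_{curve.param_index:02d}_{safe}.csv"
        pd.DataFrame(
            {
                "theta": curve.theta_grid,
                "chi2_pl": curve.chi2_pl,
                "capped": curve.capped.astype(int),
            }
        ).to_csv(p, index=False)
        written.append(p)

    plot_path = out / "profiles.png"
    _plot_profiles(report, plot_path)
    if plot_path.exists():
        written.append(plot_path)

    json_path = out / "report.json"
    save_report(report, json_path)
    written.append(json_path)

    summary = out / "summary.txt"
    lines = [
        f"design: TR={report.design.tr} s, {report.design.n_slices} slices, "
        f"{report.design.n_volumes} volumes "
        f"({report.design.duration / 60:.2f} min)",
        f"snr: {report.snr}",
        f"seed: {report.seed}",
        f"alpha: {report.alpha}",
        f"identifiable parameters: {report.n_identifiable}/{len(report.cis)}",
        _mci_line(report.mci),
    ]
    if report.diagnostic:
        lines.append(f"diagnostic: {report.diagnostic}")
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
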