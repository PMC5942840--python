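"""Report generation: figures, displacement fields and a JSON summary.

Reads the artifacts of a completed run directory and writes:

* ``figures/ranges.png`` — per-landmark prediction range bars for both
  design iterations with the observed displacements overlaid,
* ``figures/materials.png`` — pooled optimised-candidate histograms with
  the fitted Weibull density and cumulative curves,
* ``figures/envelopes_<sid>.png`` — per-landmark probability histograms
  and cumulative densities for each validation subject,
* ``figures/midline_<sid>.png`` — the predicted midline profile band,
* ``fields/<sid>_min.vtu`` / ``_max.vtu`` — displacement fields of the
  runs bounding the envelope,
* ``summary.json`` — machine-readable summary of the whole run
  (byte-identical across reruns with identical seeds).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from . import mesh_io, runio
from .fem_core import InputVector, ViscoelasticSolver, default_time_grid
from .mesh import LANDMARKS
from .runio import IncompleteRunError, _need

__all__ = ["generate_report"]


def _fig_ranges(outdir: Path, subjects, validation_ids) -> None:
    fig, axes = plt.subplots(1, len(LANDMARKS), figsize=(15, 4), sharey=True)
    sids = [s.id for s in subjects]
    truth = {s.id: s.truth for s in subjects}
    for ax, lm in zip(axes, LANDMARKS):
        for i, sid in enumerate(sids):
            _, _, ranges = None, None, runio.load_doe1(outdir, sid)[2]
            ax.plot([i, i], [ranges.loc[lm, "min"], ranges.loc[lm, "max"]],
                    color="tab:red", lw=5, alpha=0.7,
                    label="DOE I" if i == 0 else None)
            if sid in validation_ids:
                _, _, envs = runio.load_doe2(outdir, sid)
                ax.plot([i + 0.22, i + 0.22], [envs[lm].min, envs[lm].max],
                        color="tab:blue", lw=5, alpha=0.8,
                        label="DOE II" if sid == validation_ids[0] else None)
            if truth[sid] is not None:
                ax.plot(i, truth[sid][lm], "ko", ms=4,
                        label="observed" if i == 0 else None)
        ax.set_title(lm)
        ax.set_xticks(range(len(sids)), sids, rotation=90, fontsize=7)
        ax.axhline(0, color="0.8", lw=0.5)
    axes[0].set_ylabel("anterior displacement (mm)")
    axes[0].legend(fontsize=7)
    fig.suptitle("Prediction ranges per landmark (baseline = preoperative)")
    fig.tight_layout()
    fig.savefig(outdir / "figures" / "ranges.png", dpi=130)
    plt.close(fig)


def _fig_materials(outdir: Path, fits, pooled: pd.DataFrame) -> None:
    cols = list(pooled.columns)
    fig, axes = plt.subplots(1, len(cols), figsize=(4 * len(cols), 3.2))
    axes = np.atleast_1d(axes)
    for ax, col in zip(axes, cols):
        x = pooled[col].to_numpy()
        ax.hist(x, bins="fd", density=True, color="tab:green", alpha=0.6)
        f = fits[col]
        grid = np.linspace(x.min(), x.max(), 200)
        dist = stats.weibull_min(f.shape, loc=f.location, scale=f.scale)
        ax.plot(grid, dist.pdf(grid), "k-", lw=1.2, label="Weibull fit")
        ax2 = ax.twinx()
        ax2.plot(grid, dist.cdf(grid), "k:", lw=1.0)
        ax2.set_ylim(0, 1.05)
        ax.set_title(f"{col}  (k={f.shape:.2f})", fontsize=9)
        ax.set_xlabel(col)
    axes[0].set_ylabel("density")
    fig.suptitle("Optimised material-property distributions (pooled training data)")
    fig.tight_layout()
    fig.savefig(outdir / "figures" / "materials.png", dpi=130)
    plt.close(fig)


def _fig_envelopes(outdir: Path, sid: str, envelopes) -> None:
    fig, axes = plt.subplots(1, len(LANDMARKS), figsize=(15, 3.2))
    for ax, lm in zip(axes, LANDMARKS):
        env = envelopes[lm]
        counts, edges = env.histogram()
        ax.bar(edges[:-1], counts / counts.sum(), width=np.diff(edges),
               align="edge", color="tab:blue", alpha=0.6)
        cx, cp = env.cdf()
        ax2 = ax.twinx()
        ax2.plot(cx, cp, "k:", lw=1.0)
        ax2.set_ylim(0, 1.05)
        if env.truth is not None:
            ax.annotate("", xy=(env.truth, 0), xytext=(env.truth, -0.08),
                        xycoords=("data", "axes fraction"),
                        arrowprops=dict(arrowstyle="-|>", color="k"))
        ax.set_title(lm)
        ax.set_xlabel("displacement (mm)")
    axes[0].set_ylabel("probability")
    fig.suptitle(f"Subject {sid}: prediction probability histograms "
                 "(arrow = observed)")
    fig.tight_layout()
    fig.savefig(outdir / "figures" / f"envelopes_{sid}.png", dpi=130)
    plt.close(fig)


def _extreme_fields(outdir: Path, sid: str, config, mesh, landmarks, solver):
    """Solve the DOE II rows bounding UL; write VTU fields, return them."""
    design_df, responses, _ = runio.load_doe2(outdir, sid)
    _, frozen = runio.load_screening(outdir)
    fields = {}
    for tag, row_i in (("min", int(responses["UL"].idxmin())),
                       ("max", int(responses["UL"].idxmax()))):
        vals = dict(frozen)
        vals.update({k: float(v) for k, v in design_df.iloc[row_i].items()})
        fld = solver.solve(InputVector(**vals), prony=config.prony,
                           time_grid=default_time_grid(), store="last")
        u = fld.final()
        mesh_io.write_vtu(mesh, outdir / "fields" / f"{sid}_{tag}.vtu",
                          point_data={"displacement": u})
        fields[tag] = u
    return fields


def _fig_midline(outdir: Path, sid: str, mesh, landmarks, fields) -> None:
    skin = mesh.node_sets["skin"]
    mid = skin[np.abs(mesh.nodes[skin, 0]) < 1e-9]
    order = np.argsort(mesh.nodes[mid, 2])
    mid = mid[order]
    z = mesh.nodes[mid, 2]
    y0 = mesh.nodes[mid, 1]
    fig, ax = plt.subplots(figsize=(4.5, 6))
    ax.plot(y0, z, "k-", lw=1.2, label="preoperative")
    lo = y0 + np.minimum(fields["min"][mid, 1], fields["max"][mid, 1])
    hi = y0 + np.maximum(fields["min"][mid, 1], fields["max"][mid, 1])
    ax.fill_betweenx(z, lo, hi, color="tab:blue", alpha=0.4,
                     label="prediction range")
    lm_idx = {k: v for k, v in landmarks.indices.items() if k in ("N", "UL", "LL")}
    for name, idx in lm_idx.items():
        xyz = mesh.nodes[idx]
        ax.plot(xyz[1], xyz[2], "k.", ms=5)
        ax.annotate(name, (xyz[1], xyz[2]), textcoords="offset points",
                    xytext=(4, 0), fontsize=8)
    ax.set_xlabel("anterior position y (mm)")
    ax.set_ylabel("superior position z (mm)")
    ax.legend(fontsize=8)
    ax.set_title(f"Subject {sid}: midline profile prediction band")
    fig.tight_layout()
    fig.savefig(outdir / "figures" / f"midline_{sid}.png", dpi=130)
    plt.close(fig)


def generate_report(outdir) -> dict:
    """Build all report artifacts from a completed run directory.

    Raises :class:`IncompleteRunError` listing the first missing stage if
    the run directory is incomplete.  Returns the summary dict.
    """
    outdir = Path(outdir)
    config = runio.load_config(outdir)
    mesh, landmarks = runio.load_phantom(outdir)
    subjects = runio.load_subjects(outdir)
    selected, frozen = runio.load_screening(outdir)
    fits = runio.load_weibull(outdir)
    pooled = pd.read_csv(_need(outdir / "pooled.csv", "fitdist"))
    validation = runio.load_validation(outdir)

    (outdir / "figures").mkdir(exist_ok=True)
    (outdir / "fields").mkdir(exist_ok=True)

    validation_ids = [sid for sid in config.validation]
    envs_by_sid = {}
    for sid in validation_ids:
        _, _, envs = runio.load_doe2(outdir, sid)
        if not envs:
            raise IncompleteRunError(f"empty envelope set for subject {sid}")
        envs_by_sid[sid] = envs

    _fig_ranges(outdir, subjects, validation_ids)
    _fig_materials(outdir, fits, pooled)
    solver = ViscoelasticSolver(mesh)
    for sid in validation_ids:
        _fig_envelopes(outdir, sid, envs_by_sid[sid])
        fields = _extreme_fields(outdir, sid, config, mesh, landmarks, solver)
        _fig_midline(outdir, sid, mesh, landmarks, fields)

    summary = {
        "config": asdict(config),
        "selected": selected,
        "frozen": frozen,
        "weibull": {k: f.to_dict() for k, f in sorted(fits.items())},
        "doe1_ranges": {
            s.id: runio.load_doe1(outdir, s.id)[2].to_dict() for s in subjects
        },
        "envelopes": {
            sid: {lm: e.to_dict() for lm, e in sorted(envs.items())}
            for sid, envs in sorted(envs_by_sid.items())
        },
        "validation": validation.to_dict(orient="records"),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
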