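"""File-backed artifacts of the pipeline stages.

Every stage consumes and produces plain files (CSV, JSON, YAML, MSH/VTU)
inside a run directory, so any stage can be rerun in isolation:

    run/
      config.yaml
      phantom.msh, phantom.vtu, landmarks.json, node_sets.json
      subjects.csv
      screening.csv, screening.json
      doe1/<sid>_design.csv, _responses.csv, _ranges.csv, _bounds.json
      optimize/<sid>_candidates.csv
      pooled.csv, weibull.json
      doe2/<sid>_design.csv, _responses.csv, _envelopes.json
      validation.csv
      cache.json, log.jsonl
      figures/, fields/, summary.json     (report stage)
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import mesh_io
from .dist_fit import WeibullFit
from .fem_core import INPUT_FIELDS, InputVector
from .mesh import LANDMARKS, LabeledTetMesh, LandmarkSet
from .pipeline import PipelineConfig, PredictionEnvelope, Subject
from .surrogate_opt import ParetoCandidates
from .uq_design import CorrelationTable, DOEDesign


class IncompleteRunError(FileNotFoundError):
    """A stage's required input artifacts are missing from the run dir."""


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise IncompleteRunError(
            f"missing artifact {path.name!r}; run the {stage!r} stage first"
        )
    return path


def log_stage(outdir, stage: str, seed: int, t_start: float, **extra) -> None:
    rec = {
        "stage": stage,
        "seed": seed,
        "wall_s": round(time.time() - t_start, 3),
        **extra,
    }
    with (Path(outdir) / "log.jsonl").open("a") as fh:
        fh.write(json.dumps(rec, sort_keys=True) + "\n")


# -- phantom ----------------------------------------------------------------


def save_phantom(outdir, mesh: LabeledTetMesh, landmarks: LandmarkSet) -> None:
    outdir = Path(outdir)
    mesh_io.write_msh(mesh, outdir / "phantom.msh")
    mesh_io.write_vtu(mesh, outdir / "phantom.vtu")
    mesh_io.write_landmarks(landmarks, outdir / "landmarks.json")
    mesh_io.write_node_sets(mesh, outdir / "node_sets.json")
    if mesh.patch_ids is not None:
        (outdir / "patch_ids.json").write_text(
            json.dumps(np.asarray(mesh.patch_ids).tolist()) + "\n"
        )


def load_phantom(outdir) -> tuple[LabeledTetMesh, LandmarkSet]:
    outdir = Path(outdir)
    mesh = mesh_io.read_msh(_need(outdir / "phantom.msh", "phantom"))
    mesh.node_sets = mesh_io.read_node_sets(_need(outdir / "node_sets.json", "phantom"))
    patches = outdir / "patch_ids.json"
    if patches.exists():
        mesh.patch_ids = np.asarray(json.loads(patches.read_text()), dtype=np.int64)
    landmarks = mesh_io.read_landmarks(_need(outdir / "landmarks.json", "phantom"))
    return mesh, landmarks


# -- subjects ---------------------------------------------------------------


def save_subjects(outdir, subjects: list[Subject]) -> None:
    rows = []
    for s in subjects:
        row = {"id": s.id, "planned_advancement": s.planned_advancement}
        row.update({f"true_{k}": v for k, v in s.true_inputs.as_dict().items()})
        if s.truth is not None:
            row.update({f"truth_{lm}": s.truth[lm] for lm in LANDMARKS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(outdir) / "subjects.csv", index=False)


def load_subjects(outdir) -> list[Subject]:
    df = pd.read_csv(_need(Path(outdir) / "subjects.csv", "phantom"))
    subjects = []
    for _, r in df.iterrows():
        truth = None
        if f"truth_{LANDMARKS[0]}" in df.columns:
            truth = {lm: float(r[f"truth_{lm}"]) for lm in LANDMARKS}
        subjects.append(
            Subject(
                id=str(r["id"]),
                planned_advancement=float(r["planned_advancement"]),
                true_inputs=InputVector(
                    **{k: float(r[f"true_{k}"]) for k in INPUT_FIELDS}
                ),
                truth=truth,
            )
        )
    return subjects


# -- screening --------------------------------------------------------------


def save_screening(outdir, table: CorrelationTable) -> None:
    outdir = Path(outdir)
    table.to_csv(outdir / "screening.csv")
    (outdir / "screening.json").write_text(
        json.dumps(table.summary_dict(), indent=2, sort_keys=True) + "\n"
    )


def load_screening(outdir) -> tuple[list[str], dict[str, float]]:
    d = json.loads(_need(Path(outdir) / "screening.json", "screen").read_text())
    return list(d["selected"]), {k: float(v) for k, v in d["frozen"].items()}


# -- designs ----------------------------------------------------------------


def save_design(path_stem: Path, design: DOEDesign) -> None:
    design.to_csv(path_stem.with_suffix(".csv"))
    meta = {
        "bounds": {k: list(v) for k, v in design.bounds.items()},
        "method": design.method,
        "seed": design.seed,
    }
    path_stem.parent.joinpath(path_stem.stem + "_bounds.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def load_design(path_stem: Path, stage: str) -> DOEDesign:
    samples = pd.read_csv(_need(path_stem.with_suffix(".csv"), stage))
    meta = json.loads(
        _need(path_stem.parent / (path_stem.stem + "_bounds.json"), stage).read_text()
    )
    return DOEDesign(
        samples=samples,
        bounds={k: tuple(v) for k, v in meta["bounds"].items()},
        method=meta["method"],
        seed=int(meta["seed"]),
    )


def save_doe1(outdir, sid: str, design, responses, ranges) -> None:
    d = Path(outdir) / "doe1"
    d.mkdir(exist_ok=True)
    save_design(d / f"{sid}_design", design)
    responses.to_csv(d / f"{sid}_responses.csv", index=False)
    ranges.to_csv(d / f"{sid}_ranges.csv")


def load_doe1(outdir, sid: str):
    d = Path(outdir) / "doe1"
    design = load_design(d / f"{sid}_design", "doe1")
    responses = pd.read_csv(_need(d / f"{sid}_responses.csv", "doe1"))
    ranges = pd.read_csv(_need(d / f"{sid}_ranges.csv", "doe1"), index_col=0)
    return design, responses, ranges


# -- optimisation -----------------------------------------------------------


def save_candidates(outdir, sid: str, cands: ParetoCandidates) -> None:
    d = Path(outdir) / "optimize"
    d.mkdir(exist_ok=True)
    cands.to_csv(d / f"{sid}_candidates.csv")


def load_candidates(outdir, sid: str, bounds) -> ParetoCandidates:
    d = Path(outdir) / "optimize"
    df = pd.read_csv(_need(d / f"{sid}_candidates.csv", "optimize"))
    mat_cols = [c for c in df.columns if not c.startswith("obj_")]
    obj_cols = [c for c in df.columns if c.startswith("obj_")]
    return ParetoCandidates(
        candidates=df[mat_cols],
        objectives=df[obj_cols].rename(columns=lambda c: c[4:]),
        bounds={c: tuple(bounds[c]) for c in mat_cols},
    )


# -- distribution fits ------------------------------------------------------


def save_weibull(outdir, fits: dict[str, WeibullFit], pooled: pd.DataFrame) -> None:
    outdir = Path(outdir)
    (outdir / "weibull.json").write_text(
        json.dumps({k: f.to_dict() for k, f in sorted(fits.items())},
                   indent=2, sort_keys=True) + "\n"
    )
    pooled.to_csv(outdir / "pooled.csv", index=False)


def load_weibull(outdir) -> dict[str, WeibullFit]:
    d = json.loads(_need(Path(outdir) / "weibull.json", "fitdist").read_text())
    return {k: WeibullFit.from_dict(v) for k, v in d.items()}


# -- second design ----------------------------------------------------------


def save_doe2(outdir, sid: str, design_df, responses, envelopes) -> None:
    d = Path(outdir) / "doe2"
    d.mkdir(exist_ok=True)
    design_df.to_csv(d / f"{sid}_design.csv", index=False)
    responses.to_csv(d / f"{sid}_responses.csv", index=False)
    (d / f"{sid}_envelopes.json").write_text(
        json.dumps({lm: e.to_dict() for lm, e in sorted(envelopes.items())},
                   indent=2, sort_keys=True) + "\n"
    )


def load_doe2(outdir, sid: str):
    d = Path(outdir) / "doe2"
    design_df = pd.read_csv(_need(d / f"{sid}_design.csv", "doe2"))
    responses = pd.read_csv(_need(d / f"{sid}_responses.csv", "doe2"))
    raw = json.loads(_need(d / f"{sid}_envelopes.json", "doe2").read_text())
    envelopes = {
        lm: PredictionEnvelope(
            landmark=lm, samples=np.asarray(v["samples"]), truth=v["truth"]
        )
        for lm, v in raw.items()
    }
    return design_df, responses, envelopes


def save_validation(outdir, frames: dict[str, pd.DataFrame]) -> None:
    out = []
    for sid, df in frames.items():
        df = df.copy()
        df.insert(0, "subject", sid)
        out.append(df)
    pd.concat(out, ignore_index=True).to_csv(
        Path(outdir) / "validation.csv", index=False
    )


def load_validation(outdir) -> pd.DataFrame:
    return pd.read_csv(_need(Path(outdir) / "validation.csv", "validate"))


def load_config(outdir) -> PipelineConfig:
    return PipelineConfig.from_yaml(_need(Path(outdir) / "config.yaml", "init"))
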