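"""Model/Results interface to the probabilistic prediction pipeline.

:class:`MaxillaryAdvancementUQ` is built from a cohort table and a
:class:`~facefem.pipeline.PipelineConfig`; ``fit()`` runs the training
half of the pipeline (screening, first design of experiments, per-subject
optimisation, Weibull fits) and returns a :class:`UQResults` carrying the
estimated material-property distributions, their diagnostics and a
``summary()`` table.  ``UQResults.predict()`` runs the probabilistic
second design on held-out subjects and returns per-landmark prediction
envelopes plus the containment validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pipeline as pl
from .cohort import load_cohort_table
from .dist_fit import WeibullFit
from .fem_core import ViscoelasticSolver, table2_bounds
from .mesh import LANDMARKS, LabeledTetMesh, LandmarkSet
from .phantom import build_phantom
from .surrogate_opt import ParetoCandidates, Surrogate
from .uq_design import CorrelationTable

__all__ = ["MaxillaryAdvancementUQ", "UQResults"]


class MaxillaryAdvancementUQ:
    """Probabilistic soft-tissue prediction model for maxillary advancement.

    Parameters
    ----------
    cohort : DataFrame, optional
        Subject table (defaults to the packaged eight-subject cohort).
    config : PipelineConfig, optional
        Pipeline settings; defaults to the desk preset with seed 0.

    Examples
    --------
    >>> model = MaxillaryAdvancementUQ()
    >>> res = model.fit()                      # doctest: +SKIP
    >>> print(res.summary())                   # doctest: +SKIP
    >>> pred = res.predict()                   # doctest: +SKIP
    """

    def __init__(self, cohort: pd.DataFrame | None = None,
                 config: pl.PipelineConfig | None = None):
        self.cohort = cohort if cohort is not None else load_cohort_table()
        self.config = config or pl.desk_config()
        self.mesh: LabeledTetMesh | None = None
        self.landmarks: LandmarkSet | None = None
        self.solver: ViscoelasticSolver | None = None

    @classmethod
    def from_config(cls, path) -> "MaxillaryAdvancementUQ":
        return cls(config=pl.PipelineConfig.from_yaml(path))

    def _ensure_phantom(self):
        if self.mesh is None:
            self.mesh, self.landmarks = build_phantom(self.config.geometry)
            self.solver = ViscoelasticSolver(self.mesh)
        return self.mesh, self.landmarks, self.solver

    def fit(self, cache: pl.SolveCache | None = None) -> "UQResults":
        """Run screening, DOE I, optimisation and the distribution fits."""
        cfg = self.config
        mesh, landmarks, solver = self._ensure_phantom()
        subjects = pl.make_subjects(cfg, self.cohort)
        pl.observe_subjects(subjects, mesh, landmarks, cfg, solver)
        by_id = {s.id: s for s in subjects}

        screen_subject = by_id[cfg.screening_subject]
        screening, screen_design, screen_resp = pl.run_screening(
            mesh, landmarks, cfg, screen_subject.planned_advancement,
            solver=solver, cache=cache,
        )
        selected = screening.selected_inputs()
        frozen = dict(screening.frozen_values)

        doe1 = {}
        for s in subjects:
            design, resp, ranges = pl.run_doe1(
                mesh, landmarks, cfg, s, selected, frozen,
                solver=solver, cache=cache,
            )
            doe1[s.id] = {"design": design, "responses": resp, "ranges": ranges}

        surrogates, candidates = {}, {}
        for sid in cfg.training:
            s = by_id[sid]
            sur, cand = pl.run_optimization(
                doe1[sid]["design"], doe1[sid]["responses"], s, cfg, selected
            )
            surrogates[sid], candidates[sid] = sur, cand

        fits, pooled = pl.run_distribution_fit(
            [candidates[sid] for sid in cfg.training], bounds=table2_bounds()
        )
        return UQResults(
            model=self,
            config=cfg,
            subjects=subjects,
            screening=screening,
            selected=selected,
            frozen=frozen,
            doe1=doe1,
            surrogates=surrogates,
            candidates=candidates,
            pooled=pooled,
            weibull_fits=fits,
        )


@dataclass
class UQResults:
    """Fitted pipeline state: distributions, diagnostics, predictions."""

    model: MaxillaryAdvancementUQ
    config: pl.PipelineConfig
    subjects: list[pl.Subject]
    screening: CorrelationTable
    selected: list[str]
    frozen: dict[str, float]
    doe1: dict[str, dict]
    surrogates: dict[str, Surrogate]
    candidates: dict[str, ParetoCandidates]
    pooled: pd.DataFrame
    weibull_fits: dict[str, WeibullFit]
    predictions: dict[str, dict] = field(default_factory=dict)

    def subject(self, sid: str) -> pl.Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def predict(
        self,
        subject_ids: list[str] | None = None,
        n_runs: int | None = None,
        cache: pl.SolveCache | None = None,
    ) -> dict[str, dict]:
        """Probabilistic second design on the given (default validation)
        subjects; returns {subject: {design, responses, envelopes,
        validation}} and stores it on the results object."""
        cfg = self.config
        mesh, landmarks, solver = self.model._ensure_phantom()
        out = {}
        for sid in subject_ids or cfg.validation:
            s = self.subject(sid)
            design_df, resp, envs = pl.run_doe2(
                mesh, landmarks, cfg, s, self.weibull_fits, self.frozen,
                n_runs=n_runs, solver=solver, cache=cache,
            )
            ranges = self.doe1[sid]["ranges"] if sid in self.doe1 else None
            val = pl.validate_envelopes(envs, s.truth, ranges)
            out[sid] = {
                "design": design_df,
                "responses": resp,
                "envelopes": envs,
                "validation": val,
            }
        self.predictions.update(out)
        return out

    # -- reporting ---------------------------------------------------------

    def screening_summary(self) -> pd.DataFrame:
        return self.screening.r_matrix().reindex(columns=list(LANDMARKS))

    def weibull_table(self) -> pd.DataFrame:
        rows = []
        for name, f in self.weibull_fits.items():
            rows.append(
                {"parameter": name, "shape": f.shape, "scale": f.scale,
                 "location": f.location, "n": f.n, "ks": f.ks,
                 "mean": f.mean()}
            )
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        """Plain-text summary table of the fitted pipeline."""
        cfg = self.config
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Probabilistic soft-tissue prediction - maxillary advancement")
        lines.append("=" * w)
        lines.append(
            f"subjects: {len(self.subjects)}   training: {','.join(cfg.training)}"
            f"   validation: {','.join(cfg.validation)}"
        )
        lines.append(
            f"preset: {cfg.preset}   seed: {cfg.seed}   "
            f"mesh: {self.model.mesh.n_nodes} nodes / {self.model.mesh.n_tets} tets"
        )
        lines.append("-" * w)
        lines.append(f"screened inputs (n={self.screening.n} runs, "
                     f"alpha={self.screening.alpha}):")
        lines.append("  selected: " + ", ".join(self.selected))
        if self.frozen:
            lines.append(
                "  frozen:   "
                + ", ".join(f"{k}={v:g}" for k, v in self.frozen.items())
            )
        lines.append("-" * w)
        lines.append("Spearman r (inputs x landmarks):")
        lines.append(self.screening_summary().round(2).to_string())
        lines.append("-" * w)
        lines.append(
            f"optimised candidates: {len(self.candidates)} subjects x "
            f"{next(iter(self.candidates.values())).m if self.candidates else 0} "
            f"candidates -> pooled n={len(self.pooled)}"
        )
        lines.append("fitted Weibull material distributions:")
        lines.append(self.weibull_table().round(4).to_string())
        if self.predictions:
            lines.append("-" * w)
            for sid, p in self.predictions.items():
                v = p["validation"]
                lines.append(f"subject {sid} prediction envelopes (mm):")
                cols = ["landmark", "min", "max", "truth", "contains_truth"]
                if "refined" in v.columns:
                    cols.append("refined")
                lines.append(v[cols].round(3).to_string(index=False))
        lines.append("=" * w)
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        """Machine-readable run summary (deterministic key order)."""
        d = {
            "preset": self.config.preset,
            "seed": self.config.seed,
            "selected": list(self.selected),
            "frozen": {k: float(v) for k, v in sorted(self.frozen.items())},
            "weibull": {k: f.to_dict() for k, f in sorted(self.weibull_fits.items())},
            "doe1_ranges": {
                sid: self.doe1[sid]["ranges"].round(9).to_dict()
                for sid in sorted(self.doe1)
            },
            "subjects": {
                s.id: {
                    "planned_advancement": s.planned_advancement,
                    "truth": s.truth,
                }
                for s in self.subjects
            },
        }
        if self.predictions:
            d["predictions"] = {
                sid: {
                    lm: env.to_dict()
                    for lm, env in sorted(p["envelopes"].items())
                }
                for sid, p in sorted(self.predictions.items())
            }
        return d
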