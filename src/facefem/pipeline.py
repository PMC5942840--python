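"""Two-iteration probabilistic prediction pipeline.

Stages (each consumes and produces plain files when driven by the CLI, or
in-memory objects when driven by :mod:`facefem.model`):

1. *screen* — Latin-hypercube sweep of all eight uncertain inputs on the
   screening subject, Spearman selection of the influential ones.
2. *doe1* — per-subject space-filling design over the selected inputs
   (uniform literature ranges), one forward solve per row, per-landmark
   prediction ranges.
3. *optimize* — per training subject, response-surface surrogates and a
   goal-driven NSGA-II against the observed landmark displacements; best
   candidates retained.
4. *fitdist* — candidates pooled across training subjects, one Weibull
   fit per material parameter.
5. *doe2* — per validation subject, designs drawn from the fitted
   distributions (advancement stays uniform within plan +/- 2 mm), one
   solve per row, per-landmark prediction envelopes with histograms and
   cumulative densities.
6. *validate* — truth containment and range-refinement checks.

"Subjects" are phantom replicates: each cohort row gets hidden true
material properties (population reference plus small jitter) and an
achieved advancement near its planned value; synthetic truth stands in
for the postoperative CBCT measurement.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dist_fit, uq_design
from .cohort import load_cohort_table
from .fem_core import (
    MATERIAL_FIELDS,
    InputVector,
    PronySeries,
    ViscoelasticSolver,
    default_prony,
    default_time_grid,
    extract_landmarks,
    table2_bounds,
)
from .mesh import LANDMARKS, LabeledTetMesh, LandmarkSet
from .phantom import GeometryParams, synthesize_truth
from .surrogate_opt import (
    MOGAConfig,
    OptimizationTargets,
    ParetoCandidates,
    Surrogate,
    fit_surrogate,
    optimize_materials,
)

__all__ = [
    "PipelineConfig",
    "Subject",
    "PredictionEnvelope",
    "desk_config",
    "paper_config",
    "make_subjects",
    "population_truth",
    "run_screening",
    "run_doe1",
    "run_optimization",
    "run_distribution_fit",
    "run_doe2",
    "validate_envelopes",
    "SolveCache",
]

_STAGE_OFFSETS = {
    "subjects": 11,
    "truth": 23,
    "screen": 37,
    "doe1": 53,
    "optimize": 71,
    "doe2": 89,
}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage (and per-subject) seed below 2^31."""
    return (master * 9973 + _STAGE_OFFSETS[stage] * 131 + index) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with explicit per-stage seeding.

    ``preset`` is "desk" (default; halved genetic-algorithm population)
    or "paper" (1000 solutions per iteration).  ``doe1_runs`` defaults to
    the central-composite sizing for the number of selected variables;
    ``doe2_runs`` defaults to the DOE I size.
    """

    preset: str = "desk"
    seed: int = 0
    geometry: GeometryParams = field(default_factory=GeometryParams)
    prony: PronySeries = field(default_factory=default_prony)
    noise_sd: float = 0.1
    material_jitter_frac: float = 0.05
    advancement_error_sd: float = 0.75
    screening_runs: int = 100
    screening_subject: str = "P1"
    doe1_runs: int | None = None
    doe2_runs: int | None = None
    training: tuple[str, ...] = ("P2", "P3", "P5", "P7", "P8")
    validation: tuple[str, ...] = ("P1", "P4", "P6")
    moga: MOGAConfig = field(default_factory=lambda: MOGAConfig(population=500))

    def __post_init__(self) -> None:
        self.training = tuple(self.training)
        self.validation = tuple(self.validation)
        if set(self.training) & set(self.validation):
            raise ValueError("training and validation subject sets must be disjoint")

    def bounds_for(self, planned_advancement: float) -> dict:
        return table2_bounds(planned_advancement)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            g = dict(d["geometry"])
            if "cartilage_z" in g:
                g["cartilage_z"] = tuple(g["cartilage_z"])
            d["geometry"] = GeometryParams(**g)
        if "prony" in d and isinstance(d["prony"], dict):
            d["prony"] = PronySeries(
                g=tuple(d["prony"]["g"]), tau=tuple(d["prony"]["tau"])
            )
        if "moga" in d and isinstance(d["moga"], dict):
            d["moga"] = MOGAConfig(**d["moga"])
        for key in ("training", "validation"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def desk_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale preset: halved genetic-algorithm population."""
    return PipelineConfig(preset="desk", seed=seed)


def paper_config(seed: int = 0) -> PipelineConfig:
    """Reference-scale preset: 1000 solutions per optimisation iteration."""
    return PipelineConfig(preset="paper", seed=seed, moga=MOGAConfig(population=1000))


# ---------------------------------------------------------------------------
# Synthetic subjects
# ---------------------------------------------------------------------------


@dataclass
class Subject:
    """One phantom replicate: plan, hidden truth and observed landmarks."""

    id: str
    planned_advancement: float
    true_inputs: InputVector
    truth: dict[str, float] | None = None  # observed landmark displacements

    def truth_array(self) -> np.ndarray:
        return np.array([self.truth[k] for k in LANDMARKS])


def population_truth(bounds: dict | None = None) -> InputVector:
    """Hidden population-level material truth.

    Young's moduli sit at the geometric mean of their range (they span an
    order of magnitude), Poisson ratios and the relaxation scale at the
    midpoint.
    """
    b = bounds or table2_bounds()
    vals = {}
    for name, (lo, hi) in b.items():
        if name.startswith("E_"):
            vals[name] = float(np.sqrt(lo * hi))
        else:
            vals[name] = 0.5 * (lo + hi)
    return InputVector(**vals)


def make_subjects(
    config: PipelineConfig,
    cohort: pd.DataFrame | None = None,
) -> list[Subject]:
    """Per-subject hidden truths from the cohort plans.

    Materials are the population truth plus truncated-normal jitter
    (``material_jitter_frac`` of each range, clipped to the range); the
    achieved advancement is the plan plus a truncated-normal execution
    error (sd ``advancement_error_sd`` mm, clipped at +/- 2 mm).
    """
    cohort = cohort if cohort is not None else load_cohort_table()
    bounds = table2_bounds()
    pop = population_truth(bounds)
    subjects = []
    for i, row in cohort.reset_index(drop=True).iterrows():
        rng = np.random.default_rng(stage_seed(config.seed, "subjects", i))
        vals = {}
        for name in MATERIAL_FIELDS + ("E_bone", "nu_bone", "nu_cart"):
            lo, hi = bounds[name]
            sd = config.material_jitter_frac * (hi - lo)
            v = getattr(pop, name) + rng.normal(0.0, sd)
            vals[name] = float(np.clip(v, lo, hi))
        planned = float(row["planned_maxillary_advancement_mm"])
        err = np.clip(rng.normal(0.0, config.advancement_error_sd), -2.0, 2.0)
        vals["x_adv"] = planned + float(err)
        subjects.append(
            Subject(
                id=str(row["patient"]),
                planned_advancement=planned,
                true_inputs=InputVector(**vals),
            )
        )
    return subjects


def observe_subjects(
    subjects: list[Subject],
    mesh: LabeledTetMesh,
    landmarks: LandmarkSet,
    config: PipelineConfig,
    solver: ViscoelasticSolver | None = None,
) -> None:
    """Attach synthetic "postoperative" landmark observations to subjects."""
    solver = solver or ViscoelasticSolver(mesh)
    for i, s in enumerate(subjects):
        disp = synthesize_truth(
            mesh,
            landmarks,
            s.true_inputs,
            noise_sd=config.noise_sd,
            seed=stage_seed(config.seed, "truth", i),
            prony=config.prony,
            solver=solver,
        )
        s.truth = {k: float(v) for k, v in zip(LANDMARKS, disp)}


# ---------------------------------------------------------------------------
# Forward-solve caching
# ---------------------------------------------------------------------------


class SolveCache:
    """Landmark-displacement cache keyed by a hash of the solve inputs.

    Optionally file-backed (JSON) so that a rerun with an unchanged
    configuration performs zero new forward solves.
    """

    def __init__(self, path=None):
        self.path = path
        self._store: dict[str, list[float]] = {}
        self.hits = 0
        self.misses = 0
        if path is not None:
            try:
                with open(path) as fh:
                    self._store = json.load(fh)
            except (OSError, json.JSONDecodeError):
                self._store = {}

    @staticmethod
    def key(inputs: InputVector, tag: str = "") -> str:
        payload = json.dumps(
            {k: round(v, 12) for k, v in inputs.as_dict().items()}, sort_keys=True
        ) + tag
        return hashlib.sha1(payload.encode()).hexdigest()

    def get(self, key: str):
        v = self._store.get(key)
        if v is not None:
            self.hits += 1
        return None if v is None else np.asarray(v)

    def put(self, key: str, value: np.ndarray) -> None:
        self.misses += 1
        self._store[key] = [float(x) for x in value]

    def save(self) -> None:
        if self.path is not None:
            with open(self.path, "w") as fh:
                json.dump(self._store, fh)


def _solve_rows(
    design_df: pd.DataFrame,
    frozen: dict[str, float],
    solver: ViscoelasticSolver,
    landmarks: LandmarkSet,
    config: PipelineConfig,
    cache: SolveCache | None = None,
) -> pd.DataFrame:
    """One forward solve per design row; returns the landmark table."""
    tag = f"mesh{solver.mesh.n_nodes}x{solver.mesh.n_tets}"
    grid = default_time_grid()
    out = []
    for _, row in design_df.iterrows():
        vals = dict(frozen)
        vals.update({k: float(v) for k, v in row.items()})
        iv = InputVector(**vals)
        key = SolveCache.key(iv, tag)
        disp = cache.get(key) if cache is not None else None
        if disp is None:
            try:
                fld = solver.solve(iv, prony=config.prony, time_grid=grid, store="last")
            except Exception as err:
                raise RuntimeError(
                    f"forward solve failed for inputs {iv.as_dict()}: {err}"
                ) from err
            disp = extract_landmarks(fld, landmarks)
            if cache is not None:
                cache.put(key, disp)
        out.append(disp)
    return pd.DataFrame(np.asarray(out), columns=list(LANDMARKS))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_screening(
    mesh: LabeledTetMesh,
    landmarks: LandmarkSet,
    config: PipelineConfig,
    planned_advancement: float,
    solver: ViscoelasticSolver | None = None,
    cache: SolveCache | None = None,
):
    """Variable-correlation screen on the screening subject.

    Returns (CorrelationTable, design, responses).
    """
    solver = solver or ViscoelasticSolver(mesh)
    bounds = config.bounds_for(planned_advancement)
    design = uq_design.sample_design(
        bounds, n_samples=config.screening_runs,
        seed=stage_seed(config.seed, "screen"),
    )
    responses = _solve_rows(design.samples, {}, solver, landmarks, config, cache)
    table = uq_design.screen_variables(
        design.samples, responses, alpha=0.05, bounds=bounds
    )
    return table, design, responses


def run_doe1(
    mesh: LabeledTetMesh,
    landmarks: LandmarkSet,
    config: PipelineConfig,
    subject: Subject,
    selected: list[str],
    frozen: dict[str, float],
    solver: ViscoelasticSolver | None = None,
    cache: SolveCache | None = None,
):
    """First design iteration for one subject: uniform selected ranges.

    Returns (design, responses, ranges) where ranges is a per-landmark
    (min, max) DataFrame.
    """
    solver = solver or ViscoelasticSolver(mesh)
    bounds = config.bounds_for(subject.planned_advancement)
    var_bounds = {k: bounds[k] for k in selected}
    n = config.doe1_runs or uq_design.design_size(len(selected))
    design = uq_design.sample_design(
        var_bounds, n_samples=n,
        seed=stage_seed(config.seed, "doe1", _subject_index(subject.id)),
    )
    frozen_full = {k: v for k, v in frozen.items() if k not in selected}
    responses = _solve_rows(design.samples, frozen_full, solver, landmarks,
                            config, cache)
    ranges = pd.DataFrame(
        {"min": responses.min(axis=0), "max": responses.max(axis=0)}
    )
    return design, responses, ranges


def _subject_index(subject_id: str) -> int:
    try:
        return int(str(subject_id).lstrip("P"))
    except ValueError:
        return abs(hash(subject_id)) % 1000


def run_optimization(
    design: uq_design.DOEDesign,
    responses: pd.DataFrame,
    subject: Subject,
    config: PipelineConfig,
    selected: list[str],
) -> tuple[Surrogate, ParetoCandidates]:
    """Surrogate fit + goal-driven optimisation for one training subject.

    The advancement is fixed at the subject's planned value; the free
    variables are the selected material parameters.
    """
    if subject.truth is None:
        raise ValueError(f"subject {subject.id} has no observed landmarks")
    surrogate = fit_surrogate(design, responses,
                              seed=stage_seed(config.seed, "optimize"))
    material_cols = [c for c in selected if c in MATERIAL_FIELDS]
    if not material_cols:
        raise ValueError("no material parameters were selected for optimisation")
    mat_bounds = {c: design.bounds[c] for c in material_cols}
    fixed = {"x_adv": subject.planned_advancement}
    for c in design.bounds:
        if c not in material_cols and c != "x_adv":
            fixed[c] = 0.5 * (design.bounds[c][0] + design.bounds[c][1])
    targets = OptimizationTargets(targets=subject.truth)
    cands = optimize_materials(
        surrogate, targets, mat_bounds, fixed, config=config.moga,
        seed=stage_seed(config.seed, "optimize", _subject_index(subject.id)),
    )
    return surrogate, cands


def run_distribution_fit(
    candidate_sets: list[ParetoCandidates],
    bounds: dict[str, tuple[float, float]] | None = None,
) -> dict[str, dist_fit.WeibullFit]:
    """Pool training candidates and fit one Weibull per material column.

    Returns (fits, pooled).  A fit whose Kolmogorov-Smirnov statistic
    exceeds the 5 % critical value is reported with a warning (the pooled
    candidates mix five subjects, so mild lack-of-fit is expected), never
    an error.
    """
    pooled = dist_fit.pool_candidates(candidate_sets)
    bounds = bounds or table2_bounds()
    fits = {
        col: dist_fit.fit_weibull(pooled[col].to_numpy(), bounds=bounds[col])
        for col in pooled.columns
    }
    for col, f in fits.items():
        crit = 1.358 / np.sqrt(f.n)  # asymptotic 5 % KS critical value
        if f.ks > crit:
            warnings.warn(
                f"Weibull fit for {col!r}: KS statistic {f.ks:.3f} exceeds "
                f"the 5% critical value {crit:.3f} (pooled multi-subject "
                "data); fit retained",
                stacklevel=2,
            )
    return fits, pooled


@dataclass
class PredictionEnvelope:
    """Per-landmark probabilistic prediction from the second design."""

    landmark: str
    samples: np.ndarray
    truth: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("envelope needs at least one sample")

    @property
    def min(self) -> float:
        return float(self.samples.min())

    @property
    def max(self) -> float:
        return float(self.samples.max())

    @property
    def width(self) -> float:
        return self.max - self.min

    def histogram(self, bins="fd") -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin_edges); Freedman-Diaconis binning by default."""
        if np.ptp(self.samples) == 0:
            v = self.samples[0]
            return np.array([self.samples.size]), np.array([v - 0.5, v + 0.5])
        try:
            counts, edges = np.histogram(self.samples, bins=bins)
        except (ValueError, MemoryError):
            counts, edges = np.histogram(self.samples, bins="sturges")
        if np.ptp(self.samples) > 0 and len(counts) == 1:
            counts, edges = np.histogram(self.samples, bins="sturges")
        return counts, edges

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical cumulative density (x sorted, p)."""
        x = np.sort(self.samples)
        return x, np.arange(1, x.size + 1) / x.size

    @property
    def contains_truth(self) -> bool | None:
        if self.truth is None:
            return None
        return bool(self.min <= self.truth <= self.max)

    @property
    def distance_to_range(self) -> float | None:
        if self.truth is None:
            return None
        if self.truth < self.min:
            return float(self.min - self.truth)
        if self.truth > self.max:
            return float(self.truth - self.max)
        return 0.0

    def to_dict(self) -> dict:
        counts, edges = self.histogram()
        cx, cp = self.cdf()
        return {
            "landmark": self.landmark,
            "min": self.min,
            "max": self.max,
            "n": int(self.samples.size),
            "hist_counts": counts.tolist(),
            "hist_edges": [float(e) for e in edges],
            "cdf_x": [float(v) for v in cx],
            "cdf_p": [float(v) for v in cp],
            "truth": self.truth,
            "contains_truth": self.contains_truth,
            "distance_to_range": self.distance_to_range,
            "samples": [float(v) for v in self.samples],
        }


def run_doe2(
    mesh: LabeledTetMesh,
    landmarks: LandmarkSet,
    config: PipelineConfig,
    subject: Subject,
    fits: dict[str, dist_fit.WeibullFit],
    frozen: dict[str, float],
    n_runs: int | None = None,
    solver: ViscoelasticSolver | None = None,
    cache: SolveCache | None = None,
):
    """Second design iteration for one subject.

    Material parameters are drawn from the fitted Weibull distributions
    (stratified through a Latin hypercube, truncated to their physical
    bounds; the soft-tissue Poisson ratio is additionally capped at
    0.4999); the advancement stays uniform within plan +/- 2 mm.

    Returns (design_df, responses, envelopes).
    """
    solver = solver or ViscoelasticSolver(mesh)
    bounds = config.bounds_for(subject.planned_advancement)
    cols = list(fits) + ["x_adv"]
    n = n_runs or config.doe2_runs or uq_design.design_size(len(cols))
    unit = uq_design.sample_design(
        {c: (0.0, 1.0) for c in cols}, n_samples=n,
        seed=stage_seed(config.seed, "doe2", _subject_index(subject.id)),
    ).samples
    data = {}
    for c in fits:
        lo, hi = bounds[c]
        if c == "nu_soft":
            hi = min(hi, 0.4999)
        data[c] = dist_fit.sample_distribution(
            fits[c], n, bounds=(lo, hi), unit_samples=unit[c].to_numpy()
        )
    lo, hi = bounds["x_adv"]
    data["x_adv"] = lo + unit["x_adv"].to_numpy() * (hi - lo)
    design_df = pd.DataFrame(data)
    frozen_full = {k: v for k, v in frozen.items() if k not in design_df.columns}
    responses = _solve_rows(design_df, frozen_full, solver, landmarks, config, cache)
    envelopes = {
        lm: PredictionEnvelope(
            landmark=lm,
            samples=responses[lm].to_numpy(),
            truth=None if subject.truth is None else subject.truth[lm],
        )
        for lm in LANDMARKS
    }
    return design_df, responses, envelopes


def validate_envelopes(
    envelopes: dict[str, PredictionEnvelope],
    truths: dict[str, float] | None = None,
    doe1_ranges: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Containment and refinement report, one row per landmark.

    A landmark without a truth value is reported as not validated (no
    exception).  With DOE I ranges supplied, the refined-range check
    (DOE II width <= DOE I width) is included.
    """
    rows = []
    for lm, env in envelopes.items():
        truth = None
        if truths is not None and lm in truths:
            truth = truths[lm]
        elif env.truth is not None:
            truth = env.truth
        e = PredictionEnvelope(landmark=lm, samples=env.samples, truth=truth)
        row = {
            "landmark": lm,
            "min": e.min,
            "max": e.max,
            "width": e.width,
            "truth": truth,
            "validated": truth is not None,
            "contains_truth": e.contains_truth,
            "distance_to_range": e.distance_to_range,
        }
        if doe1_ranges is not None and lm in doe1_ranges.index:
            w1 = float(doe1_ranges.loc[lm, "max"] - doe1_ranges.loc[lm, "min"])
            row["doe1_width"] = w1
            row["refined"] = bool(e.width <= w1)
        rows.append(row)
    return pd.DataFrame(rows)
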