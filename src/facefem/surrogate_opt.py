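"""Response-surface surrogates and goal-driven multi-objective optimisation.

Each landmark displacement is modelled as a cheap predictor over the
screened inputs, selected by leave-one-out cross-validation from a small
candidate family (full quadratic polynomial; anisotropic-RBF Gaussian
process).  A goal-driven NSGA-II then searches the material box for input
vectors whose predicted landmarks match the observed postoperative
displacements: each objective is the absolute miss |prediction - target|,
so a reachable target is matched exactly while an unreachable one drives
candidates to the admissible bound.  The best ``n_extract`` candidates
(equally-weighted, range-normalised objective sum after non-dominated
sorting) form the optimised subset carried into the distribution fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.preprocessing import PolynomialFeatures

from .mesh import LANDMARKS

__all__ = [
    "Surrogate",
    "OptimizationTargets",
    "ParetoCandidates",
    "MOGAConfig",
    "fit_surrogate",
    "optimize_materials",
    "nsga2",
    "non_dominated_sort",
    "hypervolume_2d",
]

#: Landmarks entering the optimisation; the lower lip is excluded because
#: mandibular surgery (and hence the dominant driver of LL) is not modelled.
OPTIMIZED_LANDMARKS = ("N", "UL", "RC", "LC")


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------


class _ConstantModel:
    kind = "constant"

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.value)


class _PolyModel:
    """Full quadratic (with interactions) least-squares fit on the unit box."""

    kind = "quadratic"

    def __init__(self):
        self.features = PolynomialFeatures(degree=2, include_bias=True)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PolyModel":
        A = self.features.fit_transform(X)
        self.coef, _, self.rank, _ = np.linalg.lstsq(A, y, rcond=None)
        self._n_basis = A.shape[1]
        return self

    def loo_rmse(self, X: np.ndarray, y: np.ndarray) -> float:
        """Exact leave-one-out RMSE via the hat matrix."""
        A = self.features.fit_transform(X)
        if A.shape[0] <= A.shape[1]:
            return np.inf  # rank-deficient: interpolates, LOO undefined
        # hat diagonal through the pseudo-inverse (handles mild collinearity)
        Apinv = np.linalg.pinv(A)
        h = np.einsum("ij,ji->i", A, Apinv)
        resid = y - A @ (Apinv @ y)
        denom = np.clip(1.0 - h, 1e-10, None)
        return float(np.sqrt(np.mean((resid / denom) ** 2)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.features.transform(X) @ self.coef


class _GPModel:
    """Gaussian process with anisotropic RBF kernel on the unit box."""

    kind = "gp"

    def __init__(self, k: int, seed: int = 0):
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            np.full(k, 0.5), (1e-2, 1e2)
        ) + WhiteKernel(1e-8, (1e-12, 1e-2))
        self.gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=2,
            random_state=seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GPModel":
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # hyperparameter bounds hitting their edge is acceptable here
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp.fit(X, y)
        return self

    def loo_rmse(self, X: np.ndarray, y: np.ndarray) -> float:
        """LOO RMSE with hyperparameters fixed at the full-data optimum."""
        kernel = self.gp.kernel_
        errs = []
        for i in range(len(y)):
            m = np.ones(len(y), bool)
            m[i] = False
            g = GaussianProcessRegressor(kernel=kernel, optimizer=None, normalize_y=True)
            g.fit(X[m], y[m])
            errs.append(g.predict(X[i : i + 1])[0] - y[i])
        return float(np.sqrt(np.mean(np.square(errs))))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.gp.predict(X)


@dataclass
class Surrogate:
    """Per-landmark response surfaces over the screened inputs."""

    columns: list[str]
    bounds: dict[str, tuple[float, float]]
    models: dict[str, object]
    cv_rmse: dict[str, float]
    kinds: dict[str, str]
    n_train: int = 0

    def _unit(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo = np.array([self.bounds[c][0] for c in self.columns])
        hi = np.array([self.bounds[c][1] for c in self.columns])
        return (X - lo) / (hi - lo)

    def predict(self, X) -> pd.DataFrame:
        U = self._unit(X)
        return pd.DataFrame({k: self.models[k].predict(U) for k in self.models})


def fit_surrogate(
    design,
    responses: pd.DataFrame,
    seed: int = 0,
    outputs: tuple[str, ...] = LANDMARKS,
) -> Surrogate:
    """Fit and cross-validate a response surface per landmark.

    ``design`` is a :class:`~facefem.uq_design.DOEDesign` (or a DataFrame
    plus bounds via ``design.samples``/``design.bounds``).  For each output
    the quadratic polynomial and the GP are compared by leave-one-out RMSE
    and the better one kept; a constant response short-circuits to a
    constant predictor with zero error.
    """
    samples: pd.DataFrame = design.samples
    bounds = design.bounds
    cols = list(samples.columns)
    n, k = samples.shape
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} design points, got {n}")
    lo = np.array([bounds[c][0] for c in cols])
    hi = np.array([bounds[c][1] for c in cols])
    U = (samples.to_numpy(dtype=float) - lo) / (hi - lo)

    models, rmses, kinds = {}, {}, {}
    for out in outputs:
        y = responses[out].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            models[out] = _ConstantModel(y[0])
            rmses[out], kinds[out] = 0.0, "constant"
            continue
        poly = _PolyModel().fit(U, y)
        gp = _GPModel(k, seed=seed).fit(U, y)
        cand = [(poly.loo_rmse(U, y), 0, poly), (gp.loo_rmse(U, y), 1, gp)]
        err, _, best = min(cand)
        if not np.isfinite(err):  # both degenerate: keep GP (interpolates)
            err, best = cand[1][0], gp
        models[out], rmses[out], kinds[out] = best, float(err), best.kind
    return Surrogate(
        columns=cols, bounds=dict(bounds), models=models, cv_rmse=rmses,
        kinds=kinds, n_train=n,
    )


# ---------------------------------------------------------------------------
# Goal-driven multi-objective optimisation (NSGA-II)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MOGAConfig:
    """Genetic-algorithm settings.

    ``population`` solutions are evaluated per iteration, for at most
    ``max_iterations`` iterations; the run stops early when every
    objective's best value changes by less than ``stability_pct`` percent
    between iterations and at least ``pareto_pct`` percent of the
    population is non-dominated.  ``n_extract`` best candidates are kept.
    """

    population: int = 1000
    max_iterations: int = 10
    stability_pct: float = 2.0
    pareto_pct: float = 70.0
    n_extract: int = 100
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0
    crossover_prob: float = 0.9

    def validate(self) -> None:
        if self.population < self.n_extract:
            raise ValueError(
                f"population ({self.population}) must be >= n_extract "
                f"({self.n_extract})"
            )


def paper_moga_config() -> MOGAConfig:
    return MOGAConfig(population=1000)


def desk_moga_config() -> MOGAConfig:
    return MOGAConfig(population=500)


@dataclass(frozen=True)
class OptimizationTargets:
    """Observed landmark displacements to match; LL is never optimised."""

    targets: dict[str, float]
    included: tuple[str, ...] = OPTIMIZED_LANDMARKS

    def __post_init__(self) -> None:
        if "LL" in self.included:
            raise ValueError("the lower lip (LL) is excluded from optimisation")
        if len(self.included) != 4:
            raise ValueError("exactly four landmarks are optimised (N, UL, RC, LC)")
        missing = [k for k in self.included if k not in self.targets]
        if missing:
            raise ValueError(f"missing targets for {missing}")


@dataclass
class ParetoCandidates:
    """The optimised candidate matrix of one training subject."""

    candidates: pd.DataFrame  # (m, n_material_columns)
    objectives: pd.DataFrame  # (m, included landmarks): |miss| per landmark
    bounds: dict[str, tuple[float, float]]
    seed: int = 0

    @property
    def m(self) -> int:
        return len(self.candidates)

    def check_bounds(self) -> None:
        for c in self.candidates.columns:
            lo, hi = self.bounds[c]
            v = self.candidates[c].to_numpy()
            if np.any(v < lo - 1e-9) or np.any(v > hi + 1e-9):
                raise ValueError(f"candidate column {c!r} leaves its bounds")

    def to_csv(self, path) -> None:
        pd.concat(
            [self.candidates, self.objectives.add_prefix("obj_")], axis=1
        ).to_csv(path, index=False)


def non_dominated_sort(F: np.ndarray) -> np.ndarray:
    """Pareto rank (0 = non-dominated) of each row of the objective matrix."""
    n = F.shape[0]
    # dominated[i,j] = solution i dominates j (all <=, any <)
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1)
    current = np.where(n_dominators == 0)[0]
    r = 0
    while current.size:
        ranks[current] = r
        n_dominators = n_dominators - dom[current].sum(axis=0)
        n_dominators[ranks >= 0] = np.iinfo(np.int64).max
        current = np.where(n_dominators == 0)[0]
        r += 1
    return ranks


def _crowding(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        if span == 0:
            continue
        d[order[0]] = d[order[-1]] = np.inf
        d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


def _sbx(parents: np.ndarray, rng, eta: float, prob: float) -> np.ndarray:
    """Simulated binary crossover on the unit cube (pairs of rows)."""
    X = parents.copy()
    n2, k = X.shape
    for i in range(0, n2 - 1, 2):
        if rng.random() > prob:
            continue
        u = rng.random(k)
        beta = np.where(
            u <= 0.5, (2 * u) ** (1 / (eta + 1)), (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        )
        p1, p2 = X[i].copy(), X[i + 1].copy()
        X[i] = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
        X[i + 1] = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(X, 0.0, 1.0)


def _poly_mutation(X: np.ndarray, rng, eta: float) -> np.ndarray:
    n, k = X.shape
    pm = 1.0 / k
    mask = rng.random((n, k)) < pm
    u = rng.random((n, k))
    delta = np.where(
        u < 0.5,
        (2 * u) ** (1 / (eta + 1)) - 1,
        1 - (2 * (1 - u)) ** (1 / (eta + 1)),
    )
    return np.clip(np.where(mask, X + delta, X), 0.0, 1.0)


def nsga2(
    objective_fn,
    bounds: np.ndarray,
    config: MOGAConfig | None = None,
    seed: int = 0,
    return_history: bool = False,
):
    """NSGA-II minimisation of a vector objective over a box.

    ``objective_fn`` maps an (n, k) sample block to an (n, m) objective
    matrix.  Returns (X, F, ranks) of the final population (plus the
    per-iteration best-objective history if requested).  Deterministic for
    a given seed.
    """
    config = config or MOGAConfig()
    config.validate()
    bounds = np.asarray(bounds, dtype=float)
    k = bounds.shape[0]
    rng = np.random.default_rng(seed)

    def scale(U):
        return bounds[:, 0] + U * (bounds[:, 1] - bounds[:, 0])

    pop = config.population
    U = rng.random((pop, k))
    F = np.asarray(objective_fn(scale(U)), dtype=float)
    history = [F.min(axis=0)]
    ranks = non_dominated_sort(F)
    for _ in range(1, config.max_iterations):
        crowd = _crowding(F)
        # binary tournament on (rank, -crowding)
        a, b = rng.integers(0, pop, (2, pop))
        take_a = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] >= crowd[b]))
        parents = U[np.where(take_a, a, b)]
        off = _poly_mutation(
            _sbx(parents, rng, config.crossover_eta, config.crossover_prob),
            rng,
            config.mutation_eta,
        )
        Fo = np.asarray(objective_fn(scale(off)), dtype=float)
        allU, allF = np.vstack([U, off]), np.vstack([F, Fo])
        allR = non_dominated_sort(allF)
        # environmental selection: fill by rank, break ties by crowding
        sel: list[int] = []
        for r in range(allR.max() + 1):
            idx = np.where(allR == r)[0]
            if len(sel) + idx.size <= pop:
                sel.extend(idx.tolist())
            else:
                c = _crowding(allF[idx])
                order = np.argsort(-c, kind="stable")
                sel.extend(idx[order[: pop - len(sel)]].tolist())
                break
        sel_arr = np.array(sel)
        U, F, ranks = allU[sel_arr], allF[sel_arr], allR[sel_arr]
        best = F.min(axis=0)
        prev = history[-1]
        history.append(best)
        denom = np.where(np.abs(prev) > 1e-12, np.abs(prev), 1.0)
        stable = np.all(np.abs(best - prev) / denom < config.stability_pct / 100.0)
        nd_frac = np.mean(ranks == 0)
        if stable and nd_frac >= config.pareto_pct / 100.0:
            break
    out = (scale(U), F, non_dominated_sort(F))
    return out + (np.array(history),) if return_history else out


def optimize_materials(
    surrogate: Surrogate,
    targets: OptimizationTargets,
    material_bounds: dict[str, tuple[float, float]],
    fixed_inputs: dict[str, float],
    config: MOGAConfig | None = None,
    seed: int = 0,
) -> ParetoCandidates:
    """Extract the best candidate material vectors for one training subject.

    The advancement (and any frozen input) is held at its per-subject value
    in ``fixed_inputs``; only the material columns in ``material_bounds``
    are free.  Objectives are |surrogate - target| for N, UL, RC and LC,
    equally weighted.
    """
    config = config or MOGAConfig()
    config.validate()
    mat_cols = list(material_bounds)
    tvec = np.array([targets.targets[k] for k in targets.included])

    def objective(X: np.ndarray) -> np.ndarray:
        frame = pd.DataFrame(X, columns=mat_cols)
        for col in surrogate.columns:
            if col not in frame:
                if col not in fixed_inputs:
                    raise ValueError(f"no value for surrogate input {col!r}")
                frame[col] = fixed_inputs[col]
        pred = surrogate.predict(frame)
        return np.abs(pred[list(targets.included)].to_numpy() - tvec)

    barr = np.array([material_bounds[c] for c in mat_cols])
    X, F, ranks = nsga2(objective, barr, config=config, seed=seed)

    # candidate pool: rank-1 front, topped up with rank-2 if needed
    pool = np.where(ranks == 0)[0]
    r = 1
    while pool.size < config.n_extract and r <= ranks.max():
        pool = np.concatenate([pool, np.where(ranks == r)[0]])
        r += 1
    Fp = F[pool]
    span = np.ptp(Fp, axis=0)
    span[span == 0] = 1.0
    score = ((Fp - Fp.min(axis=0)) / span).sum(axis=1)
    order = pool[np.argsort(score, kind="stable")][: config.n_extract]
    cands = ParetoCandidates(
        candidates=pd.DataFrame(X[order], columns=mat_cols),
        objectives=pd.DataFrame(F[order], columns=list(targets.included)),
        bounds=dict(material_bounds),
        seed=seed,
    )
    cands.check_bounds()
    return cands


def hypervolume_2d(F: np.ndarray, ref: tuple[float, float]) -> float:
    """Dominated hypervolume of a bi-objective front w.r.t. a reference point."""
    F = np.asarray(F, dtype=float)
    F = F[np.all(F <= np.asarray(ref), axis=1)]
    if F.size == 0:
        return 0.0
    F = F[np.argsort(F[:, 0], kind="stable")]
    hv, best2 = 0.0, np.inf
    prev_x = None
    # sweep in f1, accumulating strips of the staircase
    pts = []
    for x, y in F:
        if y < best2:
            pts.append((x, y))
            best2 = y
    for i, (x, y) in enumerate(pts):
        x_next = pts[i + 1][0] if i + 1 < len(pts) else ref[0]
        hv += max(0.0, x_next - x) * max(0.0, ref[1] - y)
    return float(hv)
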