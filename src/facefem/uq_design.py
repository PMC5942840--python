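"""Space-filling designs of experiments and rank-correlation screening.

Designs are maximin-optimised Latin hypercubes over the uncertain-input
box (a documented stand-in for proprietary "optimal space-filling"
sampling, with the same stated goal: uniform coverage of the ranges in a
minimal number of runs).  Screening computes Spearman rank correlations
between every candidate input and every landmark output; inputs that are
significant (p < alpha) against at least one output enter the next design
as ranges, the rest are frozen at their range midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from scipy.stats import qmc

__all__ = [
    "DOEDesign",
    "CorrelationTable",
    "design_size",
    "sample_design",
    "screen_variables",
]


def design_size(k: int) -> int:
    """Default number of runs for a k-variable design iteration.

    Central-composite sizing, ``2^k + 2k + 1`` runs, switching to a
    fractional (half) factorial core for k >= 5: ``2^(k-1) + 2k + 1``.
    Five screened-in variables therefore cost 27 runs.
    """
    if k < 1:
        raise ValueError("number of variables must be >= 1")
    core = 2 ** (k - 1) if k >= 5 else 2**k
    return core + 2 * k + 1


@dataclass
class DOEDesign:
    """A sampled design: one row per simulation, one column per variable."""

    samples: pd.DataFrame
    bounds: dict[str, tuple[float, float]]
    method: str = "maximin-lhs"
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def k(self) -> int:
        return self.samples.shape[1]

    def unit_samples(self) -> np.ndarray:
        """Samples rescaled to the unit hypercube."""
        lo = np.array([self.bounds[c][0] for c in self.samples.columns])
        hi = np.array([self.bounds[c][1] for c in self.samples.columns])
        return (self.samples.to_numpy() - lo) / (hi - lo)

    def min_distance(self) -> float:
        """Minimum pairwise Euclidean distance in the unit cube."""
        return float(pdist(self.unit_samples()).min())

    def stratum_counts(self) -> np.ndarray:
        """(k, n) matrix of samples per equal-probability stratum."""
        u = self.unit_samples()
        strata = np.clip((u * self.n).astype(int), 0, self.n - 1)
        return np.stack(
            [np.bincount(strata[:, j], minlength=self.n) for j in range(self.k)]
        )

    def check(self) -> None:
        """Assert bounds containment and the Latin (one-per-stratum) property."""
        u = self.unit_samples()
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError("design contains samples outside the bounds box")
        if not np.all(self.stratum_counts() == 1):
            raise ValueError("design violates the Latin one-per-stratum property")

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def sample_design(
    bounds: dict[str, tuple[float, float]],
    n_samples: int | None = None,
    seed: int = 0,
    n_restarts: int = 100,
    optimize: bool = True,
) -> DOEDesign:
    """Maximin Latin-hypercube design over the given variable bounds.

    Among ``n_restarts`` random Latin hypercubes the one maximising the
    minimum pairwise distance in the unit cube is kept (``optimize=False``
    returns the first plain hypercube, for comparison).  Deterministic for
    a given seed.
    """
    names = list(bounds)
    k = len(names)
    for name, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"inverted bounds for {name!r}: ({lo}, {hi})")
    if n_samples is None:
        n_samples = design_size(k)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    engine = qmc.LatinHypercube(d=k, seed=rng)
    best, best_d = None, -np.inf
    for _ in range(n_restarts if optimize else 1):
        u = engine.random(n_samples)
        d = pdist(u).min()
        if d > best_d:
            best, best_d = u, d
    lo = np.array([bounds[c][0] for c in names])
    hi = np.array([bounds[c][1] for c in names])
    samples = pd.DataFrame(qmc.scale(best, lo, hi), columns=names)
    method = "maximin-lhs" if optimize else "lhs"
    return DOEDesign(samples=samples, bounds=dict(bounds), method=method, seed=seed)


@dataclass
class CorrelationTable:
    """Screening result: per (input, output) rank correlation and selection.

    ``table`` holds one row per input/output pair with the Spearman r, its
    95 % confidence interval (Fisher z with the rank-correlation variance
    adjustment 1.06/(n-3)) and the two-sided p-value.  An input is selected
    when it is significant against at least one output; non-selected inputs
    carry their frozen (range-midpoint) value for downstream stages.
    """

    table: pd.DataFrame
    selected: dict[str, bool]
    frozen_values: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.05
    n: int = 0

    def selected_inputs(self) -> list[str]:
        return [k for k, v in self.selected.items() if v]

    def r_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="input", columns="output", values="r")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n": self.n,
            "selected": self.selected_inputs(),
            "frozen": {k: float(v) for k, v in self.frozen_values.items()},
        }


def _spearman_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    if abs(r) >= 1.0 or n <= 3:
        return (r, r)
    z = np.arctanh(r)
    se = np.sqrt(1.06 / (n - 3))
    q = stats.norm.ppf(0.5 + conf / 2.0)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def screen_variables(
    inputs: pd.DataFrame,
    responses: pd.DataFrame,
    alpha: float = 0.05,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> CorrelationTable:
    """Spearman screening of candidate inputs against landmark outputs.

    Parameters
    ----------
    inputs, responses : DataFrame
        Matched simulation records (rows) of candidate inputs and landmark
        displacements.
    alpha : float
        Two-sided significance level of the inclusion criterion.
    bounds : dict, optional
        Variable ranges used to freeze non-selected inputs at their
        midpoint; columns without bounds are frozen at their sample mean.
    """
    if len(inputs) != len(responses):
        raise ValueError("inputs and responses must have matching rows")
    n = len(inputs)
    if n < 10:
        raise ValueError(f"screening needs >= 10 simulation records, got {n}")
    rows = []
    selected: dict[str, bool] = {}
    for xcol in inputs.columns:
        x = inputs[xcol].to_numpy(dtype=float)
        constant = np.ptp(x) == 0
        if constant:
            warnings.warn(
                f"input {xcol!r} is constant; correlation undefined, "
                "treated as not selected",
                stacklevel=2,
            )
        any_sig = False
        for ycol in responses.columns:
            y = responses[ycol].to_numpy(dtype=float)
            if constant or np.ptp(y) == 0:
                r, p, lo_ci, hi_ci = np.nan, np.nan, np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
                lo_ci, hi_ci = _spearman_ci(float(r), n)
            sig = bool(np.isfinite(p) and p < alpha)
            any_sig |= sig
            rows.append(
                {
                    "input": xcol,
                    "output": ycol,
                    "r": float(r) if np.isfinite(r) else np.nan,
                    "ci_lo": lo_ci,
                    "ci_hi": hi_ci,
                    "p": float(p) if np.isfinite(p) else np.nan,
                    "significant": sig,
                }
            )
        selected[xcol] = any_sig
    frozen = {}
    for xcol in inputs.columns:
        if selected[xcol]:
            continue
        if bounds and xcol in bounds:
            lo, hi = bounds[xcol]
            frozen[xcol] = 0.5 * (lo + hi)
        else:
            frozen[xcol] = float(inputs[xcol].mean())
    return CorrelationTable(
        table=pd.DataFrame(rows),
        selected=selected,
        frozen_values=frozen,
        alpha=alpha,
        n=n,
    )
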