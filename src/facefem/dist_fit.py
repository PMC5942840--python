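"""Population material-property distributions from optimised candidates.

The optimised candidate matrices of the training subjects are pooled
row-wise and a three-parameter (location-shifted) Weibull distribution is
fitted to each material column by maximum likelihood, with the location
profiled on a refined grid below the sample minimum.  The location shift
matters because parameters such as the soft-tissue Poisson ratio live on a
narrow interval far from zero, which a two-parameter Weibull anchored at
the origin cannot represent.  The fitted distributions replace the uniform
literature ranges in the second design-of-experiments iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeibullFit",
    "pool_candidates",
    "fit_weibull",
    "sample_distribution",
]


@dataclass(frozen=True)
class WeibullFit:
    """Fitted three-parameter Weibull: shape k, scale lambda, location."""

    shape: float
    scale: float
    location: float
    n: int
    ks: float  # Kolmogorov-Smirnov statistic against the fitted law

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    def frozen(self):
        return stats.weibull_min(self.shape, loc=self.location, scale=self.scale)

    def mean(self) -> float:
        return float(self.frozen().mean())

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "scale": self.scale,
            "location": self.location,
            "n": self.n,
            "ks": self.ks,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullFit":
        return cls(
            shape=float(d["shape"]),
            scale=float(d["scale"]),
            location=float(d["location"]),
            n=int(d["n"]),
            ks=float(d["ks"]),
        )


def pool_candidates(candidate_sets) -> pd.DataFrame:
    """Row-wise superimposition of per-subject candidate matrices.

    All sets must share column names *and order*; five training subjects
    with m = 100 candidates each give a 500 x n pooled matrix.
    """
    if not candidate_sets:
        raise ValueError("no candidate sets to pool")
    frames = []
    ref_cols = None
    for cs in candidate_sets:
        df = cs.candidates if hasattr(cs, "candidates") else cs
        cols = list(df.columns)
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            raise ValueError(
                f"candidate sets have mismatched columns: {cols} vs {ref_cols}"
            )
        frames.append(df)
    return pd.concat(frames, axis=0, ignore_index=True)


def _profile_loglik(x: np.ndarray, loc: float) -> tuple[float, float, float]:
    """Max log-likelihood over (shape, scale) at a fixed location."""
    shape, _, scale = stats.weibull_min.fit(x, floc=loc)
    ll = float(np.sum(stats.weibull_min.logpdf(x, shape, loc=loc, scale=scale)))
    return ll, shape, scale


def fit_weibull(
    samples,
    bounds: tuple[float, float] | None = None,
    n_grid: int = 40,
    n_refine: int = 3,
) -> WeibullFit:
    """Maximum-likelihood three-parameter Weibull fit.

    The location is profiled on a grid spanning from 10 % of the physical
    range below the physical minimum up to just under the sample minimum,
    then refined around the best grid point.  ``bounds`` is the physical
    (min, max) of the parameter; without it the sample range is used.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError(
            f"need >= 30 samples to fit (got {x.size}); pool more candidate sets"
        )
    if np.ptp(x) == 0:
        raise ValueError("samples are constant; Weibull fit undefined")
    xmin, xmax = float(x.min()), float(x.max())
    if bounds is None:
        bounds = (xmin, xmax)
    span = bounds[1] - bounds[0]
    lo = bounds[0] - 0.1 * span
    hi = xmin - 1e-9 * max(1.0, abs(xmin))  # location strictly below samples
    eps = 1e-4 * (xmax - xmin)
    hi = min(hi, xmin - eps)

    best = (-np.inf, None)
    for _ in range(n_refine + 1):
        grid = np.linspace(lo, hi, n_grid)
        for loc in grid:
            try:
                ll, shape, scale = _profile_loglik(x, loc)
            except (RuntimeError, ValueError):
                continue
            if np.isfinite(ll) and ll > best[0]:
                best = (ll, (shape, scale, loc))
        if best[1] is None:
            raise RuntimeError("Weibull location profiling failed on every grid point")
        loc_best = best[1][2]
        step = (hi - lo) / (n_grid - 1)
        lo = max(lo, loc_best - step)
        hi = min(hi, loc_best + step)
    shape, scale, loc = best[1]
    ks = float(
        stats.kstest(x, stats.weibull_min(shape, loc=loc, scale=scale).cdf).statistic
    )
    return WeibullFit(shape=shape, scale=scale, location=loc, n=int(x.size), ks=ks)


def sample_distribution(
    fit: WeibullFit,
    n: int,
    bounds: tuple[float, float] | None = None,
    seed: int = 0,
    unit_samples: np.ndarray | None = None,
) -> np.ndarray:
    """Inverse-CDF draws from a fitted Weibull, kept inside physical bounds.

    Draws falling outside ``bounds`` are rejected and redrawn; if the
    distribution puts less than 0.1 % of its mass inside the bounds an
    error is raised.  ``unit_samples`` (e.g. one column of a Latin
    hypercube) may supply the uniform variates for stratified sampling;
    otherwise uniforms come from ``seed``.  Deterministic either way.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = fit.frozen()
    if bounds is not None:
        lo_p, hi_p = dist.cdf(bounds[0]), dist.cdf(bounds[1])
        if hi_p - lo_p < 1e-3:
            raise ValueError(
                f"physical bounds {bounds} exclude nearly all fitted mass "
                f"({hi_p - lo_p:.2e})"
            )
    rng = np.random.default_rng(seed)
    if unit_samples is not None:
        u = np.asarray(unit_samples, dtype=float)
        if u.shape[0] != n:
            raise ValueError("unit_samples length must equal n")
        if bounds is not None:
            # map stratified uniforms through the bound-truncated CDF
            u = lo_p + u * (hi_p - lo_p)
        return dist.ppf(u)
    out = dist.ppf(rng.random(n))
    if bounds is not None:
        bad = (out < bounds[0]) | (out > bounds[1])
        guard = 0
        while bad.any():
            out[bad] = dist.ppf(rng.random(int(bad.sum())))
            bad = (out < bounds[0]) | (out > bounds[1])
            guard += 1
            if guard > 10000:  # pragma: no cover - bounded by the mass check
                raise ValueError("rejection sampling failed to terminate")
    return out
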