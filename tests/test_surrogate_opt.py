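"""Surrogate cross-validation and NSGA-II optimisation behaviour."""

import numpy as np
import pandas as pd
import pytest

from facefem import surrogate_opt as so
from facefem import uq_design


def _design(bounds, n, seed=0):
    return uq_design.sample_design(bounds, n_samples=n, seed=seed)


class TestSurrogate:
    def test_known_quadratic_recovered_exactly(self):
        """A quadratic truth of two inputs is recovered to machine level."""
        bounds = {"x1": (0.0, 2.0), "x2": (-1.0, 1.0)}
        d = _design(bounds, 27, seed=1)

        def truth(x1, x2):
            return 1.5 + 2 * x1 - x2 + 0.5 * x1 * x2 + 3 * x2**2

        resp = pd.DataFrame({"N": truth(d.samples["x1"], d.samples["x2"])})
        sur = so.fit_surrogate(d, resp, outputs=("N",))
        assert sur.cv_rmse["N"] < 1e-6
        rng = np.random.default_rng(0)
        probes = pd.DataFrame(
            {"x1": rng.uniform(0, 2, 100), "x2": rng.uniform(-1, 1, 100)}
        )
        pred = sur.predict(probes)["N"].to_numpy()
        assert np.allclose(pred, truth(probes["x1"], probes["x2"]), atol=1e-8)

    def test_constant_response_gives_constant_predictor(self):
        bounds = {"x1": (0.0, 1.0), "x2": (0.0, 1.0)}
        d = _design(bounds, 12, seed=2)
        resp = pd.DataFrame({"N": np.full(12, 3.25)})
        sur = so.fit_surrogate(d, resp, outputs=("N",))
        assert sur.cv_rmse["N"] == 0.0
        assert sur.kinds["N"] == "constant"
        assert np.allclose(sur.predict(d.samples)["N"], 3.25)

    def test_small_design_falls_back_to_gp(self):
        """Too few points for the quadratic basis: GP wins by default."""
        bounds = {f"x{i}": (0.0, 1.0) for i in range(4)}
        d = _design(bounds, 8, seed=3)  # quadratic basis needs 15 points
        y = d.samples.sum(axis=1)
        sur = so.fit_surrogate(d, pd.DataFrame({"N": y}), outputs=("N",))
        assert sur.kinds["N"] == "gp"
        assert np.isfinite(sur.cv_rmse["N"])

    def test_too_few_points_raise(self):
        bounds = {f"x{i}": (0.0, 1.0) for i in range(4)}
        d = _design(bounds, 5, seed=0)
        with pytest.raises(ValueError):
            so.fit_surrogate(d, pd.DataFrame({"N": np.arange(5.0)}), outputs=("N",))


class TestNonDominatedSort:
    def test_matches_bruteforce_on_random_fronts(self):
        rng = np.random.default_rng(0)
        F = rng.uniform(size=(60, 3))
        ranks = so.non_dominated_sort(F)

        def dominates(i, j):
            return np.all(F[i] <= F[j]) and np.any(F[i] < F[j])

        # rank-0 solutions are exactly the non-dominated ones
        for i in range(len(F)):
            nd = not any(dominates(j, i) for j in range(len(F)))
            assert (ranks[i] == 0) == nd
        # a dominating solution never has a larger rank
        for i in range(len(F)):
            for j in range(len(F)):
                if dominates(i, j):
                    assert ranks[i] <= ranks[j]


class TestTargets:
    def test_lower_lip_is_never_optimised(self):
        with pytest.raises(ValueError):
            so.OptimizationTargets(
                targets={k: 0.0 for k in ("N", "UL", "LL", "RC")},
                included=("N", "UL", "LL", "RC"),
            )

    def test_exactly_four_landmarks(self):
        with pytest.raises(ValueError):
            so.OptimizationTargets(targets={"N": 0.0}, included=("N",))


@pytest.fixture(scope="module")
def planted_surrogate():
    """Analytic 'surrogate' with a known interior optimum x*."""
    bounds = {"E_cart": (0.5, 5.0), "E_soft": (0.1, 1.0),
              "nu_soft": (0.45, 0.499), "G_scale": (0.488, 1.512)}
    d = _design(bounds, 40, seed=4)
    x_star = {"E_cart": 2.2, "E_soft": 0.7, "nu_soft": 0.48, "G_scale": 0.9}

    def f(samples: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for i, lm in enumerate(("N", "UL", "LL", "RC", "LC")):
            acc = np.zeros(len(samples))
            for j, (c, (lo, hi)) in enumerate(bounds.items()):
                u = (samples[c] - lo) / (hi - lo)
                u_star = (x_star[c] - lo) / (hi - lo)
                w = 1.0 + 0.5 * ((i + j) % 3)
                acc = acc + w * (u - u_star) ** 2
            out[lm] = 1.0 + acc
        return pd.DataFrame(out)

    resp = f(d.samples)
    sur = so.fit_surrogate(d, resp)
    return bounds, x_star, sur, f


class TestMOGA:
    def test_planted_optimum_recovered(self, planted_surrogate):
        """Targets at the surrogate's value at x*: best candidate lands on
        x* within 1 % of each normalised coordinate."""
        bounds, x_star, sur, f = planted_surrogate
        t = f(pd.DataFrame([x_star]))
        targets = so.OptimizationTargets(
            targets={lm: float(t[lm].iloc[0]) for lm in ("N", "UL", "RC", "LC")}
        )
        cfg = so.MOGAConfig(population=300, max_iterations=25, n_extract=50,
                            stability_pct=0.0)
        cands = so.optimize_materials(sur, targets, bounds, {"x_adv": 4.6},
                                      config=cfg, seed=0)
        best = cands.candidates.iloc[0]
        for c, (lo, hi) in bounds.items():
            assert abs(best[c] - x_star[c]) / (hi - lo) < 0.01, c

    def test_unreachable_target_drives_to_bound(self):
        """A target above the reachable range pushes candidates to the
        bound of the input that controls that landmark (the min/max
        fallback of goal-driven optimisation)."""
        bounds = {"E_cart": (0.5, 5.0), "E_soft": (0.1, 1.0),
                  "nu_soft": (0.45, 0.499), "G_scale": (0.488, 1.512)}
        d = _design(bounds, 40, seed=5)
        cols = list(bounds)

        def truth(samples: pd.DataFrame) -> pd.DataFrame:
            u = {c: (samples[c] - lo) / (hi - lo)
                 for c, (lo, hi) in bounds.items()}
            # near-separable monotone responses: one driver per landmark
            return pd.DataFrame({
                "N": 3.0 * u["E_cart"] + 0.1 * u["G_scale"],
                "UL": 2.0 * u["E_soft"],
                "LL": u["nu_soft"],
                "RC": 1.5 * u["nu_soft"],
                "LC": 1.0 * u["G_scale"],
            })

        sur = so.fit_surrogate(d, truth(d.samples))
        mid = pd.DataFrame([{c: 0.5 * sum(bounds[c]) for c in cols}])
        t = truth(mid)
        targets = {lm: float(t[lm].iloc[0]) for lm in ("UL", "RC", "LC")}
        targets["N"] = 100.0  # far above the ~3.1 maximum over the box
        cfg = so.MOGAConfig(population=300, max_iterations=20, n_extract=50)
        cands = so.optimize_materials(
            sur, so.OptimizationTargets(targets=targets), bounds,
            {"x_adv": 4.6}, config=cfg, seed=1,
        )
        lo, hi = bounds["E_cart"]
        u_cart = ((cands.candidates["E_cart"] - lo) / (hi - lo)).to_numpy()
        # candidates pile up towards the E_cart upper bound ...
        assert np.median(u_cart) > 0.65
        assert u_cart[0] > 0.6  # ... including the best-ranked one
        # ... and the best N prediction nearly reaches the box maximum (3.1)
        best_n_pred = (100.0 - cands.objectives["N"]).max()
        assert best_n_pred >= 0.9 * 3.1

    def test_candidates_within_bounds_and_reproducible(self, planted_surrogate):
        bounds, x_star, sur, f = planted_surrogate
        t = f(pd.DataFrame([x_star]))
        targets = so.OptimizationTargets(
            targets={lm: float(t[lm].iloc[0]) for lm in ("N", "UL", "RC", "LC")}
        )
        cfg = so.MOGAConfig(population=150, max_iterations=5, n_extract=100)
        a = so.optimize_materials(sur, targets, bounds, {"x_adv": 4.6},
                                  config=cfg, seed=9)
        b = so.optimize_materials(sur, targets, bounds, {"x_adv": 4.6},
                                  config=cfg, seed=9)
        a.check_bounds()
        assert a.m == 100
        pd.testing.assert_frame_equal(a.candidates, b.candidates)

    def test_population_smaller_than_extract_raises(self):
        with pytest.raises(ValueError):
            so.MOGAConfig(population=50, n_extract=100).validate()

    def test_bi_objective_front_hypervolume(self):
        """Convex analytic front f2 = 1 - sqrt(f1): achieved hypervolume
        within 95 % of the analytic optimum."""

        def zdt1(X):
            f1 = X[:, 0]
            g = 1.0 + 9.0 * X[:, 1:].mean(axis=1)
            return np.column_stack([f1, g * (1.0 - np.sqrt(f1 / g))])

        bounds = np.array([[0.0, 1.0]] * 3)
        cfg = so.MOGAConfig(population=200, max_iterations=40, n_extract=100,
                            stability_pct=0.0)
        X, F, ranks = so.nsga2(zdt1, bounds, config=cfg, seed=2)
        front = F[ranks == 0]
        ref = (1.1, 1.1)
        hv = so.hypervolume_2d(front, ref)
        hv_exact = 0.1 * 1.1 + 0.1 + 2.0 / 3.0  # integral of the true front
        assert hv >= 0.95 * hv_exact

    def test_hypervolume_helper_on_known_staircase(self):
        F = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
        # strips: (0.5-0)*(1.1-1) + (1-0.5)*(1.1-0.5) + (1.1-1)*(1.1-0)
        assert so.hypervolume_2d(F, (1.1, 1.1)) == pytest.approx(
            0.5 * 0.1 + 0.5 * 0.6 + 0.1 * 1.1
        )
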