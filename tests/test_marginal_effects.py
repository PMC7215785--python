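import numpy as np
import pytest

from carlogit.data_model import CrashRecord, chain_graph
from carlogit.likelihood import CoefficientSet, category_probs
from carlogit.marginal_effects import average_me, binary_me, continuous_me
from conftest import make_dataset

X_NAMES = ("constant", "x1", "x2")
Z_NAMES = ("constant", "x1", "z1")  # x1 enters both sides


def record(xvals, zvals, segment=1):
    return CrashRecord(
        severity=1,
        x=np.array([1.0, *xvals]),
        z=np.array([1.0, *zvals]),
        segment=segment,
    )


def random_coef(rng, n_seg=0):
    phi = rng.normal(size=n_seg) * 0.4 if n_seg else np.zeros(0)
    return CoefficientSet(
        beta=rng.normal(size=3), alpha=rng.normal(size=3) * 0.6, phi=phi
    )


class TestContinuousEffect:
    def test_threshold_only_variable_cannot_move_light(self, rng):
        # variable z1 has beta 0 by construction: effect on p1 exactly 0
        coef = CoefficientSet(beta=rng.normal(size=3), alpha=np.array([0.5, 0.1, -0.24]))
        tri = continuous_me(
            coef, record([0.3, -0.7], [0.3, 1.2]), "z1", x_names=X_NAMES, z_names=Z_NAMES
        )
        assert tri.d_p1 == 0.0
        assert tri.d_p2 == -tri.d_p3

    def test_closed_form_at_null_parameters(self):
        coef = CoefficientSet(beta=np.array([0.0, 1.0, 0.0]), alpha=np.zeros(3))
        tri = continuous_me(
            coef, record([0.0, 0.0], [0.0, 0.0]), "x1", x_names=X_NAMES, z_names=Z_NAMES
        )
        assert tri.d_p1 == pytest.approx(-0.25, abs=1e-9)
        assert tri.d_p2 == pytest.approx(0.053388, abs=1e-6)
        assert tri.d_p3 == pytest.approx(0.196612, abs=1e-6)

    def test_matches_finite_differences(self, rng):
        """Derivative formulas vs central finite differences of the category
        probabilities, on random coefficients and covariates."""
        h = 1e-6
        for _ in range(300):
            coef = random_coef(rng, n_seg=4)
            rec = record(rng.normal(size=2), rng.normal(size=2), segment=3)
            for var in ("x1", "x2", "z1"):
                tri = continuous_me(coef, rec, var, x_names=X_NAMES, z_names=Z_NAMES)
                bumped = []
                for sign in (+1, -1):
                    x = rec.x.copy()
                    z = rec.z.copy()
                    if var in X_NAMES:
                        x[X_NAMES.index(var)] += sign * h
                    if var in Z_NAMES:
                        z[Z_NAMES.index(var)] += sign * h
                    bumped.append(
                        category_probs(
                            coef, CrashRecord(severity=1, x=x, z=z, segment=3)
                        ).as_array()
                    )
                fd = (bumped[0] - bumped[1]) / (2 * h)
                assert tri.as_array() == pytest.approx(fd, abs=1e-6)

    def test_unknown_variable_rejected(self, rng):
        coef = random_coef(rng)
        with pytest.raises(ValueError):
            continuous_me(
                coef, record([0, 0], [0, 0]), "nope", x_names=X_NAMES, z_names=Z_NAMES
            )


class TestBinaryEffect:
    def test_noop_variable_gives_zero(self):
        coef = CoefficientSet(
            beta=np.array([0.4, 0.0, 0.7]), alpha=np.array([0.2, 0.0, -0.1])
        )
        tri = binary_me(
            coef, record([1.0, 0.5], [1.0, 0.0]), "x1", x_names=X_NAMES, z_names=Z_NAMES
        )
        assert tri.as_array() == pytest.approx(np.zeros(3), abs=1e-15)

    def test_matches_direct_probability_difference(self, rng):
        for _ in range(200):
            coef = random_coef(rng, n_seg=4)
            rec = record(rng.integers(0, 2, 2).astype(float), rng.normal(size=2), 2)
            tri = binary_me(coef, rec, "x1", x_names=X_NAMES, z_names=Z_NAMES)
            def probs(v):
                x = rec.x.copy()
                z = rec.z.copy()
                x[1] = v
                z[1] = v
                return category_probs(
                    coef, CrashRecord(severity=1, x=x, z=z, segment=2)
                ).as_array()
            assert tri.as_array() == pytest.approx(probs(1.0) - probs(0.0), abs=1e-12)

    def test_propensity_only_indicator_sign_structure(self):
        coef = CoefficientSet(beta=np.array([0.0, 3.0, 0.0]), alpha=np.zeros(3))
        tri = binary_me(
            coef, record([0.0, 0.0], [0.0, 0.0]), "x1",
            x_names=("constant", "x1", "x2"), z_names=("constant", "zz", "z1"),
        )
        assert tri.d_p3 > 0 and tri.d_p1 < 0

    def test_sibling_indicators_held_at_reference(self, rng):
        # exclusive sibling x2 is zeroed in both counterfactuals: the effect
        # contrasts "x1 level" against the reference level
        coef = CoefficientSet(beta=rng.normal(size=3), alpha=rng.normal(size=3) * 0.3)
        rec = record([0.0, 1.0], [0.0, 0.2])
        tri = binary_me(
            coef, rec, "x1", x_names=X_NAMES, z_names=Z_NAMES, siblings=("x2",)
        )
        def probs(x1, x2):
            x = np.array([1.0, x1, x2])
            z = np.array([1.0, x1, rec.z[2]])
            return category_probs(coef, CrashRecord(severity=1, x=x, z=z, segment=1)).as_array()
        assert tri.as_array() == pytest.approx(probs(1.0, 0.0) - probs(0.0, 0.0), abs=1e-12)


class TestAverageEffects:
    def test_single_crash_average_equals_per_crash(self, rng):
        ds = make_dataset(n=1, seed=3)
        coef = CoefficientSet(beta=rng.normal(size=3), alpha=rng.normal(size=3))
        table = average_me(coef, ds, {"x1": "continuous"})
        tri = continuous_me(
            coef, ds.record(0), "x1", x_names=ds.x_names, z_names=ds.z_names
        )
        assert table.loc["x1", ["light", "medium", "severe"]].to_numpy() == pytest.approx(
            tri.as_percent(), abs=1e-10
        )

    def test_triplets_conserve_probability(self, rng):
        ds = make_dataset(n=80, seed=4)
        coef = CoefficientSet(
            beta=rng.normal(size=3), alpha=rng.normal(size=3) * 0.5,
            phi=rng.normal(size=5) * 0.3,
        )
        table = average_me(coef, ds, {"x1": "continuous", "x2": "indicator", "z1": "continuous"})
        sums = table[["light", "medium", "severe"]].sum(axis=1)
        assert np.abs(sums.to_numpy()).max() < 1e-10 * 100

    def test_threshold_only_indicator_row_structure(self, rng):
        """A threshold-only indicator leaves the light column exactly 0 and
        moves medium and severe by equal and opposite amounts."""
        ds = make_dataset(n=50, seed=5)
        coef = CoefficientSet(beta=rng.normal(size=3), alpha=np.array([0.3, -0.2, 0.42]))
        table = average_me(coef, ds, {"z1": "indicator"})
        row = table.loc["z1"]
        assert row["light"] == 0.0
        assert row["medium"] == pytest.approx(-row["severe"], abs=1e-10)

    def test_printed_product_form_identity(self, rng):
        """The printed medium-category derivative equals minus the sum of the
        light and severe derivatives (algebraic identity), on random draws."""
        from scipy.special import expit

        for _ in range(10_000 // 50):
            beta_x, alpha_x = rng.normal(size=2)
            eta, lin_z = rng.normal(size=2)
            mu2 = np.exp(np.clip(lin_z, -5, 5))
            p1 = expit(-eta)
            p2 = expit(mu2 - eta) - expit(-eta)
            p3 = 1 - expit(mu2 - eta)
            printed_d2 = alpha_x * mu2 * p3 * (1 - p3) + beta_x * p2 * (p1 - p3)
            d1 = beta_x * p1 * (p1 - 1)
            d3 = (beta_x - alpha_x * mu2) * p3 * (1 - p3)
            assert printed_d2 == pytest.approx(-(d1 + d3), abs=1e-10)

    def test_draw_averaged_effects_bracket_plugin(self):
        """Draw-averaged effects carry intervals that contain the plug-in
        point estimate for a well-behaved chain."""
        from carlogit.marginal_effects import average_me_draws
        from carlogit.mcmc import McmcConfig, fit

        ds = make_dataset(n=200, seed=9, beta=[0.2, 0.6, 0.0], alpha=[0.5, 0.0, -0.3])
        chain = fit("nonspatial", ds, McmcConfig(n_iter=1200, burn_in=600, seed=2))
        table = average_me_draws(
            chain, ds, {"x1": "continuous"}, max_draws=100
        )
        plugin = average_me(
            chain.posterior_mean_coefficients(), ds, {"x1": "continuous"}
        )
        row = table.loc["x1"]
        for cat in ("light", "medium", "severe"):
            assert row[f"{cat}_q2.5"] <= plugin.loc["x1", cat] <= row[f"{cat}_q97.5"]

    def test_same_direction_movement_possible_with_shared_variable(self):
        """A variable in both functions can move light and severe in the same
        direction — impossible under fixed thresholds."""
        # strong positive threshold effect dominates a small propensity effect
        coef = CoefficientSet(beta=np.array([0.0, 0.05, 0.0]), alpha=np.array([0.0, 1.5, 0.0]))
        tri = continuous_me(
            coef, record([0.0, 0.0], [0.0, 0.0]), "x1", x_names=X_NAMES, z_names=Z_NAMES
        )
        assert tri.d_p1 < 0 and tri.d_p3 < 0 and tri.d_p2 > 0
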