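"""Power-law curve fitting, joint parameter-sharing models, nested F-tests
and model selection."""


import numpy as np
import pandas as pd
import pytest

from vplkit import (
    CurveData,
    JointLearningCurveModel,
    ModelSpec,
    enumerate_models,
    fit_joint,
    fit_power_law,
    nested_f_test,
    select_best_model,
)

T5 = np.arange(1, 6, dtype=float)


def curve(group, c0, rho, noise=None):
    y = c0 * T5 ** (-rho)
    if noise is not None:
        y = y + noise
    return CurveData(group, tuple(T5), tuple(y))


def grid_oracle(t, y, c0_range, rho_range, step=1e-4):
    """Brute-force (C0, rho) grid search minimising the residual sum of squares."""
    c0s = np.arange(*c0_range, step)
    rhos = np.arange(*rho_range, step)
    tt = np.asarray(t, float)
    yy = np.asarray(y, float)
    pred = c0s[:, None, None] * tt[None, None, :] ** (-rhos[None, :, None])
    rss = ((yy - pred) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return c0s[i], rhos[j], rss[i, j]


class TestSingleCurveFit:
    def test_noiseless_recovery_is_exact(self):
        res = fit_power_law(T5, 0.6 * T5**-0.3)
        assert res.c0_by_group["group"] == pytest.approx(0.6, abs=1e-6)
        assert res.rho_by_group["group"] == pytest.approx(0.3, abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_is_zero_rate_power_law(self):
        res = fit_power_law(T5, np.full(5, 0.4))
        assert res.rho_by_group["group"] == pytest.approx(0.0, abs=1e-5)
        assert res.c0_by_group["group"] == pytest.approx(0.4, abs=1e-5)
        assert res.rss == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle_on_perturbed_data(self):
        y = 0.6 * T5**-0.3 + np.array([0.01, -0.01, 0.0, 0.01, -0.01])
        res = fit_power_law(T5, y)
        c0g, rhog, rssg = grid_oracle(T5, y, (0.50, 0.70), (0.20, 0.40))
        tss = ((y - y.mean()) ** 2).sum()
        assert res.rss <= rssg + 1e-9
        assert res.r2 == pytest.approx(1.0 - rssg / tss, abs=1e-3)
        assert res.c0_by_group["group"] == pytest.approx(c0g, abs=1e-3)
        assert res.rho_by_group["group"] == pytest.approx(rhog, abs=1e-3)

    def test_oracle_equivalence_on_random_instances(self, rng):
        """NLS matches the brute-force grid oracle to 3 decimals."""
        for _ in range(20):
            c0, rho = rng.uniform(0.3, 0.8), rng.uniform(0.1, 0.8)
            y = c0 * T5 ** (-rho) + rng.normal(0, 0.01, 5)
            y = np.maximum(y, 0.01)
            res = fit_power_law(T5, y)
            c0g, rhog, rssg = grid_oracle(
                T5, y, (max(c0 - 0.15, 0.01), c0 + 0.15), (max(rho - 0.3, 0.0), rho + 0.3)
            )
            if res.rss < rssg - 1e-9:  # optimiser beat the local grid window
                continue
            assert res.c0_by_group["group"] == pytest.approx(c0g, abs=1e-3)
            assert res.rho_by_group["group"] == pytest.approx(rhog, abs=1e-3)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0], [0.5, 0.4])


class TestModelSpec:
    def test_full_and_shared(self):
        full = ModelSpec.full(["a", "b", "c"])
        shared = ModelSpec.fully_shared(["a", "b", "c"])
        assert full.k == 6
        assert shared.k == 2
        assert shared.is_nested_in(full)
        assert not full.is_nested_in(shared)

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            ModelSpec((("a",), ("a", "b")), (("a", "b"),))  # overlap
        with pytest.raises(ValueError):
            ModelSpec((("a",),), (("a", "b"),))  # cover mismatch

    def test_partial_nesting(self):
        tied_rate = ModelSpec(
            c0_partition=(("a", "b", "c", "d"),),
            rho_partition=(("a", "b", "c"), ("d",)),
        )
        full = ModelSpec.full(["a", "b", "c", "d"])
        other = ModelSpec(
            c0_partition=(("a", "b", "c", "d"),),
            rho_partition=(("a", "b"), ("c", "d")),
        )
        assert tied_rate.k == 3
        assert tied_rate.is_nested_in(full)
        assert not tied_rate.is_nested_in(other)
        assert not other.is_nested_in(tied_rate)


class TestEnumeration:
    @pytest.mark.parametrize("g, expected", [(2, 4), (3, 25), (4, 225)])
    def test_bell_squared_counts(self, g, expected):
        groups = [f"g{i}" for i in range(g)]
        specs = enumerate_models(groups)
        assert len(specs) == expected
        assert len(set(specs)) == expected
        ks = [s.k for s in specs]
        assert ks == sorted(ks)
        assert sum(s.k == 2 for s in specs) == 1
        assert sum(s.k == 2 * g for s in specs) == 1

    def test_group_count_bounds(self):
        with pytest.raises(ValueError):
            enumerate_models(["a"])
        with pytest.raises(ValueError):
            enumerate_models([f"g{i}" for i in range(7)])


class TestJointFit:
    def test_fully_shared_noiseless_recovery(self):
        data = [curve(g, 0.5, 0.4) for g in "abcd"]
        res = fit_joint(data, ModelSpec.fully_shared("abcd"))
        assert res.rss == pytest.approx(0.0, abs=1e-12)
        assert res.c0_by_group["a"] == pytest.approx(0.5, abs=1e-6)
        assert res.rho_by_group["c"] == pytest.approx(0.4, abs=1e-6)

    def test_fully_free_equals_separate_fits(self, rng):
        data = [
            curve(g, c0, rho, rng.normal(0, 0.01, 5))
            for g, c0, rho in [("a", 0.5, 0.2), ("b", 0.6, 0.5)]
        ]
        joint = fit_joint(data, ModelSpec.full(["a", "b"]))
        for d in data:
            single = fit_power_law(d.t, d.y, group=d.group)
            assert joint.c0_by_group[d.group] == pytest.approx(
                single.c0_by_group[d.group], abs=1e-6
            )
            assert joint.rho_by_group[d.group] == pytest.approx(
                single.rho_by_group[d.group], abs=1e-6
            )

    def test_nesting_monotonicity(self, rng):
        """Constraining parameters never decreases the pooled RSS."""
        groups = ["a", "b", "c"]
        specs = enumerate_models(groups)
        for _ in range(5):
            data = [
                curve(g, rng.uniform(0.3, 0.7), rng.uniform(0.1, 0.6),
                      rng.normal(0, 0.02, 5))
                for g in groups
            ]
            data = [
                CurveData(d.group, d.t, tuple(np.maximum(d.y, 0.01))) for d in data
            ]
            picks = rng.choice(len(specs), 6, replace=False)
            fits = {specs[int(i)]: fit_joint(data, specs[int(i)]) for i in picks}
            full = fit_joint(data, ModelSpec.full(groups))
            for spec, res in fits.items():
                if spec.is_nested_in(ModelSpec.full(groups)):
                    assert res.rss >= full.rss - 1e-9

    def test_from_dataframe_roundtrip(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 5 + ["b"] * 5,
                "session": list(range(1, 6)) * 2,
                "threshold": list(0.5 * T5**-0.3) + list(0.4 * T5**-0.1),
            }
        )
        model = JointLearningCurveModel.from_dataframe(df)
        res = model.fit()
        assert res.n_points == 10
        assert res.rss == pytest.approx(0.0, abs=1e-12)
        assert "power-law" in res.summary()


class TestNestedFTest:
    def test_equal_fits_give_zero_f(self):
        # reduced model contains the truth, so both fits are perfect
        data = [curve(g, 0.5, 0.4) for g in "ab"]
        full = fit_joint(data, ModelSpec.full("ab"))
        red = fit_joint(data, ModelSpec.fully_shared("ab"))
        cmp = nested_f_test(full, red)
        assert cmp.f_stat == 0.0
        assert cmp.p == 1.0

    def test_df_formula(self, rng):
        """k_full=8, k_reduced=5, N=20 gives df1=3, df2=12."""
        groups = ["a", "b", "c", "d"]
        data = [
            curve(g, rng.uniform(0.4, 0.6), rng.uniform(0.2, 0.5),
                  rng.normal(0, 0.02, 5))
            for g in groups
        ]
        data = [CurveData(d.group, d.t, tuple(np.maximum(d.y, 0.01))) for d in data]
        full = fit_joint(data, ModelSpec.full(groups))
        reduced_spec = ModelSpec(
            c0_partition=(("a", "b"), ("c",), ("d",)),
            rho_partition=(("a", "b"), ("c", "d")),
        )
        assert reduced_spec.k == 5
        cmp = nested_f_test(full, fit_joint(data, reduced_spec))
        assert (cmp.df1, cmp.df2) == (3, 12)

    def test_r2_form_equals_rss_form(self, rng):
        groups = ["a", "b"]
        data = [
            curve(g, rng.uniform(0.4, 0.6), rng.uniform(0.2, 0.5),
                  rng.normal(0, 0.03, 5))
            for g in groups
        ]
        data = [CurveData(d.group, d.t, tuple(np.maximum(d.y, 0.01))) for d in data]
        full = fit_joint(data, ModelSpec.full(groups))
        red = fit_joint(data, ModelSpec.fully_shared(groups))
        cmp = nested_f_test(full, red)
        df1, df2 = cmp.df1, cmp.df2
        f_rss = ((red.rss - full.rss) / df1) / (full.rss / df2)
        assert cmp.f_stat == pytest.approx(f_rss, abs=1e-9)

    def test_non_nested_rejected(self, rng):
        data = [
            curve(g, 0.5, 0.3, rng.normal(0, 0.01, 5)) for g in ["a", "b", "c"]
        ]
        data = [CurveData(d.group, d.t, tuple(np.maximum(d.y, 0.01))) for d in data]
        spec_a = ModelSpec(
            c0_partition=(("a", "b"), ("c",)), rho_partition=(("a",), ("b",), ("c",))
        )
        spec_b = ModelSpec(
            c0_partition=(("a",), ("b", "c")), rho_partition=(("a",), ("b",), ("c",))
        )
        with pytest.raises(ValueError):
            nested_f_test(fit_joint(data, spec_a), fit_joint(data, spec_b))


class TestModelSelection:
    def test_noiseless_shared_structure_is_found(self):
        """With shared C0 and rho tied across three of four groups, selection
        recovers exactly that sharing pattern from noiseless curves."""
        data = [curve(g, 0.45, 0.30) for g in "abc"] + [curve("d", 0.45, 0.12)]
        sel = select_best_model(data)
        assert sel.best_spec.c0_partition == (("a", "b", "c", "d"),)
        assert sel.best_spec.rho_partition == (("a", "b", "c"), ("d",))
        assert not sel.no_candidate
        assert len(sel.table) == 225

    def test_strong_group_differences_keep_the_full_model(self, rng):
        # wildly different curves with tiny noise: no reduction survives
        data = [
            curve(g, c0, rho, rng.normal(0, 1e-4, 5))
            for g, c0, rho in [("a", 0.3, 0.1), ("b", 0.9, 0.8)]
        ]
        sel = select_best_model(data)
        assert sel.best_spec.k == 4  # fully free for two groups

    def test_alpha_validation(self):
        data = [curve(g, 0.5, 0.3) for g in "ab"]
        with pytest.raises(ValueError):
            select_best_model(data, alpha=1.5)


def test_parameter_recovery_from_staircase_cohort(rng):
    """Group-mean staircase thresholds over the early stage recover the
    generative learning rate to within 0.05 (median over replicates)."""
    from vplkit import GroupDesign, generate_cohort, run_session, run_test

    design = GroupDesign(
        groups=("g",),
        n_per_group=12,
        rho_by_group={"g": (0.30, 0.05)},
    )
    errors = []
    for rep in range(6):
        cohort = generate_cohort(design, rng)
        session_means = []
        for t in range(1, 6):
            vals = []
            for obs in cohort:
                if t in (1, 5):
                    _, est = run_test(obs, t, "trained", design, rng)
                else:
                    _, est = run_session(obs, t, design, rng)
                vals.append(est.threshold)
            session_means.append(np.mean(vals))
        res = fit_power_law(np.arange(1, 6), session_means)
        errors.append(res.rho_by_group["group"] - 0.30)
    assert abs(np.median(errors)) < 0.05
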