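"""The exploration algorithms: probing, updates, strategies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protolearn.explore import (
    CoordinateAscentExplorer,
    DeltaVector,
    ExplorationError,
    GradientAscentExplorer,
    LearningConfig,
    ProgressiveExplorer,
    coordinate_candidates,
    gradient_update,
    next_directions,
    probe,
    run_coordinate_ascent,
    run_gradient_ascent,
    run_progressive,
)
from protolearn.objectives import SyntheticObjective, bundled_synthetic
from protolearn.parameters import ParameterDef, ParameterSet

from conftest import make_params


def _delta(deltas, directions=None, base=0.0):
    deltas = np.asarray(deltas, dtype=float)
    s = np.ones(len(deltas), dtype=int) if directions is None else np.asarray(directions)
    return DeltaVector(
        base_objective=base,
        deltas=deltas,
        test_directions=s,
        max_abs=float(np.max(np.abs(deltas))) if len(deltas) else 0.0,
    )


def reference_update(values, deltas, directions, e, step_form="additive"):
    """Literal transcription of the normalized simultaneous update rule.

    Independent of the implementation under test: scalar arithmetic, one
    parameter at a time, straight from the published formula (with the
    signed-slope extension for downward test directions).
    """
    max_abs = max(abs(d) for d in deltas)
    if max_abs == 0:
        return list(values)
    out = []
    for p, d, s in zip(values, deltas, directions):
        g = s * d
        frac = e * abs(g) / max_abs
        if g >= 0:
            out.append(p * (1 + frac))
        elif step_form == "additive":
            out.append(p * (1 - frac))
        else:
            out.append(p / (1 + frac))
    return out


class TestProbe:
    def test_linear_objective_hand_values(self):
        params = make_params(1.0, 1.0, upper=10.0)

        def objective(ps, rng):
            return ps.values[0] + 2.0 * ps.values[1]

        dv = probe(objective, params, 0.1, [1, 1])
        assert dv.base_objective == pytest.approx(3.0)
        assert dv.deltas == pytest.approx([0.1, 0.2])
        assert dv.max_abs == pytest.approx(0.2)

    def test_constant_objective_gives_zero_deltas(self):
        params = make_params(0.4, 0.2)
        dv = probe(lambda ps, rng: 7.0, params, 0.5, [1, -1])
        assert np.all(dv.deltas == 0.0) and dv.max_abs == 0.0

    def test_downward_probe_forms(self):
        params = make_params(0.4)
        seen = []

        def objective(ps, rng):
            seen.append(float(ps.values[0]))
            return 0.0

        probe(objective, params, 0.5, [-1], step_form="additive")
        assert seen[1] == pytest.approx(0.4 * 0.5)
        seen.clear()
        probe(objective, params, 0.5, [-1], step_form="multiplicative")
        assert seen[1] == pytest.approx(0.4 / 1.5)

    def test_non_finite_objective_aborts_with_candidate_name(self):
        params = make_params(0.4, 0.2)

        def objective(ps, rng):
            return float("nan") if ps.values[1] != 0.2 else 1.0

        with pytest.raises(ExplorationError, match="p2"):
            probe(objective, params, 0.5, [1, 1])


class TestGradientUpdate:
    def test_hand_example_mixed_signs(self):
        params = make_params(0.4, 0.2, 0.1)
        updated = gradient_update(params, _delta([2.0, -1.0, 0.0]), 0.5)
        assert updated.values == pytest.approx([0.6, 0.15, 0.1])

    def test_equal_positive_deltas_move_all_by_full_factor(self):
        params = make_params(0.4, 0.2, 0.1)
        updated = gradient_update(params, _delta([3.0, 3.0, 3.0]), 0.2)
        assert updated.values == pytest.approx(params.values * 1.2)

    def test_zero_gradient_skips_update(self):
        params = make_params(0.4, 0.2)
        assert gradient_update(params, _delta([0.0, 0.0]), 0.5) is params

    def test_multiplicative_downward_form(self):
        params = make_params(0.4)
        updated = gradient_update(
            params, _delta([-2.0]), 0.5, step_form="multiplicative"
        )
        assert updated.values[0] == pytest.approx(0.4 / 1.5)

    def test_downward_test_direction_flips_the_slope(self):
        # probing down (s=-1) and seeing improvement means "down helps":
        # the parameter must decrease
        params = make_params(0.4)
        updated = gradient_update(params, _delta([5.0], directions=[-1]), 0.5)
        assert updated.values[0] == pytest.approx(0.4 * 0.5)

    @settings(deadline=None, max_examples=300)
    @given(
        n=st.integers(1, 8),
        e=st.floats(0.01, 0.99),
        seed=st.integers(0, 2**31 - 1),
        step_form=st.sampled_from(["additive", "multiplicative"]),
    )
    def test_matches_literal_formula_transcription(self, n, e, seed, step_form):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.01, 0.9, n)
        deltas = rng.normal(0, 10, n)
        dirs = rng.choice([-1, 1], n)
        params = make_params(*values)
        got = gradient_update(params, _delta(deltas, dirs), e, step_form)
        want = reference_update(values, deltas, dirs, e, step_form)
        # clamp-free region: reference values may exceed bounds, so compare
        # only where the reference stays inside
        for g, w in zip(got.values, want):
            if 1e-12 <= w <= 1.0:
                assert g == pytest.approx(w, rel=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        n=st.integers(2, 8),
        e=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_full_step_and_sign_coherence(self, n, e, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.05, 0.5, n)
        deltas = rng.normal(0, 5, n)
        dirs = rng.choice([-1, 1], n)
        params = make_params(*values)
        dv = _delta(deltas, dirs)
        got = gradient_update(params, dv, e)
        g = dv.slopes
        rel = got.values / params.values
        at_max = np.abs(deltas) == dv.max_abs
        for i in range(n):
            if at_max[i]:
                assert rel[i] == pytest.approx(1 + e if g[i] >= 0 else 1 - e)
            else:
                assert abs(rel[i] - 1) < e
            if g[i] != 0:
                assert np.sign(got.values[i] - params.values[i]) == np.sign(g[i])


class TestNextDirections:
    @pytest.mark.parametrize(
        "dirs,deltas,zero,expected",
        [
            ([1, 1], [3.0, -2.0], "up", [1, -1]),
            ([-1], [5.0], "up", [-1]),  # moving down helped; keep testing down
            ([1], [0.0], "up", [1]),
            ([1], [0.0], "down", [-1]),
        ],
    )
    def test_direction_memory(self, dirs, deltas, zero, expected):
        dv = _delta(deltas, dirs)
        assert next_directions(dv, zero).tolist() == expected


class TestGradientAscentRuns:
    def test_constant_objective_leaves_parameters_unchanged(self, unit_defs):
        cfg = LearningConfig(learning_rate=0.3, rounds=5, seed=0)
        trace = run_gradient_ascent(lambda ps, rng: 1.0, unit_defs, cfg)
        initial = ParameterSet.from_defs(unit_defs).values
        for rec in trace.records:
            assert np.all(rec.params_after.values == initial)
            assert rec.evaluations_used == len(unit_defs) + 1

    def test_single_parameter_monotone_geometric_climb(self):
        # O(p) = p: every round moves up by the full factor until the bound
        defs = (ParameterDef(name="p", initial=0.1),)
        cfg = LearningConfig(learning_rate=0.5, rounds=12, seed=0)
        trace = run_gradient_ascent(lambda ps, rng: ps.values[0], defs, cfg)
        import warnings
        for k, rec in enumerate(trace.records, start=1):
            assert rec.params_after.values[0] == pytest.approx(min(1.0, 0.1 * 1.5**k))

    def test_concave_recovery_at_small_learning_rate(self):
        # log-quadratic surface with a known optimum; e = 0.1 parks every
        # coordinate within 5% and the objective within 1% of its start gap
        obj = bundled_synthetic()
        exp = GradientAscentExplorer(learning_rate=0.1, rounds=200, seed=3).fit(obj)
        start = exp.trace_.records[0].base_objective
        assert abs(exp.objective_value_) <= 0.01 * abs(start)
        rel_err = np.abs(exp.params_.values / obj.optimum - 1)
        assert rel_err.max() < 0.05

    def test_determinism_identical_traces(self):
        obj = bundled_synthetic(noise_sd=0.5)
        a = GradientAscentExplorer(learning_rate=0.2, rounds=8, seed=7).fit(obj)
        b = GradientAscentExplorer(learning_rate=0.2, rounds=8, seed=7).fit(obj)
        for ra, rb in zip(a.trace_.records, b.trace_.records):
            assert ra.base_objective == rb.base_objective
            assert np.all(ra.params_after.values == rb.params_after.values)

    def test_descent_on_o_equals_ascent_on_minus_o(self):
        obj = bundled_synthetic(noise_sd=0.3)

        def neg(ps, rng):
            return -obj(ps, rng)

        down = GradientAscentExplorer(
            learning_rate=0.2, rounds=6, seed=5, direction="descent"
        ).fit(neg, obj.parameter_defs)
        up = GradientAscentExplorer(learning_rate=0.2, rounds=6, seed=5).fit(obj)
        for ra, rb in zip(down.trace_.records, up.trace_.records):
            assert ra.base_objective == rb.base_objective
            assert np.all(ra.params_after.values == rb.params_after.values)

    def test_round_error_reports_round_index(self, unit_defs):
        def objective(ps, rng):
            return float("inf")

        cfg = LearningConfig(rounds=3, seed=0)
        with pytest.raises(ExplorationError, match="round 1"):
            run_gradient_ascent(objective, unit_defs, cfg)

    def test_bounds_hold_after_every_round(self):
        import warnings
        from protolearn.parameters import ClampWarning

        obj = bundled_synthetic(noise_sd=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            exp = GradientAscentExplorer(learning_rate=0.5, rounds=40, seed=11).fit(obj)
        for rec in exp.trace_.records:
            for d, v in zip(rec.params_after.defs, rec.params_after.values):
                assert d.lower <= v <= d.upper


class TestCoordinateAscent:
    def test_seven_candidates_hand_values(self):
        d = ParameterDef(name="p", initial=0.2)
        got = coordinate_candidates(0.2, 0.5, d)
        assert got == pytest.approx([0.2, 0.3, 0.45, 0.675, 0.1, 0.05, 0.025])

    def test_out_of_bounds_candidates_dropped(self):
        d = ParameterDef(name="p", initial=0.9)
        got = coordinate_candidates(0.9, 0.5, d)
        assert len(got) == 4  # 1.35, 2.025, 3.0375 all above the bound
        assert got[0] == pytest.approx(0.9)

    @settings(deadline=None, max_examples=100)
    @given(
        p=st.floats(1e-6, 1.0),
        e=st.floats(0.01, 0.99),
    )
    def test_candidates_match_geometric_ladder(self, p, e):
        d = ParameterDef(name="p", initial=0.5)
        expected = [p] + [p * (1 + e) ** k for k in (1, 2, 3)] + [
            p * (1 - e) ** k for k in (1, 2, 3)
        ]
        expected = [c for c in expected if d.lower <= c <= d.upper]
        assert coordinate_candidates(p, e, d) == pytest.approx(expected)
        assert p in coordinate_candidates(p, e, d) or not (d.lower <= p <= d.upper)

    def test_quadratic_picks_exact_optimum_candidate(self):
        defs = (ParameterDef(name="p", initial=0.2),)

        def objective(ps, rng):
            return -((ps.values[0] - 0.3) ** 2)

        cfg = LearningConfig(learning_rate=0.5, rounds=1, strategy="coordinate", seed=0)
        trace = run_coordinate_ascent(objective, defs, cfg)
        assert trace.final_params.values[0] == pytest.approx(0.3)

    def test_constant_objective_retains_incumbent(self, unit_defs):
        cfg = LearningConfig(learning_rate=0.5, rounds=2, strategy="coordinate", seed=0)
        trace = run_coordinate_ascent(lambda ps, rng: 1.0, unit_defs, cfg)
        assert np.all(
            trace.final_params.values == ParameterSet.from_defs(unit_defs).values
        )

    def test_monotone_on_deterministic_objective(self):
        obj = bundled_synthetic()
        cfg = LearningConfig(learning_rate=0.3, rounds=4, strategy="coordinate", seed=0)
        trace = run_coordinate_ascent(obj, obj.parameter_defs, cfg)
        # installed value never worse than the incumbent at any visit, so the
        # objective is non-decreasing round over round
        objs = [r.base_objective for r in trace.records]
        rng = np.random.default_rng(0)
        assert obj(trace.final_params, rng) >= objs[0]
        assert all(b >= a - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_evaluation_count_seven_per_parameter(self, unit_defs):
        cfg = LearningConfig(learning_rate=0.1, rounds=1, strategy="coordinate", seed=0)
        trace = run_coordinate_ascent(lambda ps, rng: 1.0, unit_defs, cfg)
        assert trace.records[0].evaluations_used == 7 * len(unit_defs)


class TestProgressive:
    def test_single_stage_equals_plain_gradient_ascent(self):
        obj = bundled_synthetic(noise_sd=0.2)
        cfg = LearningConfig(learning_rate=0.2, rounds=6, seed=9)
        plain = run_gradient_ascent(obj, obj.parameter_defs, cfg)
        staged = run_progressive([(obj, 6)], obj.parameter_defs, cfg)
        assert staged.stage_boundaries == ()
        for ra, rb in zip(plain.records, staged.records):
            assert ra.base_objective == rb.base_objective
            assert np.all(ra.params_after.values == rb.params_after.values)

    def test_four_stages_of_fifteen_rounds(self):
        obj = bundled_synthetic()
        exp = ProgressiveExplorer(learning_rate=0.2, seed=2).fit([(obj, 15)] * 4)
        assert len(exp.trace_.records) == 60
        assert exp.stage_boundaries_ == (15, 30, 45)
        rounds = [r.round_index for r in exp.trace_.records]
        assert rounds == list(range(1, 61))

    def test_stages_warm_start_from_previous_final_state(self):
        obj = bundled_synthetic(noise_sd=0.1)
        cfg = LearningConfig(learning_rate=0.2, rounds=1, seed=4)
        trace = run_progressive([(obj, 5), (obj, 5)], obj.parameter_defs, cfg)
        # stage 2's first probe starts exactly from stage 1's final params:
        # replay stage 2 standalone with that warm start and compare
        stage1_final = trace.records[4].params_after
        from protolearn.explore import next_directions, run_gradient_ascent
        from dataclasses import replace

        dirs = next_directions(trace.records[4].delta, "up")
        replay = run_gradient_ascent(
            obj, obj.parameter_defs, replace(cfg, rounds=5),
            initial=stage1_final, initial_directions=dirs, round_offset=5,
        )
        for ra, rb in zip(trace.records[5:], replay.records):
            assert ra.base_objective == rb.base_objective
            assert np.all(ra.params_after.values == rb.params_after.values)

    def test_staged_optimum_recovery(self):
        # stage objectives share one optimum; staging must still find it
        obj = bundled_synthetic()
        exp = ProgressiveExplorer(learning_rate=0.1, seed=6).fit([(obj, 50)] * 4)
        rel_err = np.abs(exp.params_.values / obj.optimum - 1)
        assert rel_err.max() < 0.05

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            ProgressiveExplorer().fit([], defs=bundled_synthetic().parameter_defs)


class TestEstimatorFacade:
    def test_get_params_round_trip(self):
        exp = GradientAscentExplorer(learning_rate=0.3, rounds=7, seed=2)
        clone = GradientAscentExplorer(**exp.get_params())
        assert clone.get_params() == exp.get_params()

    def test_fitted_attributes(self):
        obj = bundled_synthetic()
        exp = CoordinateAscentExplorer(learning_rate=0.3, rounds=2, seed=0).fit(obj)
        assert set(exp.best_params_) == {f"q{i}" for i in range(1, 9)}
        assert exp.n_evaluations_ == sum(
            r.evaluations_used for r in exp.trace_.records
        )

    def test_objective_without_defs_rejected(self):
        with pytest.raises(ValueError, match="parameter defs|parameter definitions"):
            GradientAscentExplorer().fit(lambda ps, rng: 0.0)


class TestLearningConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(learning_rate=0.0),
            dict(learning_rate=1.0),
            dict(rounds=0),
            dict(strategy="annealing"),
            dict(step_form="geometric"),
            dict(replicates_per_evaluation=0),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LearningConfig(**kwargs)
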