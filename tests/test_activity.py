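"""OLS activity model, correlation statistics, classification, outlier screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from g4tune import (
    ActivityRecord,
    Context,
    GeneratorConfig,
    Level,
    LinearActivityModel,
    classify_components,
    context_shift,
    fit_activity_model,
    outlier_screen,
    pearson_r,
    predict_reu,
    simulate_activities,
    simulate_context_panel,
)


def _records_from(features, reus, level=Level.DNA, host="CHO"):
    return [
        ActivityRecord(
            component_label=f"c{i}",
            level=level,
            features=f,
            reu_mean=reu,
            context=Context(cell_host=host),
        )
        for i, (f, reu) in enumerate(zip(features, reus))
    ]


class TestFit:
    def test_noiseless_fit_recovers_exactly(self, dna_specs):
        truth = (120.0, (-8.0, -5.0, 3.0))
        feats = [s.features for s in dna_specs]
        reus = [max(truth[0] + np.dot(truth[1], f), 0.0) for f in feats]
        # keep only unclipped points so the linear model is exact
        keep = [(f, y) for f, y in zip(feats, reus) if y > 0]
        model = fit_activity_model(_records_from(*zip(*keep)), Level.DNA)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(120.0, abs=1e-9)
        assert model.betas == pytest.approx((-8.0, -5.0, 3.0), abs=1e-9)

    def test_parameter_recovery_from_noisy_synthetic_data(self, dna_specs):
        cfg = GeneratorConfig(seed=5, truth_intercept=120.0,
                              truth_betas=(-8.0, -5.0, 3.0), noise_sd=5.0,
                              n_replicates=200)
        sim = simulate_activities(dna_specs, cfg)
        model = fit_activity_model(list(sim.records), Level.DNA)
        for est, true in zip(model.betas, cfg.truth_betas):
            assert abs(est / true - 1.0) < 0.10

    def test_bias_shrinks_with_replicates(self, dna_specs):
        errs = []
        for n in (50, 200, 800):
            cfg = GeneratorConfig(seed=17, n_replicates=n)
            sim = simulate_activities(dna_specs, cfg)
            m = fit_activity_model(list(sim.records), Level.DNA)
            errs.append(
                max(abs(e - t) for e, t in zip(m.betas, cfg.truth_betas))
            )
        assert errs[-1] < errs[0]

    def test_duplicated_feature_is_named_collinear(self):
        feats = [(t, t, 2.0) for t in (2, 3, 4, 5, 6)]
        with pytest.raises(ValueError, match="tract_"):
            fit_activity_model(_records_from(feats, [90, 80, 70, 60, 50]), Level.DNA)

    def test_too_few_records_rejected(self):
        feats = [(2, 4, 1.0), (3, 4, 2.0)]
        with pytest.raises(ValueError):
            fit_activity_model(_records_from(feats, [90, 80]), Level.DNA)

    def test_r_squared_invariant_to_affine_feature_rescaling(self, dna_specs):
        cfg = GeneratorConfig(seed=9)
        sim = simulate_activities(dna_specs, cfg)
        m1 = fit_activity_model(list(sim.records), Level.DNA)
        rescaled = [
            ActivityRecord(r.component_label, r.level,
                           (10 * r.features[0] + 3, 2 * r.features[1] - 1,
                            0.5 * r.features[2] + 7),
                           r.reu_mean, r.reu_sd, r.n_replicates, r.context)
            for r in sim.records
        ]
        m2 = fit_activity_model(rescaled, Level.DNA)
        assert m1.r_squared == pytest.approx(m2.r_squared, abs=1e-9)

    def test_normal_equations_match_grid_search_on_toy_problem(self):
        # brute-force least squares over a coefficient grid, 2 features
        x1 = np.array([1.0, 2, 3, 4, 5, 6])
        x2 = np.array([2.0, 1, 4, 3, 6, 5])
        y = 10 - 2 * x1 + 1 * x2
        feats = [(a, b, 1.0) for a, b in zip(x1, x2)]
        with pytest.raises(ValueError):
            # constant third feature is collinear with the intercept
            fit_activity_model(_records_from(feats, y), Level.DNA)
        feats = [(a, b, 0.1 * a * b) for a, b in zip(x1, x2)]
        model = fit_activity_model(_records_from(feats, y), Level.DNA)
        grid = np.arange(-3, 3.01, 0.001)
        best = None
        for b1 in (-2.0,):
            for b2 in grid:
                pred = 10 - 2 * x1 + b2 * x2
                sse = float(np.sum((y - pred) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, b2)
        assert model.beta_tract_count == pytest.approx(best[1], abs=1e-3)


class TestPredict:
    def test_toy_arithmetic(self):
        m = LinearActivityModel(Level.DNA, 120, -8, -5, 3, 0.9, 0.001, 40)
        assert predict_reu(m, (6, 7, 2)) == pytest.approx(43.0)

    def test_clipping(self):
        m = LinearActivityModel(Level.DNA, 120, -8, -5, 3, 0.9, 0.001, 40)
        assert predict_reu(m, (20, 20, 1)) == 0.0
        assert predict_reu(m, (2, 4, 30)) == 120.0

    def test_fitted_model_is_monotone_in_tract_count(self, dna_specs):
        sim = simulate_activities(dna_specs, GeneratorConfig(seed=2))
        m = fit_activity_model(list(sim.records), Level.DNA)
        preds = [predict_reu(m, (4, tc, 2)) for tc in (4, 5, 6, 7)]
        assert all(a >= b for a, b in zip(preds, preds[1:]))


class TestPearson:
    def test_worked_mrna_panel(self):
        r, p = pearson_r((90, 70, 50, 35), (75, 55, 35, 25))
        assert round(r, 2) >= 0.99
        assert p < 0.01

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        r, p = pearson_r(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identity_and_anti_identity(self):
        x = [1.0, 2, 3, 5]
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50),
        offset=st.floats(-100, 100),
    )
    def test_invariant_to_positive_affine_transforms(self, scale, offset):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        y = [2.0, 3.0, 7.0, 9.0, 4.0]
        r0, _ = pearson_r(x, y)
        r1, _ = pearson_r([scale * v + offset for v in x], y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert pearson_r(x, y)[0] == pytest.approx(pearson_r(y, x)[0])


class TestClassification:
    @pytest.mark.parametrize(
        "reu,expected",
        [(79.9, "structure_acting"), (80.0, "insertional_only"), (5.0, "structure_acting")],
    )
    def test_strict_threshold_boundary(self, reu, expected):
        recs = _records_from([(4, 4, 2.0)], [reu])
        parts = classify_components(recs)
        assert recs[0] in parts[expected]

    def test_mixed_contexts_rejected(self):
        a = _records_from([(4, 4, 2.0)], [50], host="CHO")
        b = _records_from([(4, 5, 2.0)], [50], host="HEK")
        with pytest.raises(ValueError):
            classify_components(a + b)

    def test_partition_matches_generator_labels_away_from_boundary(self, dna_specs):
        cfg = GeneratorConfig(seed=8)
        sim = simulate_activities(dna_specs, cfg)
        parts = classify_components(list(sim.records))
        truth = sim.truth_map
        for rec in sim.records:
            true_reu = truth[rec.component_label]
            if abs((100 - true_reu) - 20) < 5:
                continue  # within 5 REU of the boundary: noise may flip it
            expected = (100 - true_reu) > 20
            assert (rec in parts["structure_acting"]) == expected


class TestOutlierScreen:
    def test_planted_outlier_is_the_only_flag(self):
        rng = np.random.default_rng(4)
        x = np.linspace(10, 100, 24)
        y = 0.9 * x + 5 + rng.normal(0, 2.0, size=24)
        y[10] += 25.0
        res = outlier_screen(y, x)
        assert res.flags == tuple(i == 10 for i in range(24))
        assert res.r_after > res.r_before

    def test_perfectly_linear_data_unflagged(self):
        x = np.arange(10.0)
        res = outlier_screen(2 * x + 1, x)
        assert not any(res.flags)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            outlier_screen([1, 2, 3], [1, 2, 3])


class TestContextShift:
    def test_constant_offset(self):
        a = _records_from([(4, 4, 2.0)] * 4, [90, 70, 50, 30])
        b = [
            ActivityRecord(r.component_label, r.level, r.features, r.reu_mean + 7,
                           context=Context(cell_host="HEK"))
            for r in a
        ]
        shift, r = context_shift(a, b)
        assert shift == pytest.approx(7.0)
        assert r == pytest.approx(1.0)

    def test_identity_panels(self):
        a = _records_from([(4, 4, 2.0)] * 3, [90, 50, 30])
        shift, r = context_shift(a, a)
        assert shift == 0.0 and r == pytest.approx(1.0)

    def test_unpaired_labels_listed(self):
        a = _records_from([(4, 4, 2.0)] * 3, [90, 50, 30])
        with pytest.raises(ValueError, match="c2"):
            context_shift(a, a[:2])

    def test_simulated_hek_shift_recovered_within_2_reu(self, dna_specs):
        cfg = GeneratorConfig(seed=12)
        sim = simulate_activities(dna_specs, cfg)
        hek = simulate_context_panel(
            list(sim.records), "HEK", cfg, truth=sim.truth_map
        )
        shift, r = context_shift(list(sim.records), hek)
        assert abs(shift - 7.0) < 2.0
        assert r > 0.9
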