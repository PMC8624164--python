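import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enceladus_niche.io_formats import EnvStack, GridTransform, OccurrenceTable
from enceladus_niche.niche_envelope import (
    EnvelopeModel,
    clean_and_split,
    correlation_filter,
    fit_bioclim,
    predict_suitability,
    response_curve,
)
from enceladus_niche.synthetic_data import (
    SimConfig,
    generate_layers,
    generate_occurrences,
)


def brute_force_score(values, x):
    """Independent oracle: percentile-distance score by direct rank count."""
    values = list(values)
    n = len(values)
    lo, hi = min(values), max(values)
    if lo == hi:
        return 1.0 if x == lo else 0.0
    if x < lo or x > hi:
        return 0.0
    f = (sum(v < x for v in values) + 0.5 * sum(v == x for v in values)) / n
    return min(max(2.0 * min(f, 1.0 - f), 0.0), 1.0)


class TestMarginalScore:
    @pytest.fixture()
    def model(self):
        return EnvelopeModel(
            taxon="t", training={"v": np.array([1.0, 2.0, 3.0, 4.0, 5.0])})

    @pytest.mark.parametrize(
        "x,expected",
        [(3.0, 1.0),    # median: F = 0.5
         (6.0, 0.0),    # outside the envelope
         (0.0, 0.0),
         (2.0, 0.6)],   # F = 1.5/5 = 0.3
    )
    def test_hand_computed_midpoint_ecdf(self, model, x, expected):
        assert model.marginal_score("v", x) == pytest.approx(expected)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        values=st.lists(st.integers(min_value=-5, max_value=5),
                        min_size=1, max_size=8),
        x=st.floats(min_value=-7, max_value=7, allow_nan=False),
    )
    def test_agrees_with_brute_force_rank_count(self, values, x):
        vals = np.sort(np.array(values, dtype=float))
        model = EnvelopeModel(taxon="t", training={"v": vals})
        assert model.marginal_score("v", x) == pytest.approx(
            brute_force_score(values, x))

    def test_degenerate_point_envelope(self):
        model = EnvelopeModel(taxon="t", training={"v": np.array([2.0, 2.0])})
        assert model.marginal_score("v", 2.0) == 1.0
        assert model.marginal_score("v", 2.1) == 0.0


class TestCleanAndSplit:
    def _table(self, stack, n):
        centers = [stack.transform.cell_center(r, c)
                   for r in range(stack.shape[0]) for c in range(stack.shape[1])]
        return OccurrenceTable(taxon="t", records=centers[:n])

    def test_exact_duplicates_removed(self, small_stack):
        table = self._table(small_stack, 4)
        table.records.append(table.records[0])
        occ = clean_and_split(table, small_stack, seed=0)
        assert len(occ.records) == 4
        assert occ.n_duplicates_removed == 1

    def test_75_25_partition(self, small_stack):
        occ = clean_and_split(self._table(small_stack, 40), small_stack, seed=0)
        assert occ.counts()["train"] == 30
        assert occ.counts()["test"] == 10

    def test_nodata_records_dropped(self):
        stack = generate_layers(
            SimConfig(shape=(20, 20), nodata_fraction=0.3, seed=2))
        nodata_cells = np.argwhere(~stack.valid_mask)
        valid_cells = np.argwhere(stack.valid_mask)
        records = [stack.transform.cell_center(*rc) for rc in nodata_cells[:2]]
        records += [stack.transform.cell_center(*rc) for rc in valid_cells[:8]]
        occ = clean_and_split(OccurrenceTable("t", records), stack, seed=0)
        assert occ.n_nodata_dropped == 2
        assert len(occ.records) == 8

    def test_too_few_records_fatal(self, small_stack):
        with pytest.raises(ValueError, match="need >= 2"):
            clean_and_split(self._table(small_stack, 1), small_stack, seed=0)

    def test_extraction_matches_cells(self, occ_set, small_stack):
        for i in [0, len(occ_set.records) - 1]:
            lon, lat = occ_set.records[i]
            r, c = small_stack.transform.index(lon, lat)
            for name in small_stack.names:
                assert occ_set.extraction[name].iloc[i] == \
                    small_stack.layers[name][r, c]


class TestCorrelationFilter:
    def test_exact_copy_removed(self, small_stack):
        layers = dict(small_stack.layers)
        layers["temperature_copy"] = small_stack.layers["temperature"].copy()
        stack = EnvStack(layers=layers, transform=small_stack.transform,
                         nodata=small_stack.nodata)
        kept = correlation_filter(stack, n_points=2000, seed=0)
        assert "temperature_copy" not in kept
        assert "temperature" in kept

    def test_independent_noise_layers_retained(self):
        rng = np.random.default_rng(4)
        tf = GridTransform(0.0, 50.0, 0.5)
        layers = {f"w{i}": rng.standard_normal((100, 100)) for i in range(3)}
        stack = EnvStack(layers=layers, transform=tf, nodata=-9999.0)
        kept = correlation_filter(stack, n_points=10_000, seed=1)
        assert kept == ["w0", "w1", "w2"]

    def test_highly_correlated_pair_drops_later_member(self):
        rng = np.random.default_rng(8)
        tf = GridTransform(0.0, 30.0, 0.5)
        a = rng.standard_normal((60, 60))
        b = a + 0.3 * rng.standard_normal((60, 60))  # r ~ 0.96
        stack = EnvStack(layers={"a": a, "b": b}, transform=tf, nodata=-9999.0)
        sample = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert abs(sample) >= 0.8
        assert correlation_filter(stack, n_points=3600, seed=2) == ["a"]

    def test_zero_variance_layer_dropped(self, small_stack):
        layers = dict(small_stack.layers)
        layers["flat"] = np.full(small_stack.shape, 3.0)
        stack = EnvStack(layers=layers, transform=small_stack.transform,
                         nodata=small_stack.nodata)
        assert "flat" not in correlation_filter(stack, n_points=500, seed=0)


class TestPredictSuitability:
    def test_bounded_and_below_every_marginal(self, occ_set, small_stack):
        model = fit_bioclim(occ_set, small_stack)
        grid = predict_suitability(model, small_stack)
        valid = small_stack.valid_mask
        assert grid[valid].min() >= 0.0 and grid[valid].max() <= 1.0
        for var in model.variables:
            marg = model.marginal_score(var, small_stack.layers[var][valid])
            assert np.all(grid[valid] <= marg + 1e-12)

    def test_median_cells_score_one(self, occ_set, small_stack):
        model = fit_bioclim(occ_set, small_stack)
        layers = {
            v: np.full((2, 2), np.median(model.training[v]))
            for v in model.variables
        }
        stack = EnvStack(layers=layers, transform=small_stack.transform,
                         nodata=small_stack.nodata)
        np.testing.assert_allclose(predict_suitability(model, stack), 1.0)

    def test_min_rule_zero_propagates(self, occ_set, small_stack):
        model = fit_bioclim(occ_set, small_stack)
        layers = {
            v: np.full((2, 2), np.median(model.training[v]))
            for v in model.variables
        }
        layers["temperature"][:] = model.limits("temperature")[1] + 10.0
        stack = EnvStack(layers=layers, transform=small_stack.transform,
                         nodata=small_stack.nodata)
        np.testing.assert_array_equal(predict_suitability(model, stack), 0.0)

    def test_training_occurrences_score_positive(self, occ_set, small_stack):
        """Training points lie inside their own envelope (boundary may hit 0+)."""
        model = fit_bioclim(occ_set, small_stack)
        scores = model.score_frame(occ_set.subset_extraction("train"))
        assert np.all(scores >= 0.0)
        assert np.mean(scores > 0.0) > 0.9

    def test_nodata_propagates(self):
        stack = generate_layers(
            SimConfig(shape=(25, 25), nodata_fraction=0.2, seed=6))
        occ = generate_occurrences(
            stack,
            __import__("enceladus_niche").default_true_envelope(stack),
            n=80, seed=1)
        occ_set = clean_and_split(occ, stack, seed=2)
        grid = predict_suitability(fit_bioclim(occ_set, stack), stack)
        assert np.all(grid[~stack.valid_mask] == stack.nodata)


class TestResponseCurve:
    @pytest.fixture()
    def curve_and_model(self, occ_set, small_stack):
        model = fit_bioclim(occ_set, small_stack)
        return response_curve(model, "salinity"), model

    def test_unit_score_at_training_median(self, curve_and_model):
        curve, model = curve_and_model
        med = np.median(model.training["salinity"])
        assert curve.score_at(med) == pytest.approx(1.0)
        assert curve.scores.max() == pytest.approx(1.0)

    def test_zero_outside_suitable_range(self, curve_and_model):
        curve, _ = curve_and_model
        lo, hi = curve.suitable_range
        outside = (curve.values < lo) | (curve.values > hi)
        assert outside.any()
        assert np.all(curve.scores[outside] == 0.0)

    def test_unimodal_about_the_median(self, curve_and_model):
        curve, model = curve_and_model
        med = np.median(model.training["salinity"])
        below = curve.scores[curve.values <= med]
        above = curve.scores[curve.values >= med]
        assert np.all(np.diff(below) >= -1e-12)
        assert np.all(np.diff(above) <= 1e-12)

    def test_grid_spans_ten_percent_padding(self, curve_and_model):
        curve, _ = curve_and_model
        lo, hi = curve.suitable_range
        span = hi - lo
        assert curve.values[0] == pytest.approx(lo - 0.1 * span)
        assert curve.values[-1] == pytest.approx(hi + 0.1 * span)


class TestEnvelopeRecovery:
    def test_fitted_envelope_contained_in_truth(self, occ_set, small_stack,
                                                truth):
        model = fit_bioclim(occ_set, small_stack)
        for var, (lo, hi) in truth.limits.items():
            flo, fhi = model.limits(var)
            assert lo <= flo <= fhi <= hi

    def test_envelope_tightens_with_sample_size(self):
        from enceladus_niche import default_true_envelope

        stack = generate_layers(SimConfig(shape=(60, 60), seed=17))
        truth = default_true_envelope(stack)

        def hausdorff_sum(n, seed):
            occ = generate_occurrences(stack, truth, n=n, seed=seed)
            occ_set = clean_and_split(occ, stack, seed=seed + 1)
            model = fit_bioclim(occ_set, stack)
            total = 0.0
            for var, (lo, hi) in truth.limits.items():
                flo, fhi = model.limits(var)
                span = hi - lo
                total += max(abs(flo - lo), abs(fhi - hi)) / span
            return total

        assert hausdorff_sum(3000, 5) < hausdorff_sum(30, 5)


def test_model_json_round_trip(occ_set, small_stack):
    model = fit_bioclim(occ_set, small_stack)
    back = EnvelopeModel.from_dict(model.to_dict())
    assert back.variables == model.variables
    for var in model.variables:
        np.testing.assert_allclose(back.training[var], model.training[var])
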