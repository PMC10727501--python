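import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habituscope import fingerprint as fp
from habituscope.synth import simulate_screen


def make_events(rows):
    """rows: (fish, time, amp) triples with filler kinematics."""
    return pd.DataFrame(
        [(f, "W1", t, a, 0.1, 2.0, 0.8, 0.3, 20.0) for f, t, a in rows],
        columns=fp.EVENT_COLUMNS)


class TestDetectResponses:
    def test_threshold_application_by_hand(self):
        ev = make_events([("f1", 0.1, 3.5), ("f1", 10.1, 2.0),
                          ("f1", 20.1, 1.2)])
        out = fp.detect_responses(ev, [0.0, 10.0, 20.0], "dark_flash")
        assert list(out["responded"]) == [True, False, False]

    def test_tap_uses_one_radian_threshold(self):
        ev = make_events([("f1", 0.1, 1.2)])
        df = fp.detect_responses(ev, [0.0], "dark_flash")
        tap = fp.detect_responses(ev, [0.0], "tap")
        assert not df["responded"][0] and tap["responded"][0]

    def test_no_events_no_responses(self):
        ev = make_events([])
        out = fp.detect_responses(ev, [0.0, 10.0], "dark_flash",
                                  fish_ids=["f1"])
        assert len(out) == 2 and not out["responded"].any()

    def test_components_from_first_qualifying_event(self):
        ev = make_events([("f1", 0.2, 4.0), ("f1", 0.5, 6.0)])
        out = fp.detect_responses(ev, [0.0], "dark_flash")
        assert out["bend_amplitude"][0] == 4.0
        assert out["n_events"][0] == 2 and out["multi_response"][0] == 1.0

    def test_overlapping_windows_rejected(self):
        ev = make_events([("f1", 0.1, 4.0)])
        with pytest.raises(ValueError, match="ambiguous"):
            fp.detect_responses(ev, [0.0, 0.5], "dark_flash", window=1.0)


class TestEpochMeans:
    def test_probability_arithmetic(self):
        ev = make_events([("f1", 0.1, 4.0), ("f1", 10.1, 4.0)])
        resp = fp.detect_responses(ev, [0, 10, 20, 30, 40], "dark_flash")
        means = fp.epoch_component_means(resp, {"naive": range(1, 6)},
                                         ["probability", "latency"])
        assert means.loc["f1", "probability_naive"] == pytest.approx(0.4)

    def test_nonresponders_excluded_except_probability(self):
        ev = make_events([])
        resp = fp.detect_responses(ev, [0, 10, 20], "dark_flash",
                                   fish_ids=["f1"])
        means = fp.epoch_component_means(resp, {"naive": range(1, 4)},
                                         ["probability", "latency"])
        assert means.loc["f1", "probability_naive"] == 0.0
        assert np.isnan(means.loc["f1", "latency_naive"])

    def test_incomplete_tracking_yields_missing(self):
        ev = make_events([("f1", 0.1, 4.0)])
        resp = fp.detect_responses(ev, [0, 10], "dark_flash")
        means = fp.epoch_component_means(
            resp, {"test": range(1, 3)}, ["probability", "latency"],
            incomplete={"f1": {"test"}})
        assert means.loc["f1"].isna().all()

    def test_probability_required(self):
        with pytest.raises(ValueError):
            fp.epoch_component_means(pd.DataFrame({"fish_id": [],
                                                   "stim": []}),
                                     {}, ["latency"])


class TestSSMD:
    def test_identical_groups_zero(self):
        assert fp.ssmd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_closed_form(self):
        # means 2 and 0, sample variances 1 and 1 -> 2/sqrt(2)
        assert fp.ssmd([1, 2, 3], [-1, 0, 1]) == pytest.approx(np.sqrt(2))

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [0.5, 0.1, 3.0]
        assert fp.ssmd(a, b) == pytest.approx(-fp.ssmd(b, a))

    def test_degenerate_variance_signalled(self):
        with pytest.raises(ValueError, match="degenerate variance"):
            fp.ssmd([1.0, 1.0], [2.0, 2.0])
        assert fp.ssmd([1.0, 1.0], [1.0, 1.0]) == 0.0

    def test_small_groups_give_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(fp.ssmd([1.0], [1.0, 2.0]))

    @settings(deadline=None, max_examples=50)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_shift_invariance_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 9)
        base = fp.ssmd(a, b)
        assert fp.ssmd(a + shift, b + shift) == pytest.approx(base)
        assert fp.ssmd(a * scale, b * scale) == pytest.approx(base)


class TestHits:
    def test_zero_fingerprint_not_a_hit(self):
        df = pd.DataFrame({"m1": [0.0], "m2": [0.0]}, index=["c1"])
        assert not fp.call_hits(df).any()

    def test_threshold_inclusive(self):
        df = pd.DataFrame({"m1": [-2.0, -1.99]}, index=["c1", "c2"])
        hits = fp.call_hits(df, 2.0)
        assert hits["c1"] and not hits["c2"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(0, 1.5, (30, 5)))
        h1 = fp.call_hits(df, 1.0)
        h2 = fp.call_hits(df, 2.5)
        assert not (h2 & ~h1).any()


@pytest.fixture(scope="module")
def null_matrix(small_screen):
    events, layout, schedule = small_screen
    return fp.assemble_fingerprint(events, layout, schedule)


class TestAssembly:
    def test_default_spec_47_measures(self, null_matrix):
        assert len(fp.MeasureSpec().names) == 47
        assert null_matrix.values.shape[1] == 47

    def test_null_fingerprints_centred_on_zero(self, null_matrix):
        vals = null_matrix.values.to_numpy()
        assert np.nanmean(np.abs(np.nanmean(vals, axis=0))) < 0.6
        assert abs(np.nanmean(vals)) < 0.3

    def test_planted_effect_dominates_its_column(self, small_screen):
        _, layout, schedule = small_screen
        events, _ = simulate_screen(
            layout, {"C3": {"df_bend_amplitude_training": 3.0}},
            schedule=schedule, seed=21)
        mat = fp.assemble_fingerprint(events, layout, schedule)
        row = mat.values.loc["C3"]
        assert row.idxmax() == "df_bend_amplitude_training"
        assert row["df_bend_amplitude_training"] >= 2.0

    def test_paralysed_compound_not_viable(self, small_screen):
        _, layout, schedule = small_screen
        events, _ = simulate_screen(layout, {"C2": "paralysis"},
                                    schedule=schedule, seed=22)
        mat = fp.assemble_fingerprint(events, layout, schedule)
        assert not mat.viable["C2"]
        assert "C2" not in mat.values.index  # row excluded
        assert mat.viable.drop("C2").all()

    def test_needs_vehicle_wells(self, small_screen):
        events, layout, schedule = small_screen
        bare = fp.PlateLayout(wells={w: r for w, r in layout.wells.items()
                                     if r[0] == "treatment"})
        with pytest.raises(ValueError, match="vehicle"):
            fp.assemble_fingerprint(events, bare, schedule)


class TestFingerprintClustering:
    def test_identical_fingerprints_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, -1.0]],
                          index=["a", "b", "c"], columns=["m1", "m2"])
        link, flat, order = fp.cluster_fingerprints(df)
        assert link[0, 2] == 0.0  # first merge at distance zero
        assert len(order) == 3

    def test_orthogonal_phenotype_groups_separate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, (12, 10))
        x[:6, :3] += 6.0   # phenotype A
        x[6:, 5:8] -= 6.0  # phenotype B
        df = pd.DataFrame(x, index=[f"c{i}" for i in range(12)])
        _, flat, _ = fp.cluster_fingerprints(df, threshold=9.5)
        assert flat.nunique() == 2
        assert flat.iloc[:6].nunique() == 1 and flat.iloc[6:].nunique() == 1

    def test_single_hit_rejected(self):
        with pytest.raises(ValueError):
            fp.cluster_fingerprints(pd.DataFrame([[1.0]]))


class TestMeasureCorrelogram:
    def test_diagonal_and_duplicate_measure(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"m1": rng.normal(size=10)})
        df["m2"] = df["m1"]
        df["m3"] = rng.normal(size=10)
        corr, order, _ = fp.measure_correlogram(df)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["m1", "m2"] == pytest.approx(1.0)

    def test_zero_variance_measure_zeroed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"m1": rng.normal(size=8),
                           "m2": np.ones(8), "m3": rng.normal(size=8)})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _, _ = fp.measure_correlogram(df)
        assert corr.loc["m2", "m1"] == 0.0
        assert corr.loc["m2", "m2"] == 1.0

    def test_latent_effect_recovered(self):
        # two measures driven by one latent compound effect correlate at
        # the product of their loadings
        rng = np.random.default_rng(3)
        latent = rng.normal(size=4000)
        df = pd.DataFrame({
            "m1": 0.9 * latent + np.sqrt(1 - 0.81) * rng.normal(size=4000),
            "m2": 0.8 * latent + np.sqrt(1 - 0.64) * rng.normal(size=4000),
            "m3": rng.normal(size=4000)})
        corr, _, _ = fp.measure_correlogram(df)
        assert corr.loc["m1", "m2"] == pytest.approx(0.72, abs=0.05)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        p = np.full(60, 0.4)
        assert np.allclose(fp.smooth_response_curve(p), p)

    def test_quadratic_exactly_reproduced(self):
        x = np.arange(60, dtype=float)
        p = 0.01 * x ** 2 - 0.3 * x + 2.0
        assert np.allclose(fp.smooth_response_curve(p), p)

    def test_step_matches_local_least_squares(self):
        # independent oracle: centred order-2 polynomial fit per window
        p = np.zeros(60)
        p[30:] = 1.0
        sm = fp.smooth_response_curve(p)
        half = 7
        for i in range(half, 60 - half):
            w = p[i - half:i + half + 1]
            coef = np.polyfit(np.arange(-half, half + 1), w, 2)
            assert sm[i] == pytest.approx(np.polyval(coef, 0.0), abs=1e-9)

    def test_short_series_warned_unsmoothed(self):
        p = np.arange(10, dtype=float)
        with pytest.warns(UserWarning):
            out = fp.smooth_response_curve(p)
        assert np.array_equal(out, p)


class TestOMR:
    EPOCHS = [(0.0, 30.0, 1), (30.0, 60.0, -1), (60.0, 90.0, 1),
              (90.0, 120.0, -1)]

    def test_no_events_zero(self):
        assert fp.omr_score([], [], self.EPOCHS) == 0.0

    def test_reversing_directions_negates(self):
        t = np.array([5.0, 40.0, 70.0, 100.0])
        h = np.array([0.5, -0.4, 0.6, -0.2])
        rev = [(a, b, -d) for a, b, d in self.EPOCHS]
        assert fp.omr_score(t, h, rev) == pytest.approx(
            -fp.omr_score(t, h, self.EPOCHS))

    def test_planted_bias_recovered(self):
        # one event per epoch turning b radians toward the motion direction
        b = 0.7
        t = np.array([10.0, 40.0, 70.0, 100.0])
        h = np.array([d * b for _, _, d in self.EPOCHS])
        assert fp.omr_score(t, h, self.EPOCHS) == pytest.approx(b)

    def test_balanced_constant_turning_cancels(self):
        t = np.array([10.0, 40.0, 70.0, 100.0])
        h = np.full(4, 0.3)
        assert fp.omr_score(t, h, self.EPOCHS) == pytest.approx(0.0)


class TestRecount:
    def test_recount_matches_call_hits(self, tmp_path, small_screen):
        events, layout, schedule = small_screen
        mat = fp.assemble_fingerprint(events, layout, schedule)
        path = tmp_path / "fp.tsv"
        mat.to_tsv(path)
        n_viable, n_hits = fp.recount_hits(path)
        assert n_viable == len(mat.values)
        assert n_hits == int(fp.call_hits(mat.values).sum())
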