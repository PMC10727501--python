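import numpy as np
import pandas as pd
import pytest

from conftest import hungarian_accuracy
from habituscope import funcluster as fc
from habituscope.protocol import build_regressors
from habituscope.synth import archetype_template, default_archetypes


@pytest.fixture(scope="module")
def regressors(imaging_proto, kernel):
    return build_regressors(imaging_proto, kernel)


class TestCorrelateRois:
    def test_trace_equal_to_regressor(self, regressors):
        r = regressors.regressors["full_all"]
        corr = fc.correlate_rois(np.array([r, -r]), regressors)
        assert corr.loc[0, "full_all"] == pytest.approx(1.0)
        assert corr.loc[1, "full_all"] == pytest.approx(-1.0)

    def test_pure_noise_below_threshold(self, regressors):
        rng = np.random.default_rng(0)
        n = len(regressors.regressors["full_all"])
        corr = fc.correlate_rois(rng.standard_normal((50, n)), regressors)
        assert corr.abs().to_numpy().max() < 0.25

    def test_zero_variance_trace_warned(self, regressors):
        n = len(regressors.regressors["full_all"])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = fc.correlate_rois(np.zeros((1, n)), regressors)
        assert (corr.loc[0] == 0).all()

    def test_incompatible_lengths_rejected(self, regressors):
        with pytest.raises(ValueError, match="incompatible"):
            fc.correlate_rois(np.random.default_rng(1).normal(size=(2, 100)),
                              regressors)

    def test_affine_rescaling_invariance(self, regressors):
        rng = np.random.default_rng(2)
        n = len(regressors.regressors["full_all"])
        x = rng.standard_normal((5, n)) + regressors.regressors["full_all"]
        a = fc.correlate_rois(x, regressors)
        b = fc.correlate_rois(3.0 * x - 7.0, regressors)
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestFilters:
    def test_tuned_threshold_inclusive(self):
        corr = pd.DataFrame({"a": [0.25, 0.2499, -0.9]})
        mask = fc.filter_stimulus_tuned(corr)
        assert list(mask) == [True, False, False]

    def test_cross_fish_constructed_instance(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(500)
        # ROI 0 (fish 0) has 5 near-copies in fish 1; ROI 6 has only 4;
        # ROI 11 is unique to fish 0
        traces = [base]
        fish = [0]
        for _ in range(5):
            traces.append(base + 0.2 * rng.standard_normal(500))
            fish.append(1)
        other = rng.standard_normal(500)
        traces.append(other)
        fish.append(0)
        for _ in range(4):
            traces.append(other + 0.2 * rng.standard_normal(500))
            fish.append(1)
        traces.append(rng.standard_normal(500))
        fish.append(0)
        keep = fc.cross_fish_filter(np.array(traces), np.array(fish),
                                    corr_thresh=0.3, min_matches=5)
        assert keep[0]           # five matches in the other fish
        assert not keep[6]       # exactly four matches -> removed
        assert not keep[11]      # unique ROI removed

    def test_single_fish_rejected(self):
        with pytest.raises(ValueError):
            fc.cross_fish_filter(np.zeros((3, 10)), np.zeros(3))

    def test_filters_are_order_stable(self, small_roi_sim, regressors):
        table, _ = small_roi_sim
        corr = fc.correlate_rois(table.traces, regressors)
        tuned = fc.filter_stimulus_tuned(corr)
        # applying the cross-fish filter after the tuning filter equals
        # intersecting both keep-sets computed on the same candidate pool
        candidates = table.select(tuned)
        repro = fc.cross_fish_filter(candidates.traces, candidates.fish_id)
        both = np.flatnonzero(tuned)[repro]
        mask2 = np.zeros(table.n_rois, bool)
        mask2[both] = True
        assert np.array_equal(mask2, _intersect(table, tuned))


def _intersect(table, tuned):
    repro_full = np.zeros(table.n_rois, bool)
    cand = table.select(tuned)
    repro_full[np.flatnonzero(tuned)] = fc.cross_fish_filter(
        cand.traces, cand.fish_id)
    return tuned & repro_full


class TestAffinityPropagation:
    def test_identical_traces_one_cluster(self):
        rng = np.random.default_rng(4)
        t = rng.standard_normal(300)
        labels, exemplars = fc.affinity_propagation_cluster(
            np.tile(t, (20, 1)))
        assert len(exemplars) == 1 and len(set(labels)) == 1

    def test_three_planted_archetypes_recovered(self, small_roi_sim,
                                                regressors):
        table, truth = small_roi_sim
        corr = fc.correlate_rois(table.traces, regressors)
        tuned = fc.filter_stimulus_tuned(corr)
        cand = table.select(tuned)
        keep = fc.cross_fish_filter(cand.traces, cand.fish_id)
        kept = cand.select(keep)
        labels, exemplars = fc.affinity_propagation_cluster(kept.traces)
        assert len(exemplars) == 3
        truth_kept = truth.labels.loc[np.flatnonzero(tuned)[keep], "label"]
        assert hungarian_accuracy(list(truth_kept), list(labels)) >= 0.95

    def test_too_few_rois(self):
        with pytest.raises(ValueError):
            fc.affinity_propagation_cluster(np.zeros((1, 10)))


@pytest.fixture(scope="module")
def named_model(small_roi_sim, regressors, imaging_proto):
    table, truth = small_roi_sim
    corr = fc.correlate_rois(table.traces, regressors)
    tuned = fc.filter_stimulus_tuned(corr)
    cand = table.select(tuned)
    keep = fc.cross_fish_filter(cand.traces, cand.fish_id)
    kept = cand.select(keep)
    labels, _ = fc.affinity_propagation_cluster(kept.traces)
    model = fc.order_and_name_clusters(kept.traces, labels, imaging_proto)
    truth_kept = truth.labels.loc[
        np.flatnonzero(tuned)[keep], "label"].to_numpy()
    return model, labels, truth_kept


class TestTaxonomy:
    def test_planted_taxonomy_recovered(self, named_model):
        model, labels, truth_kept = named_model
        # the simulation planted an On/noA, an L/strgD and an M/Pot class
        got = set(zip(model.shape, model.adaptation))
        assert got == {("On", "noA"), ("L", "strgD"), ("M", "Pot")}

    def test_ids_follow_tree_order_and_names_compose(self, named_model):
        model, _, _ = named_model
        for i, name in enumerate(model.names):
            assert name == f"{i + 1}{model.shape[i]}{model.adaptation[i]}"

    def test_flat_trace_labels_noA(self, imaging_proto):
        rate = imaging_proto.sample_rate
        n = int(round(imaging_proto.duration * rate))
        flat = np.zeros(n)
        adapt, shape = fc.classify_cluster(flat, imaging_proto, rate)
        assert adapt == "noA"

    def test_full_taxonomy_on_noise_free_templates(self, imaging_proto,
                                                   kernel):
        rate = imaging_proto.sample_rate
        for spec in default_archetypes():
            tpl = archetype_template(spec, imaging_proto, kernel, rate)
            z = (tpl - tpl.mean()) / tpl.std()
            adapt, shape = fc.classify_cluster(z, imaging_proto, rate)
            assert (adapt, shape) == (spec.adaptation, spec.shape), spec.name


class TestReassignment:
    @pytest.fixture()
    def means(self):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((3, 400))
        return (m - m.mean(1, keepdims=True)) / m.std(1, keepdims=True)

    def test_idempotent_on_cluster_means(self, means):
        out = fc.reassign_all_rois(means, means)
        assert list(out["cluster"]) == [0, 1, 2]
        assert np.allclose(out["corr"], 1.0)

    def test_threshold_boundary(self, means):
        rng = np.random.default_rng(6)
        u = rng.standard_normal(400)
        m0 = means[0]
        u = u - (u @ m0) / (m0 @ m0) * m0  # orthogonalise
        u = (u - u.mean()) / u.std()
        x029 = 0.29 * m0 + np.sqrt(1 - 0.29 ** 2) * u
        out = fc.reassign_all_rois(x029[None, :], means)
        assert out["cluster"][0] == -1  # below 0.3 stays unassigned
        # a threshold equal to the achieved correlation assigns (inclusive)
        got = fc.reassign_all_rois(x029[None, :], means,
                                   threshold=float(out["corr"][0]))
        assert got["cluster"][0] == 0
        x031 = 0.31 * m0 + np.sqrt(1 - 0.31 ** 2) * u
        assert fc.reassign_all_rois(x031[None, :], means)["cluster"][0] == 0

    def test_ties_break_to_lowest_cluster(self, means):
        dup = np.vstack([means[1], means[1], means[0]])
        out = fc.reassign_all_rois(means[1][None, :], dup)
        assert out["cluster"][0] == 0


class TestMotorCorrelation:
    def test_motor_locked_cluster_ranks_highest(self, imaging_proto, kernel):
        rng = np.random.default_rng(7)
        rate = imaging_proto.sample_rate
        flags = rng.random(60) < 0.5
        reg = fc.build_motion_regressor(flags, imaging_proto, kernel, rate)
        reg = (reg - reg.mean()) / reg.std()
        n = len(reg)
        traces = np.vstack([reg + 0.5 * rng.standard_normal((40, n)),
                            rng.standard_normal((40, n))])
        assign = pd.DataFrame({"cluster": [0] * 40 + [1] * 40,
                               "corr": np.ones(80)})
        out = fc.motor_correlation_by_cluster(assign, traces, reg,
                                              n_boot=2000, seed=0)
        assert out.loc[0, "median"] > 0.8 > abs(out.loc[1, "median"])
        assert abs(out.loc[1, "median"]) < 0.2

    def test_ci_width_shrinks_with_cluster_size(self):
        rng = np.random.default_rng(8)
        n = 600
        reg = rng.standard_normal(n)
        small = 0.8 * reg + 0.6 * rng.standard_normal((10, n))
        big = 0.8 * reg + 0.6 * rng.standard_normal((200, n))
        traces = np.vstack([small, big])
        assign = pd.DataFrame({"cluster": [0] * 10 + [1] * 200,
                               "corr": np.ones(210)})
        out = fc.motor_correlation_by_cluster(assign, traces, reg,
                                              n_boot=3000, seed=1)
        w_small = out.loc[0, "ci_hi"] - out.loc[0, "ci_lo"]
        w_big = out.loc[1, "ci_hi"] - out.loc[1, "ci_lo"]
        assert w_big < w_small

    def test_tiny_cluster_flagged(self):
        rng = np.random.default_rng(9)
        traces = rng.standard_normal((3, 100))
        assign = pd.DataFrame({"cluster": [0, 1, 1], "corr": np.ones(3)})
        out = fc.motor_correlation_by_cluster(assign, traces, traces[0],
                                              n_boot=100, seed=2)
        assert not out.loc[0, "reliable"] and np.isnan(out.loc[0, "ci_lo"])


class TestProportions:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(10)
        assign = pd.DataFrame({"cluster": rng.integers(0, 4, 200),
                               "corr": np.ones(200)})
        treat = np.repeat(["a", "b"], 100)
        out = fc.cluster_proportions_by_treatment(assign, treat,
                                                  n_boot=200, seed=3)
        for g in ("a", "b"):
            assert np.isclose(sum(out[g]["proportion"]), 1.0)
            assert np.allclose(out[g]["bootstrap"].sum(axis=1), 1.0)

    def test_planted_enrichment_outside_99pct_interval(self):
        rng = np.random.default_rng(11)
        a = rng.choice(4, 600, p=[0.25] * 4)
        b = rng.choice(4, 600, p=[0.46, 0.18, 0.18, 0.18])  # 2x cluster 0
        assign = pd.DataFrame({"cluster": np.concatenate([a, b]),
                               "corr": np.ones(1200)})
        treat = np.repeat(["ctl", "drug"], 600)
        out = fc.cluster_proportions_by_treatment(assign, treat,
                                                  n_boot=2000, seed=4)
        lo, hi = np.percentile(out["ctl"]["bootstrap"][:, 0], [0.5, 99.5])
        assert out["drug"]["proportion"][0] > hi

    def test_identical_groups_overlap(self):
        rng = np.random.default_rng(12)
        lab = rng.integers(0, 3, 400)
        assign = pd.DataFrame({"cluster": np.tile(lab, 2),
                               "corr": np.ones(800)})
        treat = np.repeat(["x", "y"], 400)
        out = fc.cluster_proportions_by_treatment(assign, treat,
                                                  n_boot=500, seed=5)
        assert np.allclose(out["x"]["proportion"], out["y"]["proportion"])

    def test_needs_two_groups(self):
        assign = pd.DataFrame({"cluster": [0, 1], "corr": [1.0, 1.0]})
        with pytest.raises(ValueError):
            fc.cluster_proportions_by_treatment(assign, ["a", "a"])
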