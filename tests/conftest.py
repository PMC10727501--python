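import numpy as np
import pytest

from habituscope import synth
from habituscope.protocol import gcamp_kernel, imaging_protocol


@pytest.fixture(scope="session")
def imaging_proto():
    return imaging_protocol()


@pytest.fixture(scope="session")
def kernel(imaging_proto):
    return gcamp_kernel(rate=imaging_proto.sample_rate)


@pytest.fixture(scope="session")
def three_archetypes():
    """Three mutually well-separated functional classes."""
    by_name = {a.name: a for a in synth.default_archetypes()}
    return [by_name["1OnnoA"], by_name["4LstrgD"], by_name["12MPot"]]


@pytest.fixture(scope="session")
def small_roi_sim(three_archetypes, imaging_proto, kernel):
    """Compact planted-truth ROI table shared across clustering tests."""
    table, truth = synth.simulate_roi_traces(
        archetypes=three_archetypes, n_per_type=60, n_fish=3, snr=3.0,
        frac_motor=0.05, frac_untuned=0.1, protocol=imaging_proto,
        kernel=kernel, seed=7)
    return table, truth


@pytest.fixture(scope="session")
def small_screen():
    """One small plate: 6 compounds x 6 wells + 12 vehicle wells, no effects."""
    from habituscope.fingerprint import ScreenSchedule, default_layout
    from habituscope.protocol import DarkFlashProtocol

    protocol = DarkFlashProtocol()
    layout = default_layout(compounds=[f"C{i}" for i in range(1, 7)],
                            n_vehicle=12, capacity=300)
    schedule = ScreenSchedule.from_protocol(protocol)
    events, truth = synth.simulate_screen(layout, seed=11,
                                          protocol=protocol,
                                          schedule=schedule)
    return events, layout, schedule


def hungarian_accuracy(true_labels, pred_labels):
    """Best-matching membership accuracy between two labelings."""
    from scipy.optimize import linear_sum_assignment

    true_ids = {t: i for i, t in enumerate(sorted(set(true_labels)))}
    pred_ids = {p: i for i, p in enumerate(sorted(set(pred_labels)))}
    m = np.zeros((len(true_ids), max(len(pred_ids), len(true_ids))))
    for t, p in zip(true_labels, pred_labels):
        m[true_ids[t], pred_ids[p]] += 1
    r, c = linear_sum_assignment(-m)
    return m[r, c].sum() / len(true_labels)
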