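"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the data the analyses consume — fluorescence traces
of stimulus-tuned / motor / untuned ROIs with atlas-like centroids,
registration-correlation traces with movement dips, per-well behavioural
event tables, two-channel intensity pairs, and 3-D marker volumes — so the
whole pipeline runs and can be validated against known truth without any
acquisition.

Twelve response archetypes mirror the functional taxonomy observed during
dark-flash habituation: each combines an adaptation profile (noA / weakD /
medD / strgD / Pot — how per-flash response amplitude evolves over 60
flashes) with a response shape (On = fires at the luminance ramp after the
flash; S / M / L = short / medium / long responses locked to flash onset).
Depression is modelled as geometric decay of the per-flash amplitude toward
a class-specific floor, potentiation as a saturating rise, and shapes as
short impulse profiles with class-specific onset latency, duration and
envelope.  The parameters are chosen so that the twelve templates are
mutually distinguishable under Pearson affinity while every class keeps the
ordinal structure of its labels (strgD < medD < weakD < noA < Pot in
late/early response ratio, S < M < L in duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .fingerprint import EVENT_COLUMNS, MeasureSpec, PlateLayout, \
    ScreenSchedule, default_layout
from .protocol import DarkFlashProtocol, gcamp_kernel, imaging_protocol

__all__ = [
    "ATLAS_EXTENT_UM",
    "ArchetypeSpec",
    "RoiTable",
    "SimulationTruth",
    "default_archetypes",
    "simulate_roi_traces",
    "simulate_motion_trace",
    "simulate_screen",
    "simulate_two_channel",
    "simulate_marker_volumes",
]

#: Atlas-like bounding box (x, y, z) in micrometres for simulated centroids.
ATLAS_EXTENT_UM = (496.0, 1122.0, 276.0)


# ---------------------------------------------------------------------------
# archetypes

@dataclass(frozen=True)
class ArchetypeSpec:
    """Parametric template for one functional response class.

    ``level`` is the late-flash amplitude floor for depressing classes
    (relative to the first flash), the asymptotic ceiling toward 2.0 for
    potentiating ones, and 1.0 for non-adapting ones.  ``decay`` is the
    per-flash geometric rate of approach to that level.  ``onset_delay`` and
    ``duration`` (seconds, relative to flash onset) position the per-flash
    impulse profile whose within-response ``envelope`` is one of ``box``,
    ``rise``, ``decay`` or ``dual`` (an early and a late lobe).
    """

    name: str
    adaptation: str  # noA | weakD | medD | strgD | Pot
    shape: str       # On | L | M | S
    level: float
    decay: float
    onset_delay: float
    duration: float
    envelope: str = "box"

    def amplitude_multipliers(self, n_flashes: int = 60) -> np.ndarray:
        k = np.arange(n_flashes)
        if self.adaptation == "Pot":
            return self.level + (2.0 - self.level) * (1.0 - self.decay ** k)
        return self.level + (1.0 - self.level) * self.decay ** k

    def flash_profile(self, rate: float) -> np.ndarray:
        """Impulse profile of a single flash response, sampled at ``rate``."""
        m = max(1, int(round(self.duration * rate)))
        if self.envelope == "box":
            return np.ones(m)
        if self.envelope == "rise":
            return np.linspace(0.5, 1.0, m)
        if self.envelope == "decay":
            return np.exp(-np.arange(m) / (m / 2.2))
        if self.envelope == "dual":
            e = np.zeros(m)
            q = max(1, m // 3)
            e[:q] = 1.0
            e[-q:] = 0.85
            return e
        raise ValueError(f"unknown envelope {self.envelope!r}")


def default_archetypes() -> List[ArchetypeSpec]:
    """The twelve named functional classes (1OnnoA ... 12MPot)."""
    a = ArchetypeSpec
    return [
        a("1OnnoA",   "noA",   "On", 1.00, 0.93, 2.60, 1.0, "box"),
        a("2OnmedD",  "medD",  "On", 0.30, 0.90, 6.00, 2.0, "decay"),
        a("3LmedD",   "medD",  "L",  0.35, 0.88, 0.05, 12.0, "box"),
        a("4LstrgD",  "strgD", "L",  0.05, 0.75, 0.30, 10.5, "box"),
        a("5MweakD",  "weakD", "M",  0.60, 0.93, 0.05, 4.4, "box"),
        a("6MweakD",  "weakD", "M",  0.55, 0.95, 0.05, 7.5, "rise"),
        a("7SmedD",   "medD",  "S",  0.30, 0.85, 0.45, 1.1, "box"),
        a("8SstrgD",  "strgD", "S",  0.08, 0.70, 0.05, 1.0, "decay"),
        a("9MnoA",    "noA",   "M",  1.00, 0.93, 0.10, 8.0, "dual"),
        a("10SnoA",   "noA",   "S",  0.95, 0.93, 0.90, 0.3, "box"),
        a("11SweakD", "weakD", "S",  0.65, 0.95, 0.02, 2.2, "decay"),
        a("12MPot",   "Pot",   "M",  0.30, 0.95, 0.50, 3.4, "box"),
    ]


def archetype_template(spec: ArchetypeSpec, protocol: DarkFlashProtocol,
                       kernel: np.ndarray, rate: float) -> np.ndarray:
    """Noise-free fluorescence template of one archetype, peak-normalised."""
    n = int(round(protocol.duration * rate))
    prof = spec.flash_profile(rate)
    amps = spec.amplitude_multipliers(protocol.flashes_per_block)
    x = np.zeros(n)
    onsets = protocol.flash_onsets[:protocol.flashes_per_block]
    for amp, onset in zip(amps, onsets):
        i0 = int(round((onset + spec.onset_delay) * rate))
        i1 = min(i0 + len(prof), n)
        if i1 > i0:
            x[i0:i1] += amp * prof[:i1 - i0]
    y = np.convolve(x, kernel)[:n]
    peak = y.max()
    return y / peak if peak > 0 else y


# ---------------------------------------------------------------------------
# ROI tables

@dataclass
class RoiTable:
    """Traces, centroids and identity of every ROI — the unit of all
    imaging analyses."""

    traces: np.ndarray                 # (n_rois, n_frames)
    centroids: np.ndarray              # (n_rois, 3) in um, atlas-like space
    fish_id: np.ndarray                # (n_rois,) int
    treatment: np.ndarray              # (n_rois,) str
    sample_rate: float

    def __post_init__(self) -> None:
        n = self.traces.shape[0]
        if not (len(self.centroids) == len(self.fish_id)
                == len(self.treatment) == n):
            raise ValueError("RoiTable arrays disagree in length")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    def select(self, mask: np.ndarray) -> "RoiTable":
        return RoiTable(self.traces[mask], self.centroids[mask],
                        self.fish_id[mask], self.treatment[mask],
                        self.sample_rate)

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=self.traces)
            f.create_dataset("centroids", data=self.centroids)
            f.create_dataset("fish_id", data=self.fish_id)
            f.create_dataset("treatment",
                             data=np.asarray(self.treatment, dtype="S"))
            f.attrs["sample_rate"] = self.sample_rate

    @classmethod
    def from_hdf5(cls, path) -> "RoiTable":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(traces=f["traces"][()],
                       centroids=f["centroids"][()],
                       fish_id=f["fish_id"][()],
                       treatment=f["treatment"][()].astype(str),
                       sample_rate=float(f.attrs["sample_rate"]))


@dataclass
class SimulationTruth:
    """Planted ground truth of a simulation run."""

    labels: pd.DataFrame     # one row per simulated unit
    seed: int
    params: Dict = field(default_factory=dict)


def simulate_roi_traces(archetypes: Sequence[ArchetypeSpec] | None = None,
                        n_per_type: int = 150, n_fish: int = 6,
                        snr: float = 3.0, frac_motor: float = 0.1,
                        frac_untuned: float = 0.2,
                        protocol: DarkFlashProtocol | None = None,
                        kernel: np.ndarray | None = None,
                        treatment: str = "DMSO",
                        seed: int = 0) -> Tuple[RoiTable, SimulationTruth]:
    """Simulate an ROI table with planted functional classes.

    Tuned ROIs are archetype templates (standardised to unit variance) plus
    i.i.d. Gaussian noise of standard deviation ``1/snr``, so the expected
    correlation of two same-class ROIs is ``snr^2 / (snr^2 + 1)`` (0.9 at
    the default ``snr=3``).  Motor ROIs follow a per-fish movement-event
    train (habituating flash responses plus spontaneous swims) convolved
    with the kernel; untuned ROIs are pure noise.  Centroids are drawn from
    per-class 3-D Gaussian blobs in an atlas-like box.
    """
    if n_fish < 2:
        raise ValueError("need at least two fish (cross-fish filtering)")
    if snr <= 0:
        raise ValueError("snr must be > 0")
    archetypes = list(archetypes) if archetypes is not None \
        else default_archetypes()
    protocol = protocol or imaging_protocol()
    rate = protocol.sample_rate
    kernel = kernel if kernel is not None else gcamp_kernel(rate=rate)
    rng = np.random.default_rng(seed)

    templates = np.array([archetype_template(a, protocol, kernel, rate)
                          for a in archetypes])
    tz = (templates - templates.mean(1, keepdims=True)) \
        / templates.std(1, keepdims=True)
    n_frames = templates.shape[1]

    n_tuned = n_per_type * len(archetypes)
    n_motor = int(round(frac_motor * n_tuned))
    n_untuned = int(round(frac_untuned * n_tuned))
    n = n_tuned + n_motor + n_untuned
    labels = ([a.name for a in archetypes for _ in range(n_per_type)]
              + ["motor"] * n_motor + ["untuned"] * n_untuned)
    fish = rng.integers(0, n_fish, n)

    traces = np.empty((n, n_frames))
    arch_idx = np.repeat(np.arange(len(archetypes)), n_per_type)
    traces[:n_tuned] = tz[arch_idx] \
        + rng.standard_normal((n_tuned, n_frames)) / snr

    onsets = protocol.flash_onsets[:protocol.flashes_per_block]
    for f in range(n_fish):
        p = 0.25 + 0.65 * np.exp(-np.arange(len(onsets)) / 20.0)
        moved = rng.random(len(onsets)) < p
        ev = list(onsets[moved] + 0.3)
        ev += list(rng.uniform(0.0, protocol.duration,
                               rng.poisson(0.05 * protocol.duration)))
        x = np.zeros(n_frames)
        for e in ev:
            x[min(int(round(e * rate)), n_frames - 1)] += 1.0
        mt = np.convolve(x, kernel)[:n_frames]
        sd = mt.std()
        mt = (mt - mt.mean()) / sd if sd > 0 else mt
        rows = np.arange(n_tuned, n_tuned + n_motor)[
            fish[n_tuned:n_tuned + n_motor] == f]
        traces[rows] = mt + rng.standard_normal((len(rows), n_frames)) / snr
    traces[n_tuned + n_motor:] = rng.standard_normal((n_untuned, n_frames))

    # centroids: one Gaussian blob per archetype, hindbrain-ish blob for
    # motor ROIs, uniform for untuned
    ext = np.array(ATLAS_EXTENT_UM)
    centers = ext * (0.2 + 0.6 * rng.random((len(archetypes), 3)))
    centroids = np.empty((n, 3))
    centroids[:n_tuned] = centers[arch_idx] \
        + rng.standard_normal((n_tuned, 3)) * 25.0
    motor_center = ext * np.array([0.5, 0.85, 0.4])
    centroids[n_tuned:n_tuned + n_motor] = motor_center \
        + rng.standard_normal((n_motor, 3)) * 40.0
    centroids[n_tuned + n_motor:] = rng.random((n_untuned, 3)) * ext
    np.clip(centroids, 0.0, ext - 1e-9, out=centroids)

    table = RoiTable(traces=traces, centroids=centroids, fish_id=fish,
                     treatment=np.full(n, treatment, dtype=object),
                     sample_rate=rate)
    truth = SimulationTruth(
        labels=pd.DataFrame({"roi": np.arange(n), "label": labels,
                             "fish": fish}),
        seed=seed,
        params={"n_per_type": n_per_type, "n_fish": n_fish, "snr": snr,
                "frac_motor": frac_motor, "frac_untuned": frac_untuned})
    return table, truth


def simulate_motion_trace(protocol: DarkFlashProtocol,
                          response_flags: Sequence[bool],
                          baseline: float = 1.0, dip_depth: float = 0.3,
                          noise_sd: float = 0.01, latency: float = 0.3,
                          recovery: float = 1.5,
                          seed: int = 0) -> np.ndarray:
    """Per-frame registration-correlation trace with movement dips.

    The trace sits at ``baseline`` with Gaussian noise; each flagged flash
    produces a transient dip of depth ``dip_depth`` shortly after onset,
    recovering exponentially over ``recovery`` seconds.
    """
    if dip_depth <= 0:
        raise ValueError("dip_depth must be > 0")
    rate = protocol.sample_rate
    n = int(round(protocol.duration * rate))
    rng = np.random.default_rng(seed)
    x = baseline + rng.standard_normal(n) * noise_sd
    onsets = protocol.flash_onsets[:protocol.flashes_per_block]
    flags = np.asarray(response_flags, dtype=bool)
    span = np.arange(int(round(3 * recovery * rate)))
    dip = dip_depth * np.exp(-span / (recovery * rate))
    for onset, flag in zip(onsets, flags):
        if not flag:
            continue
        i0 = int(round((onset + latency) * rate))
        i1 = min(i0 + len(dip), n)
        if i1 > i0:
            x[i0:i1] -= dip[:i1 - i0]
    return x


# ---------------------------------------------------------------------------
# behavioural screen

# per-component (mean, between-fish sd, within-fish event sd)
_DF_COMPONENT_STATS = {
    "latency":        (0.25, 0.030, 0.080),
    "bend_amplitude": (5.00, 0.350, 0.600),
    "bend_duration":  (0.30, 0.030, 0.050),
    "displacement":   (3.00, 0.300, 0.800),
    "velocity":       (25.0, 2.500, 5.000),
    "heading":        (1.20, 0.120, 0.350),
}
_TAP_COMPONENT_STATS = {
    "latency":        (0.12, 0.015, 0.040),
    "bend_amplitude": (2.20, 0.200, 0.400),
    "bend_duration":  (0.20, 0.020, 0.040),
    "displacement":   (1.50, 0.150, 0.400),
    "velocity":       (15.0, 1.500, 3.000),
    "heading":        (0.70, 0.070, 0.200),
}
_PROB_FISH_SD = 0.05       # between-fish sd of epoch response probability
_SPONT_RATE_PER_MIN = 1.2
_OMR_EVENT_BIAS = 0.20     # mean heading change toward motion per OMR event
_OMR_EVENTS_PER_EPOCH = 3.0

_COMPONENT_FLOOR = {"latency": 0.02, "bend_duration": 0.05,
                    "displacement": 0.05, "velocity": 0.5, "heading": 0.0}
_DF_AMP_FLOOR = 3.05   # a dark-flash response must clear the 3 rad gate
_TAP_AMP_FLOOR = 1.05  # a tap response must clear the 1 rad gate


def _df_response_probability(j: np.ndarray, test: bool) -> np.ndarray:
    """Habituating baseline response probability by within-block position."""
    if test:
        return 0.30 + 0.35 * np.exp(-j / 20.0)
    return 0.25 + 0.65 * np.exp(-j / 20.0)


def _parse_effects(effect_map: Dict[str, Dict[str, float]] | None,
                   layout: PlateLayout,
                   spec: MeasureSpec) -> Dict[str, Dict[str, float]]:
    effect_map = effect_map or {}
    known = set(layout.compounds)
    valid = set(spec.names) | {"paralysis"}
    for cmpd, effects in effect_map.items():
        if cmpd not in known:
            raise ValueError(f"effect_map references unknown compound "
                             f"{cmpd!r}")
        if effects != "paralysis":
            for m in effects:
                if m not in valid:
                    raise ValueError(f"unknown measure {m!r} in effect_map")
    return effect_map


def simulate_screen(layout: PlateLayout | None = None,
                    effect_map: Dict[str, Dict[str, float]] | None = None,
                    n_fish_per_well: int = 1,
                    protocol: DarkFlashProtocol | None = None,
                    schedule: ScreenSchedule | None = None,
                    spec: MeasureSpec | None = None,
                    seed: int = 0) -> Tuple[pd.DataFrame, SimulationTruth]:
    """Simulate per-well tracked movement events for one screening plate.

    Vehicle wells draw from habituating baseline distributions; treated
    wells shift the underlying fish-level distribution of the targeted
    component by ``delta * sqrt(2) * sigma_fish``, so a planted effect of
    ``delta`` is recovered as an SSMD of about ``delta`` at large sample
    size.  ``effect_map`` maps compound id -> {measure name: delta}, or the
    string ``"paralysis"`` to silence a compound's fish entirely.
    """
    layout = layout or default_layout()
    protocol = protocol or DarkFlashProtocol()
    schedule = schedule or ScreenSchedule.from_protocol(protocol)
    spec = spec or MeasureSpec()
    effect_map = _parse_effects(effect_map, layout, spec)
    rng = np.random.default_rng(seed)

    n_train = protocol.n_training_flashes
    df_onsets = schedule.df_onsets
    pos_in_block = np.concatenate([
        np.tile(np.arange(protocol.flashes_per_block), protocol.n_blocks),
        np.arange(protocol.test_block_size)])
    is_test = np.arange(len(df_onsets)) >= n_train
    epoch_of = np.array(
        ["naive" if i < 5 else "training" if i < n_train else "test"
         for i in range(len(df_onsets))])

    frames: List[pd.DataFrame] = []
    fish_counter = 0
    for well, (role, cmpd) in layout.wells.items():
        effects = effect_map.get(cmpd, {}) if role == "treatment" else {}
        paralysed = effects == "paralysis"
        for _ in range(n_fish_per_well):
            fish = f"{well}:f{fish_counter}"
            fish_counter += 1
            if paralysed:
                continue
            frames.append(_simulate_fish(
                fish, well, effects, rng, df_onsets, pos_in_block, is_test,
                epoch_of, schedule))
    events = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=EVENT_COLUMNS)
    truth = SimulationTruth(
        labels=pd.DataFrame(
            [(w, role, cmpd) for w, (role, cmpd) in layout.wells.items()],
            columns=["well", "role", "compound"]),
        seed=seed, params={"effect_map": effect_map})
    return events, truth


def _shift(effects: Dict[str, float], measure: str, sigma: float) -> float:
    return effects.get(measure, 0.0) * np.sqrt(2.0) * sigma


def _simulate_fish(fish: str, well: str, effects: Dict[str, float],
                   rng: np.random.Generator, df_onsets: np.ndarray,
                   pos_in_block: np.ndarray, is_test: np.ndarray,
                   epoch_of: np.ndarray,
                   schedule: ScreenSchedule) -> pd.DataFrame:
    rows: List[Tuple] = []

    def emit(t, amp, lat, disp, head, dur, vel):
        rows.append((fish, well, t, amp, lat, disp, head, dur, vel))

    # fish-level offsets for every continuous component
    df_off = {c: rng.normal(0.0, sd_f)
              for c, (_, sd_f, _) in _DF_COMPONENT_STATS.items()}
    tap_off = {c: rng.normal(0.0, sd_f)
               for c, (_, sd_f, _) in _TAP_COMPONENT_STATS.items()}
    p_off = rng.normal(0.0, _PROB_FISH_SD)

    comp_key = {"latency": "latency", "bend_amplitude": "bend_amplitude",
                "bend_duration": "bend_duration",
                "displacement": "displacement", "velocity": "velocity",
                "heading_change": "heading"}

    def draw_event(stats, off, shifts, floors, amp_floor):
        vals = {}
        for c, (mu, _, sd_e) in stats.items():
            v = mu + off[c] + shifts.get(c, 0.0) + rng.normal(0.0, sd_e)
            vals[c] = max(v, floors.get(c, 0.0))
        vals["bend_amplitude"] = max(vals["bend_amplitude"], amp_floor)
        vals["heading"] *= rng.choice([-1.0, 1.0])
        return vals

    # --- dark flashes -----------------------------------------------------
    for i, onset in enumerate(df_onsets):
        epoch = epoch_of[i]
        shifts = {comp_key[m]: _shift(
            effects, f"df_{m}_{epoch}",
            _DF_COMPONENT_STATS[comp_key[m]][1])
            for m in comp_key}
        p = _df_response_probability(np.array([pos_in_block[i]]),
                                     bool(is_test[i]))[0]
        p += p_off + _shift(effects, f"df_probability_{epoch}",
                            _PROB_FISH_SD)
        p = float(np.clip(p, 0.01, 0.99))
        if rng.random() >= p:
            continue
        v = draw_event(_DF_COMPONENT_STATS, df_off, shifts,
                       _COMPONENT_FLOOR, _DF_AMP_FLOOR)
        lat = float(np.clip(v["latency"], 0.02, 0.9))
        emit(onset + lat, v["bend_amplitude"], lat, v["displacement"],
             v["heading"], v["bend_duration"], v["velocity"])
        # occasional second response event inside the scoring window
        n_extra_mu = 0.25 + _shift(effects, f"df_n_events_{epoch}", 0.1) \
            + _shift(effects, f"df_multi_response_{epoch}", 0.1)
        for k in range(rng.poisson(max(n_extra_mu, 0.0))):
            v2 = draw_event(_DF_COMPONENT_STATS, df_off, shifts,
                            _COMPONENT_FLOOR, _DF_AMP_FLOOR)
            t2 = onset + lat + 0.05 * (k + 1) + rng.uniform(0.0, 0.02)
            if t2 - onset < 0.99:
                emit(t2, v2["bend_amplitude"], lat, v2["displacement"],
                     v2["heading"], v2["bend_duration"], v2["velocity"])

    # --- acoustic taps ----------------------------------------------------
    p_tap = float(np.clip(
        0.6 + p_off + _shift(effects, "tap_probability", _PROB_FISH_SD),
        0.01, 0.99))
    tap_shifts = {comp_key[m]: _shift(effects, f"tap_{m}",
                                      _TAP_COMPONENT_STATS[comp_key[m]][1])
                  for m in comp_key}
    for onset in schedule.tap_times:
        if rng.random() >= p_tap:
            continue
        v = draw_event(_TAP_COMPONENT_STATS, tap_off, tap_shifts,
                       _COMPONENT_FLOOR, _TAP_AMP_FLOOR)
        lat = float(np.clip(v["latency"], 0.01, 0.9))
        emit(onset + lat, v["bend_amplitude"], lat, v["displacement"],
             v["heading"], v["bend_duration"], v["velocity"])

    # --- spontaneous swimming --------------------------------------------
    lo, hi = schedule.spont_period
    minutes = (hi - lo) / 60.0
    rate = max(_SPONT_RATE_PER_MIN * float(np.exp(rng.normal(0.0, 0.25)))
               + _shift(effects, "spont_event_rate", 0.35), 0.0)
    n_sp = rng.poisson(rate * minutes)
    amp_shift = _shift(effects, "spont_bend_amplitude", 0.10)
    disp_shift = _shift(effects, "spont_displacement", 0.10)
    for t in np.sort(rng.uniform(lo, hi, n_sp)):
        amp = float(np.clip(rng.normal(1.0 + amp_shift, 0.4), 0.05, 2.9))
        emit(t, amp, 0.0,
             max(rng.normal(1.0 + disp_shift, 0.4), 0.0),
             rng.normal(0.0, 0.6), max(rng.normal(0.2, 0.05), 0.02),
             max(rng.normal(8.0, 2.0), 0.1))

    # --- optomotor epochs -------------------------------------------------
    omr_bias = _OMR_EVENT_BIAS + rng.normal(0.0, 0.03) \
        + _shift(effects, "omr_score", 0.10) / _OMR_EVENTS_PER_EPOCH
    for start, end, direction in schedule.omr_epochs:
        for t in np.sort(rng.uniform(start, end,
                                     rng.poisson(_OMR_EVENTS_PER_EPOCH))):
            emit(t, float(np.clip(rng.normal(1.0, 0.4), 0.05, 2.9)), 0.0,
                 max(rng.normal(1.5, 0.5), 0.0),
                 rng.normal(direction * omr_bias, 0.35),
                 max(rng.normal(0.2, 0.05), 0.02),
                 max(rng.normal(10.0, 2.0), 0.1))

    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# two-channel intensities and marker volumes

def simulate_two_channel(labels: Sequence,
                         frac_positive_per_type: Dict[str, float],
                         ratio_pos: float = 0.45, ratio_neg: float = 0.12,
                         green_mean: float = 100.0,
                         seed: int = 0) -> Tuple[pd.DataFrame,
                                                 SimulationTruth]:
    """Red/green intensity pairs per ROI with planted marker positivity.

    Positives get red/green ratios around ``ratio_pos`` (above the 0.25
    classification threshold), negatives around ``ratio_neg``.
    """
    for k, v in frac_positive_per_type.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"fraction for {k!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    pos = np.zeros(len(labels), dtype=bool)
    for k, frac in frac_positive_per_type.items():
        idx = np.flatnonzero(labels == k)
        pos[idx] = rng.random(len(idx)) < frac
    green = rng.gamma(20.0, green_mean / 20.0, len(labels))
    ratio = np.where(pos, ratio_pos, ratio_neg) \
        * np.exp(rng.normal(0.0, 0.15, len(labels)))
    red = green * ratio
    table = pd.DataFrame({"label": labels, "red": red, "green": green})
    truth = SimulationTruth(
        labels=pd.DataFrame({"roi": np.arange(len(labels)),
                             "positive": pos}),
        seed=seed, params={"frac_positive_per_type": frac_positive_per_type})
    return table, truth


def simulate_marker_volumes(cluster_density_maps: Sequence[np.ndarray],
                            n_markers: int, n_matched: int,
                            noise: float = 0.3,
                            seed: int = 0) -> Tuple[np.ndarray,
                                                    SimulationTruth]:
    """Marker expression volumes: ``n_matched`` are noisy copies of cluster
    density maps, the rest are smoothed random blobs."""
    maps = np.asarray(cluster_density_maps, dtype=float)
    if n_matched > n_markers:
        raise ValueError("n_matched cannot exceed n_markers")
    if n_matched > len(maps):
        raise ValueError("not enough cluster maps to match against")
    rng = np.random.default_rng(seed)
    shape = maps.shape[1:]
    vols = np.empty((n_markers,) + shape)
    matched_to = np.full(n_markers, -1)
    for i in range(n_matched):
        src = maps[i]
        sd = src.std() or 1.0
        vols[i] = src + rng.standard_normal(shape) * noise * sd
        matched_to[i] = i
    for i in range(n_matched, n_markers):
        blob = np.zeros(shape)
        k = 5
        pts = tuple(rng.integers(0, s, k) for s in shape)
        blob[pts] = 1.0
        vols[i] = ndimage.gaussian_filter(blob, sigma=2.0)
    truth = SimulationTruth(
        labels=pd.DataFrame({"marker": np.arange(n_markers),
                             "matched_cluster": matched_to}),
        seed=seed, params={"noise": noise})
    return vols, truth
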