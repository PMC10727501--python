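"""Behavioural-screen analysis: SSMD fingerprints, hit calling, clustering.

A screened compound's phenotype is summarised as a *behavioural
fingerprint*: the strictly standardized mean difference (SSMD)

    SSMD = (mean_treated - mean_control) / sqrt(var_treated + var_control)

computed for each of 47 behavioural measures of compound-treated fish
against the pooled vehicle controls of the same plate.  Measures cover ten
components of the dark-flash response averaged over the naive / training /
test epochs (30), the same ten components for acoustic taps (10), six
spontaneous-swimming statistics and one optomotor score.  Compounds with
any |SSMD| >= 2 are hits; hits are then clustered on their fingerprints and
the measure-measure correlation structure across hits exposes which
behavioural components are co-modulated pharmacologically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.signal import savgol_filter
from scipy.spatial.distance import pdist, squareform

from .protocol import DarkFlashProtocol, EpochPartition, partition_epochs

__all__ = [
    "EVENT_COLUMNS",
    "DF_COMPONENTS",
    "PlateLayout",
    "default_layout",
    "ScreenSchedule",
    "MeasureSpec",
    "FingerprintMatrix",
    "detect_responses",
    "epoch_component_means",
    "ssmd",
    "assemble_fingerprint",
    "filter_viable",
    "call_hits",
    "cluster_fingerprints",
    "measure_correlogram",
    "smooth_response_curve",
    "omr_score",
    "recount_hits",
]

#: Schema of a tracked-movement-event table (one row per movement event).
EVENT_COLUMNS = ["fish_id", "well", "time_s", "bend_amp_rad", "latency_s",
                 "displacement_mm", "heading_rad", "duration_s",
                 "velocity_mm_s"]

#: The ten per-stimulus components of the dark-flash (and tap) response.
DF_COMPONENTS = ["probability", "latency", "bend_amplitude", "bend_duration",
                 "displacement", "velocity", "heading_change", "vigor",
                 "n_events", "multi_response"]

SPONT_MEASURES = ["spont_event_rate", "spont_displacement",
                  "spont_bend_amplitude", "spont_velocity",
                  "spont_total_distance", "spont_active_fraction"]

#: Bend-amplitude thresholds (rad) defining a response, per stimulus kind.
RESPONSE_AMP_THRESHOLD = {"dark_flash": 3.0, "tap": 1.0}


# ---------------------------------------------------------------------------
# plate layout and assay schedule

@dataclass(frozen=True)
class PlateLayout:
    """Well roles on one screening plate.

    ``wells`` maps well id -> (role, compound id or None); role is
    ``treatment`` or ``vehicle``.
    """

    wells: Dict[str, Tuple[str, str | None]]
    capacity: int = 300

    def __post_init__(self) -> None:
        if len(self.wells) > self.capacity:
            raise ValueError("occupied wells exceed plate capacity")
        for w, (role, cmpd) in self.wells.items():
            if role == "treatment" and not cmpd:
                raise ValueError(f"treatment well {w} lacks a compound id")

    @property
    def compounds(self) -> List[str]:
        seen: Dict[str, None] = {}
        for role, cmpd in self.wells.values():
            if role == "treatment":
                seen.setdefault(cmpd)
        return list(seen)

    @property
    def vehicle_wells(self) -> List[str]:
        return [w for w, (role, _) in self.wells.items() if role == "vehicle"]

    def wells_of(self, compound: str) -> List[str]:
        return [w for w, (role, c) in self.wells.items()
                if role == "treatment" and c == compound]


def default_layout(compounds: Sequence[str] | None = None,
                   wells_per_compound: int = 6,
                   n_vehicle: int = 60, capacity: int = 300) -> PlateLayout:
    """The standard 300-well plate: 40 compound groups of six wells plus 60
    vehicle wells."""
    if compounds is None:
        compounds = [f"C{i + 1:03d}" for i in range(40)]
    wells: Dict[str, Tuple[str, str | None]] = {}
    idx = 0
    for cmpd in compounds:
        for _ in range(wells_per_compound):
            wells[f"W{idx + 1:03d}"] = ("treatment", cmpd)
            idx += 1
    for _ in range(n_vehicle):
        wells[f"W{idx + 1:03d}"] = ("vehicle", None)
        idx += 1
    return PlateLayout(wells=wells, capacity=capacity)


@dataclass(frozen=True)
class ScreenSchedule:
    """Stimulus timing of the full behavioural assay on one plate.

    Dark flashes (training + test), a spontaneous-behaviour window, acoustic
    taps, and optomotor epochs of alternating motion direction.
    """

    df_onsets: np.ndarray
    partition: EpochPartition
    spont_period: Tuple[float, float]
    tap_times: np.ndarray
    omr_epochs: Tuple[Tuple[float, float, int], ...]

    @classmethod
    def from_protocol(cls, protocol: DarkFlashProtocol,
                      spont_duration: float = 1800.0,
                      tap_interval: float = 10.0,
                      tap_duration: float = 1800.0,
                      omr_delay: float = 3600.0,
                      omr_duration: float = 3600.0,
                      omr_epoch: float = 30.0) -> "ScreenSchedule":
        block_span = protocol.flashes_per_block * protocol.inter_flash_interval
        training_end = ((protocol.n_blocks - 1)
                        * (block_span + protocol.rest_between_blocks)
                        + block_span) if protocol.n_blocks else 0.0
        s0 = training_end + protocol.rest_between_blocks
        spont = (s0, s0 + spont_duration)
        taps = spont[1] + np.arange(0.0, tap_duration, tap_interval)
        omr0 = spont[1] + tap_duration + omr_delay
        n_ep = int(omr_duration // omr_epoch)
        omr = tuple((omr0 + i * omr_epoch, omr0 + (i + 1) * omr_epoch,
                     1 if i % 2 == 0 else -1) for i in range(n_ep))
        return cls(df_onsets=protocol.flash_onsets,
                   partition=partition_epochs(protocol),
                   spont_period=spont, tap_times=taps, omr_epochs=omr)


@dataclass(frozen=True)
class MeasureSpec:
    """Which measures make up a fingerprint; the default yields 47."""

    df_components: Tuple[str, ...] = tuple(DF_COMPONENTS)
    epochs: Tuple[str, ...] = ("naive", "training", "test")
    tap_components: Tuple[str, ...] = tuple(DF_COMPONENTS)
    spont_measures: Tuple[str, ...] = tuple(SPONT_MEASURES)
    include_omr: bool = True

    @property
    def names(self) -> List[str]:
        out = [f"df_{c}_{e}" for c in self.df_components for e in self.epochs]
        out += [f"tap_{c}" for c in self.tap_components]
        out += list(self.spont_measures)
        if self.include_omr:
            out.append("omr_score")
        return out


# ---------------------------------------------------------------------------
# response detection and per-fish measures

def detect_responses(events: pd.DataFrame, stimulus_times: np.ndarray,
                     kind: str = "dark_flash", window: float = 1.0,
                     fish_ids: Iterable | None = None) -> pd.DataFrame:
    """Score each stimulus for each fish.

    A stimulus counts as responded when at least one movement event with
    bend amplitude above the kind-specific threshold (3 rad for dark
    flashes, 1 rad for taps) starts within ``window`` seconds of onset.
    Component values come from the first qualifying event.  Returns one row
    per (fish, stimulus) with 1-based ``stim`` indices.
    """
    thresh = RESPONSE_AMP_THRESHOLD[kind]
    times = np.asarray(stimulus_times, dtype=float)
    if np.any(np.diff(times) < window):
        raise ValueError("ambiguous stimulus windows")
    if fish_ids is None:
        fish_ids = events["fish_id"].unique()
    comp_cols = ["latency", "bend_amplitude", "bend_duration", "displacement",
                 "velocity", "heading_change", "vigor"]
    by_fish = dict(tuple(events.groupby("fish_id", sort=False)))
    pieces = []
    n_stim = len(times)
    for fish in fish_ids:
        ev = by_fish.get(fish)
        if ev is not None:
            ev = ev[ev["bend_amp_rad"] > thresh].sort_values("time_s")
            et = ev["time_s"].to_numpy()
        else:
            et = np.empty(0)
        lo = np.searchsorted(et, times, side="right")
        hi = np.searchsorted(et, times + window, side="right")
        n_ev = hi - lo
        responded = n_ev > 0
        first = np.where(responded, lo, 0)
        block = {
            "fish_id": np.full(n_stim, fish, dtype=object),
            "stim": np.arange(1, n_stim + 1),
            "responded": responded,
            "n_events": n_ev,
            "multi_response": (n_ev >= 2).astype(float),
        }

        def col(name):
            if ev is None or not len(et):
                return np.full(n_stim, np.nan)
            vals = ev[name].to_numpy(dtype=float)[first]
            return np.where(responded, vals, np.nan)

        block["latency"] = col("latency_s")
        block["bend_amplitude"] = col("bend_amp_rad")
        dur = col("duration_s")
        block["bend_duration"] = dur
        block["displacement"] = col("displacement_mm")
        block["velocity"] = col("velocity_mm_s")
        block["heading_change"] = np.abs(col("heading_rad"))
        with np.errstate(divide="ignore", invalid="ignore"):
            block["vigor"] = np.where(dur > 0,
                                      block["bend_amplitude"] / dur, np.nan)
        pieces.append(pd.DataFrame(block))
    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
        columns=["fish_id", "stim", "responded", "n_events",
                 "multi_response"] + comp_cols)
    return out


def epoch_component_means(responses: pd.DataFrame,
                          epochs: Dict[str, Iterable[int]],
                          components: Sequence[str],
                          incomplete: Dict | None = None) -> pd.DataFrame:
    """Average response components per fish per epoch.

    Stimuli without a response are excluded from every component except
    ``probability`` (their component values are NaN, which the mean skips).
    ``incomplete`` maps fish id -> epoch names with broken tracking; those
    epochs yield NaN for every component.
    """
    if "probability" not in components:
        raise ValueError("components must include 'probability'")
    out: Dict[str, Dict] = {}
    for fish, grp in responses.groupby("fish_id"):
        rec = {}
        bad = set() if incomplete is None else set(incomplete.get(fish, ()))
        for ename, idx in epochs.items():
            sel = grp[grp["stim"].isin(set(idx))]
            for comp in components:
                key = f"{comp}_{ename}"
                if ename in bad or len(sel) == 0:
                    rec[key] = np.nan
                elif comp == "probability":
                    rec[key] = float(sel["responded"].mean())
                else:
                    rec[key] = float(sel[comp].mean())  # NaN-skipping
        out[fish] = rec
    return pd.DataFrame.from_dict(out, orient="index")


def ssmd(treated: np.ndarray, control: np.ndarray) -> float:
    """Strictly standardized mean difference with sample variances.

    Missing values are dropped; each group needs at least two finite values
    (otherwise NaN with a warning).  Zero total variance yields 0 when the
    means agree and raises "degenerate variance" when they differ.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    t, c = t[np.isfinite(t)], c[np.isfinite(c)]
    if len(t) < 2 or len(c) < 2:
        warnings.warn("ssmd needs >= 2 finite values per group", stacklevel=2)
        return float("nan")
    var_sum = t.var(ddof=1) + c.var(ddof=1)
    diff = t.mean() - c.mean()
    if var_sum == 0:
        if diff == 0:
            return 0.0
        raise ValueError("degenerate variance")
    return float(diff / np.sqrt(var_sum))


def filter_viable(events: pd.DataFrame, spont_period: Tuple[float, float],
                  fish_ids: Iterable, floor: float = 0.0) -> pd.Series:
    """Movement floor: a fish group is viable when the median number of
    spontaneous movement events per fish exceeds ``floor``."""
    lo, hi = spont_period
    sp = events[(events["time_s"] >= lo) & (events["time_s"] < hi)]
    counts = sp.groupby("fish_id").size()
    per_fish = pd.Series([float(counts.get(f, 0)) for f in fish_ids],
                         index=list(fish_ids))
    return per_fish


def omr_score(event_times: np.ndarray, heading_changes: np.ndarray,
              epochs: Sequence[Tuple[float, float, int]]) -> float:
    """Optomotor performance: average per-epoch heading change towards the
    direction of motion over 30 s epochs of alternating direction."""
    t = np.asarray(event_times, dtype=float)
    h = np.asarray(heading_changes, dtype=float)
    if len(epochs) == 0:
        raise ValueError("empty direction schedule")
    sums = []
    for start, end, direction in epochs:
        m = (t >= start) & (t < end)
        sums.append(direction * h[m].sum())
    return float(np.mean(sums))


# ---------------------------------------------------------------------------
# fingerprint assembly

@dataclass
class FingerprintMatrix:
    """Compound x measure SSMD matrix with viability and hit annotations."""

    values: pd.DataFrame
    viable: pd.Series
    hit_threshold: float = 2.0
    hits: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.hits is None:
            self.hits = call_hits(self.values, self.hit_threshold)

    @property
    def measure_names(self) -> List[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="compound")


def _fish_measures(events: pd.DataFrame, schedule: ScreenSchedule,
                   spec: MeasureSpec, fish_ids: Sequence,
                   window: float = 1.0,
                   incomplete: Dict | None = None) -> pd.DataFrame:
    """Per-fish vector of all fingerprint measures (one row per fish)."""
    epochs = {k: v for k, v in schedule.partition.as_dict().items()
              if k in spec.epochs}
    df_resp = detect_responses(events, schedule.df_onsets, "dark_flash",
                               window, fish_ids)
    df_means = epoch_component_means(df_resp, epochs, spec.df_components,
                                     incomplete)
    df_means.columns = [f"df_{c}" for c in df_means.columns]

    tap_resp = detect_responses(events, schedule.tap_times, "tap", window,
                                fish_ids)
    tap_means = epoch_component_means(
        tap_resp, {"all": range(1, len(schedule.tap_times) + 1)},
        spec.tap_components, incomplete)
    tap_means.columns = [f"tap_{c[:-4]}" for c in tap_means.columns]

    lo, hi = schedule.spont_period
    minutes = max((hi - lo) / 60.0, 1e-9)
    by_fish = dict(tuple(events.groupby("fish_id", sort=False)))
    empty = events.iloc[:0]
    spont_rows = {}
    omr_rows = {}
    for fish in fish_ids:
        ev = by_fish.get(fish, empty)
        sp = ev[(ev["time_s"] >= lo) & (ev["time_s"] < hi)]
        n = len(sp)
        spont_rows[fish] = {
            "spont_event_rate": n / minutes,
            "spont_displacement": sp["displacement_mm"].mean(),
            "spont_bend_amplitude": sp["bend_amp_rad"].mean(),
            "spont_velocity": sp["velocity_mm_s"].mean(),
            "spont_total_distance": sp["displacement_mm"].sum(),
            "spont_active_fraction":
                sp["time_s"].floordiv(60.0).nunique() / minutes,
        }
        if spec.include_omr:
            omr_rows[fish] = {"omr_score": omr_score(
                ev["time_s"].to_numpy(), ev["heading_rad"].to_numpy(),
                schedule.omr_epochs)}
    pieces = [df_means, tap_means,
              pd.DataFrame.from_dict(spont_rows, orient="index")]
    if spec.include_omr:
        pieces.append(pd.DataFrame.from_dict(omr_rows, orient="index"))
    table = pd.concat(pieces, axis=1)
    # fixed column order per the measure spec
    return table.reindex(columns=spec.names)


def assemble_fingerprint(events: pd.DataFrame, layout: PlateLayout,
                         schedule: ScreenSchedule,
                         spec: MeasureSpec | None = None,
                         window: float = 1.0,
                         viability_floor: float = 0.0,
                         hit_threshold: float = 2.0,
                         incomplete: Dict | None = None) -> FingerprintMatrix:
    """One SSMD per measure per compound against same-plate vehicle controls.

    Only viable compounds (median spontaneous movement per fish above the
    floor) get a fingerprint row; the viability series covers all compounds.
    """
    spec = spec or MeasureSpec()
    well_to_fish: Dict[str, List] = {}
    for fish, well in events[["fish_id", "well"]].drop_duplicates().values:
        well_to_fish.setdefault(well, []).append(fish)
    vehicle_fish = [f for w in layout.vehicle_wells
                    for f in well_to_fish.get(w, [])]
    if len(vehicle_fish) < 2:
        raise ValueError("need at least two vehicle wells with data")

    all_fish = sorted(set(events["fish_id"]))
    table = _fish_measures(events, schedule, spec, all_fish, window,
                           incomplete)
    spont = filter_viable(events, schedule.spont_period, all_fish)

    control = table.loc[[f for f in vehicle_fish if f in table.index]]
    rows: Dict[str, Dict[str, float]] = {}
    viable: Dict[str, bool] = {}
    for cmpd in layout.compounds:
        fish = [f for w in layout.wells_of(cmpd)
                for f in well_to_fish.get(w, [])]
        present = [f for f in fish if f in table.index]
        ok = (len(present) > 0
              and float(spont.loc[present].median()) > viability_floor)
        viable[cmpd] = ok
        if not ok:
            continue
        treated = table.loc[present]
        rec = {}
        for m in spec.names:
            try:
                rec[m] = ssmd(treated[m].to_numpy(), control[m].to_numpy())
            except ValueError:
                warnings.warn(f"degenerate variance for {cmpd}/{m}; "
                              "reporting NaN", stacklevel=2)
                rec[m] = np.nan
        rows[cmpd] = rec
    values = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=spec.names)
    return FingerprintMatrix(values=values,
                             viable=pd.Series(viable, dtype=bool),
                             hit_threshold=hit_threshold)


def call_hits(fingerprints: pd.DataFrame | FingerprintMatrix,
              threshold: float = 2.0) -> pd.Series:
    """Hit iff any measure reaches |SSMD| >= threshold (inclusive)."""
    df = fingerprints.values if isinstance(fingerprints, FingerprintMatrix) \
        else fingerprints
    return df.abs().max(axis=1, skipna=True).ge(threshold).fillna(False)


def cluster_fingerprints(hit_values: pd.DataFrame, threshold: float = 9.5):
    """Ward / standardized-Euclidean hierarchical clustering of hit
    fingerprints, cut at ``threshold``.

    Missing SSMDs are imputed to 0 for the distance computation only.
    Returns (linkage matrix, flat cluster labels, leaf order).
    """
    if len(hit_values) < 2:
        raise ValueError("need at least two hits to cluster")
    x = hit_values.fillna(0.0).to_numpy(dtype=float)
    v = x.var(axis=0, ddof=1)
    v[v == 0] = 1.0
    d = pdist(x, metric="seuclidean", V=v)
    link = hierarchy.linkage(d, method="ward")
    flat = hierarchy.fcluster(link, t=threshold, criterion="distance")
    order = hierarchy.leaves_list(link)
    return link, pd.Series(flat, index=hit_values.index), order


def measure_correlogram(hit_values: pd.DataFrame):
    """Pearson correlations between measures across hit compounds, with an
    average-linkage / correlation-distance ordering."""
    if len(hit_values) < 3:
        raise ValueError("need at least three hits for a correlogram")
    x = hit_values.fillna(0.0).to_numpy(dtype=float).T  # measures x hits
    sd = x.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance measures; their correlations are set "
                      "to 0", stacklevel=2)
    xs = x - x.mean(axis=1, keepdims=True)
    denom = np.where(zero, 1.0, sd * x.shape[1])
    corr = (xs @ xs.T) / np.outer(denom, denom) * x.shape[1]
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    corr_df = pd.DataFrame(corr, index=hit_values.columns,
                           columns=hit_values.columns)
    return corr_df, order, link


def smooth_response_curve(probabilities: np.ndarray, window: int = 15,
                          order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing of a per-flash response-probability curve."""
    p = np.asarray(probabilities, dtype=float)
    if len(p) < window:
        warnings.warn("series shorter than the smoothing window; returned "
                      "unsmoothed", stacklevel=2)
        return p.copy()
    return savgol_filter(p, window, order)


def recount_hits(fingerprint_tsv, threshold: float = 2.0) -> Tuple[int, int]:
    """Recount viable rows and hits from a fingerprint table on disk.

    Expects the TSV layout written by :meth:`FingerprintMatrix.to_tsv` (one
    row per viable compound, measure columns).  Returns
    (n_viable_rows, n_hits).
    """
    df = pd.read_csv(fingerprint_tsv, sep="\t", index_col=0)
    num = df.select_dtypes(include=[np.number])
    hits = call_hits(num, threshold)
    return len(df), int(hits.sum())
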