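"""Dark-flash stimulation protocol, epoch partition, and stimulus regressors.

A dark flash (DF) is an abrupt whole-field dimming: the lights are switched
off for ``off_duration`` seconds and then ramped linearly back to baseline
over ``ramp_duration`` seconds, so one flash perturbs luminance for
``off_duration + ramp_duration`` seconds (21 s with the defaults).  Flashes
are delivered at fixed intervals in training blocks separated by rest, with
an optional re-test block after a retention period.

The module also builds the predictors used for regression-based scoring of
fluorescence traces: the stimulus waveform (or an onset impulse train)
restricted to the first three, last three, or all flashes of a block,
convolved with an exponential kernel approximating nuclear GCaMP kinetics —
six stimulus regressors in total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

__all__ = [
    "IMAGING_SAMPLE_RATE",
    "TRACKING_SAMPLE_RATE",
    "IMAGING_N_PLANES",
    "IMAGING_Z_STEP_UM",
    "DarkFlashProtocol",
    "EpochPartition",
    "RegressorSet",
    "build_protocol",
    "imaging_protocol",
    "partition_epochs",
    "stimulus_trace",
    "gcamp_kernel",
    "build_regressors",
]

#: Volumetric two-photon acquisition rate (Hz) of the functional stack.
IMAGING_SAMPLE_RATE = 1.98
#: Online behavioural tracking rate (Hz) in the screening rig.
TRACKING_SAMPLE_RATE = 28.0
#: Functional stack geometry: planes and axial step, i.e. 120 um of coverage.
IMAGING_N_PLANES = 12
IMAGING_Z_STEP_UM = 10.0


@dataclass(frozen=True)
class DarkFlashProtocol:
    """Timing of a dark-flash habituation experiment.

    Defaults reproduce the screening protocol: four training blocks of 60
    flashes at 1 min intervals separated by 1 h of rest, plus a 60-flash
    re-test block after a 5 h retention period.
    """

    n_blocks: int = 4
    flashes_per_block: int = 60
    inter_flash_interval: float = 60.0
    off_duration: float = 1.0
    ramp_duration: float = 20.0
    rest_between_blocks: float = 3600.0
    test_block_size: int = 60
    sample_rate: float = TRACKING_SAMPLE_RATE
    test_delay: float = 5 * 3600.0  # retention period before the re-test block

    def __post_init__(self) -> None:
        if self.n_flashes == 0:
            raise ValueError("empty protocol")
        for name in ("inter_flash_interval", "off_duration", "ramp_duration",
                     "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.inter_flash_interval < self.off_duration + self.ramp_duration:
            warnings.warn(
                "inter-flash interval is shorter than the stimulus itself; "
                "flash waveforms will overlap", stacklevel=2)

    @property
    def n_training_flashes(self) -> int:
        return self.n_blocks * self.flashes_per_block

    @property
    def n_flashes(self) -> int:
        return self.n_training_flashes + self.test_block_size

    @property
    def flash_onsets(self) -> np.ndarray:
        """Onset time (s) of every flash, training blocks then test block."""
        block_span = self.flashes_per_block * self.inter_flash_interval
        onsets = []
        for b in range(self.n_blocks):
            start = b * (block_span + self.rest_between_blocks)
            onsets.append(start + np.arange(self.flashes_per_block)
                          * self.inter_flash_interval)
        if self.test_block_size:
            t0 = 0.0
            if self.n_blocks:
                t0 = (self.n_blocks - 1) * (block_span
                                            + self.rest_between_blocks) \
                    + block_span + self.test_delay
            onsets.append(t0 + np.arange(self.test_block_size)
                          * self.inter_flash_interval)
        return np.concatenate(onsets) if onsets else np.empty(0)

    @property
    def duration(self) -> float:
        """Recording length (s): last onset plus one full inter-flash interval."""
        return float(self.flash_onsets[-1] + self.inter_flash_interval)

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in (
            "n_blocks", "flashes_per_block", "inter_flash_interval",
            "off_duration", "ramp_duration", "rest_between_blocks",
            "test_block_size", "sample_rate", "test_delay")})

    @classmethod
    def from_json(cls, text: str) -> "DarkFlashProtocol":
        return cls(**json.loads(text))


def build_protocol(n_blocks: int = 4, flashes_per_block: int = 60,
                   interval: float = 60.0, off: float = 1.0,
                   ramp: float = 20.0, test_block: int = 60,
                   rest: float = 3600.0,
                   sample_rate: float = TRACKING_SAMPLE_RATE) -> DarkFlashProtocol:
    """Construct a :class:`DarkFlashProtocol`; defaults give the screen protocol."""
    if n_blocks < 0 or flashes_per_block < 0 or test_block < 0:
        raise ValueError("counts must be >= 0")
    return DarkFlashProtocol(
        n_blocks=n_blocks, flashes_per_block=flashes_per_block,
        inter_flash_interval=interval, off_duration=off, ramp_duration=ramp,
        rest_between_blocks=rest, test_block_size=test_block,
        sample_rate=sample_rate)


def imaging_protocol() -> DarkFlashProtocol:
    """Single 60-flash block at 1 min intervals, as used under the microscope."""
    return DarkFlashProtocol(n_blocks=1, flashes_per_block=60,
                             test_block_size=0,
                             sample_rate=IMAGING_SAMPLE_RATE)


@dataclass(frozen=True)
class EpochPartition:
    """1-based flash indices of the naive / training / test epochs.

    The naive epoch is the first five flashes (the unhabituated response);
    the training epoch is the remainder of the training blocks; the test
    epoch is the re-test block delivered after the retention period.
    """

    naive: frozenset
    training: frozenset
    test: frozenset

    def as_dict(self) -> Dict[str, frozenset]:
        return {"naive": self.naive, "training": self.training,
                "test": self.test}


def partition_epochs(protocol: DarkFlashProtocol,
                     n_naive: int = 5) -> EpochPartition:
    """Split flashes into naive (first five), training (rest), and test epochs."""
    n_train = protocol.n_training_flashes
    if n_train < n_naive:
        warnings.warn(
            f"protocol has only {n_train} training flashes; the naive epoch "
            "takes them all and the training epoch is empty", stacklevel=2)
        n_naive = n_train
    naive = frozenset(range(1, n_naive + 1))
    training = frozenset(range(n_naive + 1, n_train + 1))
    test = frozenset(range(n_train + 1, protocol.n_flashes + 1))
    return EpochPartition(naive=naive, training=training, test=test)


def stimulus_trace(protocol: DarkFlashProtocol,
                   rate: float | None = None) -> np.ndarray:
    """Luminance deviation from baseline, sampled at ``rate`` Hz.

    Each flash contributes a plateau of height 1 lasting ``off_duration``
    followed by a linear decay to 0 over ``ramp_duration``; overlapping
    flashes take the pointwise maximum (lights cannot be more off than off).
    """
    if rate is None:
        rate = protocol.sample_rate
    if rate <= 0:
        raise ValueError("rate must be > 0")
    n = int(round(protocol.duration * rate))
    t = np.arange(n) / rate
    out = np.zeros(n)
    off, ramp = protocol.off_duration, protocol.ramp_duration
    for onset in protocol.flash_onsets:
        s = t - onset
        dev = np.where((s >= 0) & (s < off), 1.0,
                       np.where((s >= off) & (s < off + ramp),
                                1.0 - (s - off) / ramp, 0.0))
        np.maximum(out, dev, out=out)
    return out


def gcamp_kernel(tau: float = 3.5, rate: float = IMAGING_SAMPLE_RATE,
                 duration: float = 20.0) -> np.ndarray:
    """Causal single-exponential calcium-indicator kernel, peak 1 at lag 0.

    ``tau`` is the decay time constant in seconds.  Nuclear-localised GCaMP
    decays slowly, hence the multi-second default.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    lags = np.arange(int(np.floor(max(duration, 0.0) * rate)) + 1) / rate
    return np.exp(-lags / tau)


@dataclass(frozen=True)
class RegressorSet:
    """Six stimulus regressors plus kernel metadata.

    Keys are ``{shape}_{window}`` with shape in ``full``/``onset`` and window
    in ``first3``/``last3``/``all``.  Each regressor is the (windowed)
    stimulus or onset-impulse train convolved with the kernel and
    peak-normalised to 1.
    """

    regressors: Dict[str, np.ndarray]
    kernel: np.ndarray = field(repr=False)
    kernel_tau: float = 3.5
    sample_rate: float = IMAGING_SAMPLE_RATE

    def __post_init__(self) -> None:
        if len(self.regressors) != 6:
            raise ValueError("expected exactly six stimulus regressors")

    @property
    def names(self) -> list:
        return list(self.regressors)

    def as_matrix(self) -> np.ndarray:
        return np.array([self.regressors[k] for k in self.regressors])

    def to_tsv(self, path) -> None:
        import pandas as pd
        t = np.arange(len(next(iter(self.regressors.values())))) \
            / self.sample_rate
        df = pd.DataFrame({"time_s": t, **self.regressors})
        df.to_csv(path, sep="\t", index=False)


def build_regressors(protocol: DarkFlashProtocol,
                     kernel: np.ndarray | None = None,
                     rate: float | None = None) -> RegressorSet:
    """Build the six stimulus regressors for an imaging block.

    Windows (first three / last three / all flashes) refer to the flashes of
    the protocol's first block, the one recorded under the microscope.
    """
    if rate is None:
        rate = protocol.sample_rate
    if kernel is None:
        kernel = gcamp_kernel(rate=rate)
    onsets = protocol.flash_onsets[:protocol.flashes_per_block
                                   if protocol.n_blocks else 0]
    if len(onsets) < 3:
        raise ValueError("insufficient flashes for windowed regressors")
    n = int(round(protocol.duration * rate))
    t = np.arange(n) / rate
    off, ramp = protocol.off_duration, protocol.ramp_duration

    def full_wave(sel: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        for onset in sel:
            s = t - onset
            dev = np.where((s >= 0) & (s < off), 1.0,
                           np.where((s >= off) & (s < off + ramp),
                                    1.0 - (s - off) / ramp, 0.0))
            np.maximum(out, dev, out=out)
        return out

    def onset_wave(sel: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        for onset in sel:
            out[min(int(round(onset * rate)), n - 1)] = 1.0
        return out

    windows = {"first3": onsets[:3], "last3": onsets[-3:], "all": onsets}
    regs: Dict[str, np.ndarray] = {}
    for shape, fn in (("full", full_wave), ("onset", onset_wave)):
        for wname, sel in windows.items():
            r = np.convolve(fn(sel), kernel)[:n]
            peak = r.max()
            regs[f"{shape}_{wname}"] = r / peak if peak > 0 else r
    tau = -1.0 / (np.log(kernel[1]) * rate) if len(kernel) > 1 else float("nan")
    return RegressorSet(regressors=regs, kernel=kernel, kernel_tau=tau,
                        sample_rate=rate)
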