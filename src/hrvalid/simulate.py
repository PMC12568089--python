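"""Synthetic cohort generator: ground-truth heart rate plus device corruption.

The reference trajectory is a first-order relaxation towards a per-phase
steady-state target, dHR/dt = (target - HR)/tau, with an additive
orthostatic pulse ``amp * exp(-(t - t1)/tau_o)`` fired at the sit->stand
onset, plus stationary AR(1) heart-rate variability.  Devices observe a
trailing mean of the truth on their own reporting schedule, add bias and
state-dependent Gaussian noise (inflated inside transition windows, the
motion-artifact analogue), drop samples at random and in bursts, and
optionally round to integer bpm.

All randomness flows from one root seed through per-(subject, device)
derived streams, so adding a device never perturbs any other series.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .protocol import ProtocolSpec, TransitionWindows, build_default_protocol, derive_transitions, label_array

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectParams",
    "Schedule",
    "DeviceErrorModel",
    "HRSeries",
    "CohortDataset",
    "simulate_reference_hr",
    "simulate_device",
    "generate_cohort",
    "default_device_profiles",
    "draw_subject_params",
]

HR_FLOOR, HR_CEIL = 25.0, 245.0  # physiological guard band, bpm


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters for one subject's true heart rate.

    ``phase_targets`` maps ordinal load level -> steady-state HR (bpm) and
    must be nondecreasing in load.  ``tau`` is the first-order response
    time constant (s); the orthostatic pulse models the sharp HR peak on
    standing up.  HRV is stationary AR(1) with coefficient ``hrv_phi`` and
    stationary SD ``hrv_sd``.
    """

    resting_hr: float
    phase_targets: Mapping[int, float]
    tau: float = 35.0
    orthostatic_amp: float = 12.0
    orthostatic_tau: float = 20.0
    hrv_sd: float = 2.5
    hrv_phi: float = 0.8

    def __post_init__(self) -> None:
        if not (40.0 <= self.resting_hr <= 120.0):
            raise ValueError(f"resting_hr {self.resting_hr} outside [40, 120] bpm")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not (0.0 <= self.hrv_phi < 1.0):
            raise ValueError("hrv_phi must be in [0, 1)")
        if self.hrv_sd < 0:
            raise ValueError("hrv_sd must be >= 0")
        loads = sorted(self.phase_targets)
        targets = [self.phase_targets[l] for l in loads]
        if any(b < a for a, b in zip(targets, targets[1:])):
            raise ValueError("phase_targets must be nondecreasing in load level")


@dataclass(frozen=True)
class Schedule:
    """Device reporting schedule.

    kind='fixed'    : one report every ``interval`` seconds.
    kind='jittered' : inter-report gaps drawn from a shifted log-normal
                      calibrated to (min_gap, max_gap, mean_gap), rounded to
                      whole seconds and clipped to [min_gap, max_gap].
    kind='minute'   : alias for fixed 60 s.
    """

    kind: str
    interval: float = 1.0
    min_gap: float = 1.0
    max_gap: float = 110.0
    mean_gap: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "jittered", "minute"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "fixed" and self.interval < 1:
            raise ValueError("fixed schedule interval must be >= 1 s")
        if self.kind == "jittered":
            if not (1 <= self.min_gap <= self.mean_gap <= self.max_gap):
                raise ValueError("jittered schedule needs 1 <= min <= mean <= max")

    def realize(self, duration: float, rng: np.random.Generator) -> np.ndarray:
        """Report times in (0, duration), integer seconds, strictly increasing."""
        if self.kind == "minute":
            return np.arange(0.0, duration - 0.5, 60.0)
        if self.kind == "fixed":
            return np.arange(0.0, duration - 0.5, self.interval)
        # jittered: shifted log-normal gaps. sigma fixed at 0.9 gives a
        # right-skewed gap distribution spanning the (min, max) range.
        shift = self.min_gap
        target_mean = self.mean_gap - shift
        sigma = 0.9
        mu = np.log(target_mean) - sigma**2 / 2.0
        n_max = int(np.ceil(duration / self.min_gap)) + 8
        gaps = shift + rng.lognormal(mean=mu, sigma=sigma, size=n_max)
        gaps = np.clip(np.round(gaps), self.min_gap, self.max_gap)
        times = np.cumsum(gaps)
        return times[times < duration + 0.5]


@dataclass(frozen=True)
class DeviceErrorModel:
    """Observation model for one simulated device.

    The device reports the trailing mean of the true HR over
    ``(t - lag_window, t]`` plus ``bias`` plus Gaussian noise whose SD is
    ``noise_sd_motion`` inside transition windows and ``noise_sd_steady``
    elsewhere.  Samples are dropped independently with ``dropout_p`` and
    during burst-dropout intervals (a Poisson process of bursts with
    exponential lengths).
    """

    schedule: Schedule
    lag_window: float = 1.0
    bias: float = 0.0
    noise_sd_steady: float = 0.0
    noise_sd_motion: float = 0.0
    dropout_p: float = 0.0
    burst_rate_per_1000s: float = 0.0
    burst_mean_length_s: float = 0.0
    round_to_integer: bool = False

    def __post_init__(self) -> None:
        if not (self.noise_sd_motion >= self.noise_sd_steady >= 0):
            raise ValueError("need noise_sd_motion >= noise_sd_steady >= 0")
        if not (0.0 <= self.dropout_p <= 1.0):
            raise ValueError("dropout_p must be in [0, 1]")
        if self.lag_window < 1:
            raise ValueError("lag_window must be >= 1 s")


@dataclass(frozen=True)
class HRSeries:
    """One subject-device stream of (timestamp s, HR bpm) samples."""

    subject_id: str
    device_id: str
    timestamps: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        h = np.asarray(self.hr, dtype=float)
        if t.shape != h.shape:
            raise ValueError("timestamps and hr must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if h.size and (np.any(h <= 20) or np.any(h >= 250)):
            raise ValueError("hr values must lie in (20, 250) bpm")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "hr", h)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "device_id": self.device_id,
                "t_s": self.timestamps,
                "hr_bpm": self.hr,
            }
        )


@dataclass
class CohortDataset:
    """Simulated cohort: reference stream plus device streams per subject."""

    protocol: ProtocolSpec
    reference: list[HRSeries]
    devices: dict[str, list[HRSeries]]
    seed: int
    reference_id: str = "reference"
    subject_params: dict[str, SubjectParams] = field(default_factory=dict)
    profiles: dict[str, DeviceErrorModel] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.reference]

    def to_csv_dir(self, outdir) -> None:
        """Write one tidy CSV per stream plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = [s.to_frame() for s in self.reference]
        for series_list in self.devices.values():
            frames.extend(s.to_frame() for s in series_list)
        pd.concat(frames, ignore_index=True).to_csv(outdir / "streams.csv", index=False, float_format="%.6f")
        manifest = {
            "seed": self.seed,
            "reference_id": self.reference_id,
            "protocol": self.protocol.to_dict(),
            "devices": sorted(self.devices),
            "n_subjects": len(self.reference),
            "profiles": {d: _profile_to_dict(p) for d, p in sorted(self.profiles.items())},
            "subject_params": {
                s: _subject_to_dict(p) for s, p in sorted(self.subject_params.items())
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _profile_to_dict(p: DeviceErrorModel) -> dict:
    d = asdict(p)
    return d


def _subject_to_dict(p: SubjectParams) -> dict:
    d = asdict(p)
    d["phase_targets"] = {int(k): float(v) for k, v in p.phase_targets.items()}
    return d


def _rng_for(seed: int, *key_parts) -> np.random.Generator:
    """Derived stream: stable under adding subjects/devices elsewhere."""
    key = tuple(int(zlib.crc32(str(k).encode())) if isinstance(k, str) else int(k) for k in key_parts)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def simulate_reference_hr(
    protocol: ProtocolSpec,
    sp: SubjectParams,
    seed: int | np.random.Generator,
    subject_id: str = "S01",
) -> HRSeries:
    """1 Hz ground-truth heart rate over ``[0, duration)``.

    Deterministic trajectory (exact discretisation of the first-order
    relaxation, one step per second) plus the orthostatic pulse and AR(1)
    HRV noise.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng_for(int(seed), "ref")
    duration = int(round(protocol.total_duration))
    t = np.arange(duration, dtype=float) + protocol.start_time

    phase_idx = protocol.phase_index_of_times(t)
    loads = np.array([p.load for p in protocol.phases])
    targets = np.array([sp.phase_targets[int(l)] for l in loads], dtype=float)
    target_t = targets[phase_idx]

    decay = np.exp(-1.0 / sp.tau)
    hr_det = np.empty(duration)
    hr_det[0] = sp.resting_hr
    # HR[k+1] = target + (HR[k] - target) * exp(-dt/tau), dt = 1 s
    for k in range(duration - 1):
        hr_det[k + 1] = target_t[k + 1] + (hr_det[k] - target_t[k + 1]) * decay

    # Orthostatic pulse at the sit->stand onset: the first phase boundary
    # where the load steps up from the protocol's minimum load.
    changes = protocol.phase_change_times
    pulse = np.zeros(duration)
    min_load = loads.min()
    for b, onset in enumerate(changes):
        if loads[b] == min_load and loads[b + 1] > loads[b]:
            rel = t - onset
            pulse = np.where(rel >= 0, sp.orthostatic_amp * np.exp(-rel / sp.orthostatic_tau), 0.0)
            break

    if sp.hrv_sd > 0:
        innov_sd = sp.hrv_sd * np.sqrt(1.0 - sp.hrv_phi**2)
        eps = rng.normal(0.0, innov_sd, size=duration)
        eps[0] = rng.normal(0.0, sp.hrv_sd)  # stationary start
        noise = lfilter([1.0], [1.0, -sp.hrv_phi], eps)
    else:
        noise = np.zeros(duration)

    hr = np.clip(hr_det + pulse + noise, HR_FLOOR, HR_CEIL)
    return HRSeries(subject_id=subject_id, device_id="reference", timestamps=t, hr=hr)


def simulate_device(
    ref: HRSeries,
    em: DeviceErrorModel,
    tw: TransitionWindows,
    seed: int | np.random.Generator,
    device_id: str = "device",
) -> HRSeries:
    """Corrupt a 1 Hz reference stream through one device observation model."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng_for(int(seed), "dev")
    if len(ref) == 0:
        return HRSeries(ref.subject_id, device_id, np.array([]), np.array([]))

    t0 = ref.timestamps[0]
    duration = ref.timestamps[-1] - t0 + 1.0
    rel_times = em.schedule.realize(duration, rng)
    times = t0 + rel_times
    if times.size == 0:
        return HRSeries(ref.subject_id, device_id, np.array([]), np.array([]))

    # trailing mean of the reference over (t - lag, t] via cumulative sums
    csum = np.concatenate([[0.0], np.cumsum(ref.hr)])
    hi = np.searchsorted(ref.timestamps, times, side="right")
    lo = np.searchsorted(ref.timestamps, times - em.lag_window, side="right")
    counts = (hi - lo).astype(float)
    valid = counts > 0
    times, hi, lo, counts = times[valid], hi[valid], lo[valid], counts[valid]
    values = (csum[hi] - csum[lo]) / counts + em.bias

    state = label_array(times, tw)
    sd = np.where(state > 0, em.noise_sd_motion, em.noise_sd_steady)
    values = values + rng.normal(0.0, 1.0, size=times.size) * sd

    keep = rng.random(times.size) >= em.dropout_p
    if em.burst_rate_per_1000s > 0 and em.burst_mean_length_s > 0:
        n_bursts = rng.poisson(em.burst_rate_per_1000s * duration / 1000.0)
        for _ in range(n_bursts):
            start = rng.uniform(0.0, duration) + t0
            length = rng.exponential(em.burst_mean_length_s)
            keep &= ~((times >= start) & (times < start + length))
    times, values = times[keep], values[keep]

    if em.round_to_integer:
        values = np.round(values)
    values = np.clip(values, HR_FLOOR, HR_CEIL)
    return HRSeries(ref.subject_id, device_id, times, values)


def default_device_profiles() -> dict[str, DeviceErrorModel]:
    """Six stylised profiles spanning the reporting behaviours seen in
    commercial and research-grade monitors: a 1 s chest strap, 1-3 s and
    1 s wrist trackers, two irregular ~10 s reporters, and a once-a-minute
    device.  Parameters are stylised, not claims about any vendor.
    """
    return {
        "chest_1s": DeviceErrorModel(
            schedule=Schedule("fixed", interval=1),
            lag_window=5, bias=-0.3, noise_sd_steady=1.0, noise_sd_motion=2.0,
            dropout_p=0.0, round_to_integer=True,
        ),
        "wrist_1_3s": DeviceErrorModel(
            schedule=Schedule("jittered", min_gap=1, max_gap=3, mean_gap=2),
            lag_window=5, bias=0.3, noise_sd_steady=3.0, noise_sd_motion=6.5,
            dropout_p=0.05, round_to_integer=True,
        ),
        "wrist_irregular_10s": DeviceErrorModel(
            schedule=Schedule("jittered", min_gap=1, max_gap=110, mean_gap=10),
            lag_window=10, bias=2.0, noise_sd_steady=2.5, noise_sd_motion=5.0,
            dropout_p=0.0, round_to_integer=True,
        ),
        "wrist_minute": DeviceErrorModel(
            schedule=Schedule("minute"),
            lag_window=30, bias=-0.5, noise_sd_steady=3.0, noise_sd_motion=7.0,
            dropout_p=0.15, round_to_integer=True,
        ),
        "wrist_1s": DeviceErrorModel(
            schedule=Schedule("fixed", interval=1),
            lag_window=10, bias=-0.2, noise_sd_steady=4.5, noise_sd_motion=10.0,
            dropout_p=0.10, round_to_integer=True,
        ),
        "wrist_irregular_10s_noisy": DeviceErrorModel(
            schedule=Schedule("jittered", min_gap=1, max_gap=90, mean_gap=10),
            lag_window=10, bias=3.5, noise_sd_steady=5.0, noise_sd_motion=11.0,
            dropout_p=0.20, burst_rate_per_1000s=2.0, burst_mean_length_s=20.0,
            round_to_integer=True,
        ),
    }


def draw_subject_params(rng: np.random.Generator, loads: Sequence[int]) -> SubjectParams:
    """Draw one subject's generative parameters.

    Resting HR ~ Normal(70, 8^2) truncated to [50, 95] bpm; per-load-level
    HR increments are nonnegative draws so the steady-state targets are
    nondecreasing in load.
    """
    resting = float(np.clip(rng.normal(70.0, 8.0), 50.0, 95.0))
    levels = sorted(set(int(l) for l in loads))
    # mean increments per successive load level, bpm
    mean_steps = {1: 8.0, 2: 27.0, 3: 20.0, 4: 15.0}
    targets = {}
    current = resting
    for i, lvl in enumerate(levels):
        if i == 0:
            targets[lvl] = current
            continue
        step = max(0.0, rng.normal(mean_steps.get(lvl, 10.0), 4.0))
        current = min(current + step, 185.0)
        targets[lvl] = current
    return SubjectParams(
        resting_hr=resting,
        phase_targets=targets,
        tau=float(np.clip(rng.normal(35.0, 8.0), 15.0, 60.0)),
        orthostatic_amp=float(np.clip(rng.normal(12.0, 4.0), 0.0, 30.0)),
        orthostatic_tau=float(np.clip(rng.normal(20.0, 5.0), 8.0, 40.0)),
        hrv_sd=float(np.clip(rng.normal(2.5, 0.75), 0.5, 6.0)),
        hrv_phi=0.8,
    )


def generate_cohort(
    n_subjects: int,
    profiles: Optional[Mapping[str, DeviceErrorModel]] = None,
    seed: int = 0,
    protocol: Optional[ProtocolSpec] = None,
    pre_span: float = 10.0,
    post_span: float = 60.0,
) -> CohortDataset:
    """Simulate a full cohort: reference plus one stream per device per subject."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocol = protocol or build_default_protocol()
    profiles = dict(profiles) if profiles is not None else default_device_profiles()
    tw = derive_transitions(protocol, pre_span=pre_span, post_span=post_span)
    loads = [p.load for p in protocol.phases]

    reference: list[HRSeries] = []
    devices: dict[str, list[HRSeries]] = {d: [] for d in profiles}
    subject_params: dict[str, SubjectParams] = {}
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        sp = draw_subject_params(_rng_for(seed, i, "params"), loads)
        subject_params[sid] = sp
        ref = simulate_reference_hr(protocol, sp, _rng_for(seed, i, "ref"), subject_id=sid)
        reference.append(ref)
        for dev_id, em in profiles.items():
            dev = simulate_device(ref, em, tw, _rng_for(seed, i, "dev", dev_id), device_id=dev_id)
            devices[dev_id].append(dev)
    return CohortDataset(
        protocol=protocol,
        reference=reference,
        devices=devices,
        seed=int(seed),
        subject_params=subject_params,
        profiles=dict(profiles),
    )
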