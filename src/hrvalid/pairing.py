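"""Reference/device alignment at three resolutions, with pairwise deletion.

Three paired datasets are built from each reference-device stream pair:

* ``per_second``    — pairs at timestamps present (to 1 s) in both streams,
  no averaging;
* ``trailing_10s``  — for each reference timestamp t, the device value is
  the mean of device samples in the half-open trailing window (t - w, t];
* ``sync_60s``      — both streams averaged over synchronized windows
  [k*w, (k+1)*w) anchored at protocol time zero.

A pair is emitted only when both sides have data (pairwise deletion; no
imputation, outliers retained).  The reference grid always drives pairing;
the device never defines the grid.  State labels (steady / transition k)
attach at the reference timestamp for the per-second and trailing datasets;
synchronized-window pairs carry no state because a 60 s average cannot
resolve a 70 s transition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .protocol import TransitionWindows, label_array
from .simulate import HRSeries, CohortDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RESOLUTIONS",
    "PairedDataset",
    "MissingnessReport",
    "pair_per_second",
    "pair_trailing_window",
    "pair_synchronized_windows",
    "build_paired_dataset",
    "compute_missingness",
]

RESOLUTIONS = ("per_second", "trailing_10s", "sync_60s")

_COLUMNS = ["subject_id", "t_s", "ref_bpm", "dev_bpm", "state", "transition_id"]


@dataclass
class PairedDataset:
    """Complete (no-missing) reference/device pairs at one resolution.

    ``data`` is a tidy frame with columns subject_id, t_s, ref_bpm,
    dev_bpm, state ('steady'/'transition' or NA), transition_id
    (nullable).  State is present for per_second and trailing resolutions
    and absent for synchronized windows.
    """

    resolution: str
    data: pd.DataFrame
    device_id: str = "device"
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"resolution must be one of {RESOLUTIONS}, got {self.resolution!r}")
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"paired data missing columns {missing}")
        if self.data[["ref_bpm", "dev_bpm"]].isna().any().any():
            raise ValueError("paired data must not contain missing values (pairwise deletion upstream)")
        dup = self.data.duplicated(subset=["subject_id", "t_s"])
        if dup.any():
            raise ValueError("timestamps must be unique per subject")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"].unique())

    def filter_state(self, state: str, transition_id: Optional[int] = None) -> "PairedDataset":
        """Subset to one condition ('steady', 'transition', or transition k)."""
        if self.resolution == "sync_60s":
            raise ValueError("synchronized-window pairs carry no state labels")
        mask = self.data["state"] == state
        if transition_id is not None:
            mask &= self.data["transition_id"] == transition_id
        return PairedDataset(self.resolution, self.data[mask].reset_index(drop=True),
                             self.device_id, self.reference_id)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6f")


@dataclass(frozen=True)
class MissingnessReport:
    """Fraction of expected reference-aligned points a device failed to supply."""

    device_id: str
    n_expected: int
    n_paired: int

    def __post_init__(self) -> None:
        if self.n_expected <= 0:
            raise ValueError("n_expected must be positive")
        if self.n_paired > self.n_expected:
            raise ValueError("n_paired cannot exceed n_expected")

    @property
    def fraction_missing(self) -> float:
        return 1.0 - self.n_paired / self.n_expected

    @property
    def percent_missing(self) -> float:
        return 100.0 * self.fraction_missing


def _attach_state(df: pd.DataFrame, tw: Optional[TransitionWindows]) -> pd.DataFrame:
    if tw is None:
        df["state"] = pd.array([pd.NA] * len(df), dtype="string")
        df["transition_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
        return df
    codes = label_array(df["t_s"].to_numpy(dtype=float), tw)
    df["state"] = np.where(codes > 0, "transition", "steady")
    df["transition_id"] = pd.array([int(c) if c > 0 else pd.NA for c in codes], dtype="Int64")
    return df


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": pd.Series(dtype="string"),
        "t_s": pd.Series(dtype=float),
        "ref_bpm": pd.Series(dtype=float),
        "dev_bpm": pd.Series(dtype=float),
        "state": pd.Series(dtype="string"),
        "transition_id": pd.Series(dtype="Int64"),
    })


def pair_per_second(
    ref: HRSeries, dev: HRSeries, tw: Optional[TransitionWindows] = None
) -> PairedDataset:
    """Pairs at timestamps present in both streams, without averaging.

    Timestamps are compared at 1 s resolution (floored to whole seconds).
    """
    rt = np.floor(ref.timestamps).astype(np.int64)
    dt = np.floor(dev.timestamps).astype(np.int64)
    common, ri, di = np.intersect1d(rt, dt, return_indices=True)
    if common.size == 0 and len(ref) and len(dev):
        warnings.warn(f"per-second pairing of {ref.subject_id}/{dev.device_id}: disjoint timestamp sets", stacklevel=2)
    df = pd.DataFrame({
        "subject_id": ref.subject_id,
        "t_s": common.astype(float),
        "ref_bpm": ref.hr[ri],
        "dev_bpm": dev.hr[di],
    }) if common.size else _empty_frame().assign()
    df = _attach_state(df, tw)
    return PairedDataset("per_second", df, dev.device_id or "device", ref.device_id or "reference")


def pair_trailing_window(
    ref: HRSeries,
    dev: HRSeries,
    window: float = 10.0,
    tw: Optional[TransitionWindows] = None,
) -> PairedDataset:
    """Device samples in the trailing half-open window (t - w, t] averaged
    against the untouched reference value at each reference timestamp t.
    Reference timestamps with an empty window are pairwise-deleted.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(ref) == 0 or len(dev) == 0:
        if len(ref) or len(dev):
            warnings.warn("trailing-window pairing: one stream is empty", stacklevel=2)
        return PairedDataset("trailing_10s", _attach_state(_empty_frame(), tw),
                             dev.device_id or "device", ref.device_id or "reference")
    csum = np.concatenate([[0.0], np.cumsum(dev.hr)])
    hi = np.searchsorted(dev.timestamps, ref.timestamps, side="right")
    lo = np.searchsorted(dev.timestamps, ref.timestamps - window, side="right")
    counts = hi - lo
    keep = counts > 0
    means = np.zeros(len(ref))
    means[keep] = (csum[hi[keep]] - csum[lo[keep]]) / counts[keep]
    df = pd.DataFrame({
        "subject_id": ref.subject_id,
        "t_s": ref.timestamps[keep],
        "ref_bpm": ref.hr[keep],
        "dev_bpm": means[keep],
    })
    df = _attach_state(df, tw)
    return PairedDataset("trailing_10s", df, dev.device_id or "device", ref.device_id or "reference")


def pair_synchronized_windows(
    ref: HRSeries,
    dev: HRSeries,
    window: float = 60.0,
    span: Optional[float] = None,
) -> PairedDataset:
    """Both streams averaged over consecutive [k*w, (k+1)*w) bins from t = 0.

    A bin is dropped when either side has no sample in it.  The pair's
    timestamp is the bin start.  No state labels at this resolution.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(ref) == 0 or len(dev) == 0:
        return PairedDataset("sync_60s", _attach_state(_empty_frame(), None),
                             dev.device_id or "device", ref.device_id or "reference")

    def _bin_means(s: HRSeries) -> pd.Series:
        bins = np.floor(s.timestamps / window).astype(np.int64)
        return pd.Series(s.hr).groupby(bins).mean()

    rm, dm = _bin_means(ref), _bin_means(dev)
    joined = pd.concat([rm.rename("ref_bpm"), dm.rename("dev_bpm")], axis=1, join="inner")
    df = pd.DataFrame({
        "subject_id": ref.subject_id,
        "t_s": joined.index.to_numpy(dtype=float) * window,
        "ref_bpm": joined["ref_bpm"].to_numpy(),
        "dev_bpm": joined["dev_bpm"].to_numpy(),
    })
    df = _attach_state(df, None)
    return PairedDataset("sync_60s", df, dev.device_id or "device", ref.device_id or "reference")


def build_paired_dataset(
    cohort: CohortDataset,
    device_id: str,
    resolution: str,
    tw: Optional[TransitionWindows] = None,
    trailing_window: float = 10.0,
    sync_window: float = 60.0,
    reference_streams: Optional[Sequence[HRSeries]] = None,
) -> PairedDataset:
    """Pair every subject's reference and device stream at one resolution.

    ``reference_streams`` overrides the cohort's reference (used for the
    high-resolution chest-strap-as-reference analysis).
    """
    if resolution not in RESOLUTIONS:
        raise ValueError(f"unknown resolution {resolution!r}")
    refs = {s.subject_id: s for s in (reference_streams if reference_streams is not None else cohort.reference)}
    reference_id = next(iter(refs.values())).device_id if refs else "reference"
    frames = []
    for dev in cohort.devices[device_id]:
        ref = refs.get(dev.subject_id)
        if ref is None or len(ref) == 0 or len(dev) == 0:
            continue
        if resolution == "per_second":
            pds = pair_per_second(ref, dev, tw)
        elif resolution == "trailing_10s":
            pds = pair_trailing_window(ref, dev, trailing_window, tw)
        else:
            pds = pair_synchronized_windows(ref, dev, sync_window)
        frames.append(pds.data)
    data = pd.concat(frames, ignore_index=True) if frames else _attach_state(_empty_frame(), tw if resolution != "sync_60s" else None)
    return PairedDataset(resolution, data, device_id, reference_id)


def compute_missingness(
    reference: Sequence[HRSeries] | HRSeries,
    paired: PairedDataset,
    valid_subjects: Optional[Iterable[str]] = None,
    sync_window: float = 60.0,
) -> MissingnessReport:
    """Missingness against the expected reference-aligned grid.

    Expected points are the reference timestamps (per-second and trailing
    resolutions) or the reference-occupied bins (synchronized windows),
    counted over the subjects with a valid device recording.
    """
    refs = [reference] if isinstance(reference, HRSeries) else list(reference)
    if valid_subjects is None:
        valid = {s.subject_id for s in refs}
    else:
        valid = set(valid_subjects)
    n_expected = 0
    for s in refs:
        if s.subject_id not in valid:
            continue
        if paired.resolution == "sync_60s":
            n_expected += len(np.unique(np.floor(s.timestamps / sync_window).astype(np.int64)))
        else:
            n_expected += len(s)
    if n_expected == 0:
        raise ValueError("no expected reference points for the given valid subjects")
    n_paired = int((paired.data["subject_id"].isin(valid)).sum())
    return MissingnessReport(paired.device_id, n_expected, n_paired)
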