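"""End-to-end validation runs: simulate/ingest -> pair -> segment -> stats.

``run_validation`` orchestrates the four study designs over a cohort:
full-protocol agreement per device and resolution; steady-state versus
transition accuracy; per-transition exploratory accuracy; and (when a
device is nominated as reference) a high-resolution per-second validation
against that device.  Numerical outputs (CSV tables + a JSON manifest)
are the contract; figures are best-effort artifacts and excluded from
determinism comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .protocol import ProtocolSpec, build_default_protocol, derive_transitions
from .simulate import CohortDataset, DeviceErrorModel, default_device_profiles, generate_cohort, HRSeries
from .pairing import RESOLUTIONS, PairedDataset, build_paired_dataset, compute_missingness
from .agreement import AgreementModel, accuracy_per_subject
from .comparisons import condition_test, pairwise_device_tests

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_validation", "exclude_low_coverage_devices", "load_cohort_csv"]

STATEFUL_RESOLUTIONS = ("per_second", "trailing_10s")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Unusable input data (CLI exit code 1)."""


@dataclass
class RunConfig:
    """Configuration of one validation run.

    ``source`` is 'simulate' or a directory of stream CSVs.  ``conditions``
    may contain 'full', 'steady', 'transition', 'per_transition'.
    Transition-conditioned analyses are refused at the synchronized 60 s
    resolution: that averaging window cannot resolve a 70 s transition.
    """

    source: str = "simulate"
    n_subjects: int = 24
    protocol_file: Optional[str] = None
    device_profiles: Optional[Mapping[str, DeviceErrorModel]] = None
    devices: Optional[Sequence[str]] = None
    resolutions: Sequence[str] = RESOLUTIONS
    reference_id: str = "reference"
    conditions: Sequence[str] = ("full", "steady", "transition", "per_transition")
    pre_span: float = 10.0
    post_span: float = 60.0
    trailing_window: float = 10.0
    sync_window: float = 60.0
    alpha: float = 0.05
    n_boot: int = 200
    min_pair_ratio: float = 0.25
    seed: int = 0
    outdir: Optional[str] = None
    make_plots: bool = True

    def validate(self) -> None:
        bad = set(self.resolutions) - set(RESOLUTIONS)
        if bad:
            raise ConfigError(f"unknown resolutions {sorted(bad)}")
        bad = set(self.conditions) - {"full", "steady", "transition", "per_transition"}
        if bad:
            raise ConfigError(f"unknown conditions {sorted(bad)}")
        wants_transitions = {"steady", "transition", "per_transition"} & set(self.conditions)
        if wants_transitions and set(self.resolutions) == {"sync_60s"}:
            raise ConfigError("transition/steady analyses cannot be computed at the sync_60s "
                              "resolution only; they are defined for per_second and trailing_10s")
        if self.source == "simulate" and self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_pair_ratio < 0:
            raise ConfigError("min_pair_ratio must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        profiles = raw.pop("device_profiles", None)
        cfg = cls(**raw)
        if profiles:
            from .simulate import Schedule
            parsed = {}
            for name, p in profiles.items():
                sched = p.pop("schedule")
                parsed[name] = DeviceErrorModel(schedule=Schedule(**sched), **p)
            cfg.device_profiles = parsed
        return cfg


def exclude_low_coverage_devices(
    pair_counts: Mapping[str, int], min_pair_ratio: float
) -> tuple[list[str], list[str]]:
    """Split devices into (kept, excluded) at one resolution.

    A device is excluded when its pair count falls below
    ``min_pair_ratio`` times the median pair count across devices —
    the data-accounting rule that drops once-a-minute reporters from
    second-level statistics.
    """
    if not pair_counts:
        return [], []
    if min_pair_ratio <= 0:
        return list(pair_counts), []
    med = float(np.median(list(pair_counts.values())))
    kept, excluded = [], []
    for dev, n in pair_counts.items():
        if n < min_pair_ratio * med:
            excluded.append(dev)
            logger.warning("excluding %s: %d pairs < %.2f x median (%.0f)", dev, n, min_pair_ratio, med)
        else:
            kept.append(dev)
    if not kept:
        raise DataError(f"all devices excluded by coverage rule (counts: {dict(pair_counts)})")
    return kept, excluded


def load_cohort_csv(directory, protocol: ProtocolSpec, reference_id: str = "reference") -> CohortDataset:
    """Read a cohort from ``streams.csv`` (subject_id, device_id, t_s, hr_bpm)."""
    path = Path(directory) / "streams.csv"
    if not path.exists():
        raise DataError(f"no streams.csv under {directory}")
    df = pd.read_csv(path)
    need = {"subject_id", "device_id", "t_s", "hr_bpm"}
    if not need <= set(df.columns):
        raise DataError(f"streams.csv must have columns {sorted(need)}")
    reference, devices = [], {}
    for (sid, did), g in df.groupby(["subject_id", "device_id"], sort=True):
        g = g.sort_values("t_s")
        series = HRSeries(str(sid), str(did), g["t_s"].to_numpy(float), g["hr_bpm"].to_numpy(float))
        if did == reference_id:
            reference.append(series)
        else:
            devices.setdefault(str(did), []).append(series)
    if not reference:
        raise DataError(f"reference stream {reference_id!r} not found in {path}")
    return CohortDataset(protocol=protocol, reference=reference, devices=devices,
                         seed=-1, reference_id=reference_id)


def _mape_series(paired: PairedDataset, condition=None, transition_id=None) -> Optional[pd.Series]:
    try:
        return accuracy_per_subject(paired, condition, transition_id).mape_values
    except ValueError:
        return None


def run_validation(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dictionary.

    When ``cfg.outdir`` is set, tables (CSV), the manifest (JSON) and
    best-effort figures are written there.
    """
    cfg.validate()
    protocol = ProtocolSpec.from_yaml(cfg.protocol_file) if cfg.protocol_file else build_default_protocol()
    tw = derive_transitions(protocol, cfg.pre_span, cfg.post_span)

    if cfg.source == "simulate":
        profiles = dict(cfg.device_profiles) if cfg.device_profiles else default_device_profiles()
        if cfg.devices:
            missing = set(cfg.devices) - set(profiles)
            if missing:
                raise ConfigError(f"requested devices without profiles: {sorted(missing)}")
            profiles = {d: profiles[d] for d in cfg.devices}
        cohort = generate_cohort(cfg.n_subjects, profiles, seed=cfg.seed, protocol=protocol,
                                 pre_span=cfg.pre_span, post_span=cfg.post_span)
    else:
        cohort = load_cohort_csv(cfg.source, protocol, cfg.reference_id)
        if cfg.devices:
            missing = set(cfg.devices) - set(cohort.devices)
            if missing:
                raise DataError(f"devices not present in input: {sorted(missing)}")
            cohort.devices = {d: cohort.devices[d] for d in cfg.devices}
    if not cohort.devices:
        raise DataError("no device streams to validate")

    manifest: dict = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "device_profiles"},
        "protocol": protocol.to_dict(),
        "transitions": [
            {"transition_id": w.transition_id, "onset_s": w.onset, "start_s": w.start, "end_s": w.end}
            for w in tw
        ],
        "devices": sorted(cohort.devices),
        "n_subjects": len(cohort.reference),
        "resolutions": list(cfg.resolutions),
        "results": {},
        "exclusions": {},
        "comparisons": {},
        "condition_tests": {},
    }

    # ---- pair everything, apply the coverage exclusion per resolution
    paired: dict[str, dict[str, PairedDataset]] = {}
    for res in cfg.resolutions:
        paired[res] = {}
        for dev in sorted(cohort.devices):
            p = build_paired_dataset(cohort, dev, res, tw if res in STATEFUL_RESOLUTIONS else None,
                                     cfg.trailing_window, cfg.sync_window)
            if p.n_pairs == 0:
                logger.warning("device %s has no pairs at %s; skipped", dev, res)
                continue
            paired[res][dev] = p
        kept, excluded = exclude_low_coverage_devices(
            {d: p.n_pairs for d, p in paired[res].items()}, cfg.min_pair_ratio)
        manifest["exclusions"][res] = excluded
        paired[res] = {d: paired[res][d] for d in kept}

    # ---- per device x resolution: full-protocol agreement + conditions
    rows = []
    for res in cfg.resolutions:
        manifest["results"][res] = {}
        for dev, p in paired[res].items():
            entry: dict = {}
            if "full" in cfg.conditions:
                results = AgreementModel(p, n_boot=cfg.n_boot, seed=cfg.seed).fit()
                entry["full"] = results.to_dict()
                miss = compute_missingness(cohort.reference, p,
                                           valid_subjects=p.subject_ids, sync_window=cfg.sync_window)
                entry["full"]["missingness_pct"] = miss.percent_missing
                rows.append(entry["full"])
            if res in STATEFUL_RESOLUTIONS:
                for cond in ("steady", "transition"):
                    if cond in cfg.conditions:
                        acc = _safe_accuracy(p, cond)
                        if acc is not None:
                            entry[cond] = acc
                if "per_transition" in cfg.conditions:
                    entry["per_transition"] = {}
                    for w in tw:
                        acc = _safe_accuracy(p, "transition", w.transition_id)
                        if acc is not None:
                            entry["per_transition"][str(w.transition_id)] = acc
            manifest["results"][res][dev] = entry

    # ---- pairwise device comparisons + condition tests
    for res in cfg.resolutions:
        usable = {d: _mape_series(p) for d, p in paired[res].items()}
        usable = {d: s for d, s in usable.items() if s is not None}
        if len(usable) >= 2:
            cm = pairwise_device_tests(usable, alpha=cfg.alpha)
            manifest["comparisons"][res] = cm.to_dict()
        if res in STATEFUL_RESOLUTIONS and {"steady", "transition"} <= set(cfg.conditions):
            manifest["condition_tests"][res] = {}
            for dev, p in paired[res].items():
                s = _mape_series(p, "steady")
                t = _mape_series(p, "transition")
                if s is None or t is None:
                    continue
                try:
                    pval = condition_test(s, t)
                except ValueError as exc:
                    logger.warning("condition test %s/%s skipped: %s", dev, res, exc)
                    continue
                manifest["condition_tests"][res][dev] = pval

    if cfg.outdir:
        _write_outputs(Path(cfg.outdir), manifest, rows, paired, cfg)
    return manifest


def _safe_accuracy(p: PairedDataset, condition: str, transition_id: Optional[int] = None) -> Optional[dict]:
    try:
        a = accuracy_per_subject(p, condition, transition_id)
    except ValueError:
        return None
    return {
        "n_subjects": a.n_subjects,
        "median_mape_pct": a.median_mape,
        "iqr_mape_pct": a.iqr_mape,
        "median_mae_bpm": a.median_mae,
        "iqr_mae_bpm": a.iqr_mae,
    }


def _write_outputs(outdir: Path, manifest: dict, rows: list[dict],
                   paired: dict, cfg: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    if rows:
        table = pd.DataFrame(rows)
        cols = ["device_id", "resolution", "n_pairs", "missingness_pct", "rmccc",
                "rmccc_ci", "bias_bpm", "bias_p", "loa_lower_bpm", "loa_upper_bpm",
                "median_mape_pct", "iqr_mape_pct"]
        table[[c for c in cols if c in table.columns]].to_csv(outdir / "validation_table.csv", index=False)
    for res, cm in manifest["comparisons"].items():
        pd.DataFrame([
            {"comparison": k, "p_value": v} for k, v in cm["p_values"].items()
        ]).to_csv(outdir / f"pairwise_{res}.csv", index=False)
    if cfg.make_plots:
        try:
            _make_plots(outdir, paired, manifest, cfg)
        except Exception as exc:  # figures are best-effort
            logger.warning("figure generation failed: %s", exc)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (DeviceErrorModel,)):
        return asdict(o)
    return str(o)


def _make_plots(outdir: Path, paired: dict, manifest: dict, cfg: RunConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    for res, devs in paired.items():
        for dev, p in devs.items():
            full = manifest["results"].get(res, {}).get(dev, {}).get("full")
            if not full:
                continue
            fig, ax = plt.subplots(figsize=(6, 4))
            df = p.data
            ax.scatter((df.ref_bpm + df.dev_bpm) / 2, df.dev_bpm - df.ref_bpm, s=4, alpha=0.3)
            for y, ls in ((full["bias_bpm"], "-"), (full["loa_lower_bpm"], "--"), (full["loa_upper_bpm"], "--")):
                ax.axhline(y, color="crimson", linestyle=ls, lw=1)
            ax.set_xlabel("mean HR (bpm)")
            ax.set_ylabel("device - reference (bpm)")
            ax.set_title(f"{dev} @ {res}")
            fig.savefig(figdir / f"bland_altman_{dev}_{res}.png", dpi=110)
            plt.close(fig)
    # notched boxplots: steady vs transition MAPE per device
    for res in STATEFUL_RESOLUTIONS:
        if res not in paired:
            continue
        data, labels = [], []
        for dev, p in paired[res].items():
            s = _mape_series(p, "steady")
            t = _mape_series(p, "transition")
            if s is None or t is None:
                continue
            data.extend([s.to_numpy(), t.to_numpy()])
            labels.extend([f"{dev}\nsteady", f"{dev}\ntrans"])
        if not data:
            continue
        fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(labels)), 4))
        ax.boxplot(data, notch=True, tick_labels=labels)
        ax.axhline(10.0, color="gray", lw=0.8, linestyle=":")
        ax.set_ylabel("per-subject MAPE (%)")
        ax.set_title(f"steady vs transition accuracy ({res})")
        fig.tight_layout()
        fig.savefig(figdir / f"condition_boxplot_{res}.png", dpi=110)
        plt.close(fig)
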