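"""Synthetic GC–sensor cohort generator.

Emulates the statistical structure of a paediatric faecal-VOC case–control
study run on a GC column coupled to a metal-oxide gas sensor: positive
resistance traces sampled at 0.5 s over a 40 min run, slow baseline drift,
Gaussian elution peaks with retention-time jitter, group-specific peak
abundances, matched case–control pairing, a two-batch structure with a
sensor change (gain/offset/retention shift) between batches, and 3-month
follow-up samples with attenuated disease effects.

The defaults reproduce the study layout: a training batch of 48 IBD
baselines (26 CD, 18 UC, 4 IBDU), 48 matched controls and 23 follow-ups,
and a validation batch of 28 IBD (16 CD, 10 UC, 2 IBDU) each with a
matched control plus 14 follow-ups — 152 baseline samples and 37
follow-ups in total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CD", "UC", "IBDU", "control")
IBD_GROUPS = ("CD", "UC", "IBDU")
SITES = ("Liverpool", "Bristol", "Birmingham")

#: study sample layout: baseline IBD counts per batch
TRAINING_COUNTS = {"CD": 26, "UC": 18, "IBDU": 4}
VALIDATION_COUNTS = {"CD": 16, "UC": 10, "IBDU": 2}
N_FOLLOWUP = {"training": 23, "validation": 14}


@dataclass(frozen=True)
class PeakSpec:
    """One elution peak: a Gaussian resistance deflection.

    retention_time and width (the Gaussian sigma) are in seconds from
    injection; amplitude is in resistance-deflection units; jitter_sd is
    the per-sample standard deviation of this peak's retention shift.
    """

    retention_time: float
    amplitude: float
    width: float
    jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"peak amplitude must be positive, got {self.amplitude}")
        if self.width <= 0:
            raise ValueError(f"peak width must be positive, got {self.width}")
        if self.retention_time <= 0:
            raise ValueError(f"retention_time must be positive, got {self.retention_time}")


@dataclass(frozen=True)
class DriftSpec:
    """Smooth sensor baseline: offset + linear trend + slow sine."""

    offset: float = 20.0
    slope_per_s: float = 1.5e-3
    sine_amplitude: float = 1.0
    sine_period_s: float = 1200.0

    def baseline(self, t: np.ndarray) -> np.ndarray:
        return (
            self.offset
            + self.slope_per_s * t
            + self.sine_amplitude * np.sin(2.0 * np.pi * t / self.sine_period_s)
        )


@dataclass(frozen=True)
class FcpModel:
    """Log-normal faecal-calprotectin model with group-specific medians (µg/g)."""

    median_control: float = 30.0
    median_ibd: float = 600.0
    sigma_log: float = 1.0

    def median_for(self, group: str) -> float:
        return self.median_ibd if group in IBD_GROUPS else self.median_control


def default_peak_library(n_peaks: int = 24, seed: int = 20240507) -> list[PeakSpec]:
    """Fixed library of elution peaks spread over the analysis window."""
    rng = np.random.default_rng(seed)
    times = np.linspace(80.0, 1700.0, n_peaks) + rng.uniform(-20.0, 20.0, n_peaks)
    amps = rng.uniform(1.0, 6.0, n_peaks)
    widths = rng.uniform(6.0, 14.0, n_peaks)
    return [PeakSpec(float(t), float(a), float(w)) for t, a, w in zip(times, amps, widths)]


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the synthetic cohort; seed determines everything.

    ``ibd_effect_log`` / ``subtype_effect_log`` are log-amplitude shifts on
    the planted peaks, in natural-log units.  With the default per-sample
    amplitude scatter ``amplitude_sigma_log`` = 0.25, the default effect of
    0.5 is a 2-standard-deviation shift.  ``effect_peaks`` may instead give
    an explicit {peak_index: {group: log-shift}} map, which overrides the
    scalar fields.
    """

    seed: int = 0
    run_length_s: float = 2400.0
    tick_s: float = 0.5
    peaks: tuple[PeakSpec, ...] = tuple(default_peak_library())
    drift: DriftSpec = DriftSpec()
    noise_sd: float = 0.05
    sample_jitter_sd_s: float = 2.0
    amplitude_sigma_log: float = 0.25
    ibd_effect_peaks: tuple[int, ...] = (2, 6, 10, 15, 19)
    subtype_effect_peaks: tuple[int, ...] = (4, 12, 21)
    ibd_effect_log: float = 0.5
    subtype_effect_log: float = 0.5
    effect_peaks: dict[int, dict[str, float]] | None = None
    followup_attenuation: float = 0.5
    batch_gain: float = 1.3
    batch_baseline_shift: float = 2.0
    batch_retention_shift_s: float = 4.0
    training_counts: dict[str, int] = field(default_factory=lambda: dict(TRAINING_COUNTS))
    validation_counts: dict[str, int] = field(default_factory=lambda: dict(VALIDATION_COUNTS))
    n_followup: dict[str, int] = field(default_factory=lambda: dict(N_FOLLOWUP))
    fcp_model: FcpModel = FcpModel()

    def __post_init__(self) -> None:
        if not 0.0 <= self.followup_attenuation <= 1.0:
            raise ValueError("followup_attenuation must be in [0, 1]")
        for counts in (self.training_counts, self.validation_counts):
            for g, n in counts.items():
                if n < 2:
                    raise ValueError(f"group size for {g} must be >= 2, got {n}")
        for batch, n in self.n_followup.items():
            if n > sum((self.training_counts if batch == "training" else self.validation_counts).values()):
                raise ValueError(f"more follow-ups than IBD subjects in {batch} batch")

    def planted_effects(self) -> dict[int, dict[str, float]]:
        """Per-peak, per-group log-amplitude shifts."""
        if self.effect_peaks is not None:
            return self.effect_peaks
        eff: dict[int, dict[str, float]] = {}
        for i in self.ibd_effect_peaks:
            eff[i] = {g: self.ibd_effect_log for g in IBD_GROUPS}
        for i in self.subtype_effect_peaks:
            d = eff.setdefault(i, {})
            d["CD"] = d.get("CD", 0.0) + self.subtype_effect_log
            d["UC"] = d.get("UC", 0.0) - self.subtype_effect_log
        return eff

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)

    def null(self) -> "CohortConfig":
        """Copy with every planted group effect removed."""
        return self.replace(ibd_effect_log=0.0, subtype_effect_log=0.0, effect_peaks=None)


def generate_chromatogram(
    peaks: list[PeakSpec] | tuple[PeakSpec, ...],
    drift: DriftSpec,
    noise_sd: float,
    run_length_s: float = 2400.0,
    tick_s: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
    global_shift_s: float = 0.0,
    gain: float = 1.0,
    baseline_shift: float = 0.0,
) -> np.ndarray:
    """Simulate one resistance trace: drift + jittered Gaussian peaks + noise.

    The series has ``run_length_s / tick_s + 1`` points (one per sampling
    tick, endpoints included) and is strictly positive.  ``global_shift_s``
    shifts every peak's retention time (per-sample jitter and batch shift);
    ``gain``/``baseline_shift`` apply the batch-2 sensor-change distortion.
    """
    if tick_s <= 0:
        raise ValueError("tick_s must be positive")
    n_ticks = run_length_s / tick_s
    if abs(n_ticks - round(n_ticks)) > 1e-9:
        raise ValueError(f"run_length_s={run_length_s} is not an integer multiple of tick_s={tick_s}")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(n_ticks)) + 1) * tick_s
    y = drift.baseline(t).astype(float)
    for pk in peaks:
        centre = pk.retention_time + global_shift_s
        if pk.jitter_sd > 0:
            centre += rng.normal(0.0, pk.jitter_sd)
        # a Gaussian is negligible beyond 8 sigma; restrict evaluation to that window
        lo = max(0, int((centre - 8 * pk.width) / tick_s))
        hi = min(len(t), int((centre + 8 * pk.width) / tick_s) + 1)
        if lo < hi:
            y[lo:hi] += pk.amplitude * np.exp(-0.5 * ((t[lo:hi] - centre) / pk.width) ** 2)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, y.shape)
    y = gain * y + baseline_shift
    # the sensor reports positive resistance; the offset dominates, but guard anyway
    return np.maximum(y, 1e-9)


def generate_fcp(record: pd.Series | dict, model: FcpModel, seed: int | np.random.SeedSequence) -> float:
    """Draw a faecal-calprotectin value (µg/g) from the group's log-normal."""
    group = record["group"]
    if group not in GROUPS:
        raise ValueError(f"record has unknown group {group!r}")
    rng = np.random.default_rng(seed)
    z = rng.normal() if model.sigma_log > 0 else 0.0
    return float(model.median_for(group) * np.exp(model.sigma_log * z))


def _sample_effect(cfg: CohortConfig, group: str, timepoint: str) -> dict[int, float]:
    """Log-amplitude shift per peak index for one sample."""
    atten = cfg.followup_attenuation if timepoint == "month3" else 1.0
    out = {}
    for idx, per_group in cfg.planted_effects().items():
        e = per_group.get(group, 0.0)
        if e:
            out[idx] = e * atten
    return out


def generate_cohort(config: CohortConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Generate the full two-batch cohort.

    Returns ``(chromatograms, records)`` where ``chromatograms`` maps
    sample_id to a resistance series and ``records`` is the sample-metadata
    table (one row per sample, SampleRecord fields).  The same seed always
    yields byte-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    rows: list[dict] = []
    subject_counter = 0
    pair_counter = 0

    for batch, counts in (("training", config.training_counts), ("validation", config.validation_counts)):
        ibd_subject_ids: list[str] = []
        for group in IBD_GROUPS:
            for _ in range(counts.get(group, 0)):
                subject_counter += 1
                pair_counter += 1
                case_id = f"S{subject_counter:04d}"
                ibd_subject_ids.append(case_id)
                age = float(meta_rng.uniform(4.0, 17.0))
                sex = "F" if meta_rng.random() < 0.5 else "M"
                site = SITES[int(meta_rng.integers(len(SITES)))]
                pair = f"P{pair_counter:04d}"
                activity = float(np.clip(meta_rng.normal(45.0, 12.0), 5.0, 90.0))
                rows.append(
                    dict(
                        sample_id=f"{case_id}-B",
                        subject_id=case_id,
                        group=group,
                        timepoint="baseline",
                        matched_pair_id=pair,
                        batch=batch,
                        age_years=round(age, 2),
                        sex=sex,
                        site=site,
                        activity_score=round(activity, 1),
                    )
                )
                subject_counter += 1
                ctrl_id = f"S{subject_counter:04d}"
                ctrl_age = age + float(meta_rng.uniform(-0.49, 0.49))
                rows.append(
                    dict(
                        sample_id=f"{ctrl_id}-B",
                        subject_id=ctrl_id,
                        group="control",
                        timepoint="baseline",
                        matched_pair_id=pair,
                        batch=batch,
                        age_years=round(ctrl_age, 2),
                        sex=sex,
                        site=site,
                        activity_score=np.nan,
                    )
                )
        # follow-ups: a random subset of this batch's IBD subjects returns at 3 months
        n_fu = config.n_followup.get(batch, 0)
        fu_ids = set(meta_rng.choice(ibd_subject_ids, size=n_fu, replace=False))
        base_by_subject = {r["subject_id"]: r for r in rows if r["subject_id"] in fu_ids and r["timepoint"] == "baseline"}
        for sid in sorted(fu_ids):
            base = base_by_subject[sid]
            rows.append(
                dict(
                    sample_id=f"{sid}-F",
                    subject_id=sid,
                    group=base["group"],
                    timepoint="month3",
                    matched_pair_id=None,
                    batch=batch,
                    age_years=round(base["age_years"] + 0.25, 2),
                    sex=base["sex"],
                    site=base["site"],
                    activity_score=round(base["activity_score"] * 0.3, 1),
                )
            )

    records = pd.DataFrame(rows)

    # one independent random stream per sample, spawned in record order
    child_seeds = ss.spawn(2 * len(records))
    fcp_vals = []
    chroms: dict[str, np.ndarray] = {}
    for i, rec in records.iterrows():
        eff = _sample_effect(config, rec["group"], rec["timepoint"])
        amp_rng = np.random.default_rng(child_seeds[2 * i])
        peaks = []
        for j, pk in enumerate(config.peaks):
            log_amp = np.log(pk.amplitude) + eff.get(j, 0.0)
            if config.amplitude_sigma_log > 0:
                log_amp += amp_rng.normal(0.0, config.amplitude_sigma_log)
            peaks.append(dataclasses.replace(pk, amplitude=float(np.exp(log_amp))))
        shift = float(amp_rng.normal(0.0, config.sample_jitter_sd_s)) if config.sample_jitter_sd_s > 0 else 0.0
        gain, boff = 1.0, 0.0
        if rec["batch"] == "validation":
            shift += config.batch_retention_shift_s
            gain, boff = config.batch_gain, config.batch_baseline_shift
        chroms[rec["sample_id"]] = generate_chromatogram(
            peaks,
            config.drift,
            config.noise_sd,
            config.run_length_s,
            config.tick_s,
            seed=child_seeds[2 * i + 1],
            global_shift_s=shift,
            gain=gain,
            baseline_shift=boff,
        )
        fcp_vals.append(round(generate_fcp(rec, config.fcp_model, child_seeds[2 * i]), 1))
    records["fcp_ug_per_g"] = fcp_vals
    return chroms, records


def write_cohort(
    chroms: dict[str, np.ndarray],
    records: pd.DataFrame,
    outdir: str | Path,
    tick_s: float = 0.5,
) -> Path:
    """Write one two-column text file per chromatogram, metadata.csv and manifest.csv."""
    from gcvoc.io import write_chromatogram

    outdir = Path(outdir)
    (outdir / "chromatograms").mkdir(parents=True, exist_ok=True)
    paths = []
    for sid in records["sample_id"]:
        p = outdir / "chromatograms" / f"{sid}.txt"
        write_chromatogram(p, chroms[sid], tick_s)
        paths.append(str(p.relative_to(outdir)))
    records.to_csv(outdir / "metadata.csv", index=False)
    pd.DataFrame({"sample_id": records["sample_id"], "path": paths}).to_csv(
        outdir / "manifest.csv", index=False
    )
    return outdir
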