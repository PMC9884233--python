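"""Synthetic cohorts of bilateral LDF, RR and EGG signals with known truth.

Every downstream stage (band decomposition, laterality index, HRV metrics,
EGG dominant frequency, group statistics) gets a parameter-recovery test bed:
the generator emits signals whose per-band amplitudes, left-right asymmetry,
short-term RR variability and slow-wave frequency are all recorded in a
ground-truth manifest.

Design of the signals:

* LDF, per side: baseline offset + one sinusoidal oscillator per band (tone
  frequency drawn uniformly within the band, phase per side) + white
  Gaussian noise.  Post-stimulus, per-group multipliers rescale selected
  band amplitudes on selected sides — the default scenario raises the left
  cardiac amplitude in the 30C group only, the pattern the analysis must
  recover.  The right-side amplitudes default to 0.9x the left so baseline
  asymmetry is stable and nonzero.
* RR: mean + optional slow sinusoidal trend + iid Gaussian jitter, with
  optional ectopic-like artifact excursions of +/-250-400 ms.
* EGG: 8 channels sharing one slow wave (with per-channel phase), weaker
  harmonics, white noise.

Single tones rather than 1/f processes are deliberate: band power is then
analytically known, which is what parameter-recovery tests need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hrv import RRSeries
from .signal_io import (GROUPS, BilateralSession, CohortDesign, EGGRecording,
                        PerfusionRecording, write_design_table,
                        write_egg_text, write_perfusion_text, write_rr_text,
                        write_session_sidecar)
from .wavelet_bands import BAND_REGISTRY

__all__ = ["BandSpec", "RRModel", "EGGModel", "SimCohortSpec", "Cohort",
           "SyntheticSubject", "generate_bilateral_ldf", "generate_rr_series",
           "generate_egg", "generate_cohort", "default_band_specs"]


class SpecError(ValueError):
    """Invalid simulation specification."""


@dataclass
class BandSpec:
    """One band oscillator: frequency range and per-side amplitudes (PU)."""

    band_id: str
    f_lo: float
    f_hi: float
    amplitude_left: float
    amplitude_right: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise SpecError(f"band {self.band_id}: need 0 < f_lo < f_hi")
        if self.amplitude_left < 0 or self.amplitude_right < 0:
            raise SpecError(f"band {self.band_id}: amplitudes must be >= 0")


@dataclass
class RRModel:
    mean_rr: float = 800.0        # ms
    sd_ms: float = 25.0           # iid beat-to-beat jitter
    trend_amplitude: float = 0.0  # ms, slow sinusoidal trend
    trend_period_s: float = 300.0
    artifact_rate: float = 0.0    # probability a beat becomes an excursion

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise SpecError("mean_rr must be positive")
        if not (0 <= self.artifact_rate < 1):
            raise SpecError("artifact_rate must be in [0, 1)")


@dataclass
class EGGModel:
    f_sw: float = 0.05            # Hz, slow-wave frequency (3 cpm)
    f_sw_jitter: float = 0.01     # per-subject uniform jitter, Hz
    amplitude: float = 100.0      # µV
    n_harmonics: int = 2
    noise_sd: float = 20.0        # µV
    fs: float = 10.0              # synthesis rate (spectral content < 0.25 Hz)

    def __post_init__(self) -> None:
        if not (0 < self.f_sw < self.fs / 2):
            raise SpecError("slow-wave frequency must lie in (0, fs/2)")


def default_band_specs(right_ratio: float = 0.9) -> list[BandSpec]:
    """Six band oscillators with a stable 10% baseline left>right asymmetry."""
    left_amps = {"endo_no_indep": 0.5, "endo_no_dep": 0.5, "neurogenic": 0.8,
                 "myogenic": 1.0, "respiratory": 1.2, "cardiac": 2.0}
    return [BandSpec(bid, lo, hi, left_amps[bid], left_amps[bid] * right_ratio)
            for bid, (lo, hi) in BAND_REGISTRY.items()]


@dataclass
class SimCohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the study design: 20 subjects per temperature group
    (4C/10C/30C), 64-Hz bilateral LDF with 15-min baseline and 30-min
    post-stimulus, and a post-stimulus cardiac-band asymmetry only in the
    30C group (left amplitude doubled).
    """

    n_per_group: int = 20
    fs: float = 64.0
    baseline_s: float = 900.0
    post_s: float = 1800.0
    baseline_offset: float = 20.0   # PU
    noise_sd: float = 0.3           # PU  (cardiac SNR 2.0/0.3 ~ 6.7)
    bands: list[BandSpec] = field(default_factory=default_band_specs)
    # group -> band_id -> (left multiplier, right multiplier), post-stimulus
    group_multipliers: dict = field(
        default_factory=lambda: {"30C": {"cardiac": (2.0, 1.0)}})
    rr: RRModel = field(default_factory=RRModel)
    # group -> (post mean-RR multiplier, post sd multiplier)
    group_rr_effects: dict = field(default_factory=dict)
    egg: EGGModel = field(default_factory=EGGModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise SpecError("n_per_group must be >= 1")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        for b in self.bands:
            if b.f_hi > self.fs / 2:
                raise SpecError(
                    f"band {b.band_id} upper edge {b.f_hi} Hz above Nyquist")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    session: BilateralSession
    rr: RRSeries
    egg_pre: EGGRecording
    egg_post: EGGRecording
    truth: dict


@dataclass
class Cohort:
    subjects: list[SyntheticSubject]
    design: CohortDesign
    manifest: dict


def generate_bilateral_ldf(spec: SimCohortSpec, subject_id: str, group: str,
                           seed) -> tuple[BilateralSession, dict]:
    """One subject's bilateral LDF session plus its ground truth.

    Each side is ``offset + sum_b A_side(t) sin(2 pi f_b t + phi_side) +
    noise``; the per-group amplitude multipliers switch on at the stimulus.
    Truth records the pre and post amplitude of every band on both sides.
    """
    rng = np.random.default_rng(seed)
    fs = spec.fs
    n = int(round((spec.baseline_s + spec.post_s) * fs))
    t = np.arange(n) / fs
    stim = spec.baseline_s
    post_mask = t >= stim
    mults = spec.group_multipliers.get(group, {})

    sides = {}
    truth_bands = {}
    for side in ("left", "right"):
        x = np.full(n, float(spec.baseline_offset))
        if spec.noise_sd > 0:
            x += rng.normal(0.0, spec.noise_sd, n)
        sides[side] = x
    for band in spec.bands:
        f = rng.uniform(band.f_lo, band.f_hi)
        if f > fs / 2:
            raise SpecError(f"band {band.band_id} oscillator above Nyquist")
        truth_bands[band.band_id] = {"frequency_hz": float(f)}
        for side, amp in (("left", band.amplitude_left),
                          ("right", band.amplitude_right)):
            phi = rng.uniform(0, 2 * np.pi)
            m_l, m_r = mults.get(band.band_id, (1.0, 1.0))
            m = m_l if side == "left" else m_r
            if amp != 0.0:
                envelope = np.where(post_mask, amp * m, amp)
                sides[side] += envelope * np.sin(2 * np.pi * f * t + phi)
            truth_bands[band.band_id][side] = {
                "amplitude_pre": float(amp), "amplitude_post": float(amp * m)}

    session = BilateralSession(
        left=PerfusionRecording(sides["left"], fs=fs, side="left",
                                subject_id=subject_id),
        right=PerfusionRecording(sides["right"], fs=fs, side="right",
                                 subject_id=subject_id),
        stimulus_time=stim, group=group, subject_id=subject_id)
    truth = {"bands": truth_bands, "noise_sd": spec.noise_sd,
             "baseline_offset": spec.baseline_offset}
    return session, truth


def generate_rr_series(rr_model: RRModel, seed, pre_s: float = 900.0,
                       post_s: float = 1800.0,
                       post_effects: tuple[float, float] = (1.0, 1.0)
                       ) -> tuple[RRSeries, dict]:
    """RR series spanning the pre and post phases, plus its ground truth.

    ``post_effects = (mean multiplier, sd multiplier)`` applies from the
    phase boundary onward.  Artifacts replace a beat's value with an
    excursion of +/- 250-400 ms at rate ``artifact_rate``.
    """
    rng = np.random.default_rng(seed)
    m = rr_model
    total_s = pre_s + post_s
    # upper bound on beat count, then trim by cumulative time
    n_max = int(total_s * 1000.0 / m.mean_rr * 1.5) + 10
    k = np.arange(n_max)
    base = np.full(n_max, m.mean_rr)
    sd = np.full(n_max, m.sd_ms)

    # provisional times to locate the phase boundary for the post multipliers
    t_prov = np.cumsum(base) / 1000.0
    post = t_prov > pre_s
    base[post] *= post_effects[0]
    sd[post] *= post_effects[1]
    if m.trend_amplitude:
        base = base + m.trend_amplitude * np.sin(
            2 * np.pi * t_prov / m.trend_period_s)
    intervals = base + (rng.normal(0.0, 1.0, n_max) * sd if np.any(sd > 0)
                        else 0.0)

    n_artifacts = 0
    if m.artifact_rate > 0:
        hit = rng.random(n_max) < m.artifact_rate
        n_artifacts = int(hit.sum())
        sign = rng.choice([-1.0, 1.0], size=n_artifacts)
        excursion = rng.uniform(250.0, 400.0, n_artifacts)
        intervals[hit] = intervals[hit] + sign * excursion
    intervals = np.clip(intervals, 200.0, None)  # physiological floor

    cum = np.cumsum(intervals) / 1000.0
    n_keep = int(np.searchsorted(cum, total_s, side="right")) + 1
    intervals = intervals[:min(n_keep, n_max)]
    series = RRSeries(intervals, split_time_s=pre_s)
    truth = {"mean_rr_pre": float(m.mean_rr),
             "mean_rr_post": float(m.mean_rr * post_effects[0]),
             "sd_ms_pre": float(m.sd_ms),
             "sd_ms_post": float(m.sd_ms * post_effects[1]),
             "rmssd_expected_pre": float(m.sd_ms * np.sqrt(2.0)),
             "rmssd_expected_post": float(m.sd_ms * post_effects[1] * np.sqrt(2.0)),
             "n_artifacts": n_artifacts}
    return series, truth


def generate_egg(egg_model: EGGModel, seed, duration_s: float = 900.0,
                 phase: str = "pre") -> tuple[EGGRecording, dict]:
    """8-channel EGG with a common slow wave, harmonics and noise."""
    rng = np.random.default_rng(seed)
    m = egg_model
    f_sw = m.f_sw + (rng.uniform(-m.f_sw_jitter, m.f_sw_jitter)
                     if m.f_sw_jitter else 0.0)
    if not (0 < f_sw < m.fs / 2):
        raise SpecError("jittered slow-wave frequency outside (0, fs/2)")
    n = int(round(duration_s * m.fs))
    t = np.arange(n) / m.fs
    channels = np.empty((8, n))
    for ch in range(8):
        phi = rng.uniform(0, 2 * np.pi)
        x = m.amplitude * np.sin(2 * np.pi * f_sw * t + phi)
        for h in range(2, m.n_harmonics + 2):
            if h * f_sw < m.fs / 2:
                x += (m.amplitude / (2.0 ** (h - 1))
                      * np.sin(2 * np.pi * h * f_sw * t + rng.uniform(0, 2 * np.pi)))
        if m.noise_sd > 0:
            x += rng.normal(0.0, m.noise_sd, n)
        channels[ch] = x
    rec = EGGRecording(channels, fs=m.fs, phase=phase)
    truth = {"f_sw_hz": float(f_sw), "amplitude": float(m.amplitude),
             "noise_sd": float(m.noise_sd)}
    return rec, truth


def generate_cohort(spec: SimCohortSpec, out_dir: str | Path | None = None,
                    overwrite: bool = False) -> Cohort:
    """Generate the full cohort; optionally write it in the canonical formats.

    With ``out_dir`` the cohort is written as per-subject TSV signal files +
    YAML sidecars, a design table and a JSON ground-truth manifest.  The
    target directory must be empty unless ``overwrite`` is set.  Identical
    spec and seed give a byte-identical dataset.
    """
    import pandas as pd

    root = np.random.SeedSequence(spec.seed)
    subj_seeds = root.spawn(3 * spec.n_per_group)
    subjects: list[SyntheticSubject] = []
    manifest: dict = {"seed": spec.seed, "n_per_group": spec.n_per_group,
                      "subjects": {}}
    design_rows = []
    i = 0
    for group in GROUPS:
        for k in range(spec.n_per_group):
            sid = f"S{i + 1:03d}"
            ldf_seed, rr_seed, egg_seed = subj_seeds[i].spawn(3)
            session, ldf_truth = generate_bilateral_ldf(spec, sid, group, ldf_seed)
            rr_fx = spec.group_rr_effects.get(group, (1.0, 1.0))
            rr, rr_truth = generate_rr_series(spec.rr, rr_seed,
                                              pre_s=spec.baseline_s,
                                              post_s=spec.post_s,
                                              post_effects=tuple(rr_fx))
            egg_children = egg_seed.spawn(2)
            egg_pre, egg_pre_truth = generate_egg(spec.egg, egg_children[0],
                                                  duration_s=spec.baseline_s,
                                                  phase="pre")
            egg_post, egg_post_truth = generate_egg(spec.egg, egg_children[1],
                                                    duration_s=spec.post_s,
                                                    phase="post")
            subjects.append(SyntheticSubject(sid, group, session, rr,
                                             egg_pre, egg_post,
                                             truth={"ldf": ldf_truth,
                                                    "rr": rr_truth,
                                                    "egg_pre": egg_pre_truth,
                                                    "egg_post": egg_post_truth}))
            manifest["subjects"][sid] = {"group": group,
                                         **subjects[-1].truth}
            design_rows.append({"subject_id": sid, "group": group})
            i += 1

    design = CohortDesign(pd.DataFrame(design_rows))
    cohort = Cohort(subjects=subjects, design=design, manifest=manifest)
    if out_dir is not None:
        _write_cohort(cohort, spec, Path(out_dir), overwrite)
    return cohort


def _write_cohort(cohort: Cohort, spec: SimCohortSpec, out_dir: Path,
                  overwrite: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    for sub in cohort.subjects:
        sdir = out_dir / sub.subject_id
        sdir.mkdir(exist_ok=True)
        write_perfusion_text(sub.session.left, sdir / "left.tsv")
        write_perfusion_text(sub.session.right, sdir / "right.tsv")
        write_rr_text(sub.rr.intervals, sdir / "rr.tsv")
        write_egg_text(sub.egg_pre, sdir / "egg_pre.tsv")
        write_egg_text(sub.egg_post, sdir / "egg_post.tsv")
        write_session_sidecar(
            sdir / "session.yaml", sub.subject_id, sub.group,
            sub.session.stimulus_time,
            files={"left": "left.tsv", "right": "right.tsv", "rr": "rr.tsv",
                   "egg_pre": "egg_pre.tsv", "egg_post": "egg_post.tsv"})
    write_design_table(cohort.design, out_dir / "design.tsv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=1, sort_keys=True)
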