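"""End-to-end orchestration: cohort in, tables and statistics out.

``analyze_cohort`` runs on in-memory cohorts (e.g. straight from the
synthetic generator); ``run_pipeline`` wraps it with on-disk input (a cohort
directory of per-subject sidecars) and output (CSV tables + stats.json +
run log).

Per subject: segmentation -> wavelet band decomposition -> laterality
indices (raw and per band), HRV change rates, EGG dominant frequency pre and
post.  Group stage: mixed RM-ANOVA per laterality channel with per-window
post-hoc contrasts, one-way ANOVA of the HRV change rates, paired pre/post
DF tests per group, and Spearman correlations between full-span band
laterality and the RMSSD change rate — each family FDR-corrected.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .egg_spectral import egg_dominant_frequency
from .hrv import RRSeries, hrv_pipeline
from .laterality import laterality_by_window, laterality_full_span
from .signal_io import ColumnSpec, load_session, read_egg, read_rr_text, read_session_sidecar
from .stats_pipeline import (TestResult, apply_fdr, mixed_anova, one_way_anova,
                             paired_test, posthoc_pairwise, spearman)
from .wavelet_bands import BAND_REGISTRY

log = logging.getLogger(__name__)


@dataclass
class SubjectInputs:
    subject_id: str
    group: str
    session: object                  # BilateralSession
    rr: RRSeries | None = None
    egg_pre: object | None = None    # EGGRecording
    egg_post: object | None = None


@dataclass
class PipelineResult:
    laterality: pd.DataFrame
    hrv: pd.DataFrame
    egg: pd.DataFrame
    stats: dict
    excluded: dict

    def stats_results(self, family: str) -> list[TestResult]:
        return self.stats[family]["tests"]


def _subjects_from_cohort(cohort) -> list[SubjectInputs]:
    return [SubjectInputs(s.subject_id, s.group, s.session, s.rr,
                          s.egg_pre, s.egg_post) for s in cohort.subjects]


def _subjects_from_dir(cohort_dir: Path, column_spec: ColumnSpec,
                       egg_fs: float | None) -> list[SubjectInputs]:
    subs = []
    for sidecar in sorted(cohort_dir.glob("*/session.yaml")):
        doc = read_session_sidecar(sidecar)
        base = sidecar.parent
        session = load_session(sidecar, column_spec)
        files = doc["files"]
        rr = egg_pre = egg_post = None
        if files.get("rr"):
            rr = RRSeries(read_rr_text(base / files["rr"]),
                          split_time_s=float(doc["stimulus_time_s"]))
        if files.get("egg_pre"):
            egg_pre = read_egg(base / files["egg_pre"], fs=egg_fs, phase="pre")
        if files.get("egg_post"):
            egg_post = read_egg(base / files["egg_post"], fs=egg_fs, phase="post")
        subs.append(SubjectInputs(str(doc["subject_id"]), str(doc["group"]),
                                  session, rr, egg_pre, egg_post))
    if not subs:
        raise FileNotFoundError(f"no */session.yaml sidecars under {cohort_dir}")
    return subs


def analyze_cohort(subjects: list[SubjectInputs], registry: dict | None = None,
                   band_statistic: str = "scalar", fdr_method: str = "bh",
                   min_survival: float = 0.5, **cwt_kwargs) -> PipelineResult:
    """Run the per-subject stages and the group statistics.

    Subjects failing any stage are excluded with a logged reason; the run
    aborts only if fewer than ``min_survival`` of subjects survive.
    """
    registry = registry or BAND_REGISTRY
    lat_rows, hrv_rows, egg_rows = [], [], []
    excluded: dict[str, str] = {}

    for sub in subjects:
        try:
            raw = laterality_by_window(sub.session, mode="raw")
            bands = laterality_by_window(sub.session, mode="bands",
                                         registry=registry,
                                         band_statistic=band_statistic,
                                         **cwt_kwargs)
            full = laterality_full_span(sub.session, mode="bands",
                                        registry=registry, **cwt_kwargs)
            for r in raw + bands:
                lat_rows.append({"subject": r.subject_id, "group": r.group,
                                 "window": r.window, "channel": r.channel,
                                 "index": r.index, "defined": r.defined,
                                 "reliable": r.reliable})
            for r in full:
                lat_rows.append({"subject": r.subject_id, "group": r.group,
                                 "window": "Post", "channel": r.channel,
                                 "index": r.index, "defined": r.defined,
                                 "reliable": r.reliable})
            if sub.rr is not None:
                h = hrv_pipeline(sub.rr)
                hrv_rows.append({
                    "subject": sub.subject_id, "group": sub.group,
                    "mean_rr_pre": h["pre"].mean_rr, "mean_rr_post": h["post"].mean_rr,
                    "rmssd_pre": h["pre"].rmssd, "rmssd_post": h["post"].rmssd,
                    "change_rate_mean_rr": h["change_rate_mean_rr"],
                    "change_rate_rmssd": h["change_rate_rmssd"],
                    "n_corrected": h["pre"].n_corrected + h["post"].n_corrected})
            for phase, rec in (("pre", sub.egg_pre), ("post", sub.egg_post)):
                if rec is not None:
                    df = egg_dominant_frequency(rec)
                    egg_rows.append({"subject": sub.subject_id, "group": sub.group,
                                     "phase": phase, "df_hz": df.df_hz,
                                     "df_cpm": df.df_cpm,
                                     "source_channel": df.source_channel,
                                     "defined": df.defined})
        except Exception as exc:  # noqa: BLE001 - exclusion is the contract
            log.warning("subject %s excluded: %s", sub.subject_id, exc)
            excluded[sub.subject_id] = str(exc)

    n_total = len(subjects)
    if n_total - len(excluded) < min_survival * n_total:
        raise RuntimeError(
            f"only {n_total - len(excluded)}/{n_total} subjects survived; "
            f"excluded: {excluded}")

    lat = pd.DataFrame(lat_rows)
    hrv = pd.DataFrame(hrv_rows)
    egg = pd.DataFrame(egg_rows)
    stats = _group_statistics(lat, hrv, egg, registry, fdr_method)
    return PipelineResult(lat, hrv, egg, stats, excluded)


def with_pre_reference(sub: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Add the definitional Pre level (laterality index of the baseline
    window against itself is exactly 100) to a per-channel laterality table,
    giving the 4-level within factor whose interaction captures
    post-stimulus divergence."""
    pre_rows = (sub[["subject", "group"]].drop_duplicates()
                .assign(window="Pre", channel=channel, index=100.0,
                        defined=True, reliable=True))
    out = pd.concat([pre_rows, sub], ignore_index=True)
    out["window"] = pd.Categorical(out["window"],
                                   ["Pre", "Post1", "Post2", "Post3"])
    return out


def laterality_mixed_anova(lat: pd.DataFrame, channel: str) -> list[TestResult]:
    """Mixed RM-ANOVA of one laterality channel with Pre as reference level."""
    sub = lat[(lat["channel"] == channel) & lat["defined"]
              & (lat["window"] != "Post")]
    sub = with_pre_reference(sub, channel)
    return mixed_anova(sub.rename(columns={"index": "value"}),
                       dv="value", name=channel)


def _group_statistics(lat: pd.DataFrame, hrv: pd.DataFrame, egg: pd.DataFrame,
                      registry: dict, fdr_method: str) -> dict:
    stats: dict = {}
    windowed = lat[lat["window"] != "Post"]

    # mixed RM-ANOVA per channel (raw + each band), windows within subjects
    channels = ["raw"] + list(registry)
    interaction_family: list[TestResult] = []
    for ch in channels:
        sub = windowed[(windowed["channel"] == ch) & windowed["defined"]]
        if sub.empty:
            continue
        sub = with_pre_reference(sub, ch)
        tests = mixed_anova(sub.rename(columns={"index": "value"}),
                            dv="value", name=ch)
        stats[f"laterality_anova_{ch}"] = {
            "method": "mixed RM-ANOVA", "n": int(sub["subject"].nunique()),
            "tests": tests}
        interaction_family.extend(t for t in tests if "interaction" in t.name)
        post_only = sub[sub["window"] != "Pre"]
        stats[f"laterality_posthoc_{ch}"] = {
            "method": "pairwise Welch t + FDR", "n": int(sub["subject"].nunique()),
            "tests": posthoc_pairwise(post_only.rename(columns={"index": "value"}),
                                      fdr_method=fdr_method)}
    apply_fdr(interaction_family, method=fdr_method)
    stats["laterality_interactions"] = {"method": f"FDR({fdr_method}) family",
                                        "n": len(interaction_family),
                                        "tests": interaction_family}

    if not hrv.empty:
        tests = [one_way_anova(hrv["change_rate_mean_rr"], hrv["group"],
                               name="change rate mean RR"),
                 one_way_anova(hrv["change_rate_rmssd"], hrv["group"],
                               name="change rate RMSSD")]
        apply_fdr(tests, method=fdr_method)
        stats["hrv_change_rates"] = {"method": "one-way ANOVA", "n": len(hrv),
                                     "tests": tests}

    if not egg.empty:
        tests = []
        wide = egg.pivot_table(index=["subject", "group"], columns="phase",
                               values="df_hz").reset_index()
        for grp, chunk in wide.groupby("group"):
            if {"pre", "post"} <= set(chunk.columns) and len(chunk) >= 3:
                tests.append(paired_test(chunk["pre"], chunk["post"],
                                         name=f"DF pre vs post ({grp})"))
        apply_fdr(tests, method=fdr_method)
        stats["egg_df"] = {"method": "paired t", "n": int(len(wide)),
                           "tests": tests}

    # Spearman: full-span band laterality vs RMSSD change rate, per group
    if not hrv.empty:
        full = lat[(lat["window"] == "Post") & (lat["channel"] != "raw")]
        merged = full.merge(hrv[["subject", "change_rate_rmssd"]], on="subject")
        tests = []
        for (grp, ch), chunk in merged.groupby(["group", "channel"]):
            chunk = chunk[chunk["defined"]]
            if len(chunk) >= 5:
                tests.append(spearman(chunk["index"], chunk["change_rate_rmssd"],
                                      name=f"laterality[{ch}] vs RMSSD CR ({grp})"))
        apply_fdr(tests, method=fdr_method)
        stats["laterality_rmssd_correlation"] = {
            "method": "spearman", "n": len(tests), "tests": tests}
    return stats


def stats_to_json(stats: dict) -> dict:
    return {family: {"method": block["method"], "n": block["n"],
                     "tests": [t.as_dict() for t in block["tests"]]}
            for family, block in stats.items()}


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Disk-to-disk pipeline run driven by a YAML config or dict.

    Config keys: ``cohort_dir`` (required), ``out_dir`` (required),
    ``egg_fs`` (needed for text EGG input), ``band_statistic``,
    ``fdr_method``, ``column_spec`` ({time, value, time_unit, fs}).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cohort_dir = Path(config["cohort_dir"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    cs_kwargs = config.get("column_spec") or {}
    column_spec = ColumnSpec(**cs_kwargs)
    subjects = _subjects_from_dir(cohort_dir, column_spec,
                                  config.get("egg_fs"))
    result = analyze_cohort(subjects,
                            band_statistic=config.get("band_statistic", "scalar"),
                            fdr_method=config.get("fdr_method", "bh"))
    result.laterality.to_csv(out_dir / "laterality.csv", index=False)
    result.hrv.to_csv(out_dir / "hrv.csv", index=False)
    result.egg.to_csv(out_dir / "egg.csv", index=False)
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(stats_to_json(result.stats), fh, indent=1, sort_keys=True)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({"lateroflux_version": __version__,
                   "python": platform.python_version(),
                   "config": {k: str(v) for k, v in config.items()},
                   "n_subjects": len(subjects),
                   "excluded": result.excluded}, fh, indent=1, sort_keys=True)
    return result
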