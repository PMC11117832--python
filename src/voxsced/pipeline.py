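"""Whole-study orchestration.

manifest in → per-recording acoustic measures → phase series → Tau-U
comparisons of each post phase (Post, FU1, FU2, FU3) against the pooled
three-visit baseline → significance table plus QC report.

DDK rate is carried as a control measure: it is computed and compared like
any outcome but no treatment effect on it is expected, so its flags serve
as a specificity check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_signal as cs
from . import phonation_tasks as pt
from . import prosody_timing as pr
from . import voice_quality as vq
from .io_formats import (PHASES, AudioClip, StudyManifest, RecordingEntry,
                         read_textgrid, read_wav)
from .sced_stats import (MeasureUndefined, PhaseSeries, bh_adjust,
                         significance_flag, tau_u)

__all__ = ["MeasureRegistry", "StudyResult", "run_study", "render_report",
           "DEFAULT_REGISTRY"]

COMPARISONS = ("Post", "FU1", "FU2", "FU3")

#: (measure, task) -> outcome class, mirroring the study's registry of
#: primary (trained-task) and secondary (untrained-task) outcomes.
DEFAULT_REGISTRY: dict[tuple[str, str], str] = {
    ("mean_intensity_db", "sustained"): "primary",
    ("mean_intensity_db", "personalized_sentences"): "primary",
    ("mean_intensity_db", "conversation"): "primary",
    ("f0_extreme_st", "glide_up"): "primary",
    ("f0_extreme_st", "glide_down"): "primary",
    ("f0_range_st", "glide_up"): "primary",
    ("f0_range_st", "glide_down"): "primary",
    ("cpps_db", "sustained"): "primary",
    ("jitter_pct", "sustained"): "primary",
    ("shimmer_pct", "sustained"): "primary",
    ("hnr_db", "sustained"): "primary",
    ("mean_intensity_db", "standardized_sentences"): "secondary",
    ("mean_intensity_db", "picture_description"): "secondary",
    ("avqi", "passage"): "secondary",
    ("ddk_rate_syl_s", "ddk"): "secondary",
    ("cv_f0", "picture_description"): "secondary",
    ("cv_f0", "conversation"): "secondary",
    ("cv_f0", "standardized_sentences"): "secondary",
    ("cv_f0", "personalized_sentences"): "secondary",
    ("cv_intensity", "picture_description"): "secondary",
    ("cv_intensity", "conversation"): "secondary",
    ("cv_intensity", "standardized_sentences"): "secondary",
    ("cv_intensity", "personalized_sentences"): "secondary",
    ("speaking_rate_syl_s", "passage"): "secondary",
    ("articulatory_groups_syl", "passage"): "secondary",
    ("mean_speech_duration_s", "passage"): "secondary",
    ("percent_pause", "passage"): "secondary",
}


@dataclass
class MeasureRegistry:
    """Registry of (measure, task) outcome pairs with their outcome class."""

    entries: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_REGISTRY))

    def outcome_class(self, measure: str, task: str) -> str:
        key = (measure, task)
        if key not in self.entries:
            raise KeyError(f"unknown measure/task pair {key}")
        return self.entries[key]

    def pairs(self):
        return list(self.entries)


@dataclass
class StudyResult:
    measures: pd.DataFrame      # one row per (participant, task, measure, phase, visit, trial)
    outcomes: pd.DataFrame      # one row per registry pair x comparison x participant
    qc: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def _measure_rows(entry: RecordingEntry, values: dict[str, float]) -> list[dict]:
    return [{
        "participant": entry.participant_id,
        "task": entry.task_label,
        "measure": m,
        "phase": entry.phase,
        "visit": entry.visit_index,
        "trial": entry.trial_index,
        "value": v,
    } for m, v in values.items() if v is not None]


def _analyze_recording(entry: RecordingEntry, base: Path,
                       config: dict) -> tuple[list[dict], list[dict], list[dict]]:
    """Measures, QC notes and skip notes for one manifest entry."""
    rows: list[dict] = []
    qc: list[dict] = []
    skipped: list[dict] = []
    offset = float(config.get("calibration_offset_db", 0.0))

    def skip(reason: str):
        skipped.append({"participant": entry.participant_id,
                        "task": entry.task_label, "phase": entry.phase,
                        "visit": entry.visit_index, "trial": entry.trial_index,
                        "reason": reason})

    if entry.task_label == "ddk":
        if entry.syllable_count is None:
            skip("missing_syllable_count")
            return rows, qc, skipped
        # per-trial rate; best-of-trials aggregation happens per visit later
        rows.append(_measure_rows(entry, {
            "ddk_trial_rate_syl_s": entry.syllable_count / 5.0})[0])
        return rows, qc, skipped

    if entry.audio_path is None:
        skip("missing_audio")
        return rows, qc, skipped
    clip = read_wav(base / entry.audio_path, task_label=entry.task_label,
                    session_id=entry.session_id)
    tiers = {}
    if entry.annotation_path is not None:
        tiers = {t.name: t for t in read_textgrid(base / entry.annotation_path)}

    pitch = cs.track_pitch(clip)
    inten = cs.intensity_contour(clip, calibration_offset_db=offset)
    vals: dict[str, float] = {}

    try:
        if entry.task_label == "sustained":
            periods = cs.extract_periods(clip, pitch)
            vals["mean_intensity_db"] = pt.sustained_mean_intensity(
                clip, periods, inten)
            battery = vq.voice_quality_battery(clip, pitch)
            vals["jitter_pct"] = battery.jitter_local_pct
            vals["shimmer_pct"] = battery.shimmer_local_pct
            vals["shimmer_db"] = battery.shimmer_local_db
            vals["hnr_db"] = battery.hnr_db
            vals["cpps_db"] = battery.cpps_db

        elif entry.task_label in ("glide_up", "glide_down"):
            direction = "up" if entry.task_label == "glide_up" else "down"
            flags = cs.flag_artifacts(pitch)
            g = pt.analyze_glide(pitch, flags, direction)
            vals["f0_extreme_st"] = g.extreme_f0_st
            vals["f0_range_st"] = g.range_st
            if g.reversal_detected:
                qc.append({"participant": entry.participant_id,
                           "task": entry.task_label, "phase": entry.phase,
                           "visit": entry.visit_index,
                           "trial": entry.trial_index,
                           "note": "glide_reversal"})

        elif entry.task_label in ("personalized_sentences",
                                  "standardized_sentences"):
            if "vowels" not in tiers:
                skip("missing_annotation")
            else:
                vals["mean_intensity_db"] = pt.sentence_vowel_loudness(
                    inten, tiers["vowels"]).mean_db
            seg = pr.segment_speech(inten, pitch)
            var = pr.prosodic_variability(pitch, inten, seg)
            vals["cv_f0"] = var.cv_f0
            vals["cv_intensity"] = var.cv_intensity

        elif entry.task_label in ("picture_description", "conversation"):
            if "verb_final" not in tiers:
                skip("missing_annotation")
            else:
                vals["mean_intensity_db"] = pt.verb_final_loudness(
                    inten, tiers["verb_final"]).mean_db
            seg = pr.segment_speech(inten, pitch)
            var = pr.prosodic_variability(pitch, inten, seg)
            vals["cv_f0"] = var.cv_f0
            vals["cv_intensity"] = var.cv_intensity

        elif entry.task_label == "passage":
            seg = pr.segment_speech(inten, pitch)
            if entry.syllable_count is not None:
                tm = pr.timing_measures(seg, entry.syllable_count,
                                        list(entry.group_syllables or []) or None)
                vals["speaking_rate_syl_s"] = tm.speaking_rate_syl_per_s
                vals["percent_pause"] = tm.percent_pause
                vals["mean_speech_duration_s"] = tm.mean_speech_duration_s
                if tm.mean_articulatory_group_syllables is not None:
                    vals["articulatory_groups_syl"] = \
                        tm.mean_articulatory_group_syllables
            else:
                skip("missing_syllable_count")
            var = pr.prosodic_variability(pitch, inten, seg)
            vals["cv_f0"] = var.cv_f0
            vals["cv_intensity"] = var.cv_intensity
    except MeasureUndefined as exc:
        skip(exc.reason)

    rows.extend(_measure_rows(entry, vals))
    return rows, qc, skipped


def _avqi_rows(manifest: StudyManifest, measures: list[dict],
               config: dict) -> tuple[list[dict], list[dict]]:
    """AVQI needs the sustained vowel and passage of the same visit."""
    rows: list[dict] = []
    skipped: list[dict] = []
    base = manifest.base_dir
    by_slot: dict[tuple, RecordingEntry] = {}
    for e in manifest.entries:
        by_slot.setdefault(
            (e.participant_id, e.task_label, e.phase, e.visit_index), e)
    for (part, task, phase, visit), passage in sorted(by_slot.items()):
        if task != "passage":
            continue
        vowel = by_slot.get((part, "sustained", phase, visit))
        if vowel is None or vowel.audio_path is None or passage.audio_path is None:
            skipped.append({"participant": part, "task": "passage",
                            "phase": phase, "visit": visit, "trial": 1,
                            "reason": "avqi_missing_pair"})
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score = vq.avqi(read_wav(base / vowel.audio_path),
                                read_wav(base / passage.audio_path)).score
            rows.append({"participant": part, "task": "passage",
                         "measure": "avqi", "phase": phase, "visit": visit,
                         "trial": 1, "value": score})
        except MeasureUndefined as exc:
            skipped.append({"participant": part, "task": "passage",
                            "phase": phase, "visit": visit, "trial": 1,
                            "reason": f"avqi_{exc.reason}"})
    return rows, skipped


def _phase_series(df: pd.DataFrame, participant: str, measure: str, task: str,
                  phase: str, pool_trials: bool
                  ) -> tuple[PhaseSeries | None, int]:
    sub = df[(df.participant == participant) & (df.measure == measure)
             & (df.task == task) & (df.phase == phase)]
    if sub.empty:
        return None, 0
    sub = sub.sort_values(["visit", "trial"])
    if pool_trials:
        values = list(sub.value)
    else:
        values = list(sub.groupby("visit").value.mean())
    return (PhaseSeries(participant, measure, task, phase, values),
            int(sub.visit.nunique()))


def run_study(manifest: StudyManifest, config: dict | None = None) -> StudyResult:
    """Analyze every recording and run all phase comparisons.

    Config keys: ``alpha`` (default 0.05), ``pool_trials`` (default True,
    per the protocol's use of all individual trial values),
    ``correct_baseline`` (default False), ``bh`` (Benjamini-Hochberg
    adjustment, default False), ``calibration_offset_db`` (default 0),
    ``registry`` (a :class:`MeasureRegistry`).
    """
    if not manifest.entries:
        raise ValueError("empty manifest: no recordings to analyze")
    config = dict(config or {})
    alpha = float(config.get("alpha", 0.05))
    pool_trials = bool(config.get("pool_trials", True))
    correct = bool(config.get("correct_baseline", False))
    registry: MeasureRegistry = config.get("registry") or MeasureRegistry()

    rows: list[dict] = []
    qc: list[dict] = []
    skipped: list[dict] = []
    for entry in manifest.entries:
        r, q, s = _analyze_recording(entry, manifest.base_dir, config)
        rows += r
        qc += q
        skipped += s
    av_rows, av_skip = _avqi_rows(manifest, rows, config)
    rows += av_rows
    skipped += av_skip
    measures = pd.DataFrame(rows, columns=["participant", "task", "measure",
                                           "phase", "visit", "trial", "value"])

    # DDK: best of up to three trials becomes the visit value
    if not measures.empty and (measures.measure == "ddk_trial_rate_syl_s").any():
        ddk = measures[measures.measure == "ddk_trial_rate_syl_s"]
        best = (ddk.groupby(["participant", "task", "phase", "visit"])
                .value.max().reset_index())
        best["measure"] = "ddk_rate_syl_s"
        best["trial"] = 1
        measures = pd.concat([measures, best], ignore_index=True)

    out_rows: list[dict] = []
    for part in manifest.participants:
        for measure, task in registry.pairs():
            oclass = registry.outcome_class(measure, task)
            a, _ = _phase_series(measures, part, measure, task, "Pre",
                                 pool_trials)
            for comp in COMPARISONS:
                row = {"participant": part, "outcome_class": oclass,
                       "measure": measure, "task": task, "comparison": comp,
                       "tau": np.nan, "p_exact": np.nan, "p_normal": np.nan,
                       "p": np.nan, "flag": False, "n_a": 0, "n_b": 0,
                       "notes": ""}
                b, b_visits = _phase_series(measures, part, measure, task,
                                            comp, pool_trials)
                if a is None or len(a) < 2:
                    row["notes"] = "not_computed: insufficient_baseline"
                elif b is None:
                    row["notes"] = "not_computed: missing_phase"
                else:
                    res = tau_u(a, b, correct_baseline=correct,
                                seed=config.get("seed"))
                    row.update(tau=res.tau, p_exact=res.p_exact,
                               p_normal=res.p_two_sided, p=res.p,
                               flag=significance_flag(res, alpha),
                               n_a=res.n_a, n_b=res.n_b)
                    if b_visits < 3:
                        row["notes"] = "missing_data: fewer_than_3_visits"
                out_rows.append(row)
    outcomes = pd.DataFrame(out_rows)

    if config.get("bh") and not outcomes.empty:
        computed = outcomes.p.notna()
        if computed.any():
            adj = bh_adjust(outcomes.loc[computed, "p"].to_numpy())
            outcomes.loc[computed, "p_adjusted"] = adj
            outcomes.loc[computed, "flag"] = adj <= alpha

    # drop registry rows for tasks the study never recorded (keeps the
    # table aligned with the manifest rather than padded with blanks)
    present = {(e.participant_id, e.task_label) for e in manifest.entries}
    keep = outcomes.apply(
        lambda r: (r.participant, r.task) in present, axis=1)
    outcomes = outcomes[keep].reset_index(drop=True)

    return StudyResult(measures=measures, outcomes=outcomes, qc=qc,
                       skipped=skipped,
                       config={"alpha": alpha, "pool_trials": pool_trials,
                               "correct_baseline": correct,
                               "bh": bool(config.get("bh", False))})


def render_report(result: StudyResult, out_dir: str | Path,
                  plots: bool = False) -> list[Path]:
    """Write the outcome table (CSV), per-participant checkmark matrices
    (Markdown), QC/skip notes (JSON) and optional trajectory plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "outcomes.csv"
    result.outcomes.sort_values(
        ["participant", "outcome_class", "measure", "task", "comparison"]
    ).to_csv(csv_path, index=False, float_format="%.6g")
    written.append(csv_path)

    mpath = out / "measures.csv"
    result.measures.to_csv(mpath, index=False, float_format="%.6g")
    written.append(mpath)

    for part, sub in result.outcomes.groupby("participant"):
        lines = [f"# Outcomes: {part}", "",
                 "| Measure | Task | " + " | ".join(COMPARISONS) + " |",
                 "|---|---|" + "---|" * len(COMPARISONS)]
        for (measure, task), grp in sub.groupby(["measure", "task"]):
            cells = []
            for comp in COMPARISONS:
                row = grp[grp.comparison == comp]
                if row.empty or row.iloc[0].notes.startswith("not_computed"):
                    cells.append("n.a.")
                else:
                    cells.append("x" if bool(row.iloc[0].flag) else "")
            lines.append(f"| {measure} | {task} | " + " | ".join(cells) + " |")
        lines += ["", "An 'x' marks a significant change versus baseline; "
                  "'n.a.' marks a comparison that could not be computed."]
        p = out / f"outcomes_{part}.md"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    notes = {"qc": result.qc, "skipped": result.skipped,
             "config": result.config}
    jp = out / "qc_report.json"
    jp.write_text(json.dumps(notes, indent=2))
    written.append(jp)

    if plots and not result.measures.empty:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        phase_order = {p: i for i, p in enumerate(PHASES)}
        for (part, measure, task), sub in result.measures.groupby(
                ["participant", "measure", "task"]):
            sub = sub.assign(order=sub.phase.map(phase_order))
            sub = sub.sort_values(["order", "visit", "trial"])
            xs = np.arange(len(sub))
            fig, ax = plt.subplots(figsize=(6, 3))
            ax.plot(xs, sub.value, "o-", ms=4)
            edges = np.flatnonzero(np.diff(sub.order.to_numpy())) + 0.5
            for e in edges:
                ax.axvline(e, color="grey", ls="--", lw=0.7)
            ax.set_title(f"{part}: {measure} ({task})")
            ax.set_xlabel("session (phase-ordered)")
            ax.set_ylabel(measure)
            fig.tight_layout()
            p = out / f"trajectory_{part}_{measure}_{task}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written.append(p)
    return written
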