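"""End-to-end orchestration: simulate (or load) → preprocess → ERP/ERSP →
classify → decide, plus the cohort-level operating characteristics.

The cohort configuration used for subject-level evaluation is a scaled
instance of the paradigm — one block each of the active and breathing
modes with 80/40/20/20 stimuli at 250 Hz — chosen so a full cohort of
subjects runs on a desktop in minutes while preserving every qualitative
property of the full protocol (which remains the generator default).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io
from .classify import build_features, trial_averaged_curve
from .containers import EpochSet, Recording
from .decide import ContrastMetrics, DecisionMetrics, DecisionReport, detect
from .erp import component_amplitudes
from .ersp import band_summaries
from .paradigm import ParadigmConfig, generate_event_sequence
from .preprocess import PreprocessConfig, preprocess_recording
from .simulate import (SubjectProfile, conscious_profile, synthesize_recording,
                       unconscious_profile)

log = logging.getLogger("conscidet")

M1_CONTRASTS = (
    ("deviant_vs_standard", dict(contrast="stimulus", positive="deviant",
                                 negative="standard", mode="active")),
    ("correct_vs_incorrect_novel", dict(contrast="stimulus",
                                        positive="correct_novel",
                                        negative="incorrect_novel",
                                        mode="active")),
)
M2_STIMULI = ("deviant", "correct_novel", "incorrect_novel")


def cohort_config(modality: str = "visual") -> ParadigmConfig:
    """Scaled paradigm used for cohort evaluation (see module docstring)."""
    return ParadigmConfig(modality=modality, modes=("active", "breathing"),
                          blocks_per_mode=1, n_standard=80, n_deviant=40,
                          n_correct_novel=20, n_incorrect_novel=20,
                          sampling_rate_hz=250.0)


def simulate_subject(config: ParadigmConfig, profile: SubjectProfile,
                     seed: int) -> Recording:
    seq = generate_event_sequence(config, seed)
    return synthesize_recording(seq, profile, seed + 1)


def _contrast_metrics(ep: EpochSet, spec: dict, n_repeats: int, seed: int
                      ) -> ContrastMetrics | None:
    try:
        fs = build_features(ep, **spec)
    except ValueError as err:
        log.warning("contrast skipped: %s", err)
        return None
    curve = trial_averaged_curve(fs, n_repeats=n_repeats, seed=seed)
    level1 = next(r for r in curve if r.n_avg == 1)
    top = max(curve, key=lambda r: r.n_avg)

    def _bacc_per_repeat(r):
        s = np.asarray(r.per_repeat["sensitivity"])
        p = np.asarray(r.per_repeat["specificity"])
        return 0.5 * (s + p)

    gain_se = None
    if top.n_avg > 1:
        a1, a5 = _bacc_per_repeat(level1), _bacc_per_repeat(top)
        n = min(len(a1), len(a5))
        if n > 1:
            gain_se = float((a5[:n] - a1[:n]).std(ddof=1) / np.sqrt(n))
    return ContrastMetrics(
        acc_by_navg={r.n_avg: r.accuracy for r in curve},
        n_test_by_navg={r.n_avg: r.n_test for r in curve},
        se_navg1=level1.accuracy_se, gain_se=gain_se,
        bacc_by_navg={r.n_avg: float(_bacc_per_repeat(r).mean())
                      for r in curve})


def subject_metrics(ep: EpochSet, seed: int = 0, n_repeats: int = 10,
                    breathing_mode: str = "breathing") -> DecisionMetrics:
    """Compute the three decision-metric families from clean epochs."""
    m1, m2 = {}, {}
    for i, (name, spec) in enumerate(M1_CONTRASTS):
        cm = _contrast_metrics(ep, spec, n_repeats, seed + 101 * (i + 1))
        if cm is not None:
            m1[name] = cm
    for i, stim in enumerate(M2_STIMULI):
        spec = dict(contrast="mode", positive="active", negative=breathing_mode,
                    stimulus_type=stim)
        cm = _contrast_metrics(ep, spec, n_repeats, seed + 211 * (i + 1))
        if cm is not None:
            m2[f"active_vs_{breathing_mode}_{stim}"] = cm
    return DecisionMetrics(m1=m1, m2=m2,
                           provenance={"n_repeats": n_repeats, "seed": seed,
                                       "n_trials": int(ep.n_trials)})


def evaluate_subject(config: ParadigmConfig, profile: SubjectProfile,
                     seed: int, n_repeats: int = 10, alpha: float = 0.05
                     ) -> DecisionReport:
    """Simulate one subject, preprocess, and run the decision procedure."""
    rec = simulate_subject(config, profile, seed)
    ep = preprocess_recording(rec)
    metrics = subject_metrics(ep, seed=seed, n_repeats=n_repeats)
    report = detect(metrics, alpha=alpha)
    report.provenance.update({"label": profile.label,
                              "modality": profile.modality, "seed": seed})
    return report


def cohort_verdicts(n_subjects: int, profile_factory, seed: int,
                    config: ParadigmConfig | None = None,
                    n_repeats: int = 10, alpha: float = 0.05) -> list[str]:
    """Verdicts for a cohort of independently simulated subjects."""
    config = config or cohort_config()
    verdicts = []
    for i in range(n_subjects):
        t0 = time.time()
        report = evaluate_subject(config, profile_factory(), seed + 1000 * i,
                                  n_repeats=n_repeats, alpha=alpha)
        log.info("subject %d/%d: %s (%.1fs)", i + 1, n_subjects,
                 report.verdict, time.time() - t0)
        verdicts.append(report.verdict)
    return verdicts


def run_pipeline(out_dir, profile: SubjectProfile | None = None,
                 config: ParadigmConfig | None = None, seed: int = 0,
                 n_repeats: int = 10, alpha: float = 0.05,
                 preprocess_cfg: PreprocessConfig | None = None
                 ) -> DecisionReport:
    """Full single-subject run with all intermediates persisted."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = profile or conscious_profile()
    config = config or cohort_config(profile.modality)
    preprocess_cfg = preprocess_cfg or PreprocessConfig()

    log.info("simulate: %d blocks, %d events/block, %.0f Hz", config.n_blocks,
             config.events_per_block, config.sampling_rate_hz)
    rec = simulate_subject(config, profile, seed)
    io.write_edf(out / "recording.edf", rec)
    io.write_events_tsv(out / "events.tsv", rec.events)

    ep = preprocess_recording(rec, preprocess_cfg)
    log.info("preprocess: %d/%d trials retained", ep.n_trials, len(rec.events))
    io.save_epochs(out, ep)

    table = component_amplitudes(ep, subject_id=f"seed{seed}")
    table.to_csv(out / "erp_components.tsv", sep="\t", index=False)
    ersp = band_summaries(ep, channel="FZ", by=("mode", "stimulus_type"))
    ersp.to_csv(out / "ersp_band_power.tsv", sep="\t", index=False)

    metrics = subject_metrics(ep, seed=seed, n_repeats=n_repeats)
    report = detect(metrics, alpha=alpha)
    report.provenance.update({"label": profile.label,
                              "modality": profile.modality, "seed": seed,
                              "config": asdict(config)})
    (out / "report.json").write_text(json.dumps(
        {"verdict": report.verdict, "alpha": report.alpha,
         "checks": _jsonable(report.checks), "notes": report.notes,
         "provenance": _jsonable(report.provenance)}, indent=1))
    log.info("verdict: %s", report.verdict)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


PROFILE_FACTORIES = {"conscious": conscious_profile,
                     "unconscious": unconscious_profile}
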