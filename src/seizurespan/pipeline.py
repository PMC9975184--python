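"""End-to-end pipeline: simulate -> metrics -> spread -> state-space -> report.

One call produces a run directory with a fixed schema (``metrics/``,
``spread/``, ``ssm/``, ``report/``), every stage's resolved configuration,
and bit-reproducible outputs for a given (config, seed).  Raw simulated ECoG
is processed in memory per session and not written (a full-cohort text dump
would be enormous); use ``seizurespan simulate`` to export bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import convulsions as conv
from . import ecog, spread, statespace, synth
from .session import SEIZURE_CATEGORIES

log = logging.getLogger("seizurespan")

_FLOAT_FMT = "%.17e"


def build_sim_config(overrides: dict | None, master_seed: int) -> synth.SimulationConfig:
    """SimulationConfig from a (possibly partial) mapping of overrides."""
    overrides = dict(overrides or {})
    kwargs: dict = {"master_seed": int(master_seed)}
    simple = {
        "n_rows", "n_cols", "pitch_mm", "focus_channel", "hemisphere",
        "sample_rate_hz", "noise_rms_uV", "bicuculline_min", "treatment_min",
        "subject_effect",
    }
    for key, val in overrides.items():
        if key in simple:
            kwargs[key] = val
        elif key == "na_channels":
            kwargs[key] = tuple(int(c) for c in val)
        elif key == "subjects":
            kwargs[key] = tuple(val)
        elif key == "sessions":
            kwargs[key] = tuple((s, t) for s, t in val)
        elif key == "schedule":
            kwargs[key] = synth.PhaseSchedule(tuple((p, a, b) for p, a, b in val))
        elif key == "treatment":
            kwargs[key] = synth.TreatmentEffect(**val)
        elif key == "event_rates_per_min":
            kwargs[key] = {p: dict(r) for p, r in val.items()}
        elif key == "phase_params":
            merged = dict(synth.DEFAULT_PHASE_PARAMS)
            for phase, pp in val.items():
                base = dataclasses.asdict(merged[phase])
                base.update(pp)
                if base.get("spatial_sigma_pitch") in ("inf", None):
                    base["spatial_sigma_pitch"] = math.inf
                base["spikes_per_complex"] = tuple(base["spikes_per_complex"])
                merged[phase] = synth.PhaseParams(**base)
            kwargs[key] = merged
        else:
            raise ValueError(f"unknown simulation config key {key!r}")
    return synth.SimulationConfig(**kwargs)


def _write_series_tsv(path: Path, series: ecog.NormalizedSeries,
                      report: ecog.DeviationReport, meta: dict) -> None:
    df = pd.DataFrame(
        {
            "bin_start_min": series.bin_start_min,
            "raw": series.raw.values,
            "normalized": series.values,
            "below_p95": report.below_p95.astype(int),
            "above_p95": report.above_p95.astype(int),
        }
    )
    with path.open("w") as fh:
        fh.write(f"# {json.dumps(meta, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: dict | None, seed: int, out_dir: str | Path) -> dict:
    """Run the full analysis on a simulated cohort; returns the report dict.

    ``config`` keys (all optional): ``simulation`` (SimulationConfig
    overrides), ``baseline_window_min``, ``bin_range_min``,
    ``convulsion_categories``, ``ssm`` (chains/draws/warmup),
    ``spread_fraction``.
    """
    t_start = time.time()
    config = dict(config or {})
    out = Path(out_dir)
    for sub in ("metrics", "spread", "ssm", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    sim_cfg = build_sim_config(config.get("simulation"), master_seed=seed)
    baseline_window = tuple(config.get("baseline_window_min", (-15.0, 0.0)))
    bin_range = tuple(config.get("bin_range_min", (-15, 15)))
    categories = tuple(config.get("convulsion_categories", SEIZURE_CATEGORIES))
    ssm_cfg = dict(config.get("ssm", {}))
    fraction = float(config.get("spread_fraction", 0.5))

    resolved = {
        "simulation": synth._to_jsonable(sim_cfg),
        "baseline_window_min": list(baseline_window),
        "bin_range_min": list(bin_range),
        "convulsion_categories": list(categories),
        "ssm": ssm_cfg,
        "spread_fraction": fraction,
        "seed": int(seed),
        "config_hash": sim_cfg.config_hash(),
    }
    (out / "report" / "resolved_config.json").write_text(
        json.dumps(resolved, indent=2, sort_keys=True) + "\n"
    )

    amp_sessions: list[tuple[ecog.NormalizedSeries, str, str, str]] = []
    rate_sessions: list[tuple[ecog.NormalizedSeries, str, str, str]] = []
    onsets: dict[str, float | None] = {}
    spread_rows = []

    for i, (subject, treatment) in enumerate(sim_cfg.sessions):
        sid = f"{subject}_{treatment}_{i:02d}"
        stage_t0 = time.time()
        ss = synth.session_seed(sim_cfg.master_seed, sim_cfg.subjects.index(subject), i)
        bundle = synth.simulate_session(sim_cfg, subject, treatment, ss, session_id=sid)
        try:
            rec = ecog.apply_standard_filters(bundle.recording)
            series = ecog.rms_binned(rec, bundle.timeline, bin_range_min=bin_range)
            nser = ecog.normalize_to_pretreatment(series, baseline_window)
            dev = ecog.detect_significant_deviation(nser)
            onsets[sid] = dev.suppression_onset_min
            _write_series_tsv(
                out / "metrics" / f"{sid}_amplitude.tsv", nser, dev,
                {"session": sid, "kind": "rms", "config_hash": resolved["config_hash"]},
            )
            amp_sessions.append((nser, subject, treatment, sid))

            counts = conv.bin_event_rate(
                bundle.events, bundle.timeline, categories=categories,
                bin_range_min=bin_range,
            )
            rser = conv.normalize_rate(counts, baseline_window)
            rdev = ecog.detect_significant_deviation(rser)
            _write_series_tsv(
                out / "metrics" / f"{sid}_convulsions.tsv", rser, rdev,
                {"session": sid, "kind": "event_rate",
                 "config_hash": resolved["config_hash"]},
            )
            rate_sessions.append((rser, subject, treatment, sid))

            # spread maps at epileptiform phase midpoints + a post-treatment window
            windows = []
            for phase, a, b in sim_cfg.schedule.intervals:
                if sim_cfg.phase_params[phase].amplitude_uV > 0:
                    mid = (a + b) / 2.0 * 60.0
                    windows.append((phase, (mid - 15.0, mid + 15.0)))
            t_post = min(sim_cfg.treatment_min + 5.0, sim_cfg.schedule.end_min - 0.5) * 60.0
            windows.append(("post_treatment", (t_post, t_post + 30.0)))
            for phase, win in windows:
                amap = spread.amplitude_map(bundle.recording, win)
                smap = spread.threshold_map(amap, fraction)
                spread_rows.append(
                    {
                        "session": sid, "window_label": phase,
                        "window_start_s": win[0], "window_end_s": win[1],
                        "n_members": smap.n_members,
                        "coverage_percent": smap.coverage_percent_rounded,
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'metrics/spread' failed for session {sid}") from exc
        log.info("session %s processed in %.1f s", sid, time.time() - stage_t0)

    pd.DataFrame(spread_rows).to_csv(
        out / "spread" / "coverage.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    report: dict = {"config_hash": resolved["config_hash"], "seed": int(seed),
                    "suppression_onset_min": onsets}
    for label, sessions in (("amplitude", amp_sessions), ("convulsions", rate_sessions)):
        stage_t0 = time.time()
        try:
            design = statespace.assemble_design(sessions, bin_range_min=bin_range)
            post = statespace.fit_posterior(
                design,
                chains=int(ssm_cfg.get("chains", 4)),
                draws=int(ssm_cfg.get("draws", 1000)),
                warmup=int(ssm_cfg.get("warmup", 500)),
                seed=int(seed),
            )
            summaries = statespace.summarize_effect(post)
            sep = statespace.decide_separation(summaries["DCZ_post"],
                                               summaries["vehicle_post"])
            report[label] = {
                "summaries": {
                    k: {"map": s.map_value, "ci99": list(s.interval),
                        "posterior_mean": s.posterior_mean}
                    for k, s in summaries.items()
                },
                "post_interval_separated": bool(sep.separated),
                "gap": sep.gap,
                "rhat": post.rhat,
                "observed_post_window_means": {
                    sid: float(m) for sid, m in zip(
                        design.session_ids,
                        statespace.observed_window_means(design, statespace.POST_WINDOW_MIN),
                    )
                },
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'state-space/{label}' failed") from exc
        log.info("state-space fit (%s) in %.1f s", label, time.time() - stage_t0)

    (out / "ssm" / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    _write_report_md(out / "report" / "report.md", report)
    report["elapsed_s"] = time.time() - t_start
    return report


def _write_report_md(path: Path, report: dict) -> None:
    lines = [
        "# Seizure-attenuation analysis report",
        "",
        f"Config hash: `{report['config_hash']}`  |  seed: {report['seed']}",
        "",
    ]
    for label in ("amplitude", "convulsions"):
        r = report[label]
        lines.append(f"## {label.capitalize()}")
        lines.append("")
        lines.append("| group/window | MAP | 99% CI |")
        lines.append("|---|---|---|")
        for key in ("DCZ_pre", "DCZ_post", "vehicle_pre", "vehicle_post"):
            s = r["summaries"][key]
            lines.append(
                f"| {key} | {s['map']:.3f} | [{s['ci99'][0]:.3f}, {s['ci99'][1]:.3f}] |"
            )
        verdict = "separated" if r["post_interval_separated"] else "overlapping"
        lines.append("")
        lines.append(
            f"Post-treatment 99% credible intervals (DCZ vs vehicle): **{verdict}** "
            f"(gap {r['gap']:.3f})."
        )
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
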