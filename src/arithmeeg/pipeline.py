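"""End-to-end orchestration: simulate (or load) -> preprocess -> ERD/ERS ->
behavioral summaries -> mixed-effects inference, as one reproducible run.

A run is driven by a :class:`RunConfig` (serializable to YAML), processes
participants one at a time (continuous recordings are large), and writes
tidy CSV/JSON outputs plus a machine-readable manifest with trial counts at
every stage.  Given the same config and seed, outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import consistency_filter, cohen_kappa, summarize_accuracy, summarize_rt
from .erders import (
    BANDS,
    DEFAULT_ROI_MAP,
    WindowSpec,
    TrialWindow,
    compute_participant_erders,
)
from .io import read_edf, read_events_tsv, write_edf, write_events_tsv
from .preproc import PreprocConfig, preprocess
from .stats import fit_accuracy_model, fit_erders_model, fit_rt_model, pairwise_posthoc
from .stimuli import load_problem_set
from .synthdata import (
    Recording,
    SimulationConfig,
    TrialEvent,
    simulate_participant,
    size_expected_strategy,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("arithmeeg")


class PipelineError(RuntimeError):
    """A stage failed; message carries stage and participant context."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is "simulate" (generate the dataset) or "from-files" (read EDF
    recordings + events TSVs from ``input_dir``, expecting per-participant
    pairs ``<id>_eeg.edf`` / ``<id>_events.tsv``).
    """

    mode: str = "simulate"
    input_dir: str | None = None
    output_dir: str = "arithmeeg-run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    roi_map: Mapping[tuple[str, str], Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_MAP)
    )
    window: WindowSpec = field(default_factory=WindowSpec)
    posthoc_band: str = "theta"
    posthoc_factors: tuple[str, ...] = ("strategy", "roi", "hemisphere")

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "from-files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "from-files" and not self.input_dir:
            raise ValueError("from-files mode requires input_dir")
        self.simulation.seed = self.seed

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"]["band_effects"] = [
            dataclasses.asdict(s) for s in self.simulation.band_effects
        ]
        d["simulation"]["rt_params"] = {
            f"{k[0]}/{k[1]}": list(v) for k, v in self.simulation.rt_params.items()
        }
        d["simulation"]["acc_probs"] = {
            f"{k[0]}/{k[1]}": v for k, v in self.simulation.acc_probs.items()
        }
        d["roi_map"] = {f"{roi}/{hemi}": list(chs) for (roi, hemi), chs in self.roi_map.items()}
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        from .synthdata import EffectSpec

        d = yaml.safe_load(text)
        sim = d.pop("simulation", {})
        if "band_effects" in sim:
            sim["band_effects"] = tuple(EffectSpec(**s) for s in sim["band_effects"])
        if "montage" in sim:
            sim["montage"] = tuple(sim["montage"])
        if "rt_params" in sim:
            sim["rt_params"] = {
                tuple(k.split("/")): tuple(v) for k, v in sim["rt_params"].items()
            }
        if "acc_probs" in sim:
            sim["acc_probs"] = {
                tuple(k.split("/")): v for k, v in sim["acc_probs"].items()
            }
        pre = d.pop("preproc", {})
        if "frontal_channels" in pre:
            pre["frontal_channels"] = tuple(pre["frontal_channels"])
        roi_map = {
            tuple(k.split("/")): tuple(v)
            for k, v in d.pop("roi_map", {}).items()
        } or dict(DEFAULT_ROI_MAP)
        window = WindowSpec(**d.pop("window", {}))
        d.pop("posthoc_factors", None)
        return cls(
            simulation=SimulationConfig(**sim),
            preproc=PreprocConfig(**pre),
            roi_map=roi_map,
            window=window,
            **d,
        )


def _iter_participants(config: RunConfig, problems):
    if config.mode == "simulate":
        for i in range(config.simulation.n_participants):
            part = simulate_participant(config.simulation, problems, i)
            yield part.participant, part.recording, part.events
    else:
        input_dir = Path(config.input_dir)
        edfs = sorted(input_dir.glob("*_eeg.edf"))
        if not edfs:
            raise PipelineError(f"no *_eeg.edf recordings found in {input_dir}")
        for edf in edfs:
            pid = edf.name[: -len("_eeg.edf")]
            events_path = input_dir / f"{pid}_events.tsv"
            if not events_path.exists():
                raise PipelineError(f"missing events table for {pid}: {events_path}")
            yield pid, read_edf(edf), read_events_tsv(events_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Outputs under ``config.output_dir``: cleaning reports (JSON), the
    consistency table, behavioral summaries, the tidy ERD/ERS table, effect
    tables per band, post-hoc contrast and marginal-means tables, the run
    log, the resolved config, and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    config_yaml = config.to_yaml()
    (out / "config.yaml").write_text(config_yaml)
    config_hash = hashlib.sha256(config_yaml.encode()).hexdigest()[:16]
    logger.info(
        "arithmeeg %s | seed=%d | config sha256:%s", __version__, config.seed, config_hash
    )

    problems = load_problem_set()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash,
        "participants": {},
        "stages": {},
    }

    all_events: list[TrialEvent] = []
    erders_rows: list[dict] = []
    for pid, recording, events in _iter_participants(config, problems):
        stage = "preprocess"
        try:
            cleaned, report = preprocess(recording, config.preproc)
            (out / f"cleaning_{pid}.json").write_text(report.to_json())
            stage = "erders"
            retained, _, _ = consistency_filter(events)
            usable = [ev for ev in retained if ev.correct]
            twins = [
                TrialWindow(
                    trial=i,
                    onset=ev.onset,
                    rt=ev.rt,
                    strategy=size_expected_strategy(ev.problem.size),
                    operation=ev.problem.operation.value,
                )
                for i, ev in enumerate(usable)
            ]
            records = compute_participant_erders(
                cleaned.samples,
                cleaned.channels,
                cleaned.sfreq,
                twins,
                bad_channels=cleaned.bad_channels,
                artifact_intervals=cleaned.artifact_mask,
                bands=BANDS,
                roi_map=config.roi_map,
                window=config.window,
                participant=pid,
            )
        except Exception as err:
            raise PipelineError(
                f"stage {stage!r} failed for participant {pid}: {err}"
            ) from err
        erders_rows.extend(dataclasses.asdict(r) for r in records)
        all_events.extend(events)
        manifest["participants"][pid] = {
            "n_trials": len(events),
            "n_retained": len(retained),
            "n_correct_retained": len(usable),
            "n_bad_channels": len(report.bad_channels),
            "n_masked_intervals": len(report.masked_intervals),
            "n_removed_components": len(report.removed_components),
            "n_erders_records": len(records),
        }
        logger.info(
            "%s: %d trials, %d retained, %d usable, %d ERD/ERS records",
            pid, len(events), len(retained), len(usable), len(records),
        )

    # behavior
    retained, table, excluded = consistency_filter(all_events)
    assert len(retained) + len(excluded) == len(all_events)
    p_o, kappa = cohen_kappa(table.agreement_table())
    table.to_frame().to_csv(out / "consistency_table.csv")
    acc = summarize_accuracy(retained)
    acc.to_csv(out / "accuracy_summary.csv", index=False)
    correct_trials = [ev for ev in retained if ev.correct]
    rt = summarize_rt(correct_trials)
    rt.to_csv(out / "rt_summary.csv", index=False)
    manifest["stages"]["consistency_filter"] = {
        "trials_in": len(all_events),
        "trials_retained": len(retained),
        "trials_excluded": len(excluded),
        "n_unknown": table.n_unknown,
        "agreement": round(p_o, 4),
        "kappa": round(kappa, 4),
    }
    manifest["stages"]["correct_only"] = {
        "trials_in": len(retained),
        "trials_retained": len(correct_trials),
        "trials_excluded": len(retained) - len(correct_trials),
    }

    # ERD/ERS table
    erders_df = pd.DataFrame(erders_rows)
    erders_df.to_csv(out / "erders.csv", index=False)
    manifest["stages"]["erders"] = {"n_records": len(erders_df)}

    # inference
    trial_df = pd.DataFrame(
        {
            "participant": ev.participant,
            "strategy": size_expected_strategy(ev.problem.size),
            "operation": ev.problem.operation.value,
            "rt": ev.rt,
            "correct": ev.correct,
        }
        for ev in retained
    )
    rt_effects, rt_fit = fit_rt_model(trial_df[trial_df["correct"]])
    logger.info("RT model formula: %s", rt_fit.formula)
    acc_effects, acc_fit = fit_accuracy_model(trial_df)
    logger.info("accuracy model formula: %s", acc_fit.formula)
    effect_frames = [rt_effects, acc_effects]
    band_fits = {}
    for band in BANDS:
        band_df = erders_df[erders_df["band"] == band]
        effects, fit = fit_erders_model(band_df)
        logger.info("ERD/ERS model (%s) formula: %s", band, fit.formula)
        effect_frames.append(effects)
        band_fits[band] = fit
    effects_df = pd.concat(effect_frames, ignore_index=True)
    effects_df.to_csv(out / "effects.csv", index=False)

    contrasts, emmeans = pairwise_posthoc(
        band_fits[config.posthoc_band], list(config.posthoc_factors)
    )
    tag = f"{config.posthoc_band}_" + "_".join(config.posthoc_factors)
    contrasts.to_csv(out / f"contrasts_{tag}.csv", index=False)
    emmeans.to_csv(out / f"emmeans_{tag}.csv", index=False)
    rt_con, rt_emm = pairwise_posthoc(rt_fit, ["strategy", "operation"])
    rt_con.to_csv(out / "contrasts_rt_strategy_operation.csv", index=False)
    rt_emm.to_csv(out / "emmeans_rt_strategy_operation.csv", index=False)
    manifest["stages"]["posthoc"] = {
        "band": config.posthoc_band,
        "factors": list(config.posthoc_factors),
        "n_contrasts": len(contrasts),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return manifest


def export_simulation(config: RunConfig, out_dir: str | Path) -> list[str]:
    """Write the simulated dataset to disk (EDF + events TSV per participant)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    problems = load_problem_set()
    written = []
    for i in range(config.simulation.n_participants):
        part = simulate_participant(config.simulation, problems, i)
        write_edf(part.recording, out / f"{part.participant}_eeg.edf")
        write_events_tsv(part.events, out / f"{part.participant}_events.tsv")
        written.append(part.participant)
    return written
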