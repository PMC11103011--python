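"""End-to-end orchestration: simulate -> status -> cohort/match -> encode -> train -> explain -> report.

One global seed fans out to every stage through a ``numpy.random.SeedSequence``
so a rerun with the same configuration reproduces all deterministic artifacts;
the run directory carries a manifest recording the configuration hash, the
per-stage seeds, row counts and artifact checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ehrisk import report
from ehrisk.cohort import CohortDefinition, build_cohort, identify_cases, match_controls
from ehrisk.encoding import build_static_codec, build_vocabulary, encode_pairs
from ehrisk.explain import MutationSpec, impact_table, rank_interactions
from ehrisk.model import ModelConfig, SuicideRiskModel
from ehrisk.notes import StatusRuleSet, assign_statuses
from ehrisk.simulate import SimulationConfig, simulate_cohort, write_cohort

__all__ = ["RunConfig", "PipelineError", "run"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "status", "match", "encode", "train", "explain", "report"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    definition: CohortDefinition = field(default_factory=CohortDefinition)
    model: ModelConfig = field(default_factory=ModelConfig)
    #: YAML file of status rules; None uses the built-in default rule set
    rules_file: str | None = None
    #: feature codes subject to the drug-category prevalence floor
    drug_features: tuple[str, ...] = ("antidepressant_fill",)
    #: anchor feature for the interaction ranking ("var=Level" or temporal code)
    anchor: str = "lgbt_status=Yes"
    stages: tuple[str, ...] = tuple(STAGES)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _mutation_for(key: str) -> MutationSpec:
    if key == "age":
        return MutationSpec.age()
    if "=" in key:
        return MutationSpec.static(key)
    return MutationSpec.temporal(key)


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.rules_file is not None and not Path(config.rules_file).exists():
        raise FileNotFoundError(f"rules file not found: {config.rules_file}")
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config_hash": hashlib.sha256(repr(dataclasses.asdict(config)).encode()).hexdigest(),
        "seed": config.seed, "stage_seeds": seeds, "stages": {}, "artifacts": {},
    }
    state: dict = {}

    def record(stage: str, rows: dict, files: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {"rows": rows, "seconds": round(time.time() - t0, 3)}
        for f in files:
            manifest["artifacts"][f.name] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    for stage in config.stages:
        t0 = time.time()
        logger.info(json.dumps({"stage": stage, "status": "start"}))
        try:
            if stage == "simulate":
                sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
                patients, events, notes_df = simulate_cohort(sim)
                write_cohort(patients, events, notes_df, out / "cohort")
                state.update(patients=patients, events=events, notes=notes_df)
                record(stage, {"patients": len(patients), "events": len(events),
                               "notes": len(notes_df)},
                       [out / "cohort" / f for f in ("patients.csv", "events.csv", "notes.jsonl")], t0)

            elif stage == "status":
                rules = (StatusRuleSet.from_yaml(config.rules_file)
                         if config.rules_file else StatusRuleSet())
                status = assign_statuses(state["notes"], state["patients"]["id"], rules)
                status.to_csv(out / "status.csv", index=False)
                analysis = state["patients"].drop(columns=["lgbt_status"]).merge(
                    status.rename(columns={"patient_id": "id"}), on="id")
                state["analysis_patients"] = analysis
                record(stage, {"patients": len(status),
                               "yes": int((status["lgbt_status"] == "Yes").sum()),
                               "no": int((status["lgbt_status"] == "No").sum())},
                       [out / "status.csv"], t0)

            elif stage == "match":
                cohort = build_cohort(state["analysis_patients"], state["events"],
                                      config.definition)
                cases = identify_cases(cohort, config.definition)
                pairs, unmatched = match_controls(cohort, state["events"], cases,
                                                  config.definition, seed=seeds["match"])
                pairs_out = pairs.copy()
                for col in ("case_index_date", "control_index_date"):
                    pairs_out[col] = pd.to_datetime(pairs_out[col]).dt.strftime("%Y-%m-%d")
                pairs_out.to_csv(out / "pairs.csv", index=False)
                state.update(cohort=cohort, cases=cases, pairs=pairs, unmatched=unmatched)
                record(stage, {"cohort": len(cohort), "cases": len(cases),
                               "pairs": len(pairs), "unmatched": len(unmatched)},
                       [out / "pairs.csv"], t0)

            elif stage == "encode":
                cohort = state["cohort"]
                vocab = build_vocabulary(state["events"], cohort["id"],
                                         drug_features=set(config.drug_features))
                matched_ids = set(state["pairs"]["case_id"]) | set(state["pairs"]["control_id"])
                codec = build_static_codec(cohort[cohort["id"].isin(matched_ids)])
                dataset = encode_pairs(state["pairs"], cohort, state["events"], vocab, codec)
                vocab.to_csv(out / "vocabulary.csv")
                dataset.to_jsonl(out / "encoded.jsonl")
                state.update(vocab=vocab, codec=codec, dataset=dataset)
                record(stage, {"encoded": len(dataset), "vocabulary": len(vocab)},
                       [out / "vocabulary.csv", out / "encoded.jsonl"], t0)

            elif stage == "train":
                mcfg = dataclasses.replace(config.model, seed=seeds["train"])
                results = SuicideRiskModel(state["dataset"], mcfg).fit()
                results.save(out / "model")
                (out / "metrics.json").write_text(json.dumps({
                    "train_auc": results.report.train_auc,
                    "val_auc": results.report.val_auc,
                    "threshold": results.report.threshold,
                    "sensitivity": results.report.sensitivity,
                    "specificity": results.report.specificity,
                    "n_parameters": results.report.n_parameters,
                }, indent=2))
                state["results"] = results
                record(stage, {"train_epochs": len(results.report.epoch_loss)},
                       [out / "metrics.json"], t0)

            elif stage == "explain":
                dataset = state["dataset"]
                scorer = state["results"]
                muts = [MutationSpec.temporal(c) for c in dataset.vocabulary.code_to_id]
                muts += [MutationSpec.static(c) for c in dataset.codec.columns if c != "age"]
                muts.append(MutationSpec.age())
                impacts = impact_table(scorer, dataset, muts)
                impacts.to_csv(out / "impacts.csv", index=False)
                anchor = _mutation_for(config.anchor)
                cands = [m for m in muts if m.label != anchor.label]
                inter = rank_interactions(scorer, dataset, anchor, cands)
                inter.to_csv(out / "interactions.csv", index=False)
                record(stage, {"features": len(impacts), "interactions": len(inter)},
                       [out / "impacts.csv", out / "interactions.csv"], t0)

            elif stage == "report":
                mt = report.mortality_table(state["analysis_patients"],
                                            suicide_codes=config.definition.suicide_codes)
                ct = report.characteristics_table(state["pairs"], state["analysis_patients"])
                tables = out / "tables"
                tables.mkdir(exist_ok=True)
                mt.to_csv(tables / "mortality.csv", index=False)
                ct.to_csv(tables / "characteristics.csv", index=False)
                md = (report.render_markdown(mt, "Mortality by disclosed status")
                      + "\n" + report.render_markdown(ct, "Case/control characteristics"))
                (tables / "tables.md").write_text(md)
                record(stage, {"mortality_rows": len(mt), "characteristic_rows": len(ct)},
                       [tables / "mortality.csv", tables / "characteristics.csv"], t0)
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err
        logger.info(json.dumps({"stage": stage, "status": "done"}))
    return out
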