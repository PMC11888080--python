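"""End-to-end orchestration: simulate -> train -> calibrate -> score -> evaluate.

The pipeline mirrors a train/calibration/test design on three corpora drawn
from one code universe with different seeds (the analog of training on
earlier claim years and testing on a held-out year): associations are
trained on the training corpus; the operating threshold is selected on the
labeled discordant-laterality claims of the calibration corpus; the
rule-based flag and the association model are then compared on the test
corpus.  All stages derive their seeds from one pipeline seed, every output
is deterministic given the config, and a manifest with the config echo and
SHA-256 digests of all result files is written alongside the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from lateraleye import __version__
from lateraleye.aop_model import (
    ScoreMode,
    ThresholdRule,
    precision_recall_points,
    score_claims,
    select_threshold,
    train_associations,
)
from lateraleye.claims_model import ClaimSet
from lateraleye.laterality import DISCORDANT, assign_subgroup, filter_study_population
from lateraleye.review_eval import compare_methods, render_report, suppress_small_cells
from lateraleye.synthetic_data import GeneratorConfig, build_code_universe, simulate_claims

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: Path = Path("lateraleye_run")
    seed: int = 20170101
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_train: int = 100_000
    n_calibration: int = 40_000
    n_test: int = 40_000
    alpha: float = 1.0
    mode: ScoreMode = ScoreMode.CONFIDENCE
    threshold_rule: ThresholdRule = ThresholdRule.MAX_F1
    precision_floor: Optional[float] = None
    calibration_labels: str = "ground_truth"
    evaluation_labels: str = "ground_truth"
    specialty: Optional[str] = None  # defaults to the generator's specialty code
    suppress: bool = True
    min_reportable: int = 11

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        if "mode" in raw:
            raw["mode"] = ScoreMode(str(raw["mode"]).upper())
        if "threshold_rule" in raw:
            raw["threshold_rule"] = ThresholdRule(str(raw["threshold_rule"]).upper())
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["out_dir"] = str(self.out_dir)
        data["mode"] = self.mode.value
        data["threshold_rule"] = self.threshold_rule.value
        return data


@dataclass
class PipelineResult:
    ok: bool
    out_dir: Path
    digests: dict[str, str]
    failed_stage: Optional[str] = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derive_seed(seed: int, offset: int) -> int:
    return (seed * 1_000 + offset) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages; on failure, retain partial outputs with a FAILED marker."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate"
        universe = build_code_universe(config.generator)
        corpora: dict[str, ClaimSet] = {}
        for offset, (name, size) in enumerate(
            [("train", config.n_train), ("calibration", config.n_calibration), ("test", config.n_test)]
        ):
            gen = dataclasses.replace(
                config.generator, n_claims=size, seed=_derive_seed(config.seed, offset)
            )
            corpora[name] = simulate_claims(gen, universe)
            logger.info("simulated %s corpus: %d claims", name, len(corpora[name]))

        stage = "train"
        table = train_associations(
            corpora["train"], universe.code_map, alpha=config.alpha, mode=config.mode
        )
        table.to_json(out_dir / "model.json")

        stage = "filter"
        specialty = config.specialty or config.generator.specialty_code
        populations = {
            name: filter_study_population(corpus, universe.code_map, specialty)
            for name, corpus in corpora.items()
        }
        flow = {name: pop.flow.to_dict() for name, pop in populations.items()}
        (out_dir / "selection_flow.json").write_text(json.dumps(flow, indent=2, sort_keys=True))
        for name, pop in populations.items():
            logger.info("%s population: %s", name, pop.flow.to_dict())

        stage = "threshold"
        calib = ClaimSet(
            [
                c
                for c in populations["calibration"].claims
                if assign_subgroup(c, universe.code_map) in DISCORDANT
            ],
            provenance="calibration LR/RL",
        )
        if not calib.claims:
            raise ValueError("calibration corpus has no discordant-laterality claims")
        calib_scores = score_claims(calib, table, universe.code_map)
        calib_labels = [bool(c.truth and c.truth.is_error) for c in calib]
        if config.calibration_labels == "auto_review":
            from lateraleye.review_eval import auto_review

            calib_labels = [auto_review(c, universe.code_map).is_error for c in calib]
        points = precision_recall_points(calib_scores, calib_labels)
        threshold = select_threshold(points, config.threshold_rule, config.precision_floor)
        threshold.to_json(out_dir / "threshold.json")
        logger.info(
            "threshold %.6f (rule=%s, precision=%.3f, recall=%.3f)",
            threshold.value, threshold.selection_rule.value, threshold.precision, threshold.recall,
        )

        stage = "score"
        test_pop = populations["test"].claims
        test_scores = score_claims(test_pop, table, universe.code_map, threshold)
        with open(out_dir / "subgroups.csv", "w") as handle:
            handle.write("claim_id,subgroup,claim_score,flagged\n")
            for claim, score in zip(test_pop, test_scores):
                subgroup = assign_subgroup(claim, universe.code_map).value
                handle.write(
                    f"{claim.claim_id},{subgroup},{score.claim_score:.8f},{int(score.flagged)}\n"
                )

        stage = "evaluate"
        report = compare_methods(
            test_pop, universe.code_map, table, threshold,
            labels=config.evaluation_labels, pr_points=points,
        )
        if config.suppress:
            report = suppress_small_cells(report, config.min_reportable)
        render_report(report, out_dir)

        stage = "manifest"
        result_files = sorted(
            p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        digests = {p.name: _sha256(p) for p in result_files}
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "digests": digests,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return PipelineResult(ok=True, out_dir=out_dir, digests=digests)
    except Exception:
        (out_dir / "FAILED").write_text(f"stage: {stage}\n")
        raise
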