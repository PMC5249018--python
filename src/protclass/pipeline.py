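"""End-to-end run orchestration: MSA → consensus + pattern → features →
training → prediction → metrics, with a manifest for provenance.

Reruns with an identical configuration are byte-identical: no timestamps go
into any output, JSON keys are sorted, and all randomness flows from the
configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import ScoringConfig
from .classifier import (
    SELFALIGN_GATE,
    baseline_classifiers,
    build_training_set,
    evaluate,
    predict,
    train_mlp,
)
from .features import feature_matrix
from .io import read_fasta, read_msa
from .motif import consensus_from_msa, derive_pattern

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one pipeline run."""

    msa_path: str
    candidates_path: str
    out_dir: str
    truth_path: str | None = None      # optional id→label TSV for metrics
    seed: int = 0
    gate: float = SELFALIGN_GATE
    min_conservation: float = 0.9
    refine_pattern: bool = True
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    run_baselines: bool = True

    def scoring(self) -> ScoringConfig:
        return ScoringConfig(self.matrix, self.gap_open, self.gap_extend)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write features, pattern, model, predictions,
    metrics and a manifest under ``config.out_dir``."""
    # Pre-flight checks before any computation
    for name in ("msa_path", "candidates_path"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name}: {p}")
    if config.truth_path and not Path(config.truth_path).exists():
        raise FileNotFoundError(f"truth_path: {config.truth_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scoring = config.scoring()

    logger.info("stage consensus: reading MSA %s", config.msa_path)
    msa = read_msa(config.msa_path)
    profile = consensus_from_msa(msa)
    (out / "consensus.txt").write_text(profile.consensus + "\n")

    logger.info("stage pattern: deriving conserved-domain pattern")
    pattern = derive_pattern(msa, config.min_conservation, refine=config.refine_pattern)
    (out / "pattern.txt").write_text(pattern.to_text() + "\n")

    logger.info("stage features: reading candidates %s", config.candidates_path)
    candidates = read_fasta(config.candidates_path)
    features = feature_matrix(candidates, profile.consensus, scoring)
    features.to_csv(out / "features.tsv", sep="\t", index_label="id")

    logger.info("stage train: building training set and fitting the network")
    ts = build_training_set(candidates, pattern, profile.consensus, scoring,
                            config.gate)
    model = train_mlp(ts, seed=config.seed)
    model.save(out / "model.json")

    logger.info("stage predict: classifying %d candidates", len(candidates))
    predictions = predict(model, candidates, profile.consensus, scoring,
                          config.gate)
    pd.DataFrame(
        [(p.id, p.status, p.label, p.class_name, p.score) for p in predictions],
        columns=["id", "status", "label", "class_name", "score"],
    ).to_csv(out / "predictions.tsv", sep="\t", index=False)

    metrics: dict = {"n_candidates": len(candidates),
                     "n_training": int(ts.labels.shape[0]),
                     "n_positive_training": int((ts.labels == 1).sum())}
    if config.truth_path:
        truth_df = pd.read_csv(config.truth_path, sep="\t")
        truth = dict(zip(truth_df["id"].astype(str), truth_df["label"].astype(int)))
        pred_binary = [
            1 if (p.status == "classified" and p.label == 1) else 0
            for p in predictions
        ]
        truth_binary = [1 if truth[p.id] == 1 else 0 for p in predictions]
        cm = evaluate(pred_binary, truth_binary)
        metrics["mlp"] = {
            "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
            **cm.metrics_percent(),
        }
        if config.run_baselines:
            logger.info("stage baselines: rule-based reference methods")
            for name, bcm in baseline_classifiers(
                candidates, truth, pattern, profile.consensus, scoring
            ).items():
                metrics[name] = {
                    "tp": bcm.tp, "tn": bcm.tn, "fp": bcm.fp, "fn": bcm.fn,
                    **bcm.metrics_percent(),
                }
    _dump_json(metrics, out / "metrics.json")

    manifest = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "selfalign_gate": config.gate,
        "matrix": config.matrix,
        "seed": config.seed,
        "consensus_length": len(profile.consensus),
        "pattern": pattern.to_text(),
    }
    _dump_json(manifest, out / "manifest.json")
    logger.info("run complete: %s", out)
    return out
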