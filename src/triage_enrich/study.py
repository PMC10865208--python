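"""Replicated ED-vs-BD study on synthetic cohorts.

One replicate = generate a cohort at a given letter-signal strength,
run the full pipeline for both conditions, and record each model's
evaluation macro F1. Replicating over seeds turns the single-cohort
comparison into a distribution, which is what the qualitative claim
("enrichment helps when the letters carry class signal, and only then")
is judged on.

Two study-level conventions differ from the pipeline defaults and are
documented in the methods note: evaluation rows are z-scored with the
training moments (the balanced evaluation set would otherwise be
normalized against a different class mix than training), and the
selection threshold is tau = 0.015, calibrated on this generator's
weight scale to balance the two failure modes of threshold selection —
admitting spuriously inflated binary noise flags (which score up to
~0.02-0.03 here) against dropping near-threshold informative features
from one condition but not the other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .models import ModelConfig
from .pipeline import RunConfig, run_pipeline
from .relieff import ReliefFConfig
from .synthetic import CohortSpec, inject_letter_signal

__all__ = ["StudyConfig", "run_replicate", "run_study"]

STUDY_TAU = 0.015
STUDY_ZSCORE_MODE = "train_params"


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the replicated synthetic comparison."""

    n_patients: int = 2000
    strength: float = 1.0
    effect_size: float = 0.5
    n_replicates: int = 20
    tau: float = STUDY_TAU
    zscore_mode: str = STUDY_ZSCORE_MODE
    n_runs: int = 1
    models: tuple[str, ...] = ("knn", "svm", "mlp")


def run_replicate(study: StudyConfig, seed: int) -> dict[str, dict[str, float]]:
    """One seeded cohort -> {model: {'f1_ed':..., 'f1_bd':..., 'diff_pp':...}}."""
    spec = inject_letter_signal(
        CohortSpec(n_patients=study.n_patients, effect_size=study.effect_size),
        study.strength,
    )
    cfg = RunConfig(
        cohort=spec,
        zscore_mode=study.zscore_mode,
        relieff=ReliefFConfig(tau=study.tau),
        models=tuple(
            ModelConfig(model=m, n_runs=study.n_runs) for m in study.models
        ),
        seed=seed,
    )
    result = run_pipeline(cfg)
    out = {}
    for _, row in result.comparison.iterrows():
        out[row["model"]] = {
            "f1_ed": float(row["mean_f1_ed"]),
            "f1_bd": float(row["mean_f1_bd"]),
            "diff_pp": float(row["diff_pp"]),
        }
    return out


def run_study(study: StudyConfig, base_seed: int = 0) -> pd.DataFrame:
    """Run all replicates; returns one row per (replicate, model)."""
    rows = []
    for rep in range(study.n_replicates):
        res = run_replicate(study, seed=base_seed + 1000 * rep + 1)
        for model, scores in res.items():
            rows.append({"replicate": rep, "model": model, **scores})
    return pd.DataFrame(rows)
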