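"""End-to-end orchestration: simulate/ingest -> extract -> assemble -> split ->
normalize -> rank/select -> balance -> train -> evaluate -> compare.

The pipeline runs the enriched (ED) and basic (BD) feature tables
through the identical split and evaluates every configured model on
both, so the reported per-model F1 difference isolates the contribution
of the referral-letter flags. A single master seed deterministically
derives independent per-stage seeds; rerunning an identical config is
bit-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import cohort as co
from . import lexicon_nlp as nlp
from .evaluation import (
    ConfusionMatrix,
    ScoreReport,
    average_runs,
    compare_conditions,
    confusion,
    f1_from_confusion,
    plot_confusion,
)
from .models import ModelConfig, drop_incomplete, predict, train_model
from .relieff import FeatureRanking, ReliefFConfig, relieff_rank, select_features
from .smote import SmoteConfig, smote_balance
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "PipelineResult", "stage_seed", "attach_flags", "run_pipeline"]

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable sub-seed for one pipeline stage from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    cohort: CohortSpec | None = None          # simulate when set ...
    letters_path: str | None = None           # ... otherwise ingest from disk
    features_path: str | None = None
    lexicon_path: str | None = None
    conditions: tuple[str, ...] = ("ED", "BD")
    ed_flag_names: tuple[str, ...] = co.DEFAULT_ED_FLAGS
    per_class: int = 50
    sd_convention: str = "population"
    zscore_mode: str = "per_split"
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    relieff: ReliefFConfig = field(default_factory=ReliefFConfig)
    models: tuple[ModelConfig, ...] = (
        ModelConfig(model="knn"),
        ModelConfig(model="svm"),
        ModelConfig(model="mlp"),
    )
    seed: int = 0
    out_dir: str | None = None

    def config_digest(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    from dataclasses import asdict, is_dataclass

    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


@dataclass
class PipelineResult:
    comparison: "object"                      # pandas frame, one row per model
    reports: dict                             # (model, condition) -> ScoreReport
    confusions: dict                          # (model, condition) -> ConfusionMatrix
    rankings: dict                            # condition -> FeatureRanking
    manifest: dict


def attach_flags(
    records: Sequence[co.PatientRecord],
    letters: Sequence[nlp.ReferralLetter],
    lexicon: nlp.Lexicon,
) -> list[co.PatientRecord]:
    """Extract flags from each patient's *initial* letter and attach them.

    Patients without any letter keep ``flags=None`` (and will fall to the
    inclusion rule downstream).
    """
    by_patient: dict[str, list[nlp.ReferralLetter]] = {}
    for letter in letters:
        by_patient.setdefault(letter.patient_id, []).append(letter)
    out = []
    for r in records:
        mine = by_patient.get(r.patient_id, [])
        initial = nlp.select_initial_letter(mine)
        flags = nlp.extract_flags(initial, lexicon) if initial is not None else None
        out.append(replace(r, flags=flags))
    return out


def _load_records(cfg: RunConfig) -> tuple[list[co.PatientRecord], list[nlp.ReferralLetter]]:
    import pandas as pd

    if cfg.cohort is not None:
        spec = replace(cfg.cohort, seed=stage_seed(cfg.seed, "simulate"))
        patients, letters, _truth = generate_cohort(spec)
        return [p.record for p in patients], letters
    if cfg.features_path is None:
        raise ValueError("either a cohort spec or a features_path is required")
    df = pd.read_csv(cfg.features_path)
    q_cols = [c for c in df.columns if c not in ("patient_id", "label")]
    records = [
        co.PatientRecord(
            patient_id=str(row["patient_id"]),
            questionnaire={c: float(row[c]) for c in q_cols},
            flags=None,
            label=int(row["label"]),
        )
        for _, row in df.iterrows()
    ]
    letters = []
    if cfg.letters_path:
        p = Path(cfg.letters_path)
        letters = nlp.read_letters_dir(p) if p.is_dir() else nlp.read_letters_jsonl(p)
    return records, letters


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage for the configured conditions and compare them."""
    manifest: dict = {
        "config_digest": cfg.config_digest(),
        "seeds": {s: stage_seed(cfg.seed, s) for s in ("simulate", "split", "smote")},
        "stages": {},
    }
    records, letters = _load_records(cfg)
    manifest["stages"]["input"] = {"n_records": len(records), "n_letters": len(letters)}

    need_extraction = "ED" in cfg.conditions
    if need_extraction:
        lexicon = nlp.load_lexicon(cfg.lexicon_path)
        records = attach_flags(records, letters, lexicon)
        included = co.apply_inclusion(records)
        manifest["stages"]["extract"] = nlp_summary = co.inclusion_summary(records)
        ed, bd = co.build_datasets(included, ed_flag_names=cfg.ed_flag_names)
        tables = {"ED": ed, "BD": bd}
    else:
        manifest["stages"]["extract"] = {"skipped": True}
        included = records
        q_names = list(records[0].questionnaire) if records else []
        import pandas as pd

        bd = co.FeatureTable(
            features=pd.DataFrame(
                [[r.questionnaire[n] for n in q_names] for r in records],
                columns=q_names, dtype=float,
            ),
            labels=np.array([r.label for r in records]),
            condition="BD",
            patient_ids=[r.patient_id for r in records],
        )
        tables = {"BD": bd}
    tables = {k: v for k, v in tables.items() if k in cfg.conditions}
    manifest["stages"]["assemble"] = {"n_included": len(included)}

    split_s = stage_seed(cfg.seed, "split")
    reports: dict[tuple[str, str], ScoreReport] = {}
    confusions: dict[tuple[str, str], ConfusionMatrix] = {}
    rankings: dict[str, FeatureRanking] = {}
    for cond, table in tables.items():
        table = co.split_eval(table, per_class=cfg.per_class, seed=split_s)
        table = co.zscore_by_split(
            table, sd_convention=cfg.sd_convention, mode=cfg.zscore_mode
        )
        train = table.train_rows()
        ranking = relieff_rank(train, cfg.relieff)     # pre-balancing rows only
        rankings[cond] = ranking
        selected_table = select_features(ranking, table)
        train_sel = selected_table.train_rows()
        eval_sel = selected_table.eval_rows()
        train_cc, n_drop_train = drop_incomplete(train_sel)
        eval_cc, n_drop_eval = drop_incomplete(eval_sel)
        balanced = smote_balance(
            train_cc, replace(cfg.smote, seed=stage_seed(cfg.seed, "smote"))
        )
        manifest["stages"][f"{cond}"] = {
            "n_train": len(train),
            "n_eval": len(eval_sel),
            "n_selected_features": len(ranking.selected),
            "n_train_dropped_incomplete": n_drop_train,
            "n_eval_dropped_incomplete": n_drop_eval,
            "n_train_balanced": len(balanced),
            "eval_patient_ids": sorted(eval_sel.patient_ids),
        }
        for mcfg in cfg.models:
            run_reports = []
            run_confusions = []
            for run in range(mcfg.n_runs):
                mcfg_seeded = replace(mcfg, seed=stage_seed(cfg.seed, f"model:{mcfg.model}"))
                model = train_model(balanced, mcfg_seeded, run_index=run)
                pred = predict(model, eval_cc)
                cm = confusion(eval_cc.labels, pred)
                run_confusions.append(cm)
                run_reports.append(f1_from_confusion(cm, model=mcfg.model, condition=cond))
            reports[(mcfg.model, cond)] = average_runs(run_reports)
            confusions[(mcfg.model, cond)] = ConfusionMatrix(
                counts=np.sum([c.counts for c in run_confusions], axis=0) // len(run_confusions),
                classes=run_confusions[0].classes,
            ) if len(run_confusions) > 1 else run_confusions[0]

    model_names = [m.model for m in cfg.models]
    if {"ED", "BD"} <= set(tables):
        comparison = compare_conditions(
            {m: reports[(m, "ED")] for m in model_names},
            {m: reports[(m, "BD")] for m in model_names},
        )
    else:
        import pandas as pd

        only = next(iter(tables))
        comparison = pd.DataFrame(
            [{"model": m, f"mean_f1_{only.lower()}": reports[(m, only)].mean_f1}
             for m in model_names]
        )
    manifest["results_digest"] = hashlib.sha256(
        comparison.to_csv(index=False).encode()
    ).hexdigest()[:16]

    result = PipelineResult(
        comparison=comparison,
        reports=reports,
        confusions=confusions,
        rankings=rankings,
        manifest=manifest,
    )
    if cfg.out_dir:
        _write_artifacts(cfg, result)
    return result


def _write_artifacts(cfg: RunConfig, result: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(out / "comparison.csv", index=False)
    rows = []
    for (model, cond), rep in result.reports.items():
        for i, c in enumerate(rep.classes):
            rows.append(
                {"model": model, "condition": cond, "class": c,
                 "precision": rep.precision[i], "recall": rep.recall[i], "f1": rep.f1[i],
                 "macro_f1_mean": rep.mean_f1}
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "scores.csv", index=False)
    for cond, ranking in result.rankings.items():
        ranking.to_frame().to_csv(out / f"ranking_{cond.lower()}.csv", index=False)
    for (model, cond), cm in result.confusions.items():
        cm.to_frame().to_csv(out / f"confusion_{model}_{cond.lower()}.csv")
        plot_confusion(cm, f"{model} / {cond}", str(out / f"confusion_{model}_{cond.lower()}.png"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
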