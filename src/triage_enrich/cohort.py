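"""Cohort assembly: inclusion rules, ED/BD construction, evaluation split, z-scoring.

Two parallel feature tables are built from the same patients: the
*extended data set* (ED: questionnaire items plus referral-letter flags)
and the *basic data set* (BD: questionnaire items only). The comparison
of classifier performance between the two is the point of the whole
pipeline, so both tables share row order, labels and the evaluation
split exactly.

Missing questionnaire values are carried through assembly as NaN and
never imputed here; the feature-selection stage is missing-tolerant and
the model stage enforces complete cases on the selected columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lexicon_nlp import ALL_CATEGORIES, PAG_CATEGORIES, ExtractionFlags

__all__ = [
    "PatientRecord",
    "FeatureTable",
    "DEFAULT_ED_FLAGS",
    "apply_inclusion",
    "inclusion_summary",
    "build_datasets",
    "split_eval",
    "zscore_by_split",
]

TRAIN, EVAL = "train", "eval"

#: Flag columns merged into the ED by default: four of the five referral
#: reasons plus all four patient goals. SecondOpinionReRe is left out
#: because its content (second opinion / further diagnostics) duplicates
#: the MoreCausePaG goal category; the choice is configurable.
DEFAULT_ED_FLAGS: tuple[str, ...] = (
    "AnesthesiologyReRe",
    "RehabReRe",
    "AdviceReRe",
    "OptionsReRe",
) + PAG_CATEGORIES


@dataclass(frozen=True)
class PatientRecord:
    """One patient: questionnaire answers, optional letter flags, triage label.

    ``flags is None`` means the patient has no referral letter at all;
    a patient whose letter matched no category has an all-zero flags
    object instead.
    """

    patient_id: str
    questionnaire: dict[str, float]
    flags: ExtractionFlags | None
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2, 3):
            raise ValueError(f"label must be one of 0..3, got {self.label}")


@dataclass
class FeatureTable:
    """Patient x feature numeric matrix with labels, split tags and condition.

    ``features`` is a float DataFrame where NaN marks a missing value.
    ``split`` is per-row 'train'/'eval' (empty string before splitting);
    ``synthetic`` marks oversampled rows added by balancing.
    """

    features: pd.DataFrame
    labels: np.ndarray
    condition: str = "ED"
    split: np.ndarray | None = None
    patient_ids: list[str] | None = None
    synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features row counts differ")
        if self.features.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.split is None:
            self.split = np.full(len(self.labels), "", dtype=object)
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.labels), dtype=bool)
        if self.patient_ids is None:
            self.patient_ids = [str(i) for i in range(len(self.labels))]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def __len__(self) -> int:
        return len(self.labels)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            features=self.features.copy(),
            labels=self.labels.copy(),
            condition=self.condition,
            split=self.split.copy(),
            patient_ids=list(self.patient_ids),
            synthetic=self.synthetic.copy(),
        )

    def subset_rows(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        return FeatureTable(
            features=self.features.loc[mask].reset_index(drop=True),
            labels=self.labels[mask],
            condition=self.condition,
            split=self.split[mask],
            patient_ids=[p for p, m in zip(self.patient_ids, mask) if m],
            synthetic=self.synthetic[mask],
        )

    def train_rows(self) -> "FeatureTable":
        return self.subset_rows(self.split == TRAIN)

    def eval_rows(self) -> "FeatureTable":
        return self.subset_rows(self.split == EVAL)

    def restrict_features(self, names: Sequence[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        out = self.copy()
        out.features = self.features.loc[:, list(names)].copy()
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV-ready frame with patient_id, label, split and synthetic columns."""
        df = self.features.copy()
        df.insert(0, "patient_id", self.patient_ids)
        df["label"] = self.labels
        df["split"] = self.split
        df["synthetic"] = self.synthetic.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str = "ED") -> "FeatureTable":
        meta = [c for c in ("patient_id", "label", "split", "synthetic") if c in df.columns]
        features = df.drop(columns=meta).astype(float)
        return cls(
            features=features.reset_index(drop=True),
            labels=df["label"].to_numpy(dtype=int),
            condition=condition,
            split=(df["split"].fillna("").to_numpy(dtype=object)
                   if "split" in df.columns else None),
            patient_ids=(df["patient_id"].astype(str).tolist()
                         if "patient_id" in df.columns else None),
            synthetic=(df["synthetic"].to_numpy(dtype=bool)
                       if "synthetic" in df.columns else None),
        )


def apply_inclusion(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Keep patients that have a referral letter in which at least one
    referral-reason or patient-goal category was recognised. Order preserved;
    idempotent."""
    return [
        r for r in records
        if r.flags is not None and (r.flags.has_any_rere or r.flags.has_any_pag)
    ]


def inclusion_summary(records: Sequence[PatientRecord]) -> dict[str, float]:
    """Cohort-flow counts and percentages: letters available, extraction hits."""
    n_total = len(records)
    with_letter = [r for r in records if r.flags is not None]
    included = apply_inclusion(records)
    only_pag = [r for r in included if r.flags.has_any_pag and not r.flags.has_any_rere]
    return {
        "n_total": n_total,
        "n_with_letter": len(with_letter),
        "pct_with_letter": 100.0 * len(with_letter) / n_total if n_total else float("nan"),
        "n_included": len(included),
        "pct_included_of_letters": (100.0 * len(included) / len(with_letter)
                                    if with_letter else float("nan")),
        "n_only_pag": len(only_pag),
    }


def build_datasets(
    records: Sequence[PatientRecord],
    ed_flag_names: Sequence[str] = DEFAULT_ED_FLAGS,
) -> tuple[FeatureTable, FeatureTable]:
    """Build the (ED, BD) pair from included records.

    ED = questionnaire columns plus the selected letter-flag columns (0/1,
    never missing); BD = the questionnaire columns only. Identical row order.
    """
    unknown = [n for n in ed_flag_names if n not in ALL_CATEGORIES]
    if unknown:
        raise KeyError(f"unknown flag name(s) in ed_flag_names: {unknown}")
    q_names = list(records[0].questionnaire) if records else []
    rows_q, rows_f = [], []
    for r in records:
        if list(r.questionnaire) != q_names:
            raise ValueError(f"inconsistent questionnaire features for patient {r.patient_id}")
        rows_q.append([float(r.questionnaire[n]) for n in q_names])
        if r.flags is None:
            raise ValueError(f"record {r.patient_id} has no extraction flags; run inclusion first")
        d = r.flags.as_dict()
        rows_f.append([float(d[n]) for n in ed_flag_names])
    labels = np.array([r.label for r in records], dtype=int)
    pids = [r.patient_id for r in records]
    bd_df = pd.DataFrame(rows_q, columns=q_names, dtype=float)
    ed_df = pd.concat(
        [bd_df, pd.DataFrame(rows_f, columns=list(ed_flag_names), dtype=float)], axis=1
    )
    ed = FeatureTable(features=ed_df, labels=labels, condition="ED", patient_ids=pids)
    bd = FeatureTable(features=bd_df.copy(), labels=labels.copy(), condition="BD",
                      patient_ids=list(pids))
    return ed, bd


def split_eval(table: FeatureTable, per_class: int, seed: int) -> FeatureTable:
    """Tag a class-balanced evaluation set (``per_class`` rows per class,
    drawn uniformly without replacement); everything else becomes training.

    The draw depends only on (labels, seed), so applying the same call to
    the ED and the BD — which share row order — tags identical rows.
    """
    rng = np.random.default_rng(seed)
    split = np.full(len(table), TRAIN, dtype=object)
    for c in sorted(set(table.labels.tolist())):
        idx = np.flatnonzero(table.labels == c)
        if len(idx) < per_class:
            raise ValueError(
                f"class {c} has only {len(idx)} rows, fewer than per_class={per_class}"
            )
        chosen = rng.choice(idx, size=per_class, replace=False)
        split[chosen] = EVAL
    out = table.copy()
    out.split = split
    return out


def _zscore_block(block: pd.DataFrame, params: pd.DataFrame | None, ddof: int):
    """Z-score columns of a block; returns (normalized, params used)."""
    if params is None:
        mean = block.mean(axis=0, skipna=True)
        sd = block.std(axis=0, skipna=True, ddof=ddof).fillna(0.0)
        params = pd.DataFrame({"mean": mean, "sd": sd})
    out = block.copy()
    for c in block.columns:
        m, s = params.at[c, "mean"], params.at[c, "sd"]
        if s > 0:
            out[c] = (block[c] - m) / s
        else:
            # zero-variance column: non-missing entries map to 0, missing stay NaN
            out[c] = np.where(block[c].isna(), np.nan, 0.0)
    return out, params


def zscore_by_split(
    table: FeatureTable,
    sd_convention: str = "population",
    mode: str = "per_split",
) -> FeatureTable:
    """Z-score every column within each split tag.

    ``sd_convention='population'`` divides by n (so a [1,2,3] column maps
    to [-1,0,1]); ``'sample'`` uses n-1. ``mode='per_split'`` normalizes
    each split with its own mean/SD; ``mode='train_params'`` reuses the
    training-split parameters for the evaluation split (leak-free
    deployment convention). Zero-variance columns map to 0; missing cells
    stay missing. Binary flag columns get no special casing.
    """
    if sd_convention not in ("population", "sample"):
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    if mode not in ("per_split", "train_params"):
        raise ValueError(f"unknown mode {mode!r}")
    ddof = 0 if sd_convention == "population" else 1
    out = table.copy()
    tags = [t for t in (TRAIN, EVAL, "") if (table.split == t).any()]
    train_params = None
    for tag in tags:
        mask = table.split == tag
        block = table.features.loc[mask]
        reuse = train_params if (mode == "train_params" and tag == EVAL) else None
        normed, params = _zscore_block(block, reuse, ddof)
        if tag == TRAIN:
            train_params = params
        out.features.loc[mask] = normed
    return out
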