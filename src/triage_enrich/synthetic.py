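"""Synthetic low-back-pain triage cohort with section-structured Dutch referral letters.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised end to end without clinical
data: class-imbalanced triage labels, class-conditional questionnaire
features (continuous and 1-5 ordinal) with missingness, and templated
Dutch referral letters whose referral-reason / patient-goal sections
embed category code words with class-conditional probabilities. Planted
ground truth is recorded exactly, so extraction can be scored per
category.

Default calibration follows the published cohort's *proportions*: class
priors 301:571:228:109 (other, rehabilitation, anesthesiology,
neurosurgery), per-class code-word occurrence rates from the category
statistics of the training split, and a 16.6% chance of lacking a
referral letter. Letters are templates (marker + planted code words +
neutral filler), not free-form prose: the pipeline only ever consumes
code-word presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .lexicon_nlp import (
    ALL_CATEGORIES,
    PAG_CATEGORIES,
    RERE_CATEGORIES,
    ReferralLetter,
)

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "CANONICAL_CODE_WORDS",
    "DEFAULT_RERE_PROBS",
    "DEFAULT_PAG_PROBS",
    "DEFAULT_CLASS_PRIORS",
    "generate_cohort",
    "inject_letter_signal",
]

#: label order is (0 other, 1 rehabilitation, 2 anesthesiology, 3 neurosurgery)
DEFAULT_CLASS_PRIORS: tuple[float, ...] = (301 / 1209, 571 / 1209, 228 / 1209, 109 / 1209)

_TRAIN_SIZES = {0: 251, 1: 521, 2: 178, 3: 59}

# per-class occurrence probabilities of each referral-reason category,
# calibrated to the published per-category training-split counts divided
# by the class training sizes; tuple index = class label 0..3
DEFAULT_RERE_PROBS: dict[str, tuple[float, ...]] = {
    "SecondOpinionReRe": (76 / 251, 167 / 521, 56 / 178, 33 / 59),
    "AnesthesiologyReRe": (6 / 251, 22 / 521, 80 / 178, 6 / 59),
    "RehabReRe": (47 / 251, 302 / 521, 30 / 178, 8 / 59),
    "AdviceReRe": (24 / 251, 71 / 521, 20 / 178, 7 / 59),
    "OptionsReRe": (16 / 251, 85 / 521, 36 / 178, 10 / 59),
}

DEFAULT_PAG_PROBS: dict[str, tuple[float, ...]] = {
    "MoreCausePaG": (30 / 251, 78 / 521, 9 / 178, 2 / 59),
    "PainRedPaG": (65 / 251, 126 / 521, 16 / 178, 4 / 59),
    "BetterFuncPaG": (44 / 251, 107 / 521, 13 / 178, 4 / 59),
    "AdvicePaG": (5 / 251, 13 / 521, 1 / 178, 0.0),
}

#: one canonical planting word per category, chosen so that (on the
#: shipped lexicon) it triggers exactly its own category within its family
CANONICAL_CODE_WORDS: dict[str, str] = {
    "SecondOpinionReRe": "aanvullend onderzoek",
    "AnesthesiologyReRe": "blokkade",
    "RehabReRe": "revalidatie",
    "AdviceReRe": "advies",
    "OptionsReRe": "behandelbare opties",
    "MoreCausePaG": "2e mening",
    "PainRedPaG": "pijnvermindering",
    "BetterFuncPaG": "beter functioneren",
    "AdvicePaG": "advies",
}

#: neutral Dutch filler; none of these words (or any substring pair)
#: matches a lexicon code word or section marker
DEFAULT_NOISE_VOCAB: tuple[str, ...] = (
    "de", "heer", "mevrouw", "heeft", "sinds", "geruime", "tijd", "lage",
    "rugklachten", "met", "uitstraling", "naar", "het", "linkerbeen",
    "voorgeschiedenis", "blanco", "medicatie", "paracetamol", "gebruikt",
    "dagelijks", "werkzaam", "als", "administratief", "medewerker",
    "dank", "voor", "uw", "beoordeling", "collegiale", "groet",
)

_ORDINAL_CUTS = (-1.2, -0.4, 0.4, 1.2)  # fixed cut points shared across classes


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic cohort."""

    n_patients: int = 1209
    class_priors: tuple[float, ...] = DEFAULT_CLASS_PRIORS
    n_questionnaire_features: int = 40
    n_informative: int = 10
    effect_size: float = 1.0
    missing_rate: float = 0.05
    rere_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RERE_PROBS)
    )
    pag_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PAG_PROBS)
    )
    p_no_letter: float = 1 - 1341 / 1608
    noise_vocab: tuple[str, ...] = DEFAULT_NOISE_VOCAB
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_priors) - 1.0) > 1e-9 or any(
            p < 0 for p in self.class_priors
        ):
            raise ValueError("class_priors must be non-negative and sum to 1")
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.p_no_letter <= 1:
            raise ValueError("missing_rate and p_no_letter must lie in [0, 1]")
        if self.n_informative > self.n_questionnaire_features:
            raise ValueError("n_informative cannot exceed n_questionnaire_features")
        for name, probs in {**self.rere_probs, **self.pag_probs}.items():
            if len(probs) != 4 or any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"{name}: need 4 per-class probabilities in [0, 1]")


@dataclass
class SyntheticPatient:
    """A generated patient plus its planted ground truth."""

    record: PatientRecord
    has_letter: bool
    planted: dict[str, int]  # per category, 1 iff the code word was embedded


def _questionnaire_names(spec: CohortSpec) -> list[str]:
    return [f"q{j:02d}" for j in range(spec.n_questionnaire_features)]


def _class_shift_patterns(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """(n_informative, 4) matrix of per-class mean shifts in SD units.

    Each informative feature separates the classes along a random
    permutation of the symmetric offsets (-1, -1/3, 1/3, 1), scaled by
    the effect size, so different features discriminate different class
    pairs.
    """
    base = np.array([-1.0, -1 / 3, 1 / 3, 1.0])
    return np.stack(
        [spec.effect_size * rng.permutation(base) for _ in range(spec.n_informative)]
    )


def _assemble_letter(
    planted_rere: list[str],
    planted_pag: list[str],
    rng: np.random.Generator,
    vocab: tuple[str, ...],
) -> str:
    def filler(k: int) -> str:
        return " ".join(rng.choice(vocab, size=k))

    parts = [f"geachte collega, {filler(6)}."]
    if planted_rere:
        words = ", ".join(CANONICAL_CODE_WORDS[c] for c in planted_rere)
        parts.append(f"reden van verwijzing: {words} {filler(3)}.")
    if planted_pag:
        words = ", ".join(CANONICAL_CODE_WORDS[c] for c in planted_pag)
        parts.append(f"hulpvraag: {words} {filler(3)}.")
    parts.append(f"met collegiale groet, {filler(2)}")
    return " ".join(parts)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SyntheticPatient], list[ReferralLetter], pd.DataFrame]:
    """Draw one cohort: patients with questionnaire features, letters, truth table.

    Returns ``(patients, letters, truth)`` where ``letters`` holds one
    initial referral letter per patient that has one, and ``truth`` is a
    frame with the label, letter availability and the planted 0/1
    category indicators per patient. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    labels = rng.choice(4, size=n, p=np.asarray(spec.class_priors))
    shifts = _class_shift_patterns(spec, rng)
    q_names = _questionnaire_names(spec)

    X = rng.standard_normal((n, spec.n_questionnaire_features))
    for j in range(spec.n_informative):
        X[:, j] += shifts[j, labels]
    # every second feature becomes a 1-5 ordinal item via fixed cut points
    for j in range(0, spec.n_questionnaire_features, 2):
        X[:, j] = 1.0 + np.searchsorted(_ORDINAL_CUTS, X[:, j])
    miss = rng.uniform(size=X.shape) < spec.missing_rate
    X = np.where(miss, np.nan, X)

    has_letter = rng.uniform(size=n) >= spec.p_no_letter
    base_date = date(2019, 1, 1)
    patients: list[SyntheticPatient] = []
    letters: list[ReferralLetter] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i:05d}"
        label = int(labels[i])
        planted = {c: 0 for c in ALL_CATEGORIES}
        if has_letter[i]:
            for c in RERE_CATEGORIES:
                planted[c] = int(rng.uniform() < spec.rere_probs[c][label])
            for c in PAG_CATEGORIES:
                planted[c] = int(rng.uniform() < spec.pag_probs[c][label])
            text = _assemble_letter(
                [c for c in RERE_CATEGORIES if planted[c]],
                [c for c in PAG_CATEGORIES if planted[c]],
                rng,
                spec.noise_vocab,
            )
            letters.append(
                ReferralLetter(
                    patient_id=pid,
                    letter_date=base_date + timedelta(days=int(rng.integers(0, 365))),
                    text=text,
                )
            )
        record = PatientRecord(
            patient_id=pid,
            questionnaire={name: float(X[i, j]) for j, name in enumerate(q_names)},
            flags=None,
            label=label,
        )
        patients.append(SyntheticPatient(record=record, has_letter=bool(has_letter[i]),
                                         planted=planted))
        truth_rows.append(
            {"patient_id": pid, "label": label, "has_letter": int(has_letter[i]),
             **planted}
        )

    truth = pd.DataFrame(truth_rows)
    truth.attrs["informative_features"] = q_names[: spec.n_informative]
    return patients, letters, truth


def inject_letter_signal(spec: CohortSpec, strength: float) -> CohortSpec:
    """Interpolate the letter code-word probabilities between class-independent
    (strength 0) and the fully class-conditional calibration (strength 1).

    At strength 0 every class shares the prior-weighted marginal
    occurrence rate of each category, so extraction flags carry no label
    information; at strength 1 the spec's class-conditional pattern is
    returned unchanged (e.g. the anesthesiology referral reason is far
    likelier under the anesthesiology class).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must lie in [0, 1], got {strength}")
    priors = np.asarray(spec.class_priors)

    def blend(probs: dict[str, tuple[float, ...]]) -> dict[str, tuple[float, ...]]:
        out = {}
        for cat, p in probs.items():
            p = np.asarray(p, dtype=float)
            marginal = float(priors @ p)
            out[cat] = tuple(float(v) for v in (1 - strength) * marginal + strength * p)
        return out

    return replace(spec, rere_probs=blend(spec.rere_probs), pag_probs=blend(spec.pag_probs))
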