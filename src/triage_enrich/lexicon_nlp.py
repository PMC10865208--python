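"""Lexicon/regex extraction of referral reasons and patient goals from Dutch referral letters.

The extraction engine is deliberately simple and transparent: letters are
normalized (case folding, diacritic transliteration, configurable
unification rewrites), segmented into a referral-reason section and a
patient-goal section via configurable section-marker patterns, and each
category's code-word patterns are searched inside the corresponding
segment only. A category flag is set when at least one of its patterns
matches; several categories may fire on one letter.

Nine categories are recognised: five referral reasons (what the referring
clinician asks for) and four patient goals (what the patient asks for).
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "LexiconError",
    "ReferralLetter",
    "Lexicon",
    "ExtractionFlags",
    "RERE_CATEGORIES",
    "PAG_CATEGORIES",
    "ALL_CATEGORIES",
    "default_lexicon_path",
    "load_lexicon",
    "normalize_text",
    "segment_letter",
    "extract_flags",
    "select_initial_letter",
    "corpus_occurrence_report",
    "read_letters_jsonl",
    "read_letters_dir",
    "flags_to_frame",
]

RERE_CATEGORIES = (
    "SecondOpinionReRe",
    "AnesthesiologyReRe",
    "RehabReRe",
    "AdviceReRe",
    "OptionsReRe",
)
PAG_CATEGORIES = (
    "MoreCausePaG",
    "PainRedPaG",
    "BetterFuncPaG",
    "AdvicePaG",
)
ALL_CATEGORIES = RERE_CATEGORIES + PAG_CATEGORIES


class LexiconError(ValueError):
    """Raised for malformed lexicon configuration (bad pattern, duplicate name...)."""


@dataclass(frozen=True)
class ReferralLetter:
    """One free-text referral document for one patient."""

    patient_id: str
    letter_date: date
    text: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.text is None:
            raise ValueError("text must not be None (empty string is allowed)")


def _compile(pattern: str, where: str) -> re.Pattern:
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise LexiconError(f"invalid regular expression {pattern!r} in {where}: {exc}") from exc


@dataclass
class Lexicon:
    """Code-word lexicon: categories, section markers and unification rewrites.

    Patterns are regular expressions matched on normalized (lower-case,
    ASCII) text with plain substring semantics — no implicit word
    boundaries, so ``pijn`` also matches inside ``pijnklachten``
    (Dutch compounds).
    """

    referral_reason: dict[str, list[str]]
    patient_goal: dict[str, list[str]]
    section_markers: dict[str, list[str]] = field(
        default_factory=lambda: {"referral_reason": [], "patient_goal": []}
    )
    unification_rules: list[tuple[str, str]] = field(default_factory=list)
    fallback_whole_letter: bool = True

    def __post_init__(self) -> None:
        names = list(self.referral_reason) + list(self.patient_goal)
        if len(names) != len(set(names)):
            raise LexiconError("category names must be unique across the lexicon")
        for family, cats in (("referral_reason", self.referral_reason),
                             ("patient_goal", self.patient_goal)):
            for name, patterns in cats.items():
                if not patterns:
                    raise LexiconError(f"category {name!r} has no code-word patterns")
                for p in patterns:
                    _compile(p, f"{family} category {name!r}")
        for family in ("referral_reason", "patient_goal"):
            for p in self.section_markers.get(family, []):
                _compile(p, f"section marker for {family}")
        for pat, _repl in self.unification_rules:
            _compile(pat, f"unification rule {pat!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        rules = [tuple(r) if not isinstance(r, dict) else (r["pattern"], r["replacement"])
                 for r in d.get("unification_rules", [])]
        return cls(
            referral_reason={k: list(v) for k, v in d["referral_reason"].items()},
            patient_goal={k: list(v) for k, v in d["patient_goal"].items()},
            section_markers={k: list(v) for k, v in d.get("section_markers", {}).items()},
            unification_rules=[(str(a), str(b)) for a, b in rules],
            fallback_whole_letter=bool(d.get("fallback_whole_letter", True)),
        )


@dataclass(frozen=True)
class ExtractionFlags:
    """Binary multi-label extraction result over the 9 categories."""

    referral_reason: dict[str, int]
    patient_goal: dict[str, int]

    @property
    def has_any_rere(self) -> bool:
        return any(self.referral_reason.values())

    @property
    def has_any_pag(self) -> bool:
        return any(self.patient_goal.values())

    def as_dict(self) -> dict[str, int]:
        out = dict(self.referral_reason)
        out.update(self.patient_goal)
        return out


def default_lexicon_path() -> Path:
    return Path(__file__).parent / "data" / "default_lexicon.yaml"


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a lexicon from a YAML/JSON file; with no path, the shipped default.

    The shipped lexicon is a reconstruction built from published code-word
    exemplars; site-specific deployments are expected to extend it.
    """
    path = Path(path) if path is not None else default_lexicon_path()
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    return Lexicon.from_dict(d)


_WS = re.compile(r"\s+")


def normalize_text(raw: str, lexicon: Lexicon) -> str:
    """Lower-case, transliterate diacritics to ASCII, apply unification rewrites, collapse whitespace.

    Idempotent for well-behaved rewrite rules (replacements that do not
    re-create their own pattern), which the shipped lexicon guarantees.
    """
    text = unicodedata.normalize("NFKD", raw.lower())
    text = "".join(c for c in text if not unicodedata.combining(c))
    for pat, repl in lexicon.unification_rules:
        text = _compile(pat, f"unification rule {pat!r}").sub(repl, text)
    return _WS.sub(" ", text).strip()


def _marker_hits(text: str, lexicon: Lexicon) -> list[tuple[int, int, str]]:
    hits = []
    for family in ("referral_reason", "patient_goal"):
        for pat in lexicon.section_markers.get(family, []):
            m = re.search(pat, text)
            if m:
                hits.append((m.start(), m.end(), family))
    hits.sort()
    return hits


def segment_letter(text: str, lexicon: Lexicon) -> tuple[str | None, str | None]:
    """Split a normalized letter into (referral-reason segment, patient-goal segment).

    Each segment runs from the end of the first marker of its family to
    the start of the next marker of either family, or the end of the
    letter. A family with no matching marker yields ``None`` — an absent
    section is a normal outcome, not an error.
    """
    hits = _marker_hits(text, lexicon)
    segments: dict[str, str] = {}
    for i, (_start, end, family) in enumerate(hits):
        if family in segments:
            continue
        stop = hits[i + 1][0] if i + 1 < len(hits) else len(text)
        segments[family] = text[end:stop].lstrip(" :;,-").rstrip()
    return segments.get("referral_reason"), segments.get("patient_goal")


def _match_family(segment: str | None, categories: dict[str, list[str]]) -> dict[str, int]:
    flags = {}
    for name, patterns in categories.items():
        if segment is None:
            flags[name] = 0
        else:
            flags[name] = int(any(re.search(p, segment) for p in patterns))
    return flags


def extract_flags(letter: ReferralLetter, lexicon: Lexicon) -> ExtractionFlags:
    """Extract the 9 binary category flags from one letter.

    Referral-reason patterns are only searched in the referral-reason
    segment and patient-goal patterns only in the patient-goal segment.
    When *no* section marker matches at all and the lexicon's
    ``fallback_whole_letter`` switch is on (default), both families are
    searched over the whole letter instead — real letters are frequently
    unstructured. Pure function of (text, lexicon).
    """
    text = normalize_text(letter.text, lexicon)
    rere_seg, pag_seg = segment_letter(text, lexicon)
    if rere_seg is None and pag_seg is None and lexicon.fallback_whole_letter:
        rere_seg = pag_seg = text
    return ExtractionFlags(
        referral_reason=_match_family(rere_seg, lexicon.referral_reason),
        patient_goal=_match_family(pag_seg, lexicon.patient_goal),
    )


def select_initial_letter(letters: Sequence[ReferralLetter]) -> ReferralLetter | None:
    """Return the earliest letter of one patient (stable on date ties), or None.

    Only the initial referral letter of a patient feeds extraction;
    follow-up letters are ignored.
    """
    if not letters:
        return None
    ids = {l.patient_id for l in letters}
    if len(ids) > 1:
        raise ValueError(f"letters from multiple patients passed: {sorted(ids)}")
    return min(enumerate(letters), key=lambda t: (t[1].letter_date, t[0]))[1]


def corpus_occurrence_report(
    flags: Sequence[ExtractionFlags], labels: Sequence[int]
) -> pd.DataFrame:
    """Per-category occurrence counts, overall and cross-tabulated by triage class.

    Returns one row per category with per-class counts, an ``overall``
    column (= row sum) and ``pct_of_total`` (share of letters in which
    the category occurs). A ``sum`` row totals each class column.
    """
    if len(flags) != len(labels):
        raise ValueError(f"flags ({len(flags)}) and labels ({len(labels)}) differ in length")
    classes = sorted(set(int(l) for l in labels))
    rows = {}
    for cat in ALL_CATEGORIES:
        vals = [f.as_dict()[cat] for f in flags]
        row = {f"class_{c}": sum(v for v, l in zip(vals, labels) if int(l) == c)
               for c in classes}
        row["overall"] = sum(vals)
        row["pct_of_total"] = 100.0 * sum(vals) / len(flags) if flags else 0.0
        rows[cat] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    total = df.drop(columns="pct_of_total").sum()
    df.loc["sum"] = {**total.to_dict(), "pct_of_total": float("nan")}
    return df


# ---------------------------------------------------------------------------
# letter I/O

def read_letters_jsonl(path: str | Path) -> list[ReferralLetter]:
    """Read letters from JSON-lines: one object per line with keys patient_id, letter_date (ISO-8601), text."""
    letters = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            letters.append(ReferralLetter(
                patient_id=str(obj["patient_id"]),
                letter_date=date.fromisoformat(obj["letter_date"]),
                text=obj["text"],
            ))
    return letters


def read_letters_dir(path: str | Path) -> list[ReferralLetter]:
    """Read letters from a directory of ``<patient_id>_<YYYY-MM-DD>.txt`` files."""
    letters = []
    for f in sorted(Path(path).glob("*.txt")):
        stem = f.stem
        pid, _, d = stem.rpartition("_")
        if not pid:
            raise ValueError(f"letter file name {f.name!r} is not <patient_id>_<date>.txt")
        letters.append(ReferralLetter(
            patient_id=pid, letter_date=date.fromisoformat(d),
            text=f.read_text(encoding="utf-8"),
        ))
    return letters


def flags_to_frame(patient_ids: Iterable[str], flags: Iterable[ExtractionFlags]) -> pd.DataFrame:
    """Tabulate extraction flags: one row per patient, one 0/1 column per category."""
    records = [{"patient_id": pid, **f.as_dict()} for pid, f in zip(patient_ids, flags)]
    return pd.DataFrame(records, columns=["patient_id", *ALL_CATEGORIES])
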