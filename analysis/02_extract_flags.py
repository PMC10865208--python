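#!/usr/bin/env python
"""Extract referral-reason and patient-goal flags from the cohort's letters.

Runs the lexicon/regex pipeline on every patient's initial letter and
writes per-patient flags (scratch/cohort/flags.csv) plus the per-class
occurrence table (results/occurrences.csv), the synthetic analogue of
the published category-by-treatment statistics.
"""

from pathlib import Path

import pandas as pd

from triage_enrich.lexicon_nlp import (
    corpus_occurrence_report,
    extract_flags,
    flags_to_frame,
    load_lexicon,
    read_letters_jsonl,
    select_initial_letter,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

lexicon = load_lexicon()
letters = read_letters_jsonl(COHORT / "letters.jsonl")
labels_by_pid = pd.read_csv(COHORT / "truth.csv").set_index("patient_id")["label"]

by_pid: dict[str, list] = {}
for l in letters:
    by_pid.setdefault(l.patient_id, []).append(l)

pids, flags = [], []
for pid, mine in by_pid.items():
    pids.append(pid)
    flags.append(extract_flags(select_initial_letter(mine), lexicon))

flags_to_frame(pids, flags).to_csv(COHORT / "flags.csv", index=False)
report = corpus_occurrence_report(flags, [int(labels_by_pid[p]) for p in pids])
RESULTS.mkdir(exist_ok=True)
report.to_csv(RESULTS / "occurrences.csv")

n_any = sum(1 for f in flags if f.has_any_rere or f.has_any_pag)
print(f"extracted flags for {len(pids)} letters; "
      f"{n_any} ({100 * n_any / len(pids):.1f}%) matched >= 1 category")
print(report.round(1).to_string())
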