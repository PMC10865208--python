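#!/usr/bin/env python
"""Assemble the extended (ED) and basic (BD) data sets and split them.

Applies the inclusion rule (letter present and >= 1 extracted category),
merges questionnaire features with the letter flags, draws the
50-per-class evaluation set, and z-scores the splits (evaluation rows
with the training moments, the study convention). Writes
scratch/cohort/ed.csv and bd.csv.
"""

from pathlib import Path

import pandas as pd

from triage_enrich.cohort import (
    PatientRecord,
    apply_inclusion,
    build_datasets,
    inclusion_summary,
    split_eval,
    zscore_by_split,
)
from triage_enrich.lexicon_nlp import PAG_CATEGORIES, RERE_CATEGORIES, ExtractionFlags

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
SEED = 20240902

feats = pd.read_csv(COHORT / "features.csv")
flag_df = pd.read_csv(COHORT / "flags.csv").set_index("patient_id")
q_cols = [c for c in feats.columns if c not in ("patient_id", "label")]

records = []
for _, row in feats.iterrows():
    pid = str(row["patient_id"])
    flags = None
    if pid in flag_df.index:
        d = flag_df.loc[pid]
        flags = ExtractionFlags(
            referral_reason={c: int(d[c]) for c in RERE_CATEGORIES},
            patient_goal={c: int(d[c]) for c in PAG_CATEGORIES},
        )
    records.append(PatientRecord(pid, {c: float(row[c]) for c in q_cols}, flags,
                                 int(row["label"])))

s = inclusion_summary(records)
print(f"{s['n_total']} patients; {s['n_with_letter']} with letters "
      f"({s['pct_with_letter']:.1f}%); {s['n_included']} included "
      f"({s['pct_included_of_letters']:.1f}% of lettered); "
      f"{s['n_only_pag']} via patient goals only")

included = apply_inclusion(records)
ed, bd = build_datasets(included)
for name, table in (("ed", ed), ("bd", bd)):
    table = split_eval(table, per_class=50, seed=SEED)
    table = zscore_by_split(table, mode="train_params")
    table.to_frame().to_csv(COHORT / f"{name}.csv", index=False)
    n_train = (table.split == "train").sum()
    print(f"{name.upper()}: {table.features.shape[1]} features, "
          f"{n_train} train / {(table.split == 'eval').sum()} eval rows")
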