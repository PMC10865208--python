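#!/usr/bin/env python
"""Generate the synthetic study cohort.

2000 patients with the study's class imbalance (other : rehabilitation :
anesthesiology : neurosurgery = 301 : 571 : 228 : 109), 40 questionnaire
items (10 informative, class shift 0.5 SD), 5% missing cells, and Dutch
referral letters at full letter-signal strength. Writes features.csv,
letters.jsonl and truth.csv under scratch/cohort/.
"""

import json
from pathlib import Path

import pandas as pd

from triage_enrich.synthetic import CohortSpec, generate_cohort, inject_letter_signal

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
SEED = 20240901

spec = inject_letter_signal(
    CohortSpec(n_patients=2000, effect_size=0.5, seed=SEED), strength=1.0
)
patients, letters, truth = generate_cohort(spec)

OUT.mkdir(parents=True, exist_ok=True)
rows = [
    {"patient_id": p.record.patient_id, **p.record.questionnaire, "label": p.record.label}
    for p in patients
]
pd.DataFrame(rows).to_csv(OUT / "features.csv", index=False)
with open(OUT / "letters.jsonl", "w") as fh:
    for l in letters:
        fh.write(json.dumps({"patient_id": l.patient_id,
                             "letter_date": l.letter_date.isoformat(),
                             "text": l.text}) + "\n")
truth.to_csv(OUT / "truth.csv", index=False)

n_letter = truth["has_letter"].sum()
print(f"cohort: {len(patients)} patients, {n_letter} with a referral letter "
      f"({100 * n_letter / len(patients):.1f}%)")
print("class counts:", truth["label"].value_counts().sort_index().to_dict())
print(f"wrote {OUT}/features.csv, letters.jsonl, truth.csv")
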