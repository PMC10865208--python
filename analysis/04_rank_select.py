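#!/usr/bin/env python
"""ReliefF-rank the features of the ED and BD training splits.

Ranks on the pre-balancing training rows (k=50 neighbours per class) and
applies the synthetic-study selection threshold tau=0.01. Writes
results/ranking_ed.csv and ranking_bd.csv; the question of interest is
where the letter-derived flags land in the ED ranking.
"""

from pathlib import Path

import pandas as pd

from triage_enrich.cohort import FeatureTable
from triage_enrich.relieff import ReliefFConfig, relieff_rank
from triage_enrich.study import STUDY_TAU

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

for cond in ("ed", "bd"):
    table = FeatureTable.from_frame(pd.read_csv(COHORT / f"{cond}.csv"),
                                    condition=cond.upper())
    train = table.train_rows()
    ranking = relieff_rank(train, ReliefFConfig(k=50, tau=STUDY_TAU))
    ranking.to_frame().to_csv(RESULTS / f"ranking_{cond}.csv", index=False)
    top = ranking.to_frame().head(8)[["feature", "W", "rank"]]
    print(f"\n{cond.upper()}: {len(ranking.selected)} of "
          f"{len(ranking.feature_names)} features selected (W >= {STUDY_TAU})")
    print(top.to_string(index=False))
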