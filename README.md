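# triage-enrich

Does the free text of a referral letter improve machine-learning triage
of patients with chronic low back pain?

Patients referred to a multidisciplinary spine centre are triaged to
one of four paths — rehabilitation, anesthesiologic pain therapy,
neurosurgery, or a minimal "other" intervention — and decision-support
models built on questionnaire scores alone predict this poorly. The
referral letter, however, states what the referring clinician asks for
(the *referral reason*) and what the patient wants (the *patient
goal*). `triage-enrich` is a tested pipeline that

1. **mines** Dutch referral letters with a configurable lexicon +
   regular-expression engine into nine binary category flags
   (5 referral reasons, 4 patient goals),
2. **assembles** an extended data set (ED = questionnaire + flags) and
   a basic data set (BD = questionnaire only) over the identical
   patients, split and normalization,
3. **ranks** features with multiclass ReliefF
   (`W += (Σ_c w_c·diff(x, NM_c) − diff(x, NH)) / m`, range-normalized
   differences, k nearest hits/misses per class) and selects those with
   `W ≥ τ`,
4. **balances** the imbalanced training split with from-scratch SMOTE
   (`x + u·(x_nn − x)`, k = 5 same-class neighbours),
5. **trains** kNN, SVM and MLP classifiers and scores both conditions
   on a held-out, class-balanced evaluation set with per-class
   precision / recall / F1 and 4×4 confusion matrices, reporting the
   per-model macro-F1 difference ED − BD in percentage points.

Because the underlying clinical cohort is not public, the package
includes a first-class **synthetic cohort generator** that reproduces
the study's statistical structure — class imbalance (571 : 228 : 109 :
301 across rehabilitation / anesthesiology / neurosurgery / other),
class-conditional questionnaire effects, missingness, letter
availability, and class-conditional code-word occurrence — with planted
ground truth and a *signal dial* that interpolates the letters between
uninformative and fully class-informative. Every claim the pipeline
makes is validated against that ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic 2000-patient cohort (letter signal at full strength,
questionnaire effect 0.5 SD):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_flags.py
python analysis/03_assemble_split.py
python analysis/04_rank_select.py
python analysis/05_train_evaluate.py
python analysis/06_replicate_study.py 5
```

`04_rank_select.py` prints the ReliefF ranking of the enriched table —
on a full-signal cohort the two class-informative referral reasons top
the list, ahead of every questionnaire item:

```
ED: 12 of 48 features selected (W >= 0.015)
           feature        W  rank
         RehabReRe 0.179603     1
AnesthesiologyReRe 0.107305     2
               q04 0.056676     3
               q08 0.047944     4
        PainRedPaG 0.039118     5
```

`W` is the ReliefF weight (larger = more class-relevant; a pure-noise
feature scores ≈ 0 on this scale, a perfectly separating one
approaches 1). `05_train_evaluate.py` then trains both conditions and
prints the comparison — the enrichment gain is the `diff_pp` column,
in percentage points of macro F1 on the held-out balanced evaluation
set:

```
model  mean_f1_ed  mean_f1_bd  diff_pp
  knn       0.559       0.462    9.602
  mlp       0.518       0.431    8.789
  svm       0.617       0.491   12.607

largest enrichment gain: 12.6 percentage points of macro F1
```

`06_replicate_study.py` repeats the comparison over seeded cohorts at
signal strength 1 and 0: with full signal every model gains from
enrichment in (nearly) every replicate; with the signal dialled to
zero the gain disappears, confirming the pipeline does not manufacture
a spurious benefit.

The same stages are scriptable via the CLI
(`triage-enrich simulate / extract / assemble / select / balance /
train / evaluate / run`); `triage-enrich run --config run.yaml`
executes everything from one YAML file and writes scores, rankings,
confusion-matrix heatmaps and a manifest with per-stage row counts and
seeds. See `docs/methods.md` for the models, conventions and design
choices.

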