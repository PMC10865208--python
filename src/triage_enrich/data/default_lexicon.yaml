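# Default Dutch referral-letter lexicon (reconstruction).
#
# Code words are regular expressions matched on normalized (lower-case,
# ASCII, whitespace-collapsed) text with substring semantics. The lists
# encode published exemplar terms per category plus documented common
# variants; a deployment against a real letter corpus is expected to
# extend them.

referral_reason:
  SecondOpinionReRe:          # referral for a second opinion / further diagnostics
    - aanvullend onderzoek
    - 2e mening
    - second opinion
    - nadere diagnostiek
  AnesthesiologyReRe:         # referral for anesthesiologic pain therapy
    - blockade
    - blokkade
    - pijnbestrijding
    - anesthesiolog
    - zenuwblok
  RehabReRe:                  # referral for interdisciplinary rehabilitation
    - revalidatie
    - reactivering
  AdviceReRe:                 # "could you give advice to the patient?"
    - advies
    - advisering
  OptionsReRe:                # "are there treatment options?"
    - behandelbare opties
    - behandelopties
    - behandelmogelijkheden

patient_goal:
  MoreCausePaG:               # more diagnostics / know the cause
    - 2e mening
    - oorzaak
    - wat er aan de hand is
    - wat er mis is
  PainRedPaG:                 # pain reduction
    - pijn
  BetterFuncPaG:              # better functioning
    - behandelopties
    - beter functioneren
    - functioneren
    - beter bewegen
  AdvicePaG:                  # advice
    - advies

section_markers:
  referral_reason:
    - 'reden van verwijzing'
    - 'reden verwijzing'
    - 'verwijzing voor'
    - 'verwijsreden'
  patient_goal:
    - 'hulpvraag'
    - 'vraag van (de )?patient'
    - 'wens van (de )?patient'

unification_rules:
  - ['tweede mening', '2e mening']
  - ['2de mening', '2e mening']
  - ['pati[e]?nte?\b', 'patient']

fallback_whole_letter: true
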