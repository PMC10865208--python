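"""Letter normalization, segmentation and code-word flag extraction."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triage_enrich.lexicon_nlp import (
    ALL_CATEGORIES,
    Lexicon,
    LexiconError,
    ReferralLetter,
    corpus_occurrence_report,
    extract_flags,
    flags_to_frame,
    normalize_text,
    read_letters_dir,
    read_letters_jsonl,
    segment_letter,
    select_initial_letter,
)


def letter(text, pid="P1", d=date(2020, 1, 1)):
    return ReferralLetter(patient_id=pid, letter_date=d, text=text)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Graag REVALIDATIE.", "graag revalidatie."),
            ("tweede mening", "2e mening"),            # unification rewrite
            ("", ""),
            ("  veel\t\nwitruimte  ", "veel witruimte"),
            ("patiënt", "patient"),               # diacritic transliteration
        ],
    )
    def test_examples(self, lexicon, raw, expected):
        assert normalize_text(raw, lexicon) == expected

    @given(st.text(alphabet=st.characters(max_codepoint=0x2FF), max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent(self, raw):
        lex = Lexicon(
            referral_reason={"RehabReRe": ["revalidatie"]},
            patient_goal={"PainRedPaG": ["pijn"]},
            unification_rules=[("tweede mening", "2e mening")],
        )
        once = normalize_text(raw, lex)
        assert normalize_text(once, lex) == once

    def test_invalid_rule_names_the_pattern(self):
        with pytest.raises(LexiconError, match=r"\[bad"):
            Lexicon(
                referral_reason={"RehabReRe": ["revalidatie"]},
                patient_goal={"PainRedPaG": ["pijn"]},
                unification_rules=[("[bad", "x")],
            )


class TestSegment:
    def test_both_sections(self, lexicon):
        text = "geachte collega. reden van verwijzing: graag revalidatie. hulpvraag: minder pijn."
        rere, pag = segment_letter(text, lexicon)
        assert rere == "graag revalidatie."
        assert pag == "minder pijn."

    def test_no_marker(self, lexicon):
        assert segment_letter("een brief zonder kopjes", lexicon) == (None, None)

    def test_only_patient_goal_marker(self, lexicon):
        rere, pag = segment_letter("hulpvraag: minder pijn.", lexicon)
        assert rere is None
        assert pag == "minder pijn."

    def test_segments_never_overlap(self, lexicon):
        text = "reden van verwijzing: a b c. hulpvraag: d e f."
        rere, pag = segment_letter(text, lexicon)
        assert "hulpvraag" not in rere and "d e f" not in rere
        assert "a b c" not in pag


class TestExtractFlags:
    def test_rehab_only(self, lexicon):
        f = extract_flags(letter("reden van verwijzing: graag revalidatie."), lexicon)
        assert f.referral_reason["RehabReRe"] == 1
        assert sum(f.referral_reason.values()) == 1

    def test_multilabel_patient_goals(self, lexicon):
        f = extract_flags(
            letter("hulpvraag: oplossing voor mijn pijn, graag 2e mening."), lexicon
        )
        assert f.patient_goal["PainRedPaG"] == 1
        assert f.patient_goal["MoreCausePaG"] == 1

    def test_empty_letter_all_zero(self, lexicon):
        f = extract_flags(letter(""), lexicon)
        assert all(v == 0 for v in f.as_dict().values())
        assert not f.has_any_rere and not f.has_any_pag

    def test_rere_word_outside_segment_does_not_fire(self, lexicon):
        # 'revalidatie' only in the patient-goal section: RehabReRe must stay 0
        f = extract_flags(
            letter("reden van verwijzing: advies. hulpvraag: na revalidatie minder pijn."),
            lexicon,
        )
        assert f.referral_reason["RehabReRe"] == 0
        assert f.referral_reason["AdviceReRe"] == 1

    def test_fallback_searches_whole_letter(self, lexicon):
        f = extract_flags(letter("graag revalidatie voor deze man."), lexicon)
        assert f.referral_reason["RehabReRe"] == 1

    def test_deterministic_pure_function(self, lexicon):
        l = letter("reden van verwijzing: blokkade. hulpvraag: pijn.")
        assert extract_flags(l, lexicon) == extract_flags(l, lexicon)

    def test_adding_code_word_is_monotone(self, lexicon):
        corpus = [
            letter("reden van verwijzing: wij vragen een blokkade."),
            letter("hulpvraag: minder pijn graag."),
            letter("reden van verwijzing: revalidatie."),
        ]
        before = [extract_flags(l, lexicon).as_dict() for l in corpus]
        extended = Lexicon(
            referral_reason={
                k: v + (["wij vragen"] if k == "AnesthesiologyReRe" else [])
                for k, v in lexicon.referral_reason.items()
            },
            patient_goal=dict(lexicon.patient_goal),
            section_markers=dict(lexicon.section_markers),
            unification_rules=list(lexicon.unification_rules),
        )
        after = [extract_flags(l, extended).as_dict() for l in corpus]
        for b, a in zip(before, after):
            for cat in ALL_CATEGORIES:
                assert a[cat] >= b[cat]


class TestInitialLetter:
    def test_min_by_date(self):
        l1 = letter("a", d=date(2019, 5, 1))
        l2 = letter("b", d=date(2018, 12, 31))
        assert select_initial_letter([l1, l2]) is l2

    def test_stable_tie_break(self):
        l1 = letter("first", d=date(2019, 1, 1))
        l2 = letter("second", d=date(2019, 1, 1))
        assert select_initial_letter([l1, l2]) is l1

    def test_empty(self):
        assert select_initial_letter([]) is None

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError, match="multiple patients"):
            select_initial_letter([letter("a", pid="P1"), letter("b", pid="P2")])


class TestOccurrenceReport:
    def test_counts_and_percentages(self, lexicon):
        corpus = [
            letter("reden van verwijzing: revalidatie."),
            letter("reden van verwijzing: revalidatie."),
            letter("hulpvraag: pijn."),
            letter(""),
        ]
        flags = [extract_flags(l, lexicon) for l in corpus]
        rep = corpus_occurrence_report(flags, [1, 1, 0, 0])
        assert rep.loc["RehabReRe", "overall"] == 2
        assert rep.loc["RehabReRe", "pct_of_total"] == 50.0
        assert rep.loc["RehabReRe", "class_1"] == 2

    def test_class_cells_sum_to_overall(self, lexicon, small_cohort):
        _, patients, letters, _ = small_cohort
        by_pid = {l.patient_id: l for l in letters}
        flags, labels = [], []
        for p in patients:
            if p.has_letter:
                flags.append(extract_flags(by_pid[p.record.patient_id], lexicon))
                labels.append(p.record.label)
        rep = corpus_occurrence_report(flags, labels)
        class_cols = [c for c in rep.columns if c.startswith("class_")]
        for cat in ALL_CATEGORIES:
            assert rep.loc[cat, class_cols].sum() == rep.loc[cat, "overall"]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            corpus_occurrence_report([], [1])


class TestLetterIO:
    def test_jsonl_roundtrip(self, tmp_path):
        p = tmp_path / "letters.jsonl"
        p.write_text(
            '{"patient_id": "P1", "letter_date": "2020-02-03", "text": "hulpvraag: pijn."}\n'
        )
        (l,) = read_letters_jsonl(p)
        assert l.patient_id == "P1" and l.letter_date == date(2020, 2, 3)

    def test_txt_dir(self, tmp_path):
        (tmp_path / "P7_2021-06-01.txt").write_text("reden van verwijzing: advies.")
        (l,) = read_letters_dir(tmp_path)
        assert l.patient_id == "P7" and "advies" in l.text

    def test_flags_frame_columns(self, lexicon):
        f = extract_flags(letter("hulpvraag: pijn."), lexicon)
        df = flags_to_frame(["P1"], [f])
        assert list(df.columns) == ["patient_id", *ALL_CATEGORIES]
        assert df.loc[0, "PainRedPaG"] == 1
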