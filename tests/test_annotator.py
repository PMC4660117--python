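"""Lexicon loading, dictionary matching, and the retention filter."""

import random

import pytest

from igtkb.annotator import (
    FeatureLexiconEntry,
    KeywordMatcher,
    LexiconError,
    annotate,
    load_lexicon,
    retain_features,
    write_lexicon,
)
from igtkb.cohort_builder import GroupAssignment


def _entry(fid, term, synonyms=(), tests=("X",), disorder="D"):
    return FeatureLexiconEntry(
        feature_id=fid,
        preferred_term=term,
        synonyms=tuple(synonyms),
        concept_id="C0000001",
        disorder=disorder,
        test_ids=tuple(tests),
    )


def _note(pid, text, nid="n1"):
    return {"patient_id": pid, "note_id": nid, "date": "2013-06-01",
            "text": text}


class TestLoadLexicon:
    def test_packaged_study_lexicon_sizes(self, paper_cohort, tmp_path):
        """243 entries overall; per-test feature inventories 9/86/4/74/131."""
        path = tmp_path / "lexicon.tsv"
        write_lexicon(paper_cohort.lexicon, path)
        entries = load_lexicon(path)
        assert len(entries) == 243
        per_test = {}
        for entry in entries:
            for test_id in entry.test_ids:
                per_test[test_id] = per_test.get(test_id, 0) + 1
        assert per_test == {"82993": 9, "81508": 86, "61247": 4,
                            "9497": 74, "9569": 131}

    def test_near_duplicate_terms_are_distinct_entries(self, paper_cohort):
        terms = [
            e.preferred_term
            for e in paper_cohort.lexicon
            if "9569" in e.test_ids
        ]
        assert "Seizure" in terms and "Seizures" in terms

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_lexicon([], path)
        assert load_lexicon(path) == []

    def test_empty_preferred_term_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_lexicon([_entry("CF:1", "x")], path)
        text = path.read_text().replace("\tx\t", "\t\t")
        path.write_text(text)
        with pytest.raises(LexiconError, match="line 2"):
            load_lexicon(path)

    def test_duplicate_term_within_test_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        write_lexicon([_entry("CF:1", "Ataxia"), _entry("CF:2", "ataxia")],
                      path)
        with pytest.raises(LexiconError, match="duplicate"):
            load_lexicon(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "short.tsv"
        write_lexicon([_entry("CF:1", "Ataxia")], path)
        with open(path, "a") as handle:
            handle.write("only\tthree\tfields\n")
        with pytest.raises(LexiconError, match="line 3"):
            load_lexicon(path)


class TestAnnotate:
    LEXICON = [
        _entry("CF:1", "Emphysema"),
        _entry("CF:2", "Chronic bronchitis"),
        _entry("CF:3", "Enlarged liver", synonyms=("hepatomegaly",)),
        _entry("CF:4", "Heart failure"),
        _entry("CF:5", "Congestive heart failure"),
    ]

    def _flagged(self, matrix, pid):
        return {
            fid for (test, fid) in matrix.pairs()
            if pid in matrix.patients(test, fid)
        }

    def test_direct_term_containment(self):
        matrix = annotate(
            [_note("p1", "patient has emphysema and chronic bronchitis")],
            self.LEXICON,
        )
        assert self._flagged(matrix, "p1") == {"CF:1", "CF:2"}

    def test_synonym_containment(self):
        matrix = annotate([_note("p1", "marked hepatomegaly noted")],
                          self.LEXICON)
        assert self._flagged(matrix, "p1") == {"CF:3"}

    def test_longest_match_takes_precedence(self):
        """A longer phrase claims its words: congestive heart failure does
        not additionally count as heart failure."""
        matrix = annotate(
            [_note("p1", "history of congestive heart failure.")], self.LEXICON
        )
        assert self._flagged(matrix, "p1") == {"CF:5"}
        matrix = annotate([_note("p2", "decompensated heart failure")],
                          self.LEXICON)
        assert self._flagged(matrix, "p2") == {"CF:4"}

    def test_word_boundaries_respected(self):
        matcher = KeywordMatcher()
        matcher.add("Seizure", "CF:S1")
        matcher.add("Seizures", "CF:S2")
        assert matcher.extract("recurrent seizures reported") == {"CF:S2"}
        assert matcher.extract("one seizure observed") == {"CF:S1"}

    def test_patient_level_flag_ignores_mention_multiplicity(self):
        matrix = annotate(
            [
                _note("p1", "emphysema", "n1"),
                _note("p1", "emphysema again; emphysema", "n2"),
            ],
            self.LEXICON,
        )
        assert matrix.count("X", "CF:1", {"p1"}) == 1

    def test_matching_is_order_independent(self):
        notes = [
            _note("p1", "emphysema"),
            _note("p2", "congestive heart failure"),
            _note("p3", "hepatomegaly and chronic bronchitis"),
        ]
        lexicon = list(self.LEXICON)
        base = annotate(notes, lexicon)
        rng = random.Random(3)
        for _ in range(3):
            rng.shuffle(notes)
            rng.shuffle(lexicon)
            other = annotate(notes, lexicon)
            assert {
                (pair, other.patients(*pair)) for pair in other.pairs()
            } == {(pair, base.patients(*pair)) for pair in base.pairs()}

    def test_adding_notes_never_unflags(self):
        notes = [_note("p1", "emphysema")]
        before = annotate(notes, self.LEXICON)
        after = annotate(notes + [_note("p2", "unrelated text")], self.LEXICON)
        for pair in before.pairs():
            assert before.patients(*pair) <= after.patients(*pair)

    def test_unreadable_notes_skipped_and_counted(self):
        matrix = annotate(
            [_note("p1", "emphysema"), {"text": "no patient id"},
             {"patient_id": "p2"}],
            self.LEXICON,
        )
        assert matrix.skipped_notes == 2
        assert self._flagged(matrix, "p1") == {"CF:1"}

    def test_empty_lexicon_rejected(self):
        with pytest.raises(LexiconError):
            annotate([_note("p1", "x")], [])


def _groups(positives, negatives):
    return GroupAssignment(
        per_test={
            "X": {
                "P": frozenset(positives),
                "N": frozenset(negatives),
                "T": frozenset(positives) | frozenset(negatives),
            }
        },
        reference_ids=frozenset({"a1"}),
    )


class TestRetention:
    LEXICON = [_entry("CF:1", "Emphysema"), _entry("CF:2", "Ascites")]

    def test_requires_mention_in_both_groups(self):
        notes = [
            _note("p1", "emphysema"), _note("p2", "emphysema"),
            _note("n1", "emphysema"),
            _note("p1", "ascites"), _note("p2", "ascites"),
        ]
        matrix = annotate(notes, self.LEXICON)
        groups = _groups({"p1", "p2"}, {"n1", "n2"})
        retained = retain_features(matrix, groups, self.LEXICON)
        assert retained == {("X", "CF:1")}  # ascites has no negative mention

    def test_single_mention_each_side_is_retained(self):
        matrix = annotate([_note("p1", "ascites"), _note("n1", "ascites")],
                          self.LEXICON)
        retained = retain_features(matrix, _groups({"p1"}, {"n1"}),
                                   self.LEXICON)
        assert ("X", "CF:2") in retained

    def test_disjunctive_mode_keeps_one_sided_features(self):
        matrix = annotate([_note("p1", "ascites")], self.LEXICON)
        groups = _groups({"p1"}, {"n1"})
        assert retain_features(matrix, groups, self.LEXICON) == set()
        assert retain_features(
            matrix, groups, self.LEXICON, mode="disjunction"
        ) == {("X", "CF:2")}

    def test_retention_implies_finite_positive_odds_ratio(self, paper_result):
        assert (paper_result.stats["or_pn"] > 0).all()
        assert paper_result.stats["or_pn"].map(
            lambda x: x != float("inf")
        ).all()
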