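"""Clinical-feature lexicon and dictionary-based note annotation.

The lexicon maps each genetic test to the clinical features (signs and
symptoms, HPO-style terms normalized to opaque concept ids) that are relevant
to its disorder.  Annotation is deterministic dictionary matching: a patient
is flagged for a feature as soon as any of their notes contains the feature's
preferred term or one of its synonyms.  Matching is case-insensitive, on word
boundaries, longest-match-first and non-overlapping, so a mention of
"congestive heart failure" counts as that phrase and not additionally as
"heart failure".

No negation, uncertainty, or family-history handling is attempted; mentions
are taken at face value.  Counts are patient-level: mentioning a feature in
ten notes flags the patient once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger("igtkb")

_TOKEN_RE = re.compile(r"[0-9a-z]+")

#: sentinel key marking a complete phrase inside the keyword trie
_LEAF = None


def tokenize(text: str) -> list[str]:
    """Case-folded word tokens of *text* (runs of ASCII alphanumerics)."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class FeatureLexiconEntry:
    """One clinical feature tied to one or more genetic tests.

    ``feature_id`` is an ontology-style identifier, ``concept_id`` a
    UMLS-CUI-shaped opaque string.  Near-duplicate surface forms (for example
    "Seizure" and "Seizures", or British/American spellings) are deliberately
    distinct entries.
    """

    feature_id: str
    preferred_term: str
    synonyms: tuple[str, ...]
    concept_id: str
    disorder: str
    test_ids: tuple[str, ...]

    def surfaces(self) -> tuple[str, ...]:
        return (self.preferred_term, *self.synonyms)


class LexiconError(ValueError):
    """Malformed lexicon file or invariant violation."""


LEXICON_COLUMNS = (
    "disorder",
    "feature_id",
    "preferred_term",
    "synonyms",
    "concept_id",
    "test_ids",
)


def load_lexicon(path) -> list[FeatureLexiconEntry]:
    """Parse a tab-separated lexicon file.

    Columns: ``disorder, feature_id, preferred_term, synonyms (|-separated),
    concept_id, test_ids (,-separated)``.  Raises :class:`LexiconError` with
    the offending line number on malformed rows, empty preferred terms, or a
    duplicated (test_id, preferred_term) pair.
    """
    entries: list[FeatureLexiconEntry] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if header.split("\t") != list(LEXICON_COLUMNS):
            raise LexiconError(f"{path}: line 1: unexpected header {header!r}")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(LEXICON_COLUMNS):
                raise LexiconError(
                    f"{path}: line {lineno}: expected {len(LEXICON_COLUMNS)} "
                    f"fields, got {len(parts)}"
                )
            disorder, feature_id, term, syns, concept_id, test_ids = parts
            if not term.strip():
                raise LexiconError(f"{path}: line {lineno}: empty preferred_term")
            tests = tuple(t for t in test_ids.split(",") if t)
            for test_id in tests:
                key = (test_id, term.lower())
                if key in seen:
                    raise LexiconError(
                        f"{path}: line {lineno}: duplicate entry for "
                        f"test {test_id!r}, term {term!r}"
                    )
                seen.add(key)
            entries.append(
                FeatureLexiconEntry(
                    feature_id=feature_id,
                    preferred_term=term,
                    synonyms=tuple(s for s in syns.split("|") if s),
                    concept_id=concept_id,
                    disorder=disorder,
                    test_ids=tests,
                )
            )
    return entries


def write_lexicon(entries: Iterable[FeatureLexiconEntry], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(LEXICON_COLUMNS) + "\n")
        for e in entries:
            handle.write(
                "\t".join(
                    (
                        e.disorder,
                        e.feature_id,
                        e.preferred_term,
                        "|".join(e.synonyms),
                        e.concept_id,
                        ",".join(e.test_ids),
                    )
                )
                + "\n"
            )


class KeywordMatcher:
    """Token-trie phrase matcher (longest-match-first, non-overlapping).

    Phrases are token sequences; scanning walks the text left to right and at
    every position takes the longest registered phrase, then resumes after it.
    """

    def __init__(self) -> None:
        self._trie: dict = {}

    def add(self, phrase: str, payload) -> None:
        tokens = tokenize(phrase)
        if not tokens:
            raise ValueError(f"phrase {phrase!r} has no word tokens")
        node = self._trie
        for tok in tokens:
            node = node.setdefault(tok, {})
        node.setdefault(_LEAF, []).append(payload)

    def extract(self, text: str) -> set:
        """Payloads of all phrases found in *text*."""
        tokens = tokenize(text)
        found: set = set()
        i, n = 0, len(tokens)
        while i < n:
            node = self._trie
            best_end = -1
            best_payloads = None
            j = i
            while j < n and tokens[j] in node:
                node = node[tokens[j]]
                j += 1
                if _LEAF in node:
                    best_end, best_payloads = j, node[_LEAF]
            if best_payloads is not None:
                found.update(best_payloads)
                i = best_end
            else:
                i += 1
        return found


class AnnotationMatrix:
    """Patient-level feature flags: (test_id, feature_id) -> set of patients.

    A patient is flagged at most once per (test, feature) regardless of how
    many notes or mentions they have.
    """

    def __init__(self) -> None:
        self._flags: dict[tuple[str, str], set[str]] = {}
        self.skipped_notes: int = 0

    def flag(self, test_id: str, feature_id: str, patient_id: str) -> None:
        self._flags.setdefault((test_id, feature_id), set()).add(patient_id)

    def patients(self, test_id: str, feature_id: str) -> frozenset[str]:
        return frozenset(self._flags.get((test_id, feature_id), ()))

    def count(self, test_id: str, feature_id: str, group: Iterable[str]) -> int:
        flagged = self._flags.get((test_id, feature_id))
        if not flagged:
            return 0
        group_set = group if isinstance(group, (set, frozenset)) else set(group)
        return len(flagged & group_set)

    def pairs(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._flags))

    def to_frame(self):
        import pandas as pd

        rows = [
            (t, f, p)
            for (t, f) in sorted(self._flags)
            for p in sorted(self._flags[(t, f)])
        ]
        return pd.DataFrame(rows, columns=["test_id", "feature_id", "patient_id"])


def build_matcher(lexicon: Iterable[FeatureLexiconEntry]) -> KeywordMatcher:
    matcher = KeywordMatcher()
    for entry in lexicon:
        for surface in entry.surfaces():
            matcher.add(surface, entry)
    return matcher


def annotate(
    notes: Iterable[Mapping],
    lexicon: Iterable[FeatureLexiconEntry],
) -> AnnotationMatrix:
    """Flag patients for features mentioned in their notes.

    *notes* is an iterable of mappings with at least ``patient_id`` and
    ``text``.  Unreadable records are skipped with a logged warning and
    counted in ``AnnotationMatrix.skipped_notes``.
    """
    lexicon = list(lexicon)
    if not lexicon:
        raise LexiconError("annotate() requires a non-empty lexicon")
    matcher = build_matcher(lexicon)
    matrix = AnnotationMatrix()
    for note in notes:
        try:
            patient_id = note["patient_id"]
            text = note["text"]
            if not isinstance(patient_id, str) or not isinstance(text, str):
                raise TypeError("patient_id and text must be strings")
        except (KeyError, TypeError, IndexError) as exc:
            matrix.skipped_notes += 1
            logger.warning('{"event": "note_skipped", "reason": "%s"}', exc)
            continue
        for entry in matcher.extract(text):
            for test_id in entry.test_ids:
                matrix.flag(test_id, entry.feature_id, patient_id)
    if matrix.skipped_notes:
        logger.info(
            '{"event": "notes_skipped_total", "count": %d}', matrix.skipped_notes
        )
    return matrix


def retain_features(
    matrix: AnnotationMatrix,
    groups,
    lexicon: Iterable[FeatureLexiconEntry],
    mode: str = "conjunction",
) -> set[tuple[str, str]]:
    """Apply the mention-retention filter.

    A feature is retained for a test when at least one positive-group and at
    least one negative-group patient mention it (``mode="conjunction"``, the
    default; this guarantees a finite, positive odds ratio for every retained
    feature).  ``mode="disjunction"`` keeps features mentioned in either
    group.  Tests whose retained set is empty are dropped downstream; a
    notice is logged here.
    """
    if mode not in ("conjunction", "disjunction"):
        raise ValueError(f"unknown retention mode {mode!r}")
    retained: set[tuple[str, str]] = set()
    per_test: dict[str, int] = {t: 0 for t in groups.test_ids()}
    for entry in lexicon:
        for test_id in entry.test_ids:
            if test_id not in per_test:
                continue
            c_p = matrix.count(test_id, entry.feature_id, groups.positives(test_id))
            c_n = matrix.count(test_id, entry.feature_id, groups.negatives(test_id))
            keep = (c_p >= 1 and c_n >= 1) if mode == "conjunction" else (
                c_p >= 1 or c_n >= 1
            )
            if keep:
                retained.add((test_id, entry.feature_id))
                per_test[test_id] += 1
    for test_id, n_kept in sorted(per_test.items()):
        if n_kept == 0:
            logger.info(
                '{"event": "test_dropped_no_retained_features", "test_id": "%s"}',
                test_id,
            )
    return retained
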