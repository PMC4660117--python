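"""Synthetic EHR cohort generation.

Two generators share one output schema (test-record CSV, clinical-note JSONL,
feature-lexicon TSV, reference-id list, test catalog CSV):

* :func:`generate_fixture` builds a fully deterministic cohort from explicit
  per-group sizes and per-(test, feature) patient mention counts, so that the
  downstream pipeline reproduces those numbers exactly.  The packaged study
  tables (:func:`load_paper_spec`) are the canonical input.
* :func:`generate_stochastic` draws feature mentions per patient as
  independent Bernoulli trials with configurable per-group prevalences, for
  parameter-recovery experiments with a known true odds ratio.

Mention planting writes one neutral sentence per carried surface form
("Assessment notes Emphysema."), so the dictionary matcher's recall on
generated cohorts is exactly 1 by construction.  Group sizes |P|, |N|, |T|
and |A| are treated as independent quantities: when |P| + |N| exceeds |T|,
the surplus patients receive an additional cancelled duplicate order (their
completed result still classifies them), and when |T| exceeds |P| + |N| the
shortfall is filled with unclassifiable results that land in T only.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotator import FeatureLexiconEntry, write_lexicon

RESULT_TEXT = {
    "POSITIVE": "One copy of the targeted mutation was identified.",
    "NEGATIVE": "None of the listed mutations were detected.",
    "CANCELLED": (
        "Test canceled, ordered in duplicate with a previous order. NO CHARGE"
    ),
    "UNKNOWN": "Specimen received; interpretation to follow.",
}

_SENTENCE_TEMPLATE = "Assessment notes {term}."
_NOTE_DATE = "2013-06-01"


class SpecValidationError(ValueError):
    """Invalid cohort specification; the message names the offending cell."""


@dataclass(frozen=True)
class TestSpec:
    test_id: str
    test_name: str
    disorder: str
    size_T: int
    size_P: int
    size_N: int
    lexicon_size: int | None = None


@dataclass(frozen=True)
class FeatureCell:
    """Mention counts for one (test, feature) pair in the four groups."""

    n_A: int
    n_T: int
    n_P: int
    n_N: int


@dataclass
class LexiconRowSpec:
    """One lexicon row: a term plus per-test mention counts.

    A row may span several tests (a feature shared between disorders); its
    background count must then be identical across those tests, because one
    shared population is matched against one surface form.
    """

    term: str
    cells: dict[str, FeatureCell]
    synonyms: tuple[str, ...] = ()


@dataclass
class CohortSpec:
    tests: list[TestSpec]
    population_size: int
    rows: list[LexiconRowSpec]
    filler_shared: list[tuple[tuple[str, str], int]] = field(default_factory=list)
    filler_singles: dict[str, int] = field(default_factory=dict)
    seed: int = 0


@dataclass
class PrevalenceSpec:
    """Stochastic cohort: per-(test, feature) Bernoulli prevalences."""

    tests: list[TestSpec]
    population_size: int
    features: list[dict]  # term, test_id, prev_P, prev_N, prev_A
    seed: int = 0


@dataclass
class Cohort:
    """In-memory synthetic cohort; ``write`` serializes deterministically."""

    records: pd.DataFrame
    notes: list[dict]
    lexicon: list[FeatureLexiconEntry]
    reference_ids: list[str]
    catalog: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": outdir / "records.csv",
            "notes": outdir / "notes.jsonl",
            "lexicon": outdir / "lexicon.tsv",
            "reference_ids": outdir / "reference_ids.txt",
            "catalog": outdir / "catalog.csv",
        }
        self.records.to_csv(paths["records"], index=False, lineterminator="\n")
        with open(paths["notes"], "w", encoding="utf-8", newline="\n") as handle:
            for note in self.notes:
                handle.write(json.dumps(note, sort_keys=True) + "\n")
        write_lexicon(self.lexicon, paths["lexicon"])
        with open(
            paths["reference_ids"], "w", encoding="utf-8", newline="\n"
        ) as handle:
            for pid in self.reference_ids:
                handle.write(pid + "\n")
        self.catalog.to_csv(paths["catalog"], index=False, lineterminator="\n")
        return paths


def _concept_id(term: str, disorder: str) -> str:
    digest = hashlib.md5(f"{disorder}|{term}".encode()).hexdigest()
    return "C" + str(int(digest[:12], 16) % 10_000_000).zfill(7)


def _alnum(term: str) -> str:
    return re.sub(r"[^0-9a-zA-Z]+", "", term).lower()


def _private_synonym(term: str, test_id: str) -> str:
    """A single-token surface unique to one row.

    Being one alphanumeric token, it can never word-boundary-match any other
    lexicon term, and no other term can match inside it.
    """
    return f"{_alnum(term)}q{test_id}"


def load_paper_spec() -> CohortSpec:
    """The packaged study tables as a :class:`CohortSpec`."""
    return _spec_from_tables(load_paper_tables())


def load_paper_tables() -> dict:
    ref = resources.files("igtkb.data").joinpath("paper_tables.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def _spec_from_tables(tables: dict) -> CohortSpec:
    tests = [
        TestSpec(
            test_id=t["test_id"],
            test_name=t["test_name"],
            disorder=t["disorder"],
            size_T=t["size_T"],
            size_P=t["size_P"],
            size_N=t["size_N"],
            lexicon_size=t.get("lexicon_size"),
        )
        for t in tables["tests"]
    ]
    rows = []
    for row in tables["rows"]:
        cells = {
            test_id: FeatureCell(
                n_A=cell["n_A"], n_T=cell["n_T"], n_P=cell["n_P"], n_N=cell["n_N"]
            )
            for test_id, cell in row["tests"].items()
        }
        rows.append(LexiconRowSpec(term=row["term"], cells=cells))
    filler = tables.get("filler_rows", {})
    shared = [
        ((f["tests"][0], f["tests"][1]), f["count"])
        for f in filler.get("shared", [])
    ]
    singles = dict(filler.get("singles", {}))
    return CohortSpec(
        tests=tests,
        population_size=tables["population_size"],
        rows=rows,
        filler_shared=shared,
        filler_singles=singles,
    )


def printed_stats_frame(tables: dict | None = None) -> pd.DataFrame:
    """The published per-(test, feature) statistics as a comparison frame."""
    tables = tables if tables is not None else load_paper_tables()
    out = []
    for row in tables["rows"]:
        for test_id, cell in row["tests"].items():
            printed = cell["printed"]
            out.append(
                {
                    "test_id": test_id,
                    "term": row["term"],
                    "n_A": cell["n_A"],
                    "n_T": cell["n_T"],
                    "n_N": cell["n_N"],
                    "n_P": cell["n_P"],
                    "freq_A": printed["freq_A"],
                    "freq_T": printed["freq_T"],
                    "freq_N": printed["freq_N"],
                    "freq_P": printed["freq_P"],
                    "or_pn": printed["or_pn"],
                    "dominant": bool(printed["dominant"]),
                }
            )
    return pd.DataFrame(out)


def _validate_cohort_spec(spec: CohortSpec) -> None:
    test_ids = [t.test_id for t in spec.tests]
    if len(set(test_ids)) != len(test_ids):
        raise SpecValidationError("duplicate test_id in spec")
    by_id = {t.test_id: t for t in spec.tests}
    for t in spec.tests:
        for name in ("size_T", "size_P", "size_N"):
            if getattr(t, name) < 0:
                raise SpecValidationError(f"test {t.test_id}: {name} < 0")
    if spec.population_size < 0:
        raise SpecValidationError("population_size < 0")
    for row in spec.rows:
        n_a_values = set()
        for test_id, cell in row.cells.items():
            if test_id not in by_id:
                raise SpecValidationError(
                    f"feature {row.term!r}: unknown test {test_id!r}"
                )
            t = by_id[test_id]
            label = f"(test {test_id}, feature {row.term!r})"
            for value, bound, names in (
                (cell.n_A, spec.population_size, "n_A <= |A|"),
                (cell.n_T, t.size_T, "n_T <= |T|"),
                (cell.n_P, t.size_P, "n_P <= |P|"),
                (cell.n_N, t.size_N, "n_N <= |N|"),
            ):
                if value < 0 or value > bound:
                    raise SpecValidationError(f"{label}: violates {names}")
            n_a_values.add(cell.n_A)
        if len(n_a_values) > 1:
            raise SpecValidationError(
                f"feature {row.term!r}: rows spanning several tests must have "
                f"one background count, got {sorted(n_a_values)}"
            )
    # group-structure feasibility per test
    for t in spec.tests:
        surplus_t = t.size_T - t.size_P - t.size_N  # unknown-result patients
        shortfall = -surplus_t  # cancelled duplicate orders
        max_n_n = max(
            (row.cells[t.test_id].n_N for row in spec.rows if t.test_id in row.cells),
            default=0,
        )
        for row in spec.rows:
            cell = row.cells.get(t.test_id)
            if cell is None:
                continue
            label = f"(test {t.test_id}, feature {row.term!r})"
            n_u = cell.n_T - cell.n_P - cell.n_N
            if surplus_t >= 0:
                if n_u < 0 or n_u > surplus_t:
                    raise SpecValidationError(
                        f"{label}: n_T - n_P - n_N = {n_u} not achievable with "
                        f"{surplus_t} unknown-result patients"
                    )
            elif n_u != 0:
                raise SpecValidationError(
                    f"{label}: |P| + |N| > |T| requires n_T = n_P + n_N"
                )
        if shortfall > 0 and max_n_n > t.size_N - shortfall:
            raise SpecValidationError(
                f"test {t.test_id}: cannot place {shortfall} cancelled "
                f"duplicates among mention-free negative patients"
            )


def _build_lexicon(spec: CohortSpec) -> tuple[list[FeatureLexiconEntry], dict]:
    """Lexicon entries for all rows, plus the extra-synonym plan for group A.

    Where two rows share a preferred term but disagree on the background
    count, the smaller count is planted with the shared term and each row's
    excess with a private single-token synonym, emulating per-disorder
    dictionaries that differ slightly between extraction runs.  Filler rows
    beyond the published terms are synthetic stand-ins with zero mentions.
    """
    disorder_of = {t.test_id: t.disorder for t in spec.tests}
    rows: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = []  # term, syns, tests

    by_term: dict[str, list[int]] = {}
    for idx, row in enumerate(spec.rows):
        by_term.setdefault(row.term.lower(), []).append(idx)

    extra_synonyms: dict[int, tuple[str, int]] = {}  # row idx -> (surface, count)
    for term, idxs in by_term.items():
        counts = [next(iter(spec.rows[i].cells.values())).n_A for i in idxs]
        base = min(counts)
        for i, count in zip(idxs, counts):
            if count > base:
                test_id = sorted(spec.rows[i].cells)[0]
                extra_synonyms[i] = (
                    _private_synonym(spec.rows[i].term, test_id),
                    count - base,
                )

    entries: list[FeatureLexiconEntry] = []
    for idx, row in enumerate(spec.rows):
        syns = list(row.synonyms)
        if idx in extra_synonyms:
            syns.append(extra_synonyms[idx][0])
        tests = tuple(sorted(row.cells))
        entries.append(
            FeatureLexiconEntry(
                feature_id=f"CF:{idx + 1:07d}",
                preferred_term=row.term,
                synonyms=tuple(syns),
                concept_id=_concept_id(row.term, disorder_of[tests[0]]),
                disorder=disorder_of[tests[0]],
                test_ids=tests,
            )
        )

    # synthetic filler rows: zero mentions everywhere, present only so the
    # per-test lexicon sizes match the study's feature inventory
    filler_index = 0
    filler_specs: list[tuple[str, ...]] = []
    for (test_a, test_b), count in spec.filler_shared:
        for _ in range(count):
            filler_specs.append((test_a, test_b))
    for test_id in sorted(spec.filler_singles):
        for _ in range(spec.filler_singles[test_id]):
            filler_specs.append((test_id,))
    for tests in filler_specs:
        filler_index += 1
        term = f"Synthetic phenotype {filler_index:03d}"
        entries.append(
            FeatureLexiconEntry(
                feature_id=f"CF:{len(spec.rows) + filler_index:07d}",
                preferred_term=term,
                synonyms=(),
                concept_id=_concept_id(term, disorder_of[tests[0]]),
                disorder=disorder_of[tests[0]],
                test_ids=tuple(tests),
            )
        )
    return entries, extra_synonyms


def _record(
    pid: str,
    test: TestSpec,
    index: int,
    result_key: str,
    reported_date: str = "2013-03-15",
) -> dict:
    return {
        "patient_id": pid,
        "test_id": test.test_id,
        "test_name": test.test_name,
        "dob": f"19{50 + index % 50}-01-01",
        "gender": "F" if index % 2 else "M",
        "reported_date": reported_date,
        "collected_date": "2013-03-10",
        "received_date": "2013-03-11",
        "reason_for_referral": f"Evaluation for {test.disorder}",
        "result_text": RESULT_TEXT[result_key],
        "interpretation_text": "Refer to result text.",
    }


def _notes_from_sentences(
    sentences_by_patient: dict[str, list[str]]
) -> list[dict]:
    notes = []
    for pid, sentences in sentences_by_patient.items():
        notes.append(
            {
                "patient_id": pid,
                "note_id": f"{pid}-note1",
                "date": _NOTE_DATE,
                "text": " ".join(sentences),
            }
        )
    return notes


def generate_fixture(spec: CohortSpec) -> Cohort:
    """Deterministic cohort whose pipeline output equals the spec's counts.

    Mentioned patients receive exactly one planted sentence per carried
    surface form; all other patients' notes (none are emitted) contain no
    lexicon term.  Regeneration from the same spec is byte-identical.
    """
    _validate_cohort_spec(spec)
    entries, extra_synonyms = _build_lexicon(spec)

    catalog = pd.DataFrame(
        [
            {"test_id": t.test_id, "test_name": t.test_name, "disorder": t.disorder}
            for t in spec.tests
        ]
    )

    # --- background population A -------------------------------------------
    width = max(6, len(str(max(spec.population_size - 1, 1))))
    reference_ids = [f"A{i:0{width}d}" for i in range(spec.population_size)]

    # surface -> (first patient index, carrier count); excess carriers of a
    # row-private synonym sit directly after the shared-term carriers
    surface_plan: dict[str, tuple[int, int]] = {}
    by_term: dict[str, list[LexiconRowSpec]] = {}
    for row in spec.rows:
        by_term.setdefault(row.term.lower(), []).append(row)
    base_of: dict[str, int] = {}
    for term_key, rows in by_term.items():
        term = rows[0].term
        base = min(next(iter(r.cells.values())).n_A for r in rows)
        base_of[term_key] = base
        if base:
            surface_plan[term] = (0, base)
    for idx, (surface, count) in extra_synonyms.items():
        surface_plan[surface] = (base_of[spec.rows[idx].term.lower()], count)

    plant_order = sorted(
        surface_plan.items(), key=lambda kv: (-kv[1][1], kv[0])
    )
    a_sentences: dict[str, list[str]] = {}
    for surface, (start, count) in plant_order:
        sentence = _SENTENCE_TEMPLATE.format(term=surface)
        for i in range(start, start + count):
            a_sentences.setdefault(reference_ids[i], []).append(sentence)

    notes: list[dict] = _notes_from_sentences(a_sentences)

    # --- per-test groups ----------------------------------------------------
    records: list[dict] = []
    for test in spec.tests:
        p_ids = [f"P{test.test_id}-{i:04d}" for i in range(test.size_P)]
        n_ids = [f"N{test.test_id}-{i:04d}" for i in range(test.size_N)]
        surplus_t = test.size_T - test.size_P - test.size_N
        u_ids = [f"U{test.test_id}-{i:04d}" for i in range(max(surplus_t, 0))]
        dup_cancelled = n_ids[len(n_ids) + surplus_t:] if surplus_t < 0 else []

        group_sentences: dict[str, list[str]] = {}
        test_rows = sorted(
            (row for row in spec.rows if test.test_id in row.cells),
            key=lambda r: (-r.cells[test.test_id].n_T, r.term),
        )
        for row in test_rows:
            cell = row.cells[test.test_id]
            sentence = _SENTENCE_TEMPLATE.format(term=row.term)
            for pid in p_ids[: cell.n_P]:
                group_sentences.setdefault(pid, []).append(sentence)
            for pid in n_ids[: cell.n_N]:
                group_sentences.setdefault(pid, []).append(sentence)
            n_u = cell.n_T - cell.n_P - cell.n_N
            for pid in u_ids[:n_u]:
                group_sentences.setdefault(pid, []).append(sentence)

        notes.extend(_notes_from_sentences(group_sentences))

        for i, pid in enumerate(p_ids):
            records.append(_record(pid, test, i, "POSITIVE"))
        for i, pid in enumerate(n_ids):
            records.append(_record(pid, test, i, "NEGATIVE"))
        for i, pid in enumerate(u_ids):
            records.append(_record(pid, test, i, "UNKNOWN"))
        for i, pid in enumerate(dup_cancelled):
            records.append(
                _record(pid, test, i, "CANCELLED", reported_date="2013-03-20")
            )

    records_frame = pd.DataFrame(records, columns=list(RECORD_COLUMNS_ORDER))
    return Cohort(
        records=records_frame,
        notes=notes,
        lexicon=entries,
        reference_ids=reference_ids,
        catalog=catalog,
    )


RECORD_COLUMNS_ORDER = (
    "patient_id",
    "test_id",
    "test_name",
    "dob",
    "gender",
    "reported_date",
    "collected_date",
    "received_date",
    "reason_for_referral",
    "result_text",
    "interpretation_text",
)


def _validate_prevalence_spec(spec: PrevalenceSpec) -> None:
    test_ids = {t.test_id for t in spec.tests}
    for t in spec.tests:
        if t.size_P < 0 or t.size_N < 0:
            raise SpecValidationError(f"test {t.test_id}: negative group size")
    for feat in spec.features:
        if feat["test_id"] not in test_ids:
            raise SpecValidationError(
                f"feature {feat['term']!r}: unknown test {feat['test_id']!r}"
            )
        for key in ("prev_P", "prev_N", "prev_A"):
            value = feat.get(key, 0.0)
            if not 0.0 <= value <= 1.0:
                raise SpecValidationError(
                    f"(test {feat['test_id']}, feature {feat['term']!r}): "
                    f"{key} = {value} outside [0, 1]"
                )


def generate_stochastic(spec: PrevalenceSpec) -> Cohort:
    """Bernoulli cohort: each patient carries each feature independently with
    the prevalence of their group.  Identical seeds yield identical output."""
    _validate_prevalence_spec(spec)
    rng = np.random.default_rng(spec.seed)

    disorder_of = {t.test_id: t.disorder for t in spec.tests}
    entries = []
    feats_by_test: dict[str, list[dict]] = {}
    for idx, feat in enumerate(spec.features):
        feats_by_test.setdefault(feat["test_id"], []).append(feat)
        entries.append(
            FeatureLexiconEntry(
                feature_id=f"CF:{idx + 1:07d}",
                preferred_term=feat["term"],
                synonyms=(),
                concept_id=_concept_id(feat["term"], disorder_of[feat["test_id"]]),
                disorder=disorder_of[feat["test_id"]],
                test_ids=(feat["test_id"],),
            )
        )

    catalog = pd.DataFrame(
        [
            {"test_id": t.test_id, "test_name": t.test_name, "disorder": t.disorder}
            for t in spec.tests
        ]
    )

    records: list[dict] = []
    notes: list[dict] = []
    for test in spec.tests:
        p_ids = [f"P{test.test_id}-{i:05d}" for i in range(test.size_P)]
        n_ids = [f"N{test.test_id}-{i:05d}" for i in range(test.size_N)]
        sentences: dict[str, list[str]] = {}
        for feat in feats_by_test.get(test.test_id, []):
            sentence = _SENTENCE_TEMPLATE.format(term=feat["term"])
            for ids, prev in ((p_ids, feat["prev_P"]), (n_ids, feat["prev_N"])):
                if ids:
                    mask = rng.random(len(ids)) < prev
                    for pid in np.asarray(ids)[mask]:
                        sentences.setdefault(pid, []).append(sentence)
        notes.extend(_notes_from_sentences(sentences))
        for i, pid in enumerate(p_ids):
            records.append(_record(pid, test, i, "POSITIVE"))
        for i, pid in enumerate(n_ids):
            records.append(_record(pid, test, i, "NEGATIVE"))

    width = max(6, len(str(max(spec.population_size - 1, 1))))
    reference_ids = [f"A{i:0{width}d}" for i in range(spec.population_size)]
    if spec.population_size:
        a_sentences: dict[str, list[str]] = {}
        for feat in spec.features:
            sentence = _SENTENCE_TEMPLATE.format(term=feat["term"])
            mask = rng.random(spec.population_size) < feat.get("prev_A", 0.0)
            for pid in np.asarray(reference_ids)[mask]:
                a_sentences.setdefault(pid, []).append(sentence)
        notes.extend(_notes_from_sentences(a_sentences))

    records_frame = pd.DataFrame(records, columns=list(RECORD_COLUMNS_ORDER))
    return Cohort(
        records=records_frame,
        notes=notes,
        lexicon=entries,
        reference_ids=reference_ids,
        catalog=catalog,
    )


def load_prevalence_spec(path) -> PrevalenceSpec:
    """Read a stochastic-cohort specification from YAML."""
    with open(path, encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)
    tests = [
        TestSpec(
            test_id=str(t["test_id"]),
            test_name=t.get("test_name", str(t["test_id"])),
            disorder=t.get("disorder", "synthetic disorder"),
            size_T=t.get("size_P", 0) + t.get("size_N", 0),
            size_P=t["size_P"],
            size_N=t["size_N"],
        )
        for t in payload["tests"]
    ]
    features = [
        {
            "term": f["term"],
            "test_id": str(f["test_id"]),
            "prev_P": float(f.get("prev_P", 0.0)),
            "prev_N": float(f.get("prev_N", 0.0)),
            "prev_A": float(f.get("prev_A", 0.0)),
        }
        for f in payload.get("features", [])
    ]
    return PrevalenceSpec(
        tests=tests,
        population_size=int(payload.get("population_size", 0)),
        features=features,
        seed=int(payload.get("seed", 0)),
    )
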