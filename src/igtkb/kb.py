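"""Knowledge-base assembly and feature-driven test recommendation.

Each knowledge-base entry links a genetic test and its disorder to one
clinical feature, weighted by the positive-vs-negative odds ratio (the
ranking weight) and the tested-vs-background odds ratio (the prevalence
weight).  By default only dominant features (odds ratio > 1) are deposited;
non-dominant features can be retained with their flag, since a feature with
a low P-vs-N ratio but a very high prevalence weight can still be a key
prescription signal.

Recommendation scores a test by summing the odds-ratio weights of its
dominant entries matched by the observed features (additive rule by
default; ``max`` and ``count`` rules are available for sensitivity
analysis).  Observed features may be given as feature ids, preferred terms,
or synonyms, case-insensitively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class KBEntry:
    test_id: str
    test_name: str
    disorder: str
    feature_id: str
    term: str
    concept_id: str
    or_weight: float
    prevalence_weight: float
    freq_P: float
    freq_N: float
    dominant: bool
    synonyms: tuple[str, ...] = ()


class KBError(ValueError):
    pass


def build_kb(
    stats: pd.DataFrame,
    test_catalog: Iterable[tuple[str, str, str]],
    dominant_only: bool = True,
    lexicon=None,
) -> list[KBEntry]:
    """Assemble knowledge-base entries from the statistics table.

    *test_catalog* lists (test_id, test_name, disorder); every test in
    *stats* must appear in it.  With ``dominant_only`` (default) only
    features whose odds ratio exceeds 1 are deposited; otherwise all
    retained features are kept with their dominance flag.
    """
    catalog = {}
    for test_id, test_name, disorder in test_catalog:
        catalog.setdefault(str(test_id), []).append((test_name, disorder))
    synonyms_of = {}
    concept_of = {}
    if lexicon is not None:
        for entry in lexicon:
            synonyms_of[entry.feature_id] = tuple(entry.synonyms)
            concept_of[entry.feature_id] = entry.concept_id

    entries: list[KBEntry] = []
    seen: set[tuple[str, str]] = set()
    for row in stats.itertuples(index=False):
        if row.test_id not in catalog:
            raise KBError(f"test {row.test_id!r} missing from the test catalog")
        if dominant_only and not row.dominant:
            continue
        key = (row.test_id, row.feature_id)
        if key in seen:
            raise KBError(f"duplicate KB entry for {key}")
        seen.add(key)
        test_name, disorder = catalog[row.test_id][0]
        entries.append(
            KBEntry(
                test_id=row.test_id,
                test_name=test_name,
                disorder=disorder,
                feature_id=row.feature_id,
                term=row.term,
                concept_id=concept_of.get(row.feature_id, ""),
                or_weight=float(row.or_pn),
                prevalence_weight=float(row.or_ta),
                freq_P=float(row.freq_P),
                freq_N=float(row.freq_N),
                dominant=bool(row.dominant),
                synonyms=synonyms_of.get(row.feature_id, ()),
            )
        )
    return entries


def save_kb(entries: Sequence[KBEntry], path) -> None:
    payload = {
        "igtkb_schema": SCHEMA_VERSION,
        "entries": [
            {**asdict(e), "synonyms": list(e.synonyms)} for e in entries
        ],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
        handle.write("\n")


def load_kb(path) -> list[KBEntry]:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    if payload.get("igtkb_schema") != SCHEMA_VERSION:
        raise KBError(
            f"unsupported knowledge-base schema {payload.get('igtkb_schema')!r}"
        )
    entries = []
    for item in payload["entries"]:
        item = dict(item)
        item["synonyms"] = tuple(item.get("synonyms", ()))
        entries.append(KBEntry(**item))
    return entries


def kb_to_tsv(entries: Sequence[KBEntry], path) -> None:
    frame = pd.DataFrame(
        [{**asdict(e), "synonyms": "|".join(e.synonyms)} for e in entries]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def recommend(
    kb: Sequence[KBEntry],
    observed: Iterable[str],
    rule: str = "sum",
) -> dict:
    """Rank tests for a set of observed clinical features.

    Returns ``{"recommendations": [...], "unmatched": [...]}``.  A test's
    score combines the odds-ratio weights of its matched dominant entries
    (``sum`` by default, or ``max`` / ``count``); tests with no match are
    omitted.  Results are sorted by descending score, ties broken by
    test_id.  Observed features that match nothing are reported in
    ``unmatched``, never raised.
    """
    if rule not in ("sum", "max", "count"):
        raise ValueError(f"unknown combining rule {rule!r}")
    kb = list(kb)
    if not kb:
        raise KBError("recommend() requires a non-empty knowledge base")

    index: dict[str, list[KBEntry]] = {}
    for entry in kb:
        for key in (entry.feature_id, entry.term, *entry.synonyms):
            index.setdefault(key.casefold().strip(), []).append(entry)

    matched_by_test: dict[str, dict] = {}
    unmatched: list[str] = []
    for raw in observed:
        key = raw.casefold().strip()
        hits = [e for e in index.get(key, ()) if e.dominant]
        if not hits:
            unmatched.append(raw)
            continue
        for entry in hits:
            bucket = matched_by_test.setdefault(
                entry.test_id,
                {
                    "test_name": entry.test_name,
                    "disorder": entry.disorder,
                    "weights": [],
                    "matched_features": [],
                },
            )
            if entry.term not in bucket["matched_features"]:
                bucket["weights"].append(entry.or_weight)
                bucket["matched_features"].append(entry.term)

    recommendations = []
    for test_id, bucket in matched_by_test.items():
        weights = bucket["weights"]
        score = {
            "sum": sum(weights),
            "max": max(weights),
            "count": float(len(weights)),
        }[rule]
        recommendations.append(
            {
                "test_id": test_id,
                "test_name": bucket["test_name"],
                "disorder": bucket["disorder"],
                "score": score,
                "matched_features": sorted(bucket["matched_features"]),
            }
        )
    recommendations.sort(key=lambda r: (-r["score"], r["test_id"]))
    return {"recommendations": recommendations, "unmatched": unmatched}
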