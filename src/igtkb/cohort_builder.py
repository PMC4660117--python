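"""Test-record parsing, result classification, and patient-group composition.

Each genetic-test order carries a free-text result drawn from a small set of
laboratory category strings ("None of the listed mutations were detected.",
"One copy of the deltaF508 mutation in exon 10 was identified.", "Test
canceled, ordered in duplicate ...").  An ordered, case-insensitive regex
rule set maps each result to POSITIVE / NEGATIVE / CANCELLED / UNKNOWN; the
first matching rule wins.

Per test, four analysis groups are formed:

* T (tested): patients whose order completed — any patient with a cancelled
  order is excluded from T, including patients whose duplicate order was
  cancelled while another completed;
* P / N: patients with a positive / negative classified result;
* A: the background reference population, supplied as an explicit id list.

P and N are disjoint within a test.  Because cancelled duplicate orders
remove a patient from T without removing their classified result, |P| + |N|
may legitimately exceed |T| under the ``aggregate`` duplicate policy; within
T itself every patient is positive, negative, or unknown.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable

import pandas as pd
import yaml

logger = logging.getLogger("igtkb")

RECORD_COLUMNS = (
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


class ResultLabel(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    CANCELLED = "CANCELLED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ClassificationRule:
    pattern: re.Pattern
    label: ResultLabel


@dataclass(frozen=True)
class ClassificationRuleSet:
    """Ordered result-classification rules; the first match wins."""

    rules: tuple[ClassificationRule, ...]
    default: ResultLabel = ResultLabel.UNKNOWN

    @classmethod
    def from_dict(cls, payload: dict) -> "ClassificationRuleSet":
        rules = []
        for item in payload.get("rules", []):
            rules.append(
                ClassificationRule(
                    pattern=re.compile(item["pattern"], re.IGNORECASE),
                    label=ResultLabel(item["label"]),
                )
            )
        default = ResultLabel(payload.get("default", "UNKNOWN"))
        return cls(rules=tuple(rules), default=default)

    @classmethod
    def from_yaml(cls, path) -> "ClassificationRuleSet":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle))

    @classmethod
    def default_rules(cls) -> "ClassificationRuleSet":
        """The packaged rule set mirroring the DLMP category strings."""
        ref = resources.files("igtkb.data").joinpath("default_rules.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def classify_result(result_text: str, rules: ClassificationRuleSet) -> ResultLabel:
    """Label of the first rule whose pattern matches, else the default.

    Total function: any text (including empty) yields a label.
    """
    if not rules.rules:
        raise ValueError("classification rule set is empty")
    for rule in rules.rules:
        if rule.pattern.search(result_text or ""):
            return rule.label
    return rules.default


@dataclass(frozen=True)
class GroupAssignment:
    """Per-test patient-id sets P, N, T plus the global reference set A."""

    per_test: dict
    reference_ids: frozenset
    unknown_counts: dict = field(default_factory=dict)

    def test_ids(self) -> list[str]:
        return sorted(self.per_test)

    def positives(self, test_id: str) -> frozenset:
        return self.per_test[test_id]["P"]

    def negatives(self, test_id: str) -> frozenset:
        return self.per_test[test_id]["N"]

    def tested(self, test_id: str) -> frozenset:
        return self.per_test[test_id]["T"]

    def sizes(self, test_id: str) -> dict:
        g = self.per_test[test_id]
        return {"T": len(g["T"]), "P": len(g["P"]), "N": len(g["N"]),
                "A": len(self.reference_ids)}

    def to_json(self, path) -> None:
        payload = {
            test_id: {k: sorted(v) for k, v in g.items()}
            for test_id, g in sorted(self.per_test.items())
        }
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
            handle.write("\n")


class DuplicateRecordError(ValueError):
    """Raised when a (patient, test) pair has several records under
    ``duplicate_policy="error"``."""


def read_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing record columns {sorted(missing)}")
    return frame


def build_groups(
    records: pd.DataFrame,
    reference_ids: Iterable[str],
    rules: ClassificationRuleSet,
    duplicate_policy: str = "error",
) -> GroupAssignment:
    """Compose the P/N/T groups per test from classified records.

    ``duplicate_policy`` controls multiple records per (patient, test):
    ``"error"`` (default) raises, ``"keep_latest"`` keeps the record with the
    latest reported date, ``"aggregate"`` keeps all records and combines
    their labels (any POSITIVE -> P; else any NEGATIVE -> N; any CANCELLED
    excludes the patient from T).  UNKNOWN-only patients stay in T outside
    P and N; their number is logged per test.
    """
    if duplicate_policy not in ("error", "keep_latest", "aggregate"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    reference = frozenset(reference_ids)
    if not reference:
        raise ValueError("reference_ids must be non-empty")
    if records.empty:
        return GroupAssignment(per_test={}, reference_ids=reference)
    if (records["patient_id"] == "").any() or (records["test_id"] == "").any():
        raise ValueError("records contain empty patient_id or test_id")

    records = records.copy()
    dup_mask = records.duplicated(subset=["patient_id", "test_id"], keep=False)
    if dup_mask.any():
        if duplicate_policy == "error":
            offender = records.loc[dup_mask, ["patient_id", "test_id"]].iloc[0]
            raise DuplicateRecordError(
                f"duplicate record for patient {offender['patient_id']!r}, "
                f"test {offender['test_id']!r}"
            )
        if duplicate_policy == "keep_latest":
            records = (
                records.sort_values("reported_date", kind="mergesort")
                .drop_duplicates(subset=["patient_id", "test_id"], keep="last")
            )

    records["label"] = [
        classify_result(text, rules).value for text in records["result_text"]
    ]

    per_test: dict = {}
    unknown_counts: dict = {}
    for test_id, chunk in records.groupby("test_id", sort=True):
        by_label = {
            label: set(chunk.loc[chunk["label"] == label, "patient_id"])
            for label in ("POSITIVE", "NEGATIVE", "CANCELLED", "UNKNOWN")
        }
        everyone = set(chunk["patient_id"])
        tested = everyone - by_label["CANCELLED"]
        positives = by_label["POSITIVE"]
        negatives = by_label["NEGATIVE"] - positives
        unknown = tested - positives - negatives
        per_test[test_id] = {
            "P": frozenset(positives),
            "N": frozenset(negatives),
            "T": frozenset(tested),
        }
        unknown_counts[test_id] = len(unknown)
        logger.info(
            '{"event": "groups_built", "test_id": "%s", "T": %d, "P": %d, '
            '"N": %d, "unknown_in_T": %d}',
            test_id,
            len(tested),
            len(positives),
            len(negatives),
            len(unknown),
        )
    return GroupAssignment(
        per_test=per_test, reference_ids=reference, unknown_counts=unknown_counts
    )


def read_reference_ids(path) -> frozenset:
    with open(path, encoding="utf-8") as handle:
        return frozenset(line.strip() for line in handle if line.strip())
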