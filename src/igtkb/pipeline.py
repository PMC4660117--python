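"""End-to-end orchestration: records + notes + lexicon -> statistics + KB.

The pipeline mirrors the four-step study design: select tests with enough
tested patients, compose the P/N/T/A groups from classified results, extract
feature mentions from notes, and prioritize features by odds ratio before
depositing dominant ones into the knowledge base.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import annotator, cohort_builder, kb as kb_mod, prioritizer
from .annotator import AnnotationMatrix, FeatureLexiconEntry
from .cohort_builder import ClassificationRuleSet, GroupAssignment
from .synthetic_ehr import Cohort

logger = logging.getLogger("igtkb")


@dataclass
class RunConfig:
    """Tunable pipeline knobs (paths are handled by the CLI layer)."""

    min_tested: int = 100
    duplicate_policy: str = "error"
    retention_mode: str = "conjunction"
    enrichment_criterion: str = "positive_excess"
    dominance_threshold: float = 1.0
    precision: int = 5
    dominant_only: bool = True
    allow_multi_disorder: bool = False
    with_ci: bool = False

    def __post_init__(self) -> None:
        if self.dominance_threshold <= 0:
            raise ValueError("dominance threshold must be > 0")
        if self.precision < 0:
            raise ValueError("reporting precision must be >= 0")


@dataclass
class RunResult:
    groups: GroupAssignment
    matrix: AnnotationMatrix
    retained: set
    stats: pd.DataFrame
    kb_entries: list
    excluded_tests: dict = field(default_factory=dict)


def _multi_disorder_tests(catalog: pd.DataFrame) -> set[str]:
    counts = catalog.groupby("test_id")["disorder"].nunique()
    return set(counts[counts > 1].index)


def run_pipeline(
    records: pd.DataFrame,
    notes: Iterable[Mapping],
    lexicon: Sequence[FeatureLexiconEntry],
    reference_ids: Iterable[str],
    rules: ClassificationRuleSet,
    catalog: pd.DataFrame,
    config: RunConfig | None = None,
) -> RunResult:
    """Run the full analysis on in-memory inputs."""
    config = config or RunConfig()
    groups = cohort_builder.build_groups(
        records, reference_ids, rules, duplicate_policy=config.duplicate_policy
    )

    excluded: dict[str, str] = {}
    multi = set() if config.allow_multi_disorder else _multi_disorder_tests(catalog)
    keep: dict = {}
    for test_id in groups.test_ids():
        if test_id in multi:
            excluded[test_id] = "multiple associated disorders"
        elif len(groups.tested(test_id)) < config.min_tested:
            excluded[test_id] = (
                f"fewer than {config.min_tested} tested patients"
            )
        else:
            keep[test_id] = groups.per_test[test_id]
    for test_id, reason in sorted(excluded.items()):
        logger.info(
            '{"event": "test_excluded", "test_id": "%s", "reason": "%s"}',
            test_id,
            reason,
        )
    groups = GroupAssignment(
        per_test=keep,
        reference_ids=groups.reference_ids,
        unknown_counts={t: groups.unknown_counts.get(t, 0) for t in keep},
    )

    matrix = annotator.annotate(notes, lexicon)
    retained = annotator.retain_features(
        matrix, groups, lexicon, mode=config.retention_mode
    )
    stats = prioritizer.compute_all(
        matrix,
        groups,
        retained,
        lexicon,
        enrichment_criterion=config.enrichment_criterion,
        dominance_threshold=config.dominance_threshold,
        with_ci=config.with_ci,
    )
    catalog_tuples = list(
        catalog[["test_id", "test_name", "disorder"]].itertuples(index=False)
    )
    entries = kb_mod.build_kb(
        stats, catalog_tuples, dominant_only=config.dominant_only, lexicon=lexicon
    )
    logger.info(
        '{"event": "pipeline_done", "tests": %d, "retained": %d, "dominant": %d}',
        len(groups.per_test),
        len(retained),
        int(stats["dominant"].sum()) if not stats.empty else 0,
    )
    return RunResult(
        groups=groups,
        matrix=matrix,
        retained=retained,
        stats=stats,
        kb_entries=entries,
        excluded_tests=excluded,
    )


def run_cohort(cohort: Cohort, config: RunConfig | None = None) -> RunResult:
    """Convenience wrapper running the pipeline on a generated cohort."""
    return run_pipeline(
        cohort.records,
        cohort.notes,
        cohort.lexicon,
        cohort.reference_ids,
        ClassificationRuleSet.default_rules(),
        cohort.catalog,
        config,
    )


def read_notes(path) -> list[dict]:
    notes = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                notes.append(json.loads(line))
    return notes


def write_outputs(result: RunResult, outdir, precision: int = 5) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stats": outdir / "feature_stats.tsv",
        "kb": outdir / "igtkb.json",
        "kb_tsv": outdir / "igtkb.tsv",
        "groups": outdir / "groups.json",
        "annotations": outdir / "annotations.tsv",
    }
    prioritizer.write_feature_stats(result.stats, paths["stats"], precision)
    kb_mod.save_kb(result.kb_entries, paths["kb"])
    kb_mod.kb_to_tsv(result.kb_entries, paths["kb_tsv"])
    result.groups.to_json(paths["groups"])
    result.matrix.to_frame().to_csv(
        paths["annotations"], sep="\t", index=False, lineterminator="\n"
    )
    return paths


def compare_to_printed(
    stats: pd.DataFrame, printed: pd.DataFrame, precision: int = 5
) -> list[str]:
    """Cell-by-cell diff of computed statistics against the published tables.

    Compares the (test, term) row sets, the four group counts, the four
    frequencies and the P-vs-N odds ratio at the tables' printed precision,
    and the dominance flags.  Returns human-readable difference lines; an
    empty list means exact agreement.
    """
    diffs: list[str] = []
    computed_keys = {(r.test_id, r.term) for r in stats.itertuples(index=False)}
    printed_keys = {(r.test_id, r.term) for r in printed.itertuples(index=False)}
    for key in sorted(printed_keys - computed_keys):
        diffs.append(f"missing row {key}")
    for key in sorted(computed_keys - printed_keys):
        diffs.append(f"unexpected row {key}")

    merged = stats.merge(
        printed, on=["test_id", "term"], suffixes=("", "_printed")
    )
    for row in merged.itertuples(index=False):
        where = f"({row.test_id}, {row.term})"
        for col in ("n_A", "n_T", "n_N", "n_P"):
            got = getattr(row, col)
            want = getattr(row, f"{col}_printed")
            if int(got) != int(want):
                diffs.append(f"{where} {col}: computed {got}, published {want}")
        for col in ("freq_A", "freq_T", "freq_N", "freq_P", "or_pn"):
            got = f"{getattr(row, col):.{precision}f}"
            want = getattr(row, f"{col}_printed")
            if got != want:
                diffs.append(f"{where} {col}: computed {got}, published {want}")
        if bool(row.dominant) != bool(row.dominant_printed):
            diffs.append(
                f"{where} dominant: computed {bool(row.dominant)}, "
                f"published {bool(row.dominant_printed)}"
            )
    return diffs
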