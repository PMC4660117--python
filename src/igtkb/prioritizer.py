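"""Per-group feature frequencies, odds ratios, and dominant-feature selection.

For each retained (test, feature) pair the patient-level mention counts in
the four groups give:

* the group frequency ``n_with / n_group`` (each group's own size is its
  denominator — the groups are treated as independent denominators, never as
  a partition);
* the positive-vs-negative odds ratio
  ``OR_PN = (n_P / (|P| - n_P)) / (n_N / (|N| - n_N))``, the dominance
  statistic;
* the tested-vs-background odds ratio
  ``OR_TA = (n_T / (|T| - n_T)) / (n_A / (|A| - n_A))``, the prevalence
  weight capturing how strongly the feature is over-represented among tested
  patients relative to the reference population.

No continuity correction is applied by default; the ratios are the plain
cross-product form.  Features with OR_PN strictly greater than 1 are marked
dominant.  Ranking uses the raw odds ratios; no p-values, confidence
intervals, or multiple-testing procedures enter the selection (Woolf
confidence limits are available as an optional output column only).
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd
from scipy import stats as _sps

from .annotator import AnnotationMatrix, FeatureLexiconEntry
from .cohort_builder import GroupAssignment

STATS_COLUMNS = (
    "test_id",
    "feature_id",
    "term",
    "n_A",
    "n_T",
    "n_N",
    "n_P",
    "freq_A",
    "freq_T",
    "freq_N",
    "freq_P",
    "or_pn",
    "or_ta",
    "enriched",
    "dominant",
)


class UndefinedFrequencyError(ValueError):
    """Frequency requested for an empty group."""


def frequency(n_with: int, n_total: int) -> float:
    """Proportion of patients in a group exhibiting the feature.

    Full precision; rounding to the reporting precision happens only at the
    output layer.
    """
    if n_total <= 0:
        raise UndefinedFrequencyError("group size must be >= 1")
    if not 0 <= n_with <= n_total:
        raise ValueError(f"count {n_with} outside [0, {n_total}]")
    return n_with / n_total


def odds_ratio(
    a: int, size_1: int, b: int, size_2: int, *, correction: bool = False
) -> float:
    """Cross-product odds ratio between two groups.

    ``(a / (size_1 - a)) / (b / (size_2 - b))``.  Degenerate cells yield
    sentinels instead of errors: a zero numerator odds gives ``0.0``, a zero
    denominator odds (or ``a == size_1``) gives ``+inf``, and a ratio of two
    degenerate odds gives ``nan``.  ``correction=True`` applies the
    Haldane–Anscombe 0.5 adjustment to every cell (off by default; the plain
    form is the reported statistic).
    """
    for value, size, name in ((a, size_1, "a"), (b, size_2, "b")):
        if size < 1:
            raise ValueError(f"group size for {name} must be >= 1")
        if value < 0 or value > size:
            raise ValueError(f"count {name}={value} outside [0, {size}]")
    if correction:
        num = (a + 0.5) / (size_1 - a + 0.5)
        den = (b + 0.5) / (size_2 - b + 0.5)
        return num / den

    odds_1 = math.inf if a == size_1 else a / (size_1 - a)
    odds_2 = math.inf if b == size_2 else b / (size_2 - b)
    if (odds_1 == 0.0 and odds_2 == 0.0) or (
        math.isinf(odds_1) and math.isinf(odds_2)
    ):
        return math.nan
    if math.isinf(odds_1) or odds_2 == 0.0:
        return math.inf
    if odds_1 == 0.0 or math.isinf(odds_2):
        return 0.0
    return odds_1 / odds_2


def woolf_ci(
    a: int, size_1: int, b: int, size_2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Woolf (log-normal) confidence limits for the odds ratio."""
    cells = (a, size_1 - a, b, size_2 - b)
    if any(c == 0 for c in cells):
        return (math.nan, math.nan)
    log_or = math.log(odds_ratio(a, size_1, b, size_2))
    se = math.sqrt(sum(1.0 / c for c in cells))
    z = _sps.norm.ppf(1.0 - alpha / 2.0)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def flag_enriched(
    freq_A: float,
    freq_T: float,
    freq_N: float,
    freq_P: float,
    criterion: str = "positive_excess",
) -> bool:
    """Whether a feature's frequency profile marks it as enriched.

    ``positive_excess`` (default): the positive group's frequency exceeds
    the negative group's — algebraically equivalent to OR_PN > 1 whenever
    the ratio is finite.  ``strict_monotone``: frequencies strictly increase
    from the background through tested and negative to positive.
    """
    if criterion == "positive_excess":
        return freq_P > freq_N
    if criterion == "strict_monotone":
        return freq_A < freq_T < freq_N < freq_P
    raise ValueError(f"unknown enrichment criterion {criterion!r}")


def select_dominant(
    stats: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Rows whose P-vs-N odds ratio strictly exceeds *threshold*.

    Ties at exactly the threshold are excluded; infinite ratios qualify.
    """
    if stats.empty:
        return stats
    return stats[stats["or_pn"] > threshold]


def compute_all(
    matrix: AnnotationMatrix,
    groups: GroupAssignment,
    retained: Iterable[tuple[str, str]],
    lexicon: Iterable[FeatureLexiconEntry],
    *,
    enrichment_criterion: str = "positive_excess",
    dominance_threshold: float = 1.0,
    with_ci: bool = False,
) -> pd.DataFrame:
    """One statistics row per retained (test, feature) pair."""
    retained = set(retained)
    entry_by_id = {e.feature_id: e for e in lexicon}
    size_a = len(groups.reference_ids)
    rows = []
    for test_id, feature_id in sorted(retained):
        entry = entry_by_id[feature_id]
        sizes = groups.sizes(test_id)
        n_p = matrix.count(test_id, feature_id, groups.positives(test_id))
        n_n = matrix.count(test_id, feature_id, groups.negatives(test_id))
        n_t = matrix.count(test_id, feature_id, groups.tested(test_id))
        n_a = matrix.count(test_id, feature_id, groups.reference_ids)
        row = {
            "test_id": test_id,
            "feature_id": feature_id,
            "term": entry.preferred_term,
            "n_A": n_a,
            "n_T": n_t,
            "n_N": n_n,
            "n_P": n_p,
            "freq_A": frequency(n_a, size_a),
            "freq_T": frequency(n_t, sizes["T"]),
            "freq_N": frequency(n_n, sizes["N"]),
            "freq_P": frequency(n_p, sizes["P"]),
            "or_pn": odds_ratio(n_p, sizes["P"], n_n, sizes["N"]),
            "or_ta": odds_ratio(n_t, sizes["T"], n_a, size_a),
        }
        row["enriched"] = flag_enriched(
            row["freq_A"], row["freq_T"], row["freq_N"], row["freq_P"],
            criterion=enrichment_criterion,
        )
        row["dominant"] = row["or_pn"] > dominance_threshold
        if with_ci:
            row["or_pn_ci_low"], row["or_pn_ci_high"] = woolf_ci(
                n_p, sizes["P"], n_n, sizes["N"]
            )
        rows.append(row)
    columns = list(STATS_COLUMNS)
    if with_ci:
        columns += ["or_pn_ci_low", "or_pn_ci_high"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values(["test_id", "feature_id"], ignore_index=True)


def write_feature_stats(stats: pd.DataFrame, path, precision: int = 5) -> None:
    """Serialize the statistics table, rounding floats to *precision* places
    (round-half-even, the reporting convention)."""
    out = stats.copy()
    float_cols = [c for c in out.columns if out[c].dtype.kind == "f"]
    for col in float_cols:
        out[col] = out[col].map(lambda x: f"{x:.{precision}f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
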