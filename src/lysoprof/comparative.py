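"""Cross-condition comparison of called candidate sets.

Covers the set arithmetic behind Venn/upset summaries (pairwise overlaps,
all exclusive membership regions for up to six sets), percentage reporting
with half-away-from-zero rounding, category breakdowns against a
user-supplied subcellular/functional annotation, and the two-sample test
for equality of proportions (pooled chi-square on the 2x2 table).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, NamedTuple, Sequence

from scipy import stats

from .enrichment import CandidateSet

MAX_UPSET_SETS = 6


def _members(s) -> frozenset:
    return s.members if isinstance(s, CandidateSet) else frozenset(s)


def _label(s, i: int) -> str:
    return s.label if isinstance(s, CandidateSet) else f"set{i + 1}"


class PairwiseOverlap(NamedTuple):
    size_a: int
    size_b: int
    intersection: int
    a_only: int
    b_only: int


def pairwise_overlap(a, b) -> PairwiseOverlap:
    """Venn counts for two candidate sets (or plain id collections)."""
    ma, mb = _members(a), _members(b)
    inter = len(ma & mb)
    return PairwiseOverlap(len(ma), len(mb), inter, len(ma) - inter, len(mb) - inter)


def overlap_percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * numerator/denominator, rounded half-away-from-zero.

    This is the rounding that maps 60.80 -> 61, 56.76 -> 57, 6.61 -> 7.
    (Python's builtin round() is banker's rounding and would differ.)
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    value = 100.0 * numerator / denominator
    f = 10.0**decimals
    return math.floor(abs(value) * f + 0.5) / f * (1 if value >= 0 else -1)


@dataclass
class OverlapSummary:
    """All 2^k - 1 exclusive membership regions of k candidate sets.

    ``pattern_counts`` keys are k-character strings of 0/1 in label order,
    e.g. ``"110"`` = in the first two sets only. Counts are exclusive, so
    they sum to the size of the union.
    """

    labels: tuple
    sizes: dict
    pattern_counts: dict
    union_size: int
    pattern_members: dict = field(default_factory=dict, repr=False)

    def intersection_size(self, label_a: str, label_b: str) -> int:
        """Pairwise |A n B| recovered from the exclusive regions."""
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return sum(
            n
            for pat, n in self.pattern_counts.items()
            if pat[i] == "1" and pat[j] == "1"
        )


def exclusive_regions(sets: Sequence) -> OverlapSummary:
    """Upset-style decomposition of 2-6 sets into exclusive regions."""
    if not 2 <= len(sets) <= MAX_UPSET_SETS:
        raise ValueError(f"need between 2 and {MAX_UPSET_SETS} sets")
    members = [_members(s) for s in sets]
    labels = tuple(_label(s, i) for i, s in enumerate(sets))
    if len(set(labels)) != len(labels):
        labels = tuple(f"{lab}#{i + 1}" for i, lab in enumerate(labels))
    k = len(sets)
    patterns = {
        "".join(map(str, bits)): set()
        for bits in product((0, 1), repeat=k)
        if any(bits)
    }
    union = set().union(*members)
    for el in union:
        pat = "".join("1" if el in m else "0" for m in members)
        patterns[pat].add(el)
    return OverlapSummary(
        labels=labels,
        sizes={lab: len(m) for lab, m in zip(labels, members)},
        pattern_counts={pat: len(els) for pat, els in patterns.items()},
        union_size=len(union),
        pattern_members={pat: frozenset(els) for pat, els in patterns.items()},
    )


@dataclass
class ProportionTestResult:
    p1: float
    p2: float
    statistic: float
    df: int
    p_value: float
    continuity_correction: bool


def two_proportion_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    continuity_correction: bool = False,
) -> ProportionTestResult:
    """Two-sample test for equality of proportions.

    Chi-square test of homogeneity on the 2x2 success/failure table using
    the pooled proportion; without continuity correction the statistic is
    algebraically the square of the two-sample z statistic. The optional
    Yates correction subtracts 0.5 from each |O - E| (floored at 0), as in
    R's prop.test.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn(
            "pooled proportion is degenerate (0 or 1); statistic is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return ProportionTestResult(p1, p2, 0.0, 1, 1.0, continuity_correction)
    observed = ((x1, n1 - x1), (x2, n2 - x2))
    expected = (
        (n1 * pooled, n1 * (1 - pooled)),
        (n2 * pooled, n2 * (1 - pooled)),
    )
    stat = 0.0
    for orow, erow in zip(observed, expected):
        for o, e in zip(orow, erow):
            d = abs(o - e)
            if continuity_correction:
                d = max(d - 0.5, 0.0)
            stat += d * d / e
    p = float(stats.chi2.sf(stat, df=1))
    return ProportionTestResult(p1, p2, stat, 1, p, continuity_correction)


@dataclass
class AnnotationBreakdown:
    counts: dict
    proportions: dict
    unannotated: int


def annotation_breakdown(
    candidate_set,
    annotation: Mapping[str, str],
    unknown_label: str = "unknown",
) -> AnnotationBreakdown:
    """Category counts and proportions for a candidate set under a
    protein -> category mapping (ids absent from the mapping fall in
    ``unknown_label``). Proportions sum to 1 over a nonempty set."""
    members = _members(candidate_set)
    if not members:
        warnings.warn("empty candidate set: empty breakdown", RuntimeWarning,
                      stacklevel=2)
        return AnnotationBreakdown({}, {}, 0)
    counts: dict[str, int] = {}
    unannotated = 0
    for pid in members:
        cat = annotation.get(pid)
        if cat is None:
            cat = unknown_label
            unannotated += 1
        counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    proportions = {cat: n / total for cat, n in counts.items()}
    return AnnotationBreakdown(counts, proportions, unannotated)
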