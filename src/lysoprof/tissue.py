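"""Tissue-heterogeneity classification of lysosome-enriched proteins.

Tissue-specific Lyso-IP flow-through still contains lysosomes from the
other tissues, so IP/FT ratios are not meaningful there. Instead each
protein's iFOT is normalized to the bait marker (LMP-1) in the same
replicate, and the marker-normalized ratio is compared between the
whole-body experiment and each tissue-specific experiment:

* Group I   - comparable ratios (no significant difference),
* Group II  - significantly higher in the tissue (p < alpha),
* Group III - significantly lower in the tissue (p < alpha),
* Group IV  - undetected in every tissue IP replicate.

Significance uses an unpaired two-tailed Student's t-test on per-replicate
ratios (equal variance; a Welch flag is available).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import CandidateSet
from .proteomics import QuantMatrix

GROUPS = ("I", "II", "III", "IV")


@dataclass
class TissueGroupRecord:
    protein_id: str
    tissue: str
    mean_wholebody_ratio: float
    mean_tissue_ratio: float
    p_value: float  # NaN when untestable
    direction: str  # up / down / none
    group: str  # I / II / III / IV
    untestable: bool = False


def marker_normalize(
    m: QuantMatrix,
    marker_protein_id: str,
    sample_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Divide every protein's iFOT by the bait marker's iFOT in the same
    sample. The marker row itself maps to exactly 1 everywhere.

    Raises if the marker is undetected in any selected sample (the ratio
    would be undefined), naming the sample.
    """
    cols = list(sample_subset) if sample_subset is not None else m.sample_ids
    if marker_protein_id not in m.data.index:
        raise KeyError(f"marker {marker_protein_id!r} not in matrix")
    sub = m.data[cols]
    marker = sub.loc[marker_protein_id]
    dead = marker.index[marker <= 0].tolist()
    if dead:
        raise ValueError(
            f"marker {marker_protein_id!r} undetected in sample(s): {dead}"
        )
    out = sub.div(marker, axis=1)
    out.loc[marker_protein_id] = 1.0  # exact, not up to rounding
    return out


def _student_p(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    """Two-tailed unpaired t-test p-value with explicit degenerate rules:
    both sides constant -> p = 1 if the means agree else p = 0."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def classify_groups(
    wholebody_ratios: pd.DataFrame,
    tissue_ratios: pd.DataFrame,
    candidate_set: CandidateSet | Iterable[str],
    alpha: float = 0.05,
    welch: bool = False,
    tissue: str = "tissue",
) -> list[TissueGroupRecord]:
    """Assign Groups I-IV to each candidate protein for one tissue.

    Inputs are marker-normalized ratio tables (rows = proteins, columns =
    replicates). A protein missing from the tissue table, or present but 0
    in every tissue replicate, is Group IV. Fewer than 2 usable replicates
    on either side (when not Group IV) is flagged untestable: Group I with
    p = NaN and a warning.
    """
    members = (
        candidate_set.members
        if isinstance(candidate_set, CandidateSet)
        else set(candidate_set)
    )
    missing_wb = [p for p in members if p not in wholebody_ratios.index]
    if missing_wb:
        raise KeyError(
            f"candidate(s) missing from whole-body ratios: {sorted(missing_wb)[:5]}"
        )
    records = []
    n_untestable = 0
    for pid in sorted(members):
        wb = wholebody_ratios.loc[pid].dropna().values.astype(float)
        if pid in tissue_ratios.index:
            ts = tissue_ratios.loc[pid].dropna().values.astype(float)
        else:
            ts = np.zeros(0)
        if ts.size == 0 or (ts == 0).all():
            records.append(
                TissueGroupRecord(
                    pid, tissue, float(wb.mean()) if wb.size else math.nan,
                    0.0, math.nan, "none", "IV",
                )
            )
            continue
        if wb.size < 2 or ts.size < 2:
            n_untestable += 1
            records.append(
                TissueGroupRecord(
                    pid, tissue,
                    float(wb.mean()) if wb.size else math.nan,
                    float(ts.mean()), math.nan, "none", "I",
                    untestable=True,
                )
            )
            continue
        p = _student_p(wb, ts, welch)
        mw, mt = float(wb.mean()), float(ts.mean())
        if p < alpha and mt > mw:
            group, direction = "II", "up"
        elif p < alpha and mt < mw:
            group, direction = "III", "down"
        else:
            group, direction = "I", "none"
        records.append(
            TissueGroupRecord(pid, tissue, mw, mt, p, direction, group)
        )
    if n_untestable:
        warnings.warn(
            f"{n_untestable} protein(s) untestable (<2 replicates on a side); "
            "assigned Group I with p = NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return records


@dataclass
class GroupSummary:
    per_protein: dict  # protein_id -> I/II/III/IV/discordant/untestable
    counts: dict  # group label -> number of proteins


def summarize_group_counts(
    records: Sequence[TissueGroupRecord],
) -> GroupSummary:
    """Aggregate per-tissue records to one protein-level group.

    Policy: IV only when absent in *all* analyzed tissues; any significant
    increase with no significant decrease -> II (and symmetrically III);
    increase in one tissue and decrease in another -> ``discordant``
    (excluded from the I-III totals); all-untestable -> ``untestable``;
    otherwise I.
    """
    by_protein: dict[str, list[TissueGroupRecord]] = {}
    for r in records:
        by_protein.setdefault(r.protein_id, []).append(r)
    per_protein = {}
    for pid, recs in by_protein.items():
        groups = [r.group for r in recs]
        if all(g == "IV" for g in groups):
            per_protein[pid] = "IV"
            continue
        informative = [r for r in recs if r.group != "IV"]
        if all(r.untestable for r in informative):
            per_protein[pid] = "untestable"
            continue
        ups = any(r.group == "II" for r in informative)
        downs = any(r.group == "III" for r in informative)
        if ups and downs:
            per_protein[pid] = "discordant"
        elif ups:
            per_protein[pid] = "II"
        elif downs:
            per_protein[pid] = "III"
        else:
            per_protein[pid] = "I"
    return GroupSummary(
        per_protein=per_protein, counts=dict(Counter(per_protein.values()))
    )


def records_to_frame(records: Sequence[TissueGroupRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "tissue": r.tissue,
                "mean_wholebody_ratio": r.mean_wholebody_ratio,
                "mean_tissue_ratio": r.mean_tissue_ratio,
                "p_value": r.p_value,
                "direction": r.direction,
                "group": r.group,
                "untestable": r.untestable,
            }
            for r in records
        ]
    )
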