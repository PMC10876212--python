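"""Calling the lysosome-enriched proteome from IP / flow-through / non-tag iFOT.

Three criteria define a lysosome-enriched candidate:

1. its iFOT in the purified-lysosome (IP) fraction is at least ``fold_ft``
   (default 10) times its iFOT in the paired flow-through control,
2. that enrichment repeats in every biological replicate in which the
   protein is detected in the IP fraction, with a floor of
   ``min_ip_detected`` (default 2) detected replicates, and
3. its mean IP iFOT exceeds ``fold_nontag`` (default 2, strict) times its
   mean iFOT in the non-tag bead controls.

Criterion 2's "detected replicates" reading lets a low-abundance protein
seen in only 2 of 4 IP replicates (both >= 10-fold) qualify. A protein
absent from the flow-through but present in the IP has ratio +inf, which
passes criterion 1: depletion from the flow-through is the strongest
enrichment evidence. Zeros stay semantic (undetected); no pseudocounts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .proteomics import QuantMatrix, SampleDescriptor

#: display cap used when rendering +inf ratios in profile tables
INF_DISPLAY_CAP = 1e6


@dataclass(frozen=True)
class RatioObservation:
    """One replicate's IP/FT enrichment ratio for one protein."""

    replicate: int
    ratio: float  # +inf when FT undetected
    ft_detected: bool


@dataclass
class EnrichmentRecord:
    """Per-protein evidence behind a candidate call."""

    protein_id: str
    per_replicate_ratio: list[float]
    replicates: list[int]
    n_ip_detected: int
    mean_ip: float
    mean_nontag: float
    nontag_fold: float  # +inf when the non-tag mean is 0
    pass_fold_ft: bool
    pass_all_replicates: bool
    pass_nontag: bool
    is_candidate: bool


@dataclass(frozen=True)
class CandidateSet:
    """A called lysosome-enriched proteome for one condition/marker/tissue."""

    label: str
    members: frozenset
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    def __len__(self) -> int:
        return len(self.members)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "label": self.label,
                    "members": sorted(self.members),
                    "provenance": self.provenance,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CandidateSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            label=d["label"],
            members=frozenset(d["members"]),
            provenance=d.get("provenance", {}),
        )


def _paired_ip_ft(
    m: QuantMatrix,
    condition: str,
    tissue: str,
    marker: str | None,
) -> tuple[list[SampleDescriptor], list[SampleDescriptor]]:
    """IP and FT descriptors paired one-to-one by replicate index."""
    ip = m.samples_where(
        fraction_role="lyso_ip", condition=condition, tissue=tissue, marker=marker
    )
    ft = m.samples_where(
        fraction_role="flow_through",
        condition=condition,
        tissue=tissue,
        marker=marker,
    )
    ip_reps = {s.replicate for s in ip}
    ft_reps = {s.replicate for s in ft}
    if ip_reps != ft_reps:
        raise ValueError(
            f"unpaired replicates for condition {condition!r}: "
            f"IP-only {sorted(ip_reps - ft_reps)}, "
            f"FT-only {sorted(ft_reps - ip_reps)}"
        )
    ip = sorted(ip, key=lambda s: s.replicate)
    ft = sorted(ft, key=lambda s: s.replicate)
    return ip, ft


def per_replicate_ratios(
    m: QuantMatrix,
    condition: str,
    tissue: str = "whole_body",
    marker: str | None = None,
) -> dict[str, list[RatioObservation]]:
    """IP/FT iFOT ratio per replicate, for replicates where the protein is
    detected (>0) in the IP fraction.

    FT = 0 with IP > 0 yields ratio +inf, flagged ``ft_detected=False``.
    """
    if m.unit != "iFOT":
        raise ValueError("per_replicate_ratios expects an iFOT matrix")
    ip, ft = _paired_ip_ft(m, condition, tissue, marker)
    ip_vals = m.data[[s.sample_id for s in ip]].values
    ft_vals = m.data[[s.sample_id for s in ft]].values
    reps = [s.replicate for s in ip]
    out: dict[str, list[RatioObservation]] = {}
    for i, pid in enumerate(m.protein_ids):
        obs = []
        for j, rep in enumerate(reps):
            iv, fv = ip_vals[i, j], ft_vals[i, j]
            if iv <= 0:
                continue
            ratio = iv / fv if fv > 0 else math.inf
            obs.append(RatioObservation(rep, ratio, ft_detected=fv > 0))
        if obs:
            out[pid] = obs
    return out


def call_candidates(
    m: QuantMatrix,
    condition: str,
    fold_ft: float = 10.0,
    fold_nontag: float = 2.0,
    min_ip_detected: int = 2,
    tissue: str = "whole_body",
    marker: str | None = None,
    label: str | None = None,
) -> tuple[CandidateSet, list[EnrichmentRecord]]:
    """Apply the three-criterion filter and return the candidate set plus a
    record for every protein detected in at least one IP replicate.

    Criterion 1 is inclusive (ratio >= ``fold_ft``); criterion 3 is strict
    (mean IP > ``fold_nontag`` x mean non-tag). Non-tag controls do not pair
    with IP replicates, so criterion 3 compares means across replicates.
    """
    if m.unit != "iFOT":
        raise ValueError("call_candidates expects an iFOT matrix")
    if min_ip_detected < 1:
        raise ValueError("min_ip_detected must be >= 1")
    ip, ft = _paired_ip_ft(m, condition, tissue, marker)
    if len(ip) < 2:
        raise ValueError(
            f"condition {condition!r} needs >= 2 IP/FT replicate pairs"
        )
    nontag = m.samples_where(fraction_role="non_tag")
    if not nontag:
        raise ValueError("design contains no non_tag samples")

    ip_vals = m.data[[s.sample_id for s in ip]].values
    ft_vals = m.data[[s.sample_id for s in ft]].values
    nt_vals = m.data[[s.sample_id for s in nontag]].values
    reps = np.array([s.replicate for s in ip])

    detected = ip_vals > 0
    n_det = detected.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(ft_vals > 0, ip_vals / np.where(ft_vals > 0, ft_vals, 1.0), np.inf)
    mean_ip = ip_vals.mean(axis=1)
    mean_nt = nt_vals.mean(axis=1)

    records: list[EnrichmentRecord] = []
    members = []
    for i, pid in enumerate(m.protein_ids):
        if n_det[i] == 0:
            continue
        mask = detected[i]
        r = ratios[i, mask].tolist()
        pass_ft = all(x >= fold_ft for x in r)
        pass_reps = int(n_det[i]) >= min_ip_detected
        nfold = mean_ip[i] / mean_nt[i] if mean_nt[i] > 0 else math.inf
        pass_nt = mean_ip[i] > fold_nontag * mean_nt[i]
        is_cand = pass_ft and pass_reps and pass_nt
        records.append(
            EnrichmentRecord(
                protein_id=pid,
                per_replicate_ratio=r,
                replicates=reps[mask].tolist(),
                n_ip_detected=int(n_det[i]),
                mean_ip=float(mean_ip[i]),
                mean_nontag=float(mean_nt[i]),
                nontag_fold=float(nfold),
                pass_fold_ft=pass_ft,
                pass_all_replicates=pass_reps,
                pass_nontag=pass_nt,
                is_candidate=is_cand,
            )
        )
        if is_cand:
            members.append(pid)

    cset = CandidateSet(
        label=label or f"{condition}/{marker or 'any'}/{tissue}",
        members=frozenset(members),
        provenance={
            "condition": condition,
            "tissue": tissue,
            "marker": marker,
            "fold_ft": fold_ft,
            "fold_nontag": fold_nontag,
            "min_ip_detected": min_ip_detected,
            "n_ip_ft_pairs": len(ip),
            "n_nontag": len(nontag),
        },
    )
    return cset, records


def enrichment_profile(
    records: Sequence[EnrichmentRecord] | Mapping[str, EnrichmentRecord],
    protein_ids: Iterable[str],
    inf_cap: float = INF_DISPLAY_CAP,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-replicate ratio table for chosen proteins (e.g. the v-ATPase
    subunits), rows in the requested order.

    +inf ratios are rendered as ``inf_cap`` and listed in the
    ``capped_replicates`` column. Unknown ids go to the returned warnings
    list rather than raising.
    """
    if not isinstance(records, Mapping):
        records = {r.protein_id: r for r in records}
    all_reps = sorted({rep for r in records.values() for rep in r.replicates})
    rows, warnings_, index = [], [], []
    for pid in protein_ids:
        rec = records.get(pid)
        if rec is None:
            warnings_.append(f"unknown protein id: {pid}")
            continue
        row = {f"ratio_rep{rep}": np.nan for rep in all_reps}
        capped = []
        for rep, ratio in zip(rec.replicates, rec.per_replicate_ratio):
            if math.isinf(ratio):
                row[f"ratio_rep{rep}"] = inf_cap
                capped.append(rep)
            else:
                row[f"ratio_rep{rep}"] = ratio
        row["capped_replicates"] = ";".join(str(c) for c in capped)
        rows.append(row)
        index.append(pid)
    df = pd.DataFrame(rows, index=pd.Index(index, name="protein_id"))
    return df, warnings_


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Flatten records for TSV export; +inf serialized as ``Inf``."""
    rows = []
    for r in records:
        rows.append(
            {
                "protein_id": r.protein_id,
                "replicates": ";".join(map(str, r.replicates)),
                "per_replicate_ratio": ";".join(
                    "Inf" if math.isinf(x) else repr(x)
                    for x in r.per_replicate_ratio
                ),
                "n_ip_detected": r.n_ip_detected,
                "mean_ip": r.mean_ip,
                "mean_nontag": r.mean_nontag,
                "nontag_fold": "Inf" if math.isinf(r.nontag_fold) else r.nontag_fold,
                "pass_fold_ft": r.pass_fold_ft,
                "pass_all_replicates": r.pass_all_replicates,
                "pass_nontag": r.pass_nontag,
                "is_candidate": r.is_candidate,
            }
        )
    return pd.DataFrame(rows)
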