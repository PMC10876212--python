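"""Containers and QC for gene-level label-free quantification tables.

A Lyso-IP experiment quantifies gene products in immuno-purified lysosome
fractions (IP), their paired flow-through depletion controls (FT), and
non-tag bead controls, using intensity-based absolute quantification (iBAQ).
Per-sample load variation is removed by converting iBAQ to iFOT ("fraction
of total"): each gene product's iBAQ divided by the summed iBAQ of the
sample, so every sample column sums to one.

Zeros are semantic throughout: a value of 0 means the gene product was not
detected in that sample, never "measured as zero". There are no pseudocounts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FRACTION_ROLES = ("lyso_ip", "flow_through", "non_tag")
MARKERS = ("LMP1", "CTNS1", "none")
TISSUES = ("whole_body", "hypodermis", "muscle", "intestine", "neuron")
UNITS = ("iBAQ", "iFOT")

#: column order of the sample-design TSV
DESIGN_COLUMNS = (
    "sample_id",
    "fraction_role",
    "marker",
    "condition",
    "tissue",
    "replicate",
    "temperature_C",
)

IFOT_COLSUM_TOL = 1e-9


@dataclass(frozen=True)
class SampleDescriptor:
    """Design metadata for one MS sample.

    Parameters
    ----------
    sample_id
        Unique sample column name.
    fraction_role
        One of ``lyso_ip`` (purified lysosomes), ``flow_through``
        (paired non-lysosomal remainder) or ``non_tag`` (bead control
        from animals without the epitope tag).
    marker
        Lyso-Tag bait: ``LMP1``, ``CTNS1`` or ``none`` (non-tag controls).
    condition
        Genotype/treatment label, e.g. ``WT``, ``lipl-4 Tg``, ``daf-2(lf)``.
    tissue
        Tissue of the Lyso-Tag promoter; ``whole_body`` for ubiquitous tags.
    replicate
        1-based biological replicate index.
    temperature_C
        Growth temperature (20 or 25 in the source designs).
    """

    sample_id: str
    fraction_role: str
    marker: str = "LMP1"
    condition: str = "WT"
    tissue: str = "whole_body"
    replicate: int = 1
    temperature_C: float = 20.0

    def __post_init__(self) -> None:
        if self.fraction_role not in FRACTION_ROLES:
            raise ValueError(
                f"fraction_role {self.fraction_role!r} not in {FRACTION_ROLES}"
            )
        if self.marker not in MARKERS:
            raise ValueError(f"marker {self.marker!r} not in {MARKERS}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue {self.tissue!r} not in {TISSUES}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.fraction_role == "non_tag" and self.marker != "none":
            raise ValueError("non_tag samples must have marker='none'")

    @property
    def key(self) -> tuple:
        """Design key that must be unique within one experiment."""
        return (
            self.condition,
            self.tissue,
            self.fraction_role,
            self.marker,
            self.replicate,
            self.temperature_C,
        )


class QuantMatrix:
    """Gene-products x samples abundance table (iBAQ or iFOT).

    Wraps a :class:`pandas.DataFrame` (index = protein ids, columns =
    sample ids) together with aligned :class:`SampleDescriptor` metadata.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        samples: Sequence[SampleDescriptor],
        unit: str = "iBAQ",
    ) -> None:
        if unit not in UNITS:
            raise ValueError(f"unit {unit!r} not in {UNITS}")
        data = data.astype(float)
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        if list(data.columns) != ids:
            raise ValueError(
                "sample columns do not match descriptors: "
                f"{list(data.columns)} vs {ids}"
            )
        keys = [s.key for s in samples]
        if len(set(keys)) != len(keys):
            raise ValueError(
                "(condition, tissue, fraction_role, marker, replicate, "
                "temperature) does not uniquely identify every sample"
            )
        if (data.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        if unit == "iFOT":
            colsums = data.values.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=IFOT_COLSUM_TOL, rtol=0):
                raise ValueError(
                    "iFOT columns must each sum to 1; got sums "
                    f"{colsums.tolist()}"
                )
        self.data = data
        self.samples = list(samples)
        self.unit = unit

    # -- convenience -------------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def descriptor(self, sample_id: str) -> SampleDescriptor:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_where(
        self,
        fraction_role: str | None = None,
        condition: str | None = None,
        tissue: str | None = None,
        marker: str | None = None,
        temperature_C: float | None = None,
    ) -> list[SampleDescriptor]:
        """Select descriptors matching every given (non-None) field."""
        out = []
        for s in self.samples:
            if fraction_role is not None and s.fraction_role != fraction_role:
                continue
            if condition is not None and s.condition != condition:
                continue
            if tissue is not None and s.tissue != tissue:
                continue
            if marker is not None and s.marker != marker:
                continue
            if temperature_C is not None and s.temperature_C != temperature_C:
                continue
            out.append(s)
        return out

    def design_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "fraction_role": s.fraction_role,
                "marker": s.marker,
                "condition": s.condition,
                "tissue": s.tissue,
                "replicate": s.replicate,
                "temperature_C": s.temperature_C,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"QuantMatrix({len(self.protein_ids)} proteins x "
            f"{len(self.samples)} samples, unit={self.unit})"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_design(path) -> list[SampleDescriptor]:
    """Read a sample-design TSV into descriptors (column order per spec of
    :data:`DESIGN_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return [
        SampleDescriptor(
            sample_id=str(r.sample_id),
            fraction_role=str(r.fraction_role),
            marker=str(r.marker),
            condition=str(r.condition),
            tissue=str(r.tissue),
            replicate=int(r.replicate),
            temperature_C=float(r.temperature_C),
        )
        for r in df.itertuples(index=False)
    ]


def write_design(samples: Sequence[SampleDescriptor], path) -> None:
    QuantMatrix(
        pd.DataFrame(
            np.zeros((0, len(samples))), columns=[s.sample_id for s in samples]
        ),
        samples,
    ).design_frame().to_csv(path, sep="\t", index=False)


def read_quant_table(path, design_path) -> QuantMatrix:
    """Read a quantification TSV (first column ``protein_id``, one column
    per sample) plus its design table.

    Empty cells become 0 (undetected). A sample column with no design row
    is a hard error naming the column; so is a duplicate protein id. The
    unit is iFOT if every column sums to 1 within tolerance, else iBAQ.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein id(s) in {path}: {dups}")
    df = df.fillna(0.0).astype(float)
    by_id = {s.sample_id: s for s in read_design(design_path)}
    samples = []
    for col in df.columns:
        if str(col) not in by_id:
            raise ValueError(
                f"sample column {col!r} has no row in the design table"
            )
        samples.append(by_id[str(col)])
    colsums = df.values.sum(axis=0)
    unit = (
        "iFOT"
        if len(df) and np.allclose(colsums, 1.0, atol=IFOT_COLSUM_TOL, rtol=0)
        else "iBAQ"
    )
    return QuantMatrix(df, samples, unit=unit)


def write_quant_table(m: QuantMatrix, path, design_path=None) -> None:
    """Write the matrix as TSV (and optionally its design). Floats are
    written with full repr precision so read/write round-trips exactly."""
    out = m.data.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")
    if design_path is not None:
        m.design_frame().to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization and per-protein transforms
# ---------------------------------------------------------------------------

def to_ifot(m: QuantMatrix) -> QuantMatrix:
    """iBAQ -> iFOT: divide each value by its sample's total iBAQ.

    Every output column sums to 1. An all-zero sample column is a
    degenerate sample and raises.
    """
    if m.unit != "iBAQ":
        raise ValueError(f"to_ifot expects an iBAQ matrix, got {m.unit}")
    colsums = m.data.sum(axis=0)
    dead = colsums.index[colsums <= 0].tolist()
    if dead:
        raise ValueError(f"all-zero sample column(s): {dead}")
    return QuantMatrix(m.data.div(colsums, axis=1), m.samples, unit="iFOT")


def zscore_across_samples(values: Iterable[float]) -> np.ndarray:
    """(x - mean)/sd across a per-protein sample vector, sample sd (n-1).

    A zero-variance vector maps to all zeros (the convention used when
    displaying per-protein levels across conditions).
    """
    x = np.asarray(list(values), dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def replicate_correlation(
    m: QuantMatrix, sample_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix between sample columns.

    Zero-variance samples correlate 0 with everything (with a warning);
    the diagonal is exactly 1.
    """
    cols = list(sample_subset) if sample_subset is not None else m.sample_ids
    if len(cols) < 2:
        raise ValueError("need at least 2 samples")
    X = m.data[cols].values
    sd = X.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        warnings.warn(
            f"zero-variance sample(s) {[cols[i] for i in flat]}: "
            "correlation set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    n = len(cols)
    r = np.zeros((n, n))
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(ok)
        r[np.ix_(idx, idx)] = np.clip(sub, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=cols, columns=cols)


@dataclass
class PCAResult:
    """Per-sample principal-component scores of an abundance table.

    ``variance_fraction`` covers *all* components and sums to 1 when any
    variance exists; ``scores`` holds the requested leading components.
    ``loadings`` and ``mean`` allow exact reconstruction of the centered
    input from the full decomposition.
    """

    scores: pd.DataFrame
    variance_fraction: np.ndarray
    loadings: np.ndarray
    mean: np.ndarray


def pca_scores(
    m: QuantMatrix,
    sample_subset: Sequence[str] | None = None,
    n_components: int | None = 2,
    scale: bool = False,
    log_transform: bool = False,
) -> PCAResult:
    """PCA of samples (observations) over proteins (variables) by SVD of
    the centered data matrix.

    Centering only by default; ``scale=True`` additionally divides each
    protein by its sd (zero-sd proteins are left centered). The optional
    ``log_transform`` applies log10(x + 1e-9) first. Component signs are
    fixed so each score vector's largest-magnitude entry is positive.
    """
    cols = list(sample_subset) if sample_subset is not None else m.sample_ids
    if len(cols) < 2:
        raise ValueError("need at least 2 samples")
    X = m.data[cols].values.T.astype(float)  # samples x proteins
    if log_transform:
        X = np.log10(X + 1e-9)
    mu = X.mean(axis=0)
    Xc = X - mu
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    n_max = min(len(cols) - 1, Xc.shape[1])
    if n_components is None:
        n_components = n_max
    if n_components > n_max:
        warnings.warn(
            f"requested {n_components} components but only {n_max} "
            "are available; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = n_max
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (S**2).sum()
    if total == 0:
        warnings.warn(
            "zero total variance; all components undefined (returned as 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        frac = np.zeros(len(S))
    else:
        frac = S**2 / total
    scores = U * S
    # deterministic sign: largest-|score| entry of each component positive
    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] *= -1
            Vt[j, :] *= -1
    score_df = pd.DataFrame(
        scores[:, :n_components],
        index=cols,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return PCAResult(
        scores=score_df, variance_fraction=frac, loadings=Vt, mean=mu
    )
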