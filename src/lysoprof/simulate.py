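"""Ground-truth-labeled synthetic data with the statistical structure the
analyses assume.

Proteome generator
------------------
Each gene product gets a log-normal bulk abundance. During the simulated
immunoprecipitation the protein's mass splits between the bead (IP) and
the flow-through according to its capture odds: a truly lysosomal protein
has odds equal to its enrichment factor (log-normal, median 50 by
default), every other protein has small nonspecific background odds.
Because the flow-through receives the complement mass, lysosomal proteins
are simultaneously enriched in IP and depleted from FT, just as in a real
paired IP. Non-tag controls see the bulk composition plus a small fraction
of IP-like carryover (nonspecific bead binding). Multiplicative log-normal
replicate noise is applied to every value and values whose within-sample
fraction falls below the detection limit are zeroed (abundance-dependent
dropout). All generators are pure functions of (params, seed).

Cell generator
--------------
A convex cell polygon and a contained nucleus polygon are built from
scaled convex hulls of random points. Diffraction-limited puncta are
placed at uniformly random angles from the nucleus centroid, at a radial
fraction f in [0, 1) between the nuclear and cell boundaries drawn from a
named law (uniform or Beta), and rendered as isotropic Gaussian spots over
a constant background, with optional Poisson noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .proteomics import QuantMatrix, SampleDescriptor
from .spatial import (
    CellGeometry,
    _ray_ts,
    check_convex,
    polygon_centroid,
)

# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------


@dataclass
class ProteomeSimParams:
    """Parameters of the synthetic Lyso-IP experiment.

    Defaults give 1000 proteins of which 100 are truly lysosomal with a
    median 50x capture enrichment, 4 IP/FT replicate pairs, 3 non-tag
    controls, 20% replicate noise (CV) and an iFOT detection floor of
    1e-6 -- the benchmark conditions for the enrichment caller.
    """

    n_proteins: int = 1000
    n_lysosomal: int = 100
    baseline_log_mean: float = 0.0  # ln-scale mean of bulk abundance
    baseline_log_sigma: float = 1.0  # ln-scale sd (abundance dynamic range)
    ip_enrichment_median: float = 50.0  # median capture odds, lysosomal
    ip_enrichment_log_sigma: float = 0.25  # ln-scale spread of odds
    background_capture_odds: float = 0.02  # nonspecific capture, others
    nontag_background_fraction: float = 0.05  # IP-like carryover in non-tag
    noise_cv: float = 0.2  # multiplicative replicate noise
    detection_limit: float = 1e-6  # iFOT floor; below -> 0
    n_ip_ft_pairs: int = 4
    n_nontag: int = 3
    seed: int = 0
    total_ibaq: float = 1e10  # arbitrary per-sample iBAQ scale
    condition: str = "WT"

    def validate(self) -> None:
        if not 0 <= self.n_lysosomal <= self.n_proteins:
            raise ValueError("need 0 <= n_lysosomal <= n_proteins")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if self.n_ip_ft_pairs < 1 or self.n_nontag < 1:
            raise ValueError("need >= 1 IP/FT pair and >= 1 non-tag sample")
        if self.background_capture_odds <= 0:
            raise ValueError("background_capture_odds must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with the given CV and unit median."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=shape)


def simulate_lysoip_experiment(
    p: ProteomeSimParams,
) -> tuple[QuantMatrix, pd.Series]:
    """Simulate one whole-body Lyso-IP experiment.

    Returns the iBAQ :class:`QuantMatrix` (IP, FT and non-tag columns with
    an aligned design) and a boolean truth Series (True = lysosomal)
    indexed by protein id. Identical params+seed give identical output.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    ids = [f"P{i + 1:05d}" for i in range(p.n_proteins)]
    lyso = np.zeros(p.n_proteins, dtype=bool)
    lyso[rng.choice(p.n_proteins, size=p.n_lysosomal, replace=False)] = True

    bulk = rng.lognormal(p.baseline_log_mean, p.baseline_log_sigma, p.n_proteins)
    odds = np.full(p.n_proteins, p.background_capture_odds)
    odds[lyso] = rng.lognormal(
        math.log(p.ip_enrichment_median),
        p.ip_enrichment_log_sigma,
        p.n_lysosomal,
    )
    capture = odds / (1.0 + odds)  # fraction of each protein's mass on beads

    cols: dict[str, np.ndarray] = {}
    samples: list[SampleDescriptor] = []
    for r in range(1, p.n_ip_ft_pairs + 1):
        ipv = bulk * capture * _noise(rng, p.noise_cv, p.n_proteins)
        ftv = bulk * (1.0 - capture) * _noise(rng, p.noise_cv, p.n_proteins)
        cols[f"ip_{r}"] = ipv
        cols[f"ft_{r}"] = ftv
        samples.append(
            SampleDescriptor(f"ip_{r}", "lyso_ip", "LMP1", p.condition,
                             "whole_body", r)
        )
        samples.append(
            SampleDescriptor(f"ft_{r}", "flow_through", "LMP1", p.condition,
                             "whole_body", r)
        )
    ip_comp = bulk * capture
    ip_comp = ip_comp / ip_comp.sum()
    bulk_comp = bulk / bulk.sum()
    for r in range(1, p.n_nontag + 1):
        ntv = (
            bulk_comp + p.nontag_background_fraction * ip_comp
        ) * _noise(rng, p.noise_cv, p.n_proteins)
        cols[f"nt_{r}"] = ntv
        samples.append(
            SampleDescriptor(f"nt_{r}", "non_tag", "none", p.condition,
                             "whole_body", r)
        )

    data = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    # per-sample load scaling, then abundance-dependent detection dropout
    frac = data / data.sum(axis=0)
    data = frac * p.total_ibaq
    if p.detection_limit > 0:
        data = data.where(frac.values >= p.detection_limit, 0.0)
        dead = data.sum(axis=0) <= 0
        if dead.any():  # pragma: no cover - absurd detection limit
            raise ValueError("detection limit zeroed entire sample(s)")
    truth = pd.Series(lyso, index=ids, name="is_lysosomal")
    return QuantMatrix(data, samples, unit="iBAQ"), truth


def simulate_tissue_experiment(
    base: ProteomeSimParams,
    tissue_shift: Mapping[str, float] | None = None,
    ratio_sigma: float = 0.1,
    n_wholebody_reps: int = 4,
    n_tissue_reps: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired whole-body and tissue marker-normalized ratio tables with
    truth groups.

    ``tissue_shift`` maps protein id -> fold change of the tissue ratio
    (1 = Group I, >1 = II, <1 = III, 0 = dropped from the tissue, IV);
    unlisted proteins get fold 1. ``ratio_sigma`` is the ln-scale
    replicate noise of the ratios.
    """
    base.validate()
    if tissue_shift is None:
        tissue_shift = {}
    if any(f < 0 for f in tissue_shift.values()):
        raise ValueError("tissue shifts must be >= 0 (0 drops the protein)")
    rng = np.random.default_rng(base.seed)
    ids = [f"P{i + 1:05d}" for i in range(base.n_proteins)]
    mean_ratio = rng.lognormal(
        base.baseline_log_mean, base.baseline_log_sigma, base.n_proteins
    )
    shift = np.array([float(tissue_shift.get(pid, 1.0)) for pid in ids])

    def _table(mu: np.ndarray, nreps: int, prefix: str) -> pd.DataFrame:
        noise = (
            rng.lognormal(0.0, ratio_sigma, (base.n_proteins, nreps))
            if ratio_sigma > 0
            else np.ones((base.n_proteins, nreps))
        )
        return pd.DataFrame(
            mu[:, None] * noise,
            index=pd.Index(ids, name="protein_id"),
            columns=[f"{prefix}{r + 1}" for r in range(nreps)],
        )

    wb = _table(mean_ratio, n_wholebody_reps, "wb_rep")
    ts = _table(mean_ratio * shift, n_tissue_reps, "ts_rep")
    group = np.where(
        shift == 0, "IV", np.where(shift > 1, "II", np.where(shift < 1, "III", "I"))
    )
    truth = pd.Series(group, index=ids, name="truth_group")
    return wb, ts, truth


# ---------------------------------------------------------------------------
# Cell simulation
# ---------------------------------------------------------------------------


@dataclass
class CellSimParams:
    """Parameters of the synthetic cell image.

    ``radial_distribution`` names the law of the fractional radial punctum
    position f in [0, 1): ``("uniform",)`` or ``("beta", a, b)``. Beta laws
    with a < b concentrate puncta perinuclearly, a > b peripherally.
    """

    image_shape: tuple[int, int] = (192, 192)
    n_puncta: int = 300
    radial_distribution: tuple = ("uniform",)
    punctum_intensity: float = 100.0
    spot_sigma: float = 1.5  # px, isotropic Gaussian PSF stand-in
    background: float = 0.0
    poisson_noise: bool = False
    cell_radius_frac: float = 0.42  # cell size relative to min(image dims)
    nucleus_radius_frac: float = 0.14
    n_boundary_points: int = 24  # points hulled into each polygon
    seed: int = 0

    def validate(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if not 0 < self.nucleus_radius_frac < self.cell_radius_frac < 0.5:
            raise ValueError(
                "need 0 < nucleus_radius_frac < cell_radius_frac < 0.5"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _sample_fraction(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    name = law[0].lower()
    if name == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if name == "beta":
        _, a, b = law
        return rng.beta(a, b, n)
    raise ValueError(f"unknown radial distribution {law!r}")


def _convex_blob(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    n_points: int,
) -> np.ndarray:
    """Convex hull of jittered points on a circle: a generic convex cell
    outline (counterclockwise in image coordinates)."""
    ang = np.sort(rng.uniform(0, 2 * math.pi, n_points))
    rad = radius * rng.uniform(0.75, 1.0, n_points)
    pts = center + np.c_[rad * np.cos(ang), rad * np.sin(ang)]
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return pts[hull.vertices]


def simulate_cell(
    p: CellSimParams,
) -> tuple[np.ndarray, CellGeometry, pd.DataFrame]:
    """Render one synthetic cell.

    Returns the image (float64), its :class:`CellGeometry`, and a truth
    table with one row per punctum (x, y, angle, fractional position f).
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    h, w = p.image_shape
    scale = min(h, w)
    center = np.array([w / 2.0, h / 2.0]) + rng.uniform(-0.02, 0.02, 2) * scale

    for _ in range(50):
        cell = _convex_blob(rng, center, p.cell_radius_frac * scale,
                            p.n_boundary_points)
        nucleus_center = center + rng.uniform(-0.05, 0.05, 2) * scale
        nucleus = _convex_blob(rng, nucleus_center,
                               p.nucleus_radius_frac * scale,
                               p.n_boundary_points)
        try:
            geom = CellGeometry(cell, nucleus, (h, w))
            break
        except ValueError:
            continue
    else:  # pragma: no cover - geometry params guarantee success quickly
        raise RuntimeError("could not draw a valid cell geometry")

    ox, oy = polygon_centroid(geom.nucleus_polygon)
    img = np.full((h, w), float(p.background))
    rows = []
    if p.n_puncta:
        theta = rng.uniform(0, 2 * math.pi, p.n_puncta)
        f = _sample_fraction(rng, p.radial_distribution, p.n_puncta)
        f = np.clip(f, 0.0, np.nextafter(1.0, 0.0))
        dx, dy = np.cos(theta), np.sin(theta)
        t_n = _ray_ts(geom.nucleus_polygon, ox, oy, dx, dy)
        t_c = _ray_ts(geom.cell_polygon, ox, oy, dx, dy)
        t = t_n + f * (t_c - t_n)
        px = ox + t * dx
        py = oy + t * dy
        for x, y, th, fr in zip(px, py, theta, f):
            _render_spot(img, x, y, p.punctum_intensity, p.spot_sigma)
            rows.append({"x": x, "y": y, "angle": th, "f": fr})
    if p.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    truth = pd.DataFrame(rows, columns=["x", "y", "angle", "f"])
    return img, geom, truth


def _render_spot(
    img: np.ndarray, x: float, y: float, amplitude: float, sigma: float
) -> None:
    """Add an isotropic Gaussian spot, evaluated on a +/-4 sigma window."""
    h, w = img.shape
    r = max(1, int(math.ceil(4 * sigma)))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((xs - x) ** 2 + (ys - y) ** 2) / (2 * sigma * sigma)
    )


def simulate_cell_population(
    base: CellSimParams, n_cells: int, seed: int | None = None
) -> list[tuple[np.ndarray, CellGeometry, pd.DataFrame]]:
    """n cells drawn with per-cell seeds derived from ``seed`` (defaults
    to ``base.seed``)."""
    root = np.random.default_rng(base.seed if seed is None else seed)
    out = []
    for _ in range(n_cells):
        params = CellSimParams(**{**base.__dict__,
                                  "seed": int(root.integers(2**31 - 1))})
        out.append(simulate_cell(params))
    return out
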