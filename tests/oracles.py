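"""Independent brute-force reference implementations used only by tests.

These deliberately use plain Python loops and textbook formulas, sharing
no code path with the package implementations they check.
"""

import math

import numpy as np


def brute_force_candidates(
    m, condition, fold_ft=10.0, fold_nontag=2.0, min_ip_detected=2
):
    """Loop-based three-criterion caller over an iFOT QuantMatrix."""
    ip = sorted(
        (s for s in m.samples
         if s.fraction_role == "lyso_ip" and s.condition == condition),
        key=lambda s: s.replicate,
    )
    ft = sorted(
        (s for s in m.samples
         if s.fraction_role == "flow_through" and s.condition == condition),
        key=lambda s: s.replicate,
    )
    nt = [s for s in m.samples if s.fraction_role == "non_tag"]
    members = set()
    for pid in m.protein_ids:
        ratios = []
        n_det = 0
        for si, sf in zip(ip, ft):
            iv = m.data.at[pid, si.sample_id]
            fv = m.data.at[pid, sf.sample_id]
            if iv > 0:
                n_det += 1
                ratios.append(iv / fv if fv > 0 else math.inf)
        if n_det < min_ip_detected:
            continue
        if any(r < fold_ft for r in ratios):
            continue
        mean_ip = sum(m.data.at[pid, s.sample_id] for s in ip) / len(ip)
        mean_nt = sum(m.data.at[pid, s.sample_id] for s in nt) / len(nt)
        if not (mean_ip > fold_nontag * mean_nt):
            continue
        members.add(pid)
    return members


def pearson_matrix(X):
    """Textbook Pearson r between columns of X via covariance / sd."""
    n, k = X.shape
    out = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            xi, xj = X[:, i], X[:, j]
            cov = ((xi - xi.mean()) * (xj - xj.mean())).sum() / (n - 1)
            out[i, j] = cov / (xi.std(ddof=1) * xj.std(ddof=1))
    return out


def chi_square_2x2(x1, n1, x2, n2):
    """Direct sum of (O - E)^2 / E over the pooled 2x2 table."""
    pooled = (x1 + x2) / (n1 + n2)
    table = [(x1, n1 - x1), (x2, n2 - x2)]
    expect = [(n1 * pooled, n1 * (1 - pooled)), (n2 * pooled, n2 * (1 - pooled))]
    return sum(
        (o - e) ** 2 / e for orow, erow in zip(table, expect)
        for o, e in zip(orow, erow)
    )


def _edge_crossings(poly, ox, oy, dx, dy):
    """All t > 0 where origin + t*(dx, dy) crosses an edge (scalar loops)."""
    ts = []
    n = len(poly)
    for i in range(n):
        ax, ay = poly[i]
        bx, by = poly[(i + 1) % n]
        ex, ey = bx - ax, by - ay
        denom = dx * ey - dy * ex
        if denom == 0:
            continue
        wx, wy = ax - ox, ay - oy
        t = (wx * ey - wy * ex) / denom
        s = (wx * dy - wy * dx) / denom
        if t > 0 and 0 <= s < 1:
            ts.append(t)
    return ts


def brute_force_region_labels(geom, R):
    """Per-pixel scalar ray casting against every polygon edge explicitly."""
    h, w = geom.image_shape
    from lysoprof.spatial import polygon_centroid

    ox, oy = polygon_centroid(geom.nucleus_polygon)
    labels = np.full((h, w), -2, dtype=int)
    for y in range(h):
        for x in range(w):
            dx, dy = x - ox, y - oy
            if dx == 0 and dy == 0:
                labels[y, x] = -1
                continue
            tn = min(
                _edge_crossings(geom.nucleus_polygon, ox, oy, dx, dy),
                default=math.inf,
            )
            tc = min(
                _edge_crossings(geom.cell_polygon, ox, oy, dx, dy),
                default=math.inf,
            )
            if 1.0 > tc:
                labels[y, x] = -2
            elif 1.0 < tn:
                labels[y, x] = -1
            else:
                f = (1.0 - tn) / (tc - tn)
                labels[y, x] = min(max(int(math.floor(f * R)), 0), R - 1)
    return labels


def classify_protein_level(patterns):
    """Brute-force protein-level aggregation over per-tissue
    (direction) patterns, direction in {'up', 'down', 'none'}."""
    if any(d == "up" for d in patterns) and any(d == "down" for d in patterns):
        return "discordant"
    if any(d == "up" for d in patterns):
        return "II"
    if any(d == "down" for d in patterns):
        return "III"
    return "I"
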