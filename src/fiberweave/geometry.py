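"""Low-level segment geometry shared by the phantom generator and the
crossing detector: vectorized minimum distances between 3-D segments and
closest-approach points between polylines."""

from __future__ import annotations

import numpy as np


def segment_segment_closest(p0, p1, q0, q1):
    """Closest approach between two families of 3-D segments.

    All inputs broadcast against each other with a trailing axis of length 3.
    Returns ``(dist, s, t)`` where ``s`` and ``t`` in [0, 1] parameterize the
    closest points ``p0 + s*(p1-p0)`` and ``q0 + t*(q1-q0)``.

    Uses the standard clamped quadratic minimization (robust to degenerate,
    parallel and zero-length segments).
    """
    p0, p1, q0, q1 = np.broadcast_arrays(
        np.asarray(p0, float), np.asarray(p1, float),
        np.asarray(q0, float), np.asarray(q1, float),
    )
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = np.einsum("...i,...i", d1, d1)
    e = np.einsum("...i,...i", d2, d2)
    f = np.einsum("...i,...i", d2, r)
    b = np.einsum("...i,...i", d1, d2)
    c = np.einsum("...i,...i", d1, r)
    denom = a * e - b * b

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-14, (b * f - c * e) / np.where(denom > 1e-14, denom, 1.0), 0.0)
        s = np.clip(s, 0.0, 1.0)
        t = np.where(e > 1e-14, (b * s + f) / np.where(e > 1e-14, e, 1.0), 0.0)
        t_cl = np.clip(t, 0.0, 1.0)
        # if t was clamped, recompute s for the clamped t
        s = np.where(
            t != t_cl,
            np.clip(np.where(a > 1e-14, (b * t_cl - c) / np.where(a > 1e-14, a, 1.0), 0.0), 0.0, 1.0),
            s,
        )
        t = t_cl
    cp = p0 + s[..., None] * d1
    cq = q0 + t[..., None] * d2
    dist = np.linalg.norm(cp - cq, axis=-1)
    return dist, s, t


def polyline_segments(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end arrays of the segments of an (n, 3) polyline."""
    poly = np.asarray(poly, float)
    return poly[:-1], poly[1:]


def polyline_pair_events(poly_a, poly_b, dist_thresh: float,
                         interior_margin: float = 0.0):
    """All segment pairs of two polylines that approach within ``dist_thresh``.

    Returns a list of ``(dist, midpoint, tan_a, tan_b)`` with the
    closest-approach midpoint (z, y, x) and unit tangents of the two
    segments involved.  With ``interior_margin`` > 0, contacts closer than
    that arc length to either polyline's endpoint are dropped — a genuine
    crossing has both curves passing *through* the contact, whereas traces
    broken at a junction merely touch it with an endpoint.
    """
    a0, a1 = polyline_segments(poly_a)
    b0, b1 = polyline_segments(poly_b)
    len_a = np.linalg.norm(a1 - a0, axis=1)
    len_b = np.linalg.norm(b1 - b0, axis=1)
    cum_a = np.concatenate([[0.0], np.cumsum(len_a)])
    cum_b = np.concatenate([[0.0], np.cumsum(len_b)])
    dist, s, t = segment_segment_closest(
        a0[:, None, :], a1[:, None, :], b0[None, :, :], b1[None, :, :]
    )
    ii, jj = np.nonzero(dist <= dist_thresh)
    events = []
    for i, j in zip(ii, jj):
        if interior_margin > 0:
            arc_a = cum_a[i] + s[i, j] * len_a[i]
            arc_b = cum_b[j] + t[i, j] * len_b[j]
            if (min(arc_a, cum_a[-1] - arc_a) < interior_margin
                    or min(arc_b, cum_b[-1] - arc_b) < interior_margin):
                continue
        cp = a0[i] + s[i, j] * (a1[i] - a0[i])
        cq = b0[j] + t[i, j] * (b1[j] - b0[j])
        ta = a1[i] - a0[i]
        tb = b1[j] - b0[j]
        na, nb = np.linalg.norm(ta), np.linalg.norm(tb)
        if na > 0:
            ta = ta / na
        if nb > 0:
            tb = tb / nb
        events.append((float(dist[i, j]), (cp + cq) / 2.0, ta, tb))
    return events


def polyline_min_distance(poly_a, poly_b) -> float:
    """Minimum 3-D distance between two polylines."""
    a0, a1 = polyline_segments(poly_a)
    b0, b1 = polyline_segments(poly_b)
    dist, _, _ = segment_segment_closest(
        a0[:, None, :], a1[:, None, :], b0[None, :, :], b1[None, :, :]
    )
    return float(dist.min())


def bbox_gap(poly_a, poly_b) -> float:
    """Lower bound on the distance between two polylines from their
    axis-aligned bounding boxes (cheap pre-screen)."""
    lo_a, hi_a = poly_a.min(axis=0), poly_a.max(axis=0)
    lo_b, hi_b = poly_b.min(axis=0), poly_b.max(axis=0)
    gap = np.maximum(0.0, np.maximum(lo_a - hi_b, lo_b - hi_a))
    return float(np.linalg.norm(gap))


def decimate_polyline(poly: np.ndarray, tol: float) -> np.ndarray:
    """Simplify a polyline by iterative endpoint splitting (Douglas–Peucker).

    Keeps vertices whose removal would displace the curve by more than
    ``tol`` (same units as the coordinates).
    """
    poly = np.asarray(poly, float)
    n = len(poly)
    if n <= 2:
        return poly
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = poly[j] - poly[i]
        seg_len = np.linalg.norm(seg)
        pts = poly[i + 1 : j] - poly[i]
        if seg_len < 1e-12:
            d = np.linalg.norm(pts, axis=1)
        else:
            u = seg / seg_len
            proj = pts @ u
            d = np.linalg.norm(pts - np.clip(proj, 0, seg_len)[:, None] * u, axis=1)
        k = int(np.argmax(d))
        if d[k] > tol:
            idx = i + 1 + k
            keep[idx] = True
            stack.append((i, idx))
            stack.append((idx, j))
    return poly[keep]
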