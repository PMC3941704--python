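"""Mean-shift edge bundling for connexels in 3D.

Geometrically similar connexels are deformed toward shared paths so that the
structure of a dense connectivity graph becomes visible. Similarity between
two straight edges P and Q is quantified by the product of four
compatibility criteria in [0, 1] (after Holten & van Wijk's force-directed
bundling measures):

* angle         ``Ca = |cos(alpha)|`` between the edge directions,
* scale         ``Cs = 2 / (lavg/lmin + lmax/lavg)`` with
  ``lavg = (|P| + |Q|)/2``,
* position      ``Cp = lavg / (lavg + ||Pm - Qm||)`` for midpoints Pm, Qm,
* visibility    ``Cv = min(V(P,Q), V(Q,P))`` where
  ``V(P,Q) = max(1 - 2||Pm - Im|| / ||I0 - I1||, 0)`` and I0, I1 are the
  orthogonal projections of Q's endpoints onto the line through P, Im their
  midpoint.

Edges are iteratively subdivided and each interior subdivision point is
shifted to the Gaussian-weighted mean of all interior points belonging to
edges whose overall compatibility ``Ce = Ca*Cs*Cp*Cv`` exceeds a threshold
``c_thr`` -- a mean-shift density-ascent step with kernel bandwidth ``r``.
Termination points never move. Because the kernel mean normalizes by the
local point count, sparse and dense bundles contract at comparable rates.

Compatibilities are computed once, from the original straight edges, and
reused across all cycles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import Connexel, ConnexelSet

__all__ = [
    "BundlePolyline",
    "CompatibilityMatrix",
    "BundlingParams",
    "edge_compatibility",
    "compatibility_matrix",
    "resample_polyline",
    "mean_shift_iteration",
    "bundle",
]

#: above this edge count a warning is issued; the all-pairs compatibility
#: matrix grows as E^2 (the reference desktop limit is about 40,000 edges).
EDGE_COUNT_WARNING = 40_000


@dataclass
class BundlePolyline:
    """An edge during/after bundling: ordered points with fixed endpoints."""

    points: np.ndarray          # (K, 3), K >= 2
    source: Connexel

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("polyline needs at least 2 points")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class CompatibilityMatrix:
    """Symmetric E x E matrix of overall compatibilities Ce in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class BundlingParams:
    """Mean-shift bundling parameters.

    c_thr : compatibility threshold gating which edges attract each other.
    kernel_radius : Gaussian bandwidth r in mm.
    n_cycles : number of subdivision cycles; cycle c runs ``n_cycles - c``
        mean-shift iterations.
    segment_base : per-cycle subdivision growth; cycle c uses
        ``ceil(segment_base ** c)`` segments (minimum 2).
    neighborhood_cutoff : hard kernel support in multiples of r
        (``None`` = infinite support, exact mode).
    """

    c_thr: float = 0.8
    kernel_radius: float = 5.0
    n_cycles: int = 10
    segment_base: float = 1.3
    neighborhood_cutoff: float | None = 3.0

    def __post_init__(self):
        if not 0.0 <= self.c_thr <= 1.0:
            raise ValueError("c_thr must lie in [0, 1]")
        if self.kernel_radius <= 0:
            raise ValueError("kernel_radius must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


# ---------------------------------------------------------------------------
# compatibility
# ---------------------------------------------------------------------------

def _visibility(p0, p1, q0, q1) -> float:
    """V(P,Q): how much of P's span Q occupies when projected onto P."""
    d = p1 - p0
    nd2 = float(d @ d)
    if nd2 == 0.0:
        return 0.0
    t0 = float((q0 - p0) @ d) / nd2
    t1 = float((q1 - p0) @ d) / nd2
    i0 = p0 + t0 * d
    i1 = p0 + t1 * d
    span = float(np.linalg.norm(i1 - i0))
    if span == 0.0:
        return 0.0
    im = (i0 + i1) / 2
    pm = (p0 + p1) / 2
    return max(1.0 - 2.0 * float(np.linalg.norm(pm - im)) / span, 0.0)


def edge_compatibility(P: Connexel, Q: Connexel):
    """Return (Ca, Cs, Cp, Cv, Ce) for two straight edges, each in [0, 1].

    Degenerate (zero-length) edges get all components 0.
    """
    p0, p1 = P.p, P.q
    q0, q1 = Q.p, Q.q
    lp = float(np.linalg.norm(p1 - p0))
    lq = float(np.linalg.norm(q1 - q0))
    if lp == 0.0 or lq == 0.0:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    ca = abs(float((p1 - p0) @ (q1 - q0)) / (lp * lq))
    ca = min(ca, 1.0)
    lavg = (lp + lq) / 2
    cs = 2.0 / (lavg / min(lp, lq) + max(lp, lq) / lavg)
    pm = (p0 + p1) / 2
    qm = (q0 + q1) / 2
    cp = lavg / (lavg + float(np.linalg.norm(pm - qm)))
    cv = min(_visibility(p0, p1, q0, q1), _visibility(q0, q1, p0, p1))
    return (ca, cs, cp, cv, ca * cs * cp * cv)


def compatibility_matrix(edges: ConnexelSet) -> CompatibilityMatrix:
    """All-pairs Ce, vectorized, computed from the original straight edges.

    The diagonal is 1 (each edge is fully compatible with itself) except for
    zero-length edges, which are incompatible with everything.
    """
    e = len(edges)
    if e < 1:
        raise ValueError("need at least one edge")
    p, q = edges.p, edges.q
    d = q - p                                    # (E, 3)
    lengths = np.linalg.norm(d, axis=1)          # (E,)
    ok = lengths > 0
    safe_len = np.where(ok, lengths, 1.0)
    u = d / safe_len[:, None]

    ca = np.abs(u @ u.T)
    np.clip(ca, 0.0, 1.0, out=ca)

    lavg = (lengths[:, None] + lengths[None, :]) / 2
    lmin = np.minimum(lengths[:, None], lengths[None, :])
    lmax = np.maximum(lengths[:, None], lengths[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        cs = 2.0 / (lavg / np.where(lmin == 0, 1.0, lmin) + lmax / np.where(lavg == 0, 1.0, lavg))

    mid = (p + q) / 2
    dm = np.linalg.norm(mid[:, None, :] - mid[None, :, :], axis=2)
    cp = lavg / (lavg + dm)

    # visibility: project edge b's endpoints onto edge a's line
    rel_p = p[None, :, :] - p[:, None, :]        # (a, b, 3): q0 - p0
    rel_q = q[None, :, :] - p[:, None, :]        # (a, b, 3): q1 - p0
    t0 = np.einsum("abk,ak->ab", rel_p, u) / safe_len[:, None]
    t1 = np.einsum("abk,ak->ab", rel_q, u) / safe_len[:, None]
    span = np.abs(t1 - t0) * lengths[:, None]
    tm = (t0 + t1) / 2
    # ||Pm - Im|| along edge a: |0.5 - tm| * len_a
    dist_mid = np.abs(0.5 - tm) * lengths[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(span > 0, 1.0 - 2.0 * dist_mid / np.where(span == 0, 1.0, span), 0.0)
    v = np.maximum(v, 0.0)
    cv = np.minimum(v, v.T)

    ce = ca * cs * cp * cv
    bad = ~ok
    ce[bad, :] = 0.0
    ce[:, bad] = 0.0
    np.fill_diagonal(ce, np.where(ok, 1.0, 0.0))
    ce = (ce + ce.T) / 2        # enforce exact symmetry against fp noise
    np.clip(ce, 0.0, 1.0, out=ce)
    return CompatibilityMatrix(ce)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_polyline(line: BundlePolyline, n_segments: int) -> BundlePolyline:
    """Resample to ``n_segments + 1`` points equally spaced by arc length.

    Endpoints are preserved exactly.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    pts = line.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    k = n_segments + 1
    if total == 0.0:
        new = np.repeat(pts[:1], k, axis=0)
    else:
        targets = np.linspace(0.0, total, k)
        new = np.empty((k, 3))
        for ax in range(3):
            new[:, ax] = np.interp(targets, arc, pts[:, ax])
    new[0] = pts[0]
    new[-1] = pts[-1]
    return BundlePolyline(new, line.source)


# ---------------------------------------------------------------------------
# mean shift
# ---------------------------------------------------------------------------

def mean_shift_iteration(lines, compat: CompatibilityMatrix,
                         params: BundlingParams):
    """One synchronous mean-shift step over all interior subdivision points.

    For each interior point x of edge e, the candidate set is every interior
    point of every edge f with ``compat[e, f] >= c_thr`` (including e
    itself) lying within ``neighborhood_cutoff * r`` of x; x moves to the
    Gaussian-weighted mean ``sum(w_i x_i)/sum(w_i)`` with
    ``w_i = exp(-||x - x_i||^2 / (2 r^2))``. Endpoints are untouched and all
    shifts are computed from the pre-iteration snapshot.
    """
    e = len(lines)
    k = lines[0].n_points
    for ln in lines:
        if ln.n_points != k:
            raise ValueError("all polylines must share the same point count")
    if k <= 2:
        return [BundlePolyline(ln.points.copy(), ln.source) for ln in lines]

    r = params.kernel_radius
    cutoff = (None if params.neighborhood_cutoff is None
              else params.neighborhood_cutoff * r)
    interior = np.stack([ln.points[1:-1] for ln in lines])   # (E, K-2, 3)
    flat = interior.reshape(-1, 3)
    edge_of = np.repeat(np.arange(e), k - 2)
    compat_ok = compat.values >= params.c_thr                # (E, E)

    new_interior = interior.copy()
    for a in range(e):
        mask_edges = compat_ok[a]
        cand_mask = mask_edges[edge_of]                      # (E*(K-2),)
        cand = flat[cand_mask]
        x = interior[a]                                      # (K-2, 3)
        diff = x[:, None, :] - cand[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        w = np.exp(-d2 / (2 * r * r))
        if cutoff is not None:
            w = np.where(d2 <= cutoff * cutoff, w, 0.0)
        wsum = w.sum(axis=1)
        ok = wsum > 0
        shifted = (w @ cand) / np.where(wsum == 0, 1.0, wsum)[:, None]
        new_interior[a][ok] = shifted[ok]

    out = []
    for a, ln in enumerate(lines):
        pts = ln.points.copy()
        pts[1:-1] = new_interior[a]
        out.append(BundlePolyline(pts, ln.source))
    return out


def segments_for_cycle(c: int, segment_base: float = 1.3) -> int:
    """Subdivision segment count for cycle c (1-based): ceil(base^c), >= 2."""
    return max(int(math.ceil(segment_base ** c)), 2)


def bundle(edges: ConnexelSet, params: BundlingParams | None = None,
           compat: CompatibilityMatrix | None = None,
           progress=None):
    """Run the full bundling schedule on a set of straight connexels.

    For cycle ``c = 1 .. n_cycles`` every line is resampled to
    ``ceil(segment_base ** c)`` equal arc-length segments (minimum 2) and
    then moved through ``n_cycles - c`` mean-shift iterations. The pairwise
    compatibilities are computed once from the original straight edges.
    Deterministic; an empty input yields an empty output.

    ``progress``, if given, is called as ``progress(cycle, iteration)``.
    """
    if params is None:
        params = BundlingParams()
    if len(edges) == 0:
        return []
    if len(edges) > EDGE_COUNT_WARNING:
        warnings.warn(
            f"bundling {len(edges)} edges: the all-pairs compatibility "
            f"matrix needs O(E^2) memory (reference limit ~{EDGE_COUNT_WARNING})",
            stacklevel=2,
        )
    if compat is None:
        compat = compatibility_matrix(edges)
    lines = [BundlePolyline(np.stack([edges.p[i], edges.q[i]]), edges[i])
             for i in range(len(edges))]
    for c in range(1, params.n_cycles + 1):
        n_seg = segments_for_cycle(c, params.segment_base)
        lines = [resample_polyline(ln, n_seg) for ln in lines]
        for it in range(max(params.n_cycles - c, 0)):
            lines = mean_shift_iteration(lines, compat, params)
            if progress is not None:
                progress(c, it)
    return lines
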