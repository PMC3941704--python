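"""Connectivity-glyph geometry: per-node visual summaries of a node's
whole-brain connectivity profile.

Glyph types
-----------
point
    For each above-threshold connection of a node, one point at
    ``g = pg + s * (q_d - p_d)``: the node's placement position shifted
    toward the connected node by the scaled relative position in the chosen
    geometry representation.
vector
    A segment from the node position to each of those points, emphasizing
    long-range connections.
pie
    Equal-angle triangular sectors (one per connection) in the plane
    orthogonal to a supplied view direction, sorted by orientation-color hue
    or by connectivity value; radius interpolates between a constant ``rn``
    and an equal-area-per-connection radius via ``r = i*rn + (1-i)*ra``.
difference
    One glyph per unique mesh edge, at its midpoint, showing the absolute
    difference of the two endpoint nodes' Fisher-transformed connectivity
    profiles.

Geometry, color and placement representations are independent: a glyph can
be placed on the inflated surface, shaped by pial coordinates and colored by
the spherical representation. Orientation colors map the absolute components
of the normalized connection vector to RGB (the standard DTI scheme); value
colors go through an arbitrary colormap with optional transparency ramp.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (ConnectivityMatrix, SurfaceSet, ThresholdSpec, alpha_map,
                    fisher_r_to_z)

__all__ = [
    "GlyphParams",
    "GlyphGeometry",
    "Primitive",
    "Colormap",
    "orientation_color",
    "point_glyph",
    "vector_glyph",
    "pie_glyph",
    "difference_values",
    "difference_glyphs",
    "value_color",
    "node_connections",
]


@dataclass
class GlyphParams:
    """Parameters steering glyph geometry and color.

    ``scale`` (s) sets the point/vector offset magnitude; ``interp`` (i)
    interpolates the pie radius between equal-area (i=0) and constant
    (i=1); ``rotation`` is three intrinsic x-y-z Euler angles in degrees
    applied to point/vector offsets about the glyph center.
    """

    glyph_type: str = "point"           # point | vector | pie | difference
    scale: float = 0.5
    interp: float = 1.0
    base_radius: float = 2.0            # rn, mm
    max_radius: float = 4.0             # r_max, mm
    rotation: tuple = (0.0, 0.0, 0.0)   # degrees
    color_mode: str = "orientation"     # orientation | value
    geometry_rep: str | None = None
    color_rep: str | None = None
    placement_rep: str | None = None
    min_value: float = -np.inf
    min_length: float = 0.0
    view_direction: tuple = (0.0, 0.0, 1.0)
    colormap: "Colormap | None" = None

    def __post_init__(self):
        if not 0.0 <= self.interp <= 1.0:
            raise ValueError("interp must lie in [0, 1]")
        if self.base_radius <= 0 or self.max_radius <= 0:
            raise ValueError("radii must be > 0")


@dataclass
class Primitive:
    """One renderable primitive: a point, segment or triangle with color."""

    kind: str                   # point | segment | triangle
    coordinates: np.ndarray     # (1|2|3, 3) mm
    rgba: np.ndarray            # (4,) in [0, 1]
    node_id: int
    z_order: float = 0.0        # depth hint: smaller values drawn on top

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.rgba = np.clip(np.asarray(self.rgba, dtype=float).reshape(4), 0, 1)


class GlyphGeometry:
    """A flat list of primitives plus helpers for export."""

    def __init__(self, primitives=()):
        self.primitives = list(primitives)

    def __len__(self):
        return len(self.primitives)

    def __iter__(self):
        return iter(self.primitives)

    def extend(self, other: "GlyphGeometry"):
        self.primitives.extend(other.primitives)

    def to_rows(self):
        """Rows (node_id, kind, x0..z2 padded with nan, r, g, b, a) for CSV."""
        rows = []
        for pr in self.primitives:
            coords = np.full(9, np.nan)
            flat = pr.coordinates.reshape(-1)
            coords[:len(flat)] = flat
            rows.append([pr.node_id, pr.kind, *coords, *pr.rgba])
        return rows


class Colormap:
    """Piecewise-linear colormap over a value interval [lo, hi].

    ``colors`` is an (n, 3) or (n, 4) array of anchor colors spaced evenly
    over the interval; lookups clamp outside it.
    """

    def __init__(self, colors, lo: float, hi: float):
        colors = np.asarray(colors, dtype=float)
        if colors.ndim != 2 or colors.shape[1] not in (3, 4):
            raise ValueError("colors must be (n, 3) or (n, 4)")
        if colors.shape[1] == 3:
            colors = np.hstack([colors, np.ones((len(colors), 1))])
        if not lo < hi:
            raise ValueError(f"lo ({lo}) must be < hi ({hi})")
        self.colors = colors
        self.lo = float(lo)
        self.hi = float(hi)

    def __call__(self, values) -> np.ndarray:
        v = np.clip((np.asarray(values, dtype=float) - self.lo)
                    / (self.hi - self.lo), 0.0, 1.0)
        x = np.linspace(0.0, 1.0, len(self.colors))
        out = np.stack([np.interp(v, x, self.colors[:, c]) for c in range(4)],
                       axis=-1)
        return out

    @classmethod
    def green_red(cls, lo: float, hi: float) -> "Colormap":
        """Isoluminant green-to-red opponent scale for shaded surfaces."""
        return cls(np.array([[0.0, 0.6, 0.0], [0.7, 0.7, 0.0], [0.8, 0.0, 0.0]]),
                   lo, hi)


# ---------------------------------------------------------------------------
# color
# ---------------------------------------------------------------------------

def orientation_color(p_rep, q_rep) -> np.ndarray:
    """RGB from connection orientation: |unit(q - p)| componentwise.

    Symmetric in edge direction; the standard DTI orientation scheme.
    """
    p_rep = np.asarray(p_rep, dtype=float).reshape(3)
    q_rep = np.asarray(q_rep, dtype=float).reshape(3)
    d = q_rep - p_rep
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("orientation color undefined for a zero-length edge")
    return np.abs(d / n)


def value_color(value, colormap: Colormap, alpha=None) -> np.ndarray:
    """Color a connectivity value through a linear colormap; ``alpha``, if
    given, overrides the colormap's alpha channel."""
    rgba = np.atleast_2d(colormap(value)).copy()
    if alpha is not None:
        rgba[:, 3] = alpha
    out = rgba if np.ndim(value) else rgba[0]
    return out


def _hue(rgb) -> float:
    return colorsys.rgb_to_hsv(*np.clip(rgb, 0, 1))[0]


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def node_connections(matrix: ConnectivityMatrix, node: int,
                     surfaces: SurfaceSet, params: GlyphParams):
    """Above-threshold connections of one node as (target_idx, value) arrays.

    ``min_value`` applies to the matrix value (two-sided thresholds can be
    emulated on a preprocessed matrix); ``min_length`` to the distance in
    the geometry representation.
    """
    row = matrix.values[node].copy()
    row[node] = -np.inf
    keep = row >= params.min_value
    if params.min_length > 0:
        coords = surfaces.coordinates(params.geometry_rep)
        d = np.linalg.norm(coords - coords[node], axis=1)
        keep &= d >= params.min_length
    keep[node] = False
    idx = np.where(keep)[0]
    return idx, row[idx]


def _connection_colors(node, targets, values, surfaces, params: GlyphParams):
    if params.color_mode == "orientation":
        coords = surfaces.coordinates(params.color_rep)
        out = []
        for t in targets:
            rgb = orientation_color(coords[node], coords[t])
            out.append(np.append(rgb, 1.0))
        return np.array(out).reshape(-1, 4)
    if params.color_mode == "value":
        cmap = params.colormap
        if cmap is None:
            vmax = max(np.abs(values).max(), 1e-12) if len(values) else 1.0
            cmap = Colormap.green_red(-vmax, vmax)
        return np.atleast_2d(cmap(values))
    raise ValueError(f"unknown color_mode {params.color_mode!r}")


def _rotation(params: GlyphParams) -> Rotation | None:
    if not any(params.rotation):
        return None
    return Rotation.from_euler("XYZ", params.rotation, degrees=True)


def _glyph_points(node, targets, surfaces, params: GlyphParams) -> np.ndarray:
    """Point-glyph positions g = pg + s*(q_d - p_d), optionally rotated."""
    geo = surfaces.coordinates(params.geometry_rep)
    place = surfaces.coordinates(params.placement_rep)
    offsets = params.scale * (geo[targets] - geo[node])
    rot = _rotation(params)
    if rot is not None:
        offsets = rot.apply(offsets)
    return place[node] + offsets


# ---------------------------------------------------------------------------
# glyph builders
# ---------------------------------------------------------------------------

def point_glyph(node, connections, params: GlyphParams,
                surfaces: SurfaceSet) -> GlyphGeometry:
    """One point per connection, shifted toward the connected node."""
    targets, values = _as_connection_arrays(connections)
    if len(targets) == 0:
        return GlyphGeometry()
    pts = _glyph_points(node, targets, surfaces, params)
    colors = _connection_colors(node, targets, values, surfaces, params)
    return GlyphGeometry(
        Primitive("point", pts[i:i + 1], colors[i], int(node))
        for i in range(len(targets))
    )


def vector_glyph(node, connections, params: GlyphParams,
                 surfaces: SurfaceSet) -> GlyphGeometry:
    """One segment from the node position to each point-glyph position."""
    targets, values = _as_connection_arrays(connections)
    if len(targets) == 0:
        return GlyphGeometry()
    pts = _glyph_points(node, targets, surfaces, params)
    pg = surfaces.coordinates(params.placement_rep)[node]
    colors = _connection_colors(node, targets, values, surfaces, params)
    return GlyphGeometry(
        Primitive("segment", np.stack([pg, pts[i]]), colors[i], int(node))
        for i in range(len(targets))
    )


def pie_radius(n: int, params: GlyphParams, n_ref: int) -> float:
    """Pie radius r = i*rn + (1-i)*ra with ra = r_max * sqrt(n / n_ref).

    The square root makes each connection cover an equal area at i = 0;
    ``n_ref`` is the largest connection count in the dataset. Set
    ``strict_linear`` semantics by pre-scaling if proportional radius is
    wanted instead.
    """
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    ra = params.max_radius * np.sqrt(min(n, n_ref) / n_ref)
    return params.interp * params.base_radius + (1 - params.interp) * ra


def pie_glyph(node, connections, params: GlyphParams, surfaces: SurfaceSet,
              n_ref: int | None = None) -> GlyphGeometry:
    """Equal-angle pie sectors orthogonal to the view direction.

    Sectors are sorted by orientation-color hue (orientation mode) or by
    connectivity value (value mode), ties broken by target node index, and
    laid out counterclockwise from the first in-plane axis. The glyph's
    ``z_order`` hint equals its radius so smaller pies sort on top.
    """
    targets, values = _as_connection_arrays(connections)
    n = len(targets)
    if n == 0:
        return GlyphGeometry()
    if n_ref is None:
        n_ref = n
    colors = _connection_colors(node, targets, values, surfaces, params)
    if params.color_mode == "orientation":
        keys = [(_hue(colors[i, :3]), int(targets[i])) for i in range(n)]
    else:
        keys = [(values[i], int(targets[i])) for i in range(n)]
    order = sorted(range(n), key=lambda i: keys[i])

    r = pie_radius(n, params, n_ref)
    center = surfaces.coordinates(params.placement_rep)[node]
    # orthonormal basis of the plane orthogonal to the view direction
    w = np.asarray(params.view_direction, dtype=float)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("view_direction must be non-zero")
    w = w / nw
    a = np.array([1.0, 0.0, 0.0])
    if abs(w @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = a - (a @ w) * w
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)

    prims = []
    dtheta = 2 * np.pi / n
    for slot, i in enumerate(order):
        t0, t1 = slot * dtheta, (slot + 1) * dtheta
        rim0 = center + r * (np.cos(t0) * e1 + np.sin(t0) * e2)
        rim1 = center + r * (np.cos(t1) * e1 + np.sin(t1) * e2)
        prims.append(Primitive("triangle", np.stack([center, rim0, rim1]),
                               colors[i], int(node), z_order=r))
    return GlyphGeometry(prims)


def _as_connection_arrays(connections):
    """Accept a list of (target, value) pairs or an (idx, values) tuple."""
    if isinstance(connections, tuple) and len(connections) == 2 \
            and np.ndim(connections[0]) == 1:
        return (np.asarray(connections[0], dtype=int),
                np.asarray(connections[1], dtype=float))
    pairs = list(connections)
    if not pairs:
        return np.zeros(0, dtype=int), np.zeros(0)
    t, v = zip(*pairs)
    return np.asarray(t, dtype=int), np.asarray(v, dtype=float)


# ---------------------------------------------------------------------------
# difference glyphs
# ---------------------------------------------------------------------------

def difference_values(matrix: ConnectivityMatrix, node_a: int,
                      node_b: int) -> np.ndarray:
    """Per-target |z(r_ak) - z(r_bk)| with Fisher z = atanh; entries for the
    two nodes themselves are 0."""
    n = matrix.n_nodes
    for nd in (node_a, node_b):
        if not 0 <= nd < n:
            raise IndexError(f"node {nd} out of range for {n} nodes")
    if node_a == node_b:
        raise ValueError("difference requires two distinct nodes")
    d = np.abs(fisher_r_to_z(matrix.values[node_a])
               - fisher_r_to_z(matrix.values[node_b]))
    d[[node_a, node_b]] = 0.0
    return d


def unique_mesh_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (i < j) of a triangle mesh, sorted."""
    f = np.asarray(faces, dtype=np.int64)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def difference_glyphs(matrix: ConnectivityMatrix, surfaces: SurfaceSet,
                      params: GlyphParams) -> GlyphGeometry:
    """One glyph per unique mesh edge at the edge midpoint, showing the
    thresholded absolute Fisher-z profile difference of its two nodes.

    Primitives are value-colored points placed like point glyphs but
    anchored at the edge midpoint; ``min_value`` thresholds the difference
    magnitude, ``min_length`` the midpoint-to-target distance in the
    geometry representation.
    """
    edges = unique_mesh_edges(surfaces.surfaces[0].faces)
    geo = surfaces.coordinates(params.geometry_rep)
    place = surfaces.coordinates(params.placement_rep)
    dmax = 0.0
    per_edge = []
    for a, b in edges:
        d = difference_values(matrix, int(a), int(b))
        keep = d >= params.min_value
        keep[[a, b]] = False
        mid_geo = (geo[a] + geo[b]) / 2
        if params.min_length > 0:
            dist = np.linalg.norm(geo - mid_geo, axis=1)
            keep &= dist >= params.min_length
        idx = np.where(keep)[0]
        per_edge.append((int(a), int(b), idx, d[idx], mid_geo))
        if len(idx):
            dmax = max(dmax, d[idx].max())
    cmap = params.colormap or Colormap.green_red(0.0, max(dmax, 1e-12))

    prims = []
    rot = _rotation(params)
    for a, b, idx, dvals, mid_geo in per_edge:
        if not len(idx):
            continue
        mid_place = (place[a] + place[b]) / 2
        offs = params.scale * (geo[idx] - mid_geo)
        if rot is not None:
            offs = rot.apply(offs)
        colors = np.atleast_2d(cmap(dvals))
        for k in range(len(idx)):
            prims.append(Primitive("point", (mid_place + offs[k])[None, :],
                                   colors[k], int(a)))
    return GlyphGeometry(prims)
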