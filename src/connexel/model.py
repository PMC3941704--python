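"""Core connexel data model: domain types, thresholding, and group statistics.

A *connexel* is the connection between two 3D positions (mm) together with a
connectivity strength -- a single point in the 6D pair-of-positions space.
Dense functional-connectivity data is represented here either as a square
symmetric node-by-node :class:`ConnectivityMatrix` over a cortical surface
mesh, or as an explicit :class:`ConnexelSet` of termination-point pairs.

Coordinates throughout are millimetres in a common anatomical space; surfaces
and connexels are assumed pre-aligned (rotational components of volume
affines are honoured only for volume sampling, never for display alignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Connexel",
    "ConnexelSet",
    "SurfaceMesh",
    "SurfaceSet",
    "ConnectivityMatrix",
    "ThresholdSpec",
    "matrix_to_connexels",
    "filter_connexels",
    "pearson_matrix",
    "sample_volume_to_nodes",
    "fisher_r_to_z",
    "fisher_z_to_r",
    "fisher_average",
    "covariate_correlation",
    "seed_map",
    "alpha_map",
]

#: correlations are clamped to +/- (1 - R_CLAMP_EPS) before atanh so Fisher
#: transforms stay finite for |r| = 1 inputs.
R_CLAMP_EPS = 1e-7


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Connexel:
    """A pair of 3D termination points (mm) plus a connectivity value."""

    p: np.ndarray
    q: np.ndarray
    value: float

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float).reshape(3)
        q = np.asarray(self.q, dtype=float).reshape(3)
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
            raise ValueError("connexel termination points must be finite")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "value", float(self.value))

    @property
    def length(self) -> float:
        """Euclidean distance between the termination points, mm."""
        return float(np.linalg.norm(self.q - self.p))


class ConnexelSet:
    """Ordered collection of connexels, stored columnar.

    Parameters
    ----------
    p, q : (E, 3) float arrays
        Termination points in mm.
    values : (E,) float array
        Connectivity strengths.
    space_label : str
        Free-text name of the coordinate space.
    """

    def __init__(self, p, q, values, space_label: str = "unknown"):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        q = np.atleast_2d(np.asarray(q, dtype=float))
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if p.size == 0:
            p = p.reshape(0, 3)
            q = q.reshape(0, 3)
            values = values.reshape(0)
        if p.shape != q.shape or p.shape[1] != 3 or len(values) != len(p):
            raise ValueError(
                f"inconsistent connexel arrays: p {p.shape}, q {q.shape}, "
                f"values {values.shape}"
            )
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
            raise ValueError("connexel termination points must be finite")
        self.p = p
        self.q = q
        self.values = values
        self.space_label = space_label

    @classmethod
    def from_connexels(cls, items, space_label: str = "unknown") -> "ConnexelSet":
        items = list(items)
        if not items:
            return cls.empty(space_label)
        return cls(
            np.array([c.p for c in items]),
            np.array([c.q for c in items]),
            np.array([c.value for c in items]),
            space_label,
        )

    @classmethod
    def empty(cls, space_label: str = "unknown") -> "ConnexelSet":
        z = np.zeros((0, 3))
        return cls(z, z, np.zeros(0), space_label)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i) -> Connexel:
        if isinstance(i, (int, np.integer)):
            return Connexel(self.p[i], self.q[i], self.values[i])
        raise TypeError("use .subset() for fancy indexing")

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def subset(self, mask_or_idx) -> "ConnexelSet":
        """Order-preserving subset by boolean mask or index array."""
        return ConnexelSet(
            self.p[mask_or_idx], self.q[mask_or_idx],
            self.values[mask_or_idx], self.space_label,
        )

    def lengths(self) -> np.ndarray:
        """Per-connexel Euclidean endpoint distance, mm."""
        return np.linalg.norm(self.q - self.p, axis=1)

    def __repr__(self):
        return f"ConnexelSet({len(self)} connexels, space={self.space_label!r})"


@dataclass
class SurfaceMesh:
    """Triangle mesh: vertices (N, 3) in mm, faces (M, 3) 0-based indices."""

    vertices: np.ndarray
    faces: np.ndarray
    representation_name: str = "other"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise ValueError(
                    f"face index out of range [0, {n}) in surface "
                    f"{self.representation_name!r}"
                )
            degen = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degen.any():
                raise ValueError(
                    f"{int(degen.sum())} degenerate face(s) in surface "
                    f"{self.representation_name!r}"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


class SurfaceSet:
    """Multiple corresponding representations (pial/inflated/sphere/...) of
    one cortical surface, sharing node indexing, each with a translation
    offset (mm) applied when coordinates are queried.
    """

    def __init__(self, surfaces, offsets=None):
        surfaces = list(surfaces)
        if not surfaces:
            raise ValueError("SurfaceSet requires at least one surface")
        n = surfaces[0].n_vertices
        faces0 = surfaces[0].faces
        for s in surfaces[1:]:
            if s.n_vertices != n:
                raise ValueError(
                    f"surfaces disagree on node count: {n} vs {s.n_vertices}"
                )
            if not np.array_equal(s.faces, faces0):
                raise ValueError("surfaces must share identical face arrays")
        if offsets is None:
            offsets = [np.zeros(3)] * len(surfaces)
        offsets = [np.asarray(o, dtype=float).reshape(3) for o in offsets]
        if len(offsets) != len(surfaces):
            raise ValueError("one offset per surface required")
        self.surfaces = surfaces
        self.offsets = offsets

    @property
    def n_vertices(self) -> int:
        return self.surfaces[0].n_vertices

    @property
    def names(self):
        return [s.representation_name for s in self.surfaces]

    def get(self, representation: str | None = None) -> SurfaceMesh:
        """Return the named representation (default: the first / display
        surface)."""
        if representation is None:
            return self.surfaces[0]
        for s in self.surfaces:
            if s.representation_name == representation:
                return s
        raise KeyError(
            f"no representation {representation!r}; have {self.names}"
        )

    def coordinates(self, representation: str | None = None) -> np.ndarray:
        """Vertex coordinates of a representation with its offset applied."""
        if representation is None:
            idx = 0
        else:
            names = self.names
            if representation not in names:
                raise KeyError(
                    f"no representation {representation!r}; have {names}"
                )
            idx = names.index(representation)
        return self.surfaces[idx].vertices + self.offsets[idx]


class ConnectivityMatrix:
    """Square symmetric node x node matrix of connectivity values.

    ``kind`` is one of ``correlation`` (entries in [-1, 1], unit diagonal),
    ``covariate_r`` (cross-subject correlation with a covariate, zero
    diagonal), ``z`` (Fisher-transformed) or ``generic``.
    """

    KINDS = ("correlation", "covariate_r", "z", "generic")

    def __init__(self, values, kind: str = "generic",
                 degenerate_nodes=(), validate: bool = True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {values.shape}")
        if kind not in self.KINDS:
            raise ValueError(f"unknown kind {kind!r}")
        if validate:
            asym = np.abs(values - values.T).max() if values.size else 0.0
            if asym > 1e-6:
                raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")
            if kind == "correlation" and values.size:
                if np.abs(values).max() > 1 + 1e-9:
                    raise ValueError("correlation entries must lie in [-1, 1]")
                if np.abs(np.diag(values) - 1).max() > 1e-9:
                    raise ValueError("correlation diagonal must equal 1")
        self.values = values
        self.kind = kind
        #: node indices whose correlations were degenerate (zero variance)
        self.degenerate_nodes = tuple(int(i) for i in degenerate_nodes)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def __repr__(self):
        return f"ConnectivityMatrix({self.n_nodes}x{self.n_nodes}, kind={self.kind!r})"


@dataclass
class ThresholdSpec:
    """Connexel filtering thresholds.

    ``min_value`` is compared against the signed connectivity value, or
    against its absolute value when ``two_sided`` is set (useful for matrices
    mixing positive and negative correlations). ``min_length`` (mm) uses
    Euclidean endpoint distance measured on ``geometry_representation``
    coordinates (``None`` = the display surface, i.e. the first of the set).
    """

    min_value: float = -np.inf
    min_length: float = 0.0
    geometry_representation: str | None = None
    two_sided: bool = False

    def __post_init__(self):
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")

    def value_mask(self, values: np.ndarray) -> np.ndarray:
        v = np.abs(values) if self.two_sided else values
        return v >= self.min_value


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def matrix_to_connexels(matrix: ConnectivityMatrix,
                        surface: SurfaceMesh,
                        spec: ThresholdSpec) -> ConnexelSet:
    """Turn the above-threshold upper triangle of a connectivity matrix into
    connexels anchored at surface node positions.

    One connexel is emitted per unordered node pair (i < j) whose value
    passes ``spec.min_value`` and whose node distance passes
    ``spec.min_length``; the diagonal is never emitted.
    """
    n = matrix.n_nodes
    if surface.n_vertices != n:
        raise ValueError(
            f"matrix has {n} nodes but surface has {surface.n_vertices} vertices"
        )
    ii, jj = np.triu_indices(n, k=1)
    vals = matrix.values[ii, jj]
    keep = spec.value_mask(vals)
    if spec.min_length > 0:
        d = np.linalg.norm(surface.vertices[ii] - surface.vertices[jj], axis=1)
        keep &= d >= spec.min_length
    ii, jj, vals = ii[keep], jj[keep], vals[keep]
    out = ConnexelSet(surface.vertices[ii], surface.vertices[jj], vals,
                      space_label=surface.representation_name)
    out.node_pairs = np.stack([ii, jj], axis=1)
    return out


def filter_connexels(cset: ConnexelSet, spec: ThresholdSpec) -> ConnexelSet:
    """Order-preserving subset passing both threshold predicates."""
    keep = spec.value_mask(cset.values)
    if spec.min_length > 0:
        keep = keep & (cset.lengths() >= spec.min_length)
    return cset.subset(keep)


def pearson_matrix(node_timeseries: np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation between the timeseries of every node pair.

    Zero-variance nodes get correlation 0 against all others (diagonal stays
    1) and are listed in ``degenerate_nodes`` so downstream thresholding
    remains total.
    """
    ts = np.asarray(node_timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("node_timeseries must be N x T")
    n, t = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    sd = ts.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    centered = ts - ts.mean(axis=1, keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = centered / (sd_safe[:, None] * np.sqrt(t))
    r = z @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2
    return ConnectivityMatrix(r, kind="correlation",
                              degenerate_nodes=degenerate)


def sample_volume_to_nodes(volume4d: np.ndarray, affine: np.ndarray,
                           surface: SurfaceMesh):
    """Sample a 4D volume to surface nodes by nearest-neighbour voxel lookup.

    Node positions (mm) are mapped through the inverse affine into voxel
    space and rounded to the nearest voxel centre. Nodes falling outside the
    grid get an all-zero series.

    Returns
    -------
    series : (N, T) array
    outside : int array of node indices that fell outside the volume
    """
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4:
        raise ValueError("volume4d must be X x Y x Z x T")
    affine = np.asarray(affine, dtype=float).reshape(4, 4)
    try:
        inv = np.linalg.inv(affine)
    except np.linalg.LinAlgError as e:
        raise ValueError("affine is singular") from e
    xyz1 = np.hstack([surface.vertices, np.ones((surface.n_vertices, 1))])
    ijk = np.rint((xyz1 @ inv.T)[:, :3]).astype(np.int64)
    shape = np.array(vol.shape[:3])
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    series = np.zeros((surface.n_vertices, vol.shape[3]))
    idx = ijk[inside]
    series[inside] = vol[idx[:, 0], idx[:, 1], idx[:, 2], :]
    return series, np.where(~inside)[0]


def fisher_r_to_z(r):
    """Fisher r-to-z transform, atanh(r), with |r| clamped below 1."""
    r = np.clip(np.asarray(r, dtype=float), -(1 - R_CLAMP_EPS), 1 - R_CLAMP_EPS)
    return np.arctanh(r)


def fisher_z_to_r(z):
    """Inverse Fisher transform, tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def fisher_average(matrices) -> ConnectivityMatrix:
    """Group-average correlation matrices via Fisher's transform.

    Entries are r-to-z transformed, averaged entrywise across matrices, and
    transformed back; the diagonal is forced to 1.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    shape = matrices[0].values.shape
    for m in matrices[1:]:
        if m.values.shape != shape:
            raise ValueError(
                f"shape mismatch: {shape} vs {m.values.shape}"
            )
    z = np.mean([fisher_r_to_z(m.values) for m in matrices], axis=0)
    r = fisher_z_to_r(z)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, kind="correlation")


def covariate_correlation(matrices, covariate) -> ConnectivityMatrix:
    """Per-connexel Pearson correlation between connectivity strength and a
    per-subject covariate (e.g. age), across subjects.

    Connexels whose strength is constant across subjects get r = 0; the
    diagonal is 0. Output ``kind`` is ``covariate_r``.
    """
    matrices = list(matrices)
    cov = np.asarray(covariate, dtype=float).reshape(-1)
    s = len(matrices)
    if s < 3:
        raise ValueError(f"need at least 3 subjects, got {s}")
    if len(cov) != s:
        raise ValueError("one covariate value per subject required")
    if cov.std() == 0:
        raise ValueError("covariate is constant (zero variance)")
    stack = np.stack([m.values for m in matrices])  # (S, N, N)
    c = cov - cov.mean()
    x = stack - stack.mean(axis=0)
    num = np.tensordot(c, x, axes=(0, 0))
    den = np.sqrt((x ** 2).sum(axis=0)) * np.linalg.norm(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den == 0, 1.0, den), 0.0)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, kind="covariate_r")


def seed_map(matrix: ConnectivityMatrix, node: int) -> np.ndarray:
    """Connectivity values from one seed node to every node (matrix row)."""
    n = matrix.n_nodes
    if not (-n <= node < n):
        raise IndexError(f"seed node {node} out of range for {n} nodes")
    return matrix.values[node].copy()


def alpha_map(values, v_low: float, v_high: float) -> np.ndarray:
    """Linear transparency ramp: 0 at ``v_low``, 1 at ``v_high``, clamped."""
    if not v_low < v_high:
        raise ValueError(f"v_low ({v_low}) must be < v_high ({v_high})")
    v = np.asarray(values, dtype=float)
    return np.clip((v - v_low) / (v_high - v_low), 0.0, 1.0)
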