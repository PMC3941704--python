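"""Deterministic synthetic inputs for every other module.

Stands in for real cortical-surface connectivity data: icosphere-based
surface sets with corresponding pial-like / inflated-like / spherical
representations, modular functional-connectivity matrices from latent
module timeseries, parallel connexel bundles of different densities for
bundling experiments, and per-subject matrix groups whose designated
connexels vary linearly with a covariate (an age analogue) for
group-statistics recovery tests.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .model import ConnectivityMatrix, ConnexelSet, SurfaceMesh, SurfaceSet, \
    pearson_matrix

__all__ = [
    "FixtureSpec",
    "make_surface_set",
    "make_block_connectivity",
    "make_parallel_bundles",
    "make_group_matrices",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults emulate a desk-scale version of a resting-state surface
    connectivity study: a level-2 icosphere (162 nodes) plays the role of a
    decimated hemisphere, four contiguous functional modules drive the
    connectivity structure, and the group fixture uses 65 subjects with an
    age-like covariate spanning 11-83 years.
    """

    seed: int = 0
    subdivision_level: int = 2
    radius: float = 50.0                 # sphere radius, mm
    n_modules: int = 4
    r_within: float = 0.7                # target within-module correlation
    r_between: float = 0.05
    noise_sd: float = 0.1
    n_timepoints: int = 300
    bundle_counts: tuple = (10, 100)
    bundle_separation: float = 60.0      # mm between bundle axes
    bundle_length: float = 40.0          # mm edge length
    bundle_jitter: float = 0.8           # mm endpoint jitter disc radius

    def __post_init__(self):
        if self.r_within <= self.r_between:
            raise ValueError("r_within must exceed r_between")
        if any(c < 1 for c in self.bundle_counts):
            raise ValueError("bundle counts must be >= 1")


def _sphere_angles(vertices):
    x, y, z = vertices.T
    r = np.linalg.norm(vertices, axis=1)
    theta = np.arccos(np.clip(z / r, -1, 1))
    phi = np.arctan2(y, x)
    return theta, phi


def make_surface_set(spec: FixtureSpec) -> SurfaceSet:
    """Icosphere surface set with three corresponding representations.

    The sphere representation is exact (all vertices at ``spec.radius``);
    the pial-like representation modulates the radius with low-order
    spherical-harmonic-style terms to mimic folds; the inflated-like
    representation applies the same modulation at one third amplitude
    (a mild smoothing of the folds). All share node and face indexing.
    """
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivision_level,
                                     radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    faces = np.asarray(ico.faces, dtype=np.int64)
    theta, phi = _sphere_angles(unit)
    # real low-order harmonics (degree 2-3 flavored) as fold pattern
    fold = (0.10 * np.sin(2 * theta) * np.cos(2 * phi)
            + 0.08 * np.cos(3 * theta)
            + 0.06 * np.sin(theta) ** 2 * np.sin(3 * phi))
    pial = unit * (spec.radius * (1.0 + fold))[:, None]
    inflated = unit * (spec.radius * (1.0 + fold / 3.0))[:, None]
    sphere = unit * spec.radius
    return SurfaceSet([
        SurfaceMesh(pial, faces, "pial"),
        SurfaceMesh(inflated, faces, "inflated"),
        SurfaceMesh(sphere, faces, "sphere"),
    ])


def module_labels(surface: SurfaceMesh, n_modules: int) -> np.ndarray:
    """Spatially contiguous module assignment by longitude sector."""
    _, phi = _sphere_angles(surface.vertices)
    sector = ((phi + np.pi) / (2 * np.pi) * n_modules).astype(int)
    return np.clip(sector, 0, n_modules - 1)


def make_block_connectivity(spec: FixtureSpec,
                            surface: SurfaceMesh) -> ConnectivityMatrix:
    """Modular correlation matrix from latent module timeseries plus noise.

    Each node's timeseries is its module's latent series (shared across the
    module, weakly correlated between modules) plus i.i.d. node noise; the
    matrix is the Pearson correlation of those series, so within-module
    correlations exceed between-module ones by construction.
    """
    rng = np.random.default_rng(spec.seed)
    labels = module_labels(surface, spec.n_modules)
    t = spec.n_timepoints
    shared = rng.standard_normal(t)
    latents = []
    # mix a common component to give between-module correlation ~ r_between
    b = np.sqrt(max(spec.r_between, 0.0))
    for _ in range(spec.n_modules):
        own = rng.standard_normal(t)
        latents.append(b * shared + np.sqrt(1 - b * b) * own)
    latents = np.array(latents)
    # within-module correlation target: signal/(signal+noise) variance ratio
    a = np.sqrt(spec.r_within)
    node_noise = rng.standard_normal((surface.n_vertices, t))
    series = a * latents[labels] + np.sqrt(1 - a * a) * node_noise
    if spec.noise_sd > 0:
        series = series + spec.noise_sd * rng.standard_normal(series.shape)
    m = pearson_matrix(series)
    m.module_labels = labels
    return m


def make_parallel_bundles(spec: FixtureSpec) -> ConnexelSet:
    """Parallel connexel bundles of differing density for bundling tests.

    Bundle b holds ``spec.bundle_counts[b]`` edges of equal length along x,
    with endpoints jittered inside a (y, z) disc of radius
    ``spec.bundle_jitter`` -- small against the bundle separation, so edges
    within a bundle are mutually compatible while cross-bundle
    compatibilities stay below the bundling threshold.
    """
    rng = np.random.default_rng(spec.seed + 1)
    p_all, q_all = [], []
    for b, count in enumerate(spec.bundle_counts):
        y0 = b * spec.bundle_separation
        for _ in range(count):
            jp = _disc_jitter(rng, spec.bundle_jitter)
            jq = _disc_jitter(rng, spec.bundle_jitter)
            p_all.append([0.0, y0 + jp[0], jp[1]])
            q_all.append([spec.bundle_length, y0 + jq[0], jq[1]])
    values = np.ones(len(p_all))
    cset = ConnexelSet(np.array(p_all), np.array(q_all), values,
                       space_label="synthetic-bundles")
    cset.bundle_labels = np.repeat(np.arange(len(spec.bundle_counts)),
                                   spec.bundle_counts)
    return cset


def _disc_jitter(rng, radius):
    while True:
        v = rng.uniform(-radius, radius, size=2)
        if v @ v <= radius * radius:
            return v


def make_group_matrices(spec: FixtureSpec, n_subjects: int = 65,
                        covariate=None):
    """Per-subject correlation matrices with known covariate effects.

    A designated connexel subset increases linearly in the covariate, a
    second subset decreases, and all other connexels are covariate-free;
    subject-level noise of ``spec.noise_sd`` is added throughout. The
    default covariate is an age analogue spanning 11-83 years.

    Returns
    -------
    matrices : list of ConnectivityMatrix
    covariate : (S,) array
    labels : dict with ``increasing`` and ``decreasing`` (k, 2) index pairs
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(spec.seed + 2)
    if covariate is None:
        covariate = np.linspace(11.0, 83.0, n_subjects)
    covariate = np.asarray(covariate, dtype=float)
    n = 30  # matrix nodes: kept small so S matrices stay desk-scale
    ii, jj = np.triu_indices(n, k=1)
    n_pairs = len(ii)
    order = rng.permutation(n_pairs)
    k = max(n_pairs // 10, 1)
    pos = order[:k]
    neg = order[k:2 * k]

    base = rng.uniform(0.1, 0.4, size=n_pairs)
    x = (covariate - covariate.mean()) / (covariate.max() - covariate.min())
    amplitude = 0.4   # strength swing over the covariate span
    mats = []
    for s in range(n_subjects):
        vals = base.copy()
        vals[pos] += amplitude * x[s]
        vals[neg] -= amplitude * x[s]
        if spec.noise_sd > 0:
            vals = vals + spec.noise_sd * rng.standard_normal(n_pairs)
        m = np.zeros((n, n))
        m[ii, jj] = vals
        m = m + m.T
        np.clip(m, -0.99, 0.99, out=m)
        np.fill_diagonal(m, 1.0)
        mats.append(ConnectivityMatrix(m, kind="correlation"))
    labels = {
        "increasing": np.stack([ii[pos], jj[pos]], axis=1),
        "decreasing": np.stack([ii[neg], jj[neg]], axis=1),
    }
    return mats, covariate, labels
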