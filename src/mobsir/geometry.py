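"""Particle geometry on the 2D torus.

Particles live in an ``L x L`` box with periodic boundary conditions and
move ballistically: particle *i* keeps a fixed heading ``xi_i`` drawn
uniformly on ``[0, 2pi)`` and advances a distance *v* per time step,

    x(t+1) = (x(t) + v cos xi) mod L
    y(t+1) = (y(t) + v sin xi) mod L

Two particles are "in contact" when their minimum-image torus distance is
strictly smaller than the interaction range *d*.  The instantaneous contact
graph of a uniform configuration is a random geometric graph (RGG) with
expected degree ``<k> = (N - 1) pi d^2 / L^2``, which fixes the analytic
reference scales used throughout:

* ``d_c``   -- range at which ``<k>`` hits the 2D RGG percolation degree
               (``<k>_c ~ 4.52``): the static contact graph develops a
               giant component.
* ``d_min`` -- range at which ``<k> = 1``: below it no epidemic is possible
               even with perfect mixing.
* ``d_max = L / sqrt(2)`` -- half the torus diameter: the graph is complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.spatial import cKDTree

__all__ = [
    "ParticleEnsemble",
    "ContactSet",
    "ReferenceScales",
    "initialize_particles",
    "advance_positions",
    "resample_positions",
    "contact_pairs",
    "contacts_from_sources",
    "torus_distance",
    "expected_degree",
    "radius_for_degree",
    "reference_scales",
    "RGG_PERCOLATION_DEGREE",
]

#: 2D random geometric graph percolation degree with periodic boundaries
#: (literature value; configurable wherever it is consumed).
RGG_PERCOLATION_DEGREE: float = 4.52


class ConfigurationError(ValueError):
    """Raised for invalid geometric or dynamical parameters."""


@dataclass(frozen=True)
class ParticleEnsemble:
    """Positions and fixed headings of ``n`` particles on the torus.

    Coordinates always lie in ``[0, box_size)``; headings are immutable for
    the lifetime of a run (frozen dataclass — updates return new instances).
    """

    box_size: float
    x: NDArray[np.float64]
    y: NDArray[np.float64]
    direction: NDArray[np.float64]

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def positions(self) -> NDArray[np.float64]:
        """Return an ``(n, 2)`` coordinate array (copy)."""
        return np.column_stack([self.x, self.y])

    def to_table(self):
        """Plain-text serializable snapshot (one row per particle)."""
        import pandas as pd

        return pd.DataFrame(
            {"x": self.x, "y": self.y, "direction": self.direction}
        )

    @classmethod
    def from_table(cls, table, box_size: float) -> "ParticleEnsemble":
        return cls(
            box_size=float(box_size),
            x=np.asarray(table["x"], dtype=float),
            y=np.asarray(table["y"], dtype=float),
            direction=np.asarray(table["direction"], dtype=float),
        )


@dataclass(frozen=True)
class ContactSet:
    """Unordered proximity-contact pairs, stored once with ``i < j``."""

    pairs: NDArray[np.intp]  # shape (m, 2), lexicographically sorted
    n: int

    @property
    def m(self) -> int:
        return self.pairs.shape[0]

    def degree(self) -> NDArray[np.intp]:
        """Per-particle contact count."""
        deg = np.zeros(self.n, dtype=np.intp)
        if self.m:
            np.add.at(deg, self.pairs[:, 0], 1)
            np.add.at(deg, self.pairs[:, 1], 1)
        return deg

    def directed(self) -> tuple[NDArray[np.intp], NDArray[np.intp]]:
        """Both orientations of every pair, canonically ordered by
        (source, target) so that downstream random draws are reproducible
        regardless of how the pairs were enumerated."""
        if not self.m:
            empty = np.empty(0, dtype=np.intp)
            return empty, empty
        src = np.concatenate([self.pairs[:, 0], self.pairs[:, 1]])
        dst = np.concatenate([self.pairs[:, 1], self.pairs[:, 0]])
        order = np.lexsort((dst, src))
        return src[order], dst[order]


class ReferenceScales(NamedTuple):
    d_c: float
    d_min: float
    d_max: float


# ---------------------------------------------------------------------------
# construction and motion


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def initialize_particles(
    n: int, box_size: float, seed: int | np.random.Generator
) -> ParticleEnsemble:
    """Scatter ``n`` particles uniformly and draw uniform headings.

    Deterministic given ``seed``; coordinates are i.i.d. uniform on
    ``[0, box_size)^2`` and headings i.i.d. uniform on ``[0, 2pi)``.
    """
    if n < 1:
        raise ConfigurationError(f"particle count must be >= 1, got {n}")
    if box_size <= 0:
        raise ConfigurationError(f"box size must be > 0, got {box_size}")
    rng = _as_rng(seed)
    return ParticleEnsemble(
        box_size=float(box_size),
        x=rng.uniform(0.0, box_size, size=n),
        y=rng.uniform(0.0, box_size, size=n),
        direction=rng.uniform(0.0, 2.0 * np.pi, size=n),
    )


def advance_positions(
    ensemble: ParticleEnsemble, velocity: float
) -> ParticleEnsemble:
    """One synchronous ballistic step of length ``velocity`` per particle."""
    if velocity < 0:
        raise ConfigurationError(f"velocity must be >= 0, got {velocity}")
    if velocity == 0:
        return ensemble
    L = ensemble.box_size
    return replace(
        ensemble,
        x=np.mod(ensemble.x + velocity * np.cos(ensemble.direction), L),
        y=np.mod(ensemble.y + velocity * np.sin(ensemble.direction), L),
    )


def resample_positions(
    ensemble: ParticleEnsemble, seed: int | np.random.Generator
) -> ParticleEnsemble:
    """Redraw all coordinates i.i.d. uniform, keeping headings.

    This is the uncorrelated-contact-sequence (annealed, v -> infinity)
    limit as an explicit motion mode: consecutive contact graphs are
    statistically independent RGGs.
    """
    rng = _as_rng(seed)
    L = ensemble.box_size
    return replace(
        ensemble,
        x=rng.uniform(0.0, L, size=ensemble.n),
        y=rng.uniform(0.0, L, size=ensemble.n),
    )


# ---------------------------------------------------------------------------
# distances and contact enumeration


def torus_distance(dx: NDArray, dy: NDArray, box_size: float) -> NDArray:
    """Minimum-image Euclidean distance for coordinate differences."""
    L = box_size
    dx = np.abs(np.asarray(dx, dtype=float)) % L
    dy = np.abs(np.asarray(dy, dtype=float)) % L
    dx = np.minimum(dx, L - dx)
    dy = np.minimum(dy, L - dy)
    return np.hypot(dx, dy)


def _brute_force_pairs(ensemble: ParticleEnsemble, radius: float) -> NDArray:
    """O(n^2) minimum-image enumeration — the exactness oracle."""
    x, y, L = ensemble.x, ensemble.y, ensemble.box_size
    i, j = np.triu_indices(ensemble.n, k=1)
    dist = torus_distance(x[i] - x[j], y[i] - y[j], L)
    keep = dist < radius
    return np.column_stack([i[keep], j[keep]])


def _tree_pairs(ensemble: ParticleEnsemble, radius: float) -> NDArray:
    L = ensemble.box_size
    pts = np.mod(ensemble.positions(), L)  # boxsize requires [0, L)
    tree = cKDTree(pts, boxsize=L)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size:
        # the tree reports distance <= radius; the contact rule is strict
        d = torus_distance(
            ensemble.x[pairs[:, 0]] - ensemble.x[pairs[:, 1]],
            ensemble.y[pairs[:, 0]] - ensemble.y[pairs[:, 1]],
            L,
        )
        pairs = pairs[d < radius]
    return pairs


def contact_pairs(
    ensemble: ParticleEnsemble, radius: float, method: str = "auto"
) -> ContactSet:
    """Enumerate all pairs at torus distance strictly below ``radius``.

    ``method='auto'`` uses a periodic k-d tree when the radius allows it
    (``2 d < L``, the regime where the minimum image is unique) and falls
    back to the brute-force minimum-image scan otherwise.  Both routes are
    exact and return identical pair sets.
    """
    if radius < 0:
        raise ConfigurationError(f"radius must be >= 0, got {radius}")
    if method == "auto":
        method = "tree" if 2.0 * radius < ensemble.box_size else "brute"
    if method == "tree":
        pairs = _tree_pairs(ensemble, radius)
    elif method == "brute":
        pairs = _brute_force_pairs(ensemble, radius)
    else:
        raise ValueError(f"unknown method {method!r}")
    pairs = np.sort(pairs, axis=1) if pairs.size else pairs.reshape(0, 2)
    if pairs.size:
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
    return ContactSet(pairs=pairs.astype(np.intp), n=ensemble.n)


def contacts_from_sources(
    ensemble: ParticleEnsemble,
    radius: float,
    sources: NDArray[np.intp],
    tree: cKDTree | None = None,
) -> tuple[NDArray[np.intp], NDArray[np.intp]]:
    """Directed contact edges ``source -> target`` for the given sources only.

    Equivalent to filtering :func:`contact_pairs` for edges whose source is
    in ``sources``, but only pays for the neighborhoods actually queried —
    the per-step cost of an epidemic update scales with the infectious
    population instead of N.  Edges are returned in canonical
    (source, target) order.  Pass a prebuilt periodic ``cKDTree`` to reuse
    it across queries (static motion).
    """
    if radius < 0:
        raise ConfigurationError(f"radius must be >= 0, got {radius}")
    sources = np.asarray(sources, dtype=np.intp)
    if sources.size == 0:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty
    L = ensemble.box_size
    if 2.0 * radius >= L:
        # complete-graph regime: brute-force rows for the sources
        dx = ensemble.x[sources][:, None] - ensemble.x[None, :]
        dy = ensemble.y[sources][:, None] - ensemble.y[None, :]
        hit = torus_distance(dx, dy, L) < radius
        hit[np.arange(sources.size), sources] = False
        src_idx, dst = np.nonzero(hit)
        src = sources[src_idx]
    else:
        if tree is None:
            tree = cKDTree(np.mod(ensemble.positions(), L), boxsize=L)
        pts = np.column_stack(
            [np.mod(ensemble.x[sources], L), np.mod(ensemble.y[sources], L)]
        )
        hoods = tree.query_ball_point(pts, radius)
        counts = np.fromiter((len(h) for h in hoods), dtype=np.intp,
                             count=len(hoods))
        src = np.repeat(sources, counts)
        dst = (
            np.concatenate([np.asarray(h, dtype=np.intp) for h in hoods])
            if counts.sum()
            else np.empty(0, dtype=np.intp)
        )
        keep = src != dst
        src, dst = src[keep], dst[keep]
        # enforce strict inequality (tree reports <= radius)
        d = torus_distance(
            ensemble.x[src] - ensemble.x[dst],
            ensemble.y[src] - ensemble.y[dst],
            L,
        )
        keep = d < radius
        src, dst = src[keep], dst[keep]
    order = np.lexsort((dst, src))
    return src[order], dst[order]


# ---------------------------------------------------------------------------
# analytic reference scales


def expected_degree(n: int, box_size: float, radius: float) -> float:
    """Expected RGG neighbor count ``(n - 1) pi d^2 / L^2``."""
    if n < 1:
        raise ConfigurationError(f"particle count must be >= 1, got {n}")
    if box_size <= 0:
        raise ConfigurationError(f"box size must be > 0, got {box_size}")
    return (n - 1) * np.pi * radius**2 / box_size**2


def radius_for_degree(n: int, box_size: float, mean_degree: float) -> float:
    """Interaction range giving a target expected degree (inverse of
    :func:`expected_degree`)."""
    return box_size * np.sqrt(mean_degree / ((n - 1) * np.pi))


def reference_scales(
    n: int, box_size: float, k_c: float = RGG_PERCOLATION_DEGREE
) -> ReferenceScales:
    """Analytic interaction-range scales for ``n`` particles in box ``L``.

    ``d_c = L sqrt(k_c / ((n-1) pi))`` (static percolation),
    ``d_min = L sqrt(1 / ((n-1) pi))`` (mean degree one),
    ``d_max = L / sqrt(2)`` (complete graph).
    """
    if n < 2:
        raise ConfigurationError(f"need n >= 2 for reference scales, got {n}")
    return ReferenceScales(
        d_c=radius_for_degree(n, box_size, k_c),
        d_min=radius_for_degree(n, box_size, 1.0),
        d_max=box_size / np.sqrt(2.0),
    )
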