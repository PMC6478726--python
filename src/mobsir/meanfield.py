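"""Mean-field SIR final size — the annealed-limit companion.

When particle positions are redrawn uniformly every step, consecutive
contact graphs are independent RGGs and the epidemic is exactly the
annealed-network (homogeneous mixing) limit of SIR.  The final recovered
fraction rho then solves the implicit equation

    rho = 1 - exp(-p <k> rho)

which depends on p and the expected degree only through the product
``pk = p <k>``.  A nontrivial root exists iff pk > 1, so the epidemic
threshold is ``p_c = 1 / <k>``; in terms of the geometry,
``p_c = L^2 / ((N - 1) pi d^2)``.  Because p is a probability, no epidemic
is possible at all when ``<k> < 1`` (the origin of the ``d_min`` scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import expected_degree

__all__ = [
    "final_size",
    "final_size_curve",
    "epidemic_threshold_mf",
    "threshold_from_geometry",
    "MeanFieldCurve",
]

_TOL = 1e-12


def final_size(pk: float) -> float:
    """Largest root in [0, 1] of ``rho = 1 - exp(-pk rho)``.

    Returns 0 for ``pk <= 1`` (only the trivial root exists) and the unique
    nontrivial root, to absolute tolerance 1e-12, above the bifurcation.
    """
    if pk < 0:
        raise ValueError(f"pk must be >= 0, got {pk}")
    if pk <= 1.0:
        return 0.0

    def f(rho: float) -> float:
        return rho - 1.0 + np.exp(-pk * rho)

    # f'(0) = 1 - pk < 0 and f(1) > 0, so the nontrivial root is bracketed
    # by any small eps with f(eps) < 0 and 1
    eps = 1e-14
    while f(eps) >= 0.0:  # pk barely above 1: shrink left bracket
        eps *= 0.5
        if eps < 1e-300:
            return 0.0
    return float(brentq(f, eps, 1.0, xtol=_TOL))


@dataclass(frozen=True)
class MeanFieldCurve:
    """Final-size fraction tabulated on a grid of p<k> values."""

    pk: np.ndarray
    rho: np.ndarray

    def to_table(self):
        import pandas as pd

        return pd.DataFrame({"pk": self.pk, "rho": self.rho})


def final_size_curve(pk_grid) -> MeanFieldCurve:
    pk = np.asarray(pk_grid, dtype=float)
    rho = np.array([final_size(v) for v in pk])
    return MeanFieldCurve(pk=pk, rho=rho)


def epidemic_threshold_mf(mean_degree: float) -> dict:
    """Mean-field epidemic threshold ``p_c = 1 / <k>``.

    When ``<k> <= 1`` the returned value exceeds 1, i.e. no admissible
    transmission probability can sustain an epidemic; the result carries an
    explicit feasibility flag for that case.
    """
    if mean_degree <= 0:
        raise ValueError(f"mean degree must be > 0, got {mean_degree}")
    p_c = 1.0 / mean_degree
    return {"p_c": p_c, "feasible": p_c <= 1.0}


def threshold_from_geometry(n: int, box_size: float, radius: float) -> dict:
    """Threshold in geometric form, ``p_c = L^2 / ((N-1) pi d^2)``."""
    k = expected_degree(n, box_size, radius)
    return {**epidemic_threshold_mf(k), "mean_degree": k}
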