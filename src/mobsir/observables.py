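"""Order parameters and mechanism diagnostics.

The order parameter of a run is the fraction of recovered particles in the
absorbing configuration: rho (single infection) or rho_ab (fraction of
doubly recovered, cooperative case).  The diagnostics here separate the
two spreading regimes the velocity interpolates between:

* expanding front — recovered particles form one compact growing cluster,
  so the mean recovered-component size equals the recovered count,
  ``<C>_R = R``, and at p = 1, v = 0 no susceptible ever touches a
  recovered particle;
* global mixing — recovered particles are scattered, ``<C>_R = O(1)``
  until their subgraph percolates around ``R_c = 1 + L^2 / (pi d^2)``
  (mean recovered-recovered degree of one).

The IS/(IS + IR) link ratio tracks how much of an infected particle's
neighborhood is still susceptible; its depletion at small nonzero
velocities is the front-erosion mechanism behind the optimal velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .dynamics import I, R, S, HealthStateVector, InvalidStateError, RunResult
from .geometry import ContactSet, ParticleEnsemble, contact_pairs

__all__ = [
    "outbreak_fractions",
    "link_census",
    "recovered_component_profile",
    "component_sizes",
    "estimate_threshold",
    "transition_gap",
    "classify_transition",
    "percolation_recovered_count",
    "ComponentProfile",
    "ThresholdEstimate",
    "GapClassification",
    "InsufficientSampleError",
]


class InsufficientSampleError(ValueError):
    """Raised when a diagnostic receives fewer runs than it requires."""


# ---------------------------------------------------------------------------
# outbreak fractions


def outbreak_fractions(
    states: HealthStateVector, require_absorbing: bool = True
) -> dict:
    """Recovered fractions of a final configuration.

    Single mode returns ``rho``; cooperative mode returns the per-pathogen
    fractions ``rho_a``/``rho_b`` (ever infected with that pathogen) and
    ``rho_ab`` (doubly recovered).  By default the input must be absorbing
    (no infected particles).
    """
    if require_absorbing and states.num_infected() > 0:
        raise InvalidStateError(
            "outbreak fractions are defined on absorbing configurations; "
            f"{states.num_infected()} particles are still infected"
        )
    n = states.n
    if states.mode == "single":
        return {"rho": float(np.count_nonzero(states.a == R)) / n}
    rec_a = states.a == R
    rec_b = states.b == R
    return {
        "rho_a": float(np.count_nonzero(rec_a)) / n,
        "rho_b": float(np.count_nonzero(rec_b)) / n,
        "rho_ab": float(np.count_nonzero(rec_a & rec_b)) / n,
    }


# ---------------------------------------------------------------------------
# link census


def _collapse_dual(states: HealthStateVector) -> np.ndarray:
    """Map the 9-state dual alphabet onto S/I/R: infected with any pathogen
    -> I; never infected with anything -> S; otherwise (recovered from all
    pathogens ever acquired) -> R."""
    out = np.full(states.n, R, dtype=np.int8)
    out[(states.a == I) | (states.b == I)] = I
    out[(states.a == S) & (states.b == S)] = S
    return out


_PAIR_LABEL = {
    (S, S): "SS", (S, I): "IS", (S, R): "SR",
    (I, I): "II", (I, R): "IR", (R, R): "RR",
}


def link_census(
    states: HealthStateVector,
    contacts: ContactSet,
    collapse_dual: bool = False,
) -> dict:
    """Count contacts by the state pair of their endpoints.

    Returns SS, IS, SR, II, IR, RR counts plus ``ratio_is``, the fraction
    IS / (IS + IR), or NaN when no infected-endpoint links exist.  The dual
    alphabet is only censused on explicit request (``collapse_dual=True``),
    mapping any-infected to I and recovered-from-everything-acquired to R.
    """
    if states.mode == "cooperative":
        if not collapse_dual:
            raise InvalidStateError(
                "link census uses the single alphabet; pass collapse_dual=True "
                "to census the two-pathogen states"
            )
        code = _collapse_dual(states)
    else:
        code = states.a
    out = {lab: 0 for lab in ("SS", "IS", "SR", "II", "IR", "RR")}
    if contacts.m:
        ci = code[contacts.pairs[:, 0]]
        cj = code[contacts.pairs[:, 1]]
        lo = np.minimum(ci, cj)
        hi = np.maximum(ci, cj)
        key = lo * 3 + hi
        counts = np.bincount(key, minlength=9)
        for (a, b), lab in _PAIR_LABEL.items():
            out[lab] = int(counts[a * 3 + b])
    denom = out["IS"] + out["IR"]
    out["ratio_is"] = out["IS"] / denom if denom else float("nan")
    return out


# ---------------------------------------------------------------------------
# recovered-component profile


def component_sizes(n_nodes: int, pairs: np.ndarray) -> np.ndarray:
    """Connected-component sizes of a graph given as an edge array."""
    if n_nodes == 0:
        return np.zeros(0, dtype=np.intp)
    if len(pairs) == 0:
        return np.ones(n_nodes, dtype=np.intp)
    m = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(n_nodes, n_nodes),
    )
    _, labels = connected_components(m, directed=False)
    return np.bincount(labels).astype(np.intp)


def percolation_recovered_count(box_size: float, radius: float) -> float:
    """Recovered count at which a scattered recovered subgraph reaches mean
    degree one, ``R_c = 1 + L^2 / (pi d^2)``."""
    return 1.0 + box_size**2 / (np.pi * radius**2)


@dataclass
class ComponentProfile:
    """Per-step recovered-subgraph profile of one run."""

    table: pd.DataFrame  # step, R, mean_component, largest_component
    r_c: float

    def crossing(
        self, giant_fraction: float = 0.5, min_r: int = 10
    ) -> Optional[float]:
        """Smallest recorded R (at least ``min_r``, so that a handful of
        recovered particles cannot trivially qualify) at which the largest
        recovered component exceeds ``giant_fraction * R``; None if it
        never does."""
        t = self.table[self.table["R"] >= min_r]
        hit = t[t["largest_component"] > giant_fraction * t["R"]]
        return float(hit["R"].iloc[0]) if len(hit) else None


def recovered_component_profile(result: RunResult) -> ComponentProfile:
    """Mean recovered-component size against recovered count, per step.

    Needs a run recorded with ``record_snapshots=True``: at every step the
    subgraph induced by the recovered particles under the instantaneous
    contact set is rebuilt and its mean and largest component sizes
    recorded.  An expanding front keeps ``mean == R`` (one cluster);
    global mixing keeps it O(1) until R crosses ``r_c``.
    """
    if result.snapshots is None:
        raise InvalidStateError(
            "recovered_component_profile needs a run with record_snapshots=True"
        )
    radius = result.config.radius
    rows = []
    for step, (states, ens) in enumerate(result.snapshots):
        if states.mode == "single":
            rec = np.nonzero(states.a == R)[0]
        else:
            code = _collapse_dual(states)
            rec = np.nonzero(code == R)[0]
        r_count = rec.size
        if r_count == 0:
            rows.append(
                {"step": step, "R": 0, "mean_component": np.nan,
                 "largest_component": 0}
            )
            continue
        sub = ParticleEnsemble(
            box_size=ens.box_size,
            x=ens.x[rec],
            y=ens.y[rec],
            direction=ens.direction[rec],
        )
        sizes = component_sizes(r_count, contact_pairs(sub, radius).pairs)
        rows.append(
            {
                "step": step,
                "R": int(r_count),
                "mean_component": float(sizes.mean()),
                "largest_component": int(sizes.max()),
            }
        )
    return ComponentProfile(
        table=pd.DataFrame(rows),
        r_c=percolation_recovered_count(result.config.box_size, radius),
    )


# ---------------------------------------------------------------------------
# threshold estimation


@dataclass
class ThresholdEstimate:
    """Critical control-parameter estimate from a scanned grid."""

    param: str
    grid: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    criterion: str
    rho_star: float
    critical: Optional[float]
    censored: bool
    reentrant: Optional[dict] = None  # {'v_minus': ..., 'v_plus': ...}

    def to_dict(self) -> dict:
        return {
            "param": self.param,
            "grid": self.grid.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "criterion": self.criterion,
            "rho_star": self.rho_star,
            "critical": self.critical,
            "censored": self.censored,
            "reentrant": self.reentrant,
        }


def estimate_threshold(
    sweep,
    param: str,
    order: str = "rho",
    criterion: str = "cutoff",
    rho_star: float = 0.05,
) -> ThresholdEstimate:
    """Locate the epidemic threshold along one scanned parameter.

    ``criterion='cutoff'`` (default): smallest grid value whose ensemble
    mean order parameter exceeds the macroscopic cutoff ``rho_star``;
    ``criterion='onset'``: smallest grid value at which any run produces a
    macroscopic outbreak (order parameter above ``rho_star``), the natural
    estimator when single-seed extinction keeps the all-runs mean low near
    a continuous transition; ``criterion='susceptibility'``: grid value
    maximizing the ensemble variance.  If the above-cutoff region is split
    in two (outbreaks at
    low and high velocity but not in between) the reentrant pair
    (v_c-, v_c+) is reported alongside.  No crossing -> censored flag.
    """
    table = sweep.table if hasattr(sweep, "table") else sweep
    grouped = table.groupby(param)[order]
    grid = np.array(sorted(table[param].unique()), dtype=float)
    means = grouped.mean().reindex(grid).to_numpy()
    variances = grouped.var(ddof=1).reindex(grid).fillna(0.0).to_numpy()
    if grid.size < 2:
        raise InsufficientSampleError("threshold estimation needs >= 2 grid points")

    reentrant = None
    if criterion in ("cutoff", "onset"):
        if criterion == "cutoff":
            above = means > rho_star
        else:
            # takeoff onset: a grid point is supercritical as soon as any
            # run produces a macroscopic outbreak — with a single initial
            # seed the all-runs mean is diluted by early extinctions, so
            # the first appearance of the outbreak branch locates the
            # threshold of a continuous transition far better than the
            # mean crossing does
            frac = (
                table.assign(_hit=table[order] > rho_star)
                .groupby(param)["_hit"]
                .mean()
                .reindex(grid)
                .to_numpy()
            )
            above = frac > 0.0
        if not above.any():
            critical, censored = None, True
        else:
            critical, censored = float(grid[int(np.argmax(above))]), False
            # contiguous above-cutoff segments; two or more = reentrant
            edges = np.flatnonzero(np.diff(above.astype(int)))
            segments = np.split(np.arange(grid.size), edges + 1)
            above_segments = [s for s in segments if above[s[0]]]
            if len(above_segments) >= 2:
                reentrant = {
                    "v_minus": float(grid[above_segments[0][-1]]),
                    "v_plus": float(grid[above_segments[1][0]]),
                }
    elif criterion == "susceptibility":
        critical, censored = float(grid[int(np.argmax(variances))]), False
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    return ThresholdEstimate(
        param=param,
        grid=grid,
        means=means,
        variances=variances,
        criterion=criterion,
        rho_star=rho_star,
        critical=critical,
        censored=censored,
        reentrant=reentrant,
    )


# ---------------------------------------------------------------------------
# transition-order classification


@dataclass
class GapClassification:
    gap: float  # width of the empty interval between the two branches
    classification: str  # 'continuous' | 'discontinuous'
    lower_mean: float
    upper_mean: float
    lower_fraction: float
    upper_fraction: float
    branch_separation: float  # distance between branch means

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def transition_gap(
    rho_values: Sequence[float],
    min_runs: int = 50,
    min_gap: float = 0.3,
    min_branch_fraction: float = 0.1,
) -> GapClassification:
    """Classify the transition order from final outcomes at fixed parameters.

    The empirical distribution is split into two branches at the largest
    spacing of the sorted values; the gap is the width of that empty
    interval (upper branch minimum minus lower branch maximum).  A
    discontinuous (first-order) transition shows both branches populated
    (each holding at least ``min_branch_fraction`` of the runs) around a
    genuinely macroscopic forbidden interval (``gap >= min_gap``);
    anything else is classified continuous.  Near a continuous transition
    the outbreak branch grows up from zero, so its sorted values crawl
    upward with only sampling-sized spacings, while a first-order jump
    leaves a wide empty band between extinctions and fully formed
    outbreaks; ``min_gap = 0.3`` sits between the two regimes.  Both the
    occupancy and the gap floor are heuristics — the classification is
    reported together with all branch statistics.
    """
    rho = np.sort(np.asarray(rho_values, dtype=float))
    if rho.size < min_runs:
        raise InsufficientSampleError(
            f"transition classification needs >= {min_runs} runs, got {rho.size}"
        )
    diffs = np.diff(rho)
    if diffs.size == 0 or diffs.max() == 0.0:
        return GapClassification(
            gap=0.0, classification="continuous",
            lower_mean=float(rho.mean()), upper_mean=float(rho.mean()),
            lower_fraction=1.0, upper_fraction=0.0, branch_separation=0.0,
        )
    split = int(np.argmax(diffs)) + 1
    lower, upper = rho[:split], rho[split:]
    gap = float(upper.min() - lower.max())
    lo_frac = lower.size / rho.size
    up_frac = upper.size / rho.size
    discontinuous = (
        gap >= min_gap
        and lo_frac >= min_branch_fraction
        and up_frac >= min_branch_fraction
    )
    return GapClassification(
        gap=gap,
        classification="discontinuous" if discontinuous else "continuous",
        lower_mean=float(lower.mean()),
        upper_mean=float(upper.mean()),
        lower_fraction=lo_frac,
        upper_fraction=up_frac,
        branch_separation=float(upper.mean() - lower.mean()),
    )


def classify_transition(
    sweep,
    param: str,
    order: str = "rho_ab",
    rho_star: float = 0.05,
    min_runs: int = 50,
    min_gap: float = 0.3,
    min_branch_fraction: float = 0.1,
) -> dict:
    """Transition order along a scanned control parameter.

    Classifies at the first grid point at or above the estimated threshold
    where the outbreak branch holds at least ``min_branch_fraction`` of
    the runs — at the exact crossing the branch may hold only a run or
    two, which says nothing about bimodality.  Returns the grid point
    used, its :class:`GapClassification` and the threshold estimate.
    """
    table = sweep.table if hasattr(sweep, "table") else sweep
    est = estimate_threshold(table, param, order, "cutoff", rho_star)
    grid = est.grid
    start = 0 if est.censored else int(np.searchsorted(grid, est.critical))
    chosen, gap = None, None
    for value in grid[start:]:
        rho = table.loc[table[param] == value, order].to_numpy()
        g = transition_gap(rho, min_runs, min_gap, min_branch_fraction)
        populated = (
            min(g.lower_fraction, g.upper_fraction) >= min_branch_fraction
        )
        if populated:
            chosen, gap = float(value), g
            break
    if chosen is None:  # branch never populated: nothing bimodal anywhere
        last = grid[-1]
        gap = transition_gap(
            table.loc[table[param] == last, order].to_numpy(),
            min_runs, min_gap, min_branch_fraction,
        )
        chosen = float(last)
    return {"at": chosen, "gap": gap, "threshold": est,
            "classification": gap.classification}
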