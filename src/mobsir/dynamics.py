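"""Contagion state machines and the run-to-absorption loop.

Single infection is discrete-time SIR: an infected particle transmits to
each contact with probability *p* and recovers after exactly one time step
(the recovery time is the time unit).  The cooperative variant tracks two
pathogens A and B per particle; transmission of a pathogen to a target that
has never carried either pathogen succeeds with the primary probability
*p*, while a target that carries or has recovered from the *other* pathogen
is secondarily infected with probability *q*.  ``q = p`` makes the two
pathogens statistically independent; ``q > p`` is cooperation.

Each time step first updates all states synchronously from the entering
configuration, then updates all positions (ballistic step, nothing for
static particles, or a full uniform redraw in the annealed mode).  A run
ends in the absorbing configuration — no infected particles — or at
``max_steps`` with an explicit non-absorbed flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.typing import NDArray

from .geometry import (
    ConfigurationError,
    ContactSet,
    ParticleEnsemble,
    advance_positions,
    contact_pairs,
    contacts_from_sources,
    initialize_particles,
    resample_positions,
)

__all__ = [
    "S",
    "I",
    "R",
    "HealthStateVector",
    "SimulationConfig",
    "RunResult",
    "seed_epidemic",
    "update_states_single",
    "update_states_cooperative",
    "run_to_absorbing",
]

S, I, R = 0, 1, 2  # per-pathogen compartment codes

SINGLE_LABELS = ("S", "I", "R")
# (a_state, b_state) -> conventional label; lower case = recovered-from
DUAL_LABELS = {
    (S, S): "S", (I, S): "A", (S, I): "B", (I, I): "AB",
    (R, S): "a", (S, R): "b", (R, I): "aB", (I, R): "Ab", (R, R): "ab",
}
DUAL_LABEL_ORDER = ("S", "A", "B", "AB", "a", "b", "aB", "Ab", "ab")


class InvalidStateError(ValueError):
    """Raised when an operation receives states it cannot act on."""


@dataclass
class HealthStateVector:
    """Per-particle infection state.

    ``mode='single'`` uses one S/I/R code array ``a``; ``mode='cooperative'``
    uses two, one per pathogen, so the joint alphabet is the 9-state product
    {S, A, B, AB, a, b, aB, Ab, ab}.  Per pathogen a particle only moves
    forward S -> I -> R: recovery after exactly one infectious step, and no
    reinfection with a pathogen already cleared.
    """

    mode: str
    a: NDArray[np.int8]
    b: Optional[NDArray[np.int8]] = None

    def __post_init__(self):
        if self.mode not in ("single", "cooperative"):
            raise InvalidStateError(f"unknown mode {self.mode!r}")
        if self.mode == "cooperative" and self.b is None:
            raise InvalidStateError("cooperative mode needs both pathogen arrays")

    @classmethod
    def all_susceptible(cls, n: int, mode: str) -> "HealthStateVector":
        a = np.zeros(n, dtype=np.int8)
        b = np.zeros(n, dtype=np.int8) if mode == "cooperative" else None
        return cls(mode=mode, a=a, b=b)

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def infected_mask(self) -> NDArray[np.bool_]:
        """Particles currently infectious with at least one pathogen."""
        m = self.a == I
        if self.mode == "cooperative":
            m = m | (self.b == I)
        return m

    def num_infected(self) -> int:
        return int(self.infected_mask().sum())

    def counts(self) -> dict[str, int]:
        """State counts keyed by conventional labels (they sum to n)."""
        if self.mode == "single":
            c = np.bincount(self.a, minlength=3)
            return dict(zip(SINGLE_LABELS, (int(v) for v in c)))
        joint = np.bincount(self.a.astype(np.intp) * 3 + self.b, minlength=9)
        out = {lab: 0 for lab in DUAL_LABEL_ORDER}
        for (sa, sb), lab in DUAL_LABELS.items():
            out[lab] = int(joint[sa * 3 + sb])
        return out

    def copy(self) -> "HealthStateVector":
        return HealthStateVector(
            mode=self.mode,
            a=self.a.copy(),
            b=None if self.b is None else self.b.copy(),
        )


@dataclass
class SimulationConfig:
    """Full parameterization of one run.

    ``motion='static'`` is exactly ``'ballistic'`` with ``velocity = 0``
    (identical trajectories); ``'annealed'`` redraws every position
    uniformly after each state update, the uncorrelated-contact-sequence
    (v -> infinity) limit.
    """

    n: int
    box_size: float
    radius: float
    velocity: float = 0.0
    p: float = 1.0
    q: float = 0.0
    mode: str = "single"
    motion: str = "ballistic"
    max_steps: Optional[int] = None
    seed: int = 0
    seed_state: Optional[str] = None  # 'I', 'AB', 'A' or 'B'

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if self.box_size <= 0:
            raise ConfigurationError("box_size must be > 0")
        if self.radius < 0:
            raise ConfigurationError("radius must be >= 0")
        if self.velocity < 0:
            raise ConfigurationError("velocity must be >= 0")
        for name in ("p", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.mode not in ("single", "cooperative"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.motion not in ("ballistic", "static", "annealed"):
            raise ConfigurationError(f"unknown motion {self.motion!r}")
        if self.motion == "static":
            self.velocity = 0.0
        if self.max_steps is None:
            self.max_steps = 10 * self.n
        if self.seed_state is None:
            self.seed_state = "I" if self.mode == "single" else "AB"

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class RunResult:
    """Outcome of one run: final states plus per-step time series."""

    config: SimulationConfig
    final_states: HealthStateVector
    counts: "object"  # pandas.DataFrame, one row per recorded step
    steps: int
    absorbed: bool
    seed: int
    census: Optional["object"] = None  # DataFrame of link counts per step
    snapshots: Optional[list] = None  # [(HealthStateVector, ParticleEnsemble)]
    final_ensemble: Optional[ParticleEnsemble] = None

    def to_csv(self, path) -> None:
        """Columnar export: one row per step with state counts, plus the
        link census columns when it was recorded."""
        table = self.counts
        if self.census is not None:
            table = table.merge(self.census, on="step", how="left")
        table.to_csv(path, index=False)

    def summary(self) -> dict:
        from .observables import outbreak_fractions

        fr = outbreak_fractions(self.final_states, require_absorbing=False)
        out = {
            "seed": self.seed,
            "steps": self.steps,
            "absorbed": self.absorbed,
            **fr,
        }
        out["config"] = self.config.to_dict()
        return out


# ---------------------------------------------------------------------------
# elementary updates


def seed_epidemic(
    states: HealthStateVector,
    mode: str,
    seed: int | np.random.Generator,
    seed_state: Optional[str] = None,
) -> HealthStateVector:
    """Infect one uniformly chosen particle in a fully susceptible system.

    Single mode sets it to I; cooperative mode to AB by default (both
    pathogens at once), or to a single pathogen via ``seed_state='A'/'B'``.
    """
    if np.any(states.a != S) or (
        states.b is not None and np.any(states.b != S)
    ):
        raise InvalidStateError("epidemic seeding requires all-susceptible input")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = int(rng.integers(states.n))
    out = states.copy()
    if mode == "single":
        out.a[idx] = I
    else:
        seed_state = seed_state or "AB"
        if seed_state in ("A", "AB"):
            out.a[idx] = I
        if seed_state in ("B", "AB"):
            out.b[idx] = I
        if seed_state not in ("A", "B", "AB"):
            raise InvalidStateError(f"unknown seed state {seed_state!r}")
    return out


def _transmit(
    carrier: NDArray, src: NDArray, dst: NDArray,
    prob_per_attempt: NDArray, rng: np.random.Generator,
) -> NDArray[np.intp]:
    """Resolve one pathogen's transmission attempts.

    ``src``/``dst`` are directed contact edges in canonical order;
    attempts are the edges whose source is infectious with this pathogen
    and whose target has never carried it.  Each attempt is an independent
    draw; a target is acquired on any success.
    """
    mask = (carrier[src] == I) & (carrier[dst] == S)
    targets = dst[mask]
    probs = prob_per_attempt[mask] if prob_per_attempt.ndim else prob_per_attempt
    hits = rng.random(targets.shape[0]) < probs
    return np.unique(targets[hits])


def _single_step(
    states: HealthStateVector,
    src: NDArray,
    dst: NDArray,
    p: float,
    rng: np.random.Generator,
) -> HealthStateVector:
    a = states.a
    newly = _transmit(a, src, dst, np.float64(p), rng)
    out = a.copy()
    out[a == I] = R
    out[newly] = I
    return HealthStateVector(mode="single", a=out)


def _cooperative_step(
    states: HealthStateVector,
    src: NDArray,
    dst: NDArray,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> HealthStateVector:
    a, b = states.a, states.b
    # per-attempt success probability: primary p for a fully naive target,
    # secondary q once the other pathogen has ever been carried; all
    # attempts read the entering (time-t) states, pathogen A resolved
    # before pathogen B in canonical edge order for reproducibility
    prob_a = np.where(b[dst] == S, p, q)
    new_a = _transmit(a, src, dst, prob_a, rng)
    prob_b = np.where(a[dst] == S, p, q)
    new_b = _transmit(b, src, dst, prob_b, rng)
    out_a, out_b = a.copy(), b.copy()
    out_a[a == I] = R
    out_b[b == I] = R
    out_a[new_a] = I
    out_b[new_b] = I
    return HealthStateVector(mode="cooperative", a=out_a, b=out_b)


def update_states_single(
    states: HealthStateVector,
    contacts: ContactSet,
    p: float,
    rng: np.random.Generator,
) -> HealthStateVector:
    """Synchronous SIR update: every susceptible with m infectious contacts
    becomes infected with probability ``1 - (1-p)^m``; every particle that
    entered infected leaves recovered."""
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"p must be in [0, 1], got {p}")
    if states.mode != "single":
        raise InvalidStateError("update_states_single needs the single alphabet")
    src, dst = contacts.directed()
    return _single_step(states, src, dst, p, rng)


def update_states_cooperative(
    states: HealthStateVector,
    contacts: ContactSet,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> HealthStateVector:
    """Synchronous two-pathogen update with primary rate p, secondary rate q.

    A doubly infected particle makes one independent attempt per pathogen
    per contact; a naive target reached by both pathogens in the same step
    can acquire both (all attempts read the entering states).
    """
    for name, v in (("p", p), ("q", q)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
    if states.mode != "cooperative":
        raise InvalidStateError(
            "update_states_cooperative needs the dual alphabet"
        )
    src, dst = contacts.directed()
    return _cooperative_step(states, src, dst, p, q, rng)


# ---------------------------------------------------------------------------
# run loop


def run_to_absorbing(
    config: SimulationConfig,
    record_census: bool = False,
    record_snapshots: bool = False,
) -> RunResult:
    """Run one epidemic from a single seed to the absorbing configuration.

    Each iteration records the entering state, updates states from the
    current contacts, then moves the particles.  Contact enumeration is
    restricted to the neighborhoods of infectious particles unless a full
    link census is requested; both routes produce bit-identical
    trajectories for a given seed because transmission attempts are drawn
    in canonical (source, target) order either way.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    ens = initialize_particles(config.n, config.box_size, rng)
    states = HealthStateVector.all_susceptible(config.n, config.mode)
    states = seed_epidemic(states, config.mode, rng, config.seed_state)

    static = config.motion == "static" or (
        config.motion == "ballistic" and config.velocity == 0
    )
    need_full = record_census or record_snapshots
    cached_contacts: Optional[ContactSet] = None
    cached_tree = None

    count_rows: list[dict] = []
    census_rows: list[dict] = []
    snapshots: list = []
    steps = 0
    absorbed = states.num_infected() == 0

    def record(step: int, st: HealthStateVector, contacts: Optional[ContactSet]):
        count_rows.append({"step": step, **st.counts()})
        if record_census and contacts is not None:
            from .observables import link_census

            census_rows.append(
                {
                    "step": step,
                    **link_census(
                        st, contacts, collapse_dual=st.mode == "cooperative"
                    ),
                }
            )
        if record_snapshots:
            snapshots.append((st.copy(), ens))

    while steps < config.max_steps and states.num_infected() > 0:
        if need_full:
            if static and cached_contacts is not None:
                contacts = cached_contacts
            else:
                contacts = contact_pairs(ens, config.radius)
                if static:
                    cached_contacts = contacts
            record(steps, states, contacts)
            src, dst = contacts.directed()
        else:
            record(steps, states, None)
            if static and cached_tree is None and 2 * config.radius < ens.box_size:
                from scipy.spatial import cKDTree

                cached_tree = cKDTree(
                    np.mod(ens.positions(), ens.box_size), boxsize=ens.box_size
                )
            infected = np.nonzero(states.infected_mask())[0]
            src, dst = contacts_from_sources(
                ens, config.radius, infected, tree=cached_tree
            )

        if config.mode == "single":
            states = _single_step(states, src, dst, config.p, rng)
        else:
            states = _cooperative_step(
                states, src, dst, config.p, config.q, rng
            )
        steps += 1

        if config.motion == "annealed":
            ens = resample_positions(ens, rng)
        elif not static:
            ens = advance_positions(ens, config.velocity)

    absorbed = states.num_infected() == 0
    # closing record: the absorbing (or truncated) configuration
    if need_full:
        contacts = (
            cached_contacts
            if static and cached_contacts is not None
            else contact_pairs(ens, config.radius)
        )
        record(steps, states, contacts)
    else:
        record(steps, states, None)

    return RunResult(
        config=config,
        final_states=states,
        counts=pd.DataFrame(count_rows),
        steps=steps,
        absorbed=absorbed,
        seed=config.seed,
        census=pd.DataFrame(census_rows) if record_census else None,
        snapshots=snapshots if record_snapshots else None,
        final_ensemble=ens,
    )
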