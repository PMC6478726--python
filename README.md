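# mobsir

Agent-based simulation of contagion on **mobile particles**: N particles
move ballistically on a 2D torus of side L, each with a fixed random
heading and speed v, and infect each other on proximity (torus distance
< d). The package implements single-infection SIR dynamics and
two-pathogen *cooperative* contagion, together with the analytic
mean-field companion and the diagnostics needed to map out how particle
velocity reshapes the epidemic phase diagram.

It is aimed at researchers in epidemic modelling and statistical physics
who want a reproducible sandbox for temporal contact networks generated
by motion — between the static random-geometric-graph limit (v = 0) and
the annealed, uncorrelated-contact-sequence limit (v → ∞).

## Model

- **Motion**: `x(t+1) = (x + v cos ξ) mod L`, `y(t+1) = (y + v sin ξ) mod L`,
  headings ξ fixed per particle. Modes: `ballistic`, `static` (v = 0),
  `annealed` (positions redrawn uniformly every step).
- **SIR**: an infected particle transmits to each contact with probability
  p and recovers after exactly one time step (the recovery time is the
  time unit). States are updated synchronously, then positions move.
- **Cooperative contagion**: two pathogens A and B. A transmission attempt
  against a fully naive host succeeds with the primary probability p; a
  host currently infected with, or recovered from, the *other* pathogen is
  secondarily infected with probability q. q = p is two independent
  epidemics; q > p is cooperation. Runs start from one doubly infected
  (AB) seed.
- **Order parameters**: ρ, the recovered fraction in the absorbing state,
  or ρ_ab, the doubly recovered fraction.

Instantaneous contact graphs of uniform configurations are random
geometric graphs with expected degree `⟨k⟩ = (N−1)πd²/L²`, which fixes
the reference scales `d_c` (static percolation at ⟨k⟩_c ≈ 4.52), `d_min`
(⟨k⟩ = 1, no epidemic possible below it) and `d_max = L/√2` (complete
graph). In the annealed limit the final size obeys the mean-field
implicit equation `ρ = 1 − exp(−p⟨k⟩ρ)` with threshold `p_c⟨k⟩ = 1`.

## Worked example

Reference scales for the standard geometry (N = 2¹², L = 1280):

```bash
$ mobsir scales --n 4096 --box 1280 --radius 30
{
  "d_c": 23.99259911940756,
  "d_min": 11.285169339194304,
  "d_max": 905.0966799187808,
  "k_c": 4.52,
  "mean_degree_at_radius": 7.066857742190662,
  "radius": 30.0
}
```

So at d = 30 the contact graph sits just above the static percolation
range (d_c ≈ 24) with about 7 expected neighbors. A single run at the
"worst-case" speed v = 0.5 d (density-preserving reduced scale):

```bash
$ mobsir simulate --n 1024 --box 640 --radius 30 --velocity-over-d 0.5 --p 1.0 --seed 11
{
  "seed": 11,
  "steps": 25,
  "absorbed": true,
  "rho": 0.830078125,
  ...
}
```

The epidemic absorbed after 25 steps having reached 83% of the
population — noticeably *less* than either the static front (ρ → 1.0) or
the fast-mixing limit (ρ ≈ 1 at p⟨k⟩ = 7): intermediate speeds erode the
infection front, which is exactly the non-monotonic velocity effect the
sweep machinery quantifies. The same library calls are available in
Python via `mobsir.run_to_absorbing`, `mobsir.run_sweep`,
`mobsir.estimate_threshold`, `mobsir.transition_gap`, and canned
experiment configurations via `mobsir.reproduce_figure` /
`mobsir figure`.

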