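# Methods

## Model

N point particles live on the torus `[0, L)²`. Each particle gets an
i.i.d. uniform position and an i.i.d. uniform heading ξ ∈ [0, 2π) that
never changes; motion is uniform rectilinear with speed v per time step,
wrapped by the periodic boundary. Two particles are in contact when
their minimum-image distance is strictly below the interaction range d.
A time step applies the synchronous state update first (all transmission
attempts read the entering states) and moves the particles second.

Single infection is discrete-time SIR with a one-step infectious period:
a particle infected during update t transmits only during update t+1 and
is recovered afterwards. The recovery time defines the time unit, so
velocities are naturally quoted as v/d, the fraction of the interaction
range traveled per recovery time.

The cooperative variant tracks two pathogens A and B per particle
(product alphabet {S, A, B, AB, a, b, aB, Ab, ab}, lower case =
recovered-from). Per contact and per pathogen carried, an infectious
particle makes one independent transmission attempt: success probability
p against a target that has never carried either pathogen, q against a
target that carries or has recovered from the other pathogen, nothing
against a target that already carries or cleared the same pathogen.

Interpretation choices the rules do not pin down (kept explicit because
they change microscopic trajectories):

- A naive target reached by A-attempts and B-attempts in the same update
  can acquire both pathogens at once; all concurrent attempts see the
  entering state, so a target acquiring A this step still counts as
  naive for this step's B-attempts. Forbidding simultaneous acquisition
  would need an arbitrary priority rule.
- The secondary rate q applies to *currently infected* targets as well
  as recovered ones, so an A-infectious particle acquires B at rate q
  (becoming AB).
- A doubly infectious particle makes two independent attempts per
  contact, one per pathogen.

### Motion modes

`static` is identical to `ballistic` with v = 0 (asserted by test). The
`annealed` mode redraws every coordinate uniformly after each update —
the uncorrelated-contact-sequence (v → ∞) limit as an *explicit* mode
rather than a large finite velocity, which would alias under the modulo
and retain residual correlations. Headings are untouched by resampling.

### Reference scales

Uniform configurations give random geometric graphs (RGG) with expected
degree ⟨k⟩ = (N−1)πd²/L² (exact for d ≤ L/2, where the disc does not
self-overlap). Derived scales, all configurable through the percolation
degree k_c (default 4.52, the adopted 2D RGG literature value):

| scale | formula | N = 2¹², L = 1280 |
|---|---|---|
| d_c | L√(k_c/((N−1)π)) | ≈ 24 |
| d_min | L√(1/((N−1)π)) | ≈ 11 |
| d_max | L/√2 | ≈ 905 |

The reduced scale used by the heavier experiments (N = 2¹⁰, L = 640)
preserves (N−1)/L², hence degrees, d_c and d_min carry over unchanged.

## Numerical choices

- **Contacts**: strict inequality (distance < d); ties at exactly d are
  excluded — measure zero, but fixed for reproducibility. Enumeration
  uses a periodic `scipy.spatial.cKDTree` (post-filtered to strict
  inequality) for 2d < L and a brute-force minimum-image scan otherwise;
  the two are contract-equal, and the brute-force path is the oracle in
  the tests. The run loop queries only the neighborhoods of infectious
  particles unless a full link census is requested; both paths draw the
  same random numbers (attempts sorted canonically by source, target),
  so trajectories are bit-identical either way.
- **RNG discipline**: one `numpy` Generator per run seeds everything
  (positions, headings, epidemic seed, pathogen-A attempts then
  pathogen-B attempts per step, annealed resampling). Sweeps derive
  per-run seeds from a master seed and a run counter via
  `SeedSequence`, recorded in the output, so any run can be replayed.
- **Mean field**: ρ = 1 − exp(−p⟨k⟩ρ) is solved by bracketed Brent
  iteration to 1e−12 absolute; the trivial root is returned for
  p⟨k⟩ ≤ 1, the nontrivial root above (it exists iff p⟨k⟩ > 1).
- **max_steps** defaults to 10 N, generous for the slowest static
  fronts; hitting it flags the run non-absorbed instead of raising.

## Estimators

**Threshold.** Three criteria, all reported with their cutoff ρ\*
(default 0.05, a deliberate knob — the literature rarely prints its
operational definition):

- `cutoff` (default): smallest grid value whose all-runs mean order
  parameter exceeds ρ\*. Simple, but biased upward near continuous
  transitions because single-seed runs mostly go extinct.
- `onset`: smallest grid value at which *any* run is macroscopic
  (order parameter > ρ\*). With one initial seed the infinite-size
  threshold is where the outbreak branch first carries positive
  probability; the subcritical side cannot false-positive as long as ρ\*
  exceeds the largest minor-outbreak clusters (checked for the
  geometries used).
- `susceptibility`: grid value maximizing the ensemble variance.

A velocity scan whose above-cutoff region splits in two (outbreaks at
low and at high speed, none in between) is reported as reentrant with
the pair (v_c⁻, v_c⁺).

**Transition order.** At fixed parameters near the threshold, the sorted
final ρ_ab values are split at their largest spacing; the *gap* is the
width of that empty interval (upper-branch minimum − lower-branch
maximum). Classification is discontinuous iff both branches hold ≥ 10%
of the runs and the gap is ≥ 0.3. Rationale: every finite single-seed
epidemic is "bimodal" (extinctions vs outbreaks), but near a continuous
transition the outbreak branch grows up from zero so its sorted values
crawl upward with only sampling-sized spacings (measured ≲ 0.17 at 50
runs in the slow-particle regime), while a first-order jump leaves a
wide forbidden band (measured ≳ 0.54 in the fast-particle regime); 0.3
sits between with a ~2× margin on either side. Branch-mean separation
is reported alongside. `classify_transition` walks the scanned grid
from the estimated threshold to the first point where the outbreak
branch is actually populated (≥ 10%), since the one or two outbreaks at
the exact crossing say nothing about bimodality.

**RGG percolation degree.** Ensembles of uniform configurations per
mean-degree grid point; the critical degree is the smallest grid value
at which at least half the realizations hold a giant component. "Giant"
means largest component > 0.5 N: at the 2D critical point the largest
cluster scales as N^(d_f/2) with d_f = 91/48, which at N = 4096 already
reaches a fifth to a third of the system, so a 0.2 N cutoff would
trigger on critical fluctuations; 0.5 N is reachable only by a genuinely
supercritical phase. Measured: 4.3–4.4 at N = 4096 (grid step 0.1),
consistent with the adopted 4.52 given the downward finite-size shift.

**Recovered-component profile.** Per step, the subgraph induced by
recovered particles under the instantaneous contacts; mean and largest
component sizes against the recovered count R, with the reference count
R_c = 1 + L²/(πd²) at which a *scattered* recovered population reaches
mean internal degree one. An expanding front keeps ⟨C⟩_R = R exactly;
fast mixing keeps the subgraph fragmented through R_c, with the giant
recovered component emerging a few multiples later (scattered points
percolate at mean internal degree ≈ 4.5, i.e. R ≈ 4.5 R_c — the liftoff
of ⟨C⟩_R, not the giant itself, marks R_c).

## Study conditions and problem sizes

- Annealed single-infection checks: N = 1024 at the density-preserving
  reduced scale, d = 30 (⟨k⟩ ≈ 7). Universal-curve comparison against
  the mean-field final size uses means conditional on outbreak
  (ρ > 0.05) at solidly supercritical p⟨k⟩ ∈ [1.8, 3], where major and
  minor outcomes separate cleanly and the conditioning introduces no
  truncation bias; agreement is within Monte-Carlo error at these sizes.
- Optimal velocity: p = 1, d = 25 — just above d_c = 24, where the
  threshold crest sits and the ρ(v) dip is deepest (at d ≥ 28 the dip
  shallows and drifts to higher v/d); v/d ∈ {0.1, …, 1.2}, 50 runs per
  point. The minimum lands at v/d = 0.5–0.6 across master seeds.
- Transition order with velocity: q = 1, d = 30 ≳ d_c, reduced scale,
  p⟨k⟩ ∈ [0.7, 1.6] with 50 runs per point; v = 0.9 d classifies
  continuous and v = 5 d discontinuous.
- Cooperative annealed threshold: q = 1 at the dense extreme d = 639 ≈
  L/2 (⟨k⟩ ≈ 0.8 N, the regime where position redistribution barely
  changes the topology and secondary infection is effectively
  immediate). Takeoff from a single AB seed is a rare event just above
  threshold, so the onset estimator runs 200 realizations per grid
  point (step 0.05 in p⟨k⟩); the branch first appears at p⟨k⟩ = 0.50,
  occasionally detected one grid step later. At moderate densities
  (⟨k⟩/N ≲ 0.1) the two pathogens spread nearly independently early on
  and single-seed takeoff below p⟨k⟩ = 1 becomes too rare to observe —
  the 0.5 threshold is genuinely a dense-contact limit.

## What the generator emulates — and what it does not

All inputs are self-generated: uniform initial conditions, fixed
headings, one epidemic seed. The model deliberately omits features of
real contact data: heterogeneous or state-dependent velocities, motion
coupling (flocking), daily activity rhythms, reflective walls,
reinfection and waning immunity, more than two pathogens. Passing tests
therefore validate the mechanism — front erosion at intermediate speeds,
mixing-driven change of transition order — not any empirical contact
network's quantitative behavior.

## Known limitations

- Order-parameter grids behind the canned figure configurations are
  coarse approximations of the published heat maps, sized for a single
  CPU; they reproduce structure (threshold lines, reentrant window,
  gap), not pixels.
- The transition-order gap floor (0.3) and branch occupancy (10%) are
  calibrated heuristics; genuinely weak first-order jumps (< 0.3) would
  classify as continuous.
- Threshold estimates are grid-resolution limited; no finite-size
  scaling or critical-exponent machinery is provided.
- `expected_degree` and the pk ↔ p translation assume d ≤ L/2.
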