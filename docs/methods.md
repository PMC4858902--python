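# Methods

## Model summary

`immunet` couples three layers:

1. **Genotype → network.** Every protein carries three bitstrings of
   length *L* = 10 (neutral *S_N*, input domain *S_I*, output domain
   *S_O*). On a fixed topology (R→E_S, R→E_N, C→E_S, C→E_N, E_S↔E_N,
   plus P→R during infection) each edge coefficient is
   μ = 1 − 2H/L ∈ [−1, 1], a pure function of the stored sequences.
   Specific host–parasite interfaces are all-or-nothing with an
   inclusive 60 % match threshold (at L = 10: Hamming distance ≤ 4
   activates); non-specific interfaces are the constant 0.2.
2. **Network → phenotype.** Activities evolve by the deactivation/
   activation ODE with rate φ and the piecewise saturation factor that
   keeps [0, 1] forward invariant. C and P are sources clamped at 1:
   C has no incoming edges, and a dynamic C would decay to zero and
   silence the constitutive pathway, contradicting its role as a
   constitutively active protein. The resting equilibrium (from all-zero
   activities) defines the constitutive phenotype; the infected
   equilibrium, initialised **from the resting state**, defines the
   induced one. The choice of initial states is part of the model
   semantics: induction perturbs a maintained system.
3. **Phenotype → fitness.** Efficacy E = ξ_S y_ES + ξ_N y_EN, cost
   C = κ(y_ES + y_EN), two-phase infected survival with delay δ and
   virulence ν, parasite fitness e^{−(δE₀+(1−δ)E*)}. Each survival
   bracket (1−C)(1−νe^{−E}) is floored at 0 before the fractional
   power: with κ ≤ 0.8 and two effectors the cost can exceed 1, and the
   clamp defines the boundary behaviour (fitness 0) without affecting
   the interior where evolution actually operates.

## Steady-state computation

The dynamic subsystem is three-dimensional (y_R, y_ES, y_EN). The
receptor is autonomous: with a static parasite source its equilibrium is
the closed form μ_RP/(φ+μ_RP) (0 when undriven). The effector pair is
solved by a damped fixed-point iteration on the per-node balance
y = A/(φ+A+B), where A and B are the summed activating and inhibiting
inputs; the update y ← y + ½(A/(φ+A+B) − y) has the sign of dy/dt in
every coordinate, so from a given initial state the iteration settles on
the attractor the flow itself would reach. Convergence is declared at
max |dy/dt| < 10⁻⁸ (cap 2·10⁵ sweeps, after which an error carrying the
offending genome context is raised; in practice 30–100 sweeps suffice).

Fixed-step RK4 (step 0.05, horizon 10³ time units) is the reference
semantics. The exact equilibrium is a fixed point of the RK4 map, so
long-time integration converges to it without discretisation bias; the
test suite checks fixed-point/RK4 agreement to < 10⁻⁶ on 10³ random
genomes for both the resting and infected systems, and probes
initial-state dependence (resting-state vs zero initialisation of the
infected solve) on random genomes. No multistability has surfaced in
these probes; mutual E_S↔E_N activation admits it in principle, which
is why the initial states above are fixed conventions rather than
implementation details.

## Evolutionary loop

Non-overlapping generations, fixed population sizes, no elitism, no
density dependence. Per generation: (i) one resting solve per host;
(ii) each host challenged independently with probability `p_encounter`
and paired with one parasite drawn uniformly **with replacement**;
(iii) infected solves for challenged hosts only; (iv) host fitness s₀
(unchallenged) or s₀·s* (challenged); parasite fitness is the mean
establishment probability over its realised encounters — parasites
drawn zero times receive the mean fitness of the drawn ones, which
keeps the sampling lottery selectively neutral rather than penalising
or rewarding being missed; (v) hosts reproduce sexually (both parents
fitness-lottery with replacement; each of the four proteins inherited
intact from a random parent), parasites clonally; (vi) point mutation
at rate 1 % per individual per generation, implemented as: with
probability 0.01 exactly one uniformly chosen bit among all the
individual's bitstrings flips. The per-individual single-flip reading
is a modelling commitment (a per-bit reading would give a ~100× higher
genomic rate) and is isolated in one operator so it can be swapped.

Should every fitness in a population be zero (possible only in the
clamped high-cost corner), reproduction falls back to uniform sampling
and logs a warning rather than aborting.

## Parameters

| parameter | meaning | default | note |
|---|---|---|---|
| L | bitstring length | 10 | per sequence; host genome 120 bits |
| φ | spontaneous deactivation rate | 0.3 | sets the activity scale μ/(φ+μ) |
| κ | marginal effector cost | 0.2 | explored range 0.2–0.8 |
| δ | relative induction delay | 0.2 | fraction of infection on constitutive defence only |
| ν | maximum virulence | 0.99 | undefended infection removes 99 % of fitness |
| p_encounter | per-host challenge probability | 1.0 | the swept ecological variable |
| N_host, N_parasite | population sizes | 2000 | fixed each generation |
| mutation rate | per individual per generation | 0.01 | one bit flip per event |
| generations / burn-in | run length | 10000 / 5000 | summaries interpreted post-burn-in |
| replicates | independent repeats | 20 | seeds spawned from the master seed |

Master seed → replicate seeds uses `numpy.random.SeedSequence.spawn`,
so replicates are statistically independent and individually
re-runnable; each replicate additionally splits an evolution stream
from a metrics stream so that recording frequency cannot perturb the
evolutionary trajectory.

## Summary statistics

Per recorded generation: mean constitutive activity per effector over
all hosts; mean induced component (y* − y⁰) over challenged hosts
(reported as missing, not zero, when nobody was challenged); mean
receptor activity over challenged hosts, which equals the detection
rate times the closed-form per-detection activity; parasite pairwise
diversity; mean coefficient per evolvable edge; and consensus
divergence rates per protein and sequence class.

Two metrics are package conventions rather than uniquely determined by
the model description:

- **Parasite diversity** is the mean pairwise Hamming distance on the
  concatenated functional domains (S_I + S_O, 20 bits); the neutral
  sequence would only add clock noise to a selection-driven signal and
  is excluded by default (an `include_neutral` flag restores it).
  All pairs are enumerated up to 200 individuals; above that, 10⁴
  uniformly sampled pairs estimate the mean (validated against the
  exhaustive computation in the tests).
- **Divergence rates** are consensus-based: the majority bit per
  position (ties to 0) is compared against the consensus at a reference
  generation (generation 0, re-anchored at the burn-in generation) and
  the Hamming distance is divided by generations elapsed. This
  approximates a substitution rate without lineage tracing; adaptive
  evolution appears as functional-class rates exceeding the S_N rate.
  Because the per-generation rate column is noisy at small elapsed
  times and saturates at large ones, directional comparisons in the
  tests use the end-of-run rates, where the elapsed window is longest.

## Reduced-scale test conditions

The trend tests run populations of 500 for 3000 generations (burn-in
1500) with 5 replicates, and the neutrality control runs populations of
200 for 1000 generations — sizes at which one replicate takes seconds
rather than hours while the selection differentials remain large
relative to drift for the encounter-probability contrast. What passing
shows, and what it does not: the activity-based orderings (constitutive
up / induced down with encounter rate; functional divergence exceeding
neutral under specific detection) are robust at this scale, but
diversity-mediated contrasts are not. With a mutation supply per
functional parasite bit of N·μ/30 ≈ 0.17 per generation (4× below full
scale), the clonal parasite sits in a sequential-sweep regime:
genome-wide hitchhiking purges variation about as fast as negative
frequency-dependent selection generates it, so the elevation of
parasite diversity under a specific receptor — and the consequent
suppression of detection — is at the edge of resolution here and its
sign varies between master seeds. The corresponding trend test asserts
the full-scale ordering and is allowed to fail rather than being
weakened; the full-scale configuration remains available through the
`SimulationConfig` defaults.

The synthetic initial conditions are exactly the model's own: uniform
random bitstrings, so no feature of real immune-gene sequence evolution
(codon structure, indels, gene families, linkage to other traits) is
represented, and conclusions transfer to real systems only at the level
of the conceptual constitutive/induced trade-off.

## Known limitations

- Single challenge per host; no within-host dynamics; no host or
  parasite demography; topology is fixed and only coefficients evolve.
- The consensus divergence metric understates rates under balancing
  selection that holds allele frequencies near 1/2.
- The fitness clamp at C ≥ 1 is a boundary convention; comparisons of
  absolute fitness in that corner are not meaningful.
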