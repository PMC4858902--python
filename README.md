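# immunet

An individual-based simulator of host–parasite coevolution in which the
host's immune system is a small, evolvable signal-transduction network.
It addresses a classic question in evolutionary immunology — how much
defence should be **constitutive** (always on, always paid for) versus
**induced** (cheap until triggered, but delayed) — while letting the
parasite population counter-evolve against the host's genotype-specific
receptor and effector.

It is intended for evolutionary biologists and modellers studying optimal
defence, Red Queen dynamics and the evolution of immune network
architecture.

## The model

Each host carries four proteins: a recognition receptor **R**, a
constitutively active protein **C**, a specific effector **E_S** and a
non-specific effector **E_N**. Each protein is encoded by three
bitstrings of length *L* = 10 — a neutral reference sequence *S_N*, an
input domain *S_I* and an output domain *S_O*. The strength of an
interaction from protein *j* to protein *i* on the fixed network topology
is a linear function of domain complementarity,

    μ_{i×j} = 1 − 2·H(S_I^(i), S_O^(j)) / L,

where *H* is the Hamming distance; μ > 0 activates and μ < 0 inhibits.
Protein activities y_i ∈ [0, 1] follow

    dy_i/dt = −φ·y_i + Σ_j c_{i×j}·μ_{i×j}·y_j · (1 − y_i  if μ > 0; y_i  if μ < 0),

with spontaneous deactivation rate φ = 0.3. The resting steady state
gives the constitutive effector activities y⁰; attaching a parasite
(a static source y_P = 1 driving R) and re-equilibrating gives the
infected activities y*, whose excess y* − y⁰ is the induced response.

Host–parasite interfaces are genotype-specific or not: non-specific
components act at a constant 0.2 regardless of genotype, specific
components act all-or-nothing (coefficient 1 when the sequence match
1 − H/L reaches 60 %, else 0). Defence efficacy E = ξ_S·y_ES + ξ_N·y_EN
and cost C = κ·(y_ES + y_EN) feed a two-phase survival model with
induction delay δ and maximum virulence ν = 0.99:

    s* = [(1−C₀)(1−ν·e^{−E₀})]^δ · [(1−C*)(1−ν·e^{−E*})]^{1−δ},
    W_host = s₀·s*  with  s₀ = 1 − C₀,      W_parasite = e^{−(δ·E₀ + (1−δ)·E*)}.

Populations of 2000 haploid hosts (sexual, free recombination between but
not within proteins) and 2000 clonal parasites evolve by fitness-weighted
lottery sampling with point mutations at 1 % per individual per
generation.

## Worked example

Run a reduced-scale experiment contrasting rare and frequent parasite
encounters under non-specific detection:

```python
from immunet import SimulationConfig, run_simulation

base = dict(n_host=500, n_parasite=500, generations=3000, burn_in=1500,
            replicates=3, kappa=0.2, delta=0.2, record_every=5, seed=11)
for p in (0.2, 1.0):
    df = run_simulation(SimulationConfig(p_encounter=p, **base))
    post = df[df.post_burn_in]
    print(f"p_encounter={p}: constitutive E_N={post.y0_en.mean():.3f}  "
          f"induced E_N={post.ind_en.mean():.3f}")
```

which prints

```
p_encounter=0.2: constitutive E_N=0.003  induced E_N=0.209
p_encounter=1.0: constitutive E_N=0.642  induced E_N=0.075
```

With rare encounters the non-specific effector is almost entirely
induced through the receptor (constitutive activity ≈ 0); with an
encounter every generation the evolved networks shift the same effector
onto the constitutive pathway and the induced component shrinks —
pre-emptive defence pays once threats are frequent.

The same objects expose the rest of the analysis surface: per-generation
tables carry the constitutive/induced activity split, receptor activity
(the parasite detection rate), parasite pairwise genetic diversity, the
six evolved edge strengths and per-sequence-class divergence rates.

A command-line interface wraps the library:

```bash
immunet run -c config.toml --seed 1 --out results/
immunet sweep --p-encounter 0.2,1.0 --kappa 0.2,0.8 --out grid/
```

writing `generations.tsv`, `summary.tsv` (mean ± SE across replicates)
and a `manifest.json` recording the config and per-replicate seeds.

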