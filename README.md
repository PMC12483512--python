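# idrsearch

Equilibrium binding and target-search dynamics of transcription factors
(TFs) with intrinsically disordered regions (IDRs).

Most eukaryotic TFs pair a sequence-specific DNA-binding domain (DBD)
with a long disordered tail carrying several weak DNA-binding motifs.
`idrsearch` is a toolkit for asking, quantitatively, what such a tail
buys: how much it strengthens binding to the target neighbourhood, and
how much it accelerates the diffusive search for the target. It is aimed
at biophysicists and quantitative biologists who want a coarse-grained,
fully seeded model they can interrogate end to end — from partition
functions to Brownian-dynamics first-passage times to on/off rates.

## The model in brief

The TF is an ideal bead–spring chain of `ñ = n_b + 1` sites (one DBD,
`n_b` IDR sites, segment length `l₀`). Near the specific target the DNA
is a straight "antenna": the DBD target plus `n_t` IDR targets of volume
`V₁` at spacing `d`. Lengths are in bp, energies in k_BT, times in
`t₀ = bp²/D`.

**Equilibrium.** Summing Boltzmann weights over every injective matching
of sites onto targets (ideal-chain entropy integrated out exactly) gives
the bound probability `P_TF` and the affinity gain `Q = P_TF/P_simple`
over an IDR-less TF. One contact contributes the enhancement factor

    𝓟 = e^{E_B} · V₁ · f(d, l₀),      f(r,l) = (3/2πl²)^{3/2} e^{-3r²/2l²},

so a contact pays off (`𝓟 > 1`) only above the threshold well depth

    E_th = (3/2)[ln(2π/3φ²) + 1],     φ = V₁^{1/3}/d.

**Kinetics.** An overdamped Langevin simulator follows the chain inside a
reflecting nucleus of radius `R` until the DBD first hits its target:
3D diffusion, capture by the antenna, then an effective 1D "octopusing"
walk in which IDR sites bind and unbind asynchronously. The mean search
time obeys

    t_total(L) ≈ α ñR³ ln(L/r_p)/(DL) + β L²/D,     r_p = √(ñ/6) l₀,

with a minimum at an optimal antenna length `L*`; `α`, `β` are fitted
from simulated `t_3D`, `t_1D` tables (`SearchTimeModel(...).fit()`).
Search times convert to `k_on`, `k_off`, `k_D` via the nuclear volume and
TF copy number.

## Worked example

```python
import math
from idrsearch import (TFArchitecture, make_layout, EnergyModel,
                       binding_probability, threshold_energy,
                       optimal_antenna, simple_tf_time)

d = math.sqrt(50)                       # target spacing, bp
arch = TFArchitecture(n_b=4, l0=d)      # 4 IDR sites + DBD, l0 = d
layout = make_layout("equal", n_t=4, d=d, side="one_sided")
energy = EnergyModel(E_B=10.0, E_DBD=15.0, V1=1.0, V=(1e3 / 0.34) ** 3)
print(binding_probability(arch, layout, energy).summary())
```

prints

```
Equilibrium binding of a multivalent TF
==============================================
chain: n_b = 4 IDR sites + DBD, l0 = 7.07107 bp
targets: n_t = 4, d = 7.07107 bp (equal, one_sided)
energies: E_B = 10, E_DBD = 15 kBT; V1 = 1 bp^3, V = 2.544e+10 bp^3
----------------------------------------------
configurations: 418
P_free     = 0.893558
P_IDR_only = 0.000525416
P_TF       = 0.105917
P_simple   = 0.000128469
Q = P_TF / P_simple = 824.453
```

Four weak IDR contacts (10 k_BT each, above `E_th ≈ 8.48` k_BT for
`φ² = 0.02`) turn a DBD that alone would occupy its target 0.013% of the
time into one bound 10.6% of the time — an 824-fold gain. On the kinetic
side,

```python
L_star, t_min = optimal_antenna(n_tilde=4, R=500.0, D=1.0, l0=5.0,
                                alpha=0.5, beta=14.5)
print(L_star, t_min, simple_tf_time(500.0, 1.0, 0.5) / t_min)
# 306 bp   4.88e6 t0   17.1
```

the optimal antenna is ~300 bp and the IDR-TF finds its target 17×
faster than the simple-TF baseline `R³/(3Da)`.

The same machinery is scriptable from the shell:

```bash
idrsearch equilibrium-scan --kind eb --out q_vs_eb.csv
idrsearch simulate-search --config sim.yaml --n-runs 40 --seed 1 --out runs/
idrsearch fit-search-theory --measurements runs.csv --n-tilde 3 --r 60 --l0 5 --out fit.json
idrsearch analyze-octopus --config attached.yaml --out octo/
idrsearch point-reference --r 500 --a 0.5 --n-runs 400
idrsearch figure --id fig3 --scale reduced --seed 11 --out figures/
```

Every stochastic entry point takes a seed and reproduces bit-exactly.

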