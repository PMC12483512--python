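# Methods

`idrsearch` models how a eukaryotic transcription factor (TF) whose
intrinsically disordered region (IDR) carries multiple weak DNA-binding
sites finds and holds its specific target. The package has two coupled
parts — an equilibrium configuration-sum engine for binding probability
and an overdamped Langevin simulator for search kinetics — plus the
semi-analytic theory that ties the kinetics together and converts them to
biochemical rates.

## Model

The TF is an ideal (Rouse) bead–spring chain of `n_tilde = n_b + 1`
coarse-grained sites: one DNA-binding domain (DBD) at a chain end and
`n_b` IDR sites, joined by segments of statistical length `l0`. The DNA
near the specific target is a straight "antenna": the DBD target plus
`n_t` IDR targets of volume `V1` at spacing `d`. Units are base pairs
(1 bp = 0.34 nm) for length, `k_B T` for energy, and `t0 = bp^2/D` for
time, with `D` the diffusion coefficient of a single site.

For an ideal chain, two sites `g` segments apart have a Gaussian
separation density

    f(r, l) = (3 / (2 pi l^2))^{3/2} exp(-3 r^2 / (2 l^2)),   l = sqrt(g) l0,

which is everything the equilibrium theory needs about the polymer.

### Equilibrium binding

A binding configuration is an injective partial matching of chain sites
onto targets (DBD site only to the DBD target, IDR sites only to IDR
targets; crossing matchings included). There are
`2 * sum_n C(n_b,n) C(n_t,n) n!` of them. Integrating out the unbound
degrees of freedom gives the weight convention used throughout:

* free chain: the translational volume `V`;
* first bound contact (lowest chain index): `e^{E} V1`;
* each further contact: `e^{E} V1 * f(|dR_targets|, gap_segments, l0)`,

with `E = E_DBD` for the DBD contact and `E_B` otherwise. This is the
unique convention that reduces, for `n_b = n_t = 1`, to
`P_TF / P_simple = 1 + P` with the single-contact enhancement factor
`P = e^{E_B} V1 f(d, l0)`, and whose weak-occupancy expansion is
`Q ≈ 1 + sum over matchings of products of P` term by term. It is
additionally validated against an independent Metropolis sampler (below).
Setting `P(E_th, d, d) = 1` defines the threshold well depth
`E_th = (3/2)[ln(2 pi/(3 phi^2)) + 1]`, `phi = V1^{1/3}/d`: above it one
compatible contact more than pays its entropic cost and multivalent
binding switches on.

All weight accumulation happens in log space (log-sum-exp), so arbitrarily
deep wells are exact. A vectorised enumeration reduces each configuration
to three scalars that are independent of `l0` and of the energies, so a
single enumeration serves whole parameter scans; configurations whose
chain-entropy log-factor falls below −690 are pruned. The enumeration cap
defaults to 10^7 configurations (diagonal systems up to
`n_b = n_t = 8`, ~2.9 M configurations, ~100 MB transient).

Default scan parameters are typical nuclear values: `V` = 1 um^3,
`E_DBD` = 15, `E_B` = 10, `V1` = 1 bp^3, `d = sqrt(50)` bp.

**A genuine corner disagreement.** The segment-matching principle "Q peaks
at `l0 ≈ d`" holds in this model for every combination with
`n_t >= n_b` and on the diagonal. When sites vastly outnumber targets
(e.g. `n_b = 8`, `n_t = 1`) the dominant bound states are single contacts
anchored to the DBD through multi-segment loops of end-to-end scale
`sqrt(gap) * l0`, which match the spacing at `l0 = d/sqrt(gap) < d`; the
optimum then genuinely sits near `l0 ≈ 0.5 d` (verified by two
independent code paths and consistent with the Metropolis oracle). The
corresponding acceptance check is intentionally left failing rather than
masked; the same loop entropy makes `Q(n_b, n_t)` asymmetric under
`n_b <-> n_t` when sites are in excess, while "extra targets beyond the
site count buy little" holds throughout.

### Metropolis oracle

An independent route to `P_TF`: direct Metropolis sampling of the
continuous chain (harmonic bonds, square wells of radius
`(3 V1/4 pi)^{1/3}`) in a periodic box of volume `V`, with single-site
displacements, whole-chain teleports and whole-chain local shifts. Each
target well saturates at one energy contribution so that double occupancy
(which the injective counting excludes and the dynamical model prevents
via excluded volume) carries no extra Boltzmann weight; the residual
phase-space difference is O(`V1 f(0,l0)`) ≈ 10^-3 here. Standard errors
come from batch means with a non-convergence diagnostic (any batch > 5
batch-SDs from the mean). The sampler is trustworthy only while bound and
free sectors alternate many times per batch, i.e. for moderate well
depths (`E_B` up to ~7 at the box sizes used); the configuration-sum
engine has no such restriction.

### Search dynamics

Each site obeys overdamped Langevin dynamics
`dr = f dt + sqrt(2 D dt) xi` with forces from (i) harmonic springs of
stiffness `3 k_B T / l0^2`, (ii) Gaussian wells of depth `E_B` and width
`w_d = 1` bp at every target, and (iii) WCA excluded volume (`sigma` = 1
bp, unit depth, force magnitude capped at 10^3 to keep the adaptive step
bounded; cap events are counted and reported). The chain lives in a
reflecting sphere of radius `R` (mirror reflection of the proposed move,
which preserves the uniform measure for pure diffusion); the DBD target
at the centre absorbs the DBD site at capture radius `a`, ending the
search.

Two speed regimes: within `far_threshold` = 10 bp of the antenna the full
per-site update runs with the adaptive step
`dt = 0.01 min(1, 1/max|f|)` (drift per step stays well below `w_d`);
farther away the TF translates as a rigid body with diffusion coefficient
`D/n_tilde` and an rms step of `far_threshold/5`, reflected at an
effective radius reduced by the instantaneous chain extent so no site can
cross the wall. Search times are insensitive to the threshold (tested 10
vs 20 bp).

Event definitions (the 3D/1D split needs an operational choice, made
here as package definitions): the TF is
*attached* while any site is within `2 w_d` of a target; a *detachment*
requires all sites beyond `far_threshold` for longer than one chain
relaxation time `n_tilde^2 l0^2 / D`. `t_1D` is the total attached time,
`t_3D` the rest; `n_rounds` counts attachments. Runs exceeding `max_time`
(default 50x the two-term prediction) are flagged censored, reported
separately, and excluded from means with a hard warning above 10%.

The integrator is audited by construction-independent tests: analytic
forces against central differences (1e-6), free-diffusion and
centre-of-mass MSD laws, Boltzmann occupancy of a single well against
radial quadrature (time-weighted, because the adaptive step is state
dependent), uniform-measure preservation under reflection, and bit-exact
reproducibility under fixed seeds. The production kernel uses an inline
xorshift128+ / Marsaglia-polar normal generator (~6x faster than the
library generator, which otherwise dominates the step cost); its moments
were verified to 1e-3 at 10^7 draws.

### Search-time theory

The mean search time decomposes as

    t_total(L) = alpha n_tilde R^3 ln(L/r_p) / (D L) + beta L^2 / D,

with `r_p = sqrt(n_tilde/6) l0` the gyration radius: the first term is
diffusion-limited capture onto a thin absorber of length `L` and radius
`r_p` (for a point searcher `alpha = 2/3` exactly; simulated point
searchers reproduce this), the second a 1D walk of range `L` with
effective diffusion constant `D/(2 beta)`-ish set by the octopusing
exchange kinetics. `alpha` and `beta` are fitted by weighted least
squares of measured `t_3D` and `t_1D` against their regressors (two
independent one-parameter fits; `SearchTimeModel.fit()` returns the
statsmodels-backed results object). Minimisation over `L` is restricted
to `L >= e r_p`, where the capture term decreases monotonically and the
formula is unimodal; below that the thin-absorber formula is outside its
domain. The simple-TF baseline is `t_simple = R^3/(3 D a)` with the
single-site `D` (an IDR-less TF diffuses faster than the chain, which
makes the comparison conservative).

### Rate conversion

The only SI boundary. With `copy_number` TFs searching in parallel the
per-cell association time is `t_eff = t_total/copies`; the single target
has concentration `c = 1/(N_A V_nuc)`, so `k_on = 1/(t_eff c)`,
`k_off = (1-P_TF)/(P_TF t_eff)` and `k_D = k_off/k_on`. Defaults:
`D = 1e-13 m^2/s` per site, 100 copies, nucleus volume 1 um^3 (the
typical value used by the equilibrium scans; the search sphere for the
cellular-scale estimate has radius 1 um). A shorthand sometimes used for the
on-rate, `t_total/V_c`, is dimensionally inconsistent; the package
implements the consistent expression above.

## Reduced-scale study conditions

The full-scale search-time optimum (`L* = 300 bp`, `E_B* = 11`,
`n_tilde* = 4` at `R = 500 bp`, 500 runs per point) costs on the order
of 10^5 CPU hours.
The package's frozen reduced-scale study (`figure --id fig3`) uses
`R = 60 bp`, `n_tilde = 3`, `l0 = 5`, `d = 5`, `a = 1`, `E_B = 10`,
`L ∈ {10, 24, 44, 80}` and 40 runs per point (master seed spawning one
seed per antenna length, each run seeded independently). These conditions
were chosen, before freezing, so that one CPU completes the study in
about five minutes while the qualitative claims remain statistically
decidable: the interior minimum of `t_total(L)` at `L = 44` is resolved
against both grid ends by more than two standard errors, first-passage
times at the optimum have an exponential tail, the optimal search is a
single 3D→1D round in every run, and the fitted capture prefactor is
O(1) (`alpha ≈ 0.27`; the smaller sphere and shallower wells make exact
agreement with the full-scale `alpha = 0.5`, `beta = 14.5` neither
expected nor claimed). `full` scale runs the original conditions and is
provided for completeness, not for routine runs.

What the reduced scale does *not* probe: the `L* ∝ R`, `t_min ∝ R^2`
scalings (exercised on the closed-form theory instead), persistence
length and coiled-antenna geometry (out of scope), and chromatin-scale
nonspecific background.

## Synthetic data and what passing tests show

All inputs are generated: target layouts (exact or exponential spacings),
chain conformations (exact ideal-chain statistics), and Eq.-5 synthetic
measurement tables with multiplicative Gaussian noise. Real nuclei have
crowding, chromatin geometry, heterogeneous site strengths and
sequence-dependent IDR interactions, none of which are emulated; green
tests therefore certify the model's internal consistency and its stated
design principles, not quantitative agreement with any particular
experiment.

## Numerical choices

* log-sum-exp everywhere in the equilibrium engine; weight pruning at
  exp(−690); enumeration cap 10^7 with a clear error.
* argmax ties in scans break toward the smaller parameter value.
* scalar minimisation: bounded Brent with `xatol = 1e-6 R`.
* WCA force cap 10^3 k_BT/bp with event counting; well forces truncated
  beyond `9 w_d` (relative error < 1e-17).
* per-run seeds derive from the master seed via `numpy.random.SeedSequence`
  (documented counter scheme, deterministic parallelisation).
* degenerate inputs: `n_b = 0` (simple TF) and `n_t = 0` (bare DBD
  target) are first-class; `L` too short for any IDR target yields a
  DBD-only antenna.

## Known limitations

* Ideal-chain statistics only; no excluded volume in the equilibrium sums
  (the dynamical model does include WCA repulsion between sites).
* The Metropolis oracle mixes too slowly for deep wells; oracle
  comparisons are restricted to its validity envelope.
* The far-field rigid-body mode ignores rotational diffusion and freezes
  internal modes; its boundary handling slightly reduces the accessible
  volume of a spread-out chain near the wall.
* The equilibrium segment-matching principle fails for extreme site
  excess (see above) — a real property of this model class, surfaced
  rather than hidden.
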