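# Methods

`cphlab` implements a desk-scale constant-pH λ-dynamics engine together with
the complete downstream analysis chain (titration fitting, coupling
detection, functional mode analysis). Its sites are abstract titratable
groups — two end states joined by an alchemical coordinate — not atomistic
residues; everything that a real force field contributes is condensed into a
handful of end-state energies and coupling constants with known ground
truth, so every analysis can be validated by exact parameter recovery.

## The extended Hamiltonian

Each titratable site carries a protonation coordinate λ_p treated as a
dynamical pseudo-particle (mass 60 u by default), with the convention

    λ_p = 0  protonated,   λ_p = 1  deprotonated.

The site energy interpolates linearly between end states. His-like sites add
a tautomer coordinate λ_t selecting between the two chemically distinct
deprotonated (neutral) forms:

    H = (1 − λ_p)·E_prot + λ_p·[(1 − λ_t)·E_deprot,δ + λ_t·E_deprot,ε],

so λ_t = 0 is the δ tautomer; the protonated corner is the single
doubly-protonated form, identical for both λ_t values. This convention is
isolated in one function (`tautomer_interpolation`) and swappable.

Site–site coupling is bilinear, `W_ij λ_p,i λ_p,j` (kJ/mol), mimicking the
Coulomb interaction of the unit charge differences: W > 0 makes joint
deprotonation of two acids unfavourable (anticooperative, Hill n < 1).

Each site may be paired with a solvent charge buffer whose λ is slaved to
the site's λ_p; the buffer oxygen charge interpolates −0.834 e → +0.166 e so
every (site, buffer) pair has exactly constant total charge. Spatial buffer
restraints are not modelled — only the charge bookkeeping.

## Bias stack and calibration

The potential acting on each λ coordinate is V = V_mm + V_pH + V_dw.

**V_mm** is a polynomial (degree 5 by default) equal to minus the model
deprotonation free-energy profile ΔG_MM(λ) of the isolated reference site,
estimated by thermodynamic integration: 21 equidistant windows on
[−0.1, 1.1], ⟨∂H/∂λ⟩ per window (10⁴ decorrelated Metropolis samples of any
orthogonal coordinates; exact for constant-integrand sites), trapezoid
integration. After calibration the reference landscape is flat to
< 0.1 kJ/mol, so the reference site titrates at its reference pKa — the
package's central self-consistency check. The toy sites carry deliberately
nonzero raw deprotonation energies (30 kJ/mol) so this path is genuinely
exercised.

**V_pH** is the linear ramp λ·k_BT·ln10·(pKa_ref − pH) coupling the
coordinate to the pH bath: the end-state energy difference equals the
deprotonation free energy at the simulation pH.

**V_dw** concentrates λ near the physical end states. On the normalised
coordinate u = (λ − p0)/(p1 − p0),

    V_dw = h_eff·(4u(1−u))² + d·T(u),
    T(u) = 70u³ − 315u⁴ + 546u⁵ − 420u⁶ + 120u⁷,

plus quartic walls (10⁵ kJ/mol per unit⁴) starting 0.15 beyond each well.
Because T′ = 210·u²(1−u)²(1−2u)² vanishes at 0, ½ and 1, the minima sit
exactly at the wells (values 0 and d) and the interior maximum exactly at
the midpoint for *any* depth offset d — the property the runtime correction
relies on. h_eff = barrier − |d|/2 keeps the maximum `barrier` (default
6 kJ/mol) above the lower well; the two-well topology holds for |d| <
barrier, and the partition machinery falls back to a fixed midpoint split
beyond that.

## Partition-function correction

Asymmetric well shapes bias the protonated/deprotonated populations
entropically. Before the first step — and after every runtime bias change —
the engine integrates Z_prot and Z_deprot = ∫exp(−βV) over the two halves of
the effective reference landscape (V_dw + V_pH; V_mm cancels the reference
profile by construction) on a 2401-point trapezoid grid spanning 0.3 beyond
the wells, and refines the deprotonated well-depth offset d by bracketed
Brent iteration (10⁻³ kJ/mol) until

    ΔG_deprot = (1/β)·ln(Z_prot / Z_deprot)

matches its target k_BT·ln10·(pKa_ref − pH). The quadrature is split at the
frame-classification threshold λ = 0.5, so corrected populations and counted
fractions refer to the same two states; the corrected equilibrium fraction
then follows the Henderson–Hasselbalch curve to < 10⁻³ at every pH,
*including* frames in intermediate λ states, which are therefore kept in all
analyses.

Two tautomer-specific refinements:

* the λ_p target of a tautomeric site includes −k_BT·ln 2, because the
  protonated chemical state occupies two λ_t wells of identical chemistry
  while each deprotonated tautomer occupies one (its pH ramp is referenced
  to the δ-path microscopic pKa);
* the λ_t correction is state-dependent, mirroring the dual barrier: the
  protonated-state stack targets 0 on the bias alone (the tautomerically
  degenerate state), the deprotonated-state stack targets the tautomer
  energy gap on the gap-tilted bias.

With both, the exact-quadrature oracle reproduces the three-state
thermodynamics (macro = −log10(K_δ + K_ε), both micro curves) to ~0.01 in
fraction; the residual comes from partially-deprotonated regions of the 2-D
λ landscape where the bilinear gap is only partly felt.

## Integration and thermostatting

λ coordinates follow velocity Verlet (2 fs step), thermostatted as a
separate group by stochastic velocity rescaling (exact factor with the
Gamma-distributed noise term; τ = 1 ps, 300 K). Conformational coordinates
are overdamped Langevin walkers in a symmetric double well (minima 0/1,
barrier h_c, diffusion D; basin relaxation ≈ exp(βh_c)/D), advanced with the
Euler–Maruyama step. States are saved every 0.5 ps; a 50 ps equilibration
with a 2 kJ/mol barrier precedes production and is discarded. A run aborts
with a diagnostic if |λ| > 5.

The production inner loop is a numba-compiled kernel (`_kernel.py`); the
readable single-step implementations in `dynamics.py` are the reference, and
a regression test asserts the kernel reproduces the Python gradients to
10⁻¹⁰. Multi-nanosecond protocols take seconds: the 100 ns Glu
self-consistency titration runs in ≈15 s on one core.

Each (pH, replica) pair runs in its own engine seeded from SHA-256 of
(global seed, scenario tag, pH, replica); reruns are bit-identical and the
seed is recorded in the trajectory metadata.

## Dynamic barrier and well optimization (DBO)

Two per-coordinate feedback controllers:

* **Wells** (40 ps blocks): if λ spent > 70% of the block near an end point
  (λ < 0.2 or > 0.8) and the mean λ there deviates from 0 or 1 by > 0.03,
  the well centre shifts by 0.5× the deviation, within ±0.08 cumulative.
* **Barrier** (1 ns blocks): the fraction of frames with 0.2 < λ < 0.8 is
  steered to 25% ± 5% in 1 kJ/mol steps within 1–20 kJ/mol. Tautomer
  coordinates keep two barriers selected by the partner coordinate's current
  protonation state, each with its own statistics and corrected depth.

Every adjustment re-runs the partition correction, is logged (time,
coordinate, parameter, old → new), and censors the following 10 ps
(inclusive window; 21 frames at the 0.5 ps save interval). Analyses skip
censored frames. Because the correction restores the target ΔG after every
actuation, DBO changes sampling efficiency but not the stationary
fractions — verified by the pKa-neutrality test.

## Titration analysis

Frames are classified deprotonated iff λ_p ≥ 0.5 (ε tautomer iff
λ_t ≥ 0.5). Fits act on per-replica deprotonation fractions — one data point
per (pH, replica):

* Henderson–Hasselbalch x(pH) = 1/(1 + 10^(pKa−pH)) (x → 1 at high pH);
* Hill x = 1/(1 + 10^(n(pKa−pH))), reducing to H–H at n ≡ 1;
* microscopic tautomer curves x_micro,δ = N_deprot,δ/(N_prot + N_deprot,δ)
  and the ε analogue, each fit with H–H;
* macro from micro: pKa_macro = −log10(10^(−pKa_δ) + 10^(−pKa_ε)).

Initialisation: pKa₀ = pH where the mean fraction crosses 0.5 (linear
interpolation), n₀ = 1. Confidence intervals are percentile bootstrap at 5%
significance: replicas resampled with replacement within each pH, refit,
5000 resamples by default; > 10% fit failures raise. The inter-replica SD of
x per pH (the spread-replica statistic) is reported with every curve.

## Coupling analysis

Binary per-replica series feed NMI = 2I(X;Y)/(H(X)+H(Y)) (natural-log
entropies; NMI is base-invariant, symmetric, in [0, 1], and blind to the
sign of the coupling). A pair is flagged coupled iff at some pH both the
replica-mean NMI and the replica-mean marginal entropy (average of the two
sites') exceed 0.1 — the entropy gate removes the false-positive mode where
two almost-always-protonated sites share a few coincident frames.

For flagged pairs: the four joint microstate fractions (overall and in
1.5 ns windows, whose inter-replica scatter diagnoses convergence), the
per-state coupling free energy ΔG = −k_BT·ln[P(A₁∧A₂)/(P(A₁)P(A₂))]
(0 under independence, positive for depleted states, NaN where a marginal
vanishes), and the two-proton macroscopic titration fit

    ⟨X⟩(pH) = (10^(pKa₁−pH) + 2·10^(pKa₁+pKa₂−2pH)) /
              (1 + 10^(pKa₁−pH) + 10^(pKa₁+pKa₂−2pH)),

where pKa₁ is the ⟨X⟩ = 0.5 inflection and pKa₂ the 1.5 one (reported
sorted ascending). Note that for *anticooperative* pairs this family
coincides with sums of two free H–H curves (the binding polynomial has real
roots); the model demonstrably beats the composition of the two per-site
H–H fits, which is the comparison implemented.

## Functional mode analysis

PLS regression (20 components, mean-centred X, no variance scaling) of λ_p
on configuration vectors, trained on the replicas at the pH nearest the
site's pKa with 20% of replicas (≥ 2) held out. The FMA mode is the
unit-normalised overall regression-coefficient vector — the single direction
whose projection best predicts protonation under the fitted model. Explained
variance is R² = 1 − SSE/SST on the held-out replicas (clipped at 0);
squared Pearson correlation is reported alongside. Projections are rescaled
affinely to the training range [0, 1]; percentile edges (5/25/50/75/95) of
the pooled training projections define six bins that partition all frames,
and a per-bin H–H fit (bins with < 100 frames at any pH flagged unreliable)
gives pKa as a function of the conformational sub-ensemble. The outermost
bins' mean configurations are the representative low/high structures.

Configurations here are plain numeric matrices; superposition of real
atomic coordinates is the caller's preprocessing responsibility.

## Synthetic scenarios and the master oracle

`cphlab.scenarios` builds the study systems: `single` (Glu-like, reference
pKa 4.40), `tautomer` (His-like, micro 6.53/6.92, macro 6.38),
`coupled_pair` (W configurable; W = 0 for independence checks),
`conformation_coupled` and `spread_replica` (conformational ΔpKa, default
2.0, with fast or 50× slower diffusion). The titration pH grid extends one
unit beyond the extreme reference pKa values in 0.5 steps. The
conformational shift energy k_BT·ln10·shift(c) is split symmetrically
between the end states (−½ protonated, +½ deprotonated): the pKa shift is
identical under any split, but the symmetric choice keeps both basins
populated at the titration midpoint, which is what makes the
conformation–protonation correlation observable (explained variance ≈ 0.5
at ΔpKa = 2 under converged sampling, versus ≈ 0.3 for the one-sided
placement).

`direct_boltzmann_oracle` integrates exp(−βU) of the *full* calibrated
landscape over every λ and conformational coordinate on a dense tensor grid
(≤ 3 continuous coordinates) and classifies states exactly as the analysis
does. It shares no code path with the integrator or the per-well partition
bookkeeping and is the reference for all sampling-correctness tests.

## What the generator does and does not emulate

The generator reproduces, with controllable ground truth: H–H and Hill
titration, tautomer micro/macro relations, anticooperative pair coupling,
slow conformational modulation and spread-replica phenomenology, DBO
actuation and censoring, and charge-buffer bookkeeping. It does not emulate
atomistic electrostatics, solvent, force-field specifics, reporter-atom
measurement bias, finite-size effects, or conformational landscapes beyond
one-dimensional double wells. Passing tests therefore demonstrate the
correctness of the machinery and analyses under the model's assumptions,
not pKa accuracy on real proteins.

## Numerical choices and problem sizes

Defaults throughout: dt 2 fs, save 0.5 ps, mass 60 u, τ 1 ps, 300 K
(k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹), barrier 6 kJ/mol, correction tolerance
0.01 kJ/mol, bootstrap 5000. Self-consistency titrations use 10 replicas ×
2 ns per pH point; the DBO regulation run is 20 ns with the statistic taken
over the final 10 ns; the thermostat check is 10 flat-potential coordinates
for 10 ns. These sizes give bootstrap CIs of a few hundredths of a pKa
unit, comparable to the systematic accuracy of the desk-scale model itself.

## Known limitations

* With DBO active on a tautomeric site, diverging dual barriers change the
  relative λ_t well volumes between protonation states in a way the 1-D
  per-coordinate correction cannot see; titrations of tautomeric sites are
  run without DBO by default.
* The correction assumes the per-coordinate bias stack is separable from
  the rest of the landscape; site–site coupling W and conformational shifts
  are deliberately *not* corrected away — they are the science being
  measured — so fractions of coupled systems deviate from single-site H–H
  exactly as they should.
* Microscopic ε-tautomer fractions carry a ~0.01–0.03 systematic from
  partially-deprotonated λ regions (see above); at the default run lengths
  this is below the statistical resolution.
* The two-proton macroscopic fit is limited to pairs; no clusters larger
  than two are modelled.
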