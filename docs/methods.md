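# Methods

## Model and estimators

**EVB energetics.** A reaction step is represented by two diabatic force
fields H11 and H22 = U2 + Δα, each of the additive form
U = U_rr + U_rs + U_ss, where U_ss (surroundings self-energy) is
identical for both states.  The adiabatic ground state is the lower
eigenvalue of the 2×2 Hamiltonian,
Eg = ½(H11+H22) − ½√((H11−H22)² + 4H12²), with H12 constant or Gaussian
in the energy gap, A·exp(−bΔU²).  All energies are kcal/mol, temperatures
Kelvin, R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹.

Two identities shape the numerics.  First, U_ss cancels exactly in the
energy gap X = U1 − U2; the implementation therefore computes X (and
everything built on it) from the solute components alone, so free-energy
estimates are *bitwise* invariant under any constant shift of U_ss — no
cancellation of ~10⁴-scale numbers ever occurs.  Second,
Eg − Umap(λ) = (λ−½)X − ½√(X²+4H12²) is a function of X only, which both
stabilizes the umbrella correction and underlies the reweighting
diagnostic discussed below.

**Free energies.** ΔG(λm) accumulates forward over adjacent mapping
windows by exponential averaging; since ΔUmap = −Δλ·X, the exponent is
environment-free.  All exponential averages use per-bin log-sum-exp
shifts; nothing is clipped.  The ground-state profile ΔGg(Xk) applies the
umbrella identity per bin and window — the bin indicator is averaged over
*all* samples of a window (the delta-function form), so the window's bin
probability is retained; the within-bin-only variant is available as
`estimator="within_bin"` for comparison, but cannot reproduce profile
shapes when Eg ≈ Umap and is not the default.  Window contributions to a
bin are combined with weights pm equal to the window's share of the bin's
samples.  Profiles are referenced to their minimum populated bin; bins
with fewer than `min_count` (default 10) samples are flagged, never
interpolated.

**Stationary points.** The reactant (product) state is the lowest
populated bin at negative (positive) X, the transition state the highest
bin strictly between them; ΔG‡ and ΔG0 are differences of raw bin values.
An optional moving average may be used for *locating* only.  Exact ties
break deterministically toward the bin center nearest a reference gap
(default X = 0, where the λ = 0.5 launch window centers by construction;
the profile object does not carry the launch window's sampled mean, so
the reference is an explicit argument).

**Enthalpy.** ΔHg(Xk) ≅ ⟨Eg(Xk)⟩ is the plain per-bin arithmetic mean of
the total ground-state energy pooled over windows and retained
replicates, evaluated at a single temperature — deliberately without
reweighting, matching how the estimator is used in production
simulations.  Because mapping-potential windows distribute X within a
finite bin differently from the canonical ensemble, this estimator
carries a bin-width-dependent bias away from stationary points (where the
within-bin distribution is asymmetric); at the reactant/transition bins
the effect is second order and ΔH‡ is essentially unbiased.  The
`reweight=True` mode applies within-bin weights ∝ exp(−β(Eg−Umap)) —
since that factor is a function of X alone, the reweighted estimator
converges to the exact canonical conditional mean and quantifies the
residual bias on the toys.  ΔH‡ is read between the *free-energy*
profile's reactant and transition bins, never at the enthalpy profile's
own extrema.

**Decomposition.** U_ss enters Eg once, linearly, outside the square
root, so Eg = (Eg − U_ss) + U_ss is exact per sample; the profile's total
is defined as the sum of the two component means, making the identity
hold to machine precision by construction.  Raw per-state ⟨U_rr⟩ and
⟨U_rs⟩ bin means are reported as diagnostics only: the mixed solute part
is not separable state by state because the gap enters the square root.
The record layout stores one u_ss value per sample, so state-independence
of U_ss is structural and cannot be silently violated by corrupt input.

**Errors.** The replicate is the unit of error everywhere: per-bin s.e.m.
is the scatter of replicate-level values over the replicates populating
the bin; within-replicate autocorrelation therefore never enters the
error model.  ΔH‡'s s.e.m. combines the RS and TS bins in quadrature,
treating them as independent — a documented simplification, since the
same replicates contribute to both bins.

**Entropy and Arrhenius analysis.** −TΔS‡ = ΔG‡ − ΔH‡ holds by
construction in every `ActivationParameters` object (asserted at 1e-9).
The multi-temperature route fits ΔG‡/T on 1/T by ordinary least squares
(statsmodels OLS; slope = ΔH‡, intercept = −ΔS‡, asymptotic standard
errors from the regression covariance).  The fit is unweighted by default
— published computational Arrhenius fits are typically unweighted — with
a 1/sem² weighted variant behind a flag.  Local tangent lines with slope
equal to the per-temperature direct ΔH‡ (d(ΔG/T)/d(1/T) = ΔH) provide a
curvature diagnostic; finite-difference slopes between neighbors are
intentionally not the default, since the tangents are what a direct
calculation actually measures.  Bimolecular barriers can be shifted to a
reference concentration by ΔΔG = −RT·ln(c/1 M) (e.g. the 55 M aqueous
convention), reported together with the equivalent rate factor.

## Toy systems and what they do (not) show

The built-in model systems emulate the statistical structure the method
assumes: one solute coordinate r with two diabatic potentials (harmonic
½k(r−r0)² or Morse D(1−e^(−a(r−r0)))²), a bath of n harmonic oscillators
with optional nearest-neighbor chain coupling, state-specific *bilinear*
solute–bath coupling u_rs = g_s·r·Σqᵢ, and a large constant `uss_offset`
(default −4×10⁴ kcal/mol) reproducing the condensed-phase scale
separation and stress-testing the conditioning of the enthalpy averages.

The bilinear coupling is chosen for verifiability over realism: the bath
reduces exactly to its collective coordinate s = Σqᵢ (Gaussian with
variance RT·1ᵀK⁻¹1 under the bath Gibbs measure, with closed-form
conditional environment energies), so reference profiles are a 2-D
quadrature for *any* bath size.  The quadrature uses antialiased binning
— each grid cell's Boltzmann weight is spread over the X interval spanned
by the analytic gradient of X across the cell — giving second-order
convergence; with default grids the profiles are converged to ~3×10⁻⁴
kcal/mol, verified by an automatic ×1.5 refinement check that raises
above 5×10⁻³.

Sampling uses BAOAB Langevin dynamics on Umap(λ), which samples the
canonical ensemble in the long-time limit; a weak-coupling
(velocity-rescaling) thermostat was deliberately not used because it does
not generate a strict canonical ensemble and would contaminate the oracle
comparisons.  Gaussian noise is pregenerated from numpy Generators
(counter-based SeedSequence spawning per temperature/replicate/window),
so datasets are bit-reproducible.  Windows launch from λ ≈ 0.5 and chain
outward to both endpoints, mirroring the transition-state launch
protocol.  Default parameters (k = 100 kcal/mol/Å², minima 1 Å apart,
A = 8 kcal/mol, Δα = 3 kcal/mol, 2 bath oscillators at 60/80 kcal/mol/Å²
with κ = 5 and g = ±3, masses 12 amu, γ = 40 ps⁻¹, dt = 1 fs) give a
barrier of ≈ 7.2 kcal/mol (≈ 12 RT at 300 K) with X spanning ≈ 150
kcal/mol — comparable, relative to thermal noise, to the solution
reactions the method targets.

Trapped replicas are emulated physically: an optional deep Gaussian well
shared by both diabats sits off the reaction path; replicates launched
inside it cannot escape during sampling and never traverse the reaction
coordinate.  For the planted-trap tests the diabats are Morse (their
restoring force vanishes at large r, so a modest 30 kcal/mol well at
r = 3 Å is deeply metastable yet lies ~80 kcal/mol above the reactant
minimum and is never entered spontaneously).

What passing these tests does *not* show about real data: the toys are
low-dimensional, harmonic-dominated and free of slow orthogonal degrees
of freedom, so they probe estimator correctness — not the convergence
behavior of ⟨Eg⟩ in a fluctuating hydrogen-bond network, force-field
adequacy, or finite-simulation-time conformational sampling of proteins.
The replicate counts and window lengths used in the test suite (6–10
replicates, 2×10⁴–1.2×10⁵ steps/window) are desk-scale choices that keep
the whole suite within a few minutes while leaving the statistical
criteria well-powered; production numbers (50–60 replicates, 10⁵–10⁷
samples) scale the same estimators unchanged.

## Analysis pipeline and design choices

`run_single_temperature_analysis` chains the steps: per-replicate FEP and
umbrella binning; aggregation; stationary-point location on a
*majority-supported* copy of the aggregate (bins populated by at most
half the replicates are ignored when locating, so a minority
conformational cluster cannot masquerade as the product minimum);
coverage filtering (a replicate is kept iff its X samples populate ≥ 90%
of the bins between the reactant and product bins, inclusive);
re-aggregation over survivors; enthalpy profile, ΔH‡ and the optional
convergence-vs-data-fraction curve (prefix truncation of each window's
time series).  Replicates so confined that no profile can be built at all
are routed directly to the coverage filter and must be dropped by it.
The first 10% of each window's samples is discarded as analysis-side
equilibration (configurable), on top of the sampler's own equilibration
phase.  Default bins: (sampled X range)/50.

Further choices: Δα is applied inside the diagonal energies (state 2
only) so stored records stay raw force-field terms, re-analyzable under
any EVB parameter set; the ΔU inside a Gaussian H12 includes the Δα shift
by default, with `coupling_gap_includes_shift=False` exposing the raw
diabatic difference (the convention is not universal); FEP runs forward
only, exactly as the accumulation formula is written — a backward pass
would be a different estimator, not an error check to average in.

## Known limitations

- The ΔH‡ error bar ignores RS/TS bin correlation (usually conservative).
- The plain (non-reweighted) enthalpy profile has an O(bin width)
  within-bin bias away from stationary points; halve the bin width or use
  the reweight diagnostic when per-bin values matter.
- Coverage filtering keys on the energy-gap coordinate only; a replicate
  trapped in a conformation that still samples all X bins is invisible
  to it.
- The Arrhenius fit assumes T-independent ΔH‡ and ΔS‡ over the span;
  curvature shows up in the local-slope diagnostic but is not modeled.
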