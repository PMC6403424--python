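# Methods

## The model

The system is a dissipative supramolecular polymer built from toroidal
subunits.  Thermodynamically the toroids are stable closed rings of
eclipsed-stacked macrocycle dimers; a short heat treatment switches the
stacking to a slipped arrangement that is kinetically trapped at room
temperature.  Only this *active* state can open into a one-turn spiral
with two reactive ends, and only spirals polymerize.  The model keeps
four populations — inactive free toroids, active closed, active open, and
helical chains represented by their lengths in toroid units — and couples
three processes:

1. **Activation / relaxation.**  A heat pulse converts a fraction
   `activation_efficiency` of the inactive pool to active closed
   (instantaneous: the 20-minute treatment is far shorter than the
   day-scale dynamics).  Active *closed* free toroids relax back first
   order with `k_relax_free`; free open spirals must close first (the
   open form is a high-energy conformer whose independent relaxation
   would be unidentifiable from any of the observables).
2. **Nucleation – elongation – joining.**  Opening and closing is a fast
   two-state equilibrium whose constant K = k_open/k_close is pinned at
   5.5 × 10⁻³.  Two open spirals form a dimeric chain slowly (`k_nuc`),
   chains capture open toroids fast (`k_el`, one saturating reactive end
   pair per chain, no length dependence), and chains may merge end to end
   (`k_join`, constant-kernel aggregation, switchable off).  The rate
   separation `k_el ≫ k_nuc` is the cooperative signature and produces
   the lag phase.
3. **Scission-driven collapse.**  Each in-chain subunit relaxes first
   order with `k_relax_chain`.  A relaxed (equilibrium-packing) subunit
   cannot stay in a helix of slipped subunits: it leaves immediately as
   one inactive toroid and the chain breaks at that position.  The site is
   uniform over subunits, so a chain of length n dies at total rate
   `k_relax_chain·n` — long chains collapse fastest, and no latent-defect
   bookkeeping is needed: chains remain representable as bare lengths.
   Fragments of length ≥ 2 survive as chains; length-1 fragments re-enter
   the open pool; length-0 fragments are nothing.

Every channel conserves total toroid units exactly.  UV irradiation is a
timed window (default 5 minutes) multiplying both relaxation rates by
`uv_factor`; its physical action — planarizing the aromatics and lowering
the barrier between slipped and eclipsed packing — is a rate change, not a
new channel.  A racemic preparation cannot tilt in one direction and never
opens; the model's racemic control is `k_open = 0`, and the geometry
builder refuses to construct a helix of chirality 0.

## Engines

**Stochastic.**  Direct-method SSA (exponential waiting times,
propensity-proportional channel choice) over the seven channel classes;
per-chain events are aggregated per class with a secondary draw for which
chain and which site, so the channel count never grows with the chain
population.  Bimolecular propensities use count combinatorics with the
volume-scaled rate k/Ω, Ω = counts per μM.  Protocol events interrupt the
clock at their scheduled times, which is exact for a memoryless process.
The generator is NumPy PCG64 with explicit integer seeds; replicate seeds
derive from a `SeedSequence` spawn, and every output records its seed.

**Mean-field.**  The deterministic limit of the same channels as a
length-resolved ODE over (i, a, o, c₂…c_nmax): elongation is a ladder,
joining a Smoluchowski convolution (evaluated by FFT), scission the
uniform fragment kernel (2·k_rc·Σ_{n>m} c_n gains, suffix sums).  Mass
flowing past the truncation length goes into an explicit leak accumulator;
runs abort loudly when the leak exceeds a bound (default 10⁻³ of total
units) instead of silently losing mass.  `n_max` defaults to 4000, which
holds the leak near 10⁻⁷ under the shipped calibration over 16 days.
Integration uses explicit RK45 (the fastest rate, k_close ≈ 364/day,
limits the step; the dimension makes implicit solvers with dense algebra
slower), with LSODA as an option that wins for small `n_max` fitting
configurations.  Unit drift is ≲ 10⁻¹³ relative at default tolerances.

The two engines cross-validate: `crosscheck_with_ssa` reports per-time
z-scores of the ensemble mean against the ODE and passes when |z| ≤ 3 at
≥ 95% of time points (on the default configuration the observed |z| stays
below ~1.5).

## Parameters and their anchors

Units: days, nm, μM.  The desk-scale convention maps 30 μM to 10,000
toroid units (effective volume ≈ 5.5 × 10⁻¹⁹ L), large enough that the
stochastic mean tracks the mean field, small enough for exact simulation.

| parameter | default | anchor |
| --- | --- | --- |
| k_open | 2 /day | open/close equilibration ≪ 1 day but SSA-tractable |
| k_close | 363.6 /day | pins K = k_open/k_close = 5.5 × 10⁻³ |
| k_relax_free | ln 20/20 ≈ 0.150 /day | active fraction reaches 5% at exactly 20 days (the observed CD recovery period); first-order by construction |
| k_nuc | 3 /μM/day | calibrated (see below) |
| k_el | 2000 /μM/day | calibrated; k_el/k_nuc ≈ 667 keeps the cooperative lag |
| k_join | 180 /μM/day | calibrated; sets peak chain length via the join–scission balance |
| k_relax_chain | 0.065 /day | calibrated; sets collapse duration and sustained activity under 4-day refuelling |
| uv_factor | 2 × 10⁴ | makes the 5-minute UV window remove > 95% of chain mass (weeks → minutes) |
| activation_efficiency | 1.0 | heat treatment saturates the CD signal |
| toroid external diameter | 12 nm | measured toroid size; helix diameter is length-invariant |
| tube diameter = pitch | 3 nm | assumption (not printed anywhere); config-exposed |

The absolute polymerization rates are unpublished, so k_nuc, k_el, k_join
and k_relax_chain are calibration products, fitted (mean-field objective,
verified stochastically) to the anchor behaviour: ensemble-mean assembly
length peaking 4 days after a single pulse, depolymerization taking about
7 days from decline onset to completion, an intensity-weighted
hydrodynamic diameter near 250 nm at the peak, and CD staying above half
its post-pulse value under 4-day refuelling.  Two calibration choices
deserve a note.  First, the deterministic optimum pushes k_nuc very low
(strong cooperativity reproduces the late peak most easily), but at desk
scale that leaves O(1) nucleation events per trajectory and the
stochastic ensemble departs from the mean field; k_nuc = 3 /μM/day keeps
nucleation statistics dense while preserving the lag.  Second, mean
length in the headline trajectory averages over *all* assemblies
(monomers count as length 1), which is what counting objects in
micrographs measures and which lets the observable return below 1.5
units when collapse completes; the chains-only average is also computed
everywhere and is the right metric when only polymers are measured.

## Observables

* **CD proxy** — affine in the fraction of subunits in the slipped state
  (`baseline + amplitude·active_fraction`).  Intensive, hence
  concentration-independent at fixed composition; with polymerization
  disabled its decay is exactly exponential with rate `k_relax_free`.
* **Length mapping** — a single toroid measures its external diameter
  (12 nm); a chain of n toroids forms n close-packed turns and measures
  n × pitch.
* **DLS proxy** — sphere rule for single toroids; for chains the
  short-rigid-rod approximation D_h = L/(ln(L/d) + 0.32) with d the
  helix diameter, clamped to max(d, L) below the formula's turning point
  so the proxy is continuous and monotone in length.  Population value is
  the intensity-weighted mean with weights ∝ (units)², the simplest
  DLS-like weighting.  Both the rod formula and the weighting are
  documented approximations (hence the wide ±30% tolerance used when
  judging the ~250 nm value); they are swappable functions, not
  assumptions baked into the engines.
* **Cryo-TEM sampling** — n assemblies (default 100) drawn with
  probability proportional to count, monomers included by default,
  multiplicative log-normal measurement noise (default sd 0.1 on the log
  scale; lengths stay positive and relative error is scale-free).

## Geometry and vesicles

Helix centerlines are parametric helices at the toroid centerline radius
(external − tube diameter)/2, one turn per subunit, pitch = tube diameter
(close-packed), right-handed for the S enantiomer; handedness is read
back off the discrete torsion (triple products of consecutive chords) and
mirror images are exact reflections.  A rod of length T inside a vesicle
of rest diameter 2R₀ (default 500 nm, the extrusion pore size) forces a
spherocylinder of total length T.  The default constraint conserves
membrane area (bilayers are nearly inextensible; water permeates over
days, so volume is free): 2πrT = 4πR₀² gives r = 2R₀²/T in closed form.
A fixed-volume mode solves the cubic instead.  Tubes thinner than the
helix radius (6 nm) are refused with the maximum supportable length.
Recovery returns the area-equivalent sphere.  Membrane bending energy,
helix elasticity and excluded volume are out of scope.

## Synthetic data and identifiability

The generator runs one stochastic trajectory and measures it with the
three noise models above, storing the noise-free truth and full metadata
(rates, protocol, seed, noise); regeneration from metadata is
bit-identical, and on-disk datasets carry SHA-256 checksums and a schema
version.  It emulates the statistical structure of the laboratory
streams — micrograph counts of 100 objects, additive CD noise, relative
DLS noise — not images, spectra or correlograms; passing tests therefore
demonstrate correct analysis of data *with the assumed noise structure*,
not robustness to instrument systematics such as TEM selection bias for
long chains or DLS polydispersity artefacts.

Calibration fits log₁₀-scaled rates by bounded trust-region least squares
against the mean-field solver (the optimizer needs smoothness; the SSA
verifies the optimum afterwards).  The open/closed ratio stays pinned:
freeing `k_open` moves the pair jointly, and `k_close` is refused as a
free parameter.  A coarse finite-difference step (10⁻³ on log₁₀ rates)
makes the Jacobian robust to solver noise.  Identifiability is checked by
simulate–refit round trips: with chains-only mean-length data plus a CD
trace, (k_nuc, k_el, k_relax_chain) come back with median estimates
within a factor of 2 of truth at 5% measurement noise (the recovery
benchmark uses a joining-free, shorter-chain configuration so the
length-resolved system stays small).  With all-assembly mean lengths
alone, k_nuc and k_el are nearly ridge-correlated (the growth flux
constrains their product); the chains-only average breaks the ridge
because the per-chain growth rate pins k_el directly.

## Degenerate inputs and edge rules

Heat-pulse rounding is `floor(n_inactive × efficiency)` (deterministic
for testability).  `mean_chain_length` of a chain-free state is 1.
Scission of a dimer yields one inactive plus one open toroid.  A record
time coinciding with a protocol event reports the post-event state, so
the pulse at t = 0 is visible in the first record.  Fits with all loss
weights zero return immediately, flagged degenerate.  All-zero rate sets
are valid (frozen system), used widely in tests.

## Known limitations

Temperature enters only as instantaneous pulses (no ramps or hysteresis
curves); there is no spatial resolution, no tau-leaping acceleration, no
Bayesian posterior beyond asymptotic/bootstrap intervals; the DLS and
intensity-weighting conversions are stated approximations; and in-chain
relaxation is memoryless, which makes the late collapse tail exponential —
residual chains persist longer than a sharper (age-dependent) relaxation
law would predict.
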