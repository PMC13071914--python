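# Methods

## The model

`phlinkage` analyses binary protonation records of titratable sites in a
protein that exists as a monomer (M) and a homodimer (D).  The synthetic data
generator is an Ising-like model of `n` interacting sites.  A microstate
`s ∈ {0,1}^n` (1 = proton bound) at pH has semi-grand-canonical energy

    E(s; pH) = Σ_i ln(10)·kT·(pH − pKa_int,i)·s_i + Σ_{i<j} W_ij s_i s_j

in kcal/mol, where `pKa_int,i` is the intrinsic (interaction-free) pKa of
site i and `W` is a symmetric, zero-diagonal matrix of pairwise energies
between *protonated* states.  A single isolated site reproduces the
Henderson–Hasselbalch sigmoid `⟨x⟩ = 1/(1+10^(pH−pKa))` exactly; positive
`W_ij` penalizes simultaneous protonation (anticooperative binding, Hill
h < 1, negative protonation correlation), negative `W_ij` favors it
(cooperative, h > 1, positive correlation).  Pairwise couplings only — no
three-body terms — because they are the simplest mechanism that produces the
cooperativity and correlation-network phenomenology the analyses target.

A dimer model is built from a monomer by duplicating sites into chains A and
B, adding per-site interface pKa shifts (negative shifts emulate interface
interactions stabilizing the deprotonated acid), copying intra-chain
couplings into both chains, and adding explicit inter-chain couplings.

Temperature defaults to 298.15 K and is configurable; `kT` (kcal/mol) and
the pH-coupling constant `ln(10)·kT` are always computed from the
temperature at run time.

## Exact statistics (the oracle)

The semi-grand partition function `Z(pH) = Σ_s exp(−E/kT)` and free energy
`G(pH) = −kT ln Z` are computed by explicit enumeration.  Enumeration
factorizes over connected components of the coupling graph (independent
subsystems): `G` sums over components, means concatenate, covariance is
block-diagonal.  Components are capped at 20 sites (2^20 microstates,
evaluated with log-sum-exp); larger components are refused with an explicit
error.  Sparsely coupled systems of many more than 20 sites — e.g. the
32-site toy dimer, whose largest component has 2 sites — are therefore still
solved exactly.  The identity `dG/dpH = ln(10)·kT·⟨n_protons⟩` (verified to
1e−6 relative on a 1e−4 finite-difference stencil) makes this module the
ground truth for every downstream estimator.

## Sampling

Protonation ensembles are generated by single-site Metropolis Monte Carlo:
one frame = one full sweep over the sites in fixed order; each visit
attempts a flip with per-site probability `flip_attempt_prob[i]` and accepts
with `min(1, exp(−ΔE/kT))`.  Small attempt probabilities emulate kinetically
slow proton exchangers and lengthen the protonation correlation time without
biasing the stationary distribution (verified against enumeration).  Chains
are initialized from the intrinsic Henderson–Hasselbalch occupancies, and a
default burn-in of 500 sweeps is discarded — ample for the weak-to-moderate
couplings used here, since the initialization is already exact for uncoupled
sites.  All randomness derives from one integer seed via
`numpy.random.SeedSequence`; identical settings reproduce trajectories
bit for bit.  A detail worth knowing: at a site's exact midpoint ΔE = 0, so
Metropolis accepts every attempt and a free site alternates
deterministically; time averages remain exact, but sequential samples are
strongly anti-correlated there.

## Titration analysis

Curve points are pooled time-and-replicate averages (pooling frames or
averaging replicate means are both supported and identical for equal-length
replicates).  Confidence bands are 68% percentile intervals (16th–84th) from
a bootstrap that resamples **whole replicates**, never frames: frames are
autocorrelated — correlation times of slow sites reach a substantial
fraction of a trajectory — so replicates are the only plausibly independent
unit.  Bands are widened, if necessary, to contain the point estimate; a
single replicate yields a zero-width band plus a degeneracy flag.

Hill fits minimize weighted least squares of
`⟨x⟩(pH) = 1/(1+10^(h·(pH−pKa)))` with weights 1/halfwidth² (uniform
fallback when any band is degenerate), initialized at `h = 1` and the grid
pH closest to half-protonation.  Fits are flagged `low_confidence` when the
curve never crosses 0.5 inside the grid or the fitted pKa falls outside it —
such midpoints are extrapolations and at best indicative.  Curves are never
extrapolated beyond the measured grid.

## Correlations and correlation times

Pairwise correlation of the binary state series is Pearson's r, which for
binary variables equals the phi coefficient (rank correlations are
equivalent there).  Pairs where either site has variance below 1e−6 are
masked *undefined*, never zeroed, and never contribute network edges.
Pooled-across-replicates correlation is the default; a per-replicate-mean
variant is provided because single kinetically trapped replicates can
inflate pooled correlations.  Networks threshold |phi| at 0.3 by default (a
configurable choice — "substantial correlation" has no canonical value) and
flag edges whose endpoints lie in different membrane compartments
(lumenal/stromal).

The protonation correlation time is the integrated autocorrelation time
`tau = 1/2 + Σ_{t≥1} C(t)` in frame units, with `C(t)` the normalized
fluctuation autocorrelation (FFT-based, biased normalization) averaged over
replicates and the sum truncated at the first nonpositive lag — the standard
bias/variance compromise for short noisy binary series.  White noise gives
tau = 1/2 (the estimator's lower bound); a symmetric two-state chain with
flip probability p gives `1/2 + λ/(1−λ)`, λ = 1−2p, which the estimator
reproduces within a few percent at 1e6 frames.

## Linkage energetics

The pH derivative of the dimerization free energy equals the proton-binding
difference between product and reactants, so

    ΔΔG(pH) = ln(10)·kT · ∫_ref^pH [Q_D(u) − 2 Q_M(u)] du

anchored at a reference pH (default 3 for free-energy profiles, 7.5 for
monomer-fraction work).  Only *relative* free energies are obtainable;
pH-independent offsets cancel.  Dimer chains enter as the **sum** of both
chain curves (not the average), so the stoichiometry `Q_D − 2Q_M` is exact.
Integration is trapezoidal on the measured grid with no interpolation — the
grid is the resolution; against the exact partition-function profile the
quadrature error shrinks quadratically with step (≈0.03 kcal/mol at step
0.5, ≈0.008 at step 0.25 for the systems here).  Because Q is a sum of
per-site curves, ΔΔG decomposes exactly into additive per-residue
contributions; subset restriction (e.g. lumenal-only) is a partial sum of
the same decomposition, and lumenal + stromal = total identically.  A flat
per-residue ΔΔG curve means no contribution to the *pH sensitivity* of
ΔG, not a negligible contribution to ΔG itself.

Error bands come from a replicate-level bootstrap that resamples monomer and
dimer replicates independently and recomputes the whole chain (site means →
ΔQ → integration) per resample.  `screen_key_residues` ranks residues by the
maximum |per-residue ΔΔG| over the grid, thresholded at 1 kcal/mol by
default.

## Monomer fraction

Under 2M ⇌ D mass action at fixed total chain concentration, both unknowns
(absolute dimerization constant and concentration) collapse into the
dimensionless `kappa = K_dim·C_total`, and outputs are parameterized by the
monomer fraction `f_ref` at the reference pH instead of absolute
concentrations.  Mass balance `f + 2·kappa·f² = 1` is solved in the
numerically stable closed form `f = 2/(1+√(1+8·kappa))`, exact in the
kappa → 0 limit and satisfying the residual to 1e−12.  A profile moves
kappa multiplicatively, `kappa(pH) = kappa_ref·exp(−ΔΔG(pH)/kT)`; since f is
monotone in ΔΔG, confidence bands map through the endpoints exactly.
Fractions count **chains**: f = 0.5 means half of all chains are monomeric.

## The toy fixture and what it does (not) show

The bundled fixture is a 16-site monomer (10 lumenal, 6 stromal acids;
lumenal Glu intrinsic pKa's 4.6–6.5, above the aqueous 4.25) dimerized into
32 sites with planted ground truth: interface pKa shifts of −1.3/−1.1/−1.5
on Glu55/Glu69/Glu173, inter-chain couplings Glu141:A–Glu141:B
(+2.5 kcal/mol) and Glu37:A–Glu105:B (−2.5), one intra-chain lumen–stroma
coupling Glu159–Glu20 (−3.0), and slow exchangers (attempt probabilities
0.02–0.1 on Glu55, Glu141, Glu78).  Coupling magnitudes were fixed at design
time from the enumeration oracle so planted pairs correlate strongly
(|phi| ≈ 0.8 at their most sensitive pH) and shift residues clear the
1 kcal/mol screen; the standard study conditions are 21 pH values (3–8,
step 0.25), 5 replicates × 1e5 sweeps, seed 42.

The generator emulates shifted pKa's, cooperativity, dimer-specific
interface electrostatics, replicate structure, cross-compartment coupling
and slow exchange.  It does **not** emulate conformational dynamics coupled
to protonation, explicit electrostatics or solvent, frame-level kinetics of
a real MD protocol, or force-field error — so passing tests demonstrate
the correctness and calibration of the *estimators*, not the accuracy of
any particular simulation data.

## Validation studies and their conditions

`phlinkage.workflows` fixes the study conditions in one place:

* Hill recovery on the exact aqueous-Glu curve (grid 3–8, step 0.25):
  recovers pKa and h to < 1e−6.
* Zero-linkage identity (dimer = two free monomer copies): ΔΔG and the
  monomer-fraction shift vanish to 1e−10 from exact curves; sampled ΔΔG
  stays within max(3×bootstrap SE, 0.02 kcal/mol) of zero.
* Oracle equivalence on the toy fixture at full size: sampled
  linkage-integrated ΔΔG within max(0.1 kcal/mol, 3×bootstrap SE) of the
  exact partition-function profile at every grid pH (measured max error
  ≈ 0.04 kcal/mol), and the lumenal 1 kcal/mol screen returns exactly the
  three planted residues.
* Edge recovery: 20 regenerations (3 replicates × 2e4 sweeps) of the dimer
  at the oracle-selected most-sensitive pH per planted pair; all planted
  pairs recovered in 100% of regenerations, uncoupled pairs cross the 0.3
  threshold in < 0.1%, lumen–stroma edges always flagged.
* Coverage calibration: 200 regenerations of a 4-site monomer / 8-site
  dimer (6 replicates × 1500 sweeps, n_boot 200).  Truth for the ΔΔG CIs is
  the noise-free value of the estimator (enumerated curves through the same
  trapezoid grid): the bootstrap quantifies sampling noise, and comparing
  against the exact partition-function profile instead would conflate the
  deterministic quadrature offset (≈0.03 kcal/mol at step 0.5, similar in
  size to the sampling SE at these frame counts) with miscalibration.
  Titration coverage is scored at transition-region pH points (enumerated
  mean within [0.05, 0.95]) because saturated binary data give zero-width
  intervals for which coverage is undefined; the ΔΔG anchor pH is likewise
  excluded (interval and truth are both exactly zero).  Measured coverage is
  ≈62% for both statistics — the expected mild undercoverage of percentile
  bootstrap at 6 replicates — within the 58–78% acceptance band.

## Known limitations

* Percentile bootstrap over few replicates (≤ 5) undercovers moderately and
  its SE estimate is itself noisy; bands from single-replicate data are
  zero-width and flagged, not fatal.
* The correlation-time estimator needs trajectories long relative to tau;
  for tau approaching the trajectory length the truncated sum is biased low.
* Exact enumeration requires every coupling component ≤ 20 sites; densely
  coupled systems have no oracle here (the sampler still runs).
* The mass-action stage models 2M ⇌ D only — no higher oligomers, no
  kinetics.
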