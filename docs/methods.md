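# Methods

## Model

Linear tangent hard-sphere chains in a cubic periodic box at constant
volume and temperature (athermal: k_BT = 1, all energies in k_BT, all
lengths in units of the collision diameter σ = 1).

* **Non-bonded interactions.** Hard-sphere: zero energy at
  center-to-center distance r ≥ σ, infeasible below.  Overlap is a
  constraint, never a finite energy.  1–3 and farther intra-chain pairs
  are ordinary hard-sphere pairs; at a bending angle of exactly 120° the
  1–3 pair is exactly tangent, which the ≥ comparison allows.  This
  truncates the accessible bending range at 120°, and every analytic
  density used as a sampling oracle carries that truncation.
* **Bonds.** Hard window: bond length uniform in [σ, σ + dl], default
  dl = 6.5·10⁻⁴ σ, practically enforcing tangency.  Bonded geometry is
  always computed on unwrapped coordinates; non-bonded distances use the
  minimum-image convention.
* **Bending.** U(θ) = k_θ(θ − θ₀)², with θ the angle between successive
  bond vectors (0 = collinear; the convention is fixed by the compact
  trimer being θ = 120°).  Defaults k_θ = 9 rad⁻², θ₀ ∈ {0°, 60°, 90°,
  108°, 120°}.  k_θ = 9 limits deviations to roughly ±20°; k_θ = 0 is
  the freely-jointed limit.  Torsions are unconstrained.
* **System.** Default 100 chains of mean length 12 (1200 monomers) with
  uniform length dispersity on [6, 18], maintained dynamically by the
  connectivity-altering moves.

## Monte Carlo

One MC step is one attempted move.  The default attempt mix is
reptation 10%, end rotation 10%, flip 34.8%, intermolecular reptation
25%, end-segment regrowth 20%, simplified end-bridging (sEB) 0.1%,
simplified intramolecular end-bridging (sIEB) 0.1%.

All local moves follow a configurational-bias pattern: `n_trials`
candidate positions are drawn (trial bond vectors uniform in direction
and uniform in length over the hard window), weighted by the Boltzmann
factor of every bending angle the move alters and zeroed when the
hard-sphere constraint fails; acceptance is min(1, W_new/W_old) with
the retrace weight built around the current position.  The trial count
grows with density (10 below φ = 0.45, 20 to 0.55, 40 above); it
affects efficiency only, since the weights enter the acceptance
exactly.

Move definitions (the literature leaves the exact variants to the
implementation; these are the ones used here):

* **reptation** — delete one end monomer, regrow at the opposite end;
* **end rotation** — resample a terminal monomer around its bonded
  neighbor (bond vector redrawn over the full sphere and window, CB
  weighted by the angle at the neighbor);
* **flip** — rotate an interior monomer about the axis through its two
  bonded neighbors; both adjacent bond lengths and the angle at the
  monomer itself are conserved, only the flanking angles enter the
  weights;
* **intermolecular reptation** — delete an end monomer of a donor chain
  and regrow it bonded to an end of an acceptor chain; proposed only
  when both resulting lengths stay inside the dispersity bounds (donor
  and acceptor ends chosen uniformly, so the proposal probability is
  configuration-independent and needs no correction);
* **end-segment regrowth** — delete 1–3 end monomers and regrow them
  trial-by-trial (sequential Rosenbluth weights);
* **sEB** — a chain end bonds to an interior monomer of another chain
  whose minimum-image distance lies inside the bond window; the target
  chain is severed on one side of the bridged monomer.  Both resulting
  lengths must stay in bounds.  Positions never change, so acceptance
  is min(1, (n_fwd/n_rev)·exp(−ΔU_bend)), with n_fwd/n_rev the
  eligible-target counts of the forward and reverse attacks (the
  reverse attack is always eligible, its distance being a former bond);
* **sIEB** — the same within one chain: the end re-bridges to an
  interior monomer (never its own bonded neighbor) and the intervening
  segment is reversed; chain count and length are unchanged.

The tiny bond window makes bridging targets geometrically rare at any
density; sEB/sIEB therefore contribute little at desk scale and are
exercised by construction in the unit tests.  Chain-length dispersity
is driven to its uniform stationary distribution chiefly by
intermolecular reptation.

Correctness evidence (all in the test suite): isolated-trimer bending
angles match the sinθ-weighted Boltzmann density truncated at 120°
(χ² at the 1% level over k_θ ∈ {9, 50} × θ₀ ∈ {0°, 90°, 120°}); a free
dimer's positions are uniform over the box; attempt frequencies match
the schedule; identical seeds give bit-identical trajectories.

## Generation and compression protocol

Initial states are built at φ = 0.001 as fully flexible non-overlapping
random walks, lengths drawn uniformly from [6, 18].  Compression
rescales the box isotropically; chain centers of mass transform
affinely while internal chain geometry stays rigid, so bond lengths are
untouched and only intermolecular overlaps can arise — an attempt that
creates one is rejected and the box restored.  After every attempt
(accepted or not) a fixed number of relaxation moves runs at the
current volume.  On rejection the shrink decrement is halved (factor →
√factor), and restored to its base value after the next success; the
φ sequence is therefore monotone non-decreasing and terminates within
10⁻⁶ of the target.  Near jamming the decrement collapses toward zero
and a stall raises an error carrying the last valid φ.  The relaxation
interval doubles as an annealing knob: slow compression with generous
relaxation lets rod-like systems develop nematic order progressively as
the density crosses the transition region, which is far cheaper than
equilibrating a disordered dense state after a fast quench.

## Global order

Chain long axes are the smallest-eigenvalue eigenvectors of per-chain
inertia tensors computed with unit masses and center-of-mass-relative
coordinates in both the scalar and dyadic terms — the only
translation-invariant form, and the one whose principal axes are the
chain's own.  The orientational tensor Q = ⟨u uᵀ⟩ − δ/3 over chains is
symmetric and traceless; eigenvalues are ordered by decreasing
magnitude (ties broken by signed value, eigenvector signs fixed by the
largest-magnitude component) and q = (3/2)λ₁, with the director the
corresponding eigenvector.  Mesophase labels use q ≥ 0.4 → PRO,
q ≤ −0.25 → OBL, otherwise ISO: these cutoffs leave the weak
alignment peak (q ≈ 0.15) of acute-angle systems isotropic while
cleanly capturing states approaching the ideal values 1 and −1/2.
Biaxiality |λ₂ − λ₃| is reported as a diagnostic but not classified.

## Local order

Each site's coordination shell is its 12 nearest minimum-image
neighbors (all enabled references are 12-coordinated, which removes the
need for a radial-distribution cutoff); sites with fewer than 12
neighbors within 2σ are amorphous by decision.  The per-site,
per-reference norm is

    ε_i^X = C · min_R sqrt( (1/12) Σ_j min_k | r_j/⟨r⟩ − R d_k |² )

over proper rotations R, with r_j the observed neighbor vectors, ⟨r⟩
their mean length, d_k the ideal unit directions of reference X, and
C = 1.2 a fixed scale calibration.  The rotation search seeds candidate
alignments from an observed anchor pair mapped onto every
angle-compatible ideal pair, then refines the best seeds by iterated
nearest-direction assignment and orthogonal Procrustes; the result is
invariant under rotation, translation and uniform scaling to numerical
precision.  The calibration constant exists because the labelling
threshold 0.245 presumes a norm scale on which no two ideal references
score close: the raw RMS distance between the two closest ideal shells
(FCC vs icosahedral) is ≈ 0.231, and C = 1.2 lifts the smallest
cross-norm to ≈ 0.278 while leaving ideal self-norms exactly zero.
The discrimination property is asserted by tests, not assumed.

A site is labelled argmin_X ε_i^X among references passing the
threshold, else AMO; S^X is the fraction of sites labelled X, and the
degree of crystallinity τ_c sums S^X over crystal references only
(HCP + FCC by default; BCC/HEX reference shells exist as stubs but are
disabled — dense sphere-chain packings carry no such population).
Fivefold (icosahedral) is a competing local symmetry, not a crystal,
and is reported separately.

## Phase pipeline

A state point (φ, θ₀) is simulated as dilute generation → compression →
constant-volume equilibration, recording (q, S^HCP, S^FCC, S^FIV, τ_c)
at a fixed cadence.  Steady-state averages use the trailing half of
each series; the equilibration flag requires the least-squares drift
over the window to be consistent with zero against either the
block-averaging error of the mean (4 blocks) or twice the regression
slope's own standard error — the second branch keeps white-noise
plateaus from being flagged as drifting.  Unequilibrated points are
flagged, never dropped.  The joint label is AMO/CRY × ISO/PRO/OBL with
CRY at τ̄_c ≥ 0.3: amorphous packings sit near zero (initial
close-packed fractions below ~5%) and crystals at 0.65–0.85, so the
cutoff has a wide margin on both sides.

## Synthetic reference structures

The generators produce every idealized configuration the descriptors
must recognize: single/mixed-stacking close-packed slabs (triangular
layers, letters A/B/C selecting thirds of a₁+a₂, interlayer spacing
√(2/3)·s), a periodic bulk FCC crystal (cubic cell, so all shells are
complete under the minimum image), 13-sphere icosahedra, rod bundles
with a tunable axis-jitter cap angle, planar staircase chains realizing
the ideal oblate mesogen with equally spaced in-plane directions, and
dilute random gases.  Close-packed and gas fixtures use single-monomer
dummy chains: the local descriptor ignores connectivity, which
decouples crystallinity tests from chain-geometry feasibility.  What
these fixtures do **not** emulate is thermal disorder and defect
structure of equilibrated dense melts (grain boundaries, stacking-fault
interfaces, vacancy-like free volume); descriptor robustness to
realistic displacements is probed separately by Gaussian-jitter ramps
under hard-constraint rejection.

## Desk-scale problem sizes

The reference study equilibrates 100-chain systems for 5·10¹¹–8·10¹¹
attempted moves per state point.  The package's tests and examples use
reduced systems chosen to keep each check in minutes on one core while
preserving the physics being asserted:

* descriptor checks run on a few hundred sites;
* sampling-correctness checks use single chains (bending statistics) or
  a dozen dilute chains (move mix, dispersity);
* the isotropic-nematic transition check uses 83 rod-like chains and
  measures the **ordered branch**: runs start from a perfectly aligned
  state (an in-box bundle at φ = 0.10; periodic spanning columns at
  φ = 0.30, where a straight 12-mer exceeds the box edge of ≈ 12σ) and
  relax for 1.2·10⁶ / 5·10⁵ attempted moves.  Below the transition the
  aligned start melts to the isotropic steady state (the suite asserts
  q̄ < 0.2 at φ = 0.10); above it the nematic persists (q̄ > 0.5 at
  φ = 0.30) while the connectivity-altering moves regenerate the full
  [6, 18] length dispersity.  The disordered branch is deliberately not used to
  locate the transition at this scale: from-disorder runs at φ = 0.30
  drift slowly upward in q but get trapped for over 10⁶ moves in
  interlocked multi-director states permitted by chains wrapping a
  small periodic box, and matching the study's from-disorder protocol
  would need orders of magnitude more moves.

Crystallization at φ ≈ 0.58–0.60 (final τ_c ≈ 0.65–0.85, near-perfect
FCC or HCP end states for rods) needs 10¹⁰⁺ attempts and is outside
desk scale; the descriptor stack that measures it is instead validated
on exact synthetic crystals, and the fivefold-competition property is
asserted conditionally on whatever desk-scale runs the suite produces.

## Known limitations

* The crystal-environment norm is a surrogate sharing the published
  descriptor's contracts (zero on ideal environments, joint
  orientational/radial sensitivity, discrimination at 0.245) but not
  necessarily its numeric values on intermediate environments; the
  exact reference formula can replace it behind the same interface.
* sEB/sIEB acceptance uses eligible-count symmetrization; with the
  default dl the moves are nearly silent, and their equilibration value
  at dense packings is not reproduced here.
* The stationarity rule is a pragmatic drift test, not a rigorous
  change-point analysis; short series with slow transients can pass.
* No pressure/virial computation, NPT ensemble, torsional potentials,
  non-cubic boxes, or confinement.
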