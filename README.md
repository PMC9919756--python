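# hspoly

Monte Carlo simulation and order analysis of dense packings of
semi-flexible polymers of tangent hard spheres.

## The scientific problem

Linear chains of hard spherical monomers (collision diameter σ, bond
lengths confined to the near-tangent window [σ, σ+dl]) are the minimal
athermal model of colloidal and granular polymers.  Chain stiffness is
imposed by a harmonic bending potential

    U_bend(θ) = k_θ (θ − θ₀)²       (energies in k_BT, k_BT = 1)

on the angle θ between successive bond vectors (θ = 0 is a straight
continuation, θ = 120° a compact touching trimer).  As the packing
density φ = (π/6) N_at σ³ / V grows, these systems self-organize at two
distinct levels:

* **globally**, at the level of chains, into nematic mesophases —
  prolate (all chain axes parallel) or oblate (axes spread in a plane) —
  quantified by the scalar order parameter q ∈ [−1/2, 1] obtained from
  the Q tensor over chain long axes: q = (3/2)λ₁ with λ₁ the
  largest-magnitude eigenvalue; q→1 prolate, q→−1/2 oblate, q→0
  isotropic;
* **locally**, at the level of monomers, into close-packed crystals —
  FCC, HCP and their randomly stacked mixtures (RHCP) — quantified by a
  per-site crystal-environment norm ε_i^X against ideal FCC / HCP /
  icosahedral (fivefold) coordination shells.  A site is an X-type
  crystal site when ε_i^X ≤ 0.245; the fractions S^X of crystal-labelled
  sites sum to the degree of crystallinity τ_c.

The package provides, as a reusable library with a CLI:

* `chain_model` — model types, geometry, energetics, hard-constraint
  validation;
* `mc_engine` — Metropolis / configurational-bias MC with the standard
  dense-packing move mix (reptation, end rotation, flip, intermolecular
  reptation, end-segment regrowth, simplified end-bridging moves), plus
  the dilute-generation / isotropic-compression protocol;
* `nematic` — inertia tensors, chain axes, Q tensor, q, director,
  ISO/PRO/OBL classification;
* `cce` — crystal-environment norms, site labelling, S^X and τ_c;
* `synthetic` — ideal reference structures (FCC/HCP/RHCP stacks,
  icosahedra, rod bundles, planar layered chains, random gases) used as
  descriptor fixtures;
* `pipeline` — state-point orchestration, steady-state averaging,
  AMO/CRY × ISO/PRO/OBL phase classification, phase-diagram assembly;
* `io` — plain-text extended-XYZ trajectories and YAML run configs.

## Worked example

Quantify global and local order of two synthetic systems:

```python
>>> from hspoly import nematic_order, label_sites
>>> from hspoly.synthetic import make_aligned_rods, make_close_packed

>>> rods = make_aligned_rods(n_chains=16, n_av=12, phi=0.03, jitter_angle=0.0, seed=0)
>>> res = nematic_order(rods)
>>> round(res.q, 6), res.label
(1.0, 'PRO')

>>> rhcp = make_close_packed("ABCBAB", layer_dims=(6, 6))
>>> loc = label_sites(rhcp)
>>> {k: round(v, 3) for k, v in loc.S.items()}, round(loc.tau_c, 3)
({'HCP': 0.148, 'FCC': 0.148, 'FIV': 0.0}, 0.296)
```

The rod bundle is a perfect prolate mesogen (q = 1).  In the six-layer
close-packed stack `ABCBAB`, the four interior layers split evenly
between FCC-type environments (flanking layers differ, `A_C` / `C_A`)
and HCP-type (flanking layers match, `B_B`); boundary layers and slab
edges have incomplete shells and stay amorphous, giving S^HCP = S^FCC ≈
0.148 and τ_c ≈ 0.296 of all 216 sites (the 64 interior sites split
32 / 32).

Run a small state point from the shell (dilute generation → isotropic
compression → equilibration → trajectory):

```sh
hspoly simulate --config run.yaml --out traj.xyz --seed 1
hspoly nematic --traj traj.xyz
hspoly cce --traj traj.xyz
```

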