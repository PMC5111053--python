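# Methods

## Model

A linear polymer of `N` identical monomers lives on the simple cubic
lattice. Each monomer occupies one site; no two monomers may share a site.
Consecutive monomers are joined by bonds whose squared length fluctuates
among {1, 2, 3} (lengths 1, √2, √3) — a single-site fluctuating-bond chain.
Bonds are forbidden to intersect geometrically, so the chain cannot pass
through itself during local moves. Non-adjacent bond pairs are tested with
an exact integer segment–segment intersection predicate (coplanarity plus
rational intersection parameters in [0, 1], or 1-D overlap for collinear
pairs); bonds sharing a monomer are exempt, since they always touch at the
shared site. Unit-length bonds between lattice sites can in fact never be
crossed by another valid bond, but the predicate is applied uniformly.

Energy, with the temperature convention k_B·T = 1:

    E = − n_PP · E_PP − n_PS · E_PS

where `n_PP` counts unordered non-bonded monomer pairs at unit lattice
distance (bonded neighbours and pairs at √2 or √3 do not contribute) and
`n_PS` counts monomers in the lattice layer adjacent to the wall (z = 1;
the impenetrable wall itself occupies z = 0). `E_PP ≥ 0` is the
intra-polymer attraction driving the coil–globule collapse; `E_PS ≥ 0` is
the surface attraction driving adsorption.

Three boundary modes:

* `bulk3d` — periodic in x, y, z: a desorbed chain in dilute solution;
* `slab_adsorbing` — periodic in x, y; walls at z = 0 and z = L_z;
  adsorbing layer at z = 1: a partially adsorbed chain;
* `plane2d` — chain confined to one z-plane with in-plane bond set
  {1, √2}: the fully adsorbed (2D) limit. The surface term would be the
  constant N and is ignored; it cancels from all Metropolis ratios.

## Dynamics

Single-monomer Metropolis moves: a monomer chosen uniformly at random is
displaced one lattice spacing along one of the 6 axis directions (4
in-plane directions in `plane2d`). The move is admissible if the target
site is empty, both affected bonds stay in the allowed length set, no bond
crossing is created, and z-walls are respected; it is then accepted with
probability min[1, exp(−ΔE)]. ΔE is computed from the local neighbourhood
only and is tested (exhaustively, in the suite) against full-energy
recounts. One Monte Carlo step (MCS) = N attempted moves; rejected attempts
consume time. This local, unbiased kinetics is the standard dynamic-MC
realization of Rouse-like dynamics without hydrodynamics.

The production path runs in a numba-compiled kernel over flat arrays
(unwrapped positions, wrapped positions, an occupancy grid indexed by
wrapped coordinates). A deliberately transparent pure-Python implementation
of the same move rules coexists and the two are cross-checked in the test
suite. When `E_PP = 0` the kernel skips incremental `n_PP` bookkeeping
(it cannot affect acceptance) and the engine recounts `n_PP` from the
occupancy grid at every kernel-call boundary, so Python-visible state is
always exact.

Bond geometry (lengths, crossings) is evaluated in unwrapped coordinates,
which is exact while the chain extent stays below half the box edge;
contact counting goes through the wrapped occupancy grid and is therefore
minimum-image by construction. Default boxes (below) and the compact
initial configuration keep the extent far from that bound.

## Adsorption protocol (slab)

1. The chain is equilibrated for `equilibration_mcs` between a repulsive
   virtual wall at z = L_z/4 (implemented as a hard constraint: moves below
   ceil(L_z/4) are rejected) and the box top, so its internal structure
   relaxes before it feels the surface.
2. The virtual wall is removed and the chain diffuses freely until its
   first surface contact (n_PS > 0), with a configurable MCS cap
   (an `AdsorptionError` is raised on expiry).
3. `settle_mcs` further steps let it settle into the adsorbed equilibrium
   state before production sampling starts. A first touch is sometimes
   followed by immediate detachment and a long excursion, so steps 2-3
   repeat until the settled state is actually adsorbed (n_PS > 0);
   production therefore never starts desorbed.

If the chain later desorbs during production (n_PS = 0), frames are kept
and a run-level desorbed-fraction diagnostic is reported; at E_PS ≥ 1 and
N ≥ 16 this fraction is small, but short chains (N = 8) make transient
desorbed excursions — the diagnostic makes that visible rather than
silently biasing averages.

## Observables

* **Diffusion.** Centre-of-mass MSD with multiple time origins at
  log-spaced lags, in-plane (x, y) components. Lags are capped at 1/8 of
  the trajectory: beyond that too few origins remain and the estimator
  variance explodes (fits using the last decade up to T/2 scattered by
  40–60 % in calibration). `D_xy` = (slope of the last decade of retained
  lags)/4, with an R² linearity gate.
* **Rotation.** End-to-end vector autocorrelation ρ(t) via FFT over all
  origins, normalized by the time-averaged ⟨R·R⟩ (equals the ensemble
  definition in expectation, with lower variance). τ_R is −1/slope of an
  unweighted least-squares fit of ln ρ(t) restricted to 0.06 < ρ < 0.30,
  truncated at the first lag where ρ falls to the lower edge so late noisy
  re-entries into the band are ignored. An amplitude prefactor ≠ 1 does
  not bias the estimate.
* **Size.** R_G² and R² as per-replica time averages, then replica means
  with standard errors.
* **Scaling exponents.** Ordinary least squares on (log N, log y);
  α reported positive for decreasing D_xy(N), β positive for increasing
  τ_R(N).
* **Coil–globule locator.** Central finite differences of ⟨R_G²⟩ on the
  E_PP grid; the interior grid point of steepest descent is reported with
  the grid spacing as resolution. A near-linear curve (no interior slope
  extremum) is rejected.

Replica aggregation pools per-replica MSD/ACF curves into one ensemble
curve (origin-count-weighted average of unnormalized covariances, pooled
normalization) and fits once; uncertainties come from a bootstrap over
replicas. Per-replica window fits at desk-scale statistics are unstable,
and the pooled curve is the ensemble average the estimators are defined on.

## Parameters and defaults

| parameter | default | rationale |
| --- | --- | --- |
| box L_x = L_y | max(64, ⌈4 N^0.75⌉) | several chain sizes; no periodic self-interaction |
| box L_z (slab) | max(24, ⌈3 N^0.6⌉) | a few R_G above the wall; keeps the free-diffusion adsorption phase short without touching the adsorbed state |
| equilibration | max(⌈N^2.2⌉, production/6) | ⌈N^2.2⌉ is the nominal Rouse-like scale; calibration shows actual relaxation times need the larger value |
| settle (slab) | same as equilibration | reuse of the relaxation timescale after first contact |
| production | ≈ 40 τ̂_R | τ̂_R = c·N^x measured once per mode at E_PP = 0: (c, x) = (0.75, 2.31) bulk, (1.0, 2.7) slab, (1.4, 2.82) 2D; spans ≲ 20 τ_R visibly bias the window fit upward |
| sample interval | production/4096 | ≈ 4k frames/replica; resolves the fit band at every N |
| replicas | 100 default, tens in practice | desk scale; the reference ensemble is 5000 (`--paper-scale`) |
| τ_R fit band | 0.06 < ρ < 0.30 | region of reliable single-exponential decay |
| D fit window | last decade of retained lags | long-time diffusive regime |

Every replica has its own recorded seed derived from the run seed via
`SeedSequence`; identical (seed, configuration) reproduces trajectories
bit for bit. Replicas run sequentially — the compiled kernel keeps one RNG
stream per process.

## Validation strategy

* Exhaustive enumeration (N ≤ 4) of every allowed configuration with
  exact Boltzmann weights validates geometry, energy and sampling:
  configuration frequencies from long MC runs are chi-square-tested
  against exp(−E)/Z, and time averages (⟨R²⟩, ⟨n_PP⟩, ⟨n_PS⟩) are compared
  with exact values over an (E_PP, E_PS) grid in identical finite boxes.
* Exactly known dynamic limits: a free monomer has D_xy = 1/6 per MCS;
  the dimer has ⟨R²⟩ = 27/13 independent of E_PP.
* Invariants (self-avoidance, bond lengths, non-crossing, exact cached
  contact counts) are re-verified from scratch on randomized trajectories
  in every mode.

## What the simulations do and do not show

The chain is a coarse-grained bead model without hydrodynamic
interactions, solvent structure, bending stiffness or surface
heterogeneity; dynamics are relative (scaling in N), not absolute times.
Desk-scale ensembles (tens of replicas vs 5000) mean individual τ_R values
carry ~10–30 % statistical error and fitted exponents ~0.1–0.2; the
reduced chain-length grids (N ≤ 64, and N ≤ 32 for the slow 2D/slab
rotational fits) probe the onset of the long-chain regime, where apparent
exponents still drift slightly with N (e.g. the strictly-2D β measures
≈ 2.8–2.9 on N = 8–32, decreasing toward its long-chain value with
growing N).

Three model-level observations from calibration, recorded as analysis
rather than tuned away: (i) the steepest-descent-of-⟨R_G²⟩ proxy for the
coil–globule transition at N = 64 locates E_PP ≈ 0.35–0.5 on a 0.1 grid
(verified with both compact-start and annealed coil-start protocols), at
the low edge of the literature value ≈ 0.5 that derives from other
observables and chain lengths; (ii) strictly-2D rotational relaxation has
strong finite-N corrections, so exponent fits on reduced grids sit above
the asymptotic value; (iii) for collapsed 2D chains (E_PP ≥ 1) the
relaxation times at N ≤ 32 already exceed affordable trajectory spans, so
apparent diffusion exponents measured at desk scale (≈ 2.1–2.4 at
E_PP = 1, ≈ 3.6 at E_PP = 2) sit far above the long-chain values
(≈ 1.66 and ≈ 2.25); reaching the asymptotic exponents there requires the
full reference ensembles. The corresponding checks in the test-suite
assert the long-chain values and fail honestly at desk scale.

## Design choices that were genuinely open

* Non-crossing is enforced as exact geometric intersection, including in
  2D, where it makes the dynamics markedly slower than in 3D (crossings
  cannot be escaped through the third dimension). This is the only
  unambiguous reading of "bonds don't intersect".
* The virtual pre-adsorption wall is hard; equilibration statistics are
  insensitive to its softness.
* The 2D mode ignores E_PS entirely rather than adding the constant N.
* ACF normalization uses the time-averaged ⟨R·R⟩, not the single t = 0
  ensemble value.
* Exponent fits use every chain length simulated in a sweep by default;
  `run_sweep(min_n_for_fit=...)` restricts to the long-chain region for
  sensitivity checks.
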