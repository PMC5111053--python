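# polyads

Dynamic Monte Carlo simulation of a single coarse-grained polymer chain on
the simple cubic lattice, near an attractive homogeneous surface — with the
estimators needed to study how adsorption changes polymer dynamics.

## The problem

When a flexible polymer physisorbs onto a flat attractive wall its
conformations flatten and its dynamics slow down. Two numbers summarize
the dynamics: the translational diffusion coefficient parallel to the
surface, `D_xy`, and the rotational relaxation time `τ_R` of the
end-to-end vector. For long chains both follow power laws in chain
length `N`,

    D_xy ~ N^(−α),        τ_R ~ N^(β),

and the exponents diagnose the dynamical regime: a Rouse chain in good
solvent has α ≈ 1 and β ≈ 1 + 2ν (ν ≈ 0.6 in 3D, ν = 0.75 in 2D). This
package measures how α and β respond to the surface attraction `E_PS` and
the intra-polymer attraction `E_PP` for a partially adsorbed chain, with
the desorbed 3D chain and the strictly 2D chain as limiting references.

## The model

Single-site fluctuating-bond chain: monomers occupy lattice sites
(self-avoiding), bond lengths fluctuate among 1, √2, √3, and bonds never
cross (exact integer segment-intersection test). Energy at k_B·T = 1:

    E = − n_PP·E_PP − n_PS·E_PS,

with `n_PP` the number of non-bonded nearest-neighbour monomer pairs and
`n_PS` the number of monomers in the layer adjacent to the wall. Dynamics:
single-monomer Metropolis moves of one lattice spacing, accepted with
probability min[1, exp(−ΔE)]; one Monte Carlo step (MCS) is `N` attempted
moves. Slab runs use an equilibrate-above-a-virtual-wall → release →
adsorb → settle protocol before production.

Estimators: multi-origin centre-of-mass MSD (`D_xy` = slope/4 of the
linear regime), FFT end-to-end autocorrelation with an exponential fit
restricted to 0.06 < ρ < 0.30 (`τ_R`), log-log least squares for α and β,
and a steepest-descent locator of the coil-globule transition on a ⟨R_G²⟩
vs `E_PP` sweep. Exhaustive enumeration of chains with N ≤ 4 provides
exact Boltzmann references used throughout the tests.

## Worked example

Measure the dimer and a short adsorbed chain from the command line:

```sh
polyads oracle --epp 1.0 --eps 1.5
polyads simulate --n 16 --mode slab --eps 1.0 --replicas 20 --seed 3
```

The `oracle` subcommand enumerates tiny chains exactly; it prints, among
other checks,

```
 "n2_bulk_configs": 26,
 "n2_bulk_r_sq": 2.076923076923077,
 "pass": true
```

— the 26 allowed dimer bond vectors (6 of length 1, 12 of √2, 8 of √3)
and the exact dimer mean-square end-to-end distance 27/13 ≈ 2.077.

A small scaling sweep for the athermal chain in solution (~1 min):

```python
from polyads import SweepConfig, run_sweep
table = run_sweep(SweepConfig(
    n_values=(8, 16, 32), e_pp_values=(0.0,), mode="bulk3d",
    replicas=16, seed=1))
print(table[["mode", "e_pp", "alpha", "alpha_err", "beta", "beta_err"]]
      .to_string(index=False))
```

prints

```
  mode  e_pp    alpha  alpha_err    beta  beta_err
bulk3d   0.0 1.149245   0.002975 2.32367  0.181943
```

— the diffusion coefficient falls off as `N^−1.15` and the relaxation
time grows as `N^2.3` over this short grid, consistent with Rouse-like
dynamics (long-chain references ≈ 1.06 and ≈ 2.3; apparent exponents at
small N sit slightly above them, and the quoted errors are fit standard
errors only). Python API: `run_point` simulates one (N, E_PP, E_PS, mode)
condition over independent replicas and returns a summary with `d_xy`,
`tau_r`, `rg_sq_mean`, bootstrap errors and diagnostics (acceptance rate,
desorbed fraction).

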