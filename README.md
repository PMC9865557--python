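# ilscale

Tools for tuning fixed-charge force fields of ionic liquids (ILs) against
experiment, and for analysing the simulations that drive the tuning.

Gas-phase-fitted atomic charges over-bind condensed ionic phases because they
ignore polarization and charge transfer.  The standard remedies are two
*uniform* force-field transforms applied to the solvent ions:

* **charge scaling** — every partial charge is multiplied by a factor
  *s*<sub>q</sub> < 1 (0.8 is a widely useful near-optimal value);
* **vdW σ scaling** — every Lennard-Jones collision diameter of the ions'
  atom types is multiplied by *s*<sub>σ</sub>, loosening (>1) or tightening
  (<1) bulk packing, for systems whose density barely responds to charge
  scaling.

`ilscale` implements the full desk-side workflow around these transforms:

* **`ilscale.topology`** — read/scale/write GROMACS-dialect topologies
  (`[ atomtypes ]`, `[ atoms ]`, …; everything else passes through verbatim).
  Solutes keep full charges and radii unless explicitly targeted.
* **`ilscale.esp`** — charge-quality scoring: the Coulomb potential of the
  point charges on a molecular grid versus an ab initio reference,
  RRMSE = √(Σ(V<sub>model</sub>−V<sub>ref</sub>)² / ΣV<sub>ref</sub>²),
  plus a Merz–Kollman-style shell-grid builder.
* **`ilscale.neq`** — fast-growth free energies: per-realization works W (kT)
  from two-stage (vdW coupling + charging) solute-creation switching are
  combined and fed to exponential averaging (Jarzynski),
  ΔA = −ln⟨e<sup>−W</sup>⟩, with bootstrap standard deviations and water→IL
  transfer free energies ΔΔG = ΔG<sub>IL</sub> − ΔG<sub>water</sub>.
* **`ilscale.metrics`** — experiment–calculation agreement: MAE, mean signed
  error, RMSE, Kendall τ (tau-b), Pearlman's predictive index, Pearson r,
  and ±1/±2 kcal/mol outlier counts.
* **`ilscale.density`** — density-response fitting: OLS of simulated density
  on the scaling factor, relative slope b/ρ<sub>exp</sub>, the
  density-matched factor s* solving ρ(s*) = ρ<sub>exp</sub>, and the
  balanced recommendation between the density-derived and
  solvation/partition-derived factors.
* **`ilscale.toyfluid`** — a desk-scale NPT Metropolis Monte-Carlo ionic
  fluid (LJ + damped shifted-force Coulomb, ln-V volume moves) and
  Crooks-consistent Gaussian work/paired-data generators with known truth,
  so the whole pipeline can be exercised end to end in seconds.

## Worked example

```python
from ilscale import (combine_stages, estimate_with_uncertainty,
                     generate_gaussian_works, transfer_free_energy,
                     relative_slope, report_two_decimals, balanced_factor)

# two-stage fast-growth works for one solute in an IL (100 realizations)
vdw = generate_gaussian_works(-6.0, 1.5, 100, seed=11, stage="vdw-coupling")
chg = generate_gaussian_works(-4.0, 0.8, 100, seed=12, stage="charging")
il = estimate_with_uncertainty(combine_stages(vdw, chg), seed=0)
water = estimate_with_uncertainty(generate_gaussian_works(-6.5, 1.0, 100, seed=13), seed=1)
print(il)
print(transfer_free_energy(il, water))
```

prints

```
dA = -9.6415 +- 0.2004 kT (-5.710 +- 0.119 kcal/mol, EXP, n=100, T=298.0 K)
dA = -3.1603 +- 0.2592 kT (-1.871 +- 0.153 kcal/mol, transfer, n=100, T=298.0 K)
```

i.e. the solute's solvation free energy in the IL is −5.7 kcal/mol and it
prefers the IL over water by 1.9 kcal/mol (negative transfer free energy),
with bootstrap uncertainties from the 100 pulling realizations.

Density-response interpretation works directly on published or simulated
scans.  For the two quinuclidinium ILs [QUIN6][NTF] and [QUIN8][NTF], the
fitted slopes −1.82 and −1.73 g/mL against experimental densities
1.358 and 1.295 g/mL give relative responses

```python
report_two_decimals(relative_slope(-1.82, 1.358))   # -1.34
report_two_decimals(relative_slope(-1.73, 1.295))   # -1.33
balanced_factor(1.03, 1.00, step=0.01).suggestion   # 1.02
```

— a ~1.3 % density change per percent of σ scaling, and a recommended
production factor of 102 % sitting between the density-derived 103 % and the
solvation-derived 100 %.

A command-line layer mirrors the library:

```sh
ilscale scale-top --in il.top --out il_s080.top --charge-scale 0.8
ilscale fe-estimate --works vdw.txt --works charging.txt --bootstrap 1000 --seed 1
ilscale density-fit --in scan.csv --recommend --s-solv 1.00
ilscale toy-sim --scan 0.98,1.00,1.02,1.04 --out scan.csv
```

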