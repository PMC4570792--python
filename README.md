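# desolvscan

Post-MD energetic analysis of protease–inhibitor (and other two-chain)
complexes: single-trajectory MM-GBSA effective free energies, per-residue
and pair-wise decomposition, the polar-desolvation / screened-electrostatics
repartition, computational alanine scanning, and geometric interface
statistics (contacts, hydrogen bonds, salt bridges, occupancies,
equilibration times).

## Why

Whether a canonical inhibitor binds a protease often hinges on a single
buried charge: inserting a Lys side chain into an S1 pocket costs a large
polar-desolvation penalty that only a well-placed acidic partner (a salt
bridge at the pocket bottom) can repay. Plain interaction counting cannot
see this — the repartition

    dG_ds    = sum of GB self-energy changes + intra-chain GB cross terms
    dG_el^sc = inter-chain Coulomb + GB cross terms
    dG_ds + dG_el^sc = dE_el + dG_GB   (exactly, per frame)

separates what binding *costs* in desolvation from what the interface
*pays back* in screened electrostatics. `desolvscan` implements this
analysis end to end for ensembles under the single-trajectory (ST)
approximation,

    dG_eff = dE_vw + dE_el + dG_GB + dG_SA,

with GB-OBC1/OBC2 implicit solvation, Debye salt screening, LCPO or
Shrake–Rupley surface areas (`dG_SA = 0.0072·dSA`), per-residue (prEFED)
and pair-wise (pwEFED) decomposition with exact conservation, warm/hot-spot
calling (dG_sc in (−1.0, −0.4] / ≤ −1.0 kcal/mol), and ST alanine scanning
(`ddG = dG_eff(native) − dG_eff(mutant)`; negative = favorable native
side chain). A deterministic synthetic-complex generator plants salt-bridge,
hydrogen-bond and hydrophobic motifs so every stage is testable without
external structures. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from desolvscan import (
    FixtureSpec, GBModelParams, NonpolarParams,
    make_toy_complex, make_pseudo_trajectory,
    ensemble_energies, polar_split, cas_ddg, salt_bridges,
)

spec = FixtureSpec(seed=7, n_frames=100, noise_sigma=0.1)   # planted motifs
top = make_toy_complex(spec)
ens = make_pseudo_trajectory(top, spec)
params, np_ = GBModelParams(model="OBC2", salt_molar=0.05), NonpolarParams()

e = ensemble_energies(ens, params, np_)["summary"]
print({k: round(v["mean"], 2) for k, v in e.items()})
split = polar_split(ens, params)
print(round(split.G_ds, 2), round(split.G_el_sc, 2))
print(round(salt_bridges(ens)[0].occupancy, 2))
print(round(cas_ddg(ens, ("A", 1, "LYS"), params, np_).ddG, 2))
```

prints

```
{'E_vw': -2.04, 'E_el': -148.8, 'G_GB': 141.42, 'G_SA': -1.49, 'G_eff': -10.9}
17.91 -25.29
1.0
-8.11
```

Reading: the planted Lys–Asp salt bridge makes the inter-chain
electrostatics strongly favorable (dE_el ≈ −149 kcal/mol) but is almost
entirely opposed by the desolvation of the charged groups
(dG_GB ≈ +141 kcal/mol); the repartition shows a desolvation penalty of
+17.9 against −25.3 of screened inter-chain attraction. The bridge is
present in every frame (occupancy 1.0), and truncating the Lys-like side
chain to alanine costs 8.1 kcal/mol of binding (ddG < 0: favorable native
contribution).

The same pipeline runs from the shell:

```bash
desolv-scan synth --seed 7 --frames 100 --out demo     # writes demo.pqr/.params.tsv/.pdb
desolv-scan validate demo.pqr demo.params.tsv demo.pdb
desolv-scan run config.yaml --out results/             # full report bundle
desolv-scan thermo ddg-from-ki 1.3e-9 2.35e-8          # -> -1.7142 kcal/mol
```

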