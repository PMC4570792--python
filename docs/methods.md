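# Methods

## Scope and model

`desolvscan` post-processes conformational ensembles of two-chain
(receptor:ligand) complexes with the MM-GBSA effective free energy under the
single-trajectory (ST) approximation:

    dG_eff = dE_vw + dE_el + dG_GB + dG_SA,

where every delta is value(complex) − value(receptor) − value(ligand)
evaluated on identical coordinates. The entropy term −TdS is deliberately
omitted (dG_eff, not dG_bind), and internal bonded energies cancel exactly
under ST, so the Coulomb and Lennard-Jones deltas reduce to inter-chain pair
sums. The GB and SA terms do not reduce: effective Born radii and exposed
areas change when the binding partner is removed, and that difference *is*
the desolvation physics the package exists to quantify.

The package does not run molecular dynamics. Ensembles come either from
multi-model PDB files produced elsewhere or from the built-in synthetic
generator (below).

## Energy terms

**Coulomb / Lennard-Jones.** No cutoff (this is post-processing, not
dynamics). LJ is the 12-6 form with Lorentz–Berthelot combination: minimum
at `rmin_i + rmin_j`, depth `sqrt(eps_i eps_j)`. The electrostatic constant
is 332.0636 kcal·Å/(mol·e²).

**Effective Born radii.** Pairwise-descreening (HCT) integrals with the
analytic piecewise expressions, summed over neighbors within `rgbmax`
(default 25 Å, hard truncation — the smooth switching some MD codes apply
near the cutoff is not reproduced; at 25 Å the difference is negligible for
complexes of this size). The intrinsic radius is reduced by the standard
0.09 Å offset, and the OBC tanh rescaling is applied with either published
coefficient set:

| model | alpha | beta | gamma |
|-------|-------|------|-------|
| OBC1  | 0.8   | 0.0  | 2.909125 |
| OBC2  | 1.0   | 0.8  | 4.85     |

OBC2 is the default, matching the model that best reproduced the relative
experimental affinities in the elastase–inhibitor study this pipeline
reimplements. Neck-corrected (GBn2-style) radii are out of scope.

**GB polar energy.** The Still pair function
`f_GB = sqrt(r² + R_i R_j exp(−r²/4R_iR_j))` with self terms (`f = R_i`, a
½ factor) and Debye–Hückel salt screening
`exp(−kappa·0.73·f_GB)/eps_w`, `kappa = 0.329·sqrt(salt molarity)` Å⁻¹
(aqueous, 298 K). The 0.73 attenuation matches common GB implementations
and is configurable. Defaults: `eps_in = 1`, `eps_w = 78.3`; salt presets
0.50 M and 0.05 M mirror the original study's two ionic strengths.

**Nonpolar term.** `dG_SA = gamma·dSA + beta` with `gamma = 0.0072`
kcal/(Å²·mol) and `beta = 0`. SASA comes from either Shrake–Rupley
sphere-point sampling (`numeric`, 960 points by default — the oracle and
the default for per-residue attribution) or the LCPO approximation with the
published parameter table keyed by element and bonded-heavy-neighbor count
(bonds inferred geometrically below 1.6 Å). Both operate on heavy atoms with
radii inflated by the 1.4 Å probe. LCPO is a protein-regime fit: on the
small, largely exposed fragments used here it runs systematically high —
about 5–8 % per molecule on chain-like fixtures, and worse if unphysical
clashes are present — so the numeric route is the default wherever per-atom
areas feed the decomposition. Atoms without a published LCPO class fall
back to numeric areas with a warning.

## Matrix convention and decompositions

All pair energies are stored in symmetric per-atom matrices whose diagonal
holds self terms and whose two off-diagonal slots each hold half of the full
pair energy, so `matrix.sum()` is the total. Frame-level delta matrices
(complex minus block-diagonal monomers) make the three decompositions
one-liner sums with exact conservation:

* **Per-residue (prEFED).** Half of every cross term touching the residue's
  atoms, plus its GB self-term differences and its share of `gamma·dSA`
  (numeric per-atom attribution; the ICOSA surface scheme of the original
  tooling is replaced by this — a documented deviation). Residue values sum
  to dG_eff on every frame to < 1e-12 kcal/mol in practice (guaranteed
  ≤ 1e-6 by tests). Intra-residue cross terms are attributed wholly to the
  residue. Terminal-residue atoms are attributed to their own residue; the
  side-chain restriction dG_sc (used for spot calling) counts non-backbone
  atoms only, with the backbone set fixed as {N, H, CA, HA, HA2, HA3, C, O,
  OXT} — glycine therefore has dG_sc = 0 identically.
* **Pair-wise (pwEFED).** Full (unhalved) receptor-residue × ligand-residue
  interaction energies; their sum equals dE_vw + dG_el^sc per frame.
* **Polar split.** dE_el + dG_GB is repartitioned into the polar-desolvation
  penalty dG_ds (GB self-term differences plus intra-chain GB cross terms)
  and the screened electrostatics dG_el^sc (inter-chain Coulomb plus GB
  cross terms). Valid only under ST, where intra-chain Coulomb deltas vanish;
  the code refuses unpartitioned systems.

Warm/hot-spot calling uses the side-chain contribution with hot ≤ −1.0,
warm in (−1.0, −0.4] kcal/mol; both boundaries classify into the stronger
category (the literature leaves the interval ends ambiguous).

Ensemble statistics are means ± SEM over frames, treated as independent
(energy-term correlation times in solvated-protein MD are a few ps, well
below typical 10 ps snapshot spacing).

## Alanine scanning

The ST shortcut: on every frame the target side chain is truncated beyond
C-beta and a hydrogen is placed along the C-beta→C-gamma direction at
1.09 Å; Cys, Pro, Gly, Ala are refused. Then
`ddG = dG_eff(native) − dG_eff(mutant)` frame-matched, so negative ddG
means a favorable native contribution. Charge handling is genuinely open
(the original study delegated it to its force-field tooling), so two modes
are exposed: `ala` (default) rewrites the kept atoms of the mutated residue
with a bundled alanine charge set, `keep` retains native charges and only
the placed hydrogen takes the alanine C-beta-hydrogen charge. The placed H
carries generic aliphatic-H LJ parameters, and the net system charge change
is logged — for charged residues the mutant system is no longer neutral,
which is the standard, if imperfect, behavior of truncation-based scanning.

## Interface geometry

* Contacts: inter-chain residue pairs with any heavy-atom distance ≤ 4 Å
  (hydrogens excluded for robustness).
* Hydrogen bonds: donor–acceptor distance ≤ 3.5 Å and an angle ≤ 30° at the
  donor between donor→acceptor and donor→hydrogen. Donors are N/O with a
  covalently bonded H (inferred within 1.2 Å on the first frame); acceptors
  are N/O. The criterion is sometimes written with the vertex order
  "acceptor–donor–hydrogen"; the donor-vertex reading implemented here is
  the standard one, and the cutoffs are configurable.
* Salt bridges: oppositely charged side-chain groups (Lys NZ; Arg
  NE/NH1/NH2 vs Asp OD1/OD2; Glu OE1/OE2), minimum group-atom distance ≤ 4 Å
  in at least one frame; occupancy over all frames, mean distance over
  presence frames only (reported as a bridge-strength measure).
* RMSD: least-squares (Kabsch) superposition via
  `scipy.spatial.transform.Rotation.align_vectors`.
* Equilibration time: the accumulated running mean of both the dG_eff and
  the RMSD series must stay within a tolerance (5 % of the series spread)
  from the candidate index through the end of the series, with at least 20 %
  of the frames remaining; t_eq is the later of the two indices. A series
  that never settles returns the last admissible index with a warning flag —
  the caller must not silently average over an unequilibrated window.
* Representative frames: gromos-style neighbor counting on the pairwise
  fitted-RMSD matrix; the representative is the member with the most
  neighbors in the largest cluster, ties broken toward earlier frames.

## Thermodynamic conversions

`ddG = RT ln(Ki1/Ki2)` with R = 1.9872×10⁻³ kcal/(mol·K), T = 298 K —
this pair reproduces every published conversion in the study's comparison
table at the printed precision. Errors on the exponential transform
propagate to first order (`err = ratio·sem/RT`), which matches the printed
± values; energy-component differences combine SEMs in quadrature. Spearman
correlations use average ranks on ties. The predicted affinity for an
experimentally unformed complex is reported exactly as the source arithmetic
produces it (known-variant Ki divided by the Ki ratio).

## Synthetic complexes

The generator builds two mini-chains of simplified residues (hand-assigned
charges, radii and LJ parameters — analytic control matters more here than
chemical realism): receptor chain A at y = 0, ligand chain B at y = 14 Å,
side chains facing each other. Requested motifs are planted by rigidly
translating the ligand residue until the key atom pair hits its target
separation exactly in the base frame:

* salt bridge — Lys-like NZ to Asp-like OD1 at 3.0 Å;
* hydrogen bond — Ser-like OG–HG donor to a backbone carbonyl O at
  2.9 Å / 10°;
* hydrophobic pocket — Leu-like CD pairs at 3.8 Å.

Receptors with ≥ 4 residues end in a remote neutral Leu-like residue, a
scannable null probe for the alanine-scan contract. Pseudo-trajectories add
iid isotropic Gaussian noise (default σ = 0.1 Å, chosen so planted
interactions persist with occupancy > 0.9) and can rigidly displace the
Lys-like side chain by 4 Å from a given frame onward, emulating a
binding-pocket exit ('in' → 'up') that halves the salt-bridge occupancy and
delays the apparent equilibration time. Everything is deterministic given
the seed (numpy `default_rng`).

What the generator does **not** emulate: bonded constraints and realistic
intramolecular flexibility, solvent atoms, correlated (non-iid) fluctuations,
realistic amino-acid charge distributions, and conformational sampling.
Passing tests therefore demonstrate the correctness of the energy and
statistics machinery on controlled inputs — not force-field accuracy for
real proteins, and not the absolute energetics of the elastase complexes,
which required tens of nanoseconds of explicit-solvent MD of full proteins.

## Numerical choices and problem sizes

* Conservation identities are asserted at 1e-6 kcal/mol per frame (observed
  ≲ 1e-13); oracle equivalences at their own scales: Born closed form
  ≤ 0.01 %, effective radii vs a direct numeric descreening quadrature ≤ 1 %,
  LCPO vs sphere sampling ≤ 10 % per molecule, decomposition bookkeeping vs
  brute-force double loops ≤ 1e-8.
* Default problem sizes: ~50-atom complexes, 100-frame trajectories for
  occupancy/conservation runs, 5-frame runs for alanine-scan examples —
  large enough for stable statistics on planted motifs, small enough to keep
  every computation exact-arithmetic friendly and fast on one CPU.
* Degenerate inputs: coincident charged atoms raise; zero-variance series
  raise in regressions; never-stabilizing series flag rather than fail;
  clustering ties break deterministically toward earlier frames, making
  reruns byte-identical.

## Known limitations

GBn2-style neck corrections, PB solvers and normal-mode entropies are out of
scope. LCPO should be treated as a fast approximation on these small
systems; the numeric SASA is authoritative. The alanine-scan charge modes
bracket, but do not resolve, the charged-residue truncation ambiguity.
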