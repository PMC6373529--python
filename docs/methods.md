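# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `ligplace`, and what the synthetic fixtures do and
do not demonstrate about real data.

## Molecules, structures, charges

Small molecules are RDKit graphs with explicit hydrogens; atom classes
used throughout are *heavy* (non-hydrogen), *polar hydrogen* (H bonded to
N, O or S) and *halogen* (F, Cl, Br, I), which partition the atom set.
Protein structures are flat atom tables read through Biopython's PDB
parser; crystallographic waters and non-ligand hetero groups (e.g. DMSO,
sulfate) are retained and tagged, and they count on the protein side in
every interface, contact and energy computation. Alternate locations
resolve to the highest-occupancy conformer (first on ties). When a ligand
residue occurs more than once in a file, the copy nearest the protein
centroid is kept, with a warning. Hetero-group connectivity is perceived
from coordinates, since PDB records carry none.

Partial charges are Gasteiger electronegativity-equalization charges:
deterministic, parameter-light, and accurate enough for a scoring (not a
simulation) context. The original refinement engine used force-field
charges inside an MD protocol that is out of scope here. Pseudo-protein
fixtures carry small fixed per-atom charges; real proteins read from PDB
default to no charges, in which case the electrostatic term contributes
zero to the pose score rather than failing.

## Template selection

Similarity is Tanimoto on the connected maximum common substructure:
element-exact atom typing, bond-order-insensitive edges (single may match
aromatic), similarity counted in atoms. These are the simplest published
conventions for MCS Tanimoto; the atom-count convention is isolated in
one function so it can be swapped for an atoms+bonds variant. The MCS
search (RDKit FMCS) runs under a time budget; a budget hit returns the
best-so-far size flagged approximate. Some toolkits report the
complementary "Tanimoto distance" = 1 − similarity; this package reports
similarity. Selection never fails on low similarity — template reuse is
known to be robust to modest ligand similarity — it only warns below 0.6.

## Shape and feature overlap

Each heavy atom is a spherical Gaussian ρ(r) = p·exp(−α|r−c|²) with
p = 2.7 and α = κ/r² (Bondi radii). κ is fixed once so that an isolated
atom's Gaussian self-overlap ∫ρ² equals its hard-sphere volume
(κ ≈ 2.274, exact by construction, and the calibration is asserted to 5%
in the tests). Shape similarity is the first-order overlap Tanimoto
V_AB/(V_AA+V_BB−V_AB) over all atom pairs; "color" applies the same form
to pharmacophore feature points (donor, acceptor, anion, cation,
hydrophobe from bundled SMARTS version 1, plus aromatic ring centroids
located geometrically), overlapping only within a class, with a fixed
1.0 Å feature radius. Two featureless molecules have color 0 by
definition.

The overlay maximizes the shape overlap only: principal-axes alignment
with the four proper axis flips as starts, then Nelder–Mead refinement of
the six rigid degrees of freedom (xatol 1e-4); color is evaluated at the
optimum, not optimized. Because the starts are built from the moving
molecule's own principal axes, the final combo is equivariant under any
rigid motion of the input (the flips absorb eigenvector sign ambiguity;
near-degenerate inertia tensors of linear molecules are likewise covered
by the flip starts). Whether conformer selection should score
pre-aligned or overlay-optimized poses was an open choice; this package
optimizes first and then scores, which is the stricter reading.

Conformers come from seeded ETKDG embedding with MMFF94 relaxation (UFF
fallback), deduplicated at 0.25 Å heavy-atom best-fit RMSD and ranked by
relaxed energy. The original protocol used a proprietary generator and
overlay engine; the distance-geometry + Gaussian-overlap stack is this
package's substitution and is documented as such in pose provenance.

## Energetics and pose score

E_vdw and E_elec are plain intermolecular pair sums with a hard 8.5 Å
cutoff (no switching function — a documented divergence from MD engines),
Lorentz–Berthelot mixing over a small bundled element-level OPLS-like
(σ, ε) table (unknown elements fall back to a carbon-like default with a
warning), and Coulomb constant 332.0636 kcal·Å/(mol·e²) with unit
dielectric. Intermolecular distances below 0.1 Å are outside the model's
validity and raise.

E_desolv is an empirical buried-surface term:
Σ_atoms σ_solv·(SASA_complex − SASA_free), with per-element solvation
parameters chosen so that burying hydrophobic surface (C, S, halogens;
σ_solv > 0) is favourable and burying polar surface (N, O) is penalized.
A fully occluded atom therefore contributes −σ_solv times its free
surface. SASA is deterministic Shrake–Rupley with a 960-point Fibonacci
sphere per atom and a 1.4 Å probe, evaluated in the complex's canonical
principal-axes frame so the term is exactly invariant under global rigid
motion. The units are internal empirical units, consistent within the
toolkit but not comparable to any engine's desolvation energies.

The pose score is the weighted sum 1.0·E_vdw + 0.1·E_elec + 1.0·E_desolv
+ 0.1·E_AIR with the electrostatic weight halved relative to the common
0.2 default; E_AIR is an input that defaults to 0 because no ambiguous
restraints drive this protocol. Lower scores are better.

## Refinement

The explicit-solvent MD water-refinement stage of the original protocol
(TIP3P shell, staged heating/cooling, thousands of 2 fs steps) is
replaced by a deterministic local relaxation: coordinate descent over
rigid-body translation/rotation and ligand torsions on E_vdw + 0.1·E_elec,
accepting only strictly improving moves (bounded scalar line searches,
at most 200 DOF iterations, convergence at Δ < 1e-3). The protein is
always rigid — the original allowed interface side-chain flexibility in
cross-docking, a noted divergence. Poses starting in a hard clash are
jittered with a seeded displacement and retried. The default population
mirrors the protocol's 200 refined models (10 conformers × 20
seeded-jitter restarts); the substitution is recorded in pose provenance.

## Affinity predictors

*Structure-based.* Eligible atoms are heavy atoms plus polar hydrogens —
the only reading of the contact classes that makes CC/NN/OO/XX mutually
exclusive and exhaustive: same-element C, N or O pairs feed their own
counts; every other eligible pair (S, halogens, mixed elements, polar-H
pairs) is XX. Whether nonpolar hydrogens were excluded in the original
implementation is not determinable, so an `include_nonpolar_h` switch
exists (default off). The ΔG coefficients are immutable constants trained
upstream; refitting them is explicitly out of scope. Compounds are ranked
by the mean ΔG of their 10 best-scoring poses, lower = tighter (ΔG
convention), ties broken by compound id.

*Ligand-based.* Atom-pair fingerprints use the classic typed key:
(element, heavy-neighbour count, π-electron count) per atom, unordered
type pair plus topological (shortest-path) distance, accumulated as
counts. The kernel is Σmin/Σmax on counts (a binary variant is exposed;
which the original used is unknowable, and counts are the stricter
default). Labels are converted to pIC50 = −log10(IC50/M) before fitting —
linear-scale IC50 regression is dominated by outliers — and duplicate
training SMILES collapse to their median label. The ε-SVR runs on the
precomputed kernel (tiny diagonal ridge for numerical symmetry); default
hyperparameters are C = 1, ε = 0.1 with a 5-fold CV grid helper.
Binder classification is strict: predicted affinity must be tighter than
the 10 µM assay limit (pKd > 5.0 exactly excludes the limit itself).

## Evaluation

Models are superposed on the *reference* structure's 5 Å interface
(protein heavy atoms matched by chain/residue/atom name, Kabsch least
squares — equivalent to the McLachlan solution), then ligand RMSD is
computed over heavy non-halogen atoms with no further fitting.
Symmetry-corrected RMSD (minimum over graph automorphisms, capped at
10,000 mappings) is on by default: without it a benzene-like ring flip
inflates an otherwise perfect pose; a strict-order toggle exists since
assessment pipelines differ on this point. Success rates count targets
whose best of the first n submitted models is ≤ 2.5 Å. Rank correlation
is tie-corrected Kendall tau-b (undefined and raising on an all-tied
vector); classification quality is the Matthews correlation coefficient
with the zero-denominator → 0 convention.

## Synthetic fixtures: what they show and what they don't

`make_pocket_complex` plants a ligand (default naphthalene — rigid and
elongated, so orientation is well determined) and moulds a shell of
glycine-like 4-atom pseudo-residues at the spherical dilation of the atom
cloud: every shell residue sits at a fixed 3.9 Å nearest-atom contact
distance, a typical van der Waals contact separation, with 80 shell
directions closing the cavity. The planted truth is recorded at
mechanical equilibrium of the pocket's own energy model (best of several
seeded relaxations), as a crystallographic pose is an equilibrium of the
true energetics. A spherical-cavity mode supports clash-free sanity
checks and errors when the ligand cannot fit.

`make_template_ladder` derives template ligands by deleting terminal
heavy atoms one at a time, giving exactly known MCS sizes and a
decreasing similarity ladder. `make_affinity_set` emulates a censored
bioassay table: a binder family of alkyl-decorated benzenes whose pIC50
follows 9 − 4·(1 − sim-to-probe), and a carbon-free non-binder family
(P/N/O backbones) whose atom-pair similarity to the binder family is
exactly zero, labelled at pIC50 4.5 — below the 10 µM detection limit,
mirroring compound sets dominated by measurements pinned at the assay
ceiling, and leaving a margin around the classification threshold so that
noiseless classification is well-posed.

Passing the planted-recovery and noiseless-recovery tests shows the
pipeline is *self-consistent*: it recovers poses that its own energy
model considers native in an exactly complementary pocket, and recovers
affinity rules expressible in its own kernel. It does not demonstrate
accuracy on real pockets (flexible side chains, waters, electrostatics
of real charge distributions) or on noisy heterogeneous assay data.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at reduced sizes (tens
of conformers, ~10 poses, 80-residue pockets) — the package's own choice
of desk-scale study conditions; the protocol-scale defaults (500/10/200)
remain the configuration defaults. Every stochastic step (embedding,
restart jitter, fixture generation) is driven by an explicit seed and the
whole pipeline is reproducible bit-for-bit for a fixed seed and
configuration; each structured output carries the toolkit version, a
configuration hash and the seed.

## Known limitations

No protein flexibility, no water placement, no protonation/tautomer
enumeration, no mmCIF, hard cutoff electrostatics with unit dielectric,
element-level (not atom-type) LJ and solvation parameters, and the
desolvation scale is internal. The affinity coefficients are used as
published constants; their domain of validity travels with the upstream
training data, not with this implementation.
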