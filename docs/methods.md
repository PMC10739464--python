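# Methods

## The modelling problem

A pMHC-II complex is an αβ heterodimer whose open groove binds a peptide
of 7–25 residues through a 9-residue binding core; core positions P1, P4,
P6 and P9 (offsets 0, 3, 5, 8) occupy the four main pockets and the
peptide flanking regions (PFRs) extend beyond the groove. Two empirical
facts make template-based modelling effective here: MHC folds are highly
conserved across alleles, and peptide anchoring geometry is stereotyped.
`pmhckit` exploits both — the receptor is inherited rigidly from the best
template, the peptide core is positioned on the template core, and only
the parts without structural precedent are built de novo.

## Template set

Structures are standardized to chains M (α), N (β), P (peptide) — B for
class I β2-microglobulin — with the peptide renumbered contiguously from 1.
Candidates are kept when the peptide is 7–25 residues long, no chain
matches a DM-chaperone sequence signature, and the peptide is not CLIP.
DM/CLIP recognition is by exact substring match against packaged,
user-extensible lists; the shipped DM signatures are synthetic markers
(file `dm_signatures_synthetic.json`) because a curated DM sequence set
must come from the user, while the CLIP defaults are the canonical
invariant-chain sequence PVSKMRMATPLLMQA and its core MRMATPLLM.
Alternate locations collapse to the highest occupancy (ties by altloc
label); hydrogens, waters and non-polymer groups are removed. Modified
residues map to parents through a packaged table (MSE→MET, SEP→SER, …);
an unmapped non-canonical residue raises instead of being modelled
silently. Each kept template carries the binding core observed in its
structure: the 9-mer register whose four anchor residues have the most
receptor heavy-atom contacts at 5.0 Å (ties to the smallest start).
7–8-mer peptides cannot hold a full core; they are retained in the
database but skipped by core-anchored ranking.

## Sequence comparison

MHC chains are globally homologous end to end, so identity ranking uses
global (Needleman–Wunsch/Gotoh) alignment with affine gaps: BLOSUM62,
gap open 11, gap extend 1 (a run of L gap columns costs open + L·extend —
BLAST-style protein defaults). Identity is the percentage of matching
aligned columns. Traceback ties resolve deterministically
(match > gap-in-second > gap-in-first), so rankings are reproducible.
Peptides are compared with PAM30, appropriate for short, near-identical
sequences. Both matrices ship in NCBI format and are parsed at run time.

## Template selection

The primary key is combined MHC identity — the mean of α-chain and
β-chain identity by default (`min` is available; the aggregation is a
documented choice, since chain-level identities could be combined either
way). Candidates tied on identity (within a configurable tolerance,
default exact) reorder by the core-anchored peptide score: the two 9-mer
cores pair column-to-column without gaps, flanks pair outward from the
core boundaries, and the shorter flank pads with terminal gaps. Gap
columns score 0 — flank-length differences are neutral rather than
penalized, because PFR length carries no signal about template quality.
Final ties break on resolution (ascending, unknown last) then id. The
pan-allele behaviour follows from the ranking being defined for every
template: when no template shares an allele, the best-identity one is
still returned.

## Restraints

For each of the four anchor residues of the template core, every heavy
atom within 5.0 Å of a receptor heavy atom defines one harmonic distance
restraint whose target is the observed template distance. All anchor
heavy atoms are restrained by default (`side_chain_only` restricts to
side chains); 5.0 Å is the standard interface-contact cutoff, and both
are configurable. Restraint residue numbers are re-indexed to the target
peptide through the core-anchored alignment. An anchor with no contact is
a warning; four contact-free anchors are an error.

## Conformer generation

The receptor is copied rigidly from the template (no receptor remodelling:
MHC conservation is the premise that justified template selection, and the
benchmark metric is peptide-only). Target peptide residues with a template
counterpart in the core-anchored alignment — the core always, plus every
flank position the alignment maps — inherit the template backbone; side
chains copy over when the residue type matches and otherwise rebuild as an
ideal-geometry Cβ stub (backbone L-RMSD is the quality metric; rotamer
repacking is out of scope). Flank residues beyond the template's ends grow
outward one residue at a time with ideal bond lengths and angles (NeRF
construction, ω = 180°) and (φ, ψ) drawn from a packaged
Ramachandran-favored set; among k = 32 draws the one with the lowest
soft-sphere clash score against the receptor and the peptide built so far
wins, ties to the earliest draw. If even the best draw leaves two atoms
closer than 2.0 Å, the model is kept but flagged. All draws flow from one
`numpy` generator seeded per model (model i uses seed + i), making
ensembles bitwise reproducible.

### Pseudo-energy and minimization

Each model relaxes under
`total = w_b·bonded + w_c·clash + w_r·restraint`, weights 1.0 / 1.0 / 10.0:

* **bonded** — `k (d − d₀)²` with k = 100 Å⁻² over bonded and 1-3 atom
  pairs of the peptide, where d₀ is the distance in the starting
  conformation. Regularizing toward the start (template geometry for
  inherited segments, ideal geometry for built ones) rather than toward
  absolute ideals keeps a clean self-model an exact fixed point of the
  minimizer.
* **clash** — `(r₀/d)¹² − 1` for non-bonded pairs closer than r₀ = 3.0 Å,
  with d floored at 0.8 Å (the r⁻¹² cap). The neighbor list is built once
  from the starting conformation at 4.5 Å; peptide-internal pairs within
  the same or adjacent residues are excluded.
* **restraint** — flat-bottom harmonic `((d − target)/max(σ, σ_floor))²`
  when |d − target| > σ, else 0, with σ_floor = 0.01 Å so the fixed-core
  default σ = 0 never divides by zero.

Minimization is L-BFGS-B with analytic gradients over the free atoms;
receptor atoms are always frozen, and in the default fixed-core mode every
atom of the nine core residues is frozen too (the core keeps the template
conformation exactly — the mode freezes atoms instead of relying on σ = 0
restraints). The restraint-flexible mode frees the core under restraints
with a user σ in Å. The energy trace is recorded per iteration and is
non-increasing over accepted steps; a NaN in any term raises an error
naming the term. The relaxed total is the model's pseudo-energy; the
ensemble (default 20 models) is ranked ascending by it, with per-model
failure isolation.

The engine exposes exactly two modes (fixed core, restraint-flexible core
with σ); a distinct "fully flexible" mode is not modelled separately —
σ-restrained flexibility subsumes it, which is a documented simplification.

## Evaluation

L-RMSD follows the CAPRI ligand-RMSD convention: least-squares
superposition on the receptor backbone (chains M+N, all residues; the fit
region is a documented choice, with the strict atom-correspondence check
raising on missing receptor atoms), then RMSD over peptide backbone atoms
N, Cα, C, O without refitting. Core L-RMSD covers the 9 core residues,
flanking L-RMSD the residues outside the four anchors — the anchors
themselves are excluded from the flanks, one of two defensible readings of
the boundary — and whole L-RMSD the entire peptide. When a 9-mer has no
flank residues the flanking value is reported as absent rather than 0, so
it cannot dilute aggregates. The three windows satisfy
`whole²·n_total = core²·n_core + flanking²·n_flank` identically.

The benchmark harness re-models every template of a set (leave-one-out or
self-template), evaluates all ensemble members, and reports per-case best
and top-k-ranked metrics, mean/median/sd aggregates (both location
statistics are always emitted), and the success rate — the fraction of
cases whose best whole L-RMSD among the top-k ranked models is below a
threshold (defaults 2 Å, k = 5). Anchors can come from the target
structure itself ("oracle anchors", isolating modelling quality from core
prediction) or from any `CorePredictor`.

## Synthetic fixtures

The generator emulates the groove topology — two straight α-helices
flanking the axis at ±groove_width/2 (default 18 Å), an extended-strand
floor 5.5 Å below the peptide plane, and a flat extended peptide along the
axis — with anchor Cβ stubs pointing down at the floor (guaranteeing a
receptor atom within 5 Å of every anchor) and non-anchor Cβ stubs pointing
up (making the structural core register unambiguous). Default receptor
chains are 180 residues (167 helix + 13 floor), satisfying the ≥ 70
residue MHC-chain heuristic; sequences are user-chosen or seeded-random,
so identity and PAM30 relationships can be engineered exactly.
Perturbations have closed-form ground truths: a rigid peptide shift of
d Å has every L-RMSD window equal to d; flank scrambling moves each flank
atom by exactly its magnitude (core 0, flanking = magnitude); a core
register shift relabels the core without touching coordinates (the
anchor-misprediction analogue).

What the fixtures deliberately do **not** emulate: real MHC fold geometry,
side chains beyond Cβ, sequence–structure coupling, crystallographic noise
or energetic realism. Tests passing on fixtures therefore demonstrate the
pipeline's algorithmic correctness (metrics, contracts, determinism,
recovery of known geometry), not accuracy on experimental structures —
benchmark statistics on curated experimental template sets are a property
of the data, and must be measured there.

The ready-made benchmark set builds near-duplicate fixture pairs: twins
share MHC sequences up to 2 substitutions (so identity ranking pairs them)
and peptide/core geometry, except in two pairs where one twin carries one
extra C-terminal residue to exercise de novo flank building during
leave-one-out runs.

## Verification problem sizes

The shipped verification suite uses problem sizes chosen to exercise every
code path at desk scale: 100 randomized fixtures for metric-oracle
agreement; exhaustive alignment enumeration for all sequence pairs of
length ≤ 3 over a 4-letter alphabet plus a 100-pair seeded sample up to
length 6 (full exhaustion to length 6 is ~30 M pairs and adds no coverage);
a 10-fixture (5-pair) set for self-recovery and leave-one-out modelling
with 5-model ensembles; and 20-model ensembles for the default-contract
checks.

## Known limitations

* Side chains are not repacked; mutated residues carry only a Cβ stub.
* The receptor is never remodelled toward the target allele sequence.
* The pseudo-energy ranks conformers; it is not a binding-affinity
  estimate and should not be compared across different targets.
* The built-in pocket-profile core predictor is a deterministic stand-in;
  production use should supply anchors or wrap a real predictor through
  `CorePredictor` (a subprocess adapter contract: peptide + allele names
  in, 1-based core start out).
* The clash neighbor list is static (built from the start conformation);
  very large minimization displacements could in principle move atoms into
  unlisted contacts, which the step sizes of restrained relaxation make
  unlikely.
* Post-translationally modified peptides are out of scope beyond the
  parent-residue mapping.
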