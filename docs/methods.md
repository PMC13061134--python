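# Methods

This note records the models, conventions and numerical choices behind
`abageval`, and what the synthetic test bed does and does not establish.

## Aligned error and its aggregates

A backbone frame is built per residue from its N, CA, C atoms: origin at
CA, first basis vector along C−CA, second from Gram–Schmidt on N−CA,
third completing a right-handed set.  Residues missing a backbone atom,
or with N/CA/C collinear within 1e−6, carry no frame; they are dropped
from the aligned-error matrix (rows *and* columns, shrinking the
normalization N accordingly) but still participate in contact-based
scores through their remaining atoms.

The aligned-error matrix `e[i, j]` is the distance between the Cα of
residue *j* expressed in residue *i*'s frame in the query and the same
quantity in the reference.  It is non-symmetric, has a zero diagonal,
and is deliberately not capped: discretization into the 64 half-Ångström
bins (0–31.5 Å, open last bin) applies only to *predicted* error
distributions, never to errors computed from two structures.

aeTM takes the best row mean of the kernel `f(e, N)`; aeiTM excludes the
diagonal term and uses `N−1` both in the kernel and the normalization
(D_i = all residues except *i*).  An `interchain` variant restricting
D_i to residues on other chains — the AlphaFold-multimer ipTM
convention — is available behind a flag; the default follows the
all-but-self definition.  Excluding the diagonal is a genuine choice:
the printed summation range is ambiguous, but since `e[i, i] = 0`
implies `f = 1`, including it would shift aeiTM by exactly
`1/(N−1)`, and the all-but-self reading matches the normalization.
Ties in the maximizing residue go to the lowest row index.

Row sums are accumulated strictly left to right (via a cumulative sum)
rather than with numpy's pairwise blocked summation.  This makes the
vectorized implementation bit-identical to a scalar double-loop
evaluation of the definitions, which is how the test suite checks it;
the same reduction is shared by the predicted-confidence path, so a
point PAE equal to the true aligned-error matrix reproduces
aeTM/aeiTM/aeRankConf exactly rather than to rounding error.

## Predicted confidences

pTM/ipTM replace `f(e_ij)` by its expectation under the PAE: the kernel
at the point value, or the probability-weighted kernel at bin midpoints
(0.25, 0.75, …, 31.75 Å; the open last bin is represented by 31.75 Å —
edges are fixed by the producer, representatives are ours).  Ranking
confidence is `0.2 pTM + 0.8 ipTM`.

ipSAE uses 10 Å PAE and distance cutoffs.  For each aligning residue,
the kernel is summed over inter-group partners passing *both* cutoffs,
with d0 computed from the count of those qualifying partners, and the
row is normalized by the number of inter-group partners within the
distance cutoff alone.  The cutoff-independent denominator is a
deliberate choice: pairs failing the PAE cutoff contribute zero rather
than disappearing from the average, so tightening the PAE cutoff can
only lower the score — the monotonicity one expects of an interface
confidence.  The maximum over aligning residues is reported; an empty
interface scores 0 with a warning.

pDockQ2 applies the published sigmoid (L = 1.31, x0 = 84.733,
k = 0.075, b = 0.005) to x = ⟨pLDDT⟩ over interface residues times the
mean of `1/(1+(PAE/10)²)` over interface contacts, with contacts at
8 Å CB–CB (CA for glycine).  All constants live in config dicts
(`IPSAE_CONSTANTS`, `PDOCKQ2_CONSTANTS`) for auditability.

PAE region statistics treat the two off-diagonal chain-group blocks of
the matrix as Region1 (top right, with residues ordered
antibody-then-antigen) and Region2 (bottom left).  Because producers
differ in whether rows or columns index the aligning residue, the
naming is a parameter (`region1="top_right" | "bottom_left"`), not a
guess.  Correlations of constant rows are reported as missing (NaN),
never as 0.

## Geometry scores

DockQ follows the published component conventions — native contacts at
5 Å heavy-atom distance, iRMS interface at 10 Å, LRMS after superposing
on the receptor, scaling constants 1.5 Å and 8.5 Å — with all antibody
chains merged into the receptor entity and all antigen chains into the
ligand entity, yielding one score per complex.  Zero native contacts
set the fnat term to 0 with a warning; an interface too small to
superpose contributes 0 through an infinite iRMS.  Backbone atoms are
N, CA, C, O, using per-residue atom names present on both sides.

The TM-score is computed by iterative superposition: seeds from
contiguous fragments (full length, halves, quarters, 4-mers) and from
every per-residue frame superposition, each refined by re-superposing
on the residues within a decreasing cutoff schedule (8, 4.5, 2, 1 Å,
then d0) until the included set stabilizes; the score is the best
`(1/L_ref) Σ f(d_i, L_ref)` seen.  Including the frame seeds makes the
bound aeTM ≤ TM-score hold by construction, since aligning on one
residue frame is itself an admissible superposition.  Against direct
multi-start numerical optimization of the TM objective on small decoys
the heuristic agrees to better than 0.01.

## Chain mapping and cropping

Chains are paired by global sequence alignment (BLOSUM62, gap open 11 /
extend 1; identity = matches / alignment length including gaps) through
an assignment that maximizes total identity.  Identity ties — typically
several copies of an identical antigen — are broken by each candidate
pair's aligned-Cα RMSD after one whole-complex superposition anchored
only on *unambiguous* pairs (strict row and column maxima of the
identity table); remaining ties go to the earlier reference chain id.
Pairs below 30% identity are left unpaired, and a model with no pairs
at all scores near zero downstream, which is the intended treatment of
unalignable predictions.

Cropping keeps alignment columns with residues on both sides
(substituted columns are kept — cropping is by presence, not identity).
The reference copy adopts the query's chain ids and residue numbering so
that residue keys match position-wise.  Coverage is aligned residues
divided by the *original* query residue count; below 0.9 the pair is
flagged low-quality but still scored.  Cropping is idempotent and
retention is symmetric by construction.

## Benchmark construction

Records pass, in order: modality (X-ray/EM), resolution ≤ 3.5 Å,
peptide-antigen exclusion, missing fraction ≤ 10%, redundancy against
the pre-cutoff set, then single-linkage clustering under the same
redundancy relation.  Two records are redundant when the H, L *and*
antigen identities all exceed the threshold (0.80); an `any` rule is
available in config.  Multi-chain antigens are compared under a
maximum-identity assignment and the pair's antigen identity is the
highest assigned-chain identity — a shared antigen alone therefore
never disqualifies a complex with a different antibody.  Cluster
representatives minimize (total missing residues over H+L+antigen,
total antigen length, PDB id), in that order; summing the per-chain
missing counts is our aggregation choice.  Reason codes: MODALITY,
RESOLUTION, PEPTIDE_ANTIGEN, MISSING, BEFORE_REDUNDANT,
CLUSTER_DUPLICATE.

## Ensemble analyses

Sampling curves draw k models per target with replacement, 50
iterations by default, recording the DockQ of the sample's best model
and of its top-ranked (highest-selector) model, averaging over
iterations then targets; selector ties go to the lower model id.  A
closed-form companion computes the same expectations exactly from the
order statistics of sampling with replacement, `P(max ≤ v_(m)) =
(m/n)^k`, and is used to validate the bootstrap.  PconsDock diversity
averages pairwise DockQ over 20 random partners per model (full mode
optional; an oversized partner count falls back to all pairs).  The
ranking summary reports the mean DockQ of each target's top-ranked
model, the pooled Spearman R, and the unweighted mean per-target
Spearman with zero-variance targets excluded and counted.

## Synthetic data

The generator produces what the analyses need and nothing more:

* **Toy complexes** — chains of ideal backbone geometry (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å; helix −57/−47, strand −139/135, zigzag
  −120/120 torsions), each chain oriented along its principal axis and
  stacked in parallel with a prescribed gap, random sequences from the
  seed.  O and CB atoms are placed at idealized positions so
  contact-based scores have heavy atoms to work with.
* **Decoys** — the antigen group moved by an exact rigid transform plus
  optional isotropic jitter.  For a pure translation t the cross-group
  aligned-error block equals ‖t‖ exactly, giving analytic ground truth.
* **Synthetic PAEs** — the true AE plus zero-mean Gaussian noise
  truncated at zero (truncation, not reflection, keeps the code simple
  and the bias documented), as a point matrix or a delta distribution on
  the corresponding bin.
* **Planted ensembles** — DockQ drawn from a two-mode logistic-normal
  mixture (defaults: 10% "good" around 0.8, 90% "bad" around 0.05,
  matching the hard-target regime where few samples find the right
  interface) and a confidence column coupled through a Gaussian copula
  so the population Spearman correlation equals the requested value
  (Pearson latent correlation `2 sin(πρ/6)`); both marginals are
  strictly monotone transforms, so no rank information is lost.

What this establishes — and what it does not: the synthetic bed
verifies the scoring mathematics (exact oracles, analytic decoys,
closed-form expectations) and reproduces the qualitative phenomena
(best-vs-top-ranked gap, its growth with PAE noise, log-linear
best-of-N gains).  It does not emulate real prediction error modes —
PAE noise here is i.i.d. where real PAE errors are strongly structured,
decoys are rigid-body displacements without loop remodelling, and toy
interfaces are far smaller than antibody epitopes — so passing tests
validate the implementation, not any claim about prediction accuracy on
real complexes.

## Problem sizes and determinism

Default problem sizes keep every analysis interactive: toy complexes of
14+12 residues, fixture sets of a few targets with tens of models, and
planted ensembles of 10 targets × 200 models; `scripts/acceptance.py`
uses 4 targets × 24 models for the structure-based pipeline.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; CSVs are written with a fixed float format,
so repeated runs with one seed are byte-identical.

## Known limitations

* The TM-score is a heuristic optimizer; on pathological inputs
  (incoherent per-residue noise with no rigid core) it can undershoot
  the true optimum by more than the 0.01 observed on structured decoys.
* Nucleic-acid chains, ligands, covalent modifications and structure
  repair are out of scope; non-standard amino acids map to 'X' and are
  excluded from identity counts.
* pLDDT is read from the B-factor column only when the caller asserts
  the file is a prediction; there is no heuristic detection.
* CDR annotation and antibody numbering are not implemented; benchmark
  deduplication operates on whole-chain sequences.
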