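# Methods

This note documents the models and procedures implemented in `abag-eval`,
the parameters that matter, the numerical choices, and what the synthetic
generator does and does not emulate.

## Structure model and residue mapping

Structures are parsed with gemmi (PDB and mmCIF; author chain naming in
both dialects) into a minimal chain→residue→atom hierarchy keyed by
`(chain, author position, insertion code)`; no renumbering is performed.
Alternate conformers are reduced to the highest-occupancy one (tie: first
encountered). Hydrogens are retained in the model but excluded from every
distance computation by element symbol. Predicted models carry per-residue
pLDDT in the temperature-factor column; the CA atom is used as the residue
representative (predictors write one value per residue on all atoms), with
a mean over heavy atoms as the fallback for CA-less residues.

Model-to-reference residue correspondence is built per chain role by
global pairwise alignment of one-letter sequences (match +1, mismatch 0,
gap −1, via Biopython's `PairwiseAligner`). Identity is normalised by the
shorter sequence; below a floor of 0.6 the pairing is rejected as a
probable chain mis-assignment. Multi-copy antigens are assigned greedily
by best identity, ties broken by reference chain id — the assignment is
deterministic but is this package's convention, not a community standard.
Reference residues missing from the alignment (e.g. unresolved regions)
are simply absent from the mapping and therefore from every score term.

## Superposition

Rigid superposition uses the Kabsch SVD solution with reflection
correction (the smallest-singular-value axis is negated when the
determinant of the fitted matrix is negative), in double precision, all
distances in Å. Exactly collinear point sets are rejected because the
rotation about the common axis is undetermined. Tests cross-check against
scipy's independently implemented rotation fitting and a brute-force
rotation-grid search.

## Complex accuracy scores

Receptor/ligand convention: the antigen (all antigen chains pooled) is the
receptor; the antibody (heavy + light pooled) is the ligand.

* **Contacts / fnat.** A contact is any cross-partition residue pair with
  a heavy-atom pair at distance ≤ cutoff (inclusive; each unordered pair
  counted once). Native contacts use 5.0 Å in the reference; fnat is the
  fraction preserved by the model under the residue mapping. A reference
  with no contacts at 5 Å has no measurable interface and is an error.
* **I-RMSD.** Interface residues are reference residues of either side
  with any heavy atom within 10.0 Å of the partner. The model is
  superposed on the reference over the backbone atoms (N, CA, C, O;
  residues missing some backbone atoms contribute the atoms they have) of
  those residues, and the same atoms' RMSD is reported.
* **L-RMSD.** Superpose on receptor backbone, report ligand backbone RMSD.
* **DockQ.** `(fnat + 1/(1+(I/1.5)²) + 1/(1+(L/8.5)²))/3` with the
  standard scaling constants d1 = 1.5 Å, d2 = 8.5 Å.
* **CAPRI class.** High: fnat ≥ 0.5 ∧ (I ≤ 1.0 ∨ L ≤ 1.0); Medium:
  fnat ≥ 0.3 ∧ (I ≤ 2.0 ∨ L ≤ 5.0); Acceptable: fnat ≥ 0.1 ∧ (I ≤ 4.0 ∨
  L ≤ 10.0); else Incorrect. All boundaries inclusive.

## Interface pLDDT and model confidence

I-pLDDT is the unweighted mean of per-residue pLDDT over the union of
interface residues from both sides (each residue once), with interface
membership defined by any non-hydrogen atom within 4.0 Å of the partner.
When no residue qualifies the fixed floor value 30 is returned — this
keeps contact-free (grossly mis-docked) models at the bottom of the scale
rather than undefined. Averaging is per residue, not per atom, reading the
interface definition literally.

Model confidence is `0.8·ipTM + 0.2·pTM`, the standard weighting for
multimer predictors. Ranking is by descending model confidence with ties
broken by model label (reproducible under permutation); when pTM/ipTM are
unavailable the ranking falls back to I-pLDDT and says so in the record.

## CDR loop accuracy

AHo scheme positions define the regions (CDR1 24–42, CDR2 57–76, CDR3
107–138; everything else framework). Numbering is consumed as an external
table (chain, author residue key, scheme position), e.g. from ANARCI;
re-deriving it from sequence is out of scope, and the synthetic generator
emits a consistent table so tests need no external tool. Heavy and light
frameworks are superposed jointly as one rigid body (a per-chain fit would
hide relative domain shifts); each loop's backbone RMSD is then measured
in place. Insertions at a shared scheme position are ordered
alphabetically by insertion code.

## Annotations

* **Glycans.** A hetero residue is an interface-glycan hit iff its
  component code is in the saccharide set and any of its atoms lies
  within 4.5 Å of any antibody non-hydrogen atom. The shipped code set
  (NAG, NDG, BMA, MAN, FUC, GAL, GLC, SIA, XYS, BGC) is a configurable
  stand-in for the full chemical-component-dictionary "saccharide" class,
  which is not bundled.
* **TM-score.** `TM = max over superpositions of (1/L_ref) Σ 1/(1+(dᵢ/d0)²)`
  over mapped CA pairs, `d0 = 1.24·(L_ref−15)^⅓ − 1.8` floored at 0.5 Å,
  normalised by the reference (target) length. The maximisation is a
  deterministic heuristic: seeds from the full-length least-squares fit
  plus all sliding windows of lengths 4, L/2 and L, each refined by
  refitting on residues with dᵢ < d0 until the inlier set stabilises
  (≤ 20 iterations). The full-length seed guarantees the result never
  falls below the RMSD-optimal superposition's score; on desk-scale
  inputs the heuristic matches exhaustive window enumeration.
* **Neff.** Effective sequence count = number of clusters under greedy
  incremental clustering: rows ordered longest-ungapped-first, each row
  joining the first founder with full-row identity ≥ 0.80, else founding
  a cluster. Gaps (`-`, `.`) are replaced by `U` before identity
  computation, so shared gap columns count as matches. This mirrors
  greedy CD-HIT-style clustering but does not replicate CD-HIT's word
  filters, so absolute cluster counts on real MSAs are approximate;
  planted cluster structure is recovered exactly.

## Benchmark curation

Rules are applied in order — basic (resolution ≤ 3.0 Å inclusive; release
date strictly after the cutoff, default 2018-04-30), length filters,
sequence redundancy, structural redundancy — and the first failing rule is
the one cited; manual exclusions are an explicit id list, not a rule.
Candidates are processed in (release date, entry id) order and survivors
join the comparison pool, which makes the surviving identity set
independent of input order and the whole procedure idempotent.

Choices where the rules needed operationalising: identity denominators are
the shorter sequence; the "antigen sequence match" is a local alignment of
length ≥ 30 with ≥ 30% identity (a conservative stand-in for a
default-parameter BLAST hit); the three structural-redundancy identities
(heavy, light, concatenated CDRs) are OR-ed; length-filter fractions use
the SEQRES length as denominator; antigen superposition for the structural
check uses all mappable antigen chains. An unbuildable antigen
correspondence yields "keep" with a warning, since redundancy cannot be
proven.

## Reporting

Success rate at (N, level) = percentage of complexes with at least one
model of rank ≤ N at that CAPRI level or better; levels are ordered
Incorrect < Acceptable < Medium < High. AUC uses the rank-sum (midrank)
formulation, exactly `P(s⁺ > s⁻) + ½P(tie)`. The multi-class summary is
the unweighted macro average of one-vs-rest AUCs, each taken as the
direction-free `max(AUC, 1−AUC)` because a single monotone quality score
cannot be oriented consistently for middle classes; the binary columns
(Incorrect vs High, Incorrect vs Medium-and-High) are the interpretable
ones.

## Synthetic data: what it emulates and what it does not

The toy complex is an idealized backbone-only (N, CA, C, O) helix-like
chain of 149 antibody residues (scheme position = author position, so all
CDR ranges are populated), with the antigen chain running parallel to the
CDR3-containing segment at a fixed 3.9 Å offset — inside both the 4.0 Å
confidence and 5.0 Å contact cutoffs, giving a well-defined native
interface of ≳ 100 residue contacts. Sequences are random per seed, making
alignment-based mapping unambiguous. The optional light chain is placed
away from the antigen.

Decoys move the antibody rigidly: translations default to the chain axis
so that native contacts decay gradually through register shifts (a
translation directly away from the antigen destroys all contacts within
~1 Å, collapsing the class spectrum), plus optional rotations about an
axis through the antibody interface centroid and optional Gaussian noise
on CDR atoms. For noise-free rigid decoys the planted antibody backbone
RMS displacement equals the measured L-RMSD exactly, which is the
generator's strongest ground truth. pLDDT is planted as
`clip(95 − 1.5·error + N(0, 4), 0, 100)` per residue — the simplest
mechanism that reproduces the qualitative confidence–accuracy association;
the slope, base and noise are not calibrated to any predictor. Planted
pTM/ipTM follow the same linear-with-noise pattern on the [0,1] scale.

MSAs are generated from a shared base sequence: cluster centres carry
`L·(1−√between)` substitutions (pairwise centre identity ≈ between), and
members carry exactly `round(L·(1−within))` substitutions from their
centre, which the centre-first row order turns into exact greedy
recovery. Glycans are placed along the chain axis beyond the antibody's
extremal atom, where the nearest-atom distance equals the target exactly.

None of this resembles real protein geometry: no side chains, no
secondary-structure packing, no realistic antibody fold, no predictor
internals. Passing tests therefore demonstrate the correctness of the
*measurement* pipeline (contacts, superpositions, thresholds, clustering,
aggregation) under controlled truth — not performance claims about any
structure predictor on real complexes.

## Problem sizes and determinism

Default cohorts are 10 complexes × 25 decoys (the package's desk-scale
analogue of a benchmark run); the oracle-equivalence tests use 54 decoys
over three complexes. All generators take integer seeds and use one
`numpy` Generator per call; per-complex sub-seeds are drawn below 2³¹.
Repeated runs with the same seed produce bit-identical structures,
manifests and scores.
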