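# Methods

## Descriptors

An atomic site is described only by its 2D environment: the circular
fingerprint at bond depth `d` counts SYBYL atom types in shells of exact
topological distance `k = 0..d` (breadth-first bond counts). The vector is
layer-major over a fixed, lexicographically sorted type alphabet built from
the training corpus; the alphabet is persisted with every dataset and model
because it defines the meaning of each feature index. Layer 0 is the centre
atom itself (always sums to 1) and layer `k` sums to the size of the
distance-`k` shell — an invariant the tests check against independent BFS
shell censuses. Atoms in other connected components of a salt entry are
unreachable and contribute nothing. An atom type absent from the alphabet
raises rather than being silently folded, since it signals a corpus
mismatch; extending the alphabet with zero-history columns is the caller's
explicit decision.

Candidate (rankable/labelable) sites are heavy atoms by default: hydrogen
abstraction is attributed to the attached heavy atom, while hydrogens still
contribute counts inside every fingerprint. `include_h_sites=True` lifts
the restriction.

## Classifiers

All three classifiers estimate `p(x|ω_α)` for the SoM/non-SoM classes and
form equal-prior posteriors. Numerical choices:

- Conditionals are carried in the **log domain** end to end. The NB product
  over up to hundreds of features underflows doubles otherwise; the PRW
  mean uses a log-sum-exp so that a distant test vector (all kernel terms
  tiny) still yields a finite, comparable log density. The Gaussian
  normalisation constant cancels between classes but is included for
  fidelity to the density definition.
- PRW bandwidth defaults to `h = 0.1` on the raw integer counts, with no
  feature scaling. At integer-valued inputs this makes the kernel extremely
  sharp: PRW behaves like exact matching with a nearest-neighbour fallback,
  which is precisely what makes it robust where pure matching fails.
- The Dirac-kernel (RASCAL) conditional can be exactly zero in both
  classes. That posterior is flagged *undetermined* and set to 0.5/0.5; in
  the ensemble the subclassifier then casts half a vote for each class,
  preserving vote-count normalisation without biasing either class.
- An exact posterior tie inside a determinate subclassifier goes to the
  non-SoM class by default — the conservative direction for a SoM call —
  and the policy is configurable and deterministic.

## Ensembles

One subsample set of `j` feature index draws (each `q` distinct indices,
uniform without replacement; duplicate sets across the `j` draws allowed)
is drawn per trained ensemble and shared across all test sites. Training
items are never subsampled, and duplicate training vectors are retained —
they carry frequency information for both the NB counts and the kernel
means. The ensemble SoM probability lives on the grid of multiples of
`1/(2j)`. `q="full"` runs a single subclassifier over all `L` features,
the natural mode for PRW and NB, whose performance plateaus with `q` and
gains little from subsampling.

In leave-one-out evaluation each fold's subsamples are redrawn from a seed
derived deterministically from the master seed and the fold index (via
`numpy.random.SeedSequence`), so runs are bit-reproducible while folds stay
decorrelated.

## Evaluation protocol

Cross-validation is at the molecule level: all sites of the held-out
molecule leave the training pool together (asserted in the fold iterator).
Molecules with no SoM annotation are never held out — their SoM status is
unknown — but always contribute non-SoM training sites. Pooled over folds:

- **MCC** at the majority-vote operating point (probability > 0.5 → SoM;
  an exact half-vote tie is called non-SoM). Zero denominator → 0.
- **ROC/AUC** by threshold sweep over the achieved probability grid plus
  endpoints, trapezoidal integration, one pooled curve over all folds.
  Ties in probability are resolved by the sweep itself, making the AUC
  equal to the half-credit Mann–Whitney U statistic (tested).
- **top-k%** after collapsing equivalent atoms. Equivalence is identical
  whole-ligand fingerprints, computed at depth = graph diameter (the
  smallest depth guaranteed to span the ligand). Equivalent atoms share
  fingerprints, hence probabilities — asserted, not assumed. Ranking ties
  break by ascending representative atom index, deterministically.
  Equivalent sites in *training* are retained as separate records; the
  collapse applies to predictions only.

When evaluation starts from a site-dataset TSV alone (no structures), the
equivalence collapse is proxied by identical depth-`d` feature vectors
within a molecule — coarser than whole-ligand fingerprints whenever `d` is
below the graph diameter.

The similarity split draws a seeded random 20% test set (TS1), scores each
TS1 molecule by its maximum Tanimoto similarity to any training molecule
over linear atom-type path sets (paths up to 7 bonds, canonicalised to the
smaller of forward/reverse reading), and takes the least-similar half as
TS2. Path-set Tanimoto was chosen as a toolkit-independent whole-molecule
similarity in the same spirit as standard path-based fingerprints.

## Synthetic corpora

The generator emulates what the method needs from real substrate sets —
small typed graphs, integer layered count vectors, and a local structural
signal separating SoM from non-SoM sites — and nothing more. Graphs are
uniform random spanning trees plus Binomial chord edges, degree-capped at
4; types are i.i.d. from a 6-type SYBYL-like alphabet. The planted motif of
the default study conditions is "≥ 1 N.3 at distance 1 and ≥ 1 O.2 at
distance 2" with a *wildcard* centre type, and labels are deterministic
(motif probability 1, background 0) in a 60-molecule corpus of 10–16-atom
molecules.

Two consequences are deliberate. First, the motif is a function of shells
1–2 only, so it is exactly expressible in fingerprint space at depth ≥ 2
and *invisible* at depth 0: with i.i.d. types, an atom's own type is
independent of its neighbourhood, so depth-0 fingerprints carry zero class
information and depth-0 classifiers sit at chance by construction (the
type-balanced-centres property). Second, deterministic labels isolate the
descriptor-depth effect: the recovery studies measure whether the machinery
finds an encodable signal, not its robustness to label noise. Both motif
and background probabilities are free config fields; the label-frequency
convergence test exercises the stochastic regime (0.9/0.05).

What the synthetic corpora do **not** model: valence rules beyond a degree
cap, aromaticity, hydrogen counts, realistic SYBYL type co-occurrence, or
real CYP regioselectivity chemotypes. Passing the synthetic studies shows
the pipeline is correct and the depth/subsample behaviours are as designed;
it does not certify predictive performance on real substrate sets, which
requires the curated per-isoform datasets (importable via the site-dataset
TSV dialect; the reference-reproduction test picks them up under
`data/cyp/`).

## Problem sizes

The shipped studies use 60 molecules (≈ 770 sites) with `j = 51`, `q = 5`
at depths 0 and 2 for signal recovery, and 40 molecules at depth 4
(`L = 30`, `j = 33`) for the subsample-length scan — sizes chosen so the
full pipeline runs in seconds while keeping ≈ 50 evaluable molecules per
study, enough for top-k percentages with ~2-point granularity. `j = 201`
remains the library default for production use, where vote-fraction
stability matters more than wall time.

## Known limitations

- Binary classification only (SoM vs non-SoM); no per-reaction-type calls.
- No protonation-state assignment: mol2 inputs are taken as given.
- The whole-ligand equivalence depth recomputes fingerprints at the graph
  diameter per molecule, which is quadratic in atoms — fine for drug-sized
  ligands, wasteful for polymers.
- Equivalence by fingerprint identity can in principle be coarser than
  graph automorphism on pathological regular graphs; for drug-like graphs
  and the shipped corpora it matches a brute-force automorphism oracle.
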