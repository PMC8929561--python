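# Methods

## Model

`timenet` represents a protein structure as a network whose nodes are
atoms or atom groups (residues by default) and whose edges are physical
interactions — carbon contacts and hydrogen bonds — each carrying a
*timeline*: one nonnegative integer interaction count per frame of a
structure ensemble (an NMR bundle, extracted MD snapshots, or a single
structure, in which case every timeline has length one).  Atomistic
timelines are binary indicators X_{αβk}(t) ∈ {0,1} for atom pair (α, β)
and interaction type k; group-grain timelines are frame-wise sums of the
member atomistic timelines, X_{ijk}(t) = Σ_{α∈i} Σ_{β∈j} X_{αβk}(t), so
aggregation conserves per-frame interaction counts between any two
groups and is invertible while the atomistic records are retained
(`split_node`).  The per-type adjacency A^k is symmetric and zero on the
diagonal.

## Information scores

The premise is that an allosterically active residue must be
conformationally coupled to its environment, and that this coupling is
visible as shared information between the timelines of nearby
interactions.

* **ECF** of edge (i, j, k) is Σ I(X_{ijk}; X_{nml}) over neighboring
  edges: those sharing at least one endpoint with the focal edge.  Each
  single-endpoint neighbor counts once, a parallel edge (same endpoints,
  different type) counts once, and the focal edge's self-information is
  excluded.  The neighbor-selection indicator is formally
  χ = δ_in + δ_jm − δ_in·δ_jm·(δ_kl + 1) evaluated over ordered node
  pairs with symmetric A^l; the production code uses the equivalent set
  formulation, and the literal ordered-pair enumeration survives as the
  independent test oracle.
* **NCF** of node i is the sum of ECF over its adjacent edges; each edge
  contributes its full ECF to both endpoints.
* **DNCF** replaces every mutual-information term by the difference
  between the target network's term and the matching edge pair's term in
  a reference network (e.g. peptide-bound vs apo).  Edges are matched by
  (endpoint identities, interaction type).  Reference-only edges never
  contribute; a target edge without a reference partner contributes its
  full target MI (its reference pair is treated as constant).  The score
  is therefore asymmetric under swapping target and reference whenever
  unmatched edges exist, and exactly sign-flips when topologies are
  identical.

Mutual information is the plug-in (maximum-likelihood) estimate over the
raw integer states, in log base 2 (bits): no binning, no bias
correction.  Because the difference sum over the union state alphabet
separates, DNCF terms are computed as I_target − I_reference with each
distribution estimated within its own network; target and reference
frame counts may differ.  The plug-in estimator's finite-sample bias,
approximately (|X|−1)(|Y|−1)/(2T ln 2) bits for independent timelines,
is left in place and characterised by permutation tests; scores are
reported in raw bits without min-max normalization so that absolute
thresholds in bits remain meaningful.

## Centralities

BC and CPLC are single-structure scores; multi-edges and timelines are
first collapsed to an unweighted simple graph (an edge wherever any
interaction type connects a pair in at least one frame), deliberately
ignoring interaction magnitude.  Betweenness sums, over unordered node
pairs excluding the focal node, the fraction of shortest paths passing
through it (computed via networkx; verified against exhaustive path
enumeration).  The characteristic path length L is the mean
shortest-path distance over *connected* unordered pairs; CPLC_i = L −
L_i after deleting node i.  Excluding disconnected pairs (rather than
assigning infinite distances) keeps CPLC finite when a deletion splits
the graph; the alternative convention that scores disconnecting
deletions zero is exposed as `on_disconnect="skip-node"`.  Both scores
are min-max normalized across nodes, with an all-equal vector mapping
to all zeros.

## Interaction extraction and formats

Contacts: all carbon-atom pairs in different residues, binary per frame
at Euclidean distance ≤ cutoff (default 5 Å, the upper edge of
attractive van-der-Waals range); no sequence-neighbor exclusion by
default (configurable).  Hydrogen bonds: fixed N/O/S donor/acceptor
tables for the 20 standard amino acids (backbone N donates except in
proline; backbone O and OXT accept), heavy-atom distance ≤ 3.5 Å and
donor–H–acceptor angle ≥ 135°, with hydrogens attached geometrically
(same residue, ≤ 1.25 Å, first frame).  Ensembles without hydrogens
fall back to distance-only detection and every such record is flagged
`distance-only` rather than silently accepted.  Unknown residue types
contribute contacts only.

The sidechain/backbone split uses the standard convention backbone =
{N, CA, C, O, OXT and backbone hydrogens}; CB is sidechain and glycine
has none.  Occupancy filtering keeps edges present (count > 0) in at
least the stated fraction of frames.  `residue_network` applies
occupancy/type/sidechain filters at atom grain *before* aggregation, so
a sidechain-exclusive residue network sums only sidechain–sidechain
atomistic timelines.

Timelines are exchanged in a line-oriented text format (versioned
`#AIF` header, frame count, one record per line with source atom,
target atom, type, flags and comma-separated counts); the format is a
documented dialect of this package, byte-compatibility with other
tools' files is not claimed.  Per-frame series tables from trajectory
hydrogen-bond and native/non-native contact analyses are parsed from a
whitespace-separated dialect with interaction names in the header row;
native and non-native columns for the same pair merge by frame-wise
maximum (logical OR for binary series).

## Evaluation

Score tables are benchmarked against binary residue labels by sweeping
every distinct score as a threshold with closed-≥ semantics (ties enter
together), plotting FPR/TPR (ROC) and recall/precision (PR), and
integrating by the trapezoidal rule.  The PR curve is anchored at
recall 0 with the precision of the strictest threshold — no
extrapolated precision-1 point.  Higher score means predicted
allosteric for all methods.  Residues scored but not labeled are
ignored (reference sets typically cover a subset of residues);
labeled-but-unscored residues are an error.  The operating threshold is
the ROC point closest to (FPR 0, TPR 1), ties broken toward the
stricter threshold.  The grid-search harness enumerates the canonical
6 contact cutoffs (4–9 Å) × 2 interaction subsets × 4 structure sources
= 48 configurations per scoring method and reports per-group mean/SD
summaries; missing configurations are flagged, never dropped.

## Synthetic data

Three seeded generators (single `numpy.random.Generator` per call, no
global state) define the package's test conditions:

* **Coupled timeline pairs** — master Bernoulli(occupancy) series; the
  partner copies the master per frame with probability `coupling`, else
  redraws independently.  Coupling 1 duplicates the master (I = H);
  coupling 0 leaves only plug-in bias.  Defaults T = 2000, occupancy
  0.5, coupling 0.8.
* **Planted-hub networks** — an 8-node ring of independent-timeline
  contact edges plus a hub wired to 4 ring nodes by noisy copies of one
  master series.  At the default coupling 0.8 and T = 2000 the hub's
  edges share information pairwise while ring edges do not, so the hub
  should top the NCF ranking; the recovery-rate experiment uses 100
  seeded replicates.
* **Toy coordinate ensembles** — a chain of pseudo-glycines spaced 12 Å
  apart with exactly two designed interactions: a CB–CB contact
  oscillating across the 5 Å cutoff (4.5 Å vs 6.5 Å) and a backbone
  N–H···O hydrogen bond at fixed 2.9 Å whose angle swings across the
  135° cutoff (≈157° vs ≈100°), both on a known on/off schedule.  CA
  atoms carry 0.05 Å Gaussian jitter, far too small to cross any
  boundary.

These fixtures emulate coupling structure and interaction geometry, not
real protein energetics: there is no force field, no correlated
backbone motion, no solvent, and timeline marginals are stationary
Bernoulli rather than the bursty, autocorrelated occupancy patterns of
real MD interactions.  Passing tests therefore demonstrate algorithmic
correctness (estimators, bookkeeping, conventions) and signal recovery
under controlled coupling — not predictive accuracy on real proteins.

## Numerical choices

Plug-in MI values are clamped at 0 against floating-point round-off;
probabilities are exact ratios of frame counts.  Edge iteration is
always in canonical (lexicographic endpoint, then type) order so scores
are bit-reproducible.  Min-max normalization maps degenerate all-equal
vectors to zeros.  Autocorrelation of a timeline is Pearson r between
the series and its lag-shifted copy and is reported as flagged-NaN when
either overlapping segment is constant; mean lifetime is the average
length of maximal runs of consecutive nonzero frames (NaN for all-zero
timelines).  These four per-timeline summaries are repo-defined
conveniences.

## Problem sizes

The oracle-equivalence suites use 200 random networks of ≤ 8 nodes,
≤ 3 interaction types and ≤ 50 frames for ECF/NCF/DNCF, and 200 random
graphs of ≤ 9 nodes for BC/CPLC — sizes at which literal enumeration of
the defining formulas is exact and fast.  The parameter-recovery
experiment runs 100 replicates at T = 2000, coupling 0.8.  The
acceptance script (`scripts/acceptance.py`) re-runs these experiments
plus the end-to-end toy-ensemble pipeline at the same sizes.

## Known limitations

* The published PDZ2 worked examples (final-model AUC values, the
  6.17-bit core-set threshold, and the single-structure CPLC
  replication from the peptide-bound NMR entry) require the published
  supplementary label/score tables and the RCSB structure, which are
  not redistributable inside this repository; the corresponding checks
  in `tests/test_acceptance.py` fail with instructions until those
  files are placed under `data/pdz2/`.
* Hydrogen-bond detection does not place missing hydrogens; crystal
  structures without protons are handled by the flagged distance-only
  fallback.
* No trajectory binary formats (DCD/XTC/NetCDF); ensembles enter as
  multi-model PDB or as per-frame series tables.
* BC/CPLC are defined on the collapsed unweighted graph; no weighted or
  flow-based centralities.
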