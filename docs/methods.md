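# Methods

This note records the models, conventions and numerical choices behind
`protclass`, the assumptions each one carries, and what the synthetic
benchmarks can and cannot demonstrate.

## Sequence handling

Sequences are upper-case strings over the 20 canonical amino-acid letters.
Unaligned input is sanitized on read: ambiguity codes and rare letters
(B, Z, J, U, O, X), stop marks and stray gaps are removed and counted (the
count is logged), because every descriptor below is defined only on the
canonical alphabet.  A record that becomes empty is rejected.  Alignments
keep `-` gaps and must be rectangular.  Gene tables locate genes by an
integer order index per replicon: the neighborhood analyses work in units
of *genes*, not base pairs, so coordinates are deliberately abstracted
away.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment use
BLOSUM62 with affine gap penalties, gap open 10 and gap extend 1 (the
first gap residue costs 10, each further residue 1); matrix and penalties
are configurable.  End gaps are penalized in global mode.  Identity and
positive fractions are computed over the full alignment length including
gap columns; a column is *positive* when both residues are present and
their substitution score exceeds zero.  Because co-optimal tracebacks are
not unique, the argument pair is canonically ordered before traceback, so
results are deterministic and exactly symmetric under operand swap (the
optimal score is unique regardless).  With this convention a local
alignment's identity is measured only over its own span — a short exact
match reports identity 1.0 — which makes the rule-based "cutoff score"
baseline deliberately permissive; the learned classifier is the method of
interest.

`selfalign(a, b) = (S(a,b)/S(a,a) + S(a,b)/S(b,b))/2` uses raw global
scores, is 1 for identical sequences, and is clamped to [0, 1] (unrelated
pairs can score negatively under gap penalties).  Written in terms of
scores rather than identities, the statistic is a symmetric, length-aware
similarity; candidates below the 0.2 gate are reported as
`not-candidate` and never classified.  Gated-out records count as negative
calls when metrics are computed, since the gate is part of the method's
answer.

## Feature vector (39 values, fixed order)

Order: 20 residue fractions (alphabetical) · 5 functional-group fractions
· length · selfalign vs consensus · global identity · global positive ·
local identity · local positive · pI · charge · nominal mass · aromaticity
· instability · GRAVY · entropy · energy.

- **Functional groups.** Positively charged {K,R,H}, negatively charged
  {D,E}, polar uncharged {S,T,N,Q,C,Y}, nonpolar aliphatic
  {G,A,V,L,I,P,M}, aromatic {F,W,Y}.  Groups may overlap (Y is polar and
  aromatic); each contributes its own fraction.  Any residue-partition of
  similar granularity would serve; this one covers all 20 letters with
  five chemically conventional classes.
- **pI and charge.**  Henderson–Hasselbalch occupancies over the ionizable
  groups with a pinned EMBOSS-style pK table (N-term 8.6, C-term 3.6,
  K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1; configurable).  Net
  charge is strictly decreasing in pH, so the pI is the unique zero
  crossing, found by bisection on [0, 14] to 1e-4 pH units.  Charge is
  reported at pH 7.2, a typical intracellular value.
- **Nominal mass.**  Integer nominal residue masses summed plus 18 for one
  water; an integer mass scale, not a monoisotopic or average mass.
- **Aromaticity, GRAVY, instability.**  Standard Lobry, Kyte–Doolittle and
  Guruprasad definitions, delegated to Biopython's ProtParam.  An
  instability index above 40 flags a protein as unstable in reports.
- **Co-occurrence entropy/energy.**  A 9-residue window slides along the
  sequence (step 1); each window is read right-to-left and filled row-major
  into a 3×3 grid; each horizontally adjacent grid pair increments a
  20×20 ordered-pair count.  Counts normalize to probabilities p, with
  energy = Σp² and entropy = −Σ p·log₂p.  The grid geometry (fill
  direction, horizontal-only adjacency) is a pinned dialect: several
  reasonable conventions exist, all yielding second-order texture
  statistics of equivalent discriminative character, so one is fixed and
  documented rather than made configurable.  Sequences shorter than 9
  residues get (0, 0) with a logged warning instead of an error, so
  genome-wide scans never abort on fragments.

## Consensus and conserved-domain patterns

The consensus region keeps columns with ≤ 50 % gaps and takes each
column's majority residue, ties broken alphabetically; conservation is
majority count over non-gap count.

The pattern deriver is a transparent, conservative substitute for a motif
discovery tool.  A column whose non-gap fraction is ≥ `min_conservation`
(default 0.9) emits a fixed residue (one residue observed) or the class of
all observed residues; maximal runs of the remaining columns emit one
bounded wildcard `x(m,n)` with m/n the per-row non-gap run lengths
(edge runs trimmed).  With `refine=True` only the longest contiguous run
of element columns whose *majority* conservation also clears the threshold
is kept.  Refinement matters because a full-length pattern over a family
with uniform residue-level divergence is the conjunction of many
slightly-leaky positions and matches almost nobody; real conserved domains
are short and nearly invariant, and the refined motif has that shape.  The
pipeline and benchmarks use `refine=True` with threshold 0.95.

Matching compiles the PROSITE-style elements to a regular expression:
matches are the leftmost non-overlapping ones under greedy wildcard
expansion, and a protein "has the domain" iff it matches anywhere.  The
random-occurrence probability of a pattern multiplies |allowed|/20 per
element under an i.i.d. uniform-residue model; a variable repeat
contributes its most permissive expansion (minimum repeats of a
restrictive element), making the figure an upper bound on the per-window
match probability.

## Classifier

Training sets follow the discovery protocol: gate at selfalign ≥ 0.2,
label pattern matchers 1, and take an equal number of the lowest-selfalign
non-matchers as class 0.  Balancing is a choice — the background pool in a
real screen is enormous, and an unbalanced set would reward the degenerate
always-negative answer.  Multiclass sets (one label per family, 0 for
background) can also be built from external truth labels.

The network is scikit-learn's MLPClassifier pinned to: one hidden layer of
⌊(n_features + n_classes)/2⌋ logistic units, plain SGD with constant
learning rate 0.3 and momentum 0.2, 500 epochs, no regularization, no
early stopping, fixed random state — i.e. the classical
"-L 0.3 -M 0.2 -N 500 -H a" configuration of Weka-style MLPs.  Features
are standardized to zero mean / unit variance on the training data and the
constants stored with the model.  A trained model serializes to a
self-contained JSON document (weights, scaler, class names); prediction is
a pure forward pass over the stored weights, so a saved model reproduces
its probabilities exactly.

Evaluation: binary confusion counts with sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy, reported as percentages rounded half-up
to 2 decimals; multiclass reports per-class accuracy (hits/curated) and
their mean.  Three rule-based baselines are provided: local identity >
0.30 AND local positive > 0.50 vs the consensus; conserved-domain match;
and their conjunction.

Train/test protocol: the package defaults to a stratified 70/30 split with
a fixed seed when a held-out estimate is wanted; k-fold cross-validation
can be layered on externally (the training function is a pure function of
the training set and seed).

## Co-occurrence and neighborhoods

Presence is boolean per (genome, gene).  For 0/1 columns the Pearson
correlation equals the phi coefficient of the 2×2 contingency table;
p-values come from the t distribution with n−2 degrees of freedom.  At
least 3 genomes are required; pairs involving a constant column are
reported missing with a warning.  The neighborhood scan counts, for every
focal-gene locus, the gene labels within ±window (default 5) order indices
on the same replicon, one count per (focal locus, neighbor locus) pair —
a genome with two focal copies contributes from both.  Windows truncate at
replicon ends and never cross replicons; plasmid replicons participate
unless the caller filters them out.

## Synthetic benchmarks

`generate_family` mutates a seed sequence i.i.d. per residue (uniform over
the 19 alternatives) with optional indels; an optional *conserved region*
is exempt from mutation, emulating active-site-style conservation — the
very property that makes short conserved domains discoverable.  Decoys are
i.i.d. residue strings.  `make_benchmark` mixes k families (labels 1..k)
with decoys (label 0) and builds a per-family MSA by star alignment of a
20-member subsample against the seed ("once a gap, always a gap").

Default study conditions used across tests and the acceptance script: 6
families × 50 members, per-residue substitution rate 0.10, seed length
120 with an invariant core at positions 40–64, 300 decoys of length
100–140, all driven by fixed integer seeds.  The binary discovery setting
adds 60 "distant relatives" at rate 0.5 (no conserved core) so that the
negative class contains gate-passing look-alikes, as a homology-search
hit list would.

What these benchmarks do **not** emulate: phylogenetic correlation between
family members (no tree, every member is an independent draw), rate
heterogeneity along the sequence outside the hard-conserved core,
compositional bias of real proteomes, and annotation noise.  Passing the
recovery tests therefore shows the pipeline is correct and internally
consistent — features separate what they should separate, the network
trains deterministically, the gate and pattern behave as specified — not
that the same accuracy would hold on any particular real protein family.

## Known limitations

- The pattern deriver is intentionally simple; it assumes the conserved
  region is contiguous in the MSA and will truncate a domain interrupted
  by a long insertion.
- The local-alignment identity convention makes the cutoff-score baseline
  weak (see above); it is kept for protocol parity, not as a serious
  competitor.
- selfalign is clamped at 0, so ranking among completely unrelated
  sequences is arbitrary (they tie at 0).
- The MLP hyperparameters are pinned, not tuned; on harder benchmarks a
  lower learning rate would likely help, but comparability of the pinned
  configuration was preferred.
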