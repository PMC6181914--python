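# Methods

## The problem and the approach

Cation/proton antiporters (CPAs) exchange Na⁺ or K⁺ for one or two protons.
Three phenotypes organise the superfamily: the CPA1/CPA2 division, the
electrogenic/electroneutral distinction (two protons per cation versus one),
and Na⁺/K⁺ selectivity. Because the family is highly diverse in sequence,
phenotypes are predicted here not from overall similarity but from an
eight-position motif of conserved polar/charged residues clustered around
the ion-binding site, plus one auxiliary TM-3 position. The package covers
the full workflow that produces and applies such a motif at desk scale:
pre-processing filters, profile-HMM alignment, distance-based phylogenetics,
tree-aware conservation scoring, discriminating-column discovery, rule-based
classification, and structural distance checks — with a seeded synthetic
generator standing in for a database-scale sequence pool.

## Substitution model and rates

All likelihood computations use the Le & Gascuel (LG) empirical amino-acid
model: the packaged exchangeabilities and equilibrium frequencies define a
reversible rate matrix normalised to one expected substitution per site at
equilibrium, and transition matrices come from the symmetric
eigendecomposition (a Poisson model is available as a fallback). Site-rate
heterogeneity is a mean-one gamma: the discretisation uses equal-probability
categories with conditional-mean rates (Yang's scheme), computed from the
regularised incomplete gamma function so that the categories average exactly
to one.

Per-column conservation is the empirical-Bayes posterior-mean rate: the
gamma shape α is chosen on a fixed grid (0.2–5.0, 25 points, 8 categories by
default) by maximising the summed log-likelihood under Felsenstein pruning;
a column's rate is then Σ r·L(r)/Σ L(r) with equal category priors, and
rates are renormalised to mean one over scorable columns. Gaps and X are
missing data (uniform partial likelihoods); all-gap columns are flagged and
excluded from normalisation. Rates are binned into nine equal-frequency
grades, 9 = most conserved; equal-frequency binning is a deliberate,
deterministic surrogate for ConSurf's scheme, and ties resolve by column
index.

## Pre-processing filters

The length screen drops sequences under 300 residues (too short to span the
NhaA fold). Redundancy clustering is a greedy CD-HIT surrogate: records
sorted by decreasing length, each joining the first representative with
global-alignment identity ≥ the threshold (matches / alignment length,
Needleman–Wunsch with BLOSUM62, gap open 10 / extend 1). CD-HIT's exact
identity denominator and k-mer short-circuiting are not reproduced; only
the clustering contract is. The essential-coverage screen keeps a query iff
its profile alignment covers ≥ 70% of the essential match columns *and*
aligns the column carrying motif position 7 — the TM-5 aspartate that no
functional CPA lacks.

## Profile HMM

The profile is built from a seed alignment: columns with gap fraction ≤ 0.5
become match states; match emissions are count-plus-background-pseudocount
(weight 1.0 per column); transitions are counted from each row's implied
state path with Laplace smoothing. The model has the seven plan-style
transitions (M→M/I/D, I→M/I, D→M/D) plus begin/end — no I↔D moves, no
multi-hit mode. Alignment is glocal Viterbi: the whole profile must be
traversed while flanking query residues are free; insert states emit at
background odds (zero bits). Viterbi was chosen over posterior decoding for
exact testability: the best path is verified against exhaustive path
enumeration on small profiles. Scores are log-odds in bits and are used for
ranking only; there is no E-value calibration.

## Phylogenetics

Pairwise distances are one-dimensional ML optimisations under LG on the
pattern counts of each pair (gap sites excluded pairwise, pattern matrix
symmetrised for reversibility), capped at 3.0 substitutions/site. Trees are
canonical Saitou–Nei neighbor joining with a lexicographic tie-break on the
Q criterion; negative branch lengths are clamped to zero and logged. NJ here
deliberately replaces large-scale ML tree search: at desk scale what matters
is algorithmic correctness (NJ provably recovers additive matrices, which
the suite verifies on random trees, alongside a cross-check against an
independent NJ implementation), not reproducing a 6000-leaf topology.

Bootstrap supports resample alignment columns with replacement, rebuild the
NJ tree per replicate, and annotate each internal edge of the base tree with
the fraction of replicates containing its (canonicalised) split. A per-leaf
instability report (how often a leaf's base-tree splits vanish across
replicates) is provided as a rogue-taxon diagnostic only.

Phylogenetic diversity (PD) of a leaf subset is the total branch length of
its spanning subtree; subset selection is the classic greedy: start from the
diameter pair, repeatedly add the leaf with the largest PD gain
(lexicographic tie-break). Greedy is provably optimal for PD on trees, and
the suite confirms equality with exhaustive maximisation on trees up to 12
leaves for every k.

## Motif discovery

Candidate specificity-determining positions are columns with conservation
grade ≥ 8 whose modal residue is polar or charged ({S,T,N,Q,Y,C,W} ∪
{D,E,K,R,H}) and gap fraction ≤ 0.5 — hydrophobic consensus columns mark
packing, not transport chemistry, and are excluded. Association with clade
labels is plug-in normalised mutual information I(residue; label)/H(label),
gap rows excluded per column. Discovery is greedy forward selection on the
joint-state NMI with the labels, stopping at k_max (default 8) or when the
gain falls below min_gain (default 0, i.e. run to k_max). Equal gains —
which occur systematically once the joint states separate the labels —
resolve to the column with the higher single-column association, then the
smaller index. This tie-break is the one genuinely open design choice here:
breaking ties by index alone would pad the selected set with arbitrary
low-index candidates after saturation, making the selection meaningless as a
ranked motif.

## Classifier

Extraction reads the query residue (or gap) at each anchored match column
off the alignment map, reporting 1-based query coordinates. The rules are
exactly the three listed in the README; additional behaviour: any gap among
positions 5–8 makes the family `ambiguous` (never guessed); a gap at
position 6 or 8 makes electrogenicity `unknown`; a non-acidic position 7 is
flagged `POS7_NOT_ACIDIC` (likely transport-deficient); engineered
exceptions (e.g. a K→R or K→H replacement at position 8 retaining
electrogenicity) are out of model — flagged cases, not predictions. For a
family-ambiguous motif the CPA2-style electrogenicity rule is still
evaluated, which is what lets the mammalian-NHA-like signature (D6 D7 R8 +
TM-3 Glu, flagged `NHA_LIKE_E_TM3`) be called electroneutral despite its
electrogenic-looking DD pair. Clade assignment is nearest-consensus Hamming
distance over the 8 states ('X' consensus matches anything), with the
best-versus-second-best margin reported and exact ties flagged.

The packaged clade reference carries the 6 CPA1 and 9 CPA2 clades with
consensus states, phenotype annotations and provenance tags: entries whose
states are printed in the primary literature are tagged `text-derived`;
the remainder are curated plausible states tagged `figure-derived` and
consistent with each clade's reported phenotypes. Under the electrogenicity
rule exactly four reference CPA2 clades (NhaA, NapA-I, NapA-II, GerN) come
out electrogenic.

## Structure checks

PDB parsing keeps the first model and altloc A. Residue distances support
CA, charged-side-chain-minimum ({NZ, NH1/NH2/NE, ND1/NE2} vs
{OD1/OD2, OE1/OE2}) and all-atom-minimum selections. A salt bridge requires
the minimum cross-class distance to be strictly below 4.0 Å; histidine
counts as basic by default (configurable). Author residue numbering is used
verbatim (K300, D163, E215, R432, K305, E333). The TtNapA K305–E333
separation check (expected ≈ 12 Å in both conformations, ± 2 Å) runs on
user-supplied 5BZ2/5BZ3 files; the geometry engine itself is validated on
synthetic coordinates, including invariance under random rigid transforms.

## Synthetic families: what they emulate, and what they do not

The generator emulates the statistical shape the analysis depends on: a Yule
topology with exponential branch lengths, monophyletic clades (size-weighted
random splitting of subtrees), LG + gamma sequence evolution, planted
clade-specific states at 8 motif columns plus the auxiliary column
(per-cell noise probability ε replaces a planted state with a uniformly
random other residue), and indels only outside motif columns — realised as
deletions plus explicit insertion columns so that degapping any alignment
row reproduces its unaligned sequence and motif-column indices stay exact.
Truth-table phenotypes are the classifier rules applied to each clade's
planted consensus, so the generator and classifier cannot drift apart. One
seed drives everything; identical parameters give byte-identical outputs.

Default study conditions: 120 leaves, 400 columns, 4 clades, branch-length
mean 0.2 substitutions/site, γ shape α = 2.0, indel rate 0.005 with
geometric mean length 3. The divergence level is the one genuinely free
parameter and was set by a concrete requirement: the planted columns (3–4
between-clade changes each) must rank in the top two conservation grades
against the background, which fails on shallow trees where many background
columns drift less than the planted ones. Two clade-motif tables ship:
a discovery benchmark in which every planted column carries a distinct
polar/charged state per clade (so no planted column can be lost to the
polarity filter, and each column individually separates the clades), and a
reference-derived table (NhaA, NhaP-II K⁺, Kef-like, animal-NHA-like)
covering both families, both electrogenicity classes, both selectivities
and the TM-3 flag for classifier studies.

What passing these studies does **not** show: real superfamilies have
rate variation the gamma does not capture (heterotachy), motif positions
that are *not* bijective with clades, alignment error from remote homology,
and annotation noise in the labels. The synthetic results bound the
machinery's correctness, not its field performance.

Benchmark studies score conservation on the generating tree rather than a
re-estimated one, isolating discovery performance from tree error; the
pipeline (`cpa run`) exercises the full estimate-everything path, including
profile alignment of every sequence and an NJ tree from the implied
match-column alignment. Phenotype accuracy is scored per call (leaves ×
{family, electrogenicity, selectivity}): under ε-noise each motif cell is
perturbed independently, so per-call accuracy degrades smoothly
(≈ 96% at ε = 0.05) while exact-triple-per-leaf accuracy compounds all
call-critical cells (≈ 85% at the same ε) and is not the quantity tracked.

## Numerical and degenerate-input conventions

Pruning partials are rescaled per column with accumulated logs (no
underflow at hundreds of leaves). Transition probabilities are clipped at
zero and renormalised after eigendecomposition reconstruction. Distance
optimisation brackets (1e-8, 3.0) and returns the cap when the boundary
value is as good (saturation). Identical rows short-circuit to distance 0.
Viterbi ties resolve in a fixed predecessor order (M < I < D, earliest entry
point), so alignments are bit-reproducible. Greedy-discovery gains are
rounded to 1e-9 before comparison so floating jitter cannot outrank the
association tie-break. Bootstrap replicates whose resampled columns leave a
pair with no comparable sites are skipped (counted against support). All
pipeline randomness derives from one master seed via per-stage SHA-256
derived streams, and run directories carry SHA-256 checksums of every
output.

## Problem sizes

The shipped studies use 120-leaf, 400-column families (20 for discovery,
5 per noise level for accuracy), 50 random 5–8-leaf trees for NJ recovery,
and trees up to 12 leaves for exhaustive PD comparison; the pipeline's
bootstrap runs on the PD-selected subset (default 30 leaves, 100
replicates). These sizes make every oracle comparison exact or exhaustive
while keeping a full run in the minutes range on one CPU.
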