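# Methods

This note documents the models, algorithms, defaults and design choices
behind paraloglens, and what the synthetic-data generator does and does
not emulate.

## Distances and tree construction

Pairwise distances from a protein alignment use **pairwise deletion**:
for each sequence pair, columns where either member has a gap or an 'X'
are dropped, and p = mismatches / compared columns.  Pairwise (not
complete) deletion matters for paralog families in which one family lost
a whole domain: under complete deletion that aligned gap block would
remove the columns for every pair.  The **Poisson correction**
d = −ln(1−p) converts p to expected substitutions per site under the
assumption of equal rates across sites and no repeated substitutions at a
site being distinguishable; it saturates (and the code raises) at p ≥ 1.

Tree search minimizes the **balanced minimum-evolution** criterion: for a
candidate topology, L = Σ_{i<j} d_ij · 2^(−p_ij), where p_ij is the
number of edges between leaves i and j (Pauplin's weighting).  The search
starts from the **neighbor-joining** tree (Studier–Keppler Q criterion,
ties broken by the lowest index pair) and hill-climbs with
**nearest-neighbor interchanges**: every internal edge contributes two
alternative topologies; each sweep evaluates all of them and accepts the
best strictly improving one, up to 200 sweeps.  Taxa are sorted
lexicographically on entry so the result cannot depend on input order,
and the search contains no randomness.

Branch lengths on the final topology come from **ordinary least squares**
against the distance matrix (closed-form solve of the path-incidence
system), with negative estimates clamped to zero.  OLS was chosen over
balanced least squares because it is exactly testable: on an additive
matrix it reproduces the generating leaf-path metric to machine
precision, which the test suite exploits.

**Rooting** places the root on the edge separating a monophyletic
outgroup from the rest, splitting that edge's length equally.  Equal
splitting is a convention, not an inference; for clock-like data whose
root is off-center on that edge, root-to-tip equality will not hold.
**Robinson–Foulds** distance is the symmetric difference of non-trivial
bipartition sets (rooted trees are compared as unrooted); the
implementation is cross-checked against dendropy in the tests.

## Conservation profile

Over a joint alignment of both families, each column yields: the two
reference residues (e.g. the human proteins of each family), a match flag
(equal, both non-gap), and cons1/cons2 — the fraction of family members
carrying the reference residue.  Choices that matter:

* The reference itself is **excluded** from its family's denominator
  (including it inflates identity); this is configurable.
* Family members with a gap or 'X' at a column are excluded from both
  numerator and denominator — a family that lacks a region entirely
  should read as *undefined*, not as 0 % identity.
* Where a reference has a gap, cons and the ungapped position are NaN/NA
  and the match flag is undefined.
* TSV output reports percentages in [0, 100]; internally fractions in
  [0, 1] are used throughout.

## Motif calling

A column passes when the references disagree **and** cons1 ≥ min_cons
**and** cons2 ≥ min_cons.  Calls are maximal runs of passing columns that
may bridge up to max_violations interior failing columns; runs must start
and end on passing columns and span at least min_len columns.  The
left-to-right greedy merge is deterministic.  Defaults min_cons = 0.5,
min_len = 10, max_violations = 2 are chosen so that a 17-residue fully
conserved, fully divergent segment is comfortably callable while isolated
divergent columns are not; all three are mandatory CLI parameters and are
echoed into output headers.  The divergence test deliberately uses the
reference residues, not column consensus: the profile's match flag is
defined on the reference pair, and the published per-residue scan this
mirrors is also reference-anchored.

## Sequence weights and logo matrices

**Position-based weights**: at a column with r distinct residue types, a
sequence whose residue occurs s times contributes 1/(r·s); contributions
are summed over columns and normalized to 1.  Gaps contribute nothing.

**Logo matrices**: per position, p_a = (weighted count + α·q_a)/(residue
weight + α) with pseudocount α (default 0) and background q (default
uniform 1/20; optionally empirical from the alignment).  Letter height is
p_a·log2(p_a/q_a) bits — positive iff p_a > q_a.  Letters with p_a = 0
get height 0 rather than −∞ so matrices stay bounded and plottable; total
depletion remains visible through the positive letters.  Columns with
zero residue mass or more than 50 % gap weight are flagged and carry
undefined heights.

## Ancestral reconstruction

The **equal-input model** has stationary frequencies π and
P_ij(t) = e^(−βt)·δ_ij + (1−e^(−βt))·π_j with β = 1/(1−Σπ²), so one unit
of branch length equals one expected substitution per site at
stationarity.  The closed-form P(t) avoids matrix exponentials and makes
exhaustive oracles exact; richer empirical matrices (JTT/WAG) are out of
scope rather than approximated.  π is uniform by default or estimated
from alignment residue frequencies.

Site likelihoods use the pruning algorithm with **per-node rescaling** of
partial likelihoods (the dropped factors accumulate in log space), so
results match unscaled arithmetic to ~1e-9 on feasible cases while deep
trees cannot underflow.  Marginal posteriors combine the upward pass with
a downward pass propagating the likelihood of everything outside each
subtree; the MAP residue breaks ties alphabetically.  Gaps and 'X' are
missing data (partial likelihood 1 for every state).  Branch lengths are
taken from the input tree as-is — tree building and reconstruction are
deliberately separate stages.  Because the model is time-reversible, the
total likelihood is invariant to re-rooting; the tests verify this across
all rootings of small trees.

## The synthetic generator

The generator emulates the structure of a two-paralog family study:

* a rooted 12-species tree (6-species "chordate-like" clade plus 6
  outside species; root-to-tip depths ≈ 0.2–0.3 substitutions/site);
* a duplication at the clade ancestor: both copies get a post-duplication
  stem (0.05 substitutions/site before the clade's first speciation), the
  younger copy (ISO1) exists only in the clade and all its branches are
  scaled by the rate multiplier r (default 2), reflecting the observed
  faster divergence of younger paralogs;
* per-site rate classes over 900 sites laid out like a multi-domain
  protein: a fast N-terminal region (rate 2.5) that is also deleted in
  ISO1 (residues 1–110, standing in for a domain lost after duplication),
  strongly conserved domain blocks (rates 0.25–0.35), moderate linkers
  (0.45–0.5), and a fast C-terminus (2.5);
* one planted motif block at ISO2 residues 633–649 (17 residues): frozen
  to a family-specific string after the duplication, differing between
  families at every position, with 4 flanking columns on each side frozen
  to the shared ancestral residues.  The flanks reflect the conserved
  context that anchors such motifs in real alignments, and they make the
  planted boundaries well-defined.  With the 110-residue deletion, the
  block maps to ISO1 residues 523–539.

Evolution uses the equal-input model's exact per-branch rule (keep the
state with probability e^(−β·rate·t), else redraw from π) from a single
seeded generator, so output is byte-reproducible.  Because the only indel
is the one known deletion, the generator emits the by-construction *true*
alignment — conservation, motif and tree stages are tested without an
MSA program in the loop.  What it does **not** emulate: alignment error,
other indels, site-specific amino-acid preferences, rate variation within
a class, heterotachy, partial/mispredicted database sequences, and
paralog misassignment — so passing tests demonstrate algorithmic
correctness under the generative model, not robustness to real-data
artifacts.

## Verification conditions and problem sizes

The reproduction script and acceptance tests use: 100 random additive
matrices (5 and 6 taxa, branch lengths uniform on [0.05, 0.5]) against
exhaustive enumeration of all 15/105 topologies; 40 simulated single-
family datasets (12 taxa × 2000 columns, homogeneous rates) for topology
recovery; all rootings of fixed 4- and 5-leaf trees with 4 random columns
each against brute-force enumeration over all 20^k internal-state
assignments; 50 default-condition simulations for motif recovery and
specificity; and 20 duplication simulations (1500 columns, homogeneous
site rates, r = 2) for rate-multiplier recovery.  The rate-recovery runs
use homogeneous site rates because the estimator relies on the Poisson
correction, which is consistent only under rate homogeneity; with strong
site-to-site heterogeneity the correction compresses long distances and
the measured quantity would conflate the clade multiplier with that bias.
The multiplier is estimated as the ratio of mean root-to-tip path lengths
below the MRCAs of the two copies in the reconstructed, outgroup-rooted
tree.

## Identity convention for pairwise comparisons

Percent identity from a global alignment is 100 × identities / compared
columns, where compared columns exclude only gap–gap pairs (which cannot
occur in a pairwise global alignment) and any column involving 'X'
(excluded from numerator and denominator).  Terminal and internal
gap-versus-residue columns count in the denominator — a conservative,
reproducible convention.  Published identity figures rarely state their
denominator, so comparisons against them carry a ±2 percentage-point
tolerance, and the published-value checks additionally require the
qualitative ordering (younger paralog less conserved) to hold.  Alignment
defaults are BLOSUM62, gap open 10, gap extend 0.5 (a gap of length L
costs open + (L−1)·extend); 'X' scores 0 against everything.  Among
co-optimal alignments a fixed deterministic traceback is reported.

## Known limitations

* The minimum-evolution search is NNI-only; it can in principle stop in a
  local optimum on non-additive matrices (SPR moves are not implemented).
  On additive inputs at the tested sizes it attains the global optimum.
* OLS branch lengths can be zero-clamped, slightly biasing lengths near
  zero.
* The equal-input model ignores amino-acid exchangeability structure;
  reconstructed ancestors on real data would be less accurate than under
  JTT/WAG-class models.
* Logo rendering is numeric only (TSV matrices); no graphics.
* No bootstrap or other topology-support measures.
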