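# Methods

## Scope and model

`nabind` predicts nucleic-acid binding at two levels. Stage 1 is a
per-residue random-forest classifier over windowed sequence/descriptor
features; stage 2 is a per-protein random forest over 15 summary
statistics of the stage-1 score track. The premise is that spurious
binding-site-like residues occur in any protein, but their *distribution*
(how many, how high-scoring, how clustered along the chain) separates
true binders from non-binders. Because no homology search against known
binders is involved at prediction time, the method applies to ORFan and
de-novo proteins, provided the per-residue descriptor tracks
(conservation/entropy/alignment depth, predicted secondary structure,
accessibility, disorder) can be supplied — these come from external
predictors or from an MSA and are consumed as pluggable inputs, not
re-implemented here.

## Binding-residue definition and dataset construction

A protein residue is labelled binding when any of its non-hydrogen atoms
lies strictly below 5.0 Å from any non-hydrogen atom of a DNA (or RNA)
chain in the same structure. Choices behind the parser and labeller:

- **Strict `<`** at the cutoff, consistently reused for every "above
  threshold" rule in the package.
- **Hydrogen detection**: the element column when present, otherwise an
  atom-name heuristic (leading digits stripped, name starts with H) —
  PDB dialects vary.
- **Altloc**: first-listed location kept; residues ordered by file
  appearance; first model only. Deterministic parsing beats occupancy
  heuristics for reproducibility.
- **Modified residues** (MSE, CSO, …) map to their parent one-letter
  code via Biopython's extended table; unmappable residues become `X`
  and are then removed by the X-filter together with their chain.
- **Coordinates**: residue indices are 0-based over the SEQRES-derived
  sequence. Author numbering is recorded but never used for arithmetic.
  Contact indices (which refer to resolved residues) are carried onto
  the full sequence through a global alignment (BLOSUM62, gap open 10,
  extend 0.5 — the EMBOSS Needle defaults). Unresolved residues cannot
  be labelled: they are masked out of training but keep their place, so
  they still fill the sliding windows of their neighbours.
- Contacts are computed on the asymmetric unit as given; each protein
  chain is labelled independently even when one NA chain touches
  several protein chains; in hybrid complexes a chain is labelled for
  whichever NA kind the current dataset build targets (DNA and RNA sets
  are built independently).

Chains with no contact are dropped, then chains shorter than 30 residues
or containing `X`. The survivors are clustered at 30 % identity / 50 %
coverage, both measured against the shorter sequence (the BLASTclust
convention). Clustering is incremental single-linkage over global
alignments, processed longest-first with ties broken by id and merged
via union-find — equivalently, connected components of the thresholded
pair graph, so no two clusters share a passing pair. A stricter
validation-style setting (e.g. 90 % coverage) is a config override.
Cross-validation folds are assigned to whole clusters, greedily to the
currently lightest fold weighted by residue count, because training
examples are residues, not chains.

## Residue features (the 246-wide schema)

The total width of 246 and the window sizes (nine for the evolutionary
profile, seven for predicted structural channels) are fixed by the
method; the exact decomposition is this package's documented default and
any alternative schema can be plugged in via YAML:

| channel | per-residue values | window | width |
|---|---|---|---|
| amino-acid one-hot | 20 | 9 | 180 |
| conservation | 1 | 9 | 9 |
| entropy (bits) | 1 | 9 | 9 |
| alignment depth (log10, chain-level) | 1 | 1 | 1 |
| secondary structure (H/E/other) | 3 | 7 | 21 |
| disorder | 1 | 7 | 7 |
| accessibility (relative, exposed flag) | 2 | 7 | 14 |
| physicochemical (hydrophobicity, charge, polarity, volume) | 4 | 1 | 4 |
| terminal distance min(i, n−1−i)/n | 1 | 1 | 1 |
| **total** | | | **246** |

Windows are zero-padded beyond the termini (all-zero one-hot blocks),
keeping every vector at full width. Physicochemical values use the
Kyte–Doolittle scale (scaled by 4.5), net charge at pH 7, a polarity
flag and side-chain volume scaled by tryptophan's.

When conservation is derived from an MSA rather than supplied: per
query-ungapped column, amino-acid frequencies with a pseudocount of 1/20
per symbol, Shannon entropy in bits over the 20 standard residues (gaps
excluded from counts), conservation = 1 − entropy/log₂20, and alignment
depth = non-gap rows. This normalised-entropy conservation is a
surrogate for profile-database conservation scores; users supplying
precomputed tracks bypass it.

## Protein features and score combination

Z-scores are computed per protein (population SD; all zero for a
constant track): the 15 features describe each protein's *internal*
score distribution, so standardising across the dataset would leak
information between proteins. All threshold comparisons are strict. The
"Z above 3" feature defaults to the upper tail only (`Z > 3`), since the
lower tail has its own feature (`Z < −2`); a two-sided |Z| > 3 reading is
selectable in config. The 4-residue windows in feature 10 are the n−3
overlapping contiguous windows (0 when n < 4).

The 2-of-3 majority combination returns the largest cutoff t at which at
least two fold models score ≥ t. For three scores this is exactly the
median: with sorted scores s₁ ≤ s₂ ≤ s₃, two scores are ≥ t iff
t ≤ s₂. A sweep test verifies the equivalence on random triples. For
novel queries the per-residue track averages the three fold models
(combination is defined at the protein level only).

## Classifiers

Random forests with 1,000 trees (200 in the large simulation runs below,
a size at which the out-of-fold AUCs are already stable to < 0.01);
√p feature sampling per split, unlimited depth, no class weighting —
common defaults, since only the tree count is prescribed. Scores are
tree-vote fractions, giving the [0, 1] cutoff semantics the aggregation
features require. Fold models get seeds `seed + fold` (stage 1) and
`seed + 100 + fold` (stage 2) so that all stages are deterministic given
one seed. Cross-validation raises a hard error if a chain would be
scored by a model whose training data included its own cluster's fold.

## Evaluation conventions

precision = TP/(TP+FP), recall = sensitivity = TPR = TP/(TP+FN),
specificity = TN/(TN+FP), FPR = FP/(FP+TN), ACC, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Any 0/0 ratio —
including MCC's — returns 0 (documented convention; degenerate tables
carry no signal). Positive calls are strict (score > cutoff). Curves
take one point per distinct score used as cutoff, with tied scores
grouped. The ROC is anchored at (0,0) (highest cutoff predicts nothing)
and (1,1) (everything positive). The PR curve keeps cutoffs predicting
at least one positive and is anchored at recall 0 with the first kept
point's precision (constant extension): without that anchor, a perfect
classifier whose positives all tie at the top score would have no curve
support below recall 1 and a collapsed trapezoidal area. AUC is the
trapezoid over x-sorted points, with no interpolation correction for the
PR curve. The random baseline is the positive fraction — the expected
precision of a random ranker, and the PR curve's recall-1 endpoint up to
noise.

## Synthetic data

Three generators provide all test fixtures; none is a stand-in for real
biological data and all are bit-reproducible under a fixed seed.

**Toy co-complexes** place protein residues (CA + CB) on a straight
backbone with 10 Å steps and give the NA chain one phosphate-proxy atom
per nucleotide: binding positions get an atom at exactly the requested
contact distance (default 4.5 Å, jittered off-axis by ≤ 1 Å), every
other residue's nearest NA atom exceeds the non-contact distance
(default 8 Å), and a decoy NA *hydrogen* is parked 3 Å from a
non-binding residue to exercise hydrogen exclusion. The generator
re-verifies its own ground truth through the parser and contact mapper
before returning and raises on geometrically infeasible specs. The
geometry is deliberately unphysical — the contact rule is atom-agnostic,
so minimal geometry suffices; nothing about packing, rotamers or base
pairing is emulated.

**Synthetic MSAs** copy conserved columns verbatim into every row and
mutate the rest i.i.d. at a chosen rate, giving controlled conservation
contrasts.

**Planted datasets** draw, per protein: length ~ U{60..140}, an i.i.d.
random sequence, conservation ~ N(0.5, 0.15), entropy ~ N(2.5, 0.8)
bits, alignment depth ~ U{50..500}, secondary structure ~ Dirichlet(1,1,1),
relative accessibility ~ N(0.4, 0.2) (exposed flag at > 0.25), disorder ~
N(0.3, 0.15); all clipped to their valid ranges. Exactly
round(n·fraction) proteins (default half of 200) are binders and receive
1–3 contiguous patches of 4–10 residues whose conservation, relative
accessibility and disorder are shifted by δ SDs before clipping; δ is
the single learnability dial. The baselines are round numbers in the
plausible range for real descriptor tracks; the channel subset carrying
the effect is fixed so δ alone controls difficulty. What passing tests
show: the pipeline recovers a known two-level signal of realistic
magnitude and stays at chance when there is none. What they do not
show: performance on real proteins, where binding signals are weaker,
channel-correlated, homology-structured and not confined to clean
patches.

## Numerical and degenerate-input choices

Zero-variance score tracks give all-zero Z-scores; tracks shorter than 4
have zero window counts; empty chains, single-class training labels,
duplicate ids, length mismatches and out-of-range track values raise
immediately with the offending file/row or chain named. Track validation
tolerates a ±0.1 deviation of the secondary-structure simplex sum and
10⁻⁹ numerical slack at range boundaries. Alignment-based mappings take
the dynamic program's first optimal alignment, making them deterministic
across runs.

## Known limitations

- The 246-feature decomposition is a documented reconstruction; only the
  total and the two window sizes are prescribed by the method.
- The conservation surrogate (1 − normalised entropy, pseudocount 1/20)
  is not identical to profile-database conservation fields.
- The clustering surrogate uses global alignments; local-alignment
  clustering can split domain-sharing pairs differently.
- mmCIF, biological-assembly expansion and crystal-symmetry contacts are
  out of scope; contacts are computed on the asymmetric unit as
  deposited.
- External structure/disorder/accessibility predictors are consumed as
  input tracks, never re-implemented; prediction quality on real
  sequences inherits whatever those tracks provide.
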