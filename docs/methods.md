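# Methods

## The prediction model

`ppinet` treats interactome inference as binary classification of
unordered protein pairs. A pair is represented by 11 features — four
structural, seven genomic-context — plus 11 missingness indicators, and
scored by a random forest (500 trees, √p features per split, seeded). The
score is the ensemble vote fraction; a pair is *called* an interaction at
a configurable threshold (default 0.5).

Assumptions worth stating explicitly:

- interactions are undirected and self-interactions are excluded; the
  locus (identifier with isoform suffix stripped) is the network node;
- the gold standard is treated as noise-free, and random pairs without
  evidence are treated as negatives — at genome scale the expected
  contamination of random pairs by true interactions is far below the
  false positive rates of interest, which is the standard justification
  for random-pair negatives;
- evidence channels are allowed to be missing per pair; missingness is
  informative (e.g. only pairs with a usable structural template carry
  structural features) and is exposed to the forest through the indicator
  columns rather than hidden by imputed defaults.

### Structural features

A template is a two-chain complex whose interface is the set of residue
pairs with any interatomic distance ≤ 6.05 Å (the PIBASE convention;
all-atom where atoms are available, CA trace otherwise). Each query model
is superposed onto its template chain by least-squares Kabsch/SVD rigid
superposition over a supplied residue alignment (alignments are consumed,
not searched; the fixture default is sequence-index identity). TM-score is
computed from the superposition distances with the standard normalization
d0 = 1.24·(L−15)^⅓ − 1.8 (fallback d0 = 0.5 Å for L < 16), normalized by
the query model length. A template is usable only when both chain
alignments reach TM ≥ 0.4. Features of an accepted interaction model:
TM = min over the two chains (conservative similarity), RMSD = max
(conservative distance), preserved interface size = template contacts
whose two residues are both covered by the alignments, and the preserved
fraction. Across a template library the best template is chosen by
(preserved fraction, TM), tie-broken by template id. The min/max
combination rule and the best-template ranking key are this package's
choices; both are deterministic and exposed as code-level parameters.

### Genomic features

- **Co-expression** is Pearson correlation on log2(RPKM+1);
  RPKM = 10⁹·C/(M·L). The log transform stabilizes the correlation
  against dynamic-range outliers. Genes absent, with < 3 samples, or with
  constant profiles give a missing value.
- **GO similarity** S = log(n/N)/log(2/N) per aspect (BP/MF/CC), with n
  the annotated-gene count of the lowest common GO class under the
  true-path closure (minimum count over common ancestors; ties broken by
  term id, which cannot change the value) and N the configured genome
  annotation size (default: number of annotated genes). S is clamped
  through n ≥ 2 (both genes belong to the class), giving S ∈ [0, 1] with
  S = 1 exactly when the class holds only the pair and S = 0 at the root.
- **Phylogenetic profile similarity** is the Pearson (phi) correlation of
  0/1 presence vectors over the genome panel; constant profiles are
  missing. Pearson was chosen over mutual information/Hamming as the
  simplest bounded statistic consistent with the other similarity
  features; it is a strategy choice, isolated in one function.
- **Interolog support** counts the organisms (of six) in which both genes
  have orthologs whose groups interact. The count (0–6) rather than a
  binary flag preserves evidence strength for the forest.
- **Gene fusion** is 1 when some foreign protein carries significant hits
  (e ≤ 1e-5) from both genes whose intervals overlap by < 10% of the
  shorter interval. Both thresholds are package choices, exposed as
  keyword arguments.

### Imbalance handling

Genome-scale prediction needs a very low false positive rate, so training
uses a large random-pair negative pool at a controlled 1:r ratio. SMOTE
oversamples the positive class: each synthetic sample is x + u·(x_nn − x),
u ~ U(0,1), with x_nn among the k = 5 nearest positive neighbours
(Euclidean distance on standardized features); synthetic points therefore
stay in the positive class's convex hull. The sweep utility reproduces the
fixed-pool optimisation design: without SMOTE, ratio 1:r draws r·|P|
negatives; with SMOTE the full training pool is used and positives are
oversampled to pool/r. Train metrics are reported on the actual training
rows (original positives), test metrics on a held-out 20% split of both
classes — the held-out-split reading of "test" performance, chosen because
it is self-contained and seeded.

## Evaluation

Confusion metrics use exact rational arithmetic before display rounding
(half away from zero, at each table's printed precision). F1 at
precision + recall = 0 is defined as 0 and flagged. Cross-validation is
stratified k-fold (k = 10 default); stratification is a deliberate
strengthening of plain equal shares so every fold contains both classes.
PR curves place one point per distinct score threshold (ties step
together), anchor at recall 0, and report both the trapezoid AUC over
recall and average precision. Method comparison tables accept either pair
sets (overlap by intersection) or published tallies (overlap, total), with
precision = overlap/total and recall = overlap/benchmark size.

## Network statistics

- **Pathway interactors**: union of network neighbours of a pathway's
  core proteins, excluding the cores themselves (configurable) — the
  exclusive reading keeps the overlap test about shared *partners*.
- **Overlap test**: one-sided Fisher's exact test (hypergeometric upper
  tail) on [[X12, X2−X12], [X1−X12, N−X1−X2+X12]] with N the number of
  proteins in the network; one-sided because the question is enrichment.
- **Link enrichment**: observed core–core cross-links divided by their
  mean over R = 1000 degree-preserving randomizations (double-edge swaps,
  10·|E| accepted swaps per replicate, self-loops and multi-edges
  rejected; degree sequence preserved exactly). Empirical
  p = (1 + #{null ≥ obs})/(R + 1); the +1 avoids zero p at finite R.
  Rigid graphs (no valid swap) are returned unchanged with a warning.
- **GO enrichment** is a plain hypergeometric upper tail with
  Benjamini–Hochberg FDR — a transparent substitute for modified
  Fisher variants in annotation servers, not a reproduction of them.
- **Topology**: degree histogram, least-squares log-log slope of the
  degree distribution (scale-free networks give a clearly negative
  slope), and average clustering coefficient.

## The synthetic universe

The generator plants `n_planted_pairs` true interactions among `n_genes`
and makes every evidence channel informative about them:

- expression: one multivariate Gaussian whose target correlation is
  I + ρ·A (A the planted adjacency), projected to the nearest valid
  correlation matrix by eigenvalue clipping — pairs of low-degree genes
  correlate near ρ (default 0.7), hubs get proportionally shrunk values,
  non-pairs stay near 0. Counts are Poisson at ~20 M mapped reads per
  sample, so the observed log-RPKM correlations are mildly attenuated;
- GO: a three-level toy ontology (root, 10 mid, 60 leaf terms per
  aspect); genes carry 1–3 random leaves, and a planted pair shares an
  extra leaf with probability 0.7 per aspect, pulling its lowest common
  class down the DAG;
- profiles: iid Bernoulli(½) over 30 genomes; half of planted pairs get
  a near-copy profile (2 flips);
- interologs: 40% of planted pairs get support in 1–3 organisms;
  a 1% background rate plants false support on pairs drawn label-blind,
  so zeroed dials leave strictly no class signal;
- gene fusion: 30% of planted pairs (plus a 0.5% label-blind background);
- structures: 50% of planted pairs get an antiphase two-helix dimer
  template with query chains that are noisy rigid copies (0.3 Å RMS
  noise, small random C-terminal truncations).

Default sizes (300 genes, 400 pairs, 50 samples, 30 genomes, 32,000-pool)
keep a full pipeline run under two minutes on one CPU while leaving the
negative pool ~80× the positive count, so the 1:40 SMOTE target is a
genuine oversampling. These are the problem sizes used throughout the
tests and the acceptance script.

What the fixture does **not** emulate: correlated noise across evidence
channels, study-specific expression batch structure, ortholog-inference
errors, realistic protein folds, or gold-standard contamination. Passing
tests demonstrate that the machinery is correct and that the classifier
recovers a planted signal of realistic shape — not that real-data accuracy
will match the synthetic numbers. The published benchmark tallies that the
evaluation module reproduces are pure arithmetic on printed counts and
involve no model fitting. Pathway core sets are drawn from planted-pair
genes without planted *inter-pathway* wiring, so the pipeline's crosstalk
folds on the default universe hover near 1; planted-enrichment behaviour
is exercised separately on constructed graphs.

## Numerical choices and edge cases

- Missing-feature imputation at the classifier boundary: 0 for bounded
  similarities/flags, 20 Å (a domain ceiling) for RMSD; the indicator
  columns carry the missingness itself.
- Kabsch superposition requires ≥ 3 aligned pairs and rejects collinear
  point sets (rotation degenerate).
- Fisher p-values use the scipy hypergeometric survival function; the
  test suite pins them to exact integer enumeration (max |Δ| < 1e-12 over
  all tables with N ≤ 60).
- All randomness flows through explicit seeds (numpy Generator,
  scikit-learn `random_state`, networkx swap seeds); regenerating a
  fixture with the same config is byte-identical.
- Self-pairs are rejected at parse time with a warning; duplicate rows
  collapse silently into the canonical set (count logged).

## Known limitations

- Structural alignments are consumed, not computed: there is no
  structure-alignment search, and template libraries at real scale are
  out of scope.
- The interolog channel assumes one ortholog group per gene per organism.
- The degree-preserving null uses edge swaps only; it preserves degrees
  exactly but not, e.g., clustering, so enrichment folds are against the
  configuration-model-like null, as is standard.
- SMOTE interpolates the missingness indicators along with the features;
  synthetic rows can carry fractional flags. This is deliberate but means
  flag columns are not strictly binary during training.
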