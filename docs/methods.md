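# Methods

This note documents the models, algorithmic choices and defaults behind
the three analysis stages and the planted-truth simulators, including the
decisions taken where the underlying procedure is genuinely open.

## Phylogenetic profiling

**Model.** A family co-occurring with a marker gene set is operationalised
as an orthogroup whose phyletic profile has members in at least
`min_positive = 2` marker-positive species and none in any marker-negative
species. Species with incomplete data (EST-only surveys, single-cell
transcriptomes) are *exempt*: their apparent absences are not trusted, so
they count toward neither test. Candidates are then confirmed by requiring
a representative in every species of a `required_all` set of well-sampled
positive taxa; targeted re-search results can be supplied as *rescue hits*
to fill gaps left by incomplete genome annotation (short proteins are
routinely missed by automated annotation, which is why the initial screen
is deliberately permissive).

**Pipeline.** For each gene of each proteome: collect homologues by
all-vs-all search, build a neighbour-joining tree over the seed and its
top `max_homologs = 20` hits, and extract seed-centred ortholog pairs.
Pairs are pooled over all per-seed trees into one network whose edge
weight counts the asserting phylomes (≤ 2 per pair). Trimming first drops
edges below `min_support`, then handles gene fusions: a node whose
neighbour alignment spans split into groups with pairwise interval Jaccard
≤ `fusion_jaccard_max` is divided into region-restricted sub-nodes, each
edge reattached by its span midpoint. Orthogroups are the connected
components of the trimmed graph.

Concrete choices, each behind a keyword argument because the published
architecture leaves them open:

- *Search*: Smith–Waterman (BLOSUM62, affine gaps 11/1) at desk scale,
  with bit scores and E-values from the gapped Karlin–Altschul
  approximation (λ = 0.267, K = 0.041). Production-size inputs should use
  external BLAST tabular output, which the same entry point validates,
  filters and sorts instead of re-searching.
- *Distances*: Kimura-corrected complements of normalised alignment
  identity, d = −ln(1 − p − p²/5), capped at 10.
- *Trees*: Saitou–Nei neighbour joining, hand-implemented so that Q-matrix
  ties break deterministically toward the lexicographically smallest pair
  of representative gene ids (cross-checked against scikit-bio's NJ in the
  test suite).
- *Orthology*: species-overlap labelling after midpoint rooting — an
  internal node is a duplication iff two of its child subtrees share a
  species — and (seed, x) is an ortholog pair iff their most recent common
  ancestor is a speciation node. This is the standard phylome rule; where
  a written description could be read as requiring every node on the
  connecting path to be a speciation, the worked examples of the procedure
  match the MRCA formulation, which we therefore implement. The rooting of
  the per-seed trees before labelling is not specified anywhere; midpoint
  rooting is the conventional neutral choice.
- *Paralogues* are kept: profiles store per-species counts and presence
  means count ≥ 1, since genuinely co-occurring families can carry
  lineage-specific duplicates.

## Donor-taxon inference

**Nested datasets.** With prokaryotic homologue scores in bits, dataset
membership at coefficient c is `score ≥ c · best prokaryotic score`, on
the inclusive grid c = 0.99 down to 0.70 in steps of 0.01 (30 datasets).
c values are rounded to two decimals to keep the float grid exact; the ≥
comparison makes datasets nested, with size non-increasing in c.
Eukaryotic seeds are always included.

**Rooting and monophyly.** Each tree is rooted artificially at the
midpoint of the branch separating all eukaryotes from all prokaryotes. If
no such branch exists, the run is recorded as non-monophyletic (carrying
the smallest conflicting leaf set found) rather than aborted. The support
label of the eukaryote-side node is reported verbatim; an optional
threshold turns it into a pass/fail, and a missing label with a threshold
set yields an explicit *indeterminate* rather than a silent pass.

**Proportional node taxonomy.** Prokaryotic leaves carry indicator
distributions over phylum/class tokens; every internal node of the
prokaryotic subtree receives, bottom-up, the mean of its children's
distributions. "Descending nodes" could be weighted equally
(children-mean) or by descendant leaf counts (equivalent to leaf
frequencies); both are implemented (`weighting="children" | "leaves"`),
with children-mean the default because the rule is phrased in terms of
nodes, not leaves. The two rules provably disagree on trees like
(P_alpha, (P_beta, P_beta)) — 1/2 vs 1/3 for alpha — and the tests pin
both values. Branch lengths are ignored: the rule is topological.

**Summary.** The donor call per dataset is the argmax of the distribution
at the root's prokaryotic child (exact ties → "unresolved"). Across the
grid, non-monophyletic runs are excluded from the mode and stability but
retained in the table; stability is the modal taxon's frequency among
usable runs. Zero usable runs yields mode "none", flagged.

## Organelle assignment

**Workflow** (LOPIT-style): keep proteins with ≥ 2 valid values in at
least one fraction; log2-transform (raw MaxQuant-style intensities are
log-normal; a `log2_transform=False` switch accepts pre-logged tables);
impute missing cells per sample column from
N(μ_col − downshift·σ_col, (width·σ_col)²) with downshift 1.8 and width
0.3 — the conventional left-censored ("around instrument sensitivity")
imputation defaults; project proteins onto the first two principal
components of the column-centred matrix (component signs fixed by making
each component's largest-magnitude loading positive, so runs are
deterministic); fit one Gaussian ellipse per marker set; label by ellipse
membership with distances reported per protein.

**Marker ellipses.** Location and scatter are the classical mean and
covariance of the marker points after dropping the `trim = 0.1` fraction
with the largest Mahalanobis distances and refitting; the refitted
covariance is rescaled by the standard Gaussian consistency factor
h / P(χ²₄ < χ²₂⁻¹(h)) (h = retained fraction), without which a trimmed
ellipse systematically under-covers. Near-singular covariances are ridged
by a small multiple of the identity. The membership threshold is the χ²
(2 df) quantile at `quantile = 0.99` (9.21). Markers participate in their
own cluster fit but are excluded from all accuracy metrics; marker ids
absent from the table are reported, not fatal.

**Labels.** Inside exactly one ellipse → that organelle; inside both, or
within `margin` (relative squared-distance units, default 0) of either
boundary → ambiguous; outside both → other; removed by the validity
filter → not_quantified (distinct from other). Because the workflow
operates on log2 data and PCA centres columns, uniform rescaling of all
raw intensities leaves every label unchanged.

## Planted-truth simulators

**Profile scenario.** Families evolve by a star phylogeny: one random
ancestor per family, mutated independently into each member with
per-branch substitution probability 0.10 over length-120 sequences (no
indels or rate heterogeneity — the profiler's target is set-membership
recovery, not tree shape). Decoys are unrelated random sequences spread
round-robin over the panel. The default scenario uses an
8-positive/8-negative/3-exempt panel with five planted families: one in
all eight required species, one in four positives plus two exempt, one in
exactly two positives, one in a single positive (must be rejected) and one
leaking into a negative species (must be rejected), plus 50 decoys.

**Donor scenario.** Five phyla × five leaves with random
sequential-joining topologies and exponential branch lengths; a 3-leaf
eukaryotic clade grafted two nodes below the donor-phylum root on a stem
5× the mean branch length (the long-branch separation typical of
inter-domain transfers). Homologue scores decay exponentially with
patristic distance from the eukaryotic clade and are scaled so the best
prokaryotic hit sits near 300 bits, giving the c-grid a realistic span.

**Fractionation scenario.** Log2 intensity of protein p (class c),
fraction f, replicate r is
`class_mean[c][f] + offset_p + jitter_p[f] + N(0, 0.15)` with
offset ~ U(−2, 2) (bounded dynamic range of abundance) and per-fraction
jitter ~ U(−1, 1) (bounded protein-to-protein variation in gradient
behaviour within a compartment). Cells go missing with probability
logistic(54.61 − 2.5·value): a steep, intensity-dependent left-censoring
whose intercept is calibrated to ≈ 20% missing cells overall under the
default class mix. The organelle classes are abundant — mitochondrial
means (25, 26.5, 28), peroxisomal (28.5, 26.5, 24.5) against a flat
background at 22.5 — reflecting that the gradient fractions are
organelle-enriched, so censoring concentrates in the background class.
Defaults: 200 mitochondrial, 100 peroxisomal, 400 background proteins
with 80/50 markers. `FractionationScenario.study_scale()` is a synthetic
stand-in at the dimensions of a full experiment (4198 proteins, 946/78/
3174 classes, 376/26 markers, stronger gradient contrasts, intercept
recalibrated for its class mix); it reproduces documented dimensions and
marker design only, not any deposited measurement.

What the simulators deliberately omit — realistic sequence evolution,
rate heterogeneity, alignment uncertainty, correlated replicate noise,
spectral-level proteomics artefacts, heavy-tailed abundance outliers —
bounds what passing tests show: recovery holds under the stated
generative assumptions, not under every pathology of real data. In
particular, within-class variation in the fractionation generator is
bounded by design; with heavy-tailed (e.g. Gaussian-dominated)
within-class scatter, a 0.99-quantile ellipse cannot contain 99% of a
class once estimation noise is included, and real-data accuracy should be
expected to be lower than the synthetic recovery rates.

## Numerical and degenerate-input conventions

- Alignment coordinates are 1-based inclusive throughout (BLAST
  convention); intervals use inclusive-length Jaccard.
- Missing intensity is an empty cell or NaN; literal 0 is a measurement
  unless `zero_is_missing` is set (quantification exports differ).
- NJ negative limb lengths are clamped to 0; Q-ties break
  lexicographically; distance saturation caps at d = 10.
- Newick support labels survive round-trips as plain internal labels;
  missing branch lengths stay absent rather than becoming 0.
- Imputation draws occur in fixed column order, so one seed fixes the
  whole table; observed cells are never touched.
- Degenerate marker geometries (collinear points) are ridged to a valid
  ellipse; fewer than 3 usable markers is an error.
- Every generator is a pure function of its scenario (seed included);
  repeated runs are byte-identical.

## Problem sizes

Default experiment sizes were chosen so that each recovery property is
measured with tight binomial error while the whole suite runs in well
under a minute: 10 profiling panels of ~71 sequences, 200 donor trees of
28 leaves, 200 fractionation tables of 700 proteins, plus one 4198-protein
study-scale run. Larger inputs scale linearly in the organelle stage and
quadratically in the all-vs-all search stage, where external search output
should be substituted.
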