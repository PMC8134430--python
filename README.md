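# copresence

Comparative-genomics and spatial-proteomics toolkit for characterising a
candidate organellar machinery from three independent lines of evidence:

1. **Phylogenetic profiling** (`copresence.profiling`) — find protein
   families whose presence/absence pattern across species matches a marker
   gene set. Per-seed gene trees ("phylomes") are built from all-vs-all
   sequence search, orthology is read off each tree with the
   species-overlap rule, relations are pooled into a support-weighted
   network, trimmed (weak edges, gene-fusion artefacts) and its connected
   components screened: a candidate family must occur in ≥ 2
   marker-positive species and in no marker-negative species, with
   data-poor taxa exempt from the negative test; confirmed families need a
   representative in every required species.
2. **Donor-taxon inference** (`copresence.donor`) — for a eukaryotic gene
   family of prokaryotic origin, infer the taxonomic identity of its
   prokaryotic ancestor across nested homologue datasets defined by
   `score_cutoff = c · score_best prokaryotic hit` with c = 0.99, 0.98, …,
   0.70. Each tree is rooted on the branch separating eukaryotes from
   prokaryotes; taxonomic affiliations are propagated from the prokaryotic
   leaves to the deepest prokaryotic node by proportional (children-mean)
   mixing, and the distribution at the parental node of the eukaryotic
   clade gives the donor call. A summary reports the modal donor and the
   fraction of datasets agreeing with it (stability).
3. **Organelle assignment** (`copresence.organelle`) — LOPIT-style
   classification of proteins from density-gradient fractionation
   intensities (3 fractions × 5 replicates). Proteins need ≥ 2 valid
   values in one fraction; left-censored missing values are imputed from
   N(μ_col − 1.8·σ_col, (0.3·σ_col)²); profiles are projected on the first
   two principal components; robust Gaussian ellipses (squared-Mahalanobis
   threshold at the χ²₂ 0.99 quantile) are fitted to mitochondrial and
   peroxisomal marker proteins; every protein is labelled mitochondrial,
   peroxisomal, ambiguous (inside both ellipses / on a boundary) or other.

`copresence.simulate` generates planted-truth inputs for all three stages
(star-phylogeny protein families over a species panel; gene trees with a
eukaryotic clade nested inside a known donor phylum; fractionation tables
with organelle-specific enrichment and intensity-dependent missingness),
so the whole pipeline is testable without any downloads.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/02_donor_inference.py` prints:

```
planted donor: Alphaproteobacteria; 25 prokaryotic + 3 eukaryotic leaves
c-grid: 30 nested datasets, best prokaryotic hit 300 bits

   c   n_taxa  monophyletic  top_taxon             weight
  0.99      4  True         Alphaproteobacteria    1.000
  0.93      4  True         Alphaproteobacteria    1.000
  0.87      6  True         Alphaproteobacteria    1.000
  0.81      6  True         Alphaproteobacteria    1.000
  0.75      7  True         Alphaproteobacteria    1.000

mode donor taxon: Alphaproteobacteria
stability: 1.00 over 30 usable datasets
```

The grid rows show, per cutoff coefficient c, the dataset size, whether
the eukaryotic sequences stay monophyletic after rooting between the
domains, and the highest-weighted taxon at the eukaryotic clade's parental
prokaryotic node. Stability 1.00 means all 30 nested datasets agree on the
planted Alphaproteobacterial donor; on real families a low stability is
the signature that the donor cannot be pinned down.

A thin command line mirrors the library:

```bash
copresence --seed 3 --out-dir sim simulate fractionation
copresence --seed 3 --out-dir out organelle \
    --table sim/intensities.tsv \
    --mito-markers sim/markers_mitochondrial.tsv \
    --perox-markers sim/markers_peroxisomal.tsv --no-log2
```

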