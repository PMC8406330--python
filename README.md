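# cocomet

Molecular networking and coculture-enrichment screening for untargeted
LC-MS/MS metabolomics.

Anaerobic gut fungi cocultivated with rumen bacteria secrete metabolites
that neither organism produces alone. Detecting them from untargeted
LC-MS/MS data requires two complementary analyses: **molecular
networking**, which groups features whose fragmentation spectra share
substructure into families of related compounds, and a **differential
enrichment screen**, which flags features reproducibly elevated in the
coculture relative to both monocultures. `cocomet` implements both,
plus the glue between them: cross-polarity network merging, per-sample
normalization, and a three-way color encoding of the resulting network
for figures. A synthetic data generator with full ground truth makes
every stage testable without instrument data.

## The method

**Spectral filtering.** Each feature's MS/MS spectrum loses all
fragments within ±17 Da of the precursor, then keeps only the top 6
peaks per ±50 Da sliding window.

**Modified cosine.** With per-spectrum intensities √-transformed and
L2-normalized, two spectra *a*, *b* with precursor difference
Δ = m_b − m_a score

cos_mod(a, b) = max over one-to-one pairings Σ ŵ_a(i) ŵ_b(j),

where peaks *i*, *j* may pair if |m_i − m_j| ≤ 0.05 Da **or**
|m_i + Δ − m_j| ≤ 0.05 Da. The shifted branch aligns spectra of
structurally related compounds (e.g. homologues differing by CH2) on
their shared backbone. The pairing is chosen greedily by descending
intensity product.

**Networking.** Edges require cosine > 0.70 and ≥ 6 matched peaks, must
be mutual among each endpoint's top-10 neighbours, and the
lowest-scoring edges are removed until no connected component
("molecular family") exceeds 100 nodes. Spectra can also be matched
against a library filtered the same way.

**Cross-polarity merge.** [M+H]+ and [M−H]− nodes of the same neutral
molecule (neutral masses within 20 ppm, retention times within
0.15 min) collapse into one node; each input's edges are inherited.

**Enrichment screen.** After row-sum normalization (each sample to
1,000,000) and per-group means over 4 replicates, a feature passes iff
it is detected in *all* coculture replicates, ≥ 4-fold above both
monoculture means (a zero monoculture counts as "not detectable", shown
"—"), and a one-tailed pooled-variance Student's t gives p < 0.05
against both.

**Encoding.** Node hue is the angle of the vector sum of three anchor
hues weighted by relative group intensity; opacity is
√ of the between-group range normalized to the coculture's min/max.

See `docs/methods.md` for assumptions, parameter rationale and
limitations.

## Worked example

Generate the default synthetic study (5 molecular families × 4 members,
40% dual-mode compounds, 4 compounds planted 8-fold coculture-enriched,
three groups × 4 replicates) and run the full pipeline:

```bash
cocomet simulate --seed 17 --out-dir syn
# wrote 20 positive + 5 negative spectra, 25 features -> syn

cocomet run --pos-mgf syn/positive.mgf --neg-mgf syn/negative.mgf \
            --feature-csv syn/features.csv --design-csv syn/design.csv \
            --out-dir out
# network: 20 nodes (20 displayed), 4 feature(s) pass the enrichment screen
#   graphml: out/network.graphml
#   report: out/enrichment_report.csv
#   styles: out/node_styles.csv
```

The passing rows of `out/enrichment_report.csv`:

```
feature_id  fc_vs_fungal  fc_vs_bacterial  p_vs_fungal  p_vs_bacterial  passes
cmp002_pos      4.497100         4.640289     0.000038        0.000034    True
cmp003_pos      4.762187         4.830907     0.000247        0.000270    True
cmp012_pos      4.402286         5.391407     0.000214        0.000173    True
cmp015_pos      5.566183         5.818676     0.000750        0.000703    True
```

These are exactly the four planted compounds
(`syn/ground_truth.json`). Each fold change is the coculture mean over
the monoculture mean after normalization — note they sit below the
planted 8-fold because row-sum normalization redistributes the enriched
signal across this miniature 25-feature table; the p-values are the
one-tailed Student's t upper tails. The GraphML file carries the
network with per-node m/z, RT, polarity, neutral mass, group means, hue
and alpha, ready for Cytoscape.

The same steps are available as library calls
(`cocomet.generate_dataset`, `cocomet.build_network`,
`cocomet.merge_networks`, `cocomet.enrichment_screen`, ...); the CLI is
a thin shell over them.

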