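# Methods

## Overview

`cocomet` implements the downstream analysis of an untargeted non-polar
LC-MS/MS metabolomics comparison between a fungal monoculture, a
bacterial monoculture and their coculture: spectral cleanup, molecular
networking by modified-cosine similarity, cross-polarity network
merging, per-sample normalization, a replicate-consistent
coculture-enrichment screen, and a three-way color/transparency network
encoding. A synthetic data generator with full ground truth stands in
for raw instrument data, so every stage is testable end to end.

## Spectral filtering

Each feature contributes one representative MS/MS spectrum. Two filters
are applied before any similarity is computed, mirroring standard GNPS
preprocessing:

1. **Precursor-region removal** deletes every fragment within ±17 Da of
   the precursor m/z. The boundary is inclusive (|Δ| = 17 is removed):
   "within ±17 Da" is read conservatively, removing the borderline peak.
2. **Windowed top-k** keeps a peak only if it ranks among the top 6 by
   intensity within ±50 Da of its own m/z. The window is centred on each
   peak rather than binned, which makes the filter translation-invariant
   and idempotent (removing peaks can only improve survivors' ranks).
   Intensity-rank ties break by ascending m/z so results are
   deterministic.

## Modified cosine

Intensities are square-root transformed and scaled to unit Euclidean
norm per spectrum. The square-root stabilises the dominance of base
peaks; the normalization makes self-similarity exactly 1. Candidate
fragment pairs match either directly (|Δm/z| ≤ 0.05 Da) or shifted by
the precursor-mass difference, the mechanism by which spectra of
structurally related compounds (e.g. homologues differing by CH2) align
on shared backbone fragments. A one-to-one pairing is selected greedily
by descending intensity product, ties broken by ascending m/z; the
score is the summed products. Greedy selection is O(P² log P),
deterministic, and standard in this score family; an exhaustive
optimal-assignment oracle in the test suite confirms the greedy score
never exceeds the optimum and equals it whenever the optimal pairing is
unique (it essentially always is for real tolerances).

## Network construction

Three ordered, individually pure edge rules:

1. **Threshold** — cosine > 0.70 and ≥ 6 matched peaks. The edge and
   library criteria are phrased slightly differently in common usage
   ("more than 6" vs "at least 6"); both are implemented as a single
   configurable `min_matched` with a ≥ comparison and default 6.
2. **Mutual top-10** — an edge survives only if each endpoint is in the
   other's ten highest-scoring neighbours, ranked on the thresholded
   edge set (not on all pairwise scores). Rank ties break by node id.
3. **Family cap** — while any connected component ("molecular family")
   exceeds 100 nodes, its lowest-scoring edge is removed and components
   are recomputed; recomputing after every single removal keeps the
   number of removed edges minimal under the greedy rule.

All ties everywhere break on node ids, giving a determinism contract:
identical inputs in any order produce identical networks. Degree-zero
nodes are dropped only from the *display* network; quantitative tables
keep every feature.

## Cross-polarity merge

Positive-mode nodes are assumed [M+H]+ and negative-mode [M−H]−;
neutral masses are m/z ∓ 1.007276466 Da. Candidate cross-polarity pairs
must agree to < 20 ppm in neutral mass and < 0.15 min in retention time
(both strict, as printed tolerances). The ppm reference is the mean of
the two neutral masses — the choice is immaterial at the 20 ppm scale
but must be fixed for testability. Pairs are accepted greedily by
ascending ppm (ties: RT difference, then node ids), each node used at
most once; greedy one-to-one assignment resolves the occasional node
with two candidates. Edges from both input networks are inherited onto
merged nodes, keeping the larger cosine on collision.

## Normalization and the enrichment screen

Peak heights are row-sum normalized per sample to a total of 1,000,000,
then aggregated by arithmetic mean over the four biological replicates
of each group. A feature passes the screen for a condition iff

* it is detected (height > 0) in **all** coculture replicates,
* its coculture/monoculture mean ratio is ≥ 4 against **both**
  monocultures — a monoculture mean of exactly zero is flagged "not
  detectable" (rendered "—") and counts as satisfying the fold
  criterion,
* a one-tailed two-sample Student's t-test (pooled variance,
  df = n1 + n2 − 2, alternative: coculture mean greater) gives
  p < 0.05 against both monocultures.

Pooled-variance Student's t (not Welch) is used because that is the
named test. The test runs on linear-scale normalized heights (the
quantity whose ratios the screen thresholds); a log-scale option exists
but is not default. Zero pooled variance uses the limit convention:
equal means → p = 0.5, coculture greater → p = 0, smaller → p = 1. No
multiple-testing correction enters the pass decision — the screen is a
raw one-tailed threshold, with its fold-change gate and all-replicate
detection requirement doing most of the specificity work (type-I
simulations below bear this out) — but Benjamini-Hochberg adjusted
p-values are reported as extra columns for context.

A practical caveat of row-sum normalization: it assumes enriched
features carry a small share of the total signal. On a miniature table
(tens of features) a strongly enriched, high-intensity feature inflates
the coculture row sums enough to dilute its own measured fold change.
At realistic scale (hundreds to thousands of features, as in the screen
calibration simulations) the effect is negligible.

## Three-way encoding

Hue: the three anchor hues (defaults 0°, 120°, 240°) become unit
vectors on the color wheel; the node's hue is the angle of the vector
sum weighted by the three group means normalized to sum 1. A pure
single-group node lands exactly on its anchor; equal intensities cancel
to a neutral flag, rendered mid-gray. The construction is
scale-invariant and equivariant under cyclic group/anchor permutation.
(The published description of this coloring cites an external method
without reproducing its formula; the barycentric vector-sum
construction is adopted here as a well-defined encoding with the
correct extremes.)

Alpha: d = max − min of the node's three group means (the phrase
"intensity difference" is read as the range), normalized to the min/max
of the reference group's means over all nodes (coculture by default),
clipped to [0, 1] and square-root transformed. The square root
emphasises moderately group-specific features; strongly group-specific
nodes are opaque and flat nodes transparent.

## Synthetic data generator

The generator emulates the features of the study design that the
pipeline's correctness depends on, with defaults:

| parameter | default | rationale |
|---|---|---|
| families × members | 5 × 4 | small, fully recoverable family structure |
| modification deltas | +14.0157, +2.0157 Da | CH2 and H2, common biochemical shifts |
| fragments per backbone | 8 | enough to clear the ≥ 6 matched-peak gate |
| mass error | ≤ 3 ppm (uniform) | high-resolution Orbitrap scale |
| RT jitter | ≤ 0.03 min (uniform) | well inside the 0.15 min merge tolerance |
| noise peaks | 3 per spectrum, low intensity | exercised by the window filter |
| replicate noise | log-normal, σ = 0.2 | ~20% CV, multiplicative as peak heights are positive |
| dropout | 0 (configurable) | planted-detection criteria assume complete coculture detection; dropout is switched on explicitly to emulate "not detectable" monocultures |
| dual-mode fraction | 40% | exercises the cross-polarity merge |
| replicates | 4 per group | the study design |
| planted enrichment | 4 compounds at 8-fold | comfortably above the 4-fold gate |

Family base masses sit ≥ 50 Da apart and base retention times 0.8 min
apart; within a family, member *j* carries the cumulative delta of *j*
modification steps and elutes 0.1 min later. Odd-indexed backbone
fragments shift with the modification (neutral-loss-like) while
even-indexed ones stay fixed, so family members connect through a mix
of direct and precursor-shifted matches — exactly the structure the
modified cosine is designed to capture. Every compound ionizes
positive; a seeded fraction also ionizes negative with the precursor
pair differing by exactly two proton masses.

Randomness is integer-indexed: every compound, spectrum and feature row
draws from `default_rng([seed, stage, index])`, so output is
reproducible across platforms and independent of generation order.

What the generator does **not** emulate: chromatographic peak shape and
co-elution, isotope patterns and multiple adduct types beyond
[M±H], in-source fragmentation, correlated (batch) noise, and
intensity-dependent detection limits. Passing tests therefore
demonstrate algorithmic correctness under the assumed statistical
model, not robustness to every artefact of real instrument data.

## Problem sizes and calibration checks

The test-suite simulations use 1,000 random spectrum pairs against the
exhaustive pairing oracle, 200 random 15-node score matrices against a
brute-force rule oracle, and 1,000-feature tables (250 families × 4,
4+4+4 replicates) for screen calibration; these sizes give stable rates
while the whole suite runs in well under a minute. Under the null the
one-tailed t rejects within the 99% binomial envelope of α = 0.05 and
the full screen flags ≤ 0.5% of features; with 50 features planted at
8-fold among 1,000, ≥ 90% are recovered, while 2-fold plants stay below
10% (the 4-fold gate dominates).

## Known limitations

* Greedy pairing can in principle score below the optimal assignment
  when candidate matches conflict; measured agreement on random small
  spectra is 100% wherever the optimum is unique.
* The merge assumes one representative adduct per polarity; dimers,
  sodium adducts and multiply charged species are out of scope.
* The hue construction is a faithful-extremes stand-in for the cited
  three-way coloring, not a reproduction of its exact formula.
* The screen inherits the row-sum normalization caveat above at very
  small feature counts.
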