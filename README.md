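# minigut

Toolkit for designing and analysing minimal gut-microbiome consortia
assembled from core intestinal bacteria. It reimplements, as a tested and
reusable pipeline, the computational stages of a diet-based
minimal-microbiome design study:

- **`minigut.iokit`** — shared data model (taxon tables, presence/absence
  matrices, KO profiles, 16S copy-number tables, qPCR totals, reaction
  universes), strict validation, and plain-TSV readers/writers.
- **`minigut.synthgen`** — synthetic-data generators with known ground
  truth for every input class: prevalence-structured abundance tables,
  presence/absence matrices with planted positive/negative pairs,
  core-enriched KO profiles, multinomial amplicon experiments distorted by
  16S copy numbers plus a noisy qPCR total, random reaction universes with
  plantable cross-feeding, and expressed-KO subsets of genomes. All
  generators are pure functions of (parameters, seed).
- **`minigut.corescreen`** — occupancy/core-microbiota screening
  (inclusive thresholds, defaults 0.0001 detection / 50% occupancy),
  occupancy–abundance summaries, probabilistic pairwise co-occurrence
  under the hypergeometric null (pairs with expected co-presence < 1
  excluded; optional Benjamini–Hochberg correction), whole-consortium
  co-presence, core-KO identification (75% prevalence default), and
  consortium KO coverage.
- **`minigut.quantprof`** — quantitative profiling: ASV→species
  aggregation (unclassified fraction reported), division by 16S copy
  number, renormalization and scaling to qPCR-measured total 16S copies,
  and fold changes between timepoints.
- **`minigut.revecol`** — reverse ecology: KO-derived metabolic network
  construction (OR semantics over reaction KOs), seed-set detection via
  graph condensation (seeds = compounds in in-degree-0 components,
  confidence 1/|component|), and asymmetric pairwise
  competition/complementarity indices on genome-based or expressed-KO
  bases, unweighted or confidence-weighted.
- **`minigut.gmmscore`** — gut metabolic module grammar (steps; comma
  alternatives; `+` complexes; `///` terminator), CPM normalization,
  median-estimator module scoring with coverage cutoff 0.5 and a minimum
  of 2 observed KOs, and long-format species–function tables. Shipped
  fixture modules illustrate the curation targets (cellobiose
  degradation, lactate consumption via bifurcation, 1,2-propanediol
  routes, propionate production via 1,2-PD, acetyl-CoA→crotonyl-CoA as a
  butyrate proxy); their KO contents are placeholders for testing the
  machinery, not a vetted reference.

## Command line

All pipeline stages are exposed under a single `minigut` entry point;
each command writes TSV output plus a YAML run log of its parameters.

```sh
# synthetic inputs with ground truth
minigut simulate amplicon --out-dir sim/ --seed 1 --n-species 10

# core screen at the default thresholds (detection 0.0001, occupancy 0.5)
minigut core-screen --table abundance.tsv --out core.tsv

# pairwise co-occurrence classification for a focal consortium
minigut cooccur --pa presence_absence.tsv --taxa T0001,T0002,T0003 --out pairs.tsv

# core-KO coverage of a consortium of genomes
minigut ko-coverage --profiles samples/ --genomes genomes/ --out coverage.tsv

# absolute abundances from counts + copy numbers + qPCR totals
minigut quantify --counts counts.tsv --copy-numbers cn.tsv --qpcr totals.tsv --out abs.tsv

# competition/complementarity indices (genome or expressed basis)
minigut revecol --kos genomes/ --universe universe.tsv --basis genome --out matrix.tsv

# gut metabolic module scores from per-species transcript KO counts
minigut gmm-score --expr expr/ --out scores.tsv
```

## Notes

- All file formats are plain text (TSV, YAML, JSON, module-definition
  text); no binary formats are read or written.
- Validation is strict by design: missing cells, duplicate identifiers,
  malformed KO tokens, and infeasible parameters raise immediately
  rather than being silently repaired.
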