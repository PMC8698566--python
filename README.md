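# androdyn

Temporal clustering and network analysis of rapid androgen-response
proteome profiles.

## The problem

Androgen (DHT) triggers "non-genomic" signaling in prostate cancer cells
within minutes, long before canonical AR-mediated transcription. Time-course
TMT proteomics over 0, 5, 15, 30 and 60 minutes (treated vs. vehicle, three
replicates) captures these rapid changes as per-protein ratio profiles.
`androdyn` implements the full downstream analysis for such an experiment,
for computational biologists who want a tested, scriptable version of the
workflow:

1. **Preprocessing** — peptide/replicate quantification filters,
   treated/vehicle ratios, per-sample median centering, replicate averaging,
   log2, per-protein z-score across time points.
2. **Fuzzy c-means clustering** of the standardized profiles
   x_i ∈ R^D, minimizing

   J(U, V) = Σ_i Σ_c u_ic^m ‖x_i − v_c‖²,  Σ_c u_ic = 1,

   with the fuzzifier m estimated from the data dimensions:

   m = 1 + (1418/N + 22.05)·D^(−2) + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134).

   At N = 4532 profiles and D = 5 time points this gives m = 2.01. The
   cluster count is picked at the elbow of J(k), proteins with maximum
   membership ≤ 0.4 are set aside as fuzzy, and for k = 5 the clusters get
   archetype letters A–E (signal initiators, early stimulators, signal
   mediators, late stimulators, terminal regulators) from their centroid
   shapes.
3. **Annotation enrichment** — upper-tail hypergeometric tests of
   subcellular compartments (4 classes) and molecular types (13 classes)
   within each cluster.
4. **PPI integration** — BioGRID parsing, hub ranking, AR ego networks,
   cluster-pair interaction over-representation, a directed molecular-type
   interaction map, enumeration of C→D→E signaling cascades (two PPI edges,
   transcription-regulator terminus), and their placement on the 3×3
   cluster-by-compartment grid.
5. **Concept map** — one-sided Fisher association of clusters with gene-set
   concepts, retained at p < 0.001 and odds ratio > 2.
6. **Consensus markers** — per-dataset two-sample t-tests across several
   expression cohorts; a gene is a marker when significant in the same
   direction in ≥ 2 datasets; paired tumor/normal testing at p < 0.01.

Because no public quantification table exists for this design, the package
ships a first-class synthetic-data generator (`androdyn.simulate`) that
emulates the experiment — five planted temporal archetypes plus a noise
class, archetype-biased annotations, planted cluster-pair PPI excess,
designated-cluster concepts, planted markers — so every stage is testable
end to end with known ground truth.

## Worked example

```python
import androdyn as ad

table, truth = ad.generate_profiles(n_proteins=2000, noise_sd=0.3, seed=0)
profiles = ad.standardize_profiles(
    ad.compute_ratios(ad.filter_quantified(table)))
k, diag = ad.select_k_elbow(profiles, k_range=range(2, 11), seed=0)
res = ad.FuzzyCMeans(profiles).fit(k=k, seed=0)
print(res.summary())
assignment = res.assign_archetypes(threshold=0.4)
```

This prints:

```
Fuzzy C-Means Results
====================================================
No. profiles:           1900
Time dimensions:        5
Clusters (k):           5
Fuzzifier (m):          2.0388
Objective (J):          707.396
Iterations:             20
Converged:              True
----------------------------------------------------
cluster       size(argmax)    mean max U
cluster_1              409         0.775
cluster_2              366         0.762
cluster_3              360         0.780
cluster_4              359         0.787
cluster_5              406         0.790
```

Of the 2000 generated proteins, 100 fail the quantification filters (too
few peptides or a missing replicate), the elbow lands on k = 5, and the
0.4-membership filter retains 1723 proteins labeled A–E (365/333/366/333/326)
while 177 mostly noise-class proteins are excluded — the same shape as a
real run of this design. The hard labels recover the planted archetypes
with adjusted Rand index ≈ 1.0 at this noise level.

A full pipeline run (clustering, enrichment, network, cascades, concepts,
markers, report) is one call:

```python
from androdyn.pipeline import PipelineInputs, run_pipeline
manifest = run_pipeline(ad.Config(seed=0), PipelineInputs(table, ...), "out/")
```

or from the shell:

```bash
androdyn simulate --seed 0 --outdir sim/
androdyn report --indir sim/ --seed 0 --outdir out/
```

`out/manifest.json` records the seed, a config hash and the eight completed
stages; every intermediate table is written as TSV and networks as
Cytoscape-readable GraphML/SIF.

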