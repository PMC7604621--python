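# mrnapolar

Quantitative analysis of mRNA targeting to cellular protrusions — for cell
biologists studying subcellular transcript localisation in migrating cells
(endothelial tip cells, fibroblasts, neuronal growth cones) who have
protrusion-vs-cell-body sequencing tables, smFISH images, or reporter
time-lapse movies and want the downstream statistics reproducible and
testable end to end.

The package implements four analyses that together connect transcriptome-scale
enrichment to single-cell spatial readouts:

1. **Enrichment status clustering.** Genes passing a protrusion-enrichment
   filter on the reference dataset (fold change FC > 1.6 at BH FDR
   q < 0.05, strict inequalities) are clustered on their log₂ FC across D
   comparison cell types, scaled and centred, with k-means at the
   combinatorial cluster count k = 2^D (8 for three cell types: each
   transcript is enriched or depleted in each). The *universal* cluster —
   centroid positive in every dataset, judged in raw log₂ FC units — holds
   the mRNAs targeted to protrusions in all cell types.
2. **3′UTR motif scanning.** FIMO-style scanning of 3′UTR sequences with a
   position weight matrix, scored as log₂ likelihood ratio against a
   0-order background, with *exact* match p-values computed by dynamic
   programming over 1/1000-bit-discretised scores; hits at p < 10⁻⁵, and a
   per-cluster statistic: the fraction of a cluster's genes carrying ≥ 2
   motif occurrences.
3. **Polarisation Index (PI).** For an smFISH spot pattern in a
   2D cell mask, PI = ‖mean spot position − cell centroid‖ / R_g, with R_g
   the mask's radius of gyration. PI ≈ 0 for uniform patterns, √2 for spots
   pinned to one rim point of a disk. Includes Laplacian-of-Gaussian spot
   detection with subpixel refinement, and per-cell target/control PI ratios.
4. **Filopodia–particle proximity.** Distances from newly formed filopodia
   bases to the nearest mRNA reporter particle at the emergence frame,
   compared with randomised control positions drawn uniformly in the cell
   ROI; 5-µm bin frequency profiles, Pearson trend tests (plus a
   permutation-calibrated observed-vs-control profile test), Spearman
   distance–duration correlation, Mann–Whitney direction check, and 12-µm
   distal-axis filopodia binning.

A first-class synthetic-data module generates every input — fold-change
tables with planted status structure, sequences with planted motifs, cells
with polarised spot patterns, rendered smFISH images, and particle/filopodia
time-lapses with tunable spatial coupling — from explicit seeds, with ground
truth attached, so the whole pipeline runs and is verified without any
external download.

## Worked example

```sh
mrnapolar run --seed 1 --out demo/
```

runs the full synthetic pipeline and prints (abridged):

```json
{
  "enrichment": {"k": 8, "n_genes": 500, "n_enriched": 274,
                 "universal_cluster": 0, "n_universal_genes": 35},
  "motif":      {"universal_cluster_frequency": 1.0, "n_hits": 105},
  "polarisation": {"mean_pi_target": 1.003, "mean_pi_control": 0.063,
                   "image_spots_planted": 30, "image_spots_detected": 30},
  "proximity":  {"n_events": 92,
                 "median_observed_um": 1.35, "median_control_um": 11.34,
                 "spearman_observed_rho": -0.898, "spearman_observed_p": 7.7e-34,
                 "spearman_control_rho": 0.050, "spearman_control_p": 0.63}
}
```

Reading: of 500 simulated genes, 274 pass the protrusion-enrichment filter
and fall into the 8 status clusters; cluster 0 is enriched across all three
comparison cell types (the universal cluster) and every one of its genes
carries ≥ 2 planted motif copies while no other cluster does. Polarised
cells show cohort mean PI ≈ 1.0 against ≈ 0.06 for uniform controls, and
the detector recovers all 30 rendered spots. Filopodia coupled to reporter
particles emerge a median 1.3 µm from the nearest particle versus 11.3 µm
for randomised controls, and particle proximity predicts filopodium
lifetime (Spearman ρ = −0.90) while the randomised control shows no such
relationship. `demo/` holds the per-stage tables, images, a `summary.json`,
and a `manifest.json` with the SHA-256 of every output; rerunning with the
same seed reproduces every file byte for byte.

The same stages are available as library calls (`filter_enriched`,
`StatusKMeans`, `PWMScanner`, `polarisation_index`, `proximity_analysis`,
…) and as individual subcommands (`simulate`, `enrich`, `cluster`, `scan`,
`motif-freq`, `spots`, `proximity`, `filodist`).

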