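# interface-atlas

Statistics for mapping the **tumor–microenvironment interface** in spatial
and single-cell transcriptomics.

When a melanoma invades surrounding tissue, the boundary where tumor
contacts muscle forms a transcriptionally distinct band — an *interface* —
composed of specialized tumor-like and muscle-like cells that share a
common expression program (cilia genes up, ETS-family transcription
factors down). This package implements, as a reusable and tested library,
the bespoke statistics needed to find and characterize that band from
Visium-style spot arrays plus scRNA-seq/snRNA-seq:

- **Spatial-coherence test** — for a gene set, score each spot by the mean
  normalized expression of the set; call spots *high* above mean + 2 SD
  (≥ 5 required); compare all pairwise distances among high spots with
  pooled distances of 100 random same-sized spot draws, via a studentized
  rank statistic that is calibrated under spatially random sets
  (type-I = 0.05 at nominal 0.05) yet reports p ≈ 10⁻⁸ for compact
  patterns.
- **Rank-sum markers + interface rule** — Wilcoxon rank-sum differential
  expression (exact null for combined n ≤ 12, tie-corrected normal
  otherwise) with log2 FC = log2(mean(expm1 x_in)+1) − log2(mean(expm1
  x_out)+1); a gene is interface-enriched only if its interface fold
  change exceeds the same gene's fold change in both the pure tumor and
  pure muscle contrasts (adjusted p < 0.05), which separates genuine
  boundary biology from tumor/muscle admixture.
- **MIA** — multimodal intersection analysis: for cell-state marker set of
  size n, region marker set of size K, overlap k in background N,
  enrichment = −log₁₀ P(X ≥ k) and depletion = −log₁₀ P(X < k) under the
  hypergeometric distribution, computed in log space.
- **NMF** — KL-divergence multiplicative-update factorization of
  microenvironment spots with consensus clustering across restarts;
  the rank is suggested at the first drop of the cophenetic correlation,
  and per-spot factor scores are z-scored across factors.
- **Module scores & signatures** — per-observation mean expression of a
  gene set minus expression-matched controls drawn from 24 mean-expression
  bins (100 controls per gene); cross-dataset interface signatures as the
  intersection of significantly upregulated genes (ribosomal
  "rps"/"rpl" genes removed); Pearson correlation of two scores (e.g.
  ETS vs ETS-target anti-correlation); threshold classification of
  interface-like cells.
- **Synthetic data with ground truth** — a Visium-like grid (central tumor
  disc, interface annulus, muscle) and matched cell/nucleus datasets with
  planted marker blocks, a shared interface program, negative-binomial
  counts and a latent ETS/ETS-target anti-correlation, all bit-reproducible
  from a seed.

See `docs/methods.md` for the full model descriptions, parameter defaults
and numerical choices.

## Worked example

Generate a synthetic dataset with a planted interface, test the planted
"cilia-like" program for spatial coherence within the microenvironment,
and apply the interface-enrichment rule:

```python
import numpy as np
from interface_atlas import SynthConfig, generate_spatial, synthio
from interface_atlas.preprocess import normalize_dataset
from interface_atlas.spatialcoh import coherence_test
from interface_atlas.markers import ranksum_markers, interface_enriched_genes

spots, truth = generate_spatial(SynthConfig(seed=7))
norm = normalize_dataset(spots)

# coherence of the planted program among microenvironment spots
me = np.isin(spots.cluster_of_spot, ["interface", "muscle"])
res = coherence_test(norm.subset_obs(me), spots.coords[me],
                     truth.interface_program, seed=7)
print(f"n_high={res.n_high_spots}  median_obs={res.median_observed:.0f}  "
      f"median_null={res.median_null:.0f}  p={res.p_value:.2e}")

# interface-enriched genes from three contrasts
labels = spots.cluster_of_spot
calls = interface_enriched_genes(
    ranksum_markers(norm, labels, "interface", "rest"),
    ranksum_markers(norm, labels, "tumor", "rest"),
    ranksum_markers(norm, labels, "muscle", "rest"),
)
up = [c.gene for c in calls if c.direction == "up"]
recall = len(set(up) & set(truth.interface_program)) / len(truth.interface_program)
print(f"up-calls={len(up)}  program recall={recall:.2f}")
```

Output:

```
n_high=25  median_obs=1338  median_null=1844  p=8.18e-08
up-calls=60  program recall=1.00
```

The program's high spots sit markedly closer together than random
microenvironment spots (1338 vs 1844 µm median pairwise distance) — the
planted band is detected at p ≈ 10⁻⁷ — and the enrichment rule recovers
the full planted 60-gene program (recall 1.00) without calling any pure
tumor or muscle marker.

The same analyses are scriptable from the shell:

```bash
interface-atlas simulate --out demo --seed 7
interface-atlas coherence --spatial demo/spatial --gmt demo/gene_sets.gmt \
    --region tumor --reps 100 --seed 7 --out coherence.tsv
interface-atlas run --out full_run --seed 7        # full pipeline
```

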