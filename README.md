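# phyloendemism

Grid-based analysis of taxonomic and phylogenetic endemism for regional
floras and faunas: per-cell diversity metrics, a permutation null model,
EDGE conservation scoring, multi-metric percentile hotspot detection,
species-coverage and protected-area gap analysis, and environmental model
averaging — with a synthetic island-landscape generator so the entire
pipeline can be exercised and tested without any external data.

It is aimed at conservation biogeographers working with occurrence atlases
rasterised to a regular grid (e.g. 1 × 1 km squares), a dated phylogeny of
the regional endemics (typically pruned from a published megatree), and
per-species IUCN Red List categories.

## The metrics

Given a species × cell presence/absence matrix and a rooted tree with
branch lengths `L_b`, the package computes, per occupied cell `c`:

- **RE** — endemic species richness, the number of species present;
- **WE** — weighted endemism, `Σ_s 1/range_s` over the species present,
  where `range_s` is the number of cells a species occupies; each species
  partitions one unit of weight across its range, so `Σ_c WE(c) = S`;
- **CWE** — corrected weighted endemism, `WE/RE ∈ (0, 1]`, the mean
  fraction-of-range concentrated in the cell;
- **PD** — Faith's phylogenetic diversity, the total branch length of the
  minimal subtree connecting the cell's species to the root;
- **sesPD** — the standardised effect size `z = (PD_obs − μ_null)/σ_null`
  under a whole-tree tip-label permutation null (default 1000 replicates);
  `z < −1.96` flags phylogenetic clustering, `z > +1.96` overdispersion;
- **PE** — phylogenetic endemism, `Σ_b L_b / R_b` over the cell's subtree,
  where `R_b` is the number of cells occupied by branch `b`; PE spatially
  partitions the tree, `Σ_c PE(c) = Σ_b L_b`;
- **EDGE** — per species, `ln(1 + ED) + GE·ln 2`, with fair-proportion
  evolutionary distinctiveness `ED_i = Σ_b L_b/n_b` along the root path
  and `GE` coding CR=4, EN=3, VU=2, NT=1, LC=0 (DD species are left
  unscored); per cell, the sum of the EDGE scores of the species present.

Hotspots are cells reaching the top q ∈ {1, 2.5, 5, 10}% of a metric
(ties at the threshold included); counting how many of the seven metrics
select a cell gives a 0–7 surface whose high-count cells (≥5 at q = 1% by
default) are *nano-hotspots*. Coverage tables report, per species and IUCN
category, the fraction of each species' range inside the hotspot set, and
gap analysis classifies hotspot cells by protection network (Natura 2000 /
local-only / unprotected). Environmental effects are estimated by fitting
all subsets of the screened predictors (pairwise Spearman |ρ| < 0.7) as
Gaussian GLMs on log10-transformed, z-scored surfaces and averaging the
coefficients of models within ΔAIC < 2 by Akaike weight.

## Worked example

```python
import numpy as np
import phyloendemism as pe

tree = pe.parse_newick("((A:1,B:1):1,C:2);")
inc = pe.IncidenceMatrix(["A", "B", "C"], ["c1", "c2"],
                         np.array([[1, 0], [1, 1], [0, 1]], bool))
surf = pe.endemism_metrics.taxonomic_surfaces(inc)
print("WE :", surf["WE"].values.to_dict())
print("PD :", pe.faith_pd(tree, inc).values.to_dict())
print("PE :", pe.phylogenetic_endemism(tree, inc).values.to_dict())
print("ED :", pe.fair_proportion_ed(tree).to_dict())
```

prints

```
WE : {'c1': 1.5, 'c2': 1.5}
PD : {'c1': 3.0, 'c2': 4.0}
PE : {'c1': 2.0, 'c2': 3.0}
ED : {'A': 1.5, 'B': 1.5, 'C': 2.0}
```

Reading the numbers: cell `c1` holds A (range 1) and B (range 2), so
`WE(c1) = 1/1 + 1/2 = 1.5`; its PD subtree is the A and B tip edges plus
their shared stem (3.0); PE divides each of those branches by the number
of cells it reaches (`1/1 + 1/2 + 1/2 = 2.0`). C's ED is its own 2-unit
branch; A and B each get their tip branch plus half the shared stem.
EDGE then adds extinction risk — e.g. with A listed CR,
`EDGE_A = ln(1 + 1.5) + 4 ln 2 ≈ 3.689`.

The same works end-to-end from files:

```sh
phyloendemism simulate --seed 42 -o fixtures/        # synthetic dataset
phyloendemism validate --occ fixtures/occurrences.csv \
    --cells fixtures/cells.csv --iucn fixtures/iucn.csv \
    --tree fixtures/tree.nwk
phyloendemism run --occ fixtures/occurrences.csv \
    --cells fixtures/cells.csv --iucn fixtures/iucn.csv \
    --tree fixtures/tree.nwk --reps 1000 --seed 42 -o results/
```

which writes `metrics.csv`, `species_scores.csv`, `hotspots.csv`,
`coverage.csv` and `model_avg.csv`.

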