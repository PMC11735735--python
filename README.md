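# hashdemux

Clustering-based demultiplexing of cell-hashing tag counts.

In multiplexed single-cell experiments, every sample is labeled with a
hashtag oligonucleotide (HTO, LMO or CMO) before pooling, and each cell's
sample of origin must be recovered from the resulting tag-by-cell count
matrix. Real hashing data carry two kinds of background noise that make this
hard: **ambient contamination** (cell-free tags that give some tags an
elevated baseline in every cell) and **cell-bound contamination**
(contaminating tag reads attached to cells, scaling with the cell's depth),
on top of large **sequencing-depth variability** between cells.

`hashdemux` implements a demultiplexing workflow built for that noise
regime, plus the simulator and evaluation statistics needed to benchmark it:

1. **Normalization** of the raw counts `r_ij` (tag *i*, cell *j*), by one of
   - LogNormalize: `n_ij = ln(r_ij · 10⁴ / S_j + 1)`, with `S_j` the cell total;
   - Relative Counts: `n_ij = r_ij · 10⁴ / S_j`;
   - per-tag CLR: `n_ij = ln(r_ij / G_i + 1)`, `G_i` a per-tag geometric mean
     (removes ambient baseline bias);
   - per-cell CLR: `n_ij = ln(r_ij / G_j + 1)`, `G_j` a per-cell geometric
     mean (removes depth variability — the recommended default).
2. **Clustering**: a shared-nearest-neighbor graph over cells in normalized
   tag space (Jaccard weights on k-neighborhoods, weak edges pruned),
   partitioned by Louvain community detection.
3. **Marker-tag calling** per cluster by a one-vs-rest Wilcoxon rank-sum
   test; a marker must be expressed in *every* cell of its cluster, pass
   adjusted p < .05, and clear a log-fold-change threshold.
4. **Doublet-rate calibration**: the logFC threshold is chosen from a grid so
   that the fraction of cells in multi-marker (Doublet) clusters is closest
   to the expected doublet rate — supplied by the user or estimated as
   `8×10⁻⁶ · n_cells · (n_tags − 1) / n_tags`. Clusters with no marker are
   Negative, one marker singlets, two or more Doublets.
5. **Ensemble majority vote** over a grid of (k, resolution) values
   (defaults k ∈ {5,10,15,20,25,30}, resolution ∈ {1,2,3,4}), with a
   per-cell confidence score = fraction of runs agreeing with the final
   label.

Evaluation utilities include per-tag/macro F-scores, the
doublet-to-singlet misclassification rate, AUCPR separability per tag
(Davis–Goadrich interpolation, doublets excluded), and two dataset noise
statistics (baseline expression variability; 99th/1st-percentile sequencing
depth ratio). The simulator generates tag counts with configurable ambient
(Poisson, log-uniform per-tag levels) and cell-bound (multinomial)
contamination and exact ground truth.

## Worked example

```python
import hashdemux as hd

# 5 tags x 1000 cells/tag, 10% doublets, 2% cell-bound contamination,
# ambient level up to 100 reads
ds = hd.simulate_dataset(hd.SimulationConfig(seed=0))

result = hd.demux_ensemble(
    ds.matrix, method="clr_seq_depth",
    k_grid=[10, 20], resolution_grid=[1.0, 2.0],
    expected_rate=0.10, base_seed=0,
)
report = hd.evaluate(result, ds.truth_labels(), ds.matrix)
print(round(report.average_f, 4), round(report.doublet_to_singlet_rate, 4))
```

prints `0.957 0.144`: averaged over the five tags the F-score of the
recovered sample labels is 0.957, and 14.4% of the 500 true doublets were
wrongly assigned to a single sample. The per-tag F-scores range from 0.912
to 0.985, 421 cells are called Doublet and 280 Negative, and the mean
ensemble confidence is 0.965. Per-tag AUCPR separability on this dataset is
0.99–1.00, its baseline expression variability 0.46 and its depth
variability (p99/p1 of cell totals) 7.97.

The same workflow from the shell:

```bash
hashdemux simulate --tags 5 --cells-per-tag 1000 --seed 0 -o data/
hashdemux demux -i data/ --normalization clr_seq_depth \
    --expected-doublet-rate 0.1 --seed 0 -o labels.csv --report runs.json
hashdemux evaluate --pred labels.csv --truth data/truth.csv -i data/ -o report.json
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
simulates one dataset with the default five-tag noise-grid configuration and
reports the percentage of ground-truth doublet cells it contains, computed
from the generated labels at run time.
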