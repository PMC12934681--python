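# spatialcoloc

Compartment-resolved spatial statistics for imaging-based single-cell
spatial transcriptomics (CosMx SMI-style data): who sits next to whom in
a tissue, more often than chance would allow?

The package is written for analysts of tumor-microenvironment panels —
flat tables of segmented cells (sample, field of view, centroid in
microns, cell-type label, transcript counts) from ~1,000-gene targeted
panels — who want tested, scriptable versions of the standard
neighborhood analyses:

* **Cell-type co-localization testing.** Cells within a fixed radius
  *r* (default 40 µm) of each other are spatial contacts. For an ordered
  pair (A, B) the observed statistic is the number of B contacts of the
  A ("index") cells. The null is built by shuffling cell-type labels
  among the non-index cells — across the sample, or within FOVs to
  preserve local density — giving, per pair,

  `z = (observed − E_null) / SD_null`,

  two-sided p-values, Benjamini–Hochberg q-values, and
  `log(observed / expected)` enrichment. Per-FOV maps of
  `log((obs + 0.5)/(exp + 0.5))` localize interaction "hotspots".
* **QC filtering** (cells with fewer than 50 counts removed; the
  boundary cell with exactly 50 is kept).
* **Niche assignment**: k-means over k-nearest-neighbor cell-type
  composition vectors (k = 20), with per-sample / per-niche composition
  tables.
* **Gene-set module scores** (mean of set genes minus expression-bin–
  matched controls) and **transcript-source attribution** (per-cell-type
  share of one gene's counts in a region).
* **A ground-truthed synthetic generator**: multi-FOV CSR baselines plus
  planted pairwise attraction (Thomas-style shared-parent clusters),
  repulsion (exclusion-radius rejection sampling), niche mosaics, and
  negative-binomial panel counts — so every statistic above can be
  validated against known truth.

## Worked example

Simulate a 4-FOV sample in which 80% of tumor cells and macrophages are
drawn toward shared cluster centers (σ = 15 µm), then test every
cell-type pair:

```python
import spatialcoloc as scl

spec = scl.SyntheticSpec(
    type_freqs={"Tumor": 0.4, "Macrophage": 0.3, "Tcell": 0.3},
    base_density=300, n_fovs_per_sample=4, seed=0,
    relations=[scl.PairRelation("Tumor", "Macrophage", "attract",
                                parent_intensity=10, offspring_sigma_um=15,
                                strength=0.8)],
)
cells, truth = scl.simulate_cells(spec)
graph = scl.build_neighbor_graph(cells, radius_um=40.0)
cfg = scl.PermutationConfig(n_permutations=1000, seed=0)
results = scl.coloc_all_pairs(graph, cells.labels(), cfg)
print(results[["index_type", "neighbor_type", "observed", "expected_mean",
               "z", "q", "log_enrichment"]].head(4).round(3).to_string(index=False))
```

```
index_type neighbor_type  observed  expected_mean       z   q  log_enrichment
     Tumor    Macrophage      3207       2034.622  14.999 0.0           0.455
     Tumor         Tcell       961       2133.378 -14.999 0.0          -0.797
Macrophage         Tumor      3207       2238.972  13.869 0.0           0.359
Macrophage         Tcell       782       1750.028 -13.869 0.0          -0.806
```

The planted Tumor–Macrophage attraction tops the table (z ≈ +15,
q ≈ 0): tumor cells have ~58% more macrophage contacts than the
label-shuffle null expects (log-enrichment 0.455). T cells, displaced
from the clusters, read out as depleted. The per-FOV hotspot map shows
where the excess lives:

```python
fmap = scl.fov_enrichment(graph, cells.labels(), ("Tumor", "Macrophage"), cfg)
print(fmap[["fov_id", "observed", "expected_mean", "log_enrichment"]]
      .round(3).to_string(index=False))
```

```
fov_id  observed  expected_mean  log_enrichment
S1_F01       658        419.628           0.449
S1_F02       725        462.646           0.449
S1_F03       758        483.825           0.449
S1_F04      1066        676.070           0.455
```

Here attraction was planted in every FOV, so all four score ≈ 0.45; with
FOV-restricted planting only the injected FOVs rise (see the test
suite's hotspot-localization check).

The same stages are available from the shell —
`spatialcoloc simulate|qc|graph|coloc|niche|score|attribute|run` — with
`run` driving the whole pipeline from a YAML config and writing a
manifest (parameters, derived seeds, file hashes) for byte-reproducible
reruns.

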