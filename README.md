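# minfluxpair

Post-processing for 2D MINFLUX nanoscopy localization data, built for the
question of how membrane receptors are organized in flat cellular structures
such as the NK-cell immune synapse: are they monomers, pairs, or small
clusters, and at what separations?

MINFLUX localizes single fluorophores with nanometer precision, producing a
table of localizations grouped into *traces* (one trace = one emission event
of one fluorophore). `minfluxpair` turns such tables into spatial statistics
with ground-truth validation at every stage:

1. **Quality filtering** — remove localizations with background-corrected
   emission rate `efo` > 50,000 Hz or center-frequency ratio `cfr` > 0.95
   (strict inequalities), then traces left with < 3 localizations.
2. **Trace centers** — collapse each trace to one 2D point: DBSCAN (radius
   4 nm, threshold 3) on the trace's localizations, mean of the largest
   cluster.
3. **Isolated pairs** — DBSCAN clusters of exactly 2 centers at a 40 nm
   search radius; by chaining, each detected pair is a mutual-nearest-neighbor
   pair with no third center within the radius (verified per pair).
4. **Clusters** — DBSCAN components of ≥ 4 centers within 40 nm, with
   composition, size (diameter), convex-hull area, and density.
5. **Nearest neighbors and Ripley H** — exact NN distances (ball tree) and
   K̂/L/H curves with translation edge correction; H(r) > 0 means clustering
   at scale r, H(r) < 0 dispersion.
6. **Distance-bias correction** — a measured distance between two points
   d apart, each localized with per-axis precision σ, follows a Rice
   distribution with mean > d. `expected_pair_distance(d, σ)` gives that
   mean in closed form and `invert_pair_distance` solves it back for d, so
   measured pair separations can be reported as bias-corrected estimates.
7. **Synthetic data** — a generator for monomer/dimer/cluster fields with
   configurable separation, labeling efficiency, per-localization precision,
   trace-length distribution, and out-of-range background traces, providing
   exact ground truth (and recovery metrics) for everything above.
8. **Condition comparison** — two-sided Mann–Whitney U on per-cell
   statistics (exact small-sample p by enumeration).

See `docs/methods.md` for the statistical model, conventions, and known
limitations.

## Worked example

```python
import numpy as np
import minfluxpair as mp

# a synapse-sized field: monomers (2/µm²), dimers 18 nm apart (1/µm²),
# 4-molecule clusters (0.2/µm²); 70% labeling, 2.5 nm precision
reports = [
    mp.run_pipeline(mp.PipelineConfig(simulation=mp.SimulationConfig(seed=1 + s)))
    for s in range(12)                       # 12 cells
]
pool = mp.pooled_pair_distances(reports)
print(f"pairs: {pool['n_pairs']}, pooled mean {pool['pooled_mean_nm']:.2f} nm, "
      f"median {pool['pooled_median_nm']:.2f} nm")

# correct the localization-precision bias using the centers' precision
inv_m = [1.0 / p[k] for r in reports for p in r.pairs for k in ("a_n_locs", "b_n_locs")]
sigma_point = 2.5 * np.sqrt(np.mean(inv_m))
d = mp.invert_pair_distance(pool["pooled_median_nm"], sigma_point)
print(f"bias-corrected separation: {d:.2f} nm")
```

Output:

```
pairs: 156, pooled mean 18.40 nm, median 18.05 nm
bias-corrected separation: 17.99 nm
```

The pooled mean overshoots the true 18 nm separation — partly the Rice bias
of noisy distance measurements, partly contamination by chance pairs — while
inverting the median recovers the generating separation to within ~0.1 nm.

The same chain is available from the shell:

```sh
minfluxpair simulate --seed 1 --out locs.csv --truth truth.csv
minfluxpair centers --in locs.csv --out centers.csv
minfluxpair analyze --centers centers.csv --out report.json
minfluxpair recover --truth truth.csv --report report.json
```

`report.json` carries stage counts, the pair/cluster summaries with full
distance lists, the mean nearest-neighbor distance, the Ripley curve (also
written as `report_ripley.csv`), and the complete configuration, so a run is
reproducible from its report. `minfluxpair run --config cfg.json` drives the
whole pipeline from a single JSON document.

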