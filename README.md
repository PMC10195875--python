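# annotmix

Mixing statistics for annotated, spatially embedded weighted networks —
how nodal attributes ("annotations") align with network wiring, judged
against surrogate maps that preserve spatial autocorrelation.

The package provides:

- **Domain types and I/O** (`annotmix.connectome`): `AnnotatedConnectome`
  (weighted graph + coordinates + distances + named annotation vectors),
  ordered edge expansion (`EdgeTable`), distance thresholding, delimited
  text loaders/writers.
- **Mixing statistics** (`annotmix.mixing`): strength-weighted annotation
  assortativity, rank-based and partial variants, heterophilic mixing
  between annotation pairs, per-node homophilic ratios, mean connection
  distance.
- **Spatial null models** (`annotmix.nulls`): spherical rotation nulls on
  mirrored parcel centroids, Moran spectral randomization on inverse
  distance weights, variogram-matched permute-and-smooth surrogates, plus
  naive value shuffling as the baseline; all seeded and optionally joint
  (same spatial transform for every map within a draw).
- **Inference** (`annotmix.inference`): z-scores and two-sided permutation
  p-values against null ensembles, Benjamini–Yekutieli FDR, distance-
  threshold z-profiles, term-category decoding, surrogate-based map
  correlations.
- **Edge-level regression** (`annotmix.regression`): connection-weighted
  least squares predicting one endpoint's annotation from the other's,
  with exhaustive-submodel dominance analysis.
- **Communities** (`annotmix.communities`): resolution-parameterized
  modularity, seeded Louvain, consensus clustering, z-Rand partition
  similarity, resolution scans, per-community summaries.
- **Synthetic data** (`annotmix.synthetic`): mirrored two-hemisphere
  sphere / cube geometries, exponential distance-decay networks, spatially
  autocorrelated annotation fields of controllable Moran's I, planted
  (dis)assortative wiring via degree-preserving edge swaps, term-map sets
  with planted category correlations.
- **Experiments** (`annotmix.experiments`): end-to-end type-I-error
  calibration, planted-effect power, and z-profile shape recovery.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria (oracle
equivalence, closed forms, null-model contracts, calibration, power,
dominance conservation, community machinery, inference plumbing); the
calibration and power tests run reduced-replication simulations and take
a few minutes.

## CLI

A `annotmix` console script wraps the pipeline. Inputs are delimited text:
a dense CSV adjacency (or 3-column edge list), a coordinates CSV
(`node_id,x,y,z[,hemisphere]`), and an annotations CSV (`node_id` plus one
column per annotation).

```bash
# generate a synthetic dataset to play with
annotmix synth --n-nodes 200 --density 0.1 --n-annotations 3 --seed 1 --out data/

# validate and summarize
annotmix validate -a data/adjacency.csv -c data/coords.csv -x data/annotations.csv

# assortativity of one annotation
annotmix assort -a data/adjacency.csv -c data/coords.csv -x data/annotations.csv \
    --annotation annot_0 [--rank] [--partial annot_1]

# surrogate ensemble, standardized statistics, distance profile
annotmix nulls  -a ... -c ... -x ... --method moran --n 1000 --seed 1 --out ens.npz
annotmix infer  -a ... -c ... -x ... --nulls ens.npz
annotmix profile -a ... -c ... -x ... --annotation annot_0 --nulls ens.npz \
    --percentiles 0,10,20,30,40,50,60,70,80

# heterophilic mixing (needs a joint ensemble, e.g. spins)
annotmix nulls  -a ... --method spin --n 1000 --seed 1 --out spins.npz
annotmix hetero -a ... --annotations-list annot_0,annot_1,annot_2 --nulls spins.npz

# per-node homophilic ratio / mean connection distance
annotmix local -a ... --annotations-list annot_0,annot_1

# edge-level regression with dominance analysis
annotmix regress -a ... --response annot_0 --predictors annot_1,annot_2 --with-dominance

# multiresolution consensus communities
annotmix communities -a ... --gammas 0.25:7.5:100 --runs 100 --tau 0.5 --out-dir comms/

# term-category decoding
annotmix decode --target target.csv --terms terms.csv --categories cats.csv
```

All commands accept `--out` to write tidy CSV tables.

## Conventions worth knowing

- Undirected graphs: every unordered edge enters sums twice (once per
  orientation); `2m` is the ordered weight sum. Directed graphs use
  out-strengths for endpoint-i moments, in-strengths for endpoint-j.
- Annotation standardization is strength-weighted (weights `k_i / 2m`).
- Distance thresholding removes edges strictly below the interpolated
  percentile of unordered edge distances, so percentile 0 is the identity
  and ties at the cut survive.
- Missing annotation values propagate as explicit missing (`NaN`) and are
  never imputed; statistics on maps with missing nodes raise unless the
  nodes are dropped first via `AnnotatedConnectome.drop_missing`.
- Two-sided permutation p-values measure extremeness as absolute deviation
  from the null mean, with add-one correction; p ≥ 1/(n_nulls + 1).
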