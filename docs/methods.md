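# Methods

## The screen being modeled

A condition-dependent SGA screen crosses a query mutant to an arrayed
deletion library and measures, for every array gene, four strains — wild
type (WT), the query single mutant, the library single knockout, and the
double knockout (DKO) — in two conditions, rich medium (YPD) and drug.
Colonies are pinned in 384 format (16 rows × 24 columns) and sizes are
read from scanned images as foreground pixel counts.

## Generative model (synthetic screens)

Every colony's expected size is

```
E[size] = base_size · S(r, c) · F
```

where `S(r, c)` is the plate's multiplicative spatial field and `F` is the
strain's fitness factor. Per array gene `g` the truth holds a baseline
rich-medium fitness `f_ypd[g]`, a drug multiplier `m_drug[g]`, and a
planted interaction ratio `rho[g]`; the query has drug multiplier
`m_drug_query` (default 2: the query is drug resistant) and rich-medium
fitness `query_fitness_ypd` (default 1). The factors are:

| strain / condition | F |
|---|---|
| WT, either condition | 1 |
| query, YPD / drug | `q_ypd` / `q_ypd · m_drug_query` |
| single KO, YPD / drug | `f_ypd` / `f_ypd · m_drug` |
| DKO, YPD / drug | `f_ypd · q_ypd` / `rho · m_drug_query · m_drug · f_ypd · q_ypd` |

`rho = 1` is no interaction; `rho < 1` a negative interaction (the
deletion suppresses the query's drug-resistant growth), `rho > 1` a
positive one. By default `f_ypd = m_drug = 1` for every gene, so the
planted signal lives entirely in `rho`; lognormal spreads for both are
available (`f_ypd_cv`, `m_drug_cv`). This default is also what makes the
noiseless round-trip invariant exact (see *Normalization*).

**Class generation.** `generate_truth` assigns exactly
`round(n·frac)` genes per hit class (half-up rounding); suppressor `rho`
is uniform on `[effect_low, suppressor_high]` and enhancer `rho` on
`[enhancer_low, effect_high]`. The defaults (10% suppressors ≤ 0.3, 10%
enhancers ≥ 1.7, `effect_high` 2.5) emulate a screen with strong planted
hits at roughly the hit fractions a chemogenomic screen reports.

**Artifacts.** The spatial field is a product of linear row and column
gradients and an edge-ring multiplier. Gradient amplitudes in
`ArtifactParams` are maxima: each physical layer (plate × strain class ×
condition) draws its own signed amplitude uniformly in `[−a, +a]` —
plates dry and get pinned independently, and a field shared by all layers
of a plate would cancel in the ratio-based score, leaving normalization
untested. The edge multiplier (default 0.8 in the `realistic()` preset)
is fixed across layers, as edge drying is systematic. Noise is
mean-preserving lognormal with coefficient of variation `noise_cv`
(colony sizes are positive and right-skewed); with `noise_cv = 0` sizes
are exact expectations (floats, not rounded), so clean screens round-trip
to machine precision. Positions go missing independently with probability
`missing_prob`; BLANK positions on array layers are structurally empty
and flagged missing from the start.

**Replication.** `layout_plates` places every gene once per layout;
`replicate_layouts` replica-pins each layout to `n` plate copies with
distinct plate ids (independent artifacts and noise). The pipeline
default is 16 replica plates with 16 control positions per plate — the
precision of the final score scales as `1/sqrt(replicates)`, and at 10%
colony CV roughly a dozen replicate measurements are needed before the
per-gene score error (median ≈ 0.04) is small against the hit-calling
thresholds. Control positions are scattered over distinct interior rows
and columns; controls confined to one row would inherit that row's
correction error systematically (see below).

**Images.** `render_plate_image` draws each colony as the `size` nearest
pixels to its cell center — a rasterized disk whose foreground area equals
the recorded size exactly — so image quantification is an exact inverse on
clean renders. `quantify_plate` thresholds globally (Otsu by default,
fixed threshold for reproducibility) and counts foreground pixels per
grid cell with half-open cell boundaries (a pixel belongs to the cell
containing its center). There is no grid fitting or lighting correction;
synthetic images are on-grid by construction, and real-scan registration
is out of scope.

## Normalization

Per physical layer: (1) scale so the layer median equals the table's
grand median; (2) one multiplicative row-then-column median-polish pass
(factors rescaled to geometric mean 1 so the layer scale is untouched);
(3) divide the outermost ring by the edge/interior median ratio.
Missing positions stay missing; layers with under 50% non-missing pinned
positions are flagged unusable and their genes become invalid.

Two estimation details matter. First, spatial factors are estimated only
from colonies of the layer's own strain population (array-gene positions;
on WT/query lawn layers, every position) — control colonies have different
fitness and would otherwise masquerade as plate gradients — but the
corrections are applied to every position, controls included. Second,
rows/columns with fewer than 8 usable colonies keep a factor of 1: a
median over a handful of colonies, a fifth of which may be genuine hits,
is not a robust artifact estimate, and sparse last plates are better left
uncorrected than mis-corrected.

Idempotence: on artifact-free data all correction factors are exactly 1
and normalization is exactly idempotent (the test suite checks this). On
noisy data a single polish pass is only approximately idempotent; the
single fixed pass is preferred over iteration to convergence because it
is cheap, deterministic, and removes linear gradients exactly.

## Scoring

Condition response, per strain: `w = (size_drug/size_YPD) /
(wt_drug/wt_YPD)`, with the WT reference taken from WT control-token
colonies **on the same layer type**: WT tokens on the single-KO layers
reference `w_single`; WT and query tokens on the DKO layers reference
`w_double` and `w_query`. This makes every ratio invariant to the
per-layer scale factors normalization introduces — the property that lets
a clean screen recover every planted `rho` to 1e-9.

Control medians are pooled across replica plates of the same layout
(identified by their gene position map, not by plate-id naming). Pooling
is statistically right because a strain's drug response is a strain
property, not a plate property: per-plate control medians over a handful
of colonies impose a plate-wide bias of order 10% on every gene of the
plate, while the layout-group restriction keeps the gene-composition-
dependent part of the layer scaling cancelling exactly. Per-plate
controls remain available (`controls="per_plate"`).

The interaction ratio is `rho_hat = w_double / (w_query · w_single)` and
the score `S = clamp(rho_hat, 0, s_max)` with `s_max = 2` by default.
Replicates combine by the geometric mean of `rho_hat` before clamping
(log-space unbiased under multiplicative noise; the arithmetic mean of
per-replicate scores, available as `aggregate="mean_score"`, carries a
small upward ratio bias). Zero YPD growth of the single or double mutant
invalidates the gene (synthetic sick/lethal on rich medium — reported
with reason `zero_ypd`, not scored); other failure modes get their own
reason codes (`missing_double_drug`, `bad_controls`, ...). Invalid inputs
never propagate NaN into the score table.

## Hit classification

`score_stats` reports n, mean, sample SD (ddof = 1 by default, population
SD by flag), min and max. Thresholds are `mean ± k·SD` computed from
unrounded moments; comparisons are strict, so genes exactly at a
threshold are conservative non-hits. The phenotype cross-tab splits hits
into sensitive/resistant × suppressor/enhancer cells; genes annotated
with both phenotypes (conflicting reports) are excluded from the four
cells and counted separately, and unannotated hits form the remainder.

## Network clustering

Edge lists (STRING-style TSV exports) are filtered to a node whitelist
(the hits) and a minimum confidence (default 0.4, the usual
medium-confidence convention; 0–1000 scales are auto-detected),
reciprocal duplicates merge keeping the maximum, and genes left without
edges are dropped — disconnected genes are not clustered.

The embedding uses eigenvectors of the symmetric normalized Laplacian,
skipping the trivial vector; for disconnected graphs the degenerate zero
eigenspace is replaced by deterministic per-component indicator vectors.
Two weightings exist: unit row normalization (the Ng–Jordan–Weiss
convention, the default for a known k) and a diffusion weighting that
scales eigenvector `i` by `max(1 − λᵢ, 0)^t` (t = 3). `cluster_network`
uses the diffusion weighting when it must choose k: with d = k_max equal
dimensions the within-dispersion curve of a modular graph keeps falling
past the true k (the extra dimensions are unstructured) and the gap
statistic has no elbow, while damping the high-frequency directions
restores a sharp one.

The gap statistic draws B (default 50) uniform reference datasets over
the embedding's bounding box and compares `log W_k`. Three selection
rules: `one_se` — smallest k with `gap(k) ≥ gap(k+1) − s_{k+1}` among k
whose gap exceeds its own standard error (the significance guard stops
noise-level gaps at small k from short-circuiting the scan);
`max` — global maximum; `jump` — the k with the largest single increase
of the gap over its predecessor, measured against a zero baseline at
k_min. `jump` is the default for `cluster_network` because on spectral
embeddings the gap curve steps up at the true k and then creeps slowly
upward, which defeats forward-looking rules; on planted 5-module graphs
it recovers k = 5 essentially always, where `one_se` wavers between 5
and 7. For plain point clouds (well-separated blobs) `one_se` is the
`gap_statistic` default and recovers the planted count reliably.

k-means runs `n_init` seeded restarts keeping the best inertia; labels
are canonicalized by descending cluster size with ties broken by the
smallest member gene, so results are invariant to node order.

## Enrichment

One-sided over-representation only: `P(X ≥ k)` under
Hypergeometric(N, K, n), identical to one-sided Fisher's exact.
`strength = log10(k / (n·K/N))` is undefined at k = 0 (such terms are
absent from output). BH adjustment is applied per gene set (per cluster /
per hit category), matching the way per-cluster FDR columns are reported.
The background defaults to the annotation universe (all genes with ≥ 1
annotation); a custom universe (e.g. all screened genes) is available,
since different annotation services resolve this differently. Report
filtering mirrors screen practice: FDR cap, minimum annotated-gene count
(1 for cluster tables, 4 for annotated-hit tables), strength-descending
order with FDR tie-breaks, an optional greedy Jaccard redundancy filter
plus a term blocklist as an automated stand-in for manual "redundant or
vague term" curation, and a display cap (top 10 by default). Annotations
load from two-column TSV or GAF 2.x (DB Object ID and GO ID columns); no
ontology-graph propagation is applied — annotations are used as given.

## Pipeline

`RunConfig` round-trips through YAML; every stochastic stage derives its
seed as `crc32("<global_seed>:<stage>") mod 2^31`, so toggling stages
never shifts other stages' randomness, and a rerun with the same config
is byte-identical. Stage failure aborts with the stage named (exit code 3
from the CLI; 2 for validation errors) and a MANIFEST records which
outputs are complete. The report carries the score summary, thresholds
and hit counts per cutoff, the chosen k and cluster sizes, and the top
terms per cluster; the score-distribution plot shows ascending scores
with dashed cutoff lines.

## Problem sizes and what the tests show

The default synthetic study runs 500 genes (10% suppressors, 10%
enhancers), 16 replica plates, 10% colony CV, gradients ≤ 15%, edge
factor 0.8, 1% missingness. At these conditions the suite verifies: exact
(1e-9) recovery of planted `rho` on clean screens; median |S − clamp(rho)|
< 0.05, hit sensitivity ≥ 0.9 and neutral false-positive rate ≤ 0.02 at
the 1.5 SD cutoff over 20 seeds; gap-statistic recovery of a planted
k = 5 in ≥ 80% of seeds; hypergeometric tails equal to brute-force
enumeration for all tables with N ≤ 12; and BH/strength identities.

What passing does **not** show about real screens: the generator has no
spatially correlated dropouts, no batch covariance between plates, no
colony-morphology effects, no agar or lighting variation in images, and
its missingness is uniform; real normalization must also handle grid
misregistration, which is out of scope here. Cluster memberships and
enrichment tables from live annotation databases depend on database
versions and undisclosed service internals, so the clustering and
enrichment stages are verified against planted structure and exact
combinatorial oracles, not against any published table's exact rows.

## Known limitations

- The interaction-score formula is a ratio-of-responses contract with the
  published 0/1/2 anchors; the original screen's scoring tool is not
  public, so equality with its internals (e.g. its printed 1.961 ceiling,
  which this package treats as a clamp parameter `s_max`) is not claimed.
- Median polish removes separable row/column trends only; localized
  blotches survive it.
- The gap statistic's `jump` rule assumes a single dominant scale of
  structure; nested cluster hierarchies will resolve only the strongest
  level.
- Enrichment treats annotations as flat sets; ancestor closure over an
  ontology graph is not performed.
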