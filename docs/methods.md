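# Methods

## Data model

The unit of analysis is a cells × assays matrix of qPCR cycle-threshold
(Ct) values from a targeted single-cell panel (87 assays, including the
housekeeping genes B2M and GAPDH). Lower Ct means more transcript; an
assay that fails to amplify ("Fail", or any value beyond the limit of
detection) is a *drop-out* and is recorded at the limit of detection,
Ct = 40 cycles. Each cell may additionally carry the full surface
fluorescence profile recorded by the index sorter (log2 MFI per marker)
and metadata (donor, plate, well, sort gate).

## Quality control

Assays with zero Ct standard deviation are removed; assays with fewer
than two distinct detected values or >98 % drop-out are flagged (not
removed) as lacking the expected Ct distribution. Duplicated assays are
merged when their Spearman correlation across co-detected cells is at
least 0.8 (the merged value is the mean of detected member values, and
a drop-out only when every member dropped out); poorly correlated
duplicate groups keep the member with most detections. Cells are
excluded, in a fixed order that makes the recorded reason
deterministic, when (i) more than 70 assays failed, (ii) B2M Ct > 13,
(iii) GAPDH Ct > 15, or (iv) the mean Ct over assays with detectable
amplification exceeds 20. "Low housekeeping expression" means Ct
*above* the cutoff (higher Ct = less transcript) and all comparisons
are strict, so boundary cells are retained. The retained set is
order-independent; only the reason bookkeeping depends on the order.
Expression is then normalized per cell: ΔCt = Ct − mean(B2M, GAPDH),
with drop-outs normalized from Ct 40. This convention (drop-outs enter
downstream analyses at their LOD-normalized ΔCt) is used throughout;
statistics offer an `exclude_dropouts` toggle for sensitivity analysis.

Titration series (by default eight fourfold serial dilutions of three
bulk pools in technical triplicate) validate assay linearity: after
removing values beyond the LOD and merging replicates by mean, a
no-intercept linear model of Ct on log2(dilution) plus pool indicators
estimates and removes pool (starting-concentration) offsets, then an
ordinary per-assay regression of pool-corrected Ct on log2(dilution)
yields the dilution slope (ideal: −1 cycle per halving) and r².
Assays with fewer than two surviving dilution points are flagged unfit
rather than raising.

## Subpopulation discovery

PCA is computed by exact SVD of the column-centered ΔCt matrix, without
unit-variance scaling (the prcomp defaults). Variance fractions are
σ_k²/Σσ², and each component's sign is fixed so its largest-magnitude
loading is positive, making results reproducible across linear-algebra
backends. Cells are partitioned by k-means (k = 3, 25 restarts, fixed
seed) on the first two PC scores. To make the partition independent of
input row order, the model is fitted on a lexicographically sorted copy
of the scores and every cell is then assigned to its nearest converged
centroid (the fixed point of Lloyd's algorithm). Clusters are named
from expression evidence, not from arbitrary k-means indices: the
cluster with the highest mean CD44 and lowest GATA1 (−ΔCt scale) is
Pre-MEP, the highest erythroid-program mean is E-MEP, and the highest
megakaryocyte-program mean is MK-MEP; if two names resolve to one
cluster the run aborts with the evidence table rather than guessing.

The "top-weighted genes" ranking orders genes by the Euclidean norm of
their (PC1, PC2) loadings, descending, ties broken alphabetically —
the combination rule for the two components is our choice, as is the
Ward/Euclidean default for the hierarchical-clustering cross-check
(both exposed as parameters).

For zero-inflated factor analysis, which requires drop-outs near 0, the
Ct data are inverted gene-wise: with Ct_max the largest detected value
of a gene, drop-outs are set to Ct_max + 2 and y = (Ct_max + 2) − Ct.
Anchoring the inversion at Ct_max + 2 (rather than literally inverting
[0, Ct_max]) is deliberate: it sends drop-outs to exactly 0 instead of
−2, which is the stated requirement of the downstream model. Genes
detected in no cell cannot be anchored and are excluded with a warning.

## Gene-subset stability

For each subset cardinality (10…87 by default; any stride can be
configured for quick runs), up to N distinct gene subsets are drawn —
exhaustively when C(G, size) ≤ N, otherwise uniformly without
replacement — and PCA + k-means (first two PCs, k = 3) is repeated on
each subset. Each new cluster is mapped to the *mode* of the reference
labels among its members (collisions allowed; ties to the smallest
reference label), and the congruence is the percentage of cells whose
mapped label equals their reference label. k-means inside the loop uses
a per-subset seed derived from (global seed, size, subset index), so
the whole curve is bit-for-bit reproducible yet subsets are
independent; the full-panel subset reuses the reference seed and
reproduces the reference assignment exactly (100 % congruence by
construction). Alongside each subset a uniformly random assignment is
scored the same way, giving the chance baseline.

Under the mode rule the congruence of a random assignment equals
(Σ_clusters max_label count)/n. Its expectation is computed
independently (`expected_random_congruence`) by scattering each
reference label class over the k clusters as an independent multinomial
— the exact model of a uniform assignment given fixed reference counts
— and averaging the sum of per-cluster maxima. For equal proportions
this approaches Σp² = 1/3; for skewed proportions it approaches the
majority proportion. The Monte-Carlo baseline is validated against
this oracle in the tests.

## Statistics

Population comparisons use the exact two-sample KS statistic
D = sup|F1 − F2| with asymptotic p-values, corrected by
Benjamini–Hochberg across **all** gene × population-pair tests of a run
jointly (the family is configurable); stars are assigned at q < 0.05 /
0.01 / 0.001, with boundary values (q exactly 0.05) marked NS. Fold
changes are 2^(mean ΔCt_rest − mean ΔCt_target) on the linear scale.
Gene networks are pairwise Spearman correlations of −ΔCt
(average-rank ties; drop-outs contribute ties at the detection limit),
thresholded at |ρ| ≥ 0.3 by default — the threshold has no canonical
value and is a parameter. Pairs involving a constant gene have
undefined ρ and are skipped and reported.

## Index-sort gates

Bench gating uses fluorescence-minus-one controls, which have no
computational counterpart, so thresholds are either supplied manually
(always honored verbatim) or derived as the antimode (density minimum)
between the two components of a Gaussian mixture fitted to a marker's
log2 MFI. A marker whose two components are separated by less than 2
pooled standard deviations, or whose minor component weight is < 2 %,
is treated as not bimodal and requires a manual threshold. The surface
scheme is Pre-MEP = CD44-high & CD71− & CD41−, E-MEP = CD71+ & CD41−,
MK-MEP = CD71+ & CD41+; all other combinations are "unclassified"
(between gates) and are excluded from the one-vs-rest
sensitivity/specificity but always counted and reported. When the
panel variant without CD44 is used (CD36 swapped in), Pre-MEP falls
back to the double-negative CD71− CD41− definition; the pipeline also
falls back automatically when CD44 fluorescence is not bimodal enough
to gate.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested. Defaults: three populations at proportions 0.51/0.43/0.06 (the
observed FACS frequencies of the CD71−41−, CD71+41−, and CD71+41+ MEP
subfractions — 43.6, 37.4, 5.1 % of total MEP — renormalized after
excluding between-gate cells); an 87-assay panel with B2M/GAPDH/ACTB
housekeeping, 14 erythroid, 14 megakaryocyte, 8 pre-MEP program genes,
6 surface-antigen transcripts and 42 general hematopoietic regulators.
True Ct per cell and gene is Normal(program mean, cell_sd = 1.2
cycles); program genes sit near Ct 15–16 in their own population and
~30 elsewhere, CD44 is exactly fivefold (2.32 cycles) higher in
Pre-MEP, CD71 (TFRC) is high in both primed populations, and MPO is
near-undetectable everywhere (emulating negligible myeloid
contamination). Drop-out is logistic in the true Ct with midpoint 28
and slope 0.7 cycles⁻¹ — no drop-out model is published for this assay
type; these values yield a realistic ~20–30 % overall drop-out — and
censors to Ct 40. Surface fluorescence per marker is
log2 MFI = slope·(−ΔCt of the encoding transcript) + intercept + noise
(defaults 1.0 / 22 / SD 0.5), computed from the *true* pre-drop-out
expression, since the sorter measures protein regardless of whether the
transcript amplified. One global seed drives all draws through
deterministic per-table substreams, so identical parameters and seed
give byte-identical datasets. Titration tables are generated with a
noiseless slope of exactly −1 per log2 dilution and configurable pool
offsets and noise.

What the generator does **not** emulate: plate/batch spatial effects,
amplification-curve artifacts, donor effects, correlated biological
noise within programs, the partial (≈20 %) CD42 positivity of MK-MEP,
and the much lower signal-to-noise of real single-cell qPCR — the
synthetic populations separate far more cleanly (PC1 carries ~65 % of
variance versus ~9–11 % in real data). Passing tests therefore
demonstrate correctness of the machinery and internal consistency of
estimator and generator, not expected effect sizes on real data; the
deposited-data checks in `tests/test_acceptance.py` cover the latter
when the GSE79331 download is available.

## Problem sizes and numerics

The test suite runs the pipeline at 400 cells (fixtures) and 700 cells
(end-to-end recovery), with 6–30 subsets per robustness size and 20
seeds for estimator-consistency checks; `scripts/acceptance.py` uses
700 cells and 200 subsets at size 25. These sizes give stable
statistics at interactive runtimes. Tolerances: SVD reconstruction to
1e-8 (Frobenius); titration slope recovery ±0.05 per run and ±0.02 over
20 seeds; binomial checks at ±3 SE. Degenerate inputs fail loudly:
constant matrices (PCA), all-drop-out genes (ZIFA transform), missing
housekeeping assays, fewer cells than clusters, naming conflicts.

## Known limitations

- Population naming assumes the panel annotates erythroid /
  megakaryocyte / pre-MEP program genes; an unannotated custom panel
  requires a caller-supplied naming step.
- The asymptotic KS p-value is conservative for very small groups
  (< ~30 cells per population); the rare MK-MEP population can sit near
  that regime in small experiments.
- The mixture-antimode gate assumes a two-state (positive/negative)
  marker; smeared or trimodal markers need manual thresholds.
- FDR is controlled within one run's family of tests; combining runs
  requires re-correction by the caller.
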