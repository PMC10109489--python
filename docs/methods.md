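# Methods

## The analysis model

`topnet` contrasts transcriptomes of two sample groups at the level of an
interaction network rather than gene by gene. The assumptions, in order of
load-bearing:

1. **Counts are negative binomial.** Gene g in sample j is modelled as
   NB(μ_gj, α_g) with Var = μ + αμ². α is one dispersion per gene, shared by
   the two compared groups (the classical "size" parameter is 1/α).
2. **Fold change is signal.** Perturbation is carried entirely by the ratio
   of normalized group means; per-gene significance enters only when DEGs
   are intersected with the mined subnetworks.
3. **Perturbation propagates along edges.** An interaction between two
   strongly perturbed genes is more informative than either gene alone,
   encoded by the edge weight 1/√(N_u·N_v): the weight of a path decreases
   as the perturbation of the genes along it increases, so cheapest paths =
   most perturbed chains.
4. **Specificity by exclusion.** A gene characteristic of the primary
   contrast (disease vs precursor) should not also be captured when either
   condition is contrasted against healthy controls; subtracting the
   control-contrast captured DEGs removes generic disease/inflammation
   signal.

## Differential expression

* **Normalization** — median-of-ratios size factors (per-sample median of
  counts over the per-gene geometric mean, restricted to genes positive in
  all samples), rescaled to geometric mean 1. If no gene covers all samples
  the estimator falls back to total-count ratios and logs it.
* **Dispersion** — pooled within-group method of moments,
  α_g = max((s² − μ)/μ², 10⁻⁸), with variance pooled across the two groups
  ((n_k − 1) weights) and μ the size-weighted group-mean average. No
  shrinkage toward a trend: this is a deliberate, transparent emulation of
  the heavyweight RNA-seq estimators, because downstream network mining
  consumes only (fold change, p) and the package's validation is
  planted-truth recovery, not per-tool equality. The floor keeps Poisson-like
  genes (moment estimate ≤ 0) usable.
* **Wald test** — log2fc = log₂((m_t + c)/(m_r + c)) on normalized group
  means with pseudocount c = 0.5 (keeps zero-count groups finite);
  Var(m_k) = (m_k + α m_k²)/n_k by the NB model; SE by the delta method;
  p two-sided normal. Exactly antisymmetric under swapping test and
  reference. Groups of one sample are allowed but flagged
  (`low_confidence`); their mean-variance is the lone observation's model
  variance.
* **Calibration** — at n = 5 vs 5 the moment/normal approximation is mildly
  anti-conservative: the null p < 0.05 fraction measures ≈ 0.08–0.09 on
  2000-gene NB simulations, inside the contractual [0.025, 0.10] band.
* **DEG call** — |log2fc| ≥ 1 (inclusive: "2-fold") and p < 0.05 (strict);
  Bonferroni-adjusted calls are available behind `use_adjusted`. The
  unadjusted set feeds the network stage by default; which set a published
  analysis used for weighting is generally not recoverable, so it is a flag.
* **Multiplicity** — BH and Bonferroni via `statsmodels.multipletests`.

## Network mining

* **Weights** — node weight FC (active) or 1/FC (repressed); all expressed
  genes contribute their raw fold change (no thresholding before weighting —
  thresholding would discard the gradient the path costs integrate over).
  Network nodes without expression data are dropped, never imputed, and
  counted in the log.
* **Paths** — all-vs-all Dijkstra with a heap keyed on (cost, node
  sequence): among equal-cost paths the lexicographically smallest node
  sequence wins, making results platform- and hash-order-independent.
  Unreachable pairs are omitted; a path has ≥ 1 edge.
* **Normalized cost** — cost divided by the number of edges. This makes a
  one-edge path comparable with a long chain; without it, mining returns
  only trivial single hops.
* **Selection** — default: the lowest ⌈0.005·n⌉ normalized costs per mode.
  Alternative: a permutation null (node weights shuffled k times, edge
  weights recomputed, pooled normalized costs; keep paths below the α
  quantile). The default fraction is a pragmatic knob — no principled cutoff
  exists for this statistic — and both choices are recorded in the TopNet
  provenance.
* **Scaling** — multiplying every node weight by c multiplies every edge
  weight, hence every path cost, by exactly 1/c; path ranking is invariant,
  so only relative fold changes matter.
* **Directionality** — edges are used as loaded; `--undirected` symmetrizes.
  Curated regulatory networks are directed, but the convention of a given
  source file may not be.

## Signature extraction and clustering

Exclusion is by gene identity: a gene captured with direction "up" in a
control contrast also removes a "down" primary gene of the same id, because
cross-comparison direction concordance is not well defined when the
reference groups differ. Directions from the primary contrast are retained
for reporting (up/down partition of the signature). Each subtraction step's
removed/remaining counts are recorded.

Clustering of samples on the signature: rows (genes) are Z-scored with the
population SD (each row exactly mean 0, SD 1; constant rows dropped with a
warning), then average-linkage agglomeration on Euclidean distances between
sample columns. Metric and linkage are conventional defaults, exposed as
options; linkage involves no RNG, so leaf order is deterministic.

## Enrichment

One-sided Fisher's exact test per term: p = P(X ≥ k) for hypergeometric X
with universe N, term size K, query size n. The universe defaults to genes
present in both the expression table and the collection — an offline,
reproducible stand-in for a web service's internal background, and the main
reason enrichment p-values are not comparable across universes. BH-adjusted
p-values accompany every table; the significance filter is strict (< α).

## Clinical statistics

NLR is computed per patient (neutrophil % / lymphocyte %) and then
summarized — mean of ratios, not ratio of means — so a dispersion
accompanies each group. Group summaries are mean ± sample SD (n − 1);
single observations report SD as missing. Default two-group comparison is
Welch's t (no equal-variance assumption); Mann-Whitney is available for
small or skewed groups. The test identity is always written into the output.

## The synthetic-data generator

What it emulates: a four-group whole-blood cohort (ARF 5, RHD 5, CHD 5,
HC 2 — the small-n healthy-control pathology is exercised on purpose),
log-normal baseline expression, NB counts, library-size heterogeneity, a
scale-free directed interaction network over the genes, and a clinical table
with realistic group means/SDs (clinical cohort sizes CHD 30 / RHD 30 /
ARF 17).

Defaults, chosen once as realistic study conditions:

| parameter | default | why |
|---|---|---|
| `n_genes` | 1000 | enough for stable size factors and multiplicity, small enough for seconds-scale runs |
| `network_nodes` / `network_edges_per_node` | 300 / 2 | sparse scale-free graph (~600 edges) with pronounced hubs |
| `baseline_log_mean`, `baseline_log_sd` | 5.0, 1.0 (natural log) | median ≈ 150 counts, realistic dynamic range |
| `dispersion` α | 0.05 | moderate biological variability for whole blood |
| library-size factors | log-uniform [0.7, 1.4] | makes normalization non-trivial; can be disabled |
| `planted_module_size` | 20 | large enough to be a subnetwork, small vs the graph |

Planting scheme of `simulate_study`: the 20-gene module receives +1 in RHD
and −1 in ARF (net log₂FC = 2 in the primary contrast). The arithmetic
constraint |lfc(RHD−HC)| + |lfc(ARF−HC)| ≥ |lfc(RHD−ARF)| means a gene
differential in the primary contrast is *necessarily* differential against
HC in at least one control contrast; the symmetric split keeps both control
exposures at the 2-fold borderline. Specificity of the signature therefore
rests on TopNet capture, which is controlled by two decoy modules planted in
HC (log₂FC ∓3, i.e. strongly active and strongly repressed in every
X-vs-HC contrast): the module is planted in the low-degree periphery
(BFS biased to low-degree nodes, insulated from the decoys' neighborhoods
where the graph allows), the decoys on hubs, so control-contrast shortest
paths concentrate on the decoys and the module stays out of the control
TopNets. Gene sets include the module, both decoys and 20 random sets.

What the generator does **not** emulate — hence what green tests do not
show about real data: batch effects and covariates, GC/length biases,
zero-inflation beyond NB, correlated co-expression outside the planted
module, annotation errors in the network, direction-specific edge semantics,
and clinical covariate structure. Recovery percentages on real cohorts will
be lower and should be read qualitatively.

## Numerical choices and degenerate inputs

* Pseudocount 0.5 on normalized group means; dispersion floor 10⁻⁸.
* SE = 0 with log2fc = 0 yields Wald 0, p = 1 (duplicated groups are null).
* Dijkstra ties broken by lexicographic node sequence; ranking ties by
  (normalized cost, cost, node sequence); float-equal costs are the only
  ties, which for continuous weights occur only by construction.
* Selection threshold comparisons are strict (<); an all-below-minimum
  threshold yields an empty TopNet plus a warning, not an error.
* Empty query / empty GMT / constant clustering rows degrade to empty
  outputs with warnings; zero counts-network overlap is fatal.
* All generators and the pipeline are pure functions of (config, seed);
  reruns are byte-identical (the config hash stamped on outputs excludes the
  output directory).

## Known limitations

* The Wald test is anti-conservative at n ≈ 5 (see calibration above);
  p-values should be read as ranking scores at that scale, which is how the
  network stage uses fold changes anyway.
* The top-fraction path cutoff is arbitrary; the permutation threshold is
  principled but quadratic-cost per permutation, so it defaults off.
* End-to-end signature recovery of the planted module is stochastic: the
  TopNet capture of the module and the zero-leakage guarantee are robust
  across seeds, but individual module genes sit at the 2-fold borderline in
  control contrasts by construction and can occasionally be captured (and
  excluded) there; with the shipped default seed recovery is complete.
* Enrichment p-values depend on the chosen universe and are not comparable
  with web-service results computed against proprietary backgrounds.
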