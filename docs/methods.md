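# Methods

This note documents the models, numerical choices and known limitations of
`crosstalk`, stage by stage, and what the synthetic-data generators do and
do not emulate.

## Fragment processing and differential abundance

The quantitative unit is the MS2 fragment; several fragments quantify one
phosphopeptide across (sample, condition, replicate) runs. Intensities are
linear and non-negative; all logs are base 2.

**Filter cascade.** Four gates run in a fixed, recorded order:

1. absolute intensity — values ≤ 2000 become missing (strictly-above kept;
   the boundary reading is documented here and in the docstring);
2. detection — a fragment must be observed ≥ 2 times in at least one
   condition;
3. consistency — within a peptide, a fragment is dropped when its log2
   profile correlates < 0.25 with the peptide's median fragment profile
   (computed over ≥ 3 shared runs), or when its mean log2 intensity sits
   more than 2 standard deviations from the consensus of the peptide's
   fragment means (applied when the peptide has ≥ 3 fragments; both rules
   are evaluated on the pre-drop set so one pass is deterministic);
4. fragment count — peptides with < 5 surviving fragments are dropped.

The consistency rules are this package's documented interpretation of an
"SD factor" and "minimal correlation" fragment filter; upstream tools that
implement such filters do not publish their exact predicates, so these are
substitutes, not reconstructions. The order intensity → detection →
consistency → count is likewise a package choice, recorded in the output
provenance (`attrs["filter_order"]`).

**Imputation.** Missing replicate values become 0.2 × the fragment's
minimum observed intensity; observed values are never altered; fully
missing fragments are dropped with a warning. This floor-style imputation
deliberately preserves "low because suppressed" signal: a treatment that
drives a site below the absolute filter still yields a strongly negative
fold change after imputation.

**Site mapping.** Peptides are located in their protein by exact substring
search; positions are 1-based; the residue letter is read off the protein
sequence and wins over the peptide annotation on conflict (logged). A
peptide occurring multiple times uses the first occurrence (flagged);
multiplicity is the number of phospho-residues on the peptide.

**Differential test.** Fragments are summed to a peptide signal per run;
log2 signals are compared by a two-sample Student t-test (equal-variance;
with 2–3 replicates per group a Welch correction has essentially no
leverage) and log2FC is the difference of group means. When several
peptides map to one site, the peptide with the higher mean control signal
is kept (ties: lexicographically smallest peptide id). BH adjustment runs
across sites within a treatment. This transparent engine — rollup + t-test
+ BH — replaces a model-based differential-abundance tool by design; the
engine name is recorded in the output `attrs`. Degenerate inputs: equal
groups with zero variance give p = 1; zero-variance separation gives p = 0
(only noise-free synthetic data can produce it).

## Site-centric signed enrichment

Site scores are sign(log2FC) × (−log10 max(FDR, floor)) with a default
floor of 1e-10; a zero fold change scores 0. Multiply-phosphorylated
records are demultiplexed into their constituent single sites carrying the
parent score; collisions keep the larger |score| (ties keep the
pre-existing single-site record).

For a signature, member sites annotated "down" have their scores negated
(direction adjustment); sites are then ranked by descending adjusted score
(stable sort). Walking the ranking, members add |adjusted|^w normalized by
the member total, non-members subtract 1/(#non-members). The default
statistic is the **area under the running enrichment statistic** — the mean
of the running sum over all rank positions; the classic maximum-deviation
ES is available via `statistic="max"`. The area reading was chosen as the
default because it is the variant whose name describes an integral of the
running statistic; both are exposed and the choice is recorded in the
output `attrs`. With the member and non-member contributions each summing
to one, the running sum returns to zero, which makes the area exactly
antisymmetric under negation of all input scores (a property test).

**Null model.** Permutations reassign scores to sites (site-label
permutation), preserving the number of members and their direction
composition; each signature draws its nulls from the seeded generator, so
results are reproducible. NES = ES / mean(|ES_perm|) among same-sign
permuted ES; p is the same-sign tail fraction (a signature with no
same-sign permutations is reported missing with a reason). FDR is BH per
signature category (KINASE/PERT/PATH) by default, globally on request.
1000 permutations is the desk-scale default (the permutation count is
recorded in `attrs`); raise `n_perm` for finer p resolution. Signatures
with fewer than 2 measured sites are excluded.

Under a global null the same-sign tail fraction is calibrated: p ≤ α iff
the observed ES lies in the two α/2 tails of the symmetric permutation
distribution, verified empirically over 500 random signatures.

## Subnetwork extraction

Nodes of the prior carry kinase-signature NES/FDR; edges carry the log2FC
and FDR of the measured phosphosite matching one of the edge's annotated
residues on the target (smallest FDR wins when several match). Unannotated
elements carry no attribute — absence means unmeasured, never zero.

Perturbed nodes (FDR ≤ 0.05) and perturbed edges (FDR ≤ 0.05; thresholds
inclusive) seed the candidate graph. For every ordered pair of perturbed
nodes with directed shortest-path distance ≤ 2 (hop count; unit weights),
*all* shortest paths are added. The largest component under undirected
connectivity is returned; ties break by total |NES|, then by the
lexicographically smallest node set — determinism over aesthetics. Paths
are computed on the directed graph by default (the prior is causal; the
conservative reading), with an undirected option.

**Pruning.** When a perturbed-node pair is connected by several shortest
paths and at least one is fully phosphosite-annotated, unannotated
alternatives are removed — but only elements serving no other retained path
and not themselves perturbed, and any removal that would disconnect the
subnetwork rolls back for that pair. This predicate (prefer fully annotated
paths, drop orphaned unannotated alternatives, never disconnect) is one
consistent reading of "pruning redundant paths by phosphosite annotation";
it is intentionally conservative.

**Merging and summaries.** Treatment subnetworks union into a per-sample
network; `n_subgraphs` counts the treatments containing each node;
per-treatment attributes are kept side by side, never averaged. Degree
centrality is degree/(n−1) on the undirected simple projection;
eigenvector centrality uses power iteration on A + I (the shift guarantees
convergence on bipartite graphs) to tolerance 1e-10, max-normalized; on a
disconnected merged network the vector concentrates on the spectrally
dominant component, and an isolated single node gets 1 by convention.
Mutation overrepresentation is a two-sided Fisher exact test of subnetwork
vs background (prior minus subnetwork) mutated counts, two-sided by
point-probability summation (the convention of mainstream statistics
libraries).

## Spatial statistics

Marker positivity is positive-area fraction ≥ 0.10 (inclusive). Densities
are counts / frame area with 1 mm² = 10⁶ µm².

**Voronoi neighbors.** Sites are mirrored across the four ROI edges before
tessellation, which bounds every original cell and clips it exactly to the
frame without polygon arithmetic; neighbors are pairs of original sites
whose shared ridge has positive length (> 1e-9 µm), so degenerate-lattice
point contacts are excluded. Exactly duplicated coordinates are jittered by
1e-6 µm with a logged seed; collinear inputs raise with guidance. The test
suite checks this construction against an independent half-plane polygon
oracle.

**Interaction test.** Observed neighbor-edge counts per unordered phenotype
pair (same-type pairs included) are compared with 1000 label permutations
over fixed positions; phenotype counts are preserved by construction. Z =
(obs − mean)/sd; the p value carries an add-one correction and is therefore
never exactly 0. The default p is two-sided (double the tail in the
direction of the deviation, capped at 1), which is calibrated at its
nominal level under complete spatial randomness — verified over 100 CSR
maps; a raw directional tail is available via
`alternative="directional"`. Calls: attraction Z > 2 & p < 0.01, avoidance
Z < −2 & p < 0.01 (the threshold pair reads the published "Z < 2 / Z > 2"
convention as |Z| > 2; thresholds configurable). Degenerate nulls (sd = 0,
e.g. a single phenotype) are flagged, not called. Cohort combination is
Stouffer's ΣZ/√k over ROIs, degenerate ROIs excluded upstream.

**Microaggregates.** The neighbor graph restricted to PD-L1+ tumor or
PD-1+ immune cells is decomposed into connected components; components with
at least one cell of each class qualify. The count statistic is permuted by
shuffling the two flag vectors independently (class sizes fixed). Note the
count is informative when the flagged populations are sparse: abundant
flags merge into few large components and co-aggregation can *lower* the
count. The generators provide a contact-pair placement pattern for this
regime (below).

## Complex co-abundance and mRNA–protein correlation

Complex scores are the mean of all pairwise member Pearson correlations on
pairwise-complete observations (pairs with < 3 shared samples skipped,
logged); complexes with < 5 measured members are excluded. The ranked list
splits into quartile classes: the ⌈N/4⌉ highest-scoring complexes are
labelled **stable** (coordinated subunits) and the ⌈N/4⌉ lowest **variable**
— the classes are named by what the correlation means, since "top/bottom"
phrasing is ambiguous between score and rank directions; ties break by
complex id. Subunit variance uses the unbiased n−1 denominator over
observed values (members with < 2 observations are missing, logged).
Gene-wise mRNA–protein correlation matches samples by name and requires
≥ 4 paired observations per gene.

## Synthetic-data generators

All generators funnel randomness through one `numpy.random.Generator`
seeded explicitly; identical arguments and seed give byte-identical tables.

- **Prior network**: kinases and substrates, a random spanning structure
  first (weak connectivity guaranteed; an impossible density raises with
  the minimum), then random kinase→target edges to the requested density;
  signs +1 with probability 0.7; 1–2 residues per edge with positions
  unique per target protein. The proteome generator plants the annotated
  residue letters at the annotated positions.
- **Perturbation dataset**: one peptide per annotated edge site plus
  ~30 background sites; 5–6 fragments per peptide with log-normal baselines
  (log2 mean 12, SD 1 for background — the absolute 2000 ≈ 2^11 filter
  removes a real tail, keeping it testable; planted peptides sit at log2
  mean 14.5 with 6 fragments so they survive filtering even after a −3
  shift). Sites on edges within two hops downstream of a target shift by
  ±effect_log2 opposite the edge sign (inhibition semantics). Fragments of
  a peptide share a per-run random effect (SD = 2 × noise_sd) so fragment
  profiles correlate as they do across real injections; without it the
  consistency filter would discard null-peptide fragments at random.
  Defaults (effect 3, noise 0.1, 3 replicates) are the standard validation
  conditions.
- **Cell maps**: uniform placement (CSR) for non-interacting phenotypes; a
  planted pair rearranges a fraction 1 − exp(−strength/2) of both
  phenotypes, either into shared Thomas clusters (σ = 12 µm, ~15 daughters
  per cluster assigned round-robin so every cluster mixes both phenotypes —
  broad co-aggregation) or into contact pairs (σ = 8 µm around individual
  partner cells — many small heterotypic contacts, the regime where
  microaggregate counts exceed chance). Strength 0 is exactly CSR; the
  saturating fraction makes "strength 5" a strong, reliably detectable
  aggregation. Markers default to one signature marker per phenotype,
  Beta(8, 2) on its own phenotype and Beta(1, 30) elsewhere.
- **Complex abundances**: equicorrelated members via a shared per-sample
  latent factor (pairwise correlation ρ), member means ~N(25, 2); listed
  noise complexes get ρ = 0.

**What the generators do not emulate**: raw spectra, chromatographic or
batch effects, peptide misidentification, segmentation errors, cell-size
variation, marker spillover, and any real biological network topology
(edges are random, not curated). Passing tests therefore demonstrate that
the algorithms recover what was planted under clean statistical structure,
not that they are robust to every artifact of real acquisitions.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use desk-scale sizes
chosen as the package's standard conditions: 200 random graphs (≤ 30
nodes) for subnetwork oracle equivalence; 50 seeded runs (10 kinases, 20
substrates, density 0.15; targets drawn among kinases with ≥ 2 outgoing
sites so their signature clears the minimum overlap) for parameter
recovery; 100 instances (≤ 50 sites) plus a 500-signature null at 1000
permutations for enrichment; 100 CSR maps and 50 planted maps of 500 cells
at 1000 permutations for spatial calibration and power; 100 point sets for
geometry. The full sweep runs in about a minute on one CPU.

## Known limitations

- The differential engine is a simple t-test; with 2 replicates per group
  (as in minimal designs) power rests almost entirely on the BH step and
  effect size.
- The enrichment permutation scheme is site-label permutation only; sample
  permutation is out of scope for the single-sample site-centric design.
- Eigenvector centrality on disconnected merged networks reflects the
  dominant component only.
- Voronoi adjacency treats the ROI frame as a hard boundary; cells whose
  true neighborhoods extend past an ablation edge are clipped, as they are
  in the imaging reality.
- The pruning predicate and the directed-path default are documented
  choices among several defensible readings; both have escape hatches
  (`directed=False`, pruning is optional).
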