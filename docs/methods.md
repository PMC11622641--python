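# Methods

## The specificity metric

Specificity is defined on a *landscape*: two (or more) habitats, each a set
of samples over a shared species list. For species *i* and habitat *h*,

S(i,h) = P(i,h) × A(i,h),

with P the within-habitat prevalence and A the habitat's share of the
species' landscape-wide abundance. A is computed from **habitat-mean
relative abundances**: each sample's counts are converted to relative
abundances, averaged within the habitat, and the habitat means are
normalised to sum to one across habitats (0 when the species is absent
everywhere). The habitat-mean (rather than pooled-total) form makes A
insensitive to unequal cohort sizes, which real paired cohorts almost
always have. The product form is the simplest function satisfying the
required properties — S ∈ [0,1], S = 0 iff locally absent, S = 1 iff the
species occurs in every sample of the habitat and nowhere else, and S
responds to both abundance and distribution. The formula lives in one
function (`specificity_from_groups`) so an alternative definition can be
swapped without touching the tests' interfaces. Consequences worth noting:

* S is invariant to per-sample library size (relative abundances only).
* Across habitats, a species' shares are compositional: raising its
  abundance in one habitat necessarily lowers its share elsewhere.
* The same routine serves the two-habitat tests and the multi-site
  (sites-as-habitats) network path.

The pipeline operates on counts as given; no rarefaction or normalisation
is applied (library-size invariance makes scaling moot, and normalisation
choices are deliberately out of scope).

## Specificity diversity

SD(q) is the Hill number of the relative specificities p_i = S_i / Σ S_j
over the species of an assemblage with S > 0. SD(0) is the count of
positive-specificity members — an assemblage member absent from a habitat
contributes nothing there, so SD(0) is the richness of the assemblage *as
realised in that habitat*. SD(q) is non-increasing in q and equals
richness exactly at uniform specificity. `sd_hill` accepts any real
q ≥ 0; pipelines use the grid {0, 1, 2, 3, 4}.

Degenerate conventions: in the user-facing profile (`sd_profile`) an
assemblage with no positive-specificity member in a habitat records
SD(0) = 0 and flags higher orders undefined. Inside the permutation
machinery SD of such an empty column is taken as 0 so that richness
collapse (e.g. a unique-species assemblage, empty on one side by
definition) is visible to the test statistic; without this convention the
unique-species assemblages could never be compared at all.

## Permutation tests

Both tests share one null: the m+n sample labels are reassigned uniformly
at random into groups of sizes m and n, and the full specificity table —
prevalence and abundance share — is recomputed per reassignment. Whole
samples (columns) are permuted, never per-species values, preserving
within-sample species correlation; the sample is the exchangeable unit
under "no cohort effect". The statistic is the absolute specificity
difference T = |S_A − S_B| per species (SP) and D(q) = |SD_A − SD_B| per
assemblage and order (SDP); the absolute difference is symmetric, defined
when one side is zero (a fold change is not), and makes the
duplicated-cohort control analytically exact (T ≡ 0, p ≡ 1).

P-values use the add-one estimator p = (1 + #{T\* ≥ T}) / (1 + n_perm), so
min p = 1/(1+n_perm) and p ≤ 1. Tail counting uses T\* ≥ T − 1e−12 to keep
float noise from dropping exact ties. An exhaustive mode enumerates every
distinct label assignment (capped at 5×10^5) and returns the exact null
fraction; the Monte-Carlo p converges to it. FDR control is
Benjamini–Hochberg (`statsmodels.stats.multitest`), the field default, and
is isolated behind the test interface. alpha defaults to 0.05 and is
configurable (0.01 replication is one flag away). Species with zero counts
in both habitats are excluded — their statistic is degenerate and they
cannot be classified.

SDP permutes at the landscape level with assemblage membership held fixed
(membership comes from an SP run on the observed labels). Assemblages with
fewer than two positive-specificity members anywhere are recorded as
not-testable rather than raising: a singleton's SD is 1 at every order,
leaving no variation for the null to rank.

Statistical power note baked into the tests: a lone true effect among N
tested species can only survive BH if the minimum attainable p,
1/(1+n_perm), is below alpha/N; test scenarios size n_perm accordingly.

## Volcano catalogue

x = log10(S_A/S_B), y = −log10 p. When one side is zero the log is
undefined; that side is substituted by epsilon = half the minimum positive
specificity among tested species, and a `zero_flag` records which side was
substituted, so the transform is lossless (the raw pair is also emitted).
The substitution is monotone and keeps x antisymmetric under habitat swap.
Species with both sides zero carry no information and are skipped.

## Networks

The species×site specificity matrix for one cohort treats the sites as
habitats of a multi-site landscape, so shares compete across sites; only
species with S > 0 at every site are retained. The SSN correlates species
(rows) across sites, the SHN correlates sites (columns) across species —
the two modes are transposes of each other and produce identical networks
on mutually transposed input (asserted as a property). Edges: Spearman
rho with BH-adjusted p < alpha (default 0.01), sign = sign(rho), weight =
|rho|. Spearman p-values come from scipy's t-approximation; with few
paired observations (< 5 sites/species) this is crude and a warning is
emitted. Constant profiles have undefined rho and are skipped.

Annotations: P/N ratio (undefined — `None` — with no negative edges);
hubs = maximum-degree nodes (all tied nodes flagged); clusters = Louvain
modularity on |rho| (seeded), ranked by mean intra-cluster |weight|;
core/periphery = discrete labeling maximising the Pearson correlation
between the scaled |weight| adjacency and the ideal pattern matrix
(core–core = 1, periphery–periphery = 0, core–periphery pairs free and
excluded), optimised by seeded greedy single-node label swaps with 10
restarts (one degree-informed start, the rest random) per connected
component of ≥ 3 nodes; smaller components are periphery by convention.
When either vector is constant the correlation degenerates and the score
falls back to 1 − mean|adjacency − pattern|, which ranks exact agreement
highest; ties are broken toward all-core (so a complete graph is all core,
an edgeless graph all periphery). On the 10-node clique-plus-pendants
benchmark the greedy optimum matches exhaustive search over all 2^10
labelings.

## Synthetic data generator

The generator emulates the statistical shape of 16S OTU tables, not any
real taxonomic composition:

* **Abundance**: log-normal base abundances (mean 0, sigma 1.5 on the log
  scale) — the long right tail typical of species-abundance
  distributions.
* **Occupancy**: per-species detection probability drawn from a
  Beta(0.7, 1.7) scaled onto [0.05, 1] — many sparse taxa, few
  near-ubiquitous ones, which also gives the right-skewed specificity
  distributions seen in real surveys.
* **Counts**: per sample, species are thinned by occupancy and reads drawn
  multinomially at fixed depth (default 10^4).
* **Planted unique species**: probability zero in the other habitat,
  occupancy `us_prevalence` (default 0.9) in their own.
* **Planted enriched species**: abundance ×`es_effect` (default 8) and
  occupancy +`es_prevalence_shift` (default 0.2) in their habitat, on a
  baseline-occupancy floor of 0.5 — an enriched species is by construction
  observable on both sides, otherwise a prevalence shift is meaningless.
* Planted species also get a base-abundance floor (3 relative units,
  ≈ 10 expected reads when present at default depth) so "occupied" implies
  "detectable"; a planted effect invisible to sequencing would test the
  sequencer, not the statistic.
* **Multi-site mode**: sites grouped into habitat-like blocks (default
  9 oral / 4 skin / 1 airway / 1 stool analogue); a designated ubiquitous
  subset is present everywhere with high abundance floors, each assigned a
  preferred block where its abundance is multiplied by `block_effect`
  (site-level log-normal jitter shared across that site's samples); the
  remaining species are block specialists, zero outside their block.
  Because shares compete across sites, same-block site pairs become
  positively and cross-block pairs negatively associated in specificity —
  the ground truth for SHN recovery. `block_effect = 1` switches the
  structure off.

All randomness flows through one `numpy` generator seeded from the config;
outputs are bit-reproducible. What the generator does **not** emulate:
phylogenetic correlation between species, overdispersion beyond
multinomial (no Dirichlet stage), sample-to-sample depth variation, or any
real taxon identities — so passing tests demonstrate correct behaviour of
the statistics under the modelled mechanisms, not performance guarantees
on a particular real dataset.

A compositional caveat that shows up in planted-effect runs: boosting some
species' absolute abundance in one habitat dilutes every other species'
relative abundance there, so strong planted enrichment produces genuine
(not artifactual) opposite-side enrichment signals among null species.
Recovery metrics therefore measure sensitivity on planted species, not
specificity against side effects that the metric is designed to see.

## Calibration and problem sizes

Type-I error of the SP test is assessed on a null simulation in the
detection-saturated regime (occupancy scaled onto [0.9, 1], depth 10^5):
sparse species have granular, conservative permutation p-values (often p
cannot fall below alpha at all), which is valid but would mask genuine
miscalibration; the dense regime is where a calibration failure would be
visible. The suite and the acceptance script use 200–1000 species, 25–30
samples per cohort and 1000 permutations (5000 where a lone effect must
clear BH, per the power note above), which keeps the full test run in
seconds on one CPU while matching the cohort sizes the statistics are
meant for.

## Known limitations

* The Monte-Carlo SP/SDP p-values share one set of permutations across
  species, which induces weak dependence between p-values (irrelevant for
  per-species inference, slightly inflating the variance of aggregate
  false-positive counts).
* Spearman edge p-values are asymptotic; with 15 sites they are
  approximate and no additional rho threshold is applied.
* The half-divided negative control halves the sample size, so its
  false-positive count reflects power at n/2, not only FDR behaviour.
* Fold changes with a zero denominator are reported as infinity and only
  the volcano transform substitutes epsilon; downstream consumers should
  use the raw specificity pair for arithmetic.
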