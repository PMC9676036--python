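# Methods

## Problem and model

`seapha` screens bacterial genomes for the co-occurrence of two independently
evolved capabilities: degradation of macroalgal cell-wall polysaccharides
(SPD) and biosynthesis of polyhydroxyalkanoates (PHA). The screen is purely
annotation-driven. A genome is represented as a multiset of gene labels —
CAZy family labels (`GH<j>`/`PL<j>`, optionally with subfamily, `GH16_3`) and
PHA gene names (`PhaC`, `FabG`, …) — and every decision is a deterministic
function of these multisets, a taxonomy, and fixed thresholds. No sequence
analysis, HMM searching, or flux modeling is performed; those belong to the
upstream annotation tools whose tabular output this package consumes.

### Algal class scheme

Three fixed sets of CAZy families act as proxies for degrading each algal
group: 10 green-acting (ulvan), 16 brown-acting (alginate, laminarin,
fucose-containing sulphated polysaccharides) and 12 red-acting (agar,
agarose, carrageenan, porphyran) families. The sets overlap — GH3 is both
green- and brown-acting — and every derived quantity counts a shared family
toward *each* class containing it; no exclusion or fractional weighting is
applied. Subfamilies are distinct labels: `GH16_3` is brown-acting while the
bare `GH16` matches nothing. The scheme is replaceable by a two-column TSV.

### Density and unique class counts

"Density" is the raw occurrence count of a label per entity (genome or
taxonomic family), not a per-Mb rate. Duplicate (genome, gene, label) rows
count once; a gene annotated with two distinct labels counts once per label
(multi-module CAZymes are real). Family-level densities are the sums of the
member-genome rows under the family-rank ancestor; genomes whose lineage has
no family rank go to an `UNKNOWN` row that is kept for genome-level screens
but dropped from family-level reports. For display, counts are transformed
as log2(count + 1) so zero maps to zero.

Cohort summaries report mean ± SEM of per-genome class density. Published
mean±x notation is ambiguous between SD and SEM; both are computed and
carried on the summary object.

### Filter cascade

Genome tiers are nested by construction (each rule is evaluated within the
previous tier) and every comparison — observed value, threshold, verdict —
is written to an audit table. Defaults:

| rule | default |
|---|---|
| polymerase-positive | ≥1 of PhaC, PhaC2, PhaE |
| SPD-positive | ≥1 unique scheme family |
| enriched | total unique ≥ 3 AND max class unique ≥ 2 |
| highly enriched | max class unique ≥ 3 |
| top percentile | d_class ≥ P70 within highly-enriched, per class |
| family enriched | u_red ≥ 2 OR u_green ≥ 4 OR u_brown ≥ 4 |

Design choices where the published wording is open:

* "≥2 for any of the 3 macroalgal groups" is read as *at least one* group
  reaching 2, not every group — the alternative would exclude the
  green/brown specialists the screen is known to retain.
* The highly-enriched rule is applied per genome; the families represented
  by those genomes are reported downstream rather than filtered at family
  level.
* The percentile population is the highly-enriched subset, per class, on
  occurrence sums (`percentile_metric="occurrences"`); counting unique
  families instead is a config switch, as is nearest-rank percentile
  semantics. The default percentile method is linear interpolation between
  closest ranks with an inclusive ≥ comparison, matching the default of the
  mainstream numerical stacks; ties at the threshold are all retained.
* Tier nesting is enforced by default for auditability; `nested=False`
  evaluates each rule on the full universe instead.

### PHA pathway resolution

The catalog maps 22 genes to roles (3 synthases, 12 monomer-synthesis
genes, 3 phasins, 3 regulators, 1 depolymerase) and monomer-synthesis genes
to the five hydroxyacyl-CoA monomers. Resolution is a union over present
genes; a genome with a synthase and an empty monomer set is *unresolved*.
FabG maps only to (R)-3HA-CoA by default; the literature-discussed
FabG→3HB-CoA route is available as `fabg_also_3hb=True` but off, because the
formal map keeps the default behavior reproducible. 3HV-CoA requires only
PhaB; substrate (propionate) availability is not modeled. The class III
two-subunit synthase configuration is exposed as a derived flag
(`class_iii_possible` = PhaC ∧ PhaE), never as a filter.

### Co-occurrence statistics

For label pairs over a genome cohort: sample Pearson r on raw count vectors
(log2 is switchable) with two-sided p from the t distribution on n−2 df;
Jaccard distance 1 − |A∩B|/|A∪B| over presence sets (presence = count > 0,
threshold configurable). Constant vectors make r undefined and are flagged
(NaN), not silently zeroed; an empty union makes jd undefined likewise.
Raw p-values are the reported criterion (the field convention here is
uncorrected P < 0.05); Benjamini–Hochberg q-values are exported alongside
for transparency. The co-occurrence network takes an edge wherever
co-presence reaches `min_copresence` (default 1), with node size and edge
weight log2(count+1). Cluster assignments come from agglomerative
clustering (Euclidean distance, average linkage by default) of the log2
profiles — a deterministic replacement for stochastic block-model layouts,
which are presentation-layer and parameter-unstated. Layout itself is left
to external tools via GraphML export.

### Quality gate and marine filter

All four gate comparisons are inclusive exactly as worded: N50 ≥ 50 000,
completeness ≥ 95 %, contamination ≤ 5 %, marker count = 31 (the marker
count cannot exceed 31, so equality is the same as ≥). The verdict carries
each rule's boolean; `overall` is their conjunction, which makes the gate
monotone in every metric. The marine keyword list shipped as default
(marine, sea, seawater, ocean, coastal, estuar, tidal, saline, sediment,
hydrothermal, reef, mangrove, macroalga, seaweed, kelp) is a stand-in for
externally published keyword sets and is fully replaceable; matching is
case-insensitive substring (recall over precision — "estuar" hits
"estuarine"), and the matched keyword is reported for auditing.

## Synthetic data

The generator produces the stated world every test runs in:

* **Taxonomy** — balanced root/phylum/order/family/species tree (families
  grouped 4-per-order, orders 4-per-phylum; each genome its own species).
  This exercises lineage tracing and family aggregation; it makes no claim
  of realistic taxon richness.
* **Background counts** — independent Poisson draws per (genome, label).
  Default rates give ≈1.5 distinct scheme families and a ≈50 % synthase
  carriage per genome, so the tier attrition profile is qualitatively like
  a real archive screen (most polymerase-positive genomes fail enrichment).
* **Planted correlations** — selected label pairs (default PhaG–GH50 at
  ρ = 0.54, the magnitude of the strongest association this kind of screen
  reports) are drawn from a Gaussian copula over Poisson(3) marginals. The
  latent correlation is calibrated by a dense-grid integral of
  E[X·E[Y|Z₁]] (the conditional mean is smooth even though the Poisson
  quantile is a staircase), solved by Brent's method; Monte Carlo agreement
  is within ±0.01.
* **Planted candidates** — genomes planted for a tier carry exactly a fixed
  label multiset guaranteeing that tier (e.g. `spd` = PhaC + 1 green
  family; `enriched` = PhaC + 2 green + 1 brown; `top` = PhaC + 4 green +
  4 brown + 3 red families at 8 copies each) and no background draws.
  Because all planted "top" genomes share one multiset, the percentile
  population within the planted-only case is all ties and the inclusive cut
  retains all of them; the high copy number puts them far above any
  background genome that crosses into the highly-enriched tier by chance.
  Background crossings of lower tiers are allowed and expected.
* **Metadata** — a Bernoulli marine split (default 0.3) over fixed
  marine/terrestrial source strings, and an exact-count quality partition:
  round(fraction·n) genomes violate exactly one randomly chosen gate rule
  by ≥1 unit, the rest pass every rule with margin. The default fail
  fraction 0.88 mirrors the ≈12 % high-quality yield typical of marine
  genome archives. Real metadata fails multiple rules at once; the
  single-rule construction is what makes per-rule attribution testable.

All randomness flows through one `numpy` generator seeded once; row orders
are fixed, so identical seeds produce byte-identical files. A green test on
synthetic data establishes that the pipeline's logic matches its stated
rules and recovers planted structure — it does not establish performance on
real archives, whose annotation noise, taxon imbalance and metadata
sparsity the generator deliberately does not emulate.

## Numerical choices

* Percentiles: `numpy` linear interpolation; nearest-rank is
  ceil(q/100·n)-th smallest. Comparisons inclusive.
* log2(count+1) everywhere a log display scale is needed (zeros must be
  representable).
* Pearson p-values via `scipy.stats.pearsonr`; vectors shorter than 3 or
  constant are rejected/flagged rather than approximated.
* Hierarchical clustering: `scipy` linkage on Euclidean pdist; leaf order
  is scipy's deterministic dendrogram order, ties broken by input position.
* Copula calibration: trapezoid on an 8001-point grid over z ∈ [−8, 8],
  Poisson quantiles clipped at u = 1 − 10⁻¹³ to avoid infinite tails.
* Taxonomy validation walks every node to the root with a step budget, so
  cycles and dangling parents fail construction, not traversal.

## Known limitations

* The screen reproduces rule logic, not the published candidate counts —
  those depend on specific database snapshots (CAZy v07312019, RefSeq)
  that are not shipped and not desk-recomputable.
* Family aggregation trusts the provided taxonomy; merged or renamed taxa
  across database versions are the caller's concern.
* The marine keyword list is heuristic; isolation-source free text is
  notoriously sparse and inconsistent, and substring matching trades
  precision for recall by design.
* Pathway resolution is presence/absence only; it cannot distinguish a
  functional pathway from a pseudogenized one, and divergent synthases
  missed by upstream annotation are invisible to it.
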