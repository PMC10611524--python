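# Methods

## The decontamination model

Low-biomass amplicon profiles mix three signals: a resident community, taxa
introduced by reagents and handling ("kitome"), and taxa introduced by the
sampling route. The pipeline treats these with two mechanisms, applied in a
fixed order inside `decontaminate()`:

1. **published exclusion lists** — a priori removal by name;
2. **Spearman co-occurrence screening** against indicator contaminants;
3. **manual exclusion list** — a final analyst-curated removal.

The ordering matters only for attribution, not for what the correlation
stage sees: correlations are computed once, on the table as it stands after
list removal, with relative abundances renormalized to the remaining taxa.
There is no iterative recomputation after correlation removals — a second
pass would re-rank abundances on a shifted denominator and make the audit
trail depend on removal order, without a principled stopping rule.

### The correlation screen

For taxa *t* and indicators *i*, ρ(t, i) is the Pearson correlation of the
midrank-transformed abundance vectors across samples. Design choices:

* **Transform** (`DecontamParams.transform`, default `relative_abundance`):
  Spearman is invariant to any strictly increasing transform of a *single*
  vector, but per-sample depth differences act across taxa — on raw counts,
  two unrelated taxa co-vary simply because deep samples inflate both.
  Per-sample proportions remove that artifact. `raw_counts` is available
  for tables already normalized upstream or for exact constructed examples.
* **Strict threshold** (`rho_threshold`, default 0.3): a taxon is removed
  only when its maximal ρ against any indicator is strictly greater than
  the threshold; a taxon sitting exactly on it is retained. The vectorized
  matrix path computes ρ as `(c_t · c_i) / sqrt(ss_t · ss_i)` — the same
  floating-point expression as the scalar path — so constructed boundary
  cases evaluate identically in both.
* **Constant vectors** (`constant_vector_rho`, default 0): a zero-variance
  profile has undefined rank correlation; it is assigned 0 rather than NaN
  because a flat profile carries no co-occurrence evidence either way, and
  a total filter needs every taxon to get a decision.
* **Sample floor** (`min_samples_for_correlation`, default 4): below four
  samples the screen is skipped with a prominent warning rather than run.
  At n = 2 Spearman is always ±1; at n = 3 it takes five coarse values.
  The floor is exposed rather than hard-coded because real studies do run
  small arms (e.g. a two-sample fungal cohort) and must decide explicitly.
* **Indicators are removed** as `removed_indicator`: they are contaminants
  by designation, and leaving the probes in the "clean" table would be
  incoherent.
* **Ties**: midranks (average ranks), the standard Spearman convention.

### Percent rounding

`percent_of_total` rounds to the nearest integer with halves away from
zero, computed on exact rationals (`Fraction`) so 0.5% cases do not depend
on binary representation. This is the convention of printed cohort reports
(7/65 → 11%, 35/65 → 54%), not banker's rounding.

### Other summary conventions

Presence is count > 0 with no abundance floor by default (a configurable
relative-abundance floor exists but is off — most reports state no
detection threshold). `most_abundant` maximizes the *mean of per-sample
proportions*, not pooled counts, so one deep sample cannot decide the
winner; exact ties break lexicographically. Cohort overlap compares
case-normalized names and honors a user-supplied synonym map, but never
auto-corrects spelling variants.

## The synthetic generator

`generate_table` emulates the study design the pipeline targets: a handful
of biopsy samples (default 5; `test_scale` uses 24), ≥ 10,000 reads per
sample, and three taxon classes.

Per sample *s*, a contamination load λ_s ~ LogNormal(0, 1). Expected
abundances:

* resident *i*: `a_i · ε_is`, `a_i ~ LogNormal(0, 1)` — a skewed genus
  profile with a few dominants, as real compositions show;
* correlation contaminant *j*: `w_j · λ_s · ε_js`,
  `w_j ~ LogNormal(0, 0.5)`;
* list contaminant: like a resident, but named from a (supplied or bundled)
  contaminant-genus catalogue;

with multiplicative noise `ε ~ LogNormal(0, 0.3)`. Columns are normalized
to proportions and counts drawn multinomially at depth
`depth_min + Poisson(2000)`. Five of the twenty correlation contaminants
are designated indicators. All randomness flows from the explicit seed;
identical parameters give bit-identical tables.

The load/noise/weight defaults were fixed from this model's structure: with
load σ = 1 dominating taxon noise σ = 0.3, the rank correlation between two
load-driven taxa is strong, and the realized median ρ between planted
contaminants and indicators at the 24-sample scale is ≈ 0.8 — comfortably
detectable at the 0.3 cutoff, which is the regime the generator is meant to
occupy. With the default ~25% mean contaminant mass fraction, compositional
closure pushes resident-vs-indicator correlations mildly negative, which is
also what real contamination does to relative abundances.

`generate_cohort_pair` adds a second, uncontaminated cohort (default 10
samples) sharing 54% of the first cohort's residents (the remainder are
cohort-private), emulating an unmatched biopsy-vs-surgical comparison;
with 65 residents this plants an expected overlap of ~35 genera.

**What the generator does not model** — and what passing tests therefore do
not show about real data: taxonomic misassignment, chimeras, PCR and
primer bias, overdispersion beyond the lognormal-multinomial, contaminants
that do *not* share a single load (e.g. several independent sources), and
cross-contamination between samples. The planted contamination is
single-load multiplicative — exactly the structure the ρ-filter assumes —
so recovery results are favorable by construction and validate the
implementation, not the method's power on arbitrary contamination.

### Scales

Two presets ship: `paper_scale` (5 + 10 samples, 65 residents, 10 list and
20 correlation contaminants) matching the motivating study design, and
`test_scale` (24 single-cohort samples, 70 residents) used for recovery
testing, because a rank-correlation screen on five samples is intrinsically
noisy: across seeds at `paper_scale` the screen's false-removal rate on
residents varies widely (occasionally removing a third of them on a
high-load-variance draw), which is a property of n = 5, not of the
implementation. Test and acceptance problem sizes (24 samples, 10 seeds,
20-seed overlap averages) keep the full suite in the seconds-to-minutes
range.

## Numerical and degenerate-input choices

* Counts must be integral; `"7.0"` is accepted (a common exporter
  artifact), `7.5` is an error with cell coordinates.
* Zero-depth samples make relative abundance undefined → hard error naming
  the sample.
* Writing an empty table is an error (a header-only file would silently
  round-trip to nothing), as is reading an empty exclusion list.
* Rank aggregation groups taxa unclassified at the target rank under
  `unclassified_<deepest classified parent>`, conserving per-sample totals
  exactly; distinct parents stay distinct rows.
* Duplicate display labels after aggregation get `__2`, `__3`… suffixes.

## Known limitations

* The indicator set is an input; the package provides no frequency- or
  prevalence-based contaminant inference (decontam-style) and no
  negative-control modeling — both are out of scope by design.
* BIOM support is the 1.0 JSON dialect only (dense and sparse); HDF5 BIOM
  is not read.
* Correlation screening at very small n is reported honestly rather than
  stabilized; use `min_samples_for_correlation` to refuse it outright.
* The bundled contaminant-genus list is a convenience for simulation and
  quick runs, not a substitute for the curated, citable lists a real
  analysis should supply.
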