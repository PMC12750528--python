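# Methods

## Metal-site detection and stoichiometry

A structure is reduced to flat atom records (first model only; alternative
locations collapsed to the highest-occupancy conformer, ties resolved in
favour of altloc `A`). Every atom whose element belongs to the configured
metal set — alkali and alkaline-earth metals, the full d-block,
post-transition metals, and the metalloids As/Sb/Te — is treated as a
candidate cofactor ion. Its first coordination sphere is the set of N, O
and S atoms within the distance cutoff, excluding other metal-set atoms
and, by default, waters (the stoichiometry of interest is the *protein*
coordination sphere; `include_waters` restores solvent donors).

**Cutoff.** 3.0 Å by default. First-shell metal–donor distances in
protein structures cluster between 1.9 and 2.6 Å; 3.0 Å admits the long
tail of Ca–O and alkali-metal contacts without reaching into the second
shell. It is a flag (`--cutoff`), not a constant.

**Adventitious ions.** A site with no polymer donor inside the cutoff is
flagged adventitious and excluded from stoichiometry by default:
crystallization-buffer ions (typically Na⁺, Cl⁻ partners, sulfates) sit
on surfaces or in solvent channels and would otherwise inflate the ion
counts transferred to expressed proteins.

**Chain attribution.** Each retained ion is attributed to the chain
contributing the majority of its polymer donors; an exact tie goes to the
lexicographically smallest chain id, which makes the output independent
of atom order. Stoichiometries are per chain, matching how fold
recognition matches a query to a single template chain; an assembly mode
(`per_assembly`) counts every site for every chain instead, for templates
whose biological unit shares sites across chains. Bridging sites beyond
this rule, bond-valence checks and geometry classification are out of
scope.

Detection uses a k-d tree; the test suite holds it equal to a brute-force
O(n²) all-pairs scan on random structures, so the spatial index is purely
an implementation detail.

## Homology transfer

Match tables carry (query, template, chain, confidence %). The filter is
strictly greater-than the 95% threshold — a match at exactly 95.0 is
rejected. When several templates pass for one query, the
highest-confidence one is used (ties by template then chain id); taking
the per-metal maximum over all passing templates is available
(`policy="union-max"`) but not default, because homologous templates
describe the same sites and a union double-counts them. Queries matched
only to apo templates are recorded with empty stoichiometry: they count
in the proteome denominator but carry no metal. Queries with no passing
match stay unannotated. No coverage or identity weighting is applied —
the transfer is all-or-nothing, as in annotation-lookup practice.

## Intensity normalization

Label-free zeros are treated as censoring (not detected), stored as
missing, and excluded from medians and means; no imputation is performed.

* **Median normalization** (per sample, over detected proteins) makes
  replicate columns comparable and is the scale on which per-protein
  fold changes and t-tests are computed.
* **Total normalization** (per group) yields relative abundances summing
  to 1. Replicates are aggregated mean-then-normalize by default; the
  alternative (each sample scaled to its own total first, then averaged)
  is a flag. The two coincide on complete matrices with proportional
  columns; the normalize-then-mean order additionally absorbs any
  per-sample scale factor exactly.

## Metallome reconstruction

`A(m) = Σᵢ pᵢ nᵢ(m)` with `pᵢ` the relative abundance and `nᵢ(m)` the
transferred ion count. Per-replicate profiles (each sample normalized to
its own total) are retained; the reported SD is the sample standard
deviation (ddof = 1) across replicates, and group-level tests on a single
metal run directly on these per-replicate values. Totals are conserved:
`Σₘ A(m)` equals the abundance-weighted total ion count, which the tests
assert. The unit is arbitrary; only within-species comparisons across
metals are meaningful, and all correlation statistics are invariant to
rescaling the profile.

Count summaries report, per metal, the number of proteins binding it
(a k-metal protein counts once per metal, once in the metalloprotein
total) and percentages of total identified proteins rounded half-up to
one decimal — the rounding used in the published count tables this
layout mirrors. Raw fractions are kept internally. Association
fractions (the pie-chart view) use (protein, metal) pairs as the
denominator instead.

## Comparison statistics

* **Correlation**: Pearson r² on (log₁₀ quota, log₁₀ abundance). Metal
  abundances span several orders of magnitude, and linear-space
  correlation would be dominated by Mg and Ca; log space also makes the
  arbitrary unit of the reconstruction irrelevant. Linear mode is a flag.
  Metals absent or non-positive on either side are excluded and reported,
  never silently dropped — free-ion-dominated elements must remain
  visible as unpaired rows.
* **Strain ratios**: ratio of means with first-order (delta-method)
  propagation `SD(b/a) = (b/a)√(CVₐ² + CV_b²)`. At CV ≈ 0.1 this sits
  about 3% below the Monte-Carlo SD of the ratio distribution (the
  second-order `E[1/a]` term); the tests document that gap.
* **Differential expression**: two-sided two-sample Student t-test
  (pooled variance) on median-normalized intensities, α = 0.05, Welch and
  Benjamini–Hochberg variants behind flags (raw p-values are the default
  reporting convention here). Proteins with fewer than two detected
  replicates in either group get an undefined p and are never called
  significant. Identical zero-variance groups get p = 1 by convention
  (zero t statistic).
* **Metal roll-up test**: t-test across per-replicate metallome profiles
  for one metal — "is total Co different between strains" — with the
  ratio and its propagated SD.

## Synthetic data

The generator emulates the coupled measurement stack with one seed
driving every draw, and each stage writes the parameters it used into a
manifest.

* **Structures**: planted sites with four donors at 2.0–2.6 Å
  (tetrahedral directions), sites spaced 14 Å so spheres never overlap,
  inert backbone carbons so apo chains exist, and far-field Na⁺ decoys
  (with a water contact only) that must be recovered as adventitious.
* **Proteome**: default 37% metalloproteins — the level seen in
  eukaryotic phytoplankton proteomes. Passing matches draw confidences
  from (95.5, 99.9); decoys from (60, 94.9); a fraction sits at exactly
  95.0 to exercise the strict boundary; some passing matches hit apo
  templates. Base abundances are log-normal with σ = 1.2 (ln units),
  spanning the ~3 orders of magnitude typical of label-free data.
* **Intensities**: `base × group effect × exp(N(0, σ_log²))` with
  σ_log = 0.1 by default (replicate-level CV ≈ 10%, typical for
  well-behaved label-free replicates), two strain groups of three
  replicates, missing values injected completely at random if requested.
* **Quotas**: `scale·(bound + free)·luxury·(1+ε)` with ε ~ N(0, 0.1²)
  truncated above −1, three replicate draws, sample SD reported. Defaults
  encode the known decomposition of real quotas: free-ion pools of 10×,
  5× and 10× the bound abundance for Ca, Mg and K; luxury factors Mo 3×
  in both strains and Fe 2× in the second strain. The scale (100) is an
  arbitrary calibration into the mmol/mol C range.

What the generator does **not** emulate: peptide-level inference, shared
peptides, intensity-dependent missingness, compositional artifacts of
total normalization under extreme regulation, correlated quota errors
between metals, and any sequence content. Passing tests therefore show
the pipeline's arithmetic and statistics are right under the stated noise
model — not that homology transfer is biologically accurate for any
particular organism.

## Problem sizes and numerics

Property suites run at 100–200 random structures of ≤ 200 atoms,
reconstruction scenarios at 200–300 proteins with 8–10 metals and three
replicates per strain, and the null calibration of the t-test at 2000
proteins — sizes at which every run completes in seconds while estimates
(type-I error, log-log r², ratio recovery) are stable to well within the
asserted bands. Percentages round half-up at one decimal via exact
decimal arithmetic; sums-to-one invariants are asserted at 1e-9;
coincident metal atoms abort detection (degenerate structure) rather
than silently merging.

## Known limitations

Per-chain stoichiometry cannot represent genuinely shared inter-chain
sites except through the attribution rule. The best-match transfer
ignores partial coverage: a passing match transfers the template's full
ion count even if the query aligns to half the template. Reconstruction
is relative only; no absolute (molar) metallome is computed, and
cross-species absolute comparisons are explicitly out of scope. The
published in-text percentages of expressed metalloproteins per metal in
one species are not reproducible from any single denominator in the
corresponding count table and are therefore not targeted; the table's
own G. huxleyi Zn cell (10.6%) also differs by 0.1 from half-up rounding
of its printed counts (100×298/2798 → 10.7), which this package reports
as computed rather than patching.
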