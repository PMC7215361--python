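# Methods

## Quantification model

A cysteine site in a cell population is glutathionylated in a fraction θ of
protein molecules (the occupancy). In a cleavable-ICAT redox experiment the
reduced thiols of a peptide carry the light label and the
glutaredoxin-released (formerly glutathionylated) thiols the heavy label,
so the peptide's heavy:light intensity ratio estimates the odds of the
occupancy:

    r = θ / (1 − θ),    θ = r / (1 + r),    r ∈ [0, ∞), θ ∈ [0, 1).

θ = 1 has no finite ratio; the transform pair is exact and mutually inverse
and is exposed as `occupancy_from_ratio` / `ratio_from_occupancy`.

The differential statistic is the **ratio-of-ratios**

    RoR = mean_case(H:L) / mean_control(H:L),

the fold change of the SG/SH odds between conditions. Because the ICAT
design is internally ratiometric, no protein-abundance normalization is
applied, and multiplying all H:L values in both groups by any constant
leaves RoR and the rank-test p unchanged (tested as a property).

## Pipeline stages and thresholds

| Parameter | Default | Meaning |
|---|---|---|
| `min_confidence_pct` | 95 | identification confidence floor (inclusive, %) |
| `min_h_to_l` | 0.01 | H:L floor (inclusive); lower ratios are noise-dominated |
| `fold_cutoff` | 1.5 | RoR cutoff (strict >); only increases are called by default |
| `alpha` | 0.05 | significance level (strict <) |
| `min_subjects_per_group` | 3 | minimum subjects per group per peptide |
| `mean_kind` | arithmetic | group averaging of H:L (geometric available) |
| `mtc` | none | Benjamini–Hochberg optional |
| `exact_test_max_n` | 12 | exact Mann–Whitney up to this pooled n (tie-free) |

Threshold semantics are deliberate: the confidence and ratio floors are
inclusive ("at least"), the fold cutoff and alpha strict. Technical
replicates are averaged per subject *before* any group statistic — treating
duplicate injections as independent samples would pseudo-replicate the
comparison. Group averaging is arithmetic on H:L by default; the geometric
option exists because ratio data are log-distributed, and constant inputs
give identical results under both. Peptides observed in fewer than
`min_subjects_per_group` subjects in either group are excluded and logged
("insufficient observations") rather than tested.

The Mann–Whitney unit is the peptide: subject-level H:L values per group.
For pooled samples up to `exact_test_max_n` without ties the exact
permutation distribution of U is used (the implementation delegates the
distribution to scipy; the test suite checks it against an independent
brute-force enumeration over all group labelings to 1e-12). Larger or tied
samples use the midrank normal approximation with tie and continuity
corrections; at the default design (7 vs 11 subjects, tie-free) the attained
two-sided size of that approximation at nominal 0.05 is 0.0441, computed
exactly from the U distribution, and the null-calibration test checks the
empirical rate against its Monte-Carlo band. Degenerate inputs: a pooled
sample with zero range returns p = 1 (no ordering evidence); p is clipped
to (0, 1].

Protein-level calls use the **any-peptide rule**: a protein is
differentially glutathionylated when at least one of its peptides is, with
`best_ratio_of_ratios` = max RoR and `best_p_value` = min p across its
peptides. Peptide-level results are always emitted alongside, since the
aggregation is a reporting convention, not a statistical claim.

By default only *increased* glutathionylation is called (RoR above the
cutoff); `two_sided_calls` adds RoR < 1/cutoff for symmetric calling.

## Site mapping

Coordinates are 1-based and inclusive throughout (sites read like
"Cys160"). A peptide's labeled cysteines are mapped onto its protein by
exact substring search; every occurrence contributes sites, and peptides
occurring more than once are retained and **flagged ambiguous** rather than
dropped (silent dropping would bias site counts). Consumers that need
site-resolved attribution — such as the recovery scorer — exclude
ambiguous-mapped sites, because a single H:L value cannot be attributed to
one of several occurrences. Isoleucine and leucine are treated as distinct;
the table comes from a search engine that already resolved identity. When
one peptide carries several labeled cysteines, all its sites receive the
shared peptide ratio — the peptide is the observable unit and the split is
not identifiable from H:L data; site rows record this via their shared
peptide sequence.

## Synthetic data generator

The generator emulates the study design the pipeline targets:
**11 case vs 7 control subjects, each in technical duplicate** (a second
arm, e.g. an inhibitor-treated comparison, is simulated the same way), over
a random proteome digested in silico with trypsin (cleave after K/R unless
followed by P; 0 missed cleavages by default, up to 2 configurable).

Stated assumptions where no empirical magnitudes are available:

- **Baseline occupancy** θ_control ~ Beta(2, 8) (mean 0.2, mass well inside
  (0, 1)) — plausible for an oxidative-stress-responsive cysteine pool.
- **Noise** is multiplicative lognormal on the observed ratio:
  H:L = r·exp(ε_H − ε_L) with iid normal channel errors sized so the ratio
  CV equals `noise_cv` (default 0.20); MS ratio error is multiplicative, and
  CV is the user-facing parameterization (σ² per channel = log(1+CV²)/2).
- **Missingness** is missing-completely-at-random per observation at
  `missing_rate` (default 0.10); intensity-dependent dropout is a config
  extension, not the default.
- **Confidence** is a mixture: 90% of observations draw U(95, 100), the
  rest U(50, 95), so the confidence filter removes a realistic minority.
- **Proteome composition**: vertebrate-like amino-acid background with
  K+R ≈ 11% (tryptic peptides average ~9 residues) and the cysteine
  frequency a parameter (default 0.03).

**Effect planting** operates on *site clusters* — all cysteines sharing a
tryptic peptide get one baseline occupancy and one differential status —
because a peptide carries a single H:L value, so sites within a peptide are
not separately observable; with the default of zero missed cleavages,
clusters coincide with tryptic peptides. A `fraction_differential` subset
(default 0.10) of clusters gets θ_case solved from the occupancy odds so
the true ratio-of-ratios equals `effect_ratio` (default 2.0):
θ_case = e·ρ/(1+e·ρ) with ρ = θ_control/(1−θ_control). Multi-cysteine
peptides observe the odds of the mean occupancy of their sites (identical
within a cluster by construction).

What passing recovery tests on these data shows — and does not show: the
generator validates the *statistical pipeline* (calibration, thresholding,
rollup, determinism), not the measurement process. It contains no
spectrum-level effects (interference, isotope envelopes, retention-time
drift), no subject-level biological variance component beyond measurement
noise, no correlation between peptide abundance and missingness, and no
search-engine identification errors. Sensitivity and FDP on real data will
be worse than on these simulations to the extent those effects matter.

One honest consequence of the H:L ≥ 0.01 floor: a planted site whose
control occupancy draws below ≈ 1% has its control observations filtered
out, becomes unquantifiable ("insufficient observations") and is scored as
a miss even in noise-free runs. This is the intended behavior of the
filter — ~1% occupancy is below the method's quantification floor — and it
occurs for ≈ 0.4% of Beta(2, 8) draws.

## Overlap and enrichment

Significant protein sets from two arms are compared as an exact two-set
partition (only-A / shared / only-B) with the shared fraction of the first
arm reported. Over-representation uses the upper-tail hypergeometric test,
p = P(X ≥ k) with X ~ Hypergeom(N, K, n), each annotation set intersected
with the declared universe first, and Benjamini–Hochberg q-values across
sets. The default universe is all *quantified* proteins, not all
significant ones: conditioning on detectability avoids abundance bias.
Joint proteo-metabolomic enrichment pools the two universes with
kind-tagged identifiers (`protein:` / `metabolite:`; an untagged identifier
present in both universes is an error) and runs a single hypergeometric per
pathway on the pooled counts — a transparent, testable stand-in for
topology-weighted commercial tools, which are deliberately not
re-implemented. Annotation content is user-supplied GMT, never bundled
(database snapshots drift).

## Determinism and numerics

A single mandatory seed governs all randomness; per-stage substreams are
spawned from it deterministically, so identical config + seed yields
byte-identical tables and reports (floats rendered at 12 significant
digits, rows sorted by accession/site/peptide, JSON keys sorted). The
`--threads` CLI flag is accepted for interface stability; computation is a
deterministic single pass, so results are independent of it. Empty result
tables are a write error rather than an empty file; an arm in which no
peptide survives filtering aborts with its stage counts.

## Problem sizes in tests

The test and acceptance runs use scaled simulations chosen to make the
statistical checks sharp while keeping the suite quick: ~2000 Cys peptides
(260 proteins) for null calibration, 60-protein proteomes across 10 seeds
for the effect-size sweep, and 15–25-protein proteomes for exactness and
determinism checks. These sizes are the package's own validation choices;
all thresholds and designs match the defaults above.
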