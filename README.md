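# gluquant

Differential analysis of proteome-wide cysteine *S*-glutathionylation from
isotope-coded affinity tag (ICAT) heavy:light peptide ratios.

*S*-glutathionylation is a reversible disulfide between a protein cysteine
thiol and glutathione, a central mark of cellular oxidative stress. In a
cleavable-ICAT redox workflow, reduced thiols are labeled with light
(<sup>12</sup>C) ICAT while glutathionylated thiols are released by
glutaredoxin (Grx) and labeled with heavy (<sup>13</sup>C) ICAT, so a
peptide's heavy:light intensity ratio (H:L) measures its
glutathionylated-to-reduced thiol ratio SG/SH. `gluquant` takes the
peptide-level H:L export of such an experiment and produces differential
glutathionylation calls between a case and a control group, cysteine-site
maps, cross-condition overlaps, and pathway over-representation — together
with a fully seeded synthetic-data generator that plants known effects so
the whole pipeline can be validated end to end.

It is aimed at redox-proteomics analysts who have peptide-level ICAT
quantification tables (e.g. from a search-engine export) and want a
transparent, testable implementation of the downstream statistics.

## The model and statistic

For a cysteine site with glutathionylation occupancy θ (the fraction of
molecules carrying glutathione), the observable ratio is

    r = H:L = SG/SH = θ / (1 − θ),        θ = r / (1 + r).

Per peptide the pipeline computes, for cases (e.g. patient fibroblasts) vs
controls:

1. **Filter** observations with identification confidence ≥ 95% and
   H:L ≥ 0.01 (both inclusive).
2. **Collapse technical replicates** to one H:L per subject (arithmetic
   mean), so subjects — not injections — are the experimental unit.
3. **Average subjects** within each group: r̄_case, r̄_control.
4. **Ratio-of-ratios** RoR = r̄_case / r̄_control, the fold change of the
   SG/SH ratio.
5. **Mann–Whitney test** (two-sided) of case vs control subject values:
   exact permutation distribution for small tie-free samples, midrank
   normal approximation with tie and continuity corrections otherwise.
6. **Call**: a peptide is differentially glutathionylated when
   RoR > 1.5 (strict) and p < 0.05 (strict). A protein is called when at
   least one of its peptides is.

Two comparison arms (e.g. a disease cohort and a pharmacological model of
the same lesion) can be overlapped by a Venn of their significant protein
sets, and hit sets tested for pathway over-representation with an
upper-tail hypergeometric test (optionally pooling protein and metabolite
universes for joint proteo-metabolomic enrichment).

## Worked example

Simulate a study with the default design — 11 case vs 7 control subjects,
each in technical duplicate, 20% ratio CV, 10% of sites planted with a
2-fold effect — then quantify and score recovery:

```sh
gluquant benchmark --seed 5 --out bench/
# sensitivity=0.972 fdp=0.000
```

The benchmark writes `bench/report.json`; for seed 5 it contains (excerpt):

```json
"recovery": {
  "n_sites_truth": 694, "n_sites_planted": 71, "n_sites_called": 69,
  "tp": 69, "fp": 0, "fn": 2, "sensitivity": 0.971830985915493, "fdp": 0.0
}
```

i.e. 69 of 71 planted sites were recovered with no false calls. At a 2-fold
planted effect this design has near-full power, because the limiting
criterion is the 1.5-fold cutoff on the estimated RoR (standard error ≈ 6%
of the mean here), not the rank test; the occasional miss is a planted site
whose estimated RoR lands just under the cutoff, or whose control-group
H:L sits below the 0.01 quantification floor. At a planted effect of 1.5 —
sitting exactly on the cutoff — sensitivity drops to ≈ 0.5, the expected
behavior of a strict threshold at the effect size itself.

The same stages are available piecemeal:

```sh
gluquant simulate --seed 7 --out sim/
gluquant quantify --table sim/peptide_table.tsv --fasta sim/proteome.fasta --out quant/
gluquant report --arm lhon sim/peptide_table.tsv --arm rotenone sim/peptide_table.tsv \
    --fasta sim/proteome.fasta --seed 7 --out two_arm/
gluquant enrich --hits hits.txt --gmt sets.gmt --universe universe.txt --out enrich.tsv
```

or from Python via `gluquant.run_differential`, `gluquant.run_two_arm`,
`gluquant.run_recovery_benchmark`, etc.

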