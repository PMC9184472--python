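# exonqpcr

Exon-level qRT-PCR fold-change analysis and TaqMan-assay selection for the
radiation-biodosimetry gene panel *FDXR*, *DDB2*, *WNT3* and *POU2AF1*.

After a radiological accident, expression changes of these four genes in
peripheral blood separate unexposed, low- and high-exposed individuals.
Because a TaqMan assay interrogates one exon-pair of a transcript — not the
whole gene — assays targeting different exon regions of the *same* gene can
report different fold changes. This package implements the complete
analysis needed to compare all exon-region assays of a gene panel and pick
the ones suited for biodosimetry: from raw cycle-threshold (Ct) tables to
housekeeper-normalized ΔΔCt fold changes, through a four-criterion
selection procedure, to a dose-dependency analysis of inter-individual
variability — plus a hierarchical Ct simulator that emulates the in-vitro
study design (3 donors, 0/0.5/4 Gy, 24/48 h, duplicate wells, 41 assays),
so the entire pipeline is testable without wet-lab data.

## The model

Quantification is the comparative-Ct method at amplification efficiency 2:

```
ΔCt  = Ct(target) − Ct(18S rRNA, diluted)      per sample (replicate means)
ΔΔCt = ΔCt(sample) − ΔCt(sham, same time)      reference = unexposed sample
FC   = 2^(−ΔΔCt)                               FC 1 ⇔ expression unchanged
```

Raw Ct above 40 carries no quantitative information and is censored at
ingestion (`ND`). Assay selection applies, per gene direction:

1. **baseline** — mean sham raw Ct < 33 (up-regulated genes) or < 30
   (down-regulated genes);
2. **dose dependency** — donor/time-averaged FC must grow by ≥ 2 units per
   dose category (up; tenfold at 0.5 Gy demands ≥ 12-fold at 4 Gy), or
   shrink ≥ 2-fold per category (down); passing only sham→4 Gy gives the
   intermediate "high-dose-only" verdict;
3. **time persistency** — |FC(24 h) − FC(48 h)| ≤ 1 at every exposed dose
   (10.5-fold at 24 h admits 9.5–11.5 at 48 h);
4. **inter-individual variability** — assays ranked per gene by the summed
   across-donor SD of the FC over dose(-time) cells; rank 1 = most stable.

Whether irradiation *itself* inflates inter-individual variability is
tested per gene on the coefficient of variation (CV = SD·100/mean, across
donors) with a one-way repeated-measures ANOVA (assays as subjects, dose as
the within factor) and Tukey's studentized-range post-hoc test on the
within-subject residual mean square.

## Worked example

```
exonqpcr simulate study --seed 17 --out sim/
exonqpcr run --ct-table sim/ct_table.csv --manifest sim/manifest.csv --out run/
exonqpcr report --run-dir run/
```

prints, for this draw of the simulated study:

```
FDXR (up-regulated, 14/16 detectable)
  Hs01031621_g1          baseline  28.2  dose dependency full           variability rank 13 (lower third)
  CV dose effect: F=16.03, p=2.9e-05; median CV increase 0.5 Gy: 5.9x, 4 Gy: 4.4x

WNT3 (down-regulated, 5/5 detectable)
  Hs00902258_m1          baseline  29.2  dose dependency high_dose_only variability rank 1 (upper third)
  Hs00902257_m1          baseline  29.3  dose dependency high_dose_only variability rank 3 (middle third)
  CV dose effect: F=3.94, p=0.064; median CV increase 0.5 Gy: 3.4x, 4 Gy: 1.9x
```

Reading: of the 16 FDXR exon-region assays, two never amplify (beyond the
40-Ct detection limit), so 14 are ranked; `Hs01031621_g1` passes baseline
(28.2 < 33), full dose dependency and persistency in this draw. For WNT3
the two 3'-end assays show the down-regulation confined to that end of the
gene, with a dose response detectable at 4 Gy only. The CV lines quantify
how strongly exposure inflates donor-to-donor spread (the simulated
fourfold variance inflation appears as roughly a three-to-sixfold rise of
the median CV). Per-assay details land in `run/evaluation.tsv`, machine-
readable summaries in `run/summary.json` and `run/varstats.json`.

The same steps are available as narrative scripts under `analysis/`
(`01_simulate.py` … `04_variability.py`), and everything they do is
importable from `exonqpcr.foldchange`, `.selection`, `.varstats`, `.synth`.

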