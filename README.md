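# ffworkup

Computational workup of **fertilization failure after ICSI** (intracytoplasmic
sperm injection). About 1–3% of ICSI cycles fail completely because the sperm
cannot trigger the Ca²⁺ oscillations that activate the oocyte — most often due
to variants in the sperm genes *PLCZ1* (phospholipase C zeta, the oocyte
activation factor) or *ACTL7A*/*ACTL9* (perinuclear-theca proteins required for
acrosome attachment). This package implements the quantitative pipeline used to
work such patients up and to evaluate rescue by assisted oocyte activation
(AOA):

1. **Bayesian ACMG variant classification** (`ffworkup.acmg`). Evidence
   criteria (PVS1, PS1–4, PM1–6, PP1–5; BA1, BS1–4, BP1–7) are combined on the
   naturally scaled point scale — supporting = 1, moderate = 2, strong = 4,
   very strong = 8 points, benign evidence negative — and the net total *N*
   maps to a posterior probability of pathogenicity

   *P* = (*O*·π) / ((*O* − 1)·π + 1),  *O* = 350^(*N*/8),  π = 0.10,

   with categories P (≥10), LP (6–9), VUS (0–5), LB (−6…−1), B (≤−7) and VUS
   "temperature" tiers (hot…ice-cold) by net points. Re-classification after
   functional testing is an evidence update on the same scale.
2. **Variant screening** (`ffworkup.variants`): gnomAD allele-frequency filter
   (< 5%), REVEL flag (> 0.5), AlphaMissense bins (0.34 / 0.564), per-gene
   carrier and per-change recurrence frequencies with cohort-aware
   denominators, compound-heterozygosity calls.
3. **Ca²⁺ oscillation scoring** (`ffworkup.calcium`): deterministic spike
   detection on Fura-2-style ratio traces (rolling-median baseline, robust
   MAD noise estimate, prominence threshold, refractory spacing), the
   A×F statistic (mean amplitude × spikes/hour), frequency categories
   (0 / + / ++ / +++ / ++++ at 0, 1–2, 3–9, 10–20, >20 spikes) and the
   fertilization-competence thresholds A×F > 9 AU (2-h mouse assay, MOCA)
   and > 0.6 AU (10-h human assay, HOCA).
4. **Cohort outcome statistics** (`ffworkup.outcomes`): study eligibility
   (fertilization ≤ 1/3 with ≥ 4 MII oocytes), MOAT activation groups, pooled
   fertilization / blastocyst / hCG / live-birth rates, two-sided Fisher exact
   arm comparisons, acrosome-detachment (≥ 50% rule) and ACTL7A
   immunofluorescence expression rates.
5. **Synthetic data** (`ffworkup.simulate`): seeded generators for traces
   (Poisson spike trains with exponential-decay kernels + Gaussian noise),
   binomial cycle outcomes, and random ACMG evidence sets, so every stage is
   testable without external data.

The transcribed study tables (variants with reported posteriors, MOAT/Ca²⁺
summaries, per-patient treatment cycles) ship with the package
(`ffworkup.datasets`, checksum-verified).

## Worked example

```python
from ffworkup import acmg, datasets, outcomes, variants
from ffworkup.simulate import evidence_for_points

# a hot VUS (5 points) upgraded by supporting functional evidence
base = acmg.classify(evidence_for_points(5))
up = acmg.update_with_functional(
    base, [acmg.EvidenceItem("PS3", acmg.Direction.PATHOGENIC, acmg.Strength.SUPPORTING)]
)
print(base.posterior_3dp, base.category.value, base.vus_tier.value)
print(up.posterior_3dp, up.category.value)

fx = datasets.fixtures()
plcz1 = variants.carrier_frequency(
    variants.filter_by_af(fx["variant_records"]), fx["rosters"], "PLCZ1"
)
print(f"{plcz1.numerator}/{plcz1.denominator} = {plcz1.percent}%")

fr = outcomes.compare_arms(fx["cycles"])["fertilization"]
print(fr["icsi"].percent, fr["icsi_aoa"].percent, fr["p_value"] < 0.0001)
```

prints

```
0.812 VUS hot
0.9 LP
16/55 = 29.09%
11.24 61.8 True
```

i.e. a 5-point VUS has posterior 0.812 and moves to likely pathogenic (0.900)
with one extra supporting criterion; 16 of 55 screened patients carry a
*PLCZ1* variant (29.09%); fertilization rises from 11.24% (conventional ICSI)
to 61.80% (ICSI–AOA), a difference that is significant by Fisher's exact test.

## Analysis scripts

`analysis/01…05` are thin, numbered drivers over the library: variant
re-classification, carrier frequencies, calcium scoring on simulated traces
plus competence flags, cohort outcome comparisons, and sperm-phenotype rates.
Each prints what it found and writes its tables under `results/`. The
`ffworkup` console script exposes the same steps as subcommands
(`classify-variants`, `screen-variants`, `score-calcium`, `cohort-report`,
`simulate`, `study-report`); `ffworkup study-report --out report.json`
regenerates every summary number from the packaged tables and exits non-zero
if any deviates.

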