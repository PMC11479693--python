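# Methods

## Bayesian point-based variant classification

Evidence combination follows the naturally scaled point formulation of the
ACMG/AMP framework. Each applied criterion carries a strength (supporting,
moderate, strong, very strong) worth 1, 2, 4 or 8 points; benign evidence is
negative. Strength is a field of the evidence item, decoupled from the
criterion code, so a strength-modified criterion (e.g. PS3 applied at
supporting level) is expressed directly. The net total *N* converts to a
posterior probability of pathogenicity via

    posterior = (O * prior) / ((O - 1) * prior + 1),   O = O_vs^(N/8)

with defaults `prior = 0.10` and `O_vs = 350` (the odds of pathogenicity
assigned to one very-strong criterion). These two constants are not stated in
the study report itself; they are the canonical values of the framework it
applies, and they are validated here rather than assumed: the eleven distinct
posterior probabilities that appear in the study's variant table (0.1, 0.188,
0.325, 0.5, 0.675, 0.812, 0.9, 0.949, 0.988, 0.994, 0.997) are reproduced to
three decimals by the integer point totals 0–7, 9–11, and the posterior at
zero points equals the prior exactly. Both constants are configurable
(`BayesParams`).

Categories follow the point bounds ≥10 pathogenic, 6–9 likely pathogenic,
0–5 VUS, −6…−1 likely benign, ≤−7 benign; BA1 (stand-alone benign) overrides
the point total and forces benign. VUS temperature tiers are assigned by net
points (5 = hot, 4 = warm, 3 = tepid, 2 = cool, 1 = cold, 0 = ice cold). A
posterior-range tier rule was rejected because the source table labels the
same posterior (0.188) with two different tiers in different rows; the
point rule matches every label except that single self-contradiction.

Posteriors are kept at full precision internally; the three-decimal values
are presentation only (round half-up). `invert_posterior` recovers the
integer point total from a reported posterior by nearest-posterior search
over −20…20 (ties toward 0); it round-trips exactly over −15…15. Because the
study publishes per-variant posteriors but not the itemized criteria (those
are in supplementary material not shipped here), the packaged variant table
stores reported posteriors, and analyses reconstruct point totals via this
inversion; reclassification after functional testing is then an evidence
update with the point delta.

## Variant screening

The rarity filter keeps variants with gnomAD allele frequency strictly below
the threshold (default 5%, the study's deliberately permissive cut-off for a
condition with unknown penetrance); variants with no gnomAD entry pass, since
novelty cannot argue commonness. The filter is idempotent and
order-preserving. REVEL flags pathogenicity strictly above 0.5. AlphaMissense
bins partition [0, 1] as [0, 0.34) likely benign, [0.34, 0.564) uncertain,
[0.564, 1] likely pathogenic — half-open below, closed at the top, a
convention choice the source states only as ranges.

Carrier frequencies use per-gene denominators: the first recruitment cohort
(28 patients) was screened only for *PLCZ1*, the second (27 patients) for
*PLCZ1*, *ACTL7A* and *ACTL9*, so *PLCZ1* rates are over 55 patients and
ACTL-gene rates over 27. Whether the study's 5% filter used global or
subpopulation frequencies is unstated; global is assumed.

## Calcium trace scoring

The spike detector is deliberately simple and fully deterministic, since the
original analysis used an interactive commercial tool with unpublished
settings:

1. baseline = rolling median over `baseline_window` (default 300 s), which
   tracks slow drift but is insensitive to spikes occupying less than half
   the window;
2. noise SD = 1.4826 × median absolute deviation of the baseline-subtracted
   residual;
3. spikes = local maxima of the residual whose height *and* prominence exceed
   `max(noise_k × noise SD, min_amplitude)` (defaults 4 and 0.05 AU), at
   least `refractory` (default 30 s) apart. The prominence requirement stops
   noise bumps riding a decaying tail from being re-counted; the absolute
   floor stops rare >4σ noise excursions on long spike-free traces from
   being called spikes.

Amplitude is peak minus local baseline, making scores invariant to constant
offsets. A = mean spike amplitude (AU); F = spike count / recording duration
in hours (the source never states F's units — per-hour is this package's
definition, and absolute A×F values therefore depend on detector settings);
A×F = A·F. Frequency categories use the raw spike count over the full
recording: 0, + (1–2), ++ (3–9), +++ (10–20), ++++ (>20). Competence
thresholds are strict: mean A×F > 9 AU (MOCA, 2-h mouse recordings) or
> 0.6 AU (HOCA, 10-h human recordings) is the normal-fertilization range;
equality is deficient. Published per-patient mean A×F values are **not**
reproduction targets — the raw traces were never released — so detector
correctness is established by parameter recovery on simulated traces
instead.

Patient-vs-control comparisons are normality-gated: Shapiro–Wilk on both
samples at α (default 0.05); two-sample t-test if both pass, otherwise
two-sided Mann–Whitney U; constant samples (e.g. all-zero A×F) skip the
normality test and use the rank test with a warning.

## Cohort outcomes

Eligibility (≥1 ICSI cycle with ≥4 MII oocytes and fertilization ≤ 33.33%)
compares exact rationals against 1/3, immune to decimal-rounding artifacts.
MOAT groups: rate ≤ 20% → 1, ≥ 85% → 3, else 2 — the published group bounds
leave (84%, 85%) unassigned; it resolves to group 2 here (group 3 requires
≥ 0.85). Pooled rates are numerator/denominator sums: fertilization =
Σ2PN/ΣMII, blastocyst = Σblastocysts/Σ2PN restricted to cycles with
blastocyst culture, hCG and live-birth rates per started cycle. Cycle records
may be pooled per patient and arm (`n_cycles` > 1), exactly as the source
table prints them; pooling is aggregation-invariant. All rates carry their
integer counts; percentages (2 dp, half-up) are presentation only.

Arm comparisons use the two-sided conditional Fisher exact test
(probability-mass definition with 1e-7 relative slack, as implemented by
`scipy.stats.fisher_exact`); an independent exact-rational hypergeometric
enumeration serves as the test oracle. Acrosome detachment is called at
≥ 50% of acrosome length detached, or > 50% when the acrosome is folded and
curved; rates are over intact-acrosome cells with a 20-cell floor (warning
below it). ACTL7A immunofluorescence classes (invisible/weak/obvious) cut
background-corrected mean grey values at user-supplied thresholds — the
source gives no numeric defaults, so they are required configuration
(the analyses here use 10 and 50 AU against a 5 AU background).

## Synthetic data

`simulate_trace` draws spike times from a homogeneous Poisson process thinned
by a refractory period (keep an event only if ≥ refractory after the last
kept one, giving effective rate λ/(1+λr)), snaps onsets to the sampling grid,
adds an instant-rise/exponential-decay kernel per spike (amplitudes truncated
normal, τ default 15 s, support truncated at 6τ), linear drift, and i.i.d.
Gaussian noise. It returns the ground-truth spike train for recovery tests.
Noiseless, well-separated spikes are recovered exactly — count, time and
amplitude — provided inter-spike gaps exceed half the baseline window plus
the kernel support (~240 s at defaults) and the spike is not inside the last
half-window of the recording, where boundary padding biases the local
median; outside that regime counts stay exact and amplitudes are recovered
to ~1%. Real Fura-2 noise is structured (photobleaching, motion); the
i.i.d.-Gaussian knob only sets an SNR for detector tests, so passing
recovery tests demonstrates detector correctness on the modelled trace
family, not performance on arbitrary real recordings.

`simulate_cohort` draws per-cycle 2PN ~ Binomial(MII, fert_rate(arm)), hCG ~
Bernoulli, live birth ~ Bernoulli given hCG. The default rates are the
observed study rates (fertilization 0.11 ICSI vs 0.62 ICSI–AOA, hCG 0.11 vs
0.60, live birth 0.62 given hCG) with 19 patients, 1–4 cycles per arm and
4–18 MII per cycle, matching the study's scale. Null-calibration runs
(identical arms at 0.3) reject at ~5% across 500 seeds.

`simulate_evidence` draws random criteria sets from a strength distribution;
`evidence_for_points` builds a minimal generic set for any target total
(greedy 8/4/2/1 decomposition). `synthetic_sperm_cells` reconstructs per-cell
TEM/immunofluorescence tables whose counts match the published per-sample
summary rates; the per-cell values are synthetic stand-ins (the study
published only the rates).

## Numerical and testing choices

- Rates are exact integer ratios (`fractions.Fraction` where compared against
  bounds); floating point enters only at presentation.
- Rounding is half-up via `decimal`, matching the reported tables (Python's
  builtin banker's rounding would print 0.5 for 0.49988 but fail elsewhere).
- The detector is deterministic; all simulators take explicit seeds and are
  reproducible bit-for-bit.
- Problem sizes in tests and analyses are chosen to keep the full suite
  around ten seconds: 50-seed detector recovery at SNR 20, 500-seed null
  cohort calibration, exhaustive Fisher enumeration for margins ≤ 12.

## Known limitations

- ACMG criteria are consumed pre-asserted; no automated criterion derivation
  from annotations (no PVS1 decision tree, no PM2 frequency logic).
- No HGVS normalization or liftover; variant identity is string-based.
- A×F absolute values are detector-parameter-dependent; only within-pipeline
  comparisons (patient vs control, vs thresholds) are meaningful.
- Per-transfer pregnancy accounting is out of scope; hCG and live births are
  per started cycle, and a pooled record can legitimately carry more
  positives than cycles in edge cases (fresh + frozen transfers), which the
  per-cycle model stores as a count.
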