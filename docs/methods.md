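# Methods

## Breeding-population simulator

The simulator tracks two haplotypes per line over a marker map. Alleles
take two states, donor and recipient; the F1 is heterozygous at every
locus. Each target QTL is tracked by five markers — the peak flanked at
±spacing and ±2·spacing cM (default spacing 5 cM, a typical SSR flanking
density; configurable down to 0 for complete linkage). QTLs on the same
chromosome are separated by a 50 cM gap by default, so their marker sets
never interleave and cross-QTL linkage is negligible.

Meiosis uses the **Haldane mapping function**, r = (1 − e^(−2d/100))/2, with
no crossover interference: a gamete starts from a random parental haplotype
and switches between adjacent loci with probability r of their distance;
chromosomes assort independently. Haldane is the simplest standard choice
given that no map distances are published for these marker panels.

Pedigrees follow the `F{m}` / `BC{n}F{m}` grammar (case-sensitive).
Selfing increments the filial number; a backcross to the recurrent parent
increments the backcross number and resets the filial number to 1.

### Trait model

Grain yield of line *i* in environment *e* (NS or RS), replicate *k*,
block *l* is

```
y = baseline(e) + Σ_j a_j(e)·x_j + Σ_{j<k} γ_jk(e)·x_j·x_k
    + line_i + rep_k + block_kl + ε
```

where x_j ∈ {0, ½, 1} is the line's true donor dosage at QTL j's peak
locus. Simulation uses the true genotype so that the marker-based
classifier's error is measurable against truth. Defaults, chosen to
represent a realistic reproductive-stage drought program:

| parameter | default | rationale |
|---|---|---|
| baseline NS / RS | 5077 / 2691 kg ha⁻¹ | calibrates a ≈47% stress-induced trial-mean reduction, typical of moderate RS stress (reported reductions span 22–98%) |
| per-QTL RS effect | uniform on [300, 500] kg ha⁻¹ | the established per-QTL yield advantage under RS stress |
| per-QTL NS effect | 0.3 × RS effect | qDTY effects are expressed mainly under stress |
| QTL×QTL interaction | 0 (configurable, either sign) | pair-specific; no published magnitudes |
| line effect SD | 300 kg ha⁻¹ | residual genetic background variation |
| plot residual SD | 500 kg ha⁻¹ | ≈10–20% CV of plot yield |
| replicate SD / block SD | 150 / 100 kg ha⁻¹ | modest trial-structure effects |
| replicates | 2 | matches the costed trial design (plot size 1.54 m²) |
| blocks per replicate | 1 (RCBD) | block counts were never published; exposed as config |

Every stochastic operation takes an explicit `numpy.random.Generator`;
pipelines split a single integer seed through `SeedSequence`, so one
(config, seed) pair determines every output byte.

## QTL calling and class assignment

Genotype codes are A (donor homozygote), B (recipient homozygote), H
(heterozygote), `-` (missing). The default call per (line, QTL):
**present** if the peak and both immediate flanks are A, **absent** if all
three are B, otherwise **segregating**. Outer-flank values never flip a
call; they contribute only through missingness (more than one missing
outer flank degrades the call to segregating, as does a missing peak or
immediate flank). A `peak_only` rule (call read off the peak marker alone)
is available for sensitivity analysis.

Whether heterozygous-QTL lines were retained in the published early
generations is not stated, so both policies are implemented:
`drop_segregating` (default; lines with any segregating call are excluded,
giving fixed classes consistent with per-class means) and `peak_only`.
Class labels are canonical — members sorted with Sub1 first, then qDTY
loci by chromosome and sub-index — and class identity is the member *set*,
not the label string. The empty set is the recipient-parent class `X`.

## Class analysis

Per trial (one generation × one environment) the model is
`y = μ + r_k + b(r)_kl + q_i + g(q)_ij + e_ijkl`. Estimation uses a
fixed-effects skeleton (intercept, replicate, block-within-replicate, and
line dummies) solved by SVD pseudo-inverse; line least-squares means are
grid averages over replicate × block, so class LS means equal arithmetic
class means on balanced data.

**Error stratum.** The class F test and all pairwise comparisons are
computed on the adjusted line means with the genotype-within-class
variation as the error term (k − 1 and N_lines − k df). This is the
containment denominator for a factor whose experimental units are the
lines: it keeps the test exact when line-level genetic background variance
is present, and with a single plot per line it collapses to the ordinary
one-way ANOVA across lines (F = squared pooled t for two classes).
Testing against the plot residual instead would treat plots, not lines, as
replicates of a class and be anti-conservative whenever lines vary within
classes.

Replicate and block variance components are descriptive (they never enter
means, tests or letters). By default they are method-of-moments
balanced-ANOVA estimates truncated at zero; REML via `statsmodels` MixedLM
is available (`vc_method="reml"`), with an automatic fall-back to the
ANOVA estimator if REML fails. For the balanced layouts the simulator
produces the two coincide in expectation; the ANOVA path keeps the
1000-dataset calibration studies fast.

**Mean separation** is Fisher's protected LSD at α = 0.05 by default —
pairwise t tests on the within-class error, interpreted only when the
class F test is significant (otherwise all classes share the letter `a`);
Tukey HSD (studentized range) is available via `comparison="tukey"`. No
procedure is named in the source tables; protected LSD is the SAS-era
default for such letter tables. The **compact letter display** assigns the
maximal cliques of the non-significance graph (Bron–Kerbosch) as letter
groups ordered by their best member's mean — the fixed point of the
insert-and-absorb construction, guaranteeing that two classes share a
letter iff they are not significantly different. Classes with fewer than
3 lines are reported but flagged.

Degenerate inputs: a single class raises (the F test is undefined); zero
within-class df yields means without tests; zero within-class variance
with distinct means gives F = ∞, p = 0.

## Superior-class selection

The published studies state only that the "high mean grain yield" F3
classes were advanced; the rule here is a reconstruction with its
parameters exposed. A class is selected iff it

1. shares a letter with the top-mean class under RS,
2. shares a letter with the top-mean class under NS (when an NS trial
   exists; `require_both_envs` controls whether NS is mandatory),
3. has at least `min_lines_per_class` lines (default 3), and
4. has an RS mean ≥ the recipient-parent class `X` (vacuous when `X` is
   absent; the ≥ lets `X` itself survive when nothing separates).

## Cost model

Genotyping: `n_lines × n_qtls × 5 markers × USD 0.50` per generation.
Phenotyping: `n_entries × USD 36.18` (the per-entry price already covers
two replications under NS and RS). Costs accumulate unrounded; displayed
dollars are rounded half-up at presentation, and savings are computed on
the unrounded totals before rounding. The bundled five-background
generation plans treat the selected-strategy population sizes as inputs —
the per-class advancement counts behind them were field decisions and are
not derivable. One published ledger mixes rounding conventions (a
selected-classes total printed as the sum of per-row rounded values, and a
savings figure differing by one dollar between table and text); tests
therefore assert reproduction within ±2 USD, exact wherever the
conventions agree.

## Validation studies (`masbreed.studies`)

The published per-class means cannot be reproduced (raw plot data are not
public), so the analysis is validated on simulated data with known truth:

- **Null calibration** — 1000 pure-noise trials (4 classes × 15 lines ×
  2 replicates, no class effect): the class F test's rejection rate at
  α = 0.05 must fall in the binomial 95% band [0.037, 0.064].
- **Top-class recovery** — 200 seeded two-QTL F3 programs (300 F2 lines;
  RS effects 400 and 350 kg ha⁻¹ against a 150 kg ha⁻¹ plot residual,
  i.e. every class gap ≥ 2 residual SDs; ≥ 20 lines per retained class):
  the top-mean RS class must be the true double-QTL pyramid in ≥ 95% of
  runs.
- **Selection persistence** — same programs advanced to F5 and F7 with
  generation-stable effects: the F3-selected class set must still contain
  the top-mean RS class in ≥ 95% of runs.
- **Mendelian checks** — F2 segregation 1:2:1 (χ² at n = 10 000), selfing
  heterozygosity (1/2)^t at t = 1…5 over 5000 lines, and the Haldane
  recombinant fraction at 10 cM over 20 000 gametes, all within 3 SE.

These sizes keep the whole validation suite to a few minutes on one CPU
while leaving the binomial bands tight enough to be informative.

## What the simulator does and does not emulate

It reproduces the statistical structure the class analysis assumes:
Mendelian segregation with linkage, pedigree-correct selfing/backcrossing,
additive stress-specific QTL effects with optional pairwise interaction,
line-level background variation, and replicate/block trial structure with
a stress-induced mean reduction. It does **not** model soil-water
dynamics, flowering time, plant height, grain quality, submergence
physiology, spatial field trend, genotype×season variability, linkage drag
with undesirable donor alleles, or marker genotyping error (missing data
enter only through the calling rule's tolerance). Passing the validation
studies therefore shows the statistics behave correctly under the stated
genetic model — not that real field trials meet its assumptions.

## Known limitations

- Per-trial analysis only; no multi-season META analysis.
- With multiple blocks per replicate and lines fully nested in blocks the
  fixed-skeleton adjustment is an intrablock analysis; class means are
  then defined up to the block-connectivity of the design (the default
  RCBD layout is unaffected).
- The selection rule is a reconstruction; alternative rules (e.g. RS-only,
  stricter NS veto) are parameter changes away but have no published gold
  standard to compare against.
- Costs cover the two published unit prices only — no currency conversion,
  inflation, or labor breakdown, and no optimization of which classes to
  advance under a budget.
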