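# Methods

## Quantification model

qPCR reports a quantification cycle Cq, the cycle at which amplification
fluorescence crosses a threshold; at perfect efficiency each cycle doubles
the product, so Cq is −log2 of the starting quantity up to an assay
constant. All quantification here assumes a per-cycle factor of exactly 2
(the plain ΔΔCq convention). Measured amplification efficiency — from OLS
of Cq on log10(template amount) over a dilution series, with
`E = (10^(−1/slope) − 1) × 100` — is treated as assay QC metadata, not as a
quantification input: an assay far from 90–110% should be redesigned, not
rescaled.

**gDNA correction.** An exon-targeted amplicon amplifies cDNA and
contaminating genomic DNA alike; an intron-targeted amplicon on the same
gene amplifies only gDNA. Subtracting in the linear quantity domain and
converting back gives the mRNA-only cycle value

    Cq_mRNA = −log2(2^−Cq_exon − 2^−Cq_intron),

evaluated as `Cq_exon − log2(1 − 2^(Cq_exon − Cq_intron))` with `log1p`,
which is exact for the half-signal identity (intron one cycle above exon ⇒
Cq_mRNA = Cq_exon + 1) and stable as the two signals approach each other.
When `Cq_exon ≥ Cq_intron` the subtraction has no positive argument — the
well is gDNA-dominated — and the result is *censored with a reason*, never
an exception or a sentinel 40. The correction applies to target genes only;
the reference gene is used as measured. Censoring propagates through
relative expression, correlation (dropped with a logged count) and
classification (sample not evaluable), so downstream n shrinks explicitly.

**ΔΔCq.** ΔCq_s = Cq_target,s − Cq_reference,s; relative expression is
2^−(ΔCq_s − ΔCq_calibrator), exactly 1 for the calibrator sample.
Because the method only ever uses Cq differences, adding a constant to all
Cq values on a plate leaves every fold change unchanged (plate-offset
invariance, enforced by a property test). Multi-reference normalization
(geometric means of several reference genes) is out of scope.

**Censored wells.** An "Undetermined" well is represented as a distinct
censored state, not 40.0. The single place a numeric substitution occurs is
negative-control validation, where a censored no-RT well is replaced by the
cycle ceiling to obtain a conservative lower bound on the no-RT − template
difference; means elsewhere are computed on observed replicates only, with
the censored count carried alongside.

## Melt-curve QC

Product identity is checked on the dissociation curve: Tm is the
temperature of the −dF/dT maximum, computed by central differences with an
optional 3-point boxcar (on by default, window 3). Within each gene group a
curve is excluded when |Tm − group median Tm| > `tm_tolerance` (default
1.5 °C) or when its peak height is below `peak_fraction` (default 0.5) of
the group median — the two signatures of an off-target product: shifted
melting temperature and reduced amplification peak. The defaults encode a
qualitative exclusion rule as an explicit, reproducible threshold; at least
two curves per gene are required so a median exists.

## Statistics conventions

* Summaries are mean ± SE with the n−1 SD; a single value has SE 0.
* Two groups: two-tailed Student's t-test with pooled variance (Welch
  behind a flag); more: one-way ANOVA, then Tukey HSD (Tukey–Kramer for
  unbalanced sizes, via statsmodels) or Duncan's multiple range test,
  rendered as a compact letter display. Shapiro–Wilk and Levene p-values
  are always reported as diagnostics, not gates.
* Duncan's MRT is implemented stepwise on the sorted means: the range over
  p means is significant when it exceeds `r_p · sqrt(MSE/n_h)` with `r_p`
  the studentized-range quantile at protection level 1 − (1 − α)^(p−1)
  (scipy's `studentized_range`), and no sub-range of a non-significant
  range is retested. The implementation reproduces the classical
  five-treatment worked example (means 9.8/15.4/17.6/21.6/10.8, MSE 8.06,
  20 df) pair for pair.
* Quantiles use linear interpolation between order statistics ("type 7"),
  so quartile deviation is (Q3 − Q1)/2 under that convention; CV% is
  100·SD/mean and is reported as undefined for non-positive means.

## Fertility evaluation

Correlation is Pearson's r with the OLS line of expression on litter size
and the two-sided p from the t distribution with n − 2 df. Classification
dichotomizes at a fixed litter-size cutoff (default 13); the positive class
is *subfertile* (litter strictly below the cutoff, ties negative), an
orientation chosen so the classifier detects the animals one would cull,
and configurable. ROC curves sweep all distinct thresholds with ties
grouped; AUC is the trapezoid area, equal to the normalized Mann–Whitney U
on tie-free data (tested against that oracle). For markers negatively
associated with fertility the `auto` direction negates scores so the curve
is computed in the informative orientation, and the flip is recorded.
The reported cutoff maximises Youden's J; a user-fixed cutoff can be
evaluated alongside.

**Confusion-table reconstruction.** Published diagnostic percentages
usually appear without the underlying 2×2 table. `reconstruct_confusion`
searches all integer tables with total ≤ `max_total` whose SN/SP/PPV/NPV —
rounded half-up to 2 dp in exact integer arithmetic — match the printed
values (tolerance 0.005, i.e. equality at the printed precision; half-up
matters: 78.125 prints as 78.13). All tables in a proportional family share
the same overall accuracy, so OA is recoverable even when the match is not
unique. The search doubles as an audit that printed percentages are
mutually consistent; it cannot resolve what the evaluation unit was
(animal vs. replicate) when multiple totals match.

## Synthetic cohorts

The generator emulates the design the analysis targets: a 20-boar cohort
with per-boar mean litter size ~ Normal(12.67, 0.65) (the SD back-derived
from a cohort SE of 0.14 at n = 20), two markers whose standardized log2
abundance is correlated with litter size at target r = −0.34 (EQTN-like)
and +0.32 (PRDX4-like) via
`z_m = r·z(litter) + sqrt(1 − r²)·ε`, a per-sample gDNA load (SD 1 cycle)
that sets the intron Cq 5 cycles above the marker baseline, triplicate
wells with Gaussian Cq noise (SD 0.2 cycles), a reference gene uncorrelated
with fertility (biological SD 0.3 cycles), and RNA yields drawn lognormally
to match the reference cohort's untreated mean (~102 ng/µL) and spread.
The exon Cq is the exact linear-domain mixture of the mRNA and gDNA
components, so the analytical correction inverts the generator up to
replicate noise — which makes parameter recovery a genuine end-to-end test
rather than a tautology, since noise, normalization and censoring all
intervene.

The DNase arm models the treatment's two observed consequences: yield
multiplied by 0.44 (mean-one lognormal jitter, SD 0.25) and the
abundance–fertility correlation severed (effective r = 0). Additionally 6
cycles of mRNA signal are removed, placing the residual mRNA just below
the gDNA floor: exon and intron Cq become nearly indistinguishable, and a
fraction of corrected values censor — the degraded-RNA phenotype. The
mechanistic cause (digestion of small RNAs) is not modeled, only its
statistical signature. Randomness is one `numpy` Generator per named
stream, keyed by (seed, stream name, gene), so adding a marker or changing
replicate counts does not perturb draws already assigned to other streams.

What the generator does **not** emulate: plate/batch effects (an optional
plate-offset exists only to exercise the invariance property), inter-assay
efficiency differences, non-Gaussian Cq error, boar-level covariates
(season, age, motility), or raw amplification curves. Passing tests
therefore demonstrate correctness of the computations and recoverability
of the generative parameters, not robustness to every artefact of real
instrument data.

## Numerical and scale choices

Parameter-recovery checks simulate 2,000-boar cohorts with one replicate —
large enough that the sampling SE of r (~0.02) is well inside the ±0.05
recovery band — and marginal checks use 10,000 boars. The pipeline estimate
of r is computed on log2 expression (the natural scale for Cq-derived
quantities; Pearson r on linear fold changes is attenuated by the lognormal
transform) and is compared against the cohort's *realized* sample
correlation, which absorbs the small (~0.02–0.03) measurement-error
attenuation contributed by reference-gene and replicate noise. For an
uninformative marker the best overall accuracy over all ROC thresholds
converges to the no-information rate max(p, 1 − p): that maximum, not the
accuracy at the Youden threshold (which is unstable under the null), is the
quantity checked against the no-information rate.

## Known limitations

* Single reference gene; no geNorm/NormFinder-style multi-reference
  normalization.
* The confusion-table search is exact but exponential in spirit; totals
  beyond a few hundred are slow and rarely identifiable anyway.
* Duncan's test is provided for fidelity to common usage in this
  literature; Tukey HSD is the default and the better-protected choice.
* The melt-curve model is a single sigmoid; multi-product melts (two-peak
  derivatives) are flagged only insofar as their Tm or peak height departs
  from the group.
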