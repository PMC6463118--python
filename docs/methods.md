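# Methods

## Scoring model

The engine ranks four antihypertensive drug classes from functional-allele
dosages at 17 variant sites in 11 genes. Each site belongs to one organ
system, which fixes the class(es) it scores for: cardiac sites →
beta-blocker; vascular sites → ACE inhibitor and ARB; renal sites →
diuretic. The model is *additive in dosage*: a site contributes
weight × dosage, with dosage 2/1/0 for homozygous-functional /
heterozygous / homozygous-non-functional carriers. Additivity is the
minimal model consistent with the qualitative responsiveness gradient the
panel encodes (homozygous functional > heterozygous > homozygous
non-functional); no dominance or epistasis terms are fitted, because no
data exist to fit them to.

Scores are normalized by the maximum achievable weighted sum over the
*observed* sites of the class, giving a dimensionless value in [0, 1].
This renormalization is also the missing-data policy: an unobserved site
leaves numerator and denominator together, so partially genotyped patients
remain scorable, and a patient missing an entire organ system simply
receives a ranking over the remaining classes (at least two classes must
be scorable).

Three structural adjustments:

* **Literature tier** — sites with the strongest peer-reviewed support are
  up-weighted by `tier_factor` before summation. The magnitude of this
  priority is not identifiable from published information; the default
  1.25 is an explicit, documented convention, configurable in the panel
  file.
* **Vascular emphasis** — ACEI and ARB score over the same six vascular
  sites and would otherwise tie identically. The receptor variant (AGTR1
  rs5186) is up-weighted `arb_emphasis`-fold (default 2×) for the ARB
  score, and the ACE indel (rs1799752) equally for the ACEI score,
  following the mechanistic pairing of each variant with its drug target.
  Both numerator and denominator see the emphasized weight, so the [0, 1]
  scale is preserved.
* **Metabolizer flag** — the CYP2D6\*4 loss-of-function allele alters
  beta-blocker plasma levels but has no established BP effect, so it
  carries weight 0 and is excluded from the sums; any carried \*4 allele
  instead sets `metabolizer_flag = "reduced"` on the beta-blocker score.
  The flag does not change the ranking.

Ranking sorts by normalized score, breaking exact ties by raw score and
then by a configured class order (default: diuretic, ACEI, beta-blocker,
ARB — highest single-site weight first). Ties are compared exactly, not
within a tolerance: identical inputs give bit-identical rankings.
A consequence of the shared vascular sites worth noting: raising the
dosage of a shared site never lowers either vascular class's *score*, but
can reorder ACEI and ARB relative to each other, since each gains a
different emphasis-weighted amount. The monotonicity guarantee is
therefore: a class's score never decreases, and it never drops below a
class whose score the change did not touch.

Unquantified panel weights (two renal sites whose literature reports no
effect size) are resolved at load time: by default to the median of the
organ's quantified weights (6.0 mmHg for the renal sites), keeping the
sites informative; a `fixed_value` policy (e.g. 0) is available for
sensitivity analysis.

## Cohort analysis

Visits are binned into calendar-aligned six-month intervals from the
diagnosis date; each interval gets the arithmetic mean of its visits.
Endpoints per patient:

* **Nadir change** — the interval minimizing interval-mean MAP
  (MAP = (SBP + 2 DBP)/3) defines the nadir; ΔSBP/ΔDBP/ΔMAP are all read
  from that one interval relative to the diagnosis measurement, so the
  per-patient MAP delta is internally consistent. A `per_component`
  option instead takes each component's own minimum.
* **Current-year change / current BP** — mean over visits in the 365 days
  preceding the last visit.
* **Control** — strict inequalities: JNC <140/<90, SPRINT <120/<80
  (SPRINT control therefore implies JNC control).

Matched patients are those whose currently prescribed classes intersect
the algorithm's top `depth` recommendations (depth 1 or 2; depth-1 match
implies depth-2 match). Patients on none of the four ranked classes are
excluded from the contrast and counted. Group contrasts use Welch's
two-sample test per BP component with Bonferroni correction across the
three components (equivalent to two-group one-way ANOVA with post-hoc
correction), Levene's test reported as the variance check (reported, not
gating), and a univariate OLS of each delta on the match indicator, whose
slope equals the matched-minus-unmatched mean difference. α = 0.05.
Either group with n < 2 is an error naming the group.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, with
ground truth recorded for every patient:

* **Genotypes** — independent Hardy–Weinberg draws (dosage ~
  Binomial(2, p)) at configurable per-site functional-allele frequencies.
  No linkage disequilibrium is modeled — a documented limitation, as no
  haplotype information is available for the panel.
* **Drug assignment** — each patient is on one class (probability
  `monotherapy_fraction`, default 0.409) or two, drawn without replacement
  from a per-slot selection distribution over the four classes plus
  "other" (defaults derived from the study population's class
  distribution, normalized to one slot). Policies: natural
  (`random_by_prevalence`), always-matching (`genotype_guided`),
  never-matching (`adversarial_mismatch`). Setting `n_matched` forces an
  exact matched/unmatched split: designated patients receive their
  engine-computed rank-1 class, the rest draw ranked classes avoiding
  rank 1 (so none are excluded as "other"-only and realized group sizes
  equal the designation; the default file designates 92 of 384).
* **BP trajectories** — diagnosis BP ~ N(160, 12)/N(93, 8) mmHg
  (back-derived as current BP minus the one-year change, since diagnosis
  BP itself is not published); each patient's total ΔSBP/ΔDBP is drawn
  from the matched or unmatched group distribution according to realized
  match status (defaults: matched −39.2/−19.4, unmatched −32.1/−14.0,
  SDs reconstructed from published SEMs via SD = SEM·√n with n = 92/292).
  The trajectory is strict linear decay to that endpoint over the 36-month
  window — the simplest interpolant consistent with endpoint-only
  information — with two visits per interval and N(0, 2 mmHg) measurement
  noise per visit, small enough that the min-over-intervals nadir
  estimator is essentially unbiased (interval spacing ≈ Δ/6 ≈ 5 mmHg
  against a 1.4 mmHg interval-mean noise SE). At zero noise with one
  visit per interval the analysis recovers each drawn delta exactly.
  Physiological floors (final SBP ≥ 75, DBP ≥ 40, pulse pressure ≥ 12)
  clip only the far tails (≲2σ events, ≈ +0.2 mmHg effect on the matched
  SBP mean).

What passing tests show — and don't: recovery tests demonstrate that the
analysis stage is an unbiased estimator of the generator's group
parameters under this structure; they cannot validate the algorithm's
clinical effect, model medication changes over time, adherence,
genotype–covariate correlation, or BP rebound after nadir (the simulated
one-year-average change equals ≈ 11/12 of the nadir change by
construction, slightly larger in magnitude than the published ratio).

## Problem sizes and determinism

The test suite runs the study-scale configuration (384 patients) once,
a 10⁴-genotype Hardy–Weinberg check, a 2000-patient match-rate
convergence check and 1000-shuffle permutation nulls; everything is
seeded through `numpy.random.default_rng`, and the single fixed
acceptance seed is 20190228. The study-scale significance check is a
single draw at the published effect size, where the Bonferroni-corrected
SBP contrast has roughly 60% power by design — a failed significance
clause at one seed reflects that sampling distribution, not an
implementation defect; the recovery band (±2 SEM) is the primary check.
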