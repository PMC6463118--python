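# htnpgx

Weighted multi-gene pharmacogenomic ranking of antihypertensive drug
classes, plus the retrospective cohort analysis that evaluates it.

Hypertension pharmacotherapy is usually chosen by trial and error, yet each
first-line drug class works in only about half of patients, and response is
strongly heritable. `htnpgx` implements a multi-gene, literature-weighted
scoring algorithm over a 17-variant panel in 11 genes spanning the heart
(β-adrenergic signalling, CYP2D6 drug metabolism), vasculature
(renin–angiotensin system) and kidney (sodium handling). For each patient
it ranks the four first-line drug classes — thiazide-type diuretic, ACE
inhibitor (ACEI), angiotensin-II receptor blocker (ARB) and beta-blocker —
from most to least likely to lower blood pressure. A companion analysis
pipeline reproduces the retrospective chart-review design used to evaluate
such algorithms: patients whose prescribed therapy *matches* the top
recommendation are contrasted with those whose therapy does not, on
longitudinal BP endpoints. It is aimed at pharmacogenomics researchers and
biostatisticians who want a transparent, testable reference implementation
of this class of algorithm.

## The model

For drug class *C* with panel sites *i* (dosage $d_i \in \{0,1,2\}$ =
functional-allele count, literature effect-size weight $w_i$ in mmHg MAP):

$$\mathrm{raw}_C = \sum_i w_i d_i, \qquad
  \mathrm{norm}_C = \frac{\mathrm{raw}_C}{2\sum_i w_i} \in [0,1]$$

with high-literature-tier weights multiplied by `tier_factor` (default
1.25), the shared vascular sites emphasis-split between ACEI (ACE indel
rs1799752) and ARB (receptor variant rs5186), missing sites dropped from
numerator and denominator alike, and ties broken by raw score then a
configurable class order. The CYP2D6\*4 allele contributes no score but
raises a `reduced` metabolizer flag on the beta-blocker recommendation.

The analysis stage bins three years of visits into six-month intervals from
diagnosis, takes the lowest-MAP interval as the nadir
(MAP = (SBP + 2 DBP)/3), computes diagnosis-to-nadir and
diagnosis-to-current-one-year-average changes, classifies control under
JNC (<140/<90) and SPRINT (<120/<80) cutoffs, and contrasts matched vs
unmatched groups with Welch tests (Bonferroni-corrected over SBP/DBP/MAP),
Levene's variance check and a univariate OLS on the match indicator.

Because no patient-level data accompany the study design this models, a
synthetic-cohort generator (Hardy–Weinberg genotypes, controllable match
rate, noisy linear BP trajectories with known ground truth) makes the whole
pipeline testable end-to-end; see `docs/methods.md`.

## Worked example

```python
import htnpgx

panel = htnpgx.load_panel()                      # shipped 17-variant panel
g = htnpgx.PatientGenotype("pt1", {s.rsid: 0 for s in panel.sites})
g.dosages.update({"rs4961": 2, "rs2277869": 2})  # renal responder genotype
ranking = htnpgx.rank_classes(g, panel)
print([c.value for c in ranking.order])
print(round(ranking.score(ranking.order[0]).normalized, 3))
```

prints

```
['diuretic', 'ace_inhibitor', 'beta_blocker', 'arb']
0.507
```

— the two functional renal genotypes (ADD1 rs4961, WNK1 rs2277869) push
the diuretic to rank 1 with a normalized score of 0.507 (about half the
maximum achievable renal score, since the patient is homozygous functional
at two of six renal sites); the other classes score 0 and fall back to the
configured tie-break order.

The same flow from the shell:

```sh
htnpgx simulate --out-dir sim/ --seed 17
htnpgx score --table sim/genotypes.tsv --out sim/ranks.tsv
htnpgx analyze --cohort sim/cohort.tsv --visits sim/visits.tsv \
               --ranks sim/ranks.tsv --subset all --depth 1 --out sim/report.json
```

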