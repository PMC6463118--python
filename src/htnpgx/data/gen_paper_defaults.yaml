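# Default synthetic-cohort parameters.
#
# Group structure and BP-change distributions follow the published study
# conditions: 384 patients of whom exactly 92 match the algorithm's top
# recommendation; diagnosis-to-nadir changes drawn per realized match status
# (matched  dSBP -39.2, dDBP -19.4 mmHg; unmatched dSBP -32.1, dDBP -14.0),
# with SDs recovered from the printed SEMs via SD = SEM * sqrt(n)
# (n = 92 / 292).  Class-selection probabilities are the study population's
# drug-class distribution normalized to one selection slot (remainder =
# "other"); the monotherapy fraction is 157/384.

n_patients: 384
n_matched: 92            # exact matched-group size; null lets policy decide
seed: 17
assignment_policy: random_by_prevalence

# per-drug-slot selection probabilities (sum <= 1; remainder -> "other")
class_prevalence:
  diuretic: 0.289
  ace_inhibitor: 0.314
  arb: 0.154
  beta_blocker: 0.154
monotherapy_fraction: 0.409

# functional-allele frequencies; sites not listed use default_allele_freq
default_allele_freq: 0.5
allele_freqs:
  rs3892097: 0.21
  rs1801252: 0.85
  rs1801253: 0.70
  rs1042713: 0.60
  rs1042714: 0.43
  rs1799752: 0.56
  rs699: 0.70
  rs5051: 0.67
  rs7079: 0.72
  rs5186: 0.28
  rs12750834: 0.82
  rs2228576: 0.69
  rs1159744: 0.74
  rs2107614: 0.37
  rs2277869: 0.12
  rs1529927: 0.93
  rs4961: 0.21

# diagnosis BP (mmHg); means back-derived as current BP minus 1-year delta
diagnosis_sbp_mean: 160.0
diagnosis_sbp_sd: 12.0
diagnosis_dbp_mean: 93.0
diagnosis_dbp_sd: 8.0

# diagnosis-to-nadir BP change (mmHg), drawn per realized match status
matched_delta_sbp_mean: -39.2
matched_delta_sbp_sd: 23.0     # 2.4 * sqrt(92)
matched_delta_dbp_mean: -19.4
matched_delta_dbp_sd: 10.6     # 1.1 * sqrt(92)
unmatched_delta_sbp_mean: -32.1
unmatched_delta_sbp_sd: 22.2   # 1.3 * sqrt(292)
unmatched_delta_dbp_mean: -14.0
unmatched_delta_dbp_sd: 22.2   # 1.3 * sqrt(292)

# visit schedule: 6-month intervals over 3 years
n_intervals: 6
window_months: 6
visits_per_interval: 2
noise_sd: 2.0            # per-visit measurement noise (mmHg)
diagnosis_date: 2015-01-15
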