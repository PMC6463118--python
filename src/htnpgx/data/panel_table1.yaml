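# Default 17-variant antihypertensive pharmacogenomic panel.
#
# One entry per variant site: the gene, the target organ system (which fixes
# the drug class(es) the site scores for), the functional allele (the allele
# associated with response to the targeted class; "D" is the ACE deletion),
# the literature effect-size weight in mmHg of mean arterial pressure, the
# literature tier and the PubMed publication count supporting the gene.
# `weight_mmhg: null` marks sites whose effect size is not quantified in the
# literature; they are resolved at load time per `na_weight_policy`.
# `other_allele` is only used by genotype I/O to interpret allele-pair calls.

tiebreak_order: [diuretic, ace_inhibitor, beta_blocker, arb]
na_weight_policy: median_of_organ
fixed_na_weight: 0.0
tier_factor: 1.25
arb_emphasis: 2.0

sites:
  # --- cardiac (beta-blockade) ---
  - rsid: rs3892097        # CYP2D6*4 loss-of-function allele; metabolizer flag only
    gene: CYP2D6
    organ: cardiac
    functional_allele: A
    other_allele: G
    weight_mmhg: 0
    literature_tier: high
    n_publications: 353
    modifier_only: true
  - rsid: rs1801252        # ADRB1 Ser49
    gene: ADRB1
    organ: cardiac
    functional_allele: A
    other_allele: G
    weight_mmhg: 5.2
    literature_tier: high
    n_publications: 2749
  - rsid: rs1801253        # ADRB1 Arg389
    gene: ADRB1
    organ: cardiac
    functional_allele: C
    other_allele: G
    weight_mmhg: 8.7
    literature_tier: high
    n_publications: 2749
  - rsid: rs1042713        # ADRB2 Arg16
    gene: ADRB2
    organ: cardiac
    functional_allele: A
    other_allele: G
    weight_mmhg: 3.7
    literature_tier: moderate
    n_publications: 3067
  - rsid: rs1042714        # ADRB2 Glu27; literature effect reported on SBP
    gene: ADRB2
    organ: cardiac
    functional_allele: G
    other_allele: C
    weight_mmhg: 7
    sbp_only: true
    literature_tier: high
    n_publications: 3067

  # --- vascular (ACE inhibitor / angiotensin-II receptor blocker) ---
  - rsid: rs1799752        # ACE insertion/deletion; deletion allele is functional
    gene: ACE
    organ: vascular
    functional_allele: D
    other_allele: I
    weight_mmhg: 4.7
    literature_tier: moderate
    n_publications: 1377
  - rsid: rs699            # AGT M268T, C variant
    gene: AGT
    organ: vascular
    functional_allele: C
    other_allele: T
    weight_mmhg: 8.3
    literature_tier: high
    n_publications: 2797
  - rsid: rs5051           # AGT promoter
    gene: AGT
    organ: vascular
    functional_allele: C
    other_allele: T
    weight_mmhg: 8
    literature_tier: high
    n_publications: 2797
  - rsid: rs7079           # AGT 3' region
    gene: AGT
    organ: vascular
    functional_allele: A
    other_allele: C
    weight_mmhg: 4.3
    literature_tier: moderate
    n_publications: 2797
  - rsid: rs5186           # AGTR1 A1166C, C variant
    gene: AGTR1
    organ: vascular
    functional_allele: C
    other_allele: A
    weight_mmhg: 3.3
    literature_tier: moderate
    n_publications: 1451
  - rsid: rs12750834       # REN promoter, C variant
    gene: REN
    organ: vascular
    functional_allele: C
    other_allele: T
    weight_mmhg: 3.7
    literature_tier: moderate
    n_publications: 1085

  # --- renal (thiazide / thiazide-like diuretic) ---
  - rsid: rs2228576        # SCNN1A Thr663Ala; effect size not quantified
    gene: SCNN1A
    organ: renal
    functional_allele: A
    other_allele: G
    weight_mmhg: null
    literature_tier: moderate
    n_publications: 31
  - rsid: rs1159744        # WNK1 (a)
    gene: WNK1
    organ: renal
    functional_allele: G
    other_allele: C
    weight_mmhg: 3.7
    literature_tier: moderate
    n_publications: 35
  - rsid: rs2107614        # WNK1 (b)
    gene: WNK1
    organ: renal
    functional_allele: C
    other_allele: T
    weight_mmhg: 5.0
    literature_tier: moderate
    n_publications: 35
  - rsid: rs2277869        # WNK1 (c)
    gene: WNK1
    organ: renal
    functional_allele: C
    other_allele: T
    weight_mmhg: 7.0
    literature_tier: high
    n_publications: 35
  - rsid: rs1529927        # SLC12A3, C variant; effect size not quantified
    gene: SLC12A3
    organ: renal
    functional_allele: G
    other_allele: C
    weight_mmhg: null
    literature_tier: moderate
    n_publications: 103
  - rsid: rs4961           # ADD1 Gly460Trp, T variant
    gene: ADD1
    organ: renal
    functional_allele: T
    other_allele: G
    weight_mmhg: 10
    literature_tier: high
    n_publications: 52
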