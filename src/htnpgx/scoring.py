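"""Weighted multi-gene drug-class scoring and 1-4 ranking.

The model is additive in functional-allele dosage: for drug class *C* with
panel sites :math:`i` (non-modifier, non-missing),

.. math::

    \\mathrm{raw}_C = \\sum_i w_i \\, d_i, \\qquad
    \\mathrm{norm}_C = \\frac{\\mathrm{raw}_C}{2 \\sum_i w_i} \\in [0, 1]

where :math:`d_i \\in \\{0, 1, 2\\}` is the dosage and :math:`w_i` the
site's literature effect-size weight (mmHg) after two adjustments:

* high-literature-tier sites are multiplied by the panel's ``tier_factor``
  (stronger peer-reviewed support counts more);
* the two vascular classes share the same sites, so the ARB score
  up-weights the receptor variant (rs5186) and the ACE-inhibitor score the
  ACE indel (rs1799752) by ``arb_emphasis``, letting the classes separate.

Normalization divides by the maximum achievable raw score over the *same*
(observed) sites, so missing genotypes drop out of numerator and
denominator alike and patients with partial panels remain scorable.
Homozygous functional carriers everywhere score 1, homozygous
non-functional carriers 0, matching the responsiveness gradient
homozygous-functional > heterozygous > homozygous non-functional.

The CYP2D6*4 site never enters the sums (weight 0, modifier-only); a
carried *4 allele instead raises a ``reduced`` metabolizer flag on the
beta-blocker score, signalling elevated beta-blocker plasma exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genotype_io import PatientGenotype
from .panel import DrugClass, Panel, VariantSite

__all__ = [
    "DrugClassScore",
    "DrugClassRanking",
    "ScoreUndefinedError",
    "effective_weight",
    "score_class",
    "rank_classes",
    "recommend",
]

#: Site whose *4 allele flags reduced hepatic beta-blocker metabolism.
CYP2D6_RSID = "rs3892097"
#: Receptor variant emphasized for ARB scoring.
ARB_EMPHASIS_RSID = "rs5186"
#: ACE indel emphasized for ACE-inhibitor scoring.
ACEI_EMPHASIS_RSID = "rs1799752"


class ScoreUndefinedError(ValueError):
    """All sites of a drug class are missing for this patient."""


@dataclass(frozen=True)
class DrugClassScore:
    """Score of one drug class for one patient."""

    drug_class: DrugClass
    raw: float  # sum of weight x dosage over observed sites (mmHg-dosage)
    normalized: float  # raw / max achievable raw over the same sites, in [0, 1]
    n_sites_used: int
    metabolizer_flag: str = "normal"  # "reduced" only on beta_blocker


@dataclass(frozen=True)
class DrugClassRanking:
    """Deterministic 1-4 ordering of the scorable drug classes."""

    patient_id: str
    scores: tuple[DrugClassScore, ...]
    order: tuple[DrugClass, ...]  # rank 1 first

    def score(self, drug_class: DrugClass) -> DrugClassScore:
        for s in self.scores:
            if s.drug_class == drug_class:
                return s
        raise KeyError(drug_class)

    def rank_of(self, drug_class: DrugClass) -> int:
        """1-based rank position; raises if the class was not scorable."""
        return self.order.index(drug_class) + 1


def effective_weight(site: VariantSite, drug_class: DrugClass, panel: Panel) -> float:
    """Site weight after literature-tier and vascular-emphasis adjustment."""
    w = float(site.weight_mmhg)  # panel must be resolved
    if site.literature_tier == "high":
        w *= panel.tier_factor
    if drug_class is DrugClass.ARB and site.rsid == ARB_EMPHASIS_RSID:
        w *= panel.arb_emphasis
    if drug_class is DrugClass.ACE_INHIBITOR and site.rsid == ACEI_EMPHASIS_RSID:
        w *= panel.arb_emphasis
    return w


def score_class(
    genotype: PatientGenotype, panel: Panel, drug_class: DrugClass
) -> DrugClassScore:
    """Score one drug class from weighted functional-allele dosages.

    Raises
    ------
    ScoreUndefinedError
        If every site targeting the class is missing in this genotype.
    """
    if not panel.is_resolved:
        raise ValueError("panel has unresolved weights; call resolve_weights first")
    sites = panel.sites_for(drug_class)
    observed = [s for s in sites if genotype.dosage(s.rsid) is not None]
    if not observed:
        raise ScoreUndefinedError(
            f"{genotype.patient_id}: all {drug_class.value} sites missing"
        )
    raw = 0.0
    denom = 0.0
    n_used = 0
    for s in observed:
        if s.modifier_only:
            continue
        w = effective_weight(s, drug_class, panel)
        raw += w * genotype.dosage(s.rsid)
        denom += w
        n_used += 1
    normalized = raw / (2.0 * denom) if denom > 0 else 0.0
    flag = "normal"
    if drug_class is DrugClass.BETA_BLOCKER:
        cyp = genotype.dosage(CYP2D6_RSID)
        if cyp is not None and cyp >= 1:
            flag = "reduced"
    return DrugClassScore(
        drug_class=drug_class,
        raw=raw,
        normalized=normalized,
        n_sites_used=n_used,
        metabolizer_flag=flag,
    )


def rank_classes(genotype: PatientGenotype, panel: Panel) -> DrugClassRanking:
    """Rank the four drug classes, most to least likely to respond.

    Classes sort by normalized score descending; exact ties fall back to the
    larger raw score, then to the panel's ``tiebreak_order``.  Classes whose
    sites are all missing are excluded with a warning; at least two classes
    must remain scorable.
    """
    scores: list[DrugClassScore] = []
    for dc in DrugClass:
        try:
            scores.append(score_class(genotype, panel, dc))
        except ScoreUndefinedError as exc:
            warnings.warn(str(exc), stacklevel=2)
    if len(scores) < 2:
        raise ScoreUndefinedError(
            f"{genotype.patient_id}: fewer than two drug classes scorable"
        )
    priority = {dc: k for k, dc in enumerate(panel.tiebreak_order)}
    ordered = sorted(
        scores, key=lambda s: (-s.normalized, -s.raw, priority[s.drug_class])
    )
    return DrugClassRanking(
        patient_id=genotype.patient_id,
        scores=tuple(scores),
        order=tuple(s.drug_class for s in ordered),
    )


def recommend(cohort: Sequence[PatientGenotype], panel: Panel) -> pd.DataFrame:
    """Rank every patient; one row per patient, sorted by patient_id.

    Columns: ``rank1..rank4`` (drug-class names, empty where a class was
    unscorable), ``score_<class>`` normalized scores (NaN where unscorable)
    and ``metabolizer_flag``.
    """
    rows = []
    for g in sorted(cohort, key=lambda g: g.patient_id):
        ranking = rank_classes(g, panel)
        row: dict[str, object] = {"patient_id": g.patient_id}
        for k in range(4):
            row[f"rank{k + 1}"] = (
                ranking.order[k].value if k < len(ranking.order) else ""
            )
        for dc in DrugClass:
            try:
                row[f"score_{dc.value}"] = ranking.score(dc).normalized
            except KeyError:
                row[f"score_{dc.value}"] = float("nan")
        try:
            row["metabolizer_flag"] = ranking.score(
                DrugClass.BETA_BLOCKER
            ).metabolizer_flag
        except KeyError:
            row["metabolizer_flag"] = "normal"
        rows.append(row)
    columns = (
        ["patient_id", "rank1", "rank2", "rank3", "rank4"]
        + [f"score_{dc.value}" for dc in DrugClass]
        + ["metabolizer_flag"]
    )
    return pd.DataFrame(rows, columns=columns)
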