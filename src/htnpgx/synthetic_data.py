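"""Synthetic cohort generator with known ground truth.

No patient-level data accompany the study this package models, so the
pipeline is exercised on simulated cohorts that reproduce its statistical
structure: genotypes in Hardy-Weinberg proportions at configurable
functional-allele frequencies, drug-class assignment with a controllable
match rate against the scoring engine's top recommendation, and three-year
six-month-interval BP trajectories in which each patient's total
diagnosis-to-nadir change is drawn from the matched or unmatched group
distribution according to their realized match status.

Trajectories are linear decay from the diagnosis BP to the drawn endpoint
over the chart window plus Gaussian per-visit measurement noise, so the
final interval is the noiseless nadir and, at zero noise with one visit
per interval, the analysis stage recovers each drawn delta exactly.

The shipped ``data/gen_paper_defaults.yaml`` carries the study-scale
defaults (384 patients, 92 matched, group delta distributions with SDs
recovered from printed SEMs).  Ground truth (true rank-1 class, realized
match status, drawn deltas) is emitted alongside the observable tables so
tests can measure parameter recovery.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_analysis import BPVisit, PatientRecord
from .genotype_io import (
    PatientGenotype,
    write_genotypes_table,
    write_genotypes_vcf,
)
from .panel import DrugClass, Panel
from .scoring import rank_classes

__all__ = [
    "GeneratorConfig",
    "default_generator_config_path",
    "load_generator_config",
    "simulate_genotypes",
    "simulate_cohort",
    "write_simulation",
]

ASSIGNMENT_POLICIES = (
    "random_by_prevalence",
    "genotype_guided",
    "adversarial_mismatch",
)

# Plausibility floors applied to drawn trajectory endpoints (mmHg); they
# keep every visit inside the BPVisit validity range and bite only in the
# far tails of the delta distributions.
_MIN_FINAL_SBP = 75.0
_MIN_FINAL_DBP = 40.0
_MIN_PULSE_PRESSURE = 12.0

_DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Delta means/SDs are the matched- and unmatched-group distributions of
    the total diagnosis-to-nadir BP change (mmHg, negative = drop).
    ``n_matched`` forces the exact matched-group size (drug assignment is
    then made to match or avoid the top recommendation per patient);
    ``None`` lets ``assignment_policy`` determine the match rate.
    """

    n_patients: int = 384
    seed: int = 17
    assignment_policy: str = "random_by_prevalence"
    n_matched: Optional[int] = 92
    class_prevalence: dict = field(
        default_factory=lambda: {
            "diuretic": 0.289,
            "ace_inhibitor": 0.314,
            "arb": 0.154,
            "beta_blocker": 0.154,
        }
    )
    monotherapy_fraction: float = 0.409
    default_allele_freq: float = 0.5
    allele_freqs: dict = field(default_factory=dict)
    diagnosis_sbp_mean: float = 160.0
    diagnosis_sbp_sd: float = 12.0
    diagnosis_dbp_mean: float = 93.0
    diagnosis_dbp_sd: float = 8.0
    matched_delta_sbp_mean: float = -39.2
    matched_delta_sbp_sd: float = 23.0
    matched_delta_dbp_mean: float = -19.4
    matched_delta_dbp_sd: float = 10.6
    unmatched_delta_sbp_mean: float = -32.1
    unmatched_delta_sbp_sd: float = 22.2
    unmatched_delta_dbp_mean: float = -14.0
    unmatched_delta_dbp_sd: float = 22.2
    n_intervals: int = 6
    window_months: int = 6
    visits_per_interval: int = 2
    noise_sd: float = 2.0
    diagnosis_date: dt.date = dt.date(2015, 1, 15)

    def __post_init__(self) -> None:
        if self.assignment_policy not in ASSIGNMENT_POLICIES:
            raise ValueError(
                f"unknown assignment policy {self.assignment_policy!r}"
            )
        total = sum(self.class_prevalence.values())
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"class prevalences sum to {total:.3f} > 1 "
                "(they are per-drug-slot selection probabilities)"
            )
        for rsid, f in {**self.allele_freqs, "default": self.default_allele_freq}.items():
            if f is None or not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency out of [0,1] for {rsid}: {f}")
        if self.n_matched is not None and not 0 <= self.n_matched <= self.n_patients:
            raise ValueError("n_matched must lie in [0, n_patients]")
        for name in (
            "matched_delta_sbp_sd",
            "matched_delta_dbp_sd",
            "unmatched_delta_sbp_sd",
            "unmatched_delta_dbp_sd",
            "diagnosis_sbp_sd",
            "diagnosis_dbp_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def allele_freq(self, rsid: str) -> float:
        return float(self.allele_freqs.get(rsid, self.default_allele_freq))


def default_generator_config_path() -> Path:
    return Path(
        importlib.resources.files("htnpgx").joinpath("data/gen_paper_defaults.yaml")
    )


def load_generator_config(path: str | Path | None = None) -> GeneratorConfig:
    """Load a generator config YAML (``None`` -> shipped study defaults)."""
    path = default_generator_config_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "diagnosis_date" in raw and not isinstance(raw["diagnosis_date"], dt.date):
        raw["diagnosis_date"] = dt.date.fromisoformat(str(raw["diagnosis_date"]))
    return GeneratorConfig(**raw)


def simulate_genotypes(
    config: GeneratorConfig,
    panel: Panel,
    rng: np.random.Generator | int | None = None,
) -> list[PatientGenotype]:
    """Draw per-site dosages from Hardy-Weinberg proportions.

    At functional-allele frequency *p* the genotype dosages 2/1/0 occur
    with probabilities p^2, 2p(1-p), (1-p)^2 — a Binomial(2, p) draw —
    independently across sites (no linkage disequilibrium is modeled).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    freqs = np.array([config.allele_freq(s.rsid) for s in panel.sites])
    dosages = rng.binomial(2, freqs, size=(config.n_patients, len(panel.sites)))
    width = len(str(config.n_patients))
    return [
        PatientGenotype(
            patient_id=f"P{i + 1:0{width}d}",
            dosages={s.rsid: int(dosages[i, k]) for k, s in enumerate(panel.sites)},
        )
        for i in range(config.n_patients)
    ]


def _selection_pool(config: GeneratorConfig) -> tuple[list[str], np.ndarray]:
    classes = list(config.class_prevalence)
    probs = np.array([config.class_prevalence[c] for c in classes], dtype=float)
    other = 1.0 - probs.sum()
    if other > 1e-9:
        classes.append("other")
        probs = np.append(probs, other)
    return classes, probs / probs.sum()


def _draw_classes(
    rng: np.random.Generator,
    pool: list[str],
    probs: np.ndarray,
    n_drugs: int,
    rank1: str,
    want_match: Optional[bool],
) -> frozenset[str]:
    """Draw ``n_drugs`` distinct classes honoring the match constraint.

    Under a forced designation the drawn set always contains at least one
    of the four ranked classes, so forced-unmatched patients stay in the
    match-vs-no-match contrast (the study analyzed every enrolled patient)
    and the realized group sizes equal the designated ones exactly.
    """
    pool = list(pool)
    probs = probs.copy()
    chosen: list[str] = []
    if want_match is True:
        chosen.append(rank1)
    if want_match is not None and rank1 in pool:
        k = pool.index(rank1)
        pool.pop(k)
        probs = np.delete(probs, k)
    if want_match is False:
        ranked = [k for k, c in enumerate(pool) if c != "other"]
        p_ranked = probs[ranked] / probs[ranked].sum()
        pick = ranked[rng.choice(len(ranked), p=p_ranked)]
        chosen.append(pool.pop(pick))
        probs = np.delete(probs, pick)
    while len(chosen) < n_drugs and pool:
        probs = probs / probs.sum()
        pick = rng.choice(len(pool), p=probs)
        chosen.append(pool.pop(pick))
        probs = np.delete(probs, pick)
    return frozenset(chosen)


def _trajectory(
    rng: np.random.Generator,
    config: GeneratorConfig,
    diag_sbp: float,
    diag_dbp: float,
    d_sbp: float,
    d_dbp: float,
) -> list[BPVisit]:
    """Linear decay to the drawn endpoint, one noisy visit per time point."""
    horizon = config.n_intervals * config.window_months
    n_visits = config.n_intervals * config.visits_per_interval
    months = horizon * (np.arange(1, n_visits + 1) / n_visits)
    visits = []
    for m in months:
        frac = m / horizon
        sbp = diag_sbp + d_sbp * frac + rng.normal(0.0, config.noise_sd)
        dbp = diag_dbp + d_dbp * frac + rng.normal(0.0, config.noise_sd)
        sbp = float(np.clip(sbp, 56.0, 295.0))
        dbp = float(np.clip(dbp, 36.0, sbp - 5.0))
        date = config.diagnosis_date + dt.timedelta(days=round(m * _DAYS_PER_MONTH))
        visits.append(BPVisit(date=date, sbp=sbp, dbp=dbp))
    return visits


def _demographics(rng: np.random.Generator) -> dict:
    height = float(np.clip(rng.normal(160.0, 10.0), 140.0, 200.0))
    weight = float(np.clip(rng.normal(91.0, 15.0), 45.0, 160.0))
    return {
        "age": float(np.clip(rng.normal(61.0, 10.0), 20.0, 85.0)),
        "height_cm": height,
        "weight_kg": weight,
        "bmi": weight / (height / 100.0) ** 2,
        "sex": "F" if rng.random() < 0.5 else "M",
        "past_smoker": bool(rng.random() < 0.40),
        "drinks_per_week": float(max(0.0, rng.normal(5.9, 4.0))),
        "exercise_min_week": float(max(0.0, rng.normal(176.0, 120.0))),
        "health_status": float(np.clip(rng.normal(3.15, 0.5), 0.0, 4.0)),
    }


def simulate_cohort(
    config: GeneratorConfig,
    panel: Panel,
    seed: int | None = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a full cohort plus its ground-truth table.

    Pipeline per patient: draw a genotype, rank the four drug classes with
    the scoring engine, assign currently prescribed class(es) per the
    configured policy (or the forced matched/unmatched designation when
    ``n_matched`` is set), draw the total BP change from the matched or
    unmatched distribution according to the *realized* depth-1 match
    status, and lay a noisy linear trajectory over the visit schedule.

    Returns the records and a ground-truth DataFrame with columns
    ``patient_id, rank1, rank2, assigned_classes, n_drugs, matched,
    true_delta_sbp, true_delta_dbp, diagnosis_sbp, diagnosis_dbp``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genotypes = simulate_genotypes(config, panel, rng)
    pool, probs = _selection_pool(config)

    if config.n_matched is not None:
        want = np.zeros(config.n_patients, dtype=bool)
        idx = rng.choice(config.n_patients, size=config.n_matched, replace=False)
        want[idx] = True
        want_flags: list[Optional[bool]] = [bool(w) for w in want]
    elif config.assignment_policy == "genotype_guided":
        want_flags = [True] * config.n_patients
    elif config.assignment_policy == "adversarial_mismatch":
        want_flags = [False] * config.n_patients
    else:
        want_flags = [None] * config.n_patients

    records: list[PatientRecord] = []
    truth_rows = []
    for g, want in zip(genotypes, want_flags):
        ranking = rank_classes(g, panel)
        rank1 = ranking.order[0].value
        n_drugs = 1 if rng.random() < config.monotherapy_fraction else 2
        classes = _draw_classes(rng, pool, probs, n_drugs, rank1, want)
        matched = rank1 in classes

        diag_sbp = float(rng.normal(config.diagnosis_sbp_mean, config.diagnosis_sbp_sd))
        diag_dbp = float(rng.normal(config.diagnosis_dbp_mean, config.diagnosis_dbp_sd))
        diag_dbp = min(diag_dbp, diag_sbp - 2 * _MIN_PULSE_PRESSURE)
        grp = "matched" if matched else "unmatched"
        d_sbp = float(
            rng.normal(
                getattr(config, f"{grp}_delta_sbp_mean"),
                getattr(config, f"{grp}_delta_sbp_sd"),
            )
        )
        d_dbp = float(
            rng.normal(
                getattr(config, f"{grp}_delta_dbp_mean"),
                getattr(config, f"{grp}_delta_dbp_sd"),
            )
        )
        d_sbp = max(d_sbp, _MIN_FINAL_SBP - diag_sbp)
        d_dbp = max(d_dbp, _MIN_FINAL_DBP - diag_dbp)
        d_dbp = min(d_dbp, (diag_sbp + d_sbp - _MIN_PULSE_PRESSURE) - diag_dbp)

        visits = _trajectory(rng, config, diag_sbp, diag_dbp, d_sbp, d_dbp)
        records.append(
            PatientRecord(
                patient_id=g.patient_id,
                diagnosis_bp=BPVisit(config.diagnosis_date, diag_sbp, diag_dbp),
                visits=visits,
                current_classes=classes,
                n_current_drugs=len(classes),
                genotype=g,
                demographics=_demographics(rng),
            )
        )
        truth_rows.append(
            {
                "patient_id": g.patient_id,
                "rank1": rank1,
                "rank2": ranking.order[1].value,
                "assigned_classes": "+".join(sorted(classes)),
                "n_drugs": len(classes),
                "matched": matched,
                "true_delta_sbp": d_sbp,
                "true_delta_dbp": d_dbp,
                "diagnosis_sbp": diag_sbp,
                "diagnosis_dbp": diag_dbp,
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_simulation(
    records: Sequence[PatientRecord],
    truth: pd.DataFrame,
    panel: Panel,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the observable tables + ground truth for a simulated cohort.

    Emits ``genotypes.vcf``, ``genotypes.tsv``, ``cohort.tsv`` (one row per
    patient), ``visits.tsv`` (long format: patient_id, date, sbp, dbp) and
    ``truth.tsv``; returns the paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotypes = [r.genotype for r in records if r.genotype is not None]
    paths = {
        "genotypes_vcf": out_dir / "genotypes.vcf",
        "genotypes_tsv": out_dir / "genotypes.tsv",
        "cohort": out_dir / "cohort.tsv",
        "visits": out_dir / "visits.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_genotypes_vcf(genotypes, panel, paths["genotypes_vcf"])
    write_genotypes_table(genotypes, panel, paths["genotypes_tsv"])

    cohort_rows = []
    visit_rows = []
    for r in records:
        cohort_rows.append(
            {
                "patient_id": r.patient_id,
                "diagnosis_date": r.diagnosis_bp.date.isoformat(),
                "diagnosis_sbp": round(r.diagnosis_bp.sbp, 1),
                "diagnosis_dbp": round(r.diagnosis_bp.dbp, 1),
                "current_classes": "+".join(sorted(r.current_classes)),
                "n_current_drugs": r.n_current_drugs,
                **{k: r.demographics.get(k) for k in sorted(r.demographics)},
            }
        )
        for v in r.visits:
            visit_rows.append(
                {
                    "patient_id": r.patient_id,
                    "date": v.date.isoformat(),
                    "sbp": round(v.sbp, 1),
                    "dbp": round(v.dbp, 1),
                }
            )
    pd.DataFrame(cohort_rows).to_csv(paths["cohort"], sep="\t", index=False)
    pd.DataFrame(visit_rows).to_csv(paths["visits"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
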