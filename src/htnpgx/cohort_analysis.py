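"""Retrospective cohort analysis: match status vs. blood-pressure response.

Implements the chart-review analysis stage: longitudinal BP visits are
collapsed into six-month intervals from the diagnosis date, per-patient
endpoints are derived (diagnosis-to-nadir change, diagnosis-to-current-
one-year-average change, current BP, JNC/SPRINT control status), patients
are split by whether their prescribed drug classes match the algorithm's
top recommendation(s), and the two groups are contrasted with Welch tests
(Bonferroni-corrected over the three BP components), Levene's variance
check, and a univariate OLS of each BP change on the match indicator.

Conventions: BP drops are negative deltas; mean arterial pressure is
MAP = (SBP + 2 DBP) / 3; control thresholds are strict (JNC < 140/< 90,
SPRINT < 120/< 80).  The nadir is the six-month interval with the lowest
interval-mean MAP; per-patient MAP deltas are computed from that interval's
SBP/DBP and then averaged across patients.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import PatientGenotype
from .panel import DrugClass, Panel
from .scoring import DrugClassRanking, rank_classes

__all__ = [
    "BPVisit",
    "PatientRecord",
    "CohortReport",
    "mean_arterial_pressure",
    "interval_average",
    "nadir_delta",
    "current_year_delta",
    "current_bp",
    "control_status",
    "match_status",
    "group_contrast",
    "compare_groups",
    "read_cohort_tables",
    "read_rankings_table",
]

BP_COMPONENTS = ("sbp", "dbp", "map")
#: Strict control cutoffs (sbp_limit, dbp_limit) per guideline.
GUIDELINES = {"JNC": (140.0, 90.0), "SPRINT": (120.0, 80.0)}
DRUG_CLASS_NAMES = {dc.value for dc in DrugClass}


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = (SBP + 2 DBP) / 3."""
    return (sbp + 2.0 * dbp) / 3.0


@dataclass(frozen=True)
class BPVisit:
    """One dated office blood-pressure measurement."""

    date: dt.date
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not 50 < self.sbp < 300:
            raise ValueError(f"implausible SBP {self.sbp} on {self.date}")
        if not 30 < self.dbp < 200:
            raise ValueError(f"implausible DBP {self.dbp} on {self.date}")
        if self.dbp >= self.sbp:
            raise ValueError(
                f"DBP {self.dbp} not below SBP {self.sbp} on {self.date}"
            )

    @property
    def map(self) -> float:
        return mean_arterial_pressure(self.sbp, self.dbp)


@dataclass
class PatientRecord:
    """One chart-review record: diagnosis BP, follow-up visits, medications."""

    patient_id: str
    diagnosis_bp: BPVisit
    visits: list[BPVisit]
    current_classes: frozenset[str]  # drug-class names, may include "other"
    n_current_drugs: int = 1
    genotype: Optional[PatientGenotype] = None
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.visits = sorted(self.visits, key=lambda v: v.date)
        self.current_classes = frozenset(self.current_classes)
        if self.n_current_drugs < 1:
            raise ValueError(
                f"{self.patient_id}: patients must be on >= 1 drug class"
            )
        unknown = self.current_classes - DRUG_CLASS_NAMES - {"other"}
        if unknown:
            raise ValueError(
                f"{self.patient_id}: unknown drug class(es) {sorted(unknown)}"
            )

    @property
    def on_panel_class(self) -> bool:
        """True when at least one current class is one of the four ranked."""
        return bool(self.current_classes & DRUG_CLASS_NAMES)


def _months_between(start: dt.date, end: dt.date) -> int:
    """Completed calendar months from ``start`` to ``end`` (>= start)."""
    months = (end.year - start.year) * 12 + (end.month - start.month)
    if end.day < start.day:
        months -= 1
    return months


def interval_average(
    visits: Sequence[BPVisit],
    start_date: dt.date,
    window_months: int = 6,
) -> pd.DataFrame:
    """Collapse visits into calendar-aligned intervals from ``start_date``.

    Interval *k* covers months ``[k*window, (k+1)*window)`` after the start
    date; each interval gets the arithmetic mean of its visits' SBP and DBP
    (and the MAP of those means).  Intervals without visits are absent.

    Returns a DataFrame indexed by interval number with columns
    ``sbp``, ``dbp``, ``map``, ``n_visits``.
    """
    if not visits:
        raise ValueError("no visits to average")
    rows = []
    for v in visits:
        if v.date < start_date:
            continue
        rows.append((_months_between(start_date, v.date) // window_months, v.sbp, v.dbp))
    if not rows:
        raise ValueError("no visits on or after the start date")
    df = pd.DataFrame(rows, columns=["interval", "sbp", "dbp"])
    out = df.groupby("interval").agg(
        sbp=("sbp", "mean"), dbp=("dbp", "mean"), n_visits=("sbp", "size")
    )
    out["map"] = mean_arterial_pressure(out["sbp"], out["dbp"])
    return out[["sbp", "dbp", "map", "n_visits"]]


def _delta_from_interval(
    record: PatientRecord, interval: pd.Series
) -> tuple[float, float, float]:
    d = record.diagnosis_bp
    return (
        float(interval["sbp"] - d.sbp),
        float(interval["dbp"] - d.dbp),
        float(mean_arterial_pressure(interval["sbp"], interval["dbp"]) - d.map),
    )


def nadir_delta(
    record: PatientRecord,
    window_months: int = 6,
    component: str = "map",
) -> tuple[float, float, float]:
    """Change in (SBP, DBP, MAP) from diagnosis to the nadir interval.

    The nadir is the six-month interval with the lowest interval-mean value
    of ``component`` (default the MAP of the interval means); all three
    deltas are read from that single interval, so a patient's MAP delta is
    internally consistent with their SBP/DBP at nadir.
    ``component="per_component"`` instead takes each component's own
    minimum over intervals (separate nadirs).
    """
    bins = interval_average(record.visits, record.diagnosis_bp.date, window_months)
    if component == "per_component":
        d = record.diagnosis_bp
        return (
            float(bins["sbp"].min() - d.sbp),
            float(bins["dbp"].min() - d.dbp),
            float(bins["map"].min() - d.map),
        )
    if component not in BP_COMPONENTS:
        raise ValueError(f"unknown nadir component {component!r}")
    return _delta_from_interval(record, bins.loc[bins[component].idxmin()])


def _last_year_mean(record: PatientRecord) -> pd.Series:
    last = record.visits[-1].date
    cutoff = last - dt.timedelta(days=365)
    recent = [v for v in record.visits if v.date > cutoff]
    sbp = float(np.mean([v.sbp for v in recent]))
    dbp = float(np.mean([v.dbp for v in recent]))
    return pd.Series(
        {"sbp": sbp, "dbp": dbp, "map": mean_arterial_pressure(sbp, dbp)}
    )


def current_year_delta(record: PatientRecord) -> tuple[float, float, float]:
    """Change in (SBP, DBP, MAP) from diagnosis to the mean of the most
    recent one-year window of visits."""
    if not record.visits:
        raise ValueError(f"{record.patient_id}: no visits")
    return _delta_from_interval(record, _last_year_mean(record))


def current_bp(record: PatientRecord) -> tuple[float, float, float]:
    """Current (SBP, DBP, MAP): the most recent one-year visit average."""
    if not record.visits:
        raise ValueError(f"{record.patient_id}: no visits")
    m = _last_year_mean(record)
    return float(m["sbp"]), float(m["dbp"]), float(m["map"])


def control_status(sbp: float, dbp: float, guideline: str = "JNC") -> bool:
    """Strict BP control: JNC < 140/< 90; SPRINT < 120/< 80."""
    try:
        s_lim, d_lim = GUIDELINES[guideline.upper()]
    except KeyError:
        raise ValueError(f"unknown guideline {guideline!r}") from None
    return sbp < s_lim and dbp < d_lim


def _ranking_order(ranking) -> list[str]:
    if isinstance(ranking, DrugClassRanking):
        return [dc.value for dc in ranking.order]
    return [str(getattr(c, "value", c)) for c in ranking]


def match_status(record: PatientRecord, ranking, depth: int = 1) -> bool:
    """True iff a currently prescribed class is ranked within ``depth``.

    ``ranking`` may be a :class:`~htnpgx.scoring.DrugClassRanking` or any
    sequence of drug-class names ordered rank 1 first.
    """
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    top = set(_ranking_order(ranking)[:depth])
    return bool(record.current_classes & top)


def group_contrast(values: np.ndarray, matched: np.ndarray) -> dict:
    """Welch contrast + univariate OLS of one endpoint on the match indicator.

    The OLS slope of ``value ~ matched`` equals the matched-minus-unmatched
    mean difference; its p-value is reported from the homoskedastic
    regression, alongside the Welch two-sample p and Levene's test of equal
    variances.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    matched = np.asarray(matched, dtype=bool)
    a, b = values[matched], values[~matched]
    welch_t, welch_p = stats.ttest_ind(a, b, equal_var=False)
    lev_stat, lev_p = stats.levene(a, b)
    X = sm.add_constant(matched.astype(float))
    fit = sm.OLS(values, X).fit()
    return {
        "matched_mean": float(np.mean(a)),
        "matched_sem": float(stats.sem(a)),
        "unmatched_mean": float(np.mean(b)),
        "unmatched_sem": float(stats.sem(b)),
        "welch_t": float(welch_t),
        "welch_p": float(welch_p),
        "levene_stat": float(lev_stat),
        "levene_p": float(lev_p),
        "ols_coef": float(fit.params[1]),
        "ols_p": float(fit.pvalues[1]),
    }


@dataclass
class CohortReport:
    """Machine-readable twin of the study-style group-contrast tables."""

    subset: str
    depth: int
    n_analyzed: int
    n_matched: int
    n_unmatched: int
    n_excluded_other: int
    alpha: float
    #: {"matched"/"unmatched": {"sbp"/"dbp"/"map": (mean, sem)}}
    current: dict
    #: {"nadir"/"year": {"sbp"/"dbp"/"map": contrast dict + "p_bonferroni"}}
    deltas: dict
    #: {"matched"/"unmatched": {"jnc"/"sprint": percent}}
    control: dict

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "depth": self.depth,
            "n_analyzed": self.n_analyzed,
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "n_excluded_other": self.n_excluded_other,
            "alpha": self.alpha,
            "current": self.current,
            "deltas": self.deltas,
            "control": self.control,
        }

    def format_text(self) -> str:
        """Human-readable table: current BP, deltas (mean +/- SEM), control."""
        g = ["matched", "unmatched"]
        lines = [
            f"Match vs no-match (subset={self.subset}, depth={self.depth})",
            f"N                     {self.n_matched:>10d}  {self.n_unmatched:>10d}"
            f"   (excluded other-only: {self.n_excluded_other})",
        ]
        for comp in BP_COMPONENTS:
            vals = [
                f"{self.current[grp][comp][0]:.0f} +/- {self.current[grp][comp][1]:.0f}"
                for grp in g
            ]
            lines.append(
                f"Current {comp.upper():<4} (mmHg)   {vals[0]:>10}  {vals[1]:>10}"
            )
        for family, label in (("nadir", "nadir"), ("year", "1-yr avg")):
            for comp in BP_COMPONENTS:
                c = self.deltas[family][comp]
                star = " *" if c["p_bonferroni"] < self.alpha else ""
                lines.append(
                    f"d{comp.upper():<4} to {label:<8} "
                    f"{c['matched_mean']:>7.1f} +/- {c['matched_sem']:.1f}  "
                    f"{c['unmatched_mean']:>7.1f} +/- {c['unmatched_sem']:.1f}"
                    f"{star}"
                )
        for gl in ("jnc", "sprint"):
            lines.append(
                f"Controlled ({gl.upper():<6})   "
                f"{self.control['matched'][gl]:>9.0f}%  "
                f"{self.control['unmatched'][gl]:>9.0f}%"
            )
        return "\n".join(lines)


def _resolve_rankings(
    records: Sequence[PatientRecord],
    panel: Optional[Panel],
    rankings,
) -> dict[str, list[str]]:
    if rankings is not None:
        return {pid: _ranking_order(r) for pid, r in dict(rankings).items()}
    if panel is None:
        raise ValueError("either precomputed rankings or a panel is required")
    out = {}
    for r in records:
        if r.genotype is None:
            raise ValueError(f"{r.patient_id}: record has no genotype to rank")
        out[r.patient_id] = _ranking_order(rank_classes(r.genotype, panel))
    return out


def read_cohort_tables(
    cohort_path: str | Path, visits_path: str | Path
) -> list[PatientRecord]:
    """Assemble records from a per-patient table and a long visits table.

    ``cohort.tsv`` columns: patient_id, diagnosis_date, diagnosis_sbp,
    diagnosis_dbp, current_classes ("+"-separated), n_current_drugs, plus
    any demographic columns (kept verbatim).  ``visits.tsv`` columns:
    patient_id, date, sbp, dbp.
    """
    cohort = pd.read_csv(cohort_path, sep="\t", dtype={"patient_id": str})
    visits = pd.read_csv(visits_path, sep="\t", dtype={"patient_id": str})
    core = {
        "patient_id",
        "diagnosis_date",
        "diagnosis_sbp",
        "diagnosis_dbp",
        "current_classes",
        "n_current_drugs",
    }
    missing = core - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    by_patient: dict[str, list[BPVisit]] = {}
    for row in visits.itertuples(index=False):
        by_patient.setdefault(row.patient_id, []).append(
            BPVisit(dt.date.fromisoformat(str(row.date)), float(row.sbp), float(row.dbp))
        )
    records = []
    for row in cohort.to_dict(orient="records"):
        pid = str(row["patient_id"])
        records.append(
            PatientRecord(
                patient_id=pid,
                diagnosis_bp=BPVisit(
                    dt.date.fromisoformat(str(row["diagnosis_date"])),
                    float(row["diagnosis_sbp"]),
                    float(row["diagnosis_dbp"]),
                ),
                visits=by_patient.get(pid, []),
                current_classes=frozenset(
                    str(row["current_classes"]).split("+")
                ),
                n_current_drugs=int(row["n_current_drugs"]),
                demographics={k: row[k] for k in row if k not in core},
            )
        )
    return records


def read_rankings_table(path: str | Path) -> dict[str, list[str]]:
    """Read a rank table (as written by ``recommend``) into rank orders."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        order = [
            getattr(row, f"rank{k}")
            for k in range(1, 5)
            if isinstance(getattr(row, f"rank{k}", None), str)
            and getattr(row, f"rank{k}")
        ]
        out[row.patient_id] = order
    return out


def compare_groups(
    records: Sequence[PatientRecord],
    panel: Optional[Panel] = None,
    rankings: Optional[Mapping[str, object]] = None,
    subset: str = "all",
    depth: int = 1,
    alpha: float = 0.05,
    nadir_component: str = "map",
) -> CohortReport:
    """Contrast matched vs. unmatched patients on BP endpoints.

    Parameters
    ----------
    records:
        Chart-review records (visits, diagnosis BP, current classes).
    panel, rankings:
        Either precomputed rankings (mapping patient_id -> rank order) or a
        panel to rank each record's genotype with.
    subset:
        ``"all"`` or ``"monotherapy"`` (patients on exactly one drug class).
    depth:
        Match against the top recommendation (1) or the top two (2).

    Welch p-values are Bonferroni-corrected across the three BP components
    within each endpoint family.  Patients on none of the four ranked
    classes ("other" only) are excluded from the contrast and counted.
    """
    if subset not in ("all", "monotherapy"):
        raise ValueError(f"unknown subset {subset!r}")
    order_by_pid = _resolve_rankings(records, panel, rankings)

    pool = [r for r in records if subset == "all" or r.n_current_drugs == 1]
    excluded = [r for r in pool if not r.on_panel_class]
    pool = [r for r in pool if r.on_panel_class]

    rows = []
    for r in pool:
        nad = nadir_delta(r, component=nadir_component)
        yr = current_year_delta(r)
        cur = current_bp(r)
        rows.append(
            {
                "patient_id": r.patient_id,
                "matched": match_status(r, order_by_pid[r.patient_id], depth),
                "cur_sbp": cur[0],
                "cur_dbp": cur[1],
                "cur_map": cur[2],
                "jnc": control_status(cur[0], cur[1], "JNC"),
                "sprint": control_status(cur[0], cur[1], "SPRINT"),
                "nadir_sbp": nad[0],
                "nadir_dbp": nad[1],
                "nadir_map": nad[2],
                "year_sbp": yr[0],
                "year_dbp": yr[1],
                "year_map": yr[2],
            }
        )
    df = pd.DataFrame(rows)
    n_matched = int(df["matched"].sum()) if len(df) else 0
    n_unmatched = len(df) - n_matched
    for name, n in (("matched", n_matched), ("unmatched", n_unmatched)):
        if n < 2:
            raise ValueError(
                f"degenerate {name} group (n={n}) in subset={subset!r}, depth={depth}"
            )
    matched = df["matched"].to_numpy()

    current = {}
    control = {}
    for grp, mask in (("matched", matched), ("unmatched", ~matched)):
        sub = df[mask]
        current[grp] = {
            comp: (
                float(sub[f"cur_{comp}"].mean()),
                float(stats.sem(sub[f"cur_{comp}"])),
            )
            for comp in BP_COMPONENTS
        }
        control[grp] = {
            gl: float(100.0 * sub[gl].mean()) for gl in ("jnc", "sprint")
        }

    deltas: dict[str, dict] = {}
    for family in ("nadir", "year"):
        fam: dict[str, dict] = {}
        for comp in BP_COMPONENTS:
            c = group_contrast(df[f"{family}_{comp}"].to_numpy(), matched)
            c["p_bonferroni"] = min(1.0, c["welch_p"] * len(BP_COMPONENTS))
            fam[comp] = c
        deltas[family] = fam

    return CohortReport(
        subset=subset,
        depth=depth,
        n_analyzed=len(df),
        n_matched=n_matched,
        n_unmatched=n_unmatched,
        n_excluded_other=len(excluded),
        alpha=alpha,
        current=current,
        deltas=deltas,
        control=control,
    )
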