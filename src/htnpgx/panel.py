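"""Variant panel: the knowledge base of the drug-ranking algorithm.

A :class:`Panel` holds the functional variant sites the algorithm scores,
each with a gene, a target organ system, a functional allele, a literature
effect-size weight (mmHg of mean arterial pressure) and a literature tier.
The organ system determines which drug class(es) a site contributes to:

========  =======================================
organ     target drug class(es)
========  =======================================
cardiac   beta_blocker
vascular  ace_inhibitor, arb
renal     diuretic
========  =======================================

The default panel shipped with the package (``data/panel_table1.yaml``)
carries 17 sites in 11 genes spanning the heart, vasculature and kidney.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from statistics import median
from typing import Optional

import yaml

__all__ = [
    "DrugClass",
    "Organ",
    "ORGAN_TARGETS",
    "VariantSite",
    "Panel",
    "PanelValidationError",
    "load_panel",
    "resolve_weights",
    "write_panel",
    "default_panel_path",
]


class DrugClass(str, enum.Enum):
    """The four ranked antihypertensive drug classes."""

    DIURETIC = "diuretic"
    ACE_INHIBITOR = "ace_inhibitor"
    ARB = "arb"
    BETA_BLOCKER = "beta_blocker"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Organ(str, enum.Enum):
    CARDIAC = "cardiac"
    VASCULAR = "vascular"
    RENAL = "renal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Organ system -> drug classes targeted by variants in that system.
ORGAN_TARGETS: dict[Organ, tuple[DrugClass, ...]] = {
    Organ.CARDIAC: (DrugClass.BETA_BLOCKER,),
    Organ.VASCULAR: (DrugClass.ACE_INHIBITOR, DrugClass.ARB),
    Organ.RENAL: (DrugClass.DIURETIC,),
}


class PanelValidationError(ValueError):
    """Raised when a panel config violates a structural invariant."""


@dataclass(frozen=True)
class VariantSite:
    """One panel entry: a functional variant and its scoring metadata.

    ``weight_mmhg`` is the literature effect size — the average difference in
    mean arterial pressure response between functional and non-functional
    carriers on the targeted therapy.  ``None`` marks sites whose effect is
    documented but not quantified; :func:`resolve_weights` substitutes a
    concrete value.  ``modifier_only`` marks sites that modulate drug
    exposure (metabolism) rather than blood pressure and are excluded from
    additive scoring.
    """

    rsid: str
    gene: str
    organ: Organ
    functional_allele: str
    weight_mmhg: Optional[float]
    literature_tier: str  # "high" | "moderate"
    n_publications: int = 0
    modifier_only: bool = False
    sbp_only: bool = False
    other_allele: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None

    @property
    def target_classes(self) -> tuple[DrugClass, ...]:
        return ORGAN_TARGETS[self.organ]

    def targets(self, drug_class: DrugClass) -> bool:
        return drug_class in self.target_classes


#: Default priority used to break exact score ties (highest single-site
#: weight first: the diuretic panel carries the 10 mmHg ADD1 site).
DEFAULT_TIEBREAK: tuple[DrugClass, ...] = (
    DrugClass.DIURETIC,
    DrugClass.ACE_INHIBITOR,
    DrugClass.BETA_BLOCKER,
    DrugClass.ARB,
)


@dataclass(frozen=True)
class Panel:
    """An ordered collection of :class:`VariantSite` plus scoring knobs.

    Parameters
    ----------
    sites:
        Panel entries, in file order.
    tiebreak_order:
        Drug-class priority used when scores tie exactly.
    na_weight_policy:
        How unquantified (``weight_mmhg: null``) sites get a numeric weight:
        ``"median_of_organ"`` (median of the organ's quantified weights) or
        ``"fixed_value"`` (use ``fixed_na_weight``).
    tier_factor:
        Multiplier applied to high-literature-tier site weights during
        scoring (>= 1; sites with stronger literature count more).
    arb_emphasis:
        Multiplier separating the two vascular classes: the receptor variant
        (rs5186) is up-weighted for ARB scoring and the ACE indel (rs1799752)
        for ACE-inhibitor scoring.
    """

    sites: tuple[VariantSite, ...]
    tiebreak_order: tuple[DrugClass, ...] = DEFAULT_TIEBREAK
    na_weight_policy: str = "median_of_organ"
    fixed_na_weight: float = 0.0
    tier_factor: float = 1.25
    arb_emphasis: float = 2.0

    def __post_init__(self) -> None:
        _validate(self)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.sites)

    def site(self, rsid: str) -> VariantSite:
        for s in self.sites:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)

    def sites_for(self, drug_class: DrugClass) -> tuple[VariantSite, ...]:
        """All sites targeting ``drug_class`` (including modifier-only)."""
        return tuple(s for s in self.sites if s.targets(drug_class))

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.gene, None)
        return tuple(seen)

    @property
    def is_resolved(self) -> bool:
        return all(s.weight_mmhg is not None for s in self.sites)


def _validate(panel: Panel) -> None:
    seen: set[str] = set()
    for s in panel.sites:
        if s.rsid in seen:
            raise PanelValidationError(f"duplicate rsID in panel: {s.rsid}")
        seen.add(s.rsid)
        if s.weight_mmhg is not None and s.weight_mmhg < 0:
            raise PanelValidationError(
                f"negative weight for {s.rsid}: {s.weight_mmhg}"
            )
        if s.literature_tier not in ("high", "moderate"):
            raise PanelValidationError(
                f"unknown literature tier for {s.rsid}: {s.literature_tier!r}"
            )
        if s.modifier_only and (s.weight_mmhg or 0) != 0:
            raise PanelValidationError(
                f"modifier-only site {s.rsid} must carry weight 0"
            )
    if set(panel.tiebreak_order) != set(DrugClass):
        raise PanelValidationError(
            "tiebreak_order must be a permutation of the four drug classes"
        )
    if panel.na_weight_policy not in ("median_of_organ", "fixed_value"):
        raise PanelValidationError(
            f"unknown na_weight_policy: {panel.na_weight_policy!r}"
        )
    # every class must have at least one scorable (non-modifier) site
    for dc in DrugClass:
        contributing = [
            s for s in panel.sites if s.targets(dc) and not s.modifier_only
        ]
        if not contributing:
            raise PanelValidationError(f"no contributing sites for class {dc.value}")


def default_panel_path() -> Path:
    """Path of the shipped default panel config."""
    return Path(
        importlib.resources.files("htnpgx").joinpath("data/panel_table1.yaml")
    )


def _site_from_mapping(entry: dict) -> VariantSite:
    try:
        organ = Organ(entry["organ"])
    except ValueError:
        raise PanelValidationError(
            f"unknown organ {entry.get('organ')!r} for {entry.get('rsid')}"
        ) from None
    except KeyError:
        raise PanelValidationError(f"site entry missing organ: {entry}") from None
    weight = entry.get("weight_mmhg", None)
    return VariantSite(
        rsid=str(entry["rsid"]),
        gene=str(entry["gene"]),
        organ=organ,
        functional_allele=str(entry["functional_allele"]),
        other_allele=(
            None if entry.get("other_allele") is None else str(entry["other_allele"])
        ),
        weight_mmhg=None if weight is None else float(weight),
        literature_tier=str(entry.get("literature_tier", "moderate")),
        n_publications=int(entry.get("n_publications", 0)),
        modifier_only=bool(entry.get("modifier_only", False)),
        sbp_only=bool(entry.get("sbp_only", False)),
        chrom=entry.get("chrom"),
        pos=None if entry.get("pos") is None else int(entry["pos"]),
    )


def load_panel(path: str | Path | None = None, *, resolve: bool = True) -> Panel:
    """Read and validate a panel config.

    Parameters
    ----------
    path:
        YAML panel file; ``None`` loads the shipped default panel.
    resolve:
        When true (default) the returned panel has every unquantified weight
        replaced with a concrete value via :func:`resolve_weights`.
    """
    path = default_panel_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "sites" not in raw:
        raise PanelValidationError(f"{path}: not a panel config (no 'sites' key)")
    try:
        tiebreak = tuple(DrugClass(c) for c in raw.get("tiebreak_order", DEFAULT_TIEBREAK))
    except ValueError as exc:
        raise PanelValidationError(f"unknown drug class in tiebreak_order: {exc}") from None
    panel = Panel(
        sites=tuple(_site_from_mapping(e) for e in raw["sites"]),
        tiebreak_order=tiebreak,
        na_weight_policy=raw.get("na_weight_policy", "median_of_organ"),
        fixed_na_weight=float(raw.get("fixed_na_weight", 0.0)),
        tier_factor=float(raw.get("tier_factor", 1.25)),
        arb_emphasis=float(raw.get("arb_emphasis", 2.0)),
    )
    return resolve_weights(panel) if resolve else panel


def resolve_weights(panel: Panel) -> Panel:
    """Return a panel in which every site has a concrete numeric weight.

    Unquantified (``None``) weights are replaced according to the panel's
    ``na_weight_policy``; under ``median_of_organ`` the substitute is the
    median of the quantified, non-modifier weights of the same organ system.
    Modifier-only sites keep weight 0 so additive scoring ignores them.
    """
    new_sites = []
    for s in panel.sites:
        if s.modifier_only:
            new_sites.append(replace(s, weight_mmhg=0.0))
        elif s.weight_mmhg is None:
            if panel.na_weight_policy == "fixed_value":
                w = panel.fixed_na_weight
            else:
                organ_weights = [
                    x.weight_mmhg
                    for x in panel.sites
                    if x.organ == s.organ
                    and x.weight_mmhg is not None
                    and not x.modifier_only
                ]
                if not organ_weights:
                    raise PanelValidationError(
                        f"cannot resolve weight for {s.rsid}: "
                        f"no quantified weights in organ {s.organ.value}"
                    )
                w = float(median(organ_weights))
            new_sites.append(replace(s, weight_mmhg=w))
        else:
            new_sites.append(replace(s, weight_mmhg=float(s.weight_mmhg)))
    return replace(panel, sites=tuple(new_sites))


def write_panel(panel: Panel, path: str | Path) -> None:
    """Serialize a panel back to YAML (round-trips with :func:`load_panel`)."""
    doc = {
        "tiebreak_order": [c.value for c in panel.tiebreak_order],
        "na_weight_policy": panel.na_weight_policy,
        "fixed_na_weight": panel.fixed_na_weight,
        "tier_factor": panel.tier_factor,
        "arb_emphasis": panel.arb_emphasis,
        "sites": [
            {
                "rsid": s.rsid,
                "gene": s.gene,
                "organ": s.organ.value,
                "functional_allele": s.functional_allele,
                "other_allele": s.other_allele,
                "weight_mmhg": s.weight_mmhg,
                "literature_tier": s.literature_tier,
                "n_publications": s.n_publications,
                "modifier_only": s.modifier_only,
                "sbp_only": s.sbp_only,
                "chrom": s.chrom,
                "pos": s.pos,
            }
            for s in panel.sites
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
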