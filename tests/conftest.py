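import dataclasses

import pytest

from htnpgx import PatientGenotype, load_panel
from htnpgx.panel import DrugClass, Organ, Panel, VariantSite


@pytest.fixture(scope="session")
def panel():
    """The shipped 17-variant panel, weights resolved."""
    return load_panel()


@pytest.fixture(scope="session")
def flat_panel(panel):
    """Default panel with tier and vascular emphasis switched off."""
    return dataclasses.replace(panel, tier_factor=1.0, arb_emphasis=1.0)


@pytest.fixture
def mini_panel():
    """Three-site panel (one site per organ) for exhaustive enumeration."""
    return Panel(
        sites=(
            VariantSite("rs1801253", "ADRB1", Organ.CARDIAC, "C",
                        weight_mmhg=8.7, literature_tier="high", other_allele="G"),
            VariantSite("rs699", "AGT", Organ.VASCULAR, "C",
                        weight_mmhg=8.3, literature_tier="high", other_allele="T"),
            VariantSite("rs4961", "ADD1", Organ.RENAL, "T",
                        weight_mmhg=10.0, literature_tier="high", other_allele="G"),
        ),
    )


def make_genotype(panel, dosage=0, pid="pt", **overrides):
    """Genotype with a uniform dosage everywhere, plus per-rsID overrides."""
    dosages = {s.rsid: dosage for s in panel.sites}
    dosages.update(overrides)
    return PatientGenotype(pid, dosages)


@pytest.fixture
def genotype_factory():
    return make_genotype
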