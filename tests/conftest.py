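import dataclasses

import pytest

from cnvpathways.simulate import (
    SimulationScenario,
    scenario_presets,
    simulate_study,
)
from cnvpathways.types import CnvRecord, CnvType, GeneInterval, Inheritance, Label


def make_cnv(
    cnv_id="A:0",
    sample_id=None,
    chrom="chr1",
    start=1_000_000,
    end=1_600_000,
    cnv_type=CnvType.DUPLICATION,
    label=Label.CASE,
    cohort="A",
    inheritance=Inheritance.UNKNOWN,
):
    return CnvRecord(
        cnv_id=cnv_id,
        sample_id=sample_id or f"S{cnv_id}",
        chrom=chrom,
        start=start,
        end=end,
        cnv_type=cnv_type,
        label=label,
        cohort=cohort,
        inheritance=inheritance,
    )


@pytest.fixture(scope="session")
def tiny_scenario():
    """A fast, small study: enough structure for end-to-end runs."""
    return SimulationScenario(
        seed=11,
        n_chrom=2,
        chrom_length=40_000_000,
        n_genes=800,
        n_pathways=40,
        pathway_size_range=(10, 10),
        n_case_a=40,
        n_ctrl_a=40,
        n_case_b=60,
        n_ctrl_b=80,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_scenario):
    return simulate_study(tiny_scenario)


@pytest.fixture(scope="session")
def null_study():
    """The full-scale null preset, simulated once per session."""
    return simulate_study(scenario_presets()["null"])
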