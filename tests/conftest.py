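"""Shared fixtures: packaged schema, mini CCD/PRD, reference DB, depositions."""

import pytest

from minidep.fixture_factory import (DefectPlan, make_deposition, mini_ccd,
                                     mini_prd, packaged_schema, refdb_records,
                                     source_organism_block)


@pytest.fixture(scope="session")
def schema():
    return packaged_schema()


@pytest.fixture(scope="session")
def ccd():
    return mini_ccd()


@pytest.fixture(scope="session")
def refdb():
    return refdb_records(1)


@pytest.fixture(scope="session")
def prd_db():
    return mini_prd()


@pytest.fixture(scope="session")
def source_organism_meta():
    return source_organism_block()


@pytest.fixture()
def base_deposition():
    dep, manifest = make_deposition(DefectPlan())
    return dep, manifest


def comp_instance(comp, seq_num=1):
    """Residue instance of a CCD component at its ideal coordinates."""
    from minidep.entity_builder import AtomRecord, ResidueRecord

    return ResidueRecord(
        comp_id=comp.comp_id, seq_num=seq_num,
        atoms=[AtomRecord(n, el, comp.ideal_xyz[n])
               for n, el, _ in comp.atoms])
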