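import numpy as np
import pytest
from hypothesis import settings

import greycnv as g
from greycnv.simulate import random_unit_and_flanks

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def locus_model():
    """Genomic-scale locus geometry (unit 4.6 kb, flank 3.1 kb)."""
    return g.CnvLocusModel()


@pytest.fixture(scope="session")
def small_locus_model():
    """Desk-scale locus (unit 460 bp, flank 310 bp) for sequence simulations."""
    return g.CnvLocusModel.scaled_down()


@pytest.fixture(scope="session")
def unit_and_flanks(small_locus_model):
    return random_unit_and_flanks(small_locus_model, seed=11)


def make_trio(dam_total, sire_total, child_total, child_phenotype=g.UNKNOWN,
              dam_phenotype=g.UNKNOWN, sire_phenotype=g.UNKNOWN):
    """Pedigree of one mating with one measured offspring."""
    ped = g.Pedigree()
    ped.add(g.Individual("dam", phenotype=dam_phenotype,
                         measured_total_copies=dam_total))
    ped.add(g.Individual("sire", phenotype=sire_phenotype,
                         measured_total_copies=sire_total))
    ped.add(g.Individual("child", dam_id="dam", sire_id="sire",
                         phenotype=child_phenotype,
                         measured_total_copies=child_total))
    return ped
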