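import numpy as np
import pytest

from killerome.types import (
    CuringState,
    GenotypeMatrix,
    KillerAssay,
    PcrPanel,
    StrainRecord,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230727)


@pytest.fixture
def small_cohort():
    """A hand-built three-strain cohort with a cured derivative."""
    from killerome.io import Cohort

    strains = {
        "P1": StrainRecord("P1", population_label="wine", clinical_origin=True),
        "P2": StrainRecord("P2", population_label="mosaic"),
        "P1c": StrainRecord("P1c", derivative_of="P1", curing_state=CuringState.LA0_M0),
    }
    panels = [
        PcrPanel("P1", "L-A", (1, 1, 0, 1, 1, 1, 0)),
        PcrPanel("P1", "M1", (1, 1)),
        PcrPanel("P2", "L-A", (0,) * 7),
        PcrPanel("P1c", "L-A", (0,) * 7),
        PcrPanel("P1c", "M1", (0, 0)),
    ]
    assays = [
        KillerAssay("P1", "P2", zone_bin=2.0, stain_bin=2.0),
        KillerAssay("P1c", "P2", zone_bin=0.0, stain_bin=0.0),
    ]
    gm = GenotypeMatrix(
        strain_ids=["P1", "P2", "P1c"],
        site_ids=["s1", "s2"],
        dosages=np.array([[0, 2], [1, 1], [0, 2]]),
    )
    return Cohort(strains=strains, panels=panels, assays=assays, genotypes=gm)
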