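"""Shared fixtures: tiny hand-written pedigrees and simulated studies."""

import numpy as np
import pytest

import poetrio as pt

# A 4-variant MAP matching the default FLG panel.
MAP_TEXT = """\
1\tc.2282del4\t0\t152284896
1\tp.R501X\t0\t152285861
1\tp.R2447X\t0\t152280023
1\tp.S3247X\t0\t152277622
"""

# One complete family (two affected children, mother het at variant 1),
# one father-missing family, and one unrelated affected + one control.
PED_TEXT = """\
fam1 mo 0 0 2 1 D I C C C C C C
fam1 fa 0 0 1 1 I I C C C C C C
fam1 c1 fa mo 1 2 D I C C C C C C
fam1 c2 fa mo 2 2 I I C C C C C C
fam2 mo 0 0 2 0 I I T C C C C C
fam2 c1 0 mo 1 2 I I T C C C C C
case1 a1 0 0 1 2 D I C C C C C C
ctrl1 u1 0 0 2 1 I I C C C C C C
"""


@pytest.fixture
def ped_files(tmp_path):
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text(PED_TEXT)
    mp.write_text(MAP_TEXT)
    return ped, mp


@pytest.fixture(scope="session")
def sim_study():
    """A moderate simulated study with covariates, reused across tests."""
    cfg = pt.SimulationConfig(n_families=200, n_cases=50, n_controls=200,
                              seed=11)
    families, truth = pt.simulate_families(cfg)
    cases, controls = pt.simulate_unrelated(cfg)
    return cfg, families, truth, cases, controls
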