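import io as stdio

import numpy as np
import pytest

from grdose import simulate as sim
from grdose.io import _write_tsv


CASE_A_TEXT = """\
concentration\tcell_count\tcell_count__ctrl\tcell_count__time0\tcell_line\tagent
0.01\t700\t800\t100\tMCF7\tdrugA
0.1\t400\t800\t100\tMCF7\tdrugA
1\t150\t800\t100\tMCF7\tdrugA
10\t90\t800\t100\tMCF7\tdrugA
"""


@pytest.fixture
def case_a_stream():
    return stdio.StringIO(CASE_A_TEXT)


@pytest.fixture
def small_design():
    """2 cell lines x 2 agents x 9 concentrations x 3 replicates."""
    return sim.SimulationDesign(
        cell_lines=[
            sim.CellLineSpec("fast", division_time=0.75),
            sim.CellLineSpec("slow", division_time=1.5),
        ],
        agents=[
            sim.AgentSpec("cytostatic_drug", sc50=0.1, sc_max=1.0, h=2.0),
            sim.AgentSpec("cytotoxic_drug", sc50=0.05, sc_max=2.0, h=1.5),
        ],
        replicates=3,
    )


@pytest.fixture
def noiseless_table(small_design):
    return sim.generate_dataset(small_design, sim.NoiseModel(0.0, 0), case="A")


@pytest.fixture
def noisy_table(small_design):
    return sim.generate_dataset(small_design, sim.NoiseModel(0.05, 11), case="A")


def write_tsv(df, path):
    _write_tsv(df, path)


@pytest.fixture
def design_yaml(tmp_path, small_design):
    text = """\
cell_lines:
  - {name: fast, division_time: 0.75}
  - {name: slow, division_time: 1.5}
agents:
  - {name: cytostatic_drug, sc50: 0.1, sc_max: 1.0, h: 2.0}
  - {name: cytotoxic_drug, sc50: 0.05, sc_max: 2.0, h: 1.5}
replicates: 3
"""
    path = tmp_path / "design.yaml"
    path.write_text(text)
    return path
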