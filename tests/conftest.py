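import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aquamark import synthetic
from aquamark.transitions import Peptide, select_transitions


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_design():
    """Validation-cohort layout with a fixed seed."""
    return synthetic.CohortDesign(seed=7)


@pytest.fixture
def marker_truth():
    """Two marker proteins, log2 effect 1 on both stage contrasts."""
    effects = {
        "P0001": {("PDR", "NPDR"): 1.0, ("NVG", "PDR"): 1.0},
        "P0002": {("PDR", "NPDR"): -1.0, ("NVG", "PDR"): -1.0},
    }
    return synthetic.GroundTruth(true_marker_effects=effects)


@pytest.fixture
def marker_transition_list():
    return synthetic.spikein_transitions() + synthetic.marker_transitions(
        ["P0001", "P0002"]
    )


@pytest.fixture
def fasta_file(tmp_path, rng):
    """49 synthetic proteins assembled from eligible tryptic blocks."""
    alphabet = list("ADEFGHILNPQSTVWY")
    lines = []
    for i in range(1, 50):
        blocks = []
        for _ in range(rng.integers(4, 8)):
            n = int(rng.integers(6, 15))
            blocks.append("".join(rng.choice(alphabet, size=n)) + "K")
        lines.append(f">PROT{i:02d} synthetic protein {i}")
        lines.append("".join(blocks))
    path = tmp_path / "db.fasta"
    path.write_text("\n".join(lines) + "\n")
    return path
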