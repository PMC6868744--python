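import warnings

import numpy as np
import pytest

from sulfenpred import (
    CVSpec,
    EncoderConfig,
    SynthConfig,
    assemble_feature_matrix,
    generate_dataset,
    strong_enrichment,
)
from sulfenpred.ensemble import labels_to_binary
from sulfenpred.motif_io import Motif

warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated"
)


def make_motif(sequence: str, protein_id: str = "P1", position: int = 11,
               label: str = "unknown") -> Motif:
    return Motif(protein_id, position, sequence, label)


@pytest.fixture
def poly_a_motif():
    return make_motif("AAAAAAAAAACAAAAAAAAAA")


@pytest.fixture
def padded_motif():
    """Fully padded motif: central cysteine surrounded by X."""
    return make_motif("X" * 10 + "C" + "X" * 10, position=1)


@pytest.fixture(scope="session")
def small_strong_data():
    """Small strong-signal synthetic dataset with annotations."""
    cfg = SynthConfig(n_pos=40, n_neg=40, seed=11,
                      enrichment=strong_enrichment())
    dataset, store, sequences = generate_dataset(cfg)
    return dataset, store, sequences


@pytest.fixture(scope="session")
def small_strong_matrix(small_strong_data):
    dataset, store, _ = small_strong_data
    fm = assemble_feature_matrix(
        dataset, providers=store, config=EncoderConfig().table2()
    )
    return fm, labels_to_binary(dataset)
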