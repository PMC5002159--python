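import numpy as np
import pytest

from bfadbp import gen_protein_triple


@pytest.fixture
def triple_files(tmp_path):
    """A mutually consistent FASTA/PSSM/ss2 triple on disk (L=60, seed 3)."""
    fasta, pssm, ss2 = gen_protein_triple(60, seed=3, record_id="syn1")
    paths = {}
    for name, text in (("syn1.fasta", fasta), ("syn1.pssm", pssm), ("syn1.ss2", ss2)):
        p = tmp_path / name
        p.write_text(text)
        paths[name.split(".")[1]] = p
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
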