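import numpy as np
import pytest

from dimerscan.motifs import Motif


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def prob_motif(mid: str, cols, total: float = 100.0, pseudocount: float = 0.25) -> Motif:
    """Motif from explicit per-column probability vectors (A,C,G,T)."""
    probs = np.array(cols, dtype=float).T
    return Motif(mid, probs * total, pseudocount=pseudocount)


def write_fasta(path, seqs: dict) -> str:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)
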