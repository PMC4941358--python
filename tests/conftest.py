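import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acpred import LabeledDataset, Peptide

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def separable_dataset():
    """Homopolymer classes: positives all-A, negatives all-C.

    At every gap the positive composition is a point mass on AA and the
    negative on CC, so the classes are perfectly separated in feature
    space at a distance the RBF kernel resolves.
    """
    pos = [Peptide(f"pos{i}", "A" * (10 + i % 3)) for i in range(10)]
    neg = [Peptide(f"neg{i}", "C" * (10 + i % 3)) for i in range(10)]
    labels = np.r_[np.ones(10, int), -np.ones(10, int)]
    return LabeledDataset(pos + neg, labels)


@pytest.fixture
def random_peptides():
    """Deterministic random peptides over the standard alphabet."""

    def _make(n, length_range=(6, 40), seed=0):
        from acpred import ALPHABET

        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            L = int(rng.integers(*length_range))
            seq = "".join(rng.choice(list(ALPHABET), size=L))
            out.append(Peptide(f"r{i}", seq))
        return out

    return _make
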