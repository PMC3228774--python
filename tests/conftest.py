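import numpy as np
import pytest

from popisk import AMINO_ACIDS, LabeledDataset, beta_weights


def random_peptide(rng: np.random.Generator, length: int = 9) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_peptides(rng: np.random.Generator, n: int, length: int = 9) -> list[str]:
    return [random_peptide(rng, length) for _ in range(n)]


def naive_wd_kernel(s1: str, s2: str, d: int) -> float:
    """Independent oracle: enumerate every substring of every length and
    count position-aligned matches, weighted by beta_p."""
    assert len(s1) == len(s2)
    betas = beta_weights(d)
    total = 0.0
    for p in range(1, d + 1):
        for l in range(len(s1) - p + 1):
            if s1[l:l + p] == s2[l:l + p]:
                total += betas[p - 1]
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20111115)


@pytest.fixture
def tiny_dataset(rng):
    """12 peptides, labels determined by 'G' at position 4 (separable)."""
    peps, labels = [], []
    for i in range(12):
        p = random_peptide(rng)
        if i % 2 == 0:
            p = p[:3] + "G" + p[4:]
            labels.append(1)
        else:
            while p[3] == "G":
                p = random_peptide(rng)
            labels.append(-1)
        peps.append(p)
    return LabeledDataset(peps, np.array(labels))
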