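import numpy as np
import pytest

from phosfuse import (
    GeneratorConfig, PeptideWindow, WindowSet, extract_windows,
    generate_proteome,
)
from phosfuse.alphabet import ALPHABET20, ALPHABET21, GAP


def make_window(peptide, label=1, protein_id="P1", pos=None):
    w = (len(peptide) - 1) // 2
    return PeptideWindow(protein_id, pos if pos is not None else w + 1,
                         w, peptide, label)


def random_peptide(rng, w=12, allow_padding=True):
    """A random window peptide: 20-letter flanks, center 'S', optional terminal gaps."""
    flanks = rng.choice(list(ALPHABET20), size=2 * w)
    pep = "".join(flanks[:w]) + "S" + "".join(flanks[w:])
    if allow_padding and rng.random() < 0.3:
        left = int(rng.integers(0, w + 1))
        pep = GAP * left + pep[left:]
    if allow_padding and rng.random() < 0.3:
        right = int(rng.integers(0, w + 1))
        pep = pep[:len(pep) - right] + GAP * right if right else pep
    return pep


def random_window_set(rng, n, w=12):
    return WindowSet([
        make_window(random_peptide(rng, w), label=int(rng.integers(0, 2)),
                    protein_id=f"R{i}")
        for i in range(n)
    ])


@pytest.fixture(scope="session")
def small_proteome():
    """A small synthetic proteome with the default planted signal."""
    cfg = GeneratorConfig(n_proteins=40, length_range=(100, 200), seed=7)
    return generate_proteome(cfg)


@pytest.fixture(scope="session")
def small_windows(small_proteome):
    proteins, _ = small_proteome
    return extract_windows(proteins, 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
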