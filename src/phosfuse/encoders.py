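"""The three sequence encoders: CKSAAP, positional binary, and AAC.

CKSAAP (composition of k-spaced amino-acid pairs) counts, for each gap
``k = 0..kmax``, every ordered pair of letters from the 21-letter window
alphabet separated by ``k`` intervening positions, normalized by the number
of such pairs, ``N_tal(k) = L - k - 1`` for a window of length ``L``. With
``kmax = 5`` and 21 letters this yields ``441 * 6 = 2646`` features; each
per-k block of 441 fractions sums to exactly 1.

Binary encoding one-hot encodes each of the ``2w`` flanking positions (the
center serine, being constant, is skipped) over the 21-letter alphabet:
``21 * 24 = 504`` features for a 25-mer.

AAC (amino-acid composition) is the relative frequency of the 20 standard
residues over the flanks only; the gap symbol is excluded from both the
numerator and the denominator, so the 20 values sum to 1 whenever at least
one flank residue is real.

Feature names are stable strings — ``k{gap}|{ab}``, ``p{offset}|{aa}`` with
signed offsets, ``aac|{aa}`` — so that feature-selection provenance survives
serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .alphabet import AA_INDEX, ALPHABET20, ALPHABET21, GAP
from .types import PeptideWindow, WindowSet

logger = logging.getLogger(__name__)

SCHEMES = ("CKSAAP", "BINARY", "AAC")

_N21 = len(ALPHABET21)  # 21


@dataclass
class FeatureVector:
    scheme: str
    names: list
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")


@dataclass
class FeatureMatrix:
    """Windows-by-features dense matrix with encoder provenance."""

    scheme: str
    names: list
    X: np.ndarray
    labels: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.X.shape != (len(self.labels), len(self.names)):
            raise ValueError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.labels)} windows x {len(self.names)} features"
            )

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def select_columns(self, indices) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(self.scheme, [self.names[i] for i in indices],
                             self.X[:, indices], self.labels, dict(self.params))


# ---------------------------------------------------------------------------
# feature names
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def cksaap_feature_names(kmax: int = 5) -> tuple:
    return tuple(f"k{k}|{a}{b}"
                 for k in range(kmax + 1)
                 for a in ALPHABET21 for b in ALPHABET21)


@lru_cache(maxsize=None)
def binary_feature_names(w: int = 12) -> tuple:
    offsets = list(range(-w, 0)) + list(range(1, w + 1))
    return tuple(f"p{o:+d}|{a}" for o in offsets for a in ALPHABET21)


@lru_cache(maxsize=None)
def aac_feature_names() -> tuple:
    return tuple(f"aac|{a}" for a in ALPHABET20)


def _codes(peptide: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in peptide], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"letter {exc} outside the 21-letter alphabet") from exc


# ---------------------------------------------------------------------------
# per-window encoders
# ---------------------------------------------------------------------------

def encode_cksaap(window: PeptideWindow, kmax: int = 5) -> FeatureVector:
    """k-spaced pair composition of the whole window (center included)."""
    pep = window.peptide
    L = len(pep)
    if L < kmax + 2:
        raise ValueError(f"peptide length {L} < kmax+2 = {kmax + 2}")
    codes = _codes(pep)
    vec = np.zeros(_N21 * _N21 * (kmax + 1))
    for k in range(kmax + 1):
        n_tal = L - k - 1
        pair_idx = codes[:n_tal] * _N21 + codes[k + 1:]
        counts = np.bincount(pair_idx, minlength=_N21 * _N21)
        vec[k * _N21 * _N21:(k + 1) * _N21 * _N21] = counts / n_tal
    return FeatureVector("CKSAAP", list(cksaap_feature_names(kmax)), vec)


def encode_binary(window: PeptideWindow) -> FeatureVector:
    """One-hot encoding of the 2w flanking positions (center serine skipped)."""
    w = window.half_width
    codes = _codes(window.flanks())
    vec = np.zeros(2 * w * _N21)
    vec[np.arange(2 * w) * _N21 + codes] = 1.0
    return FeatureVector("BINARY", list(binary_feature_names(w)), vec)


def encode_aac(window: PeptideWindow) -> FeatureVector:
    """Flank amino-acid composition over the 20 standard residues.

    Returns an all-zero vector (with a warning) if every flank position is
    terminal padding.
    """
    codes = _codes(window.flanks())
    counts = np.bincount(codes[codes < 20], minlength=20).astype(float)
    total = counts.sum()
    if total == 0:
        logger.warning("window %s:%d has all-gap flanks; AAC is all-zero",
                       window.protein_id, window.center_pos)
        return FeatureVector("AAC", list(aac_feature_names()), counts)
    return FeatureVector("AAC", list(aac_feature_names()), counts / total)


# ---------------------------------------------------------------------------
# vectorized matrix encoders
# ---------------------------------------------------------------------------

def _codes_matrix(peptides: list) -> np.ndarray:
    L = len(peptides[0])
    if any(len(p) != L for p in peptides):
        raise ValueError("all peptides must have equal length")
    flat = "".join(peptides)
    lut = np.full(128, -1, dtype=np.int64)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
    codes = lut[np.frombuffer(flat.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({flat[i] for i in np.nonzero(codes < 0)[0][:5]})
        raise ValueError(f"letters outside the 21-letter alphabet: {bad}")
    return codes.reshape(len(peptides), L)


def _cksaap_matrix(codes: np.ndarray, kmax: int) -> np.ndarray:
    n, L = codes.shape
    if L < kmax + 2:
        raise ValueError(f"peptide length {L} < kmax+2 = {kmax + 2}")
    blocks = []
    row_off = np.arange(n)[:, None] * (_N21 * _N21)
    for k in range(kmax + 1):
        n_tal = L - k - 1
        pair_idx = codes[:, :n_tal] * _N21 + codes[:, k + 1:]
        flat = (row_off + pair_idx).ravel()
        counts = np.bincount(flat, minlength=n * _N21 * _N21)
        blocks.append(counts.reshape(n, _N21 * _N21) / n_tal)
    return np.hstack(blocks)


def _binary_matrix(codes: np.ndarray) -> np.ndarray:
    n, L = codes.shape
    w = (L - 1) // 2
    flank = np.delete(codes, w, axis=1)
    X = np.zeros((n, 2 * w * _N21))
    cols = np.arange(2 * w) * _N21 + flank
    X[np.arange(n)[:, None], cols] = 1.0
    return X


def _aac_matrix(codes: np.ndarray) -> np.ndarray:
    n, L = codes.shape
    w = (L - 1) // 2
    flank = np.delete(codes, w, axis=1)
    X = np.zeros((n, 20))
    for r in range(20):
        X[:, r] = (flank == r).sum(axis=1)
    totals = X.sum(axis=1, keepdims=True)
    empty = totals[:, 0] == 0
    if empty.any():
        logger.warning("%d windows have all-gap flanks; AAC rows are all-zero",
                       int(empty.sum()))
    totals[empty] = 1.0
    return X / totals


def encode_matrix(ws: WindowSet, scheme: str, kmax: int = 5) -> FeatureMatrix:
    """Encode every window of *ws* under *scheme*, preserving order and labels."""
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if len(ws) == 0:
        raise ValueError("cannot encode an empty window set")
    codes = _codes_matrix(ws.peptides)
    w = ws.half_width
    if scheme == "CKSAAP":
        X = _cksaap_matrix(codes, kmax)
        names = list(cksaap_feature_names(kmax))
        params = {"kmax": kmax, "w": w}
    elif scheme == "BINARY":
        X = _binary_matrix(codes)
        names = list(binary_feature_names(w))
        params = {"w": w}
    else:
        X = _aac_matrix(codes)
        names = list(aac_feature_names())
        params = {"w": w}
    return FeatureMatrix(scheme, names, X, ws.labels, params)


def feature_names_for(scheme: str, w: int, kmax: int = 5) -> list:
    scheme = scheme.upper()
    if scheme == "CKSAAP":
        return list(cksaap_feature_names(kmax))
    if scheme == "BINARY":
        return list(binary_feature_names(w))
    if scheme == "AAC":
        return list(aac_feature_names())
    raise ValueError(f"unknown scheme {scheme!r}")


def write_matrix_tsv(fm: FeatureMatrix, path, header: str = "") -> None:
    """Serialize a feature matrix as TSV with named columns."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write(f"# scheme={fm.scheme} params={fm.params}\n")
        fh.write("label\t" + "\t".join(fm.names) + "\n")
        for y, row in zip(fm.labels, fm.X):
            fh.write(str(int(y)) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
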