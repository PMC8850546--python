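"""Reading sequences and site tables, window extraction, sampling and splits.

File conventions
----------------
* FASTA (multi-record) for protein sequences, via Biopython.
* Site table: TSV with header columns ``protein_id``, ``position`` (1-based),
  ``label`` (1 = phosphosite, 0 = explicit negative). Lines starting with
  ``#`` are ignored.
* Windows file: one peptide per line, tab-separated columns
  ``peptide, label, protein_id, position``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import GAP, NON_STANDARD
from .types import NEGATIVE, POSITIVE, AnnotatedProtein, PeptideWindow, WindowSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# file input
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file into ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(proteins: list[AnnotatedProtein], path) -> None:
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n")
            seq = prot.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_site_table(path) -> pd.DataFrame:
    """Read the TSV site table (protein_id, position, label)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"protein_id": str, "position": int, "label": int})
    missing = {"protein_id", "position", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns: {sorted(missing)}")
    return df


def write_site_table(proteins: list[AnnotatedProtein], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("protein_id\tposition\tlabel\n")
        for prot in proteins:
            for pos in sorted(prot.positive_sites):
                fh.write(f"{prot.id}\t{pos}\t1\n")


def load_annotated(fasta_path, sites_path) -> list[AnnotatedProtein]:
    """Join a FASTA file with a site table into validated AnnotatedProteins.

    Proteins without any table entry are kept with no positive sites (all of
    their serines become negative candidates). If a protein has explicit
    label-0 rows, those — and only those — are its negatives.
    """
    sites = read_site_table(sites_path)
    by_protein = dict(tuple(sites.groupby("protein_id", sort=False)))
    proteins = []
    for pid, seq in read_fasta(fasta_path):
        sub = by_protein.get(pid)
        if sub is None:
            proteins.append(AnnotatedProtein(pid, seq))
            continue
        pos = frozenset(sub.loc[sub["label"] == 1, "position"].tolist())
        neg_rows = sub.loc[sub["label"] == 0, "position"].tolist()
        neg = frozenset(neg_rows) if neg_rows else None
        proteins.append(AnnotatedProtein(pid, seq, pos, neg))
    return proteins


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def _cut_window(sequence: str, pos: int, w: int) -> str:
    """Extract the 2w+1 window around 1-based *pos*, padding termini with 'O'."""
    i = pos - 1
    left = sequence[max(0, i - w):i]
    right = sequence[i + 1:i + 1 + w]
    return GAP * (w - len(left)) + left + sequence[i] + right + GAP * (w - len(right))


def extract_windows(proteins: list[AnnotatedProtein], w: int = 12) -> WindowSet:
    """Extract one labeled window per serine site from every protein.

    Positions within ``w`` of a terminus are padded with the gap symbol so
    every peptide has length ``2w+1``. Windows whose flanks contain
    non-standard residue codes (B, J, X, Z, U) are excluded with a warning.
    """
    if w < 1:
        raise ValueError(f"half-width w must be >= 1, got {w}")
    windows = []
    n_skipped = 0
    for prot in proteins:
        sites = [(p, POSITIVE) for p in sorted(prot.positive_sites)]
        sites += [(p, NEGATIVE) for p in prot.negative_candidates()]
        for pos, label in sorted(sites):
            pep = _cut_window(prot.sequence, pos, w)
            if any(c in NON_STANDARD for c in pep):
                n_skipped += 1
                continue
            windows.append(PeptideWindow(prot.id, pos, w, pep, label))
    if n_skipped:
        logger.warning("excluded %d windows containing non-standard residues",
                       n_skipped)
    return WindowSet(windows)


def locate_window(win: PeptideWindow, proteins_by_id: dict) -> int:
    """Strip padding from *win* and re-locate it in its source protein.

    Returns the recovered 1-based center position (padding round-trip check).
    """
    prot = proteins_by_id[win.protein_id]
    n_left_pad = len(win.peptide) - len(win.peptide.lstrip(GAP))
    core = win.peptide.strip(GAP)
    start = win.center_pos - 1 - (win.half_width - n_left_pad)
    if prot.sequence[start:start + len(core)] != core:
        raise ValueError(
            f"window {win.protein_id}:{win.center_pos} does not match its source"
        )
    return start + (win.half_width - n_left_pad) + 1


# ---------------------------------------------------------------------------
# sampling and splitting
# ---------------------------------------------------------------------------

def subsample_ratio(ws: WindowSet, ratio: int, seed: int) -> WindowSet:
    """Keep all positives plus ``ratio * n1`` negatives sampled without replacement.

    The training sets in this problem are built at controlled
    positive:negative ratios (1:1, 1:2, 1:3) because the raw serine background
    is heavily imbalanced. Output preserves the input window order.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be a positive integer, got {ratio}")
    pos_idx = [i for i, win in enumerate(ws.windows) if win.is_positive]
    neg_idx = [i for i, win in enumerate(ws.windows) if not win.is_positive]
    need = ratio * len(pos_idx)
    if len(neg_idx) < need:
        raise ValueError(
            f"insufficient negatives: need {need} (= {ratio} x {len(pos_idx)}), "
            f"have {len(neg_idx)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(neg_idx), size=need, replace=False)
    keep = sorted(pos_idx + [neg_idx[i] for i in chosen])
    return ws.subset(keep)


def split_proteins(proteins: list[AnnotatedProtein], test_fraction: float,
                   seed: int) -> tuple[list[AnnotatedProtein], list[AnnotatedProtein]]:
    """Protein-level train/test split: no protein contributes windows to both sides.

    The test count is ``floor(n * test_fraction)`` clamped to ``[1, n-1]``
    (e.g. 766 proteins at 0.10 -> 690 train / 76 test).
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    n = len(proteins)
    if n < 2:
        raise ValueError(f"need at least 2 proteins to split, got {n}")
    n_test = min(n - 1, max(1, int(np.floor(n * test_fraction))))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_ids = set(order[:n_test])
    train = [p for i, p in enumerate(proteins) if i not in test_ids]
    test = [p for i, p in enumerate(proteins) if i in test_ids]
    return train, test


def dedup_exact(proteins: list[AnnotatedProtein]) -> list[AnnotatedProtein]:
    """Drop byte-identical duplicate sequences, keeping the first occurrence.

    This is deliberately only an exact-duplicate filter; similarity-based
    redundancy reduction (e.g. 30% identity clustering) is an upstream,
    external concern.
    """
    seen = set()
    out = []
    for prot in proteins:
        if prot.sequence not in seen:
            seen.add(prot.sequence)
            out.append(prot)
    return out


# ---------------------------------------------------------------------------
# windows file round-trip
# ---------------------------------------------------------------------------

def write_windows(ws: WindowSet, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("peptide\tlabel\tprotein_id\tposition\n")
        for win in ws:
            fh.write(f"{win.peptide}\t{win.label}\t{win.protein_id}\t{win.center_pos}\n")


def read_windows(path) -> WindowSet:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"peptide": str, "label": int})
    windows = []
    for i, row in enumerate(df.itertuples(index=False)):
        pep = row.peptide
        w = (len(pep) - 1) // 2
        pid = getattr(row, "protein_id", f"win{i}")
        pos = int(getattr(row, "position", w + 1))
        windows.append(PeptideWindow(str(pid), pos, w, pep, int(row.label)))
    return WindowSet(windows)
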