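"""Window extraction, subsampling, protein-level splits and file round-trips."""

import numpy as np
import pytest

from phosfuse import (
    AnnotatedProtein, WindowSet, dedup_exact, extract_windows, load_annotated,
    read_windows, split_proteins, subsample_ratio, write_fasta,
    write_site_table, write_windows,
)
from phosfuse.sequence_io import locate_window

from conftest import make_window


def test_terminal_padding_geometry():
    """S at position 2 of a 5-mer protein: 11 left gaps, 9 right gaps."""
    prot = AnnotatedProtein("P1", "MSAAA", frozenset({2}))
    ws = extract_windows([prot], w=12)
    assert len(ws) == 1
    pep = ws.windows[0].peptide
    assert pep == "O" * 11 + "MSAAA" + "O" * 9
    assert len(pep) == 25


def test_one_window_per_serine_with_counts():
    # 30-residue protein with 4 serines, one labeled positive
    seq = "ASAAAAAAAS" + "AAAAAAAAAS" + "AAAAAAAAS" + "A"
    assert seq.count("S") == 4 and len(seq) == 30
    prot = AnnotatedProtein("P1", seq, frozenset({2}))
    ws = extract_windows([prot], w=12)
    assert (ws.n1, ws.n2) == (1, 3)
    for win in ws:
        assert len(win.peptide) == 25
        assert win.peptide[12] == "S"


def test_site_not_serine_is_hard_error():
    with pytest.raises(ValueError, match="P1.*expected 'S'"):
        AnnotatedProtein("P1", "MAAAA", frozenset({2}))
    with pytest.raises(ValueError, match="outside"):
        AnnotatedProtein("P1", "MSAAA", frozenset({99}))


def test_nonstandard_residue_windows_excluded(caplog):
    prot = AnnotatedProtein("P1", "AAXAASAAAAA", frozenset({6}))
    with caplog.at_level("WARNING"):
        ws = extract_windows([prot], w=12)
    assert len(ws) == 0
    assert "non-standard" in caplog.text


def test_padding_roundtrip_recovers_center(small_proteome):
    proteins, _ = small_proteome
    ws = extract_windows(proteins, 12)
    by_id = {p.id: p for p in proteins}
    for win in ws.windows[::17]:
        assert locate_window(win, by_id) == win.center_pos


def test_explicit_negative_listing_wins(tmp_path):
    prot = AnnotatedProtein("P1", "SASAS", frozenset({1}))
    write_fasta([prot], tmp_path / "p.fasta")
    (tmp_path / "sites.tsv").write_text(
        "protein_id\tposition\tlabel\nP1\t1\t1\nP1\t3\t0\n")
    loaded = load_annotated(tmp_path / "p.fasta", tmp_path / "sites.tsv")
    ws = extract_windows(loaded, w=2)
    # serine at 5 is not a negative candidate because negatives are explicit
    assert {(w.center_pos, w.label) for w in ws} == {(1, 1), (3, 0)}


def test_subsample_ratio_counts_and_determinism(rng):
    windows = [make_window("A" * 12 + "S" + "A" * 12, label=1, protein_id=f"p{i}")
               for i in range(10)]
    windows += [make_window("C" * 12 + "S" + "C" * 12, label=0, protein_id=f"n{i}")
                for i in range(100)]
    ws = WindowSet(windows)
    out = subsample_ratio(ws, ratio=3, seed=11)
    assert (out.n1, out.n2) == (10, 30)
    again = subsample_ratio(ws, ratio=3, seed=11)
    assert [w.protein_id for w in again] == [w.protein_id for w in out]
    other = subsample_ratio(ws, ratio=3, seed=12)
    assert {w.protein_id for w in other} != {w.protein_id for w in out}


def test_subsample_ratio_identity_and_errors():
    windows = [make_window("A" * 12 + "S" + "A" * 12, label=1, protein_id=f"p{i}")
               for i in range(5)]
    windows += [make_window("C" * 12 + "S" + "C" * 12, label=0, protein_id=f"n{i}")
                for i in range(5)]
    ws = WindowSet(windows)
    out = subsample_ratio(ws, ratio=1, seed=0)
    assert [w.protein_id for w in out] == [w.protein_id for w in ws]
    with pytest.raises(ValueError, match="insufficient negatives: need 10"):
        subsample_ratio(ws, ratio=2, seed=0)


def test_split_proteins_partition_and_counts():
    proteins = [AnnotatedProtein(f"P{i}", "AS", frozenset()) for i in range(766)]
    train, test = split_proteins(proteins, 0.10, seed=3)
    assert (len(train), len(test)) == (690, 76)
    ids = {p.id for p in train} | {p.id for p in test}
    assert len(ids) == 766
    assert not ({p.id for p in train} & {p.id for p in test})

    two_train, two_test = split_proteins(proteins[:2], 0.5, seed=0)
    assert (len(two_train), len(two_test)) == (1, 1)

    a = split_proteins(proteins[:10], 0.3, seed=5)
    b = split_proteins(proteins[:10], 0.3, seed=5)
    assert [p.id for p in a[1]] == [p.id for p in b[1]]
    with pytest.raises(ValueError, match="at least 2"):
        split_proteins(proteins[:1], 0.5, seed=0)


def test_dedup_exact_keeps_first_occurrence():
    mk = lambda i, seq: AnnotatedProtein(f"P{i}", seq, frozenset())
    proteins = [mk(0, "AAS"), mk(1, "AAS"), mk(2, "AAS"), mk(3, "CCS"), mk(4, "DDS")]
    out = dedup_exact(proteins)
    assert [p.id for p in out] == ["P0", "P3", "P4"]
    assert dedup_exact(proteins[2:]) == proteins[2:]


def test_windows_file_roundtrip(tmp_path, small_windows):
    path = tmp_path / "windows.tsv"
    write_windows(small_windows, path, header="# test\n")
    back = read_windows(path)
    assert back.peptides == small_windows.peptides
    assert list(back.labels) == list(small_windows.labels)
    assert [w.protein_id for w in back] == [w.protein_id for w in small_windows]


def test_fasta_site_table_roundtrip(tmp_path, small_proteome):
    proteins, _ = small_proteome
    write_fasta(proteins, tmp_path / "p.fasta")
    write_site_table(proteins, tmp_path / "s.tsv")
    loaded = load_annotated(tmp_path / "p.fasta", tmp_path / "s.tsv")
    assert [p.id for p in loaded] == [p.id for p in proteins]
    assert [p.sequence for p in loaded] == [p.sequence for p in proteins]
    assert [p.positive_sites for p in loaded] == [p.positive_sites for p in proteins]


def test_window_invariants_over_corpus(small_windows):
    labels = small_windows.labels
    assert small_windows.n1 + small_windows.n2 == len(small_windows)
    assert small_windows.n1 == int(np.sum(labels == 1))
    for win in small_windows:
        assert len(win.peptide) == 25
        assert win.peptide[12] == "S"
        assert "O" not in win.peptide.strip("O")
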