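"""Core domain containers: annotated proteins, peptide windows, window sets.

Coordinates are 1-based in all files and public fields (``positive_sites``,
``center_pos``); internal array indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP

#: Integer labels used throughout: 1 = phosphorylated (positive) serine,
#: 0 = non-phosphorylated (negative) serine.
POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein sequence with labeled serine sites.

    ``positive_sites`` are 1-based positions of experimentally annotated
    phospho-serines. Negative candidates are all remaining serines, unless
    ``negative_sites`` is given explicitly (explicit listing wins).
    """

    id: str
    sequence: str
    positive_sites: frozenset = frozenset()
    negative_sites: frozenset | None = None

    def __post_init__(self):
        n = len(self.sequence)
        for pos in self.positive_sites:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"protein {self.id}: positive site {pos} outside [1, {n}]"
                )
            if self.sequence[pos - 1] != "S":
                raise ValueError(
                    f"protein {self.id}: site {pos} is "
                    f"{self.sequence[pos - 1]!r}, expected 'S'"
                )
        if self.negative_sites is not None:
            for pos in self.negative_sites:
                if not 1 <= pos <= n:
                    raise ValueError(
                        f"protein {self.id}: negative site {pos} outside [1, {n}]"
                    )
                if self.sequence[pos - 1] != "S":
                    raise ValueError(
                        f"protein {self.id}: negative site {pos} is "
                        f"{self.sequence[pos - 1]!r}, expected 'S'"
                    )

    def serine_positions(self) -> list[int]:
        """All 1-based serine positions in the sequence."""
        return [i + 1 for i, c in enumerate(self.sequence) if c == "S"]

    def negative_candidates(self) -> list[int]:
        """Negative sites: explicit list if given, else all unlisted serines."""
        if self.negative_sites is not None:
            return sorted(self.negative_sites)
        return [p for p in self.serine_positions() if p not in self.positive_sites]


@dataclass(frozen=True)
class PeptideWindow:
    """A ``2w+1``-mer centered on a candidate serine.

    The peptide lives over the 21-letter alphabet; the gap symbol ``O``
    occurs only as a contiguous prefix and/or suffix (terminal padding).
    """

    protein_id: str
    center_pos: int  # 1-based position of the center serine in the protein
    half_width: int
    peptide: str
    label: int  # POSITIVE or NEGATIVE

    def __post_init__(self):
        w = self.half_width
        if len(self.peptide) != 2 * w + 1:
            raise ValueError(
                f"window {self.protein_id}:{self.center_pos}: peptide length "
                f"{len(self.peptide)} != 2w+1 = {2 * w + 1}"
            )
        if self.peptide[w] != "S":
            raise ValueError(
                f"window {self.protein_id}:{self.center_pos}: center residue "
                f"{self.peptide[w]!r} is not 'S'"
            )
        if GAP in self.peptide.strip(GAP):
            raise ValueError(
                f"window {self.protein_id}:{self.center_pos}: interior gap "
                f"symbol in {self.peptide!r}"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE

    def flanks(self) -> str:
        """The 2w flanking residues (center serine removed)."""
        w = self.half_width
        return self.peptide[:w] + self.peptide[w + 1:]


@dataclass
class WindowSet:
    """An ordered collection of peptide windows with class counts."""

    windows: list = field(default_factory=list)

    @property
    def n1(self) -> int:
        """Number of positive windows."""
        return sum(1 for win in self.windows if win.is_positive)

    @property
    def n2(self) -> int:
        """Number of negative windows."""
        return len(self.windows) - self.n1

    @property
    def labels(self) -> np.ndarray:
        return np.array([win.label for win in self.windows], dtype=int)

    @property
    def peptides(self) -> list[str]:
        return [win.peptide for win in self.windows]

    @property
    def half_width(self) -> int:
        if not self.windows:
            raise ValueError("empty window set has no half-width")
        return self.windows[0].half_width

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def subset(self, indices) -> "WindowSet":
        """New WindowSet holding the windows at *indices* (original order of indices)."""
        return WindowSet([self.windows[i] for i in indices])
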