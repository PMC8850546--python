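"""Synthetic annotated proteomes with planted phosphosite signal.

The generator emulates the structure — not the biology — of a
phosphoproteomics training corpus: proteins of uniform random length with
serines planted at a fixed per-residue rate, a fraction of which are labeled
phosphorylated. Positive sites carry two separable kinds of signal so that
encoder-level ablations are meaningful:

* positional enrichment — at configured flank offsets the residue is drawn
  as the enriched letter with the configured probability (so the empirical
  frequency at that offset converges to the configured value), defaults
  loosely shaped after real serine-kinase motifs (R at -3, P at +1, D at +2);
* pair enrichment — a k-spaced ordered residue pair is injected somewhere in
  the flanks with the configured probability, signal visible to the CKSAAP
  encoder but only weakly to the positional one.

Everything is deterministic per seed; a truth table records every planted
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alphabet import ALPHABET20
from .types import AnnotatedProtein

_NON_S = [a for a in ALPHABET20 if a != "S"]


@dataclass(frozen=True)
class PositionalEnrichment:
    offset: int  # flank offset relative to the center serine (never 0)
    residue: str
    prob: float  # probability of the residue at this offset in positives


@dataclass(frozen=True)
class PairEnrichment:
    gap: int  # number of intervening positions (CKSAAP's k)
    pair: str  # ordered residue pair, e.g. "KK"
    prob: float  # probability of injecting the pair into a positive window


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic proteome.

    Defaults: 300 proteins of 200-600 residues, serines planted at rate
    0.08 per residue, 10% of serines positive, uniform background over the
    20 standard amino acids, three positional enrichments at probability
    0.35 (background 0.05) and two pair boosts at probability 0.50.
    """

    n_proteins: int = 300
    length_range: tuple = (200, 600)
    serine_rate: float = 0.08
    positive_fraction: float = 0.10
    background: tuple = tuple([0.05] * 20)
    positional: tuple = (
        PositionalEnrichment(-3, "R", 0.35),
        PositionalEnrichment(+1, "P", 0.35),
        PositionalEnrichment(+2, "D", 0.35),
    )
    pairs: tuple = (
        PairEnrichment(1, "KK", 0.50),
        PairEnrichment(3, "ED", 0.50),
    )
    w: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length range {self.length_range}")
        for p in (self.serine_rate, self.positive_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if len(bg) != 20 or (bg < 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be 20 probabilities summing to 1")
        by_offset: dict = {}
        for enr in self.positional:
            if not 0 <= enr.prob <= 1:
                raise ValueError(f"enrichment probability {enr.prob} outside [0,1]")
            if enr.offset == 0 or abs(enr.offset) > self.w:
                raise ValueError(f"offset {enr.offset} outside the +-{self.w} flanks")
            if enr.residue not in _NON_S:
                raise ValueError(
                    f"enriched residue must be a standard non-S letter, "
                    f"got {enr.residue!r}"
                )
            by_offset.setdefault(enr.offset, 0.0)
            by_offset[enr.offset] += enr.prob
        for offset, total in by_offset.items():
            if total > 1:
                raise ValueError(
                    f"enrichment probabilities at offset {offset} sum to "
                    f"{total} > 1: infeasible"
                )
        for pe in self.pairs:
            if not 0 <= pe.prob <= 1:
                raise ValueError(f"pair probability {pe.prob} outside [0,1]")
            if pe.gap < 0 or pe.gap + 1 >= 2 * self.w:
                raise ValueError(f"pair gap {pe.gap} does not fit in the flanks")
            if len(pe.pair) != 2 or any(c not in _NON_S for c in pe.pair):
                raise ValueError(
                    f"pair must be two standard non-S letters, got {pe.pair!r}"
                )


def null_config(**overrides) -> GeneratorConfig:
    """A configuration with no planted signal (positives == negatives)."""
    overrides.setdefault("positional", ())
    overrides.setdefault("pairs", ())
    return GeneratorConfig(**overrides)


def _draw_background(rng, n, bg):
    return rng.choice(20, size=n, p=bg)


def generate_proteome(cfg: GeneratorConfig) -> tuple[list, pd.DataFrame]:
    """Generate annotated proteins plus the planted-signal truth table.

    Returns ``(proteins, truth)`` where *truth* has one row per serine site
    with columns ``protein_id, position, label, planted`` (a ';'-joined
    list of the enrichment events that fired for positives).
    """
    rng = np.random.default_rng(cfg.seed)
    bg = np.asarray(cfg.background, dtype=float)
    letters = np.array(list(ALPHABET20))
    non_s_idx = np.array([ALPHABET20.index(a) for a in _NON_S])
    proteins = []
    truth_rows = []
    for i in range(cfg.n_proteins):
        pid = f"SYN{i:04d}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        res = _draw_background(rng, length, bg)
        planted_s = rng.random(length) < cfg.serine_rate
        res[planted_s] = ALPHABET20.index("S")
        serines = np.nonzero(res == ALPHABET20.index("S"))[0]
        is_pos = rng.random(len(serines)) < cfg.positive_fraction
        pos_centers = set(serines[is_pos].tolist())
        planted: dict = {c: [] for c in pos_centers}
        for center in sorted(pos_centers):
            for pe in cfg.pairs:
                if rng.random() >= pe.prob:
                    continue
                offsets = [o for o in range(-cfg.w, cfg.w - pe.gap)
                           if o != 0 and o + pe.gap + 1 != 0]
                rng.shuffle(offsets)
                for o in offsets:
                    a, b = center + o, center + o + pe.gap + 1
                    if 0 <= a < length and 0 <= b < length and \
                            a not in pos_centers and b not in pos_centers:
                        res[a] = ALPHABET20.index(pe.pair[0])
                        res[b] = ALPHABET20.index(pe.pair[1])
                        planted[center].append(f"k{pe.gap}{pe.pair}@{o:+d}")
                        break
            # positional enrichment second: a site's own positional draw
            # takes priority over its pair injections at the same offset
            for enr in cfg.positional:
                j = center + enr.offset
                if not 0 <= j < length or j in pos_centers:
                    continue
                if rng.random() < enr.prob:
                    res[j] = ALPHABET20.index(enr.residue)
                    planted[center].append(f"pos{enr.offset:+d}{enr.residue}")
                else:
                    # redraw from the background excluding the enriched
                    # letter (and S, to keep serine labels unambiguous) so
                    # the enriched letter's frequency equals enr.prob exactly
                    excl = {ALPHABET20.index(enr.residue), ALPHABET20.index("S")}
                    allowed = np.array([r for r in non_s_idx if r not in excl])
                    p = bg[allowed] / bg[allowed].sum()
                    res[j] = rng.choice(allowed, p=p)
        seq = "".join(letters[res])
        # mutation may have removed background serines; recompute candidates
        final_serines = [k + 1 for k, c in enumerate(seq) if c == "S"]
        positives = frozenset(c + 1 for c in pos_centers)
        assert positives <= set(final_serines)
        proteins.append(AnnotatedProtein(pid, seq, positives))
        for p in final_serines:
            lab = 1 if p in positives else 0
            truth_rows.append((pid, p, lab,
                               ";".join(planted.get(p - 1, []))))
    truth = pd.DataFrame(truth_rows,
                         columns=["protein_id", "position", "label", "planted"])
    return proteins, truth


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return asdict(cfg)
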