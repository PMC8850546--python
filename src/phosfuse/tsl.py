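"""Two-sample-logo statistics: per-position residue enrichment tests.

For every flank offset j and every letter r of the 21-letter alphabet the
0/1 indicator "residue at offset j equals r" is compared between the
positive and negative window groups. Two tests are available:

* ``binomial`` (default): two-proportion pooled z-test on the counts versus
  group sizes — the better-calibrated choice;
* ``ttest``: two-sample t-test on the indicators — faster in spirit, kept
  for parity with common two-sample-logo tools.

A cell is *enriched* when the positive-group frequency exceeds the
negative-group frequency at p < alpha, *depleted* for the opposite sign,
and ``ns`` otherwise. No multiple-testing correction is applied: the
statistic is a per-cell descriptive display, not an inference procedure.
The gap symbol 'O' is a first-class category (it is informative about
terminal proximity); ``mask_gap=True`` drops it from the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, ttest_ind

from .alphabet import ALPHABET21
from .encoders import _codes_matrix
from .types import WindowSet


@dataclass
class TSLResult:
    """Per (offset, residue) enrichment table plus test metadata."""

    table: pd.DataFrame  # offset, residue, counts, freqs, diff, p, direction
    alpha: float
    method: str
    n_pos: int
    n_neg: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]

    def logo_matrix(self) -> pd.DataFrame:
        """Offsets x residues matrix of frequency differences where significant.

        Positive entries are enriched in the positive group, negative entries
        depleted; non-significant cells are 0. Consumable by logo-rendering
        tools.
        """
        sig = self.table.copy()
        sig.loc[sig["direction"] == "ns", "diff"] = 0.0
        return sig.pivot(index="offset", columns="residue", values="diff")

    def to_tsv(self, path, header: str = "") -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(header)
            self.table.to_csv(fh, sep="\t", index=False)


def _two_proportion_p(c1, n1, c0, n0):
    """Two-sided pooled two-proportion z-test, vectorized."""
    c1 = np.asarray(c1, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    p1, p0 = c1 / n1, c0 / n0
    pooled = (c1 + c0) / (n1 + n0)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p0) / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2 * norm.sf(np.abs(z)), 1.0)
    return p


def tsl_test(ws: WindowSet, alpha: float = 0.05, method: str = "binomial",
             mask_gap: bool = False) -> TSLResult:
    """Per-position, per-residue enrichment test between the two groups."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if method not in ("binomial", "ttest"):
        raise ValueError(f"method must be 'binomial' or 'ttest', got {method!r}")
    y = ws.labels
    if (y == 1).sum() == 0 or (y != 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    codes = _codes_matrix(ws.peptides)
    w = ws.half_width
    pos_codes = codes[y == 1]
    neg_codes = codes[y != 1]
    n_pos, n_neg = len(pos_codes), len(neg_codes)
    letters = ALPHABET21[:-1] if mask_gap else ALPHABET21
    rows = []
    for j in range(2 * w + 1):
        offset = j - w
        c1 = np.bincount(pos_codes[:, j], minlength=21)
        c0 = np.bincount(neg_codes[:, j], minlength=21)
        if method == "binomial":
            pvals = _two_proportion_p(c1, n_pos, c0, n_neg)
        else:
            pvals = np.ones(21)
            for r in range(21):
                if c1[r] + c0[r] in (0, n_pos + n_neg):
                    continue  # constant indicator in the pooled sample
                ind1 = (pos_codes[:, j] == r).astype(float)
                ind0 = (neg_codes[:, j] == r).astype(float)
                t = ttest_ind(ind1, ind0)
                pvals[r] = t.pvalue if np.isfinite(t.pvalue) else 1.0
        for r, letter in enumerate(ALPHABET21):
            if letter not in letters:
                continue
            if c1[r] + c0[r] == 0:
                pvals[r] = 1.0  # residue absent from both groups
            f1, f0 = c1[r] / n_pos, c0[r] / n_neg
            p = float(pvals[r])
            if p < alpha and f1 > f0:
                direction = "enriched"
            elif p < alpha and f1 < f0:
                direction = "depleted"
            else:
                direction = "ns"
            rows.append((offset, letter, int(c1[r]), int(c0[r]), f1, f0,
                         f1 - f0, p, direction))
    table = pd.DataFrame(rows, columns=["offset", "residue", "count_pos",
                                        "count_neg", "freq_pos", "freq_neg",
                                        "diff", "p_value", "direction"])
    return TSLResult(table, alpha, method, n_pos, n_neg)
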