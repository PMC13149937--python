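"""Shared in-memory containers for LD information.

LD is represented as a list of independent blocks (block-diagonal genome-wide
LD), each carrying the SNP ids it covers and the square correlation matrix.
Correlation between SNPs in different blocks is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LDBlock:
    """One LD block: SNP ids plus their square correlation matrix."""

    snp_ids: list[str]
    R: np.ndarray
    chrom: int | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.snp_ids)
        if self.R.shape != (n, n):
            raise ValueError("LD matrix shape does not match SNP count")

    @property
    def ld_scores(self) -> np.ndarray:
        """Per-SNP LD score: row sum of squared correlations in the block."""
        return (self.R**2).sum(axis=1)


class LDCollection:
    """Indexed set of LD blocks with SNP-level lookup.

    Provides the two queries the pipeline needs: the correlation submatrix
    for an arbitrary SNP list (block-diagonal, zero across blocks) and the
    pairwise r^2 used by clumping.
    """

    def __init__(self, blocks: list[LDBlock]):
        self.blocks = list(blocks)
        self._index: dict[str, tuple[int, int]] = {}
        for bi, block in enumerate(self.blocks):
            for si, snp in enumerate(block.snp_ids):
                if snp in self._index:
                    raise ValueError(f"duplicate SNP id {snp!r} across blocks")
                self._index[snp] = (bi, si)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def submatrix(self, snp_ids: list[str]) -> np.ndarray:
        """Correlation matrix for the given SNPs (zero across blocks)."""
        locs = [self._index[s] for s in snp_ids]  # KeyError on missing SNP
        n = len(snp_ids)
        out = np.zeros((n, n))
        for i, (bi, si) in enumerate(locs):
            for j, (bj, sj) in enumerate(locs):
                if bi == bj:
                    out[i, j] = self.blocks[bi].R[si, sj]
        np.fill_diagonal(out, 1.0)
        return out

    def r2(self, snp_a: str, snp_b: str) -> float:
        """Squared correlation between two SNPs; 0 when in different blocks."""
        bi, si = self._index[snp_a]
        bj, sj = self._index[snp_b]
        if bi != bj:
            return 0.0
        return float(self.blocks[bi].R[si, sj] ** 2)

    def ld_score_table(self) -> pd.DataFrame:
        """Per-SNP LD scores as a DataFrame with columns snp_id, l2."""
        rows = []
        for block in self.blocks:
            rows.extend(zip(block.snp_ids, block.ld_scores))
        return pd.DataFrame(rows, columns=["snp_id", "l2"])
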