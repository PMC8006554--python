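"""Founder-haplotype matrices for a MAGIC population.

Each line of an 8-founder MAGIC population carries chromosomes that are
mosaics of founder segments; at every SNP a line is labelled by its
founder of origin (1..8, or 0 for missing).  The matrix of labels over
lines x SNPs, together with a SNP map (chromosome, bp position), is the
genotype substrate for haplotype-based GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

__all__ = ["FOUNDERS", "HaplotypeMatrix", "read_snp_map", "write_snp_map"]

#: founder codes 1..8: four japonica then four indica rice cultivars
FOUNDERS = ("AK", "BE", "TC", "MI", "SU", "TK", "HO", "RU")
#: default indica founder group (codes 5..8), used for allele-class splits
INDICA = ("SU", "TK", "HO", "RU")


@dataclass
class HaplotypeMatrix:
    """Lines x SNPs grid of founder labels.

    Attributes
    ----------
    values
        ``(n_lines, n_snps)`` int8 array with entries in {0..8};
        0 encodes a missing label.
    line_ids
        Line identifiers, one per row.
    snp_map
        DataFrame with columns ``snp_id``, ``chrom``, ``pos`` sorted by
        (chrom, pos) with strictly increasing positions per chromosome,
        one row per matrix column.
    """

    values: np.ndarray
    line_ids: List[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (lines x SNPs)")
        if v.min() < 0 or v.max() > 8:
            raise ValueError("founder labels must be in {0..8} (0 = missing)")
        if len(self.line_ids) != v.shape[0]:
            raise ValueError("line_ids length must match the number of rows")
        m = self.snp_map
        if len(m) != v.shape[1]:
            raise ValueError("snp_map length must match the number of columns")
        for col in ("snp_id", "chrom", "pos"):
            if col not in m.columns:
                raise ValueError(f"snp_map lacks column {col!r}")
        by_chrom = m.groupby("chrom", sort=False)["pos"]
        if not by_chrom.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
            raise ValueError("positions must be strictly increasing within chromosomes")
        self.values = v

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = self.snp_map.index[self.snp_map["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return int(idx[0])

    def to_tsv(self, genotype_path: str | Path, map_path: str | Path) -> None:
        """Write genotypes (rows=lines, cols=SNP ids, cells=1..8 or NA)
        and the SNP map as TSV."""
        df = pd.DataFrame(
            self.values.astype(float),
            index=pd.Index(self.line_ids, name="line_id"),
            columns=self.snp_map["snp_id"],
        ).replace(0.0, np.nan)
        df.to_csv(genotype_path, sep="\t", float_format="%.0f", na_rep="NA")
        write_snp_map(self.snp_map, map_path)

    @classmethod
    def from_tsv(cls, genotype_path: str | Path, map_path: str | Path) -> "HaplotypeMatrix":
        df = pd.read_csv(genotype_path, sep="\t", index_col="line_id")
        snp_map = read_snp_map(map_path)
        df = df[snp_map["snp_id"]]  # enforce map order
        values = df.fillna(0).to_numpy().astype(np.int8)
        return cls(values=values, line_ids=[str(i) for i in df.index], snp_map=snp_map)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": int, "pos": int})
    return m.reset_index(drop=True)


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    snp_map[["snp_id", "chrom", "pos"]].to_csv(path, sep="\t", index=False)
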