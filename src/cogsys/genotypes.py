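"""Core genotype container shared by the simulation, QC and association layers.

Dosages are additively coded alternate-allele counts (0, 1, 2) held as float64
with ``numpy.nan`` marking missing calls, which keeps every downstream matrix
operation vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix plus per-SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` float array with entries in {0, 1, 2, nan}.
    snps
        Data frame with columns ``snp_id, chrom, pos, ref, alt``; ``pos`` is a
        1-based basepair coordinate, strictly increasing within a chromosome.
    individuals
        Individual identifiers, one per dosage row.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    individuals: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        if not isinstance(self.snps, pd.DataFrame):
            self.snps = pd.DataFrame(self.snps)
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"SNP metadata lacks columns: {missing_cols}")
        if len(self.snps) != self.dosages.shape[1]:
            raise ValueError(
                f"metadata rows ({len(self.snps)}) != SNP columns "
                f"({self.dosages.shape[1]})"
            )
        if self.individuals is None:
            self.individuals = np.array(
                [f"ind{i:05d}" for i in range(self.dosages.shape[0])]
            )
        self.individuals = np.asarray(self.individuals, dtype=object)
        if len(self.individuals) != self.dosages.shape[0]:
            raise ValueError("individual ids do not match dosage rows")
        self.snps = self.snps.reset_index(drop=True)
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must lie in {0, 1, 2} or be missing (nan)")

    # ------------------------------------------------------------------ views

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def alt_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls (nan if none)."""
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNPs
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP (nan where all calls are missing)."""
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def heterozygosity(self) -> np.ndarray:
        """Per-individual fraction of heterozygous calls among non-missing calls."""
        het = (self.dosages == 1.0).sum(axis=1)
        called = (~np.isnan(self.dosages)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, het / called, np.nan)

    # --------------------------------------------------------------- subsets

    def take_snps(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP positions (boolean or integer index)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snps.iloc[index].reset_index(drop=True),
            self.individuals.copy(),
        )

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.snps.copy(),
            self.individuals[index],
        )

    def select_snp_ids(self, snp_ids) -> "GenotypeMatrix":
        keep = set(snp_ids)
        mask = self.snps["snp_id"].isin(keep).to_numpy()
        return self.take_snps(mask)

    def chromosomes(self) -> list:
        seen = dict.fromkeys(self.snps["chrom"].tolist())
        return list(seen)

    def standardized(self, impute: bool = True) -> np.ndarray:
        """Centered/scaled dosage matrix ``(x - 2p) / sqrt(2p(1-p))``.

        Missing calls are mean-imputed (i.e. zero after centering) when
        ``impute`` is set. Monomorphic or all-missing SNPs yield zero columns.
        """
        p = self.alt_frequency()
        z = self.dosages - 2.0 * p
        if impute:
            z = np.where(np.isnan(z), 0.0, z)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.sqrt(2.0 * p * (1.0 - p))
            z = np.where(scale > 0, z / np.where(scale > 0, scale, 1.0), 0.0)
        return z
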