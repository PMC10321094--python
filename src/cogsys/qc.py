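"""Genotype quality control: per-variant and per-sample filters.

Filters are composable pure operations on :class:`~cogsys.genotypes.GenotypeMatrix`
plus an orchestrator (:func:`run_qc`) that applies them in a documented order
and returns an auditable :class:`QcReport`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- report

@dataclass
class QcReport:
    """Per-filter removal counts, in application order."""

    steps: list = field(default_factory=list)
    n_individuals_in: int = 0
    n_snps_in: int = 0
    n_individuals_out: int = 0
    n_snps_out: int = 0

    def record(self, step: str, removed_snps: int, removed_individuals: int,
               detail: str = "") -> None:
        self.steps.append(
            {
                "step": step,
                "removed_snps": int(removed_snps),
                "removed_individuals": int(removed_individuals),
                "detail": detail,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "removed_snps", "removed_individuals", "detail"]
        )

    def check_conservation(self) -> None:
        df = self.to_frame()
        if self.n_snps_in - df["removed_snps"].sum() != self.n_snps_out:
            raise AssertionError("QC report SNP counts do not reconcile")
        if self.n_individuals_in - df["removed_individuals"].sum() != self.n_individuals_out:
            raise AssertionError("QC report individual counts do not reconcile")


# -------------------------------------------------------------- variant-level

def maf_filter(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency strictly below ``threshold``.

    Frequencies are computed over non-missing calls; SNPs with no calls at all
    have undefined MAF and are removed with a warning.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("MAF threshold must lie in (0, 0.5)")
    maf = G.maf()
    undefined = np.isnan(maf)
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} all-missing SNPs removed (MAF undefined)")
    keep = ~undefined & (maf >= threshold)
    return G.take_snps(keep)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test on one SNP's genotype counts.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed table (the standard exact, non-mid-p convention). Degenerate
    tables (no copies of one allele) return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele copies
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # distribution over heterozygote counts h (parity of n_rare), by recurrence
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if (mid % 2) != (n_rare % 2):
        mid += 1
    probs = {mid: 1.0}
    h, hom_r, hom_c = mid, (n_rare - mid) // 2, n - mid - (n_rare - mid) // 2
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    h, hom_r, hom_c = mid, (n_rare - mid) // 2, n - mid - (n_rare - mid) // 2
    while h <= n_rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
        hom_r -= 1
        hom_c -= 1
    total = math.fsum(probs.values())
    p_obs = probs[n_het] / total
    p = math.fsum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12))
    return min(1.0, p)


def hwe_filter(G: GenotypeMatrix, p_threshold: float = 1e-6) -> GenotypeMatrix:
    """Drop SNPs failing the exact Hardy-Weinberg test at ``p < p_threshold``."""
    keep = np.ones(G.n_snps, dtype=bool)
    for j in range(G.n_snps):
        x = G.dosages[:, j]
        x = x[~np.isnan(x)]
        if x.size == 0:
            continue
        n_het = int((x == 1).sum())
        n_ref = int((x == 0).sum())
        n_alt = int((x == 2).sum())
        keep[j] = hwe_exact_test(n_ref, n_het, n_alt) >= p_threshold
    return G.take_snps(keep)


def missingness_filters(
    G: GenotypeMatrix, snp_max: float = 0.05, ind_max: float = 0.05
) -> GenotypeMatrix:
    """Remove individuals, then SNPs, whose missing-call fraction exceeds a cap."""
    for frac in (snp_max, ind_max):
        if not 0 <= frac <= 1:
            raise ValueError("missingness thresholds must lie in [0, 1]")
    keep_ind = G.individual_missing_rate() <= ind_max
    G = G.take_individuals(keep_ind)
    keep_snp = G.snp_missing_rate() <= snp_max
    logger.info(
        "missingness_filters: removed %d individuals then %d SNPs",
        int((~keep_ind).sum()), int((~keep_snp).sum()),
    )
    return G.take_snps(keep_snp)


# --------------------------------------------------------------- sample-level

def het_outlier_filter(G: GenotypeMatrix, k_sd: float = 3.0) -> GenotypeMatrix:
    """Remove individuals whose heterozygosity rate is > ``k_sd`` SD from the mean."""
    if G.n_individuals < 3:
        raise ValueError("heterozygosity filter needs at least 3 individuals")
    rate = G.heterozygosity()
    mu = np.nanmean(rate)
    sd = np.nanstd(rate, ddof=0)
    if sd == 0 or not np.isfinite(sd):
        return G
    keep = np.abs(rate - mu) <= k_sd * sd
    keep |= np.isnan(rate)
    return G.take_individuals(keep)


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list:
    """Greedy windowed LD pruning; returns the retained SNP ids.

    Within each ``window``-SNP window (slid by ``step``, per chromosome), for
    every retained pair with dosage r-squared above ``r2_max`` the member with
    the lower MAF is removed (ties: the later position). Missing dosages are
    mean-imputed for the correlation.
    """
    if window < 2:
        raise ValueError("window must cover at least 2 SNPs")
    maf = G.maf()
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    removed = np.zeros(G.n_snps, dtype=bool)
    chrom = G.snps["chrom"].to_numpy()
    for c in G.chromosomes():
        idx = np.flatnonzero(chrom == c)  # already position-sorted
        for w0 in range(0, len(idx), step):
            win = idx[w0:w0 + window]
            live = win[~removed[win]]
            if len(live) < 2:
                continue
            Z = X[:, live]
            Z = Z - Z.mean(axis=0)
            sd = Z.std(axis=0)
            sd[sd == 0] = 1.0
            R = (Z / sd).T @ (Z / sd) / Z.shape[0]
            r2 = R**2
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    ia, ib = live[a], live[b]
                    if removed[ia] or removed[ib]:
                        continue
                    if r2[a, b] > r2_max:
                        if maf[ia] < maf[ib]:
                            removed[ia] = True
                        elif maf[ib] < maf[ia]:
                            removed[ib] = True
                        else:  # tie -> drop the later position
                            removed[ib] = True
            if w0 + window >= len(idx):
                break
    return [sid for sid, gone in zip(G.snp_ids, removed) if not gone]


def relatedness_filter(
    G: GenotypeMatrix, threshold: float = 0.185
) -> GenotypeMatrix:
    """Remove one member of each pair with genomic relatedness above ``threshold``.

    Relatedness is the off-diagonal of the standardized genetic relationship
    matrix. The member with the higher missingness is dropped (ties: the later
    index), iterating until no pair exceeds the threshold.
    """
    from .association import compute_grm

    if G.n_individuals < 2:
        raise ValueError("relatedness filter needs at least 2 individuals")
    A = compute_grm(G).matrix
    miss = G.individual_missing_rate()
    retained = np.ones(G.n_individuals, dtype=bool)
    iu, ju = np.triu_indices(G.n_individuals, k=1)
    order = np.argsort(-A[iu, ju], kind="stable")  # most related first
    for k in order:
        i, j = iu[k], ju[k]
        if A[i, j] <= threshold:
            break
        if not (retained[i] and retained[j]):
            continue
        if miss[i] > miss[j]:
            retained[i] = False
        elif miss[j] > miss[i]:
            retained[j] = False
        else:
            retained[j] = False  # tie -> later index
    return G.take_individuals(retained)


def assign_ancestry(
    G_samples: GenotypeMatrix,
    reference_panels: list,
    n_pcs: int = 2,
    k_sd: float = 5.0,
) -> pd.DataFrame:
    """Centroid-based ancestry assignment against labeled reference panels.

    Principal components are computed on the combined standardized dosage
    matrix of samples plus references (shared SNPs only). A sample belongs to a
    reference cluster when it lies within ``k_sd`` of the cluster centroid on
    every retained PC, in units of that cluster's per-PC SD. Samples matching
    several clusters are flagged ambiguous; those matching none are unassigned.

    ``reference_panels`` is a list of ``(label, GenotypeMatrix)`` pairs.
    Returns a frame with ``individual_id, ancestry, ambiguous`` where
    ``ancestry`` joins all matching labels with ``|``.
    """
    shared = set(G_samples.snps["snp_id"])
    for _, panel in reference_panels:
        shared &= set(panel.snps["snp_id"])
    shared = sorted(shared)
    if len(shared) < n_pcs:
        raise ValueError(
            f"only {len(shared)} shared SNPs for {n_pcs} PCs; cannot assign ancestry"
        )
    sample_block = G_samples.select_snp_ids(shared)
    panel_blocks = [(lab, p.select_snp_ids(shared)) for lab, p in reference_panels]
    X = np.vstack([sample_block.dosages] + [p.dosages for _, p in panel_blocks])
    meta = sample_block.snps
    combined = GenotypeMatrix(
        X, meta,
        np.concatenate([sample_block.individuals]
                       + [p.individuals for _, p in panel_blocks]),
    )
    Z = combined.standardized()
    Zc = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Zc, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    n_samp = G_samples.n_individuals
    offsets = [n_samp]
    for _, p in panel_blocks:
        offsets.append(offsets[-1] + p.n_individuals)
    labels = []
    for idx in range(n_samp):
        matches = []
        for k, (lab, _) in enumerate(panel_blocks):
            ref_scores = scores[offsets[k]:offsets[k + 1]]
            centroid = ref_scores.mean(axis=0)
            sd = ref_scores.std(axis=0, ddof=0)
            dev = np.abs(scores[idx] - centroid)
            # degenerate (zero-SD) PCs require an exact centroid hit
            ok = np.where(sd > 0, dev <= k_sd * sd, dev == 0)
            if ok.all():
                matches.append(lab)
        labels.append(matches)
    return pd.DataFrame(
        {
            "individual_id": G_samples.individuals,
            "ancestry": ["|".join(m) if m else "unassigned" for m in labels],
            "ambiguous": [len(m) > 1 for m in labels],
        }
    )


# ----------------------------------------------------------------- pipeline

@dataclass
class QcConfig:
    """Thresholds for the QC orchestrator, applied in field order."""

    het_k_sd: float = 3.0
    ind_missing_max: float = 0.05
    snp_missing_max: float = 0.05
    relatedness_max: float = 0.185
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    ld_prune_enabled: bool = False
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2


def run_qc(G: GenotypeMatrix, config: QcConfig | None = None):
    """Apply the sample- then variant-level filters and report removals.

    Order: heterozygosity outliers -> missingness (individuals, SNPs) ->
    relatedness -> MAF -> Hardy-Weinberg -> optional LD pruning. Each step's
    removal counts are recorded with the thresholds applied.
    """
    config = config or QcConfig()
    report = QcReport(n_individuals_in=G.n_individuals, n_snps_in=G.n_snps)

    def _log(step, before, after, detail):
        report.record(
            step,
            removed_snps=before.n_snps - after.n_snps,
            removed_individuals=before.n_individuals - after.n_individuals,
            detail=detail,
        )
        logger.info("qc %s: %s", step, detail)

    cur = het_outlier_filter(G, k_sd=config.het_k_sd)
    _log("het_outlier", G, cur, f"|het - mean| > {config.het_k_sd} SD")
    prev = cur
    cur = missingness_filters(
        prev, snp_max=config.snp_missing_max, ind_max=config.ind_missing_max
    )
    _log("missingness", prev, cur,
         f"ind > {config.ind_missing_max}, snp > {config.snp_missing_max}")
    prev = cur
    cur = relatedness_filter(prev, threshold=config.relatedness_max)
    _log("relatedness", prev, cur, f"GRM off-diagonal > {config.relatedness_max}")
    prev = cur
    cur = maf_filter(prev, threshold=config.maf_min)
    _log("maf", prev, cur, f"MAF < {config.maf_min}")
    prev = cur
    cur = hwe_filter(prev, p_threshold=config.hwe_p_min)
    _log("hwe", prev, cur, f"exact HWE p < {config.hwe_p_min}")
    if config.ld_prune_enabled:
        prev = cur
        kept = ld_prune(prev, config.ld_window, config.ld_step, config.ld_r2_max)
        cur = prev.select_snp_ids(kept)
        _log("ld_prune", prev, cur,
             f"window {config.ld_window}, step {config.ld_step}, r2 > {config.ld_r2_max}")
    if cur.n_snps == 0 or cur.n_individuals == 0:
        raise ValueError("QC removed all SNPs or all individuals")
    report.n_individuals_out = cur.n_individuals
    report.n_snps_out = cur.n_snps
    report.check_conservation()
    return cur, report
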