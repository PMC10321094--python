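"""Mixed-linear-model SNP association with leave-one-chromosome-out control.

The model for a candidate SNP is ``y = a + b x + g + e`` where ``y`` is the
binarized performance label (0 = poor, 1 = good) treated as a quantitative
trait, ``x`` the 0/1/2 dosage, ``g ~ N(0, sigma2_g K)`` a polygenic random
effect with ``K`` a genetic relationship matrix, and ``e ~ N(0, sigma2_e I)``.
Under the LOCO scheme ``K`` excludes the candidate SNP's chromosome, so the
polygenic term never absorbs the signal being tested.

Variance components are estimated once per LOCO partition by restricted
maximum likelihood (spectral decomposition of ``K`` plus a bracketed scalar
search over the variance ratio). Each SNP is then tested by generalized least
squares with the fitted covariance *structure* held fixed; the residual scale
is re-profiled per SNP on the whitened regression, which makes the test reduce
exactly to ordinary least squares when ``sigma2_g = 0``. Two-sided p-values
use the standard normal reference on the Wald ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "allele_alt", "freq", "beta", "se", "z", "p",
    "n", "status",
]


# ------------------------------------------------------------------------ GRM

@dataclass
class GRM:
    """Standardized genetic relationship matrix.

    ``A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
    over the ``m`` included non-monomorphic SNPs, with missing dosages
    mean-imputed per SNP before standardization.
    """

    matrix: np.ndarray
    n_snps_used: int
    excluded_chrom: object = None


def compute_grm(G: GenotypeMatrix, exclude_chrom=None) -> GRM:
    """GRM from standardized dosages, optionally leaving out one chromosome."""
    mask = np.ones(G.n_snps, dtype=bool)
    if exclude_chrom is not None:
        mask &= (G.snps["chrom"] != exclude_chrom).to_numpy()
    maf = G.maf()
    mask &= ~np.isnan(maf) & (maf > 0)
    m = int(mask.sum())
    if m < 1:
        raise ValueError("no usable (polymorphic) SNPs for the GRM")
    Z = G.standardized()[:, mask]
    return GRM(matrix=(Z @ Z.T) / m, n_snps_used=m, excluded_chrom=exclude_chrom)


def _loco_pieces(G: GenotypeMatrix):
    """Total standardized cross-product and per-chromosome pieces for LOCO."""
    maf = G.maf()
    usable = ~np.isnan(maf) & (maf > 0)
    Z = G.standardized()
    chrom = G.snps["chrom"].to_numpy()
    total = np.zeros((G.n_individuals, G.n_individuals))
    pieces = {}
    counts = {}
    for c in G.chromosomes():
        sel = usable & (chrom == c)
        Zc = Z[:, sel]
        S = Zc @ Zc.T
        pieces[c] = S
        counts[c] = int(sel.sum())
        total += S
    return total, pieces, counts


# ----------------------------------------------------------------------- REML

@dataclass
class VarianceComponents:
    """REML estimates of the polygenic and residual variances."""

    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray  # fixed effects (intercept first)
    loglik: float
    variance_ratio: float  # sigma2_g / sigma2_e
    converged: bool = True


class ConvergenceError(RuntimeError):
    """REML failed to converge; ``best`` carries the best iterate."""

    def __init__(self, message: str, best: VarianceComponents):
        super().__init__(message)
        self.best = best


def _reml_profile(log_ratio, s, y_rot, X_rot):
    """Negative restricted log-likelihood profiled over the variance ratio."""
    lam = np.exp(log_ratio)
    d = lam * s + 1.0
    w = 1.0 / d
    Xw = X_rot * w[:, None]
    XtWX = X_rot.T @ Xw
    XtWy = Xw.T @ y_rot
    beta = np.linalg.solve(XtWX, XtWy)
    r = y_rot - X_rot @ beta
    n, p = X_rot.shape
    rss = float(np.sum(w * r * r))
    sigma2_e = rss / (n - p)
    sign, logdet = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(sigma2_e) + np.sum(np.log(d)) + logdet + (n - p))
    return -ll, beta, sigma2_e


def fit_null(
    y: np.ndarray,
    K: GRM | np.ndarray,
    covariates: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """REML fit of the polygenic null model ``y = X beta + g + e``.

    ``covariates`` (if any) are augmented with an intercept column. The
    variance ratio ``sigma2_g / sigma2_e`` is profiled on the log scale over
    the eigenbasis of ``K``; a pure-noise model (ratio -> 0) is always
    evaluated as a candidate so the fit never does worse than OLS.
    """
    A = K.matrix if isinstance(K, GRM) else np.asarray(K)
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.unique(y).size < 2:
        raise ValueError("phenotype is constant; variance components unidentifiable")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    s, U = np.linalg.eigh(A)
    s = np.clip(s, 0.0, None)  # PSD guard against round-off
    y_rot = U.T @ y
    X_rot = U.T @ X

    res = optimize.minimize_scalar(
        lambda lr: _reml_profile(lr, s, y_rot, X_rot)[0],
        bounds=(-15.0, 15.0),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    # boundary candidate: no polygenic variance
    nll0, _, _ = _reml_profile(-40.0, s, y_rot, X_rot)
    candidates = [(res.fun, float(res.x)), (nll0, -40.0)]
    nll, log_ratio = min(candidates, key=lambda t: t[0])
    _, beta, sigma2_e = _reml_profile(log_ratio, s, y_rot, X_rot)
    ratio = float(np.exp(log_ratio))
    if ratio < 1e-12:
        ratio = 0.0
    vc = VarianceComponents(
        sigma2_g=ratio * sigma2_e,
        sigma2_e=sigma2_e,
        beta=beta,
        loglik=-nll,
        variance_ratio=ratio,
        converged=bool(res.success),
    )
    if not res.success:
        raise ConvergenceError(f"REML did not converge: {res.message}", best=vc)
    return vc


# ------------------------------------------------------------------ the model

class MixedLinearAssociation:
    """Per-SNP mixed-model association scan over a genotype matrix.

    Parameters
    ----------
    y
        0/1 phenotype labels, one per individual in ``G``.
    G
        Genotypes after quality control.
    covariates
        Optional fixed-effect columns beyond the intercept (the phenotype
        pipeline residualizes age/sex upstream, so the default is none).
    loco
        Use a leave-one-chromosome-out GRM per tested chromosome. With a
        single chromosome the scan falls back to no exclusion, with a warning.
    variance_ratio
        Pin ``sigma2_g / sigma2_e`` instead of estimating it by REML
        (``0`` reduces every test to ordinary least squares).
    """

    def __init__(
        self,
        y,
        G: GenotypeMatrix,
        covariates=None,
        loco: bool = True,
        variance_ratio: float | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        if self.y.size != G.n_individuals:
            raise ValueError("phenotype length does not match genotype rows")
        self.G = G
        self.covariates = covariates
        self.loco = loco
        self.variance_ratio = variance_ratio

    @classmethod
    def from_phenotype(
        cls, pheno: pd.DataFrame, G: GenotypeMatrix, **kwargs
    ) -> "MixedLinearAssociation":
        """Build from a prepared phenotype table, keeping labeled individuals.

        ``good`` maps to 1 and ``poor`` to 0; unassigned rows are dropped.
        """
        labeled = pheno[pheno["label"].isin(["poor", "good"])]
        ids = dict(zip(labeled["individual_id"], labeled["label"]))
        keep = np.array([i in ids for i in G.individuals])
        Gsub = G.take_individuals(keep)
        y = np.array([1.0 if ids[i] == "good" else 0.0 for i in Gsub.individuals])
        return cls(y, Gsub, **kwargs)

    def _design(self) -> np.ndarray:
        X = np.ones((self.y.size, 1))
        if self.covariates is not None:
            C = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if C.shape[0] != self.y.size:
                C = C.T
            X = np.column_stack([X, C])
        return X

    def fit(self) -> "AssociationResults":
        G = self.G
        chroms = G.chromosomes()
        use_loco = self.loco and len(chroms) > 1
        if self.loco and not use_loco:
            warnings.warn("single chromosome: LOCO impossible, using whole-genome GRM")
        total, pieces, counts = _loco_pieces(G)
        m_total = sum(counts.values())
        X = self._design()
        chrom_arr = G.snps["chrom"].to_numpy()
        freqs = G.alt_frequency()
        n = G.n_individuals

        vcs = {}
        if use_loco:
            rows = np.full((G.n_snps, 4), np.nan)  # beta, se, z, p
            status = np.array(["ok"] * G.n_snps, dtype=object)
            for c in chroms:
                m_loco = m_total - counts[c]
                if m_loco < 2:
                    raise ValueError(f"fewer than 2 SNPs off chromosome {c}")
                K = (total - pieces[c]) / m_loco
                vc = self._fit_partition(K, X)
                vcs[c] = vc
                sel = np.flatnonzero(chrom_arr == c)
                r, st = self._test_snps(vc, K, X, sel)
                rows[sel] = r
                status[sel] = st
        else:
            K = total / m_total
            vc = self._fit_partition(K, X)
            vcs["all"] = vc
            rows, status = self._test_snps(vc, K, X, np.arange(G.n_snps))

        table = pd.DataFrame(
            {
                "snp_id": G.snp_ids,
                "chrom": chrom_arr,
                "pos": G.snps["pos"].to_numpy(),
                "allele_alt": G.snps["alt"].to_numpy(),
                "freq": freqs,
                "beta": rows[:, 0],
                "se": rows[:, 1],
                "z": rows[:, 2],
                "p": rows[:, 3],
                "n": n,
                "status": status,
            }
        )
        return AssociationResults(table=table, variance_components=vcs, model=self)

    def _fit_partition(self, K: np.ndarray, X: np.ndarray) -> VarianceComponents:
        """Variance components for one LOCO partition (REML or pinned ratio)."""
        if self.variance_ratio is None:
            return fit_null(self.y, K, covariates=self.covariates)
        ratio = float(self.variance_ratio)
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        nll, beta, sig_e = _reml_profile(
            np.log(ratio) if ratio > 0 else -40.0, s, U.T @ self.y, U.T @ X
        )
        return VarianceComponents(
            sigma2_g=ratio * sig_e, sigma2_e=sig_e, beta=beta,
            loglik=-nll, variance_ratio=ratio,
        )

    def _test_snps(self, vc: VarianceComponents, K: np.ndarray, X: np.ndarray, sel):
        """GLS Wald tests for the SNP columns ``sel`` under covariance ``K``.

        The whitened regression re-profiles the residual scale per SNP, so the
        statistic is exactly the OLS t-ratio when the variance ratio is zero.
        """
        G = self.G
        n = G.n_individuals
        p_cov = X.shape[1]
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        w = 1.0 / np.sqrt(vc.variance_ratio * s + 1.0)
        y_t = w * (U.T @ self.y)
        X_t = w[:, None] * (U.T @ X)
        Q, _ = np.linalg.qr(X_t)
        y_perp = y_t - Q @ (Q.T @ y_t)
        Xc = G.dosages[:, sel].copy()
        col_mean = np.nanmean(Xc, axis=0)
        nan_mask = np.isnan(Xc)
        if nan_mask.any():
            Xc[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
        mono = np.nanstd(Xc, axis=0) == 0
        G_t = w[:, None] * (U.T @ Xc)
        G_perp = G_t - Q @ (Q.T @ G_t)
        denom = np.sum(G_perp * G_perp, axis=0)
        safe = (denom > 0) & ~mono
        beta_j = np.zeros(len(sel))
        beta_j[safe] = (G_perp[:, safe].T @ y_perp) / denom[safe]
        rss = float(y_perp @ y_perp) - beta_j**2 * denom
        sigma2_j = np.where(safe, rss / (n - p_cov - 1), np.nan)
        se_j = np.sqrt(np.where(safe, sigma2_j / np.where(safe, denom, 1.0), np.nan))
        z = np.where(safe & (se_j > 0), beta_j / se_j, np.nan)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        rows = np.column_stack([np.where(safe, beta_j, np.nan), se_j, z, pval])
        status = np.where(safe, "ok", "monomorphic").astype(object)
        return rows, status


@dataclass
class AssociationResults:
    """Per-SNP estimates plus the per-partition variance components."""

    table: pd.DataFrame
    variance_components: dict
    model: MixedLinearAssociation | None = field(default=None, repr=False)

    def genomic_inflation(self) -> float:
        """Genomic-control lambda: median chi-square over its null median."""
        p = self.table["p"].dropna()
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))

    def top_hits(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "p")

    def summary(self) -> str:
        lines = [
            "Mixed linear model association (LOCO)",
            "=" * 46,
            f"individuals: {int(self.table['n'].iloc[0])}"
            f"    SNPs tested: {int((self.table['status'] == 'ok').sum())}"
            f" of {len(self.table)}",
            f"genomic inflation lambda: {self.genomic_inflation():.4f}",
            "",
            "variance components per LOCO partition (excluded chrom):",
        ]
        for key, vc in self.variance_components.items():
            lines.append(
                f"  {key!s:>6}: sigma2_g={vc.sigma2_g:.5f} "
                f"sigma2_e={vc.sigma2_e:.5f} ratio={vc.variance_ratio:.4f} "
                f"logL={vc.loglik:.2f}"
            )
        lines.append("")
        lines.append("top associations:")
        top = self.top_hits(5)[["snp_id", "chrom", "pos", "freq", "beta", "se", "p"]]
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def mlma_loco(y, G: GenotypeMatrix, covariates=None, **kwargs) -> AssociationResults:
    """Convenience wrapper: fit the LOCO mixed-model scan in one call."""
    return MixedLinearAssociation(y, G, covariates=covariates, **kwargs).fit()


# -------------------------------------------------- fast engine (score test)

def linear_score_assoc(y, G: GenotypeMatrix) -> pd.DataFrame:
    """Plain per-SNP linear association (no polygenic term).

    Vectorised correlation-based OLS: ``t = r sqrt((n-2)/(1-r^2))`` with a
    normal reference. Used as the fast engine for permutation nulls, where the
    observed run must use the identical statistic.
    """
    P = linear_score_pvalues(np.asarray(y, float)[:, None], G)
    table = pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.snps["chrom"].to_numpy(),
            "pos": G.snps["pos"].to_numpy(),
            "p": P[:, 0],
        }
    )
    return table


def linear_score_pvalues(Y: np.ndarray, G: GenotypeMatrix) -> np.ndarray:
    """p-value matrix (SNPs x phenotype columns) for many label vectors at once."""
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    Yc = Y - Y.mean(axis=0)
    sy = Yc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Yc) / n / np.outer(sx, sy)
        R = np.clip(R, -1.0, 1.0)
        T = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
    P = 2.0 * stats.norm.sf(np.abs(T))
    P[sx == 0, :] = np.nan
    return P
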