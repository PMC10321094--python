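"""Synthetic cohort generator.

Generates genotype, phenotype, annotation and pathway fixtures carrying the
statistical structure the analysis assumes — diploid dosages with a chosen
minor-allele-frequency spectrum and block LD, a continuous cognitive-style
score with additive age/sex/causal/polygenic/noise components, and annotation
fixtures in which designated causal genes populate one designated pathway —
together with the ground truth needed for recovery tests.

Genotypes are built from two independent haplotypes per individual. Within an
LD block each haplotype copies the previous SNP's allele with probability
``ld_rho`` and otherwise redraws from the SNP's allele frequency, so adjacent
alleles correlate at about ``ld_rho`` at equal frequencies. The polygenic term
is an explicit sum of many small random effects over the non-causal SNPs —
deliberately *not* drawn from ``N(0, sigma2_g K)`` so the generative model
stays independent of the GRM estimator under test.

Coordinates: SNP positions are 1-based; interval fixtures are 0-based
half-open (the BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .gsea import PathwayDB
from .snp2gene import AnnotationBundle, derive_regions

SNP_SPACING = 2_000  # bp between adjacent simulated SNPs
CHROM_OFFSET = 10_000  # bp of leading telomere-like buffer


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions at desk scale: a peri-adolescent
    cohort of ~3,100 individuals aged 8-21, cognitive-score heritability around
    0.3, and a planted 30-gene causal pathway explaining 8% of score variance.
    """

    n_individuals: int = 3116
    n_snps: int = 5000
    n_chromosomes: int = 10
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.8
    missing_rate: float = 0.01
    age_range: tuple = (8.0, 21.0)
    sex_balance: float = 0.5
    beta_age: float = 0.1
    beta_sex: float = 0.2
    h2_poly: float = 0.3
    causal_gene_count: int = 30
    causal_effect_total: float = 0.08
    noise_var: float | None = None  # default: 1 - h2_poly - causal_effect_total
    n_genes: int = 800
    n_pathways: int = 40
    pathway_size_range: tuple = (20, 60)
    eqtl_fraction: float = 0.05
    hic_fraction: float = 0.02
    invalid_code_fraction: float = 0.01
    medical_exclusion_fraction: float = 0.02
    intercept: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.n_individuals < 2:
            raise ConfigError("need at least 2 individuals")
        if self.h2_poly + self.causal_effect_total >= 1:
            raise ConfigError("h2_poly + causal_effect_total must be < 1")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho must lie in [0, 1)")
        if not (1 <= self.pathway_size_range[0] <= self.pathway_size_range[1]):
            raise ConfigError("invalid pathway_size_range")
        if self.causal_gene_count > self.pathway_size_range[1]:
            raise ConfigError("causal_gene_count exceeds the maximum pathway size")
        if self.n_genes < self.pathway_size_range[1]:
            raise ConfigError("n_genes must cover the largest pathway")

    def rng(self, stream: int) -> np.random.Generator:
        """Named child stream so each step is independently reproducible."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    snps: pd.DataFrame
    genes: pd.DataFrame
    causal_snp_ids: list
    causal_gene_ids: list
    effect_sizes: dict = field(default_factory=dict)  # snp_id -> realized beta
    causal_pathway_id: str | None = None
    realized_variance: dict = field(default_factory=dict)


# ------------------------------------------------------------- genome layout

def _split_counts(total: int, bins: int) -> list:
    base, extra = divmod(total, bins)
    return [base + (1 if i < extra else 0) for i in range(bins)]


def plan_genome(config: SimConfig):
    """Deterministic toy-genome layout: SNP grid and non-overlapping genes.

    SNPs are assigned to chromosomes in contiguous blocks on a fixed
    ``SNP_SPACING`` grid. Genes tile each chromosome in equal slots, bodies
    separated by inter-genic margins, with alternating strand and a sprinkling
    of non-coding biotypes.
    """
    snp_counts = _split_counts(config.n_snps, config.n_chromosomes)
    gene_counts = _split_counts(config.n_genes, config.n_chromosomes)
    snp_rows = []
    gene_rows = []
    snp_idx = 0
    gene_idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_s = snp_counts[c]
        for j in range(n_s):
            snp_rows.append(
                (f"snp{snp_idx:06d}", chrom, CHROM_OFFSET + (j + 1) * SNP_SPACING,
                 "A", "G")
            )
            snp_idx += 1
        span = CHROM_OFFSET + (n_s + 2) * SNP_SPACING + 40_000
        n_g = gene_counts[c]
        if n_g == 0:
            continue
        slot = span // n_g
        margin = max(slot // 8, 200)
        for k in range(n_g):
            start = k * slot + margin + 1
            end = (k + 1) * slot - margin
            biotype = "lncRNA" if gene_idx % 17 == 0 else "protein_coding"
            strand = "+" if gene_idx % 2 == 0 else "-"
            gid = f"G{gene_idx:04d}"
            gene_rows.append((gid, gid, biotype, chrom, strand, start, end))
            gene_idx += 1
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "symbol", "biotype", "chrom", "strand", "start", "end"],
    )
    return snps, genes


# ----------------------------------------------------------------- genotypes

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Diploid dosages with block LD via haplotype copying."""
    rng = config.rng(1)
    snps, _ = plan_genome(config)
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    n = config.n_individuals
    haps = np.empty((2, n, config.n_snps), dtype=np.int8)
    chrom = snps["chrom"].to_numpy()
    for h in range(2):
        prev = None
        for j in range(config.n_snps):
            new_block = (
                j == 0
                or chrom[j] != chrom[j - 1]
                or (j % config.ld_block_size) == 0
            )
            draw = (rng.random(n) < p[j]).astype(np.int8)
            if new_block or config.ld_rho == 0:
                allele = draw
            else:
                copy = rng.random(n) < config.ld_rho
                allele = np.where(copy, prev, draw).astype(np.int8)
            haps[h, :, j] = allele
            prev = allele
    dosages = haps.sum(axis=0).astype(np.float64)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    return GenotypeMatrix(dosages, snps)


# --------------------------------------------------------------------- truth

def make_truth(config: SimConfig, G: GenotypeMatrix) -> SimTruth:
    """Pick causal genes (each containing at least one SNP) and causal SNPs."""
    rng = config.rng(2)
    snps, genes = plan_genome(config)
    coding = genes[genes["biotype"] == "protein_coding"]
    pos_by_chrom = {c: grp for c, grp in snps.groupby("chrom", sort=False)}
    candidates = []
    inner_snp = {}
    for _, g in coding.iterrows():
        grp = pos_by_chrom.get(g["chrom"])
        if grp is None:
            continue
        inside = grp[(grp["pos"] >= g["start"]) & (grp["pos"] <= g["end"])]
        if len(inside):
            mid = (g["start"] + g["end"]) / 2
            best = inside.iloc[(inside["pos"] - mid).abs().argmin()]
            candidates.append(g["gene_id"])
            inner_snp[g["gene_id"]] = best["snp_id"]
    if len(candidates) < config.causal_gene_count:
        raise ConfigError(
            f"only {len(candidates)} protein-coding genes contain a SNP; "
            f"cannot place {config.causal_gene_count} causal genes"
        )
    chosen = sorted(rng.choice(candidates, config.causal_gene_count, replace=False))
    causal_snps = [inner_snp[g] for g in chosen]
    return SimTruth(
        snps=snps, genes=genes, causal_snp_ids=causal_snps, causal_gene_ids=chosen
    )


# ----------------------------------------------------------------- phenotype

def _scaled(component: np.ndarray, target_var: float) -> np.ndarray:
    sd = component.std(ddof=0)
    if target_var == 0:
        return np.zeros_like(component)
    if sd == 0:
        raise ConfigError("cannot scale a constant component to positive variance")
    return component * (np.sqrt(target_var) / sd)


def simulate_phenotype(
    G: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Additive phenotype with exact realized variance fractions.

    ``score = intercept + beta_age*age + beta_sex*sex + causal + polygenic +
    noise`` where the causal, polygenic and noise components are rescaled so
    their realized variances equal ``causal_effect_total``, ``h2_poly`` and
    the remainder of a unit non-covariate variance. Components are stored in
    ``.attrs['components']`` and their variances in ``truth.realized_variance``.
    """
    rng = config.rng(3)
    noise_var = (
        config.noise_var
        if config.noise_var is not None
        else 1.0 - config.h2_poly - config.causal_effect_total
    )
    if noise_var < 0:
        raise ConfigError("variance fractions exceed 1")
    n = G.n_individuals
    age = rng.uniform(*config.age_range, size=n)
    sex = (rng.random(n) < config.sex_balance).astype(float)

    snp_index = {s: j for j, s in enumerate(G.snp_ids)}
    missing = [s for s in truth.causal_snp_ids if s not in snp_index]
    if missing:
        raise ValueError(f"causal SNPs absent from genotypes: {missing[:5]}")
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    causal_cols = [snp_index[s] for s in truth.causal_snp_ids]
    if causal_cols and config.causal_effect_total > 0:
        raw_beta = rng.normal(size=len(causal_cols))
        raw = X[:, causal_cols] @ raw_beta
        causal = _scaled(raw, config.causal_effect_total)
        # realized per-SNP effects after the common rescaling
        factor = np.sqrt(config.causal_effect_total) / raw.std(ddof=0)
        truth.effect_sizes = {
            s: float(b * factor) for s, b in zip(truth.causal_snp_ids, raw_beta)
        }
    else:
        causal = np.zeros(n)
        truth.effect_sizes = {s: 0.0 for s in truth.causal_snp_ids}

    bg_cols = [j for j in range(G.n_snps) if j not in set(causal_cols)]
    if bg_cols and config.h2_poly > 0:
        bg_beta = rng.normal(size=len(bg_cols)) / np.sqrt(len(bg_cols))
        poly = _scaled(X[:, bg_cols] @ bg_beta, config.h2_poly)
    else:
        poly = np.zeros(n)

    noise = rng.normal(size=n)
    noise = _scaled(noise, noise_var) if noise_var > 0 else np.zeros(n)

    cov_age = config.beta_age * age
    cov_sex = config.beta_sex * sex
    score = config.intercept + cov_age + cov_sex + causal + poly + noise

    valid = np.where(rng.random(n) < config.invalid_code_fraction, "N",
                     np.where(rng.random(n) < 0.5, "V", "V2"))
    medical = rng.integers(0, 4, size=n)
    medical = np.where(
        rng.random(n) < config.medical_exclusion_fraction, 4, medical
    )

    pheno = pd.DataFrame(
        {
            "individual_id": G.individuals,
            "raw_score": score,
            "age": age,
            "sex": sex.astype(int),
            "valid_code": valid,
            "medical_rating": medical,
        }
    )
    components = {
        "covariate_age": cov_age,
        "covariate_sex": cov_sex,
        "causal": causal,
        "polygenic": poly,
        "noise": noise,
    }
    pheno.attrs["components"] = components
    pheno.attrs["intercept"] = config.intercept
    truth.realized_variance = {
        k: float(v.var(ddof=0)) for k, v in components.items()
    }
    truth.realized_variance["total"] = float(score.var(ddof=0))
    return pheno


# --------------------------------------------------------------- annotations

def simulate_annotations(config: SimConfig, truth: SimTruth):
    """Annotation bundle plus pathways consistent with the planted truth.

    A fraction of non-causal SNPs receive brain eQTL links (with open
    chromatin over the SNP); another fraction sit inside promoter anchors of
    enhancer-promoter Hi-C contacts. Causal SNPs lie inside causal gene bodies
    and map positionally. One pathway holds exactly the causal genes plus
    filler; the rest are random draws from the non-causal coding genes.
    """
    rng = config.rng(4)
    snps, genes = truth.snps, truth.genes
    coding = genes[genes["biotype"] == "protein_coding"].copy()
    plus = coding["strand"] == "+"
    coding["tss"] = np.where(plus, coding["start"], coding["end"])

    causal_set = set(truth.causal_snp_ids)
    free = snps[~snps["snp_id"].isin(causal_set)].reset_index(drop=True)
    n_eqtl = int(round(config.eqtl_fraction * config.n_snps))
    n_hic = int(round(config.hic_fraction * config.n_snps))
    picks = rng.choice(len(free), size=min(n_eqtl + n_hic, len(free)),
                       replace=False)
    eqtl_snps = free.iloc[sorted(picks[:n_eqtl])]
    hic_snps = free.iloc[sorted(picks[n_eqtl:])]

    state_rows = []

    def _nearest_gene(chrom: str, pos: int):
        g = coding[coding["chrom"] == chrom]
        if g.empty:
            return None
        return g.iloc[(g["tss"] - pos).abs().argmin()]

    eqtl_rows = []
    for _, s in eqtl_snps.iterrows():
        g = _nearest_gene(s["chrom"], s["pos"])
        if g is None:
            continue
        eqtl_rows.append((s["snp_id"], g["gene_id"], "brain"))
        state_rows.append((s["chrom"], s["pos"] - 251, s["pos"] + 250, 2, "TssAFlnk"))

    hic_rows = []
    for _, s in hic_snps.iterrows():
        g = _nearest_gene(s["chrom"], s["pos"])
        if g is None:
            continue
        tss = int(g["tss"])
        if g["strand"] == "+":
            w_lo, w_hi = tss - 250, tss + 500
        else:
            w_lo, w_hi = tss - 500, tss + 250
        prom_start = max(min(w_lo - 1, s["pos"] - 1) - 50, 0)
        prom_end = max(w_hi, s["pos"]) + 50
        enh_start = max(prom_end + 50_000, 0)
        enh_end = enh_start + 1_000
        hic_rows.append(
            (s["chrom"], enh_start, enh_end, s["chrom"], prom_start, prom_end,
             "enh_prom")
        )
        state_rows.append((s["chrom"], enh_start, enh_end, 7, "Enh"))

    # inert decoy segments exercise the state filter
    for c, grp in snps.groupby("chrom", sort=False):
        last = int(grp["pos"].max())
        state_rows.append((c, last + 5_000, last + 6_000, 15, "Quies"))

    state_table = pd.DataFrame(
        state_rows, columns=["chrom", "start", "end", "state_value", "state_label"]
    )
    open_chromatin, enhancers = derive_regions(state_table)

    bundle = AnnotationBundle(
        genes=genes,
        open_chromatin=open_chromatin,
        enhancers=enhancers,
        eqtls=pd.DataFrame(eqtl_rows, columns=["snp_id", "gene_id", "tissue"]),
        hic=pd.DataFrame(
            hic_rows,
            columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                     "orientation"],
        ),
        state_table=state_table,
    )

    # pathways: one carries the causal genes (plus filler), the rest are noise
    lo, hi = config.pathway_size_range
    coding_ids = coding["gene_id"].tolist()
    non_causal = [g for g in coding_ids if g not in set(truth.causal_gene_ids)]
    causal_size = int(min(max(config.causal_gene_count + 5, lo), hi))
    n_filler = causal_size - config.causal_gene_count
    filler = list(rng.choice(non_causal, size=n_filler, replace=False))
    causal_members = sorted(set(truth.causal_gene_ids) | set(filler))
    causal_slot = config.n_pathways // 2
    sets = {}
    for i in range(config.n_pathways):
        name = f"PW{i:04d}"
        if i == causal_slot:
            sets[name] = causal_members
            truth.causal_pathway_id = name
            continue
        size = int(rng.integers(lo, hi + 1))
        sets[name] = sorted(rng.choice(non_causal, size=size, replace=False))
    pathways = PathwayDB(sets, {name: "simulated pathway" for name in sets})
    return bundle, pathways


# -------------------------------------------------------------- orchestrator

def simulate_cohort(config: SimConfig):
    """Full fixture set: genotypes, truth, phenotype, annotations, pathways."""
    G = simulate_genotypes(config)
    truth = make_truth(config, G)
    pheno = simulate_phenotype(G, truth, config)
    bundle, pathways = simulate_annotations(config, truth)
    return G, truth, pheno, bundle, pathways
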