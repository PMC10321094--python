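"""File formats and run configuration.

All tabular text uses tab separation with ``NA`` as the single missing-value
token. BED files are 0-based half-open; gene tables and SNP positions are
1-based. Every coordinate conversion between external formats and the internal
convention happens here. Writers emit deterministic column and row order so a
fixed config and seed reproduce files byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import SNP_COLUMNS, GenotypeMatrix
from .gsea import PathwayDB
from .qc import QcConfig

NA = "NA"


# ------------------------------------------------------------------ genotypes

def write_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT-only biallelic records."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in G.individuals)
            + "\n"
        )
        snps = G.snps
        for j in range(G.n_snps):
            row = snps.iloc[j]
            calls = "\t".join(
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in G.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read dosages from the GT field; multi-allelic records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = np.array(vcf.samples, dtype=object)
    rows = []
    dosage_cols = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        col = np.empty(len(individuals))
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            col[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append((var.ID, var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosage_cols.append(col)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic VCF records")
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    return GenotypeMatrix(np.column_stack(dosage_cols), snps, individuals)


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    """SNPs-as-rows dosage table: metadata columns then one column per individual."""
    df = G.snps.copy()
    dos = pd.DataFrame(
        G.dosages.T, columns=[str(i) for i in G.individuals]
    )
    out = pd.concat([df.reset_index(drop=True), dos], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.0f")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV lacks columns: {missing}")
    ind_cols = [c for c in df.columns if c not in SNP_COLUMNS]
    dosages = df[ind_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, df[SNP_COLUMNS], np.array(ind_cols, dtype=object))


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on ``format`` ('vcf' | 'tsv'), inferring from the suffix if unset."""
    if format is None:
        format = "vcf" if str(path).endswith(".vcf") else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")


# ------------------------------------------------------------------ phenotype

PHENO_FLOAT_FMT = "%.10g"


def write_phenotype_tsv(pheno: pd.DataFrame, path) -> None:
    cols = [c for c in ["individual_id", "raw_score", "age", "sex", "valid_code",
                        "medical_rating", "residual_score", "label"]
            if c in pheno.columns]
    pheno[cols].to_csv(path, sep="\t", index=False, na_rep=NA,
                       float_format=PHENO_FLOAT_FMT)


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


# ---------------------------------------------------------------- annotations

def write_gene_tsv(genes: pd.DataFrame, path) -> None:
    cols = ["gene_id", "symbol", "biotype", "chrom", "strand", "start", "end"]
    genes[cols].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_gene_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise ValueError(f"gene {bad['gene_id']}: start > end")
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals = intervals.sort_values(["chrom", "start", "end"])
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
    )
    bad = df["start"] > df["end"]
    if bad.any():
        first = df[bad].iloc[0]
        raise ValueError(
            f"BED interval with start > end: "
            f"{first['chrom']}:{first['start']}-{first['end']}"
        )
    return df


def write_eqtl_tsv(eqtls: pd.DataFrame, path) -> None:
    eqtls[["snp_id", "gene_id", "tissue"]].to_csv(path, sep="\t", index=False)


def read_eqtl_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


HIC_COLUMNS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
               "orientation"]


def write_hic_tsv(hic: pd.DataFrame, path) -> None:
    out = hic.copy()
    if "orientation" not in out.columns:
        out["orientation"] = ""
    out[HIC_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_hic_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if "orientation" in df.columns:
        df["orientation"] = df["orientation"].fillna("")
    return df


def write_state_tsv(state_table: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "state_value", "state_label"]
    state_table[cols].to_csv(path, sep="\t", index=False)


def read_state_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


# ----------------------------------------------------------------------- GMT

def write_gmt(pathways: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways.sets):
            desc = pathways.descriptions.get(name, "")
            genes = "\t".join(sorted(pathways.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> PathwayDB:
    sets = {}
    descriptions = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if len(genes) != len(set(genes)):
                warnings.warn(f"GMT set {name}: duplicate genes deduplicated")
            sets[name] = set(genes)
            descriptions[name] = desc
    return PathwayDB(sets, descriptions)


# ------------------------------------------------------------- summary stats

def write_sumstats_tsv(table: pd.DataFrame, path) -> None:
    cols = [c for c in ["snp_id", "chrom", "pos", "allele_alt", "freq", "beta",
                        "se", "z", "p", "n", "status"] if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False, na_rep=NA,
                       float_format="%.10g")


def read_sumstats_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_map_tsv(snp_gene_map: pd.DataFrame, path) -> None:
    out = snp_gene_map.sort_values(["snp_id", "gene_id", "evidence"])
    out[["snp_id", "gene_id", "evidence"]].to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


# --------------------------------------------------------------- run config

@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, serializable to YAML losslessly.

    ``steps`` toggles individual pipeline stages; ``sim``, ``pheno``, ``qc``,
    ``gwas``, ``snp2gene`` and ``gsea`` hold per-stage parameters (defaults as
    documented on the stage functions). Unknown keys anywhere are rejected.
    """

    seed: int = 0
    out_dir: str = "cogsys_run"
    steps: dict = field(
        default_factory=lambda: {
            "simulate": True, "pheno_prep": True, "qc": True, "gwas": True,
            "snp2gene": True, "gsea": True,
        }
    )
    sim: dict = field(default_factory=dict)
    pheno: dict = field(
        default_factory=lambda: {"k_sd": 4.0, "lower_q": 1 / 3, "upper_q": 2 / 3}
    )
    qc: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=lambda: {"loco": True})
    snp2gene: dict = field(
        default_factory=lambda: {
            "max_dist": 60_000, "positional_mode": "nearest",
            "hic_snp_side": "promoter",
        }
    )
    gsea: dict = field(
        default_factory=lambda: {
            "n_perm": 100, "weight_exponent": 1.0, "engine": "fast",
            "min_size": 20, "max_size": 500,
        }
    )

    _STEP_NAMES = ("simulate", "pheno_prep", "qc", "gwas", "snp2gene", "gsea")

    def __post_init__(self) -> None:
        unknown = set(self.steps) - set(self._STEP_NAMES)
        if unknown:
            raise ValueError(f"unknown step toggles: {sorted(unknown)}")
        from .sim import SimConfig

        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(self.sim) - sim_fields
        if bad:
            raise ValueError(f"unknown sim keys: {sorted(bad)}")
        qc_fields = {f.name for f in dataclasses.fields(QcConfig)}
        bad = set(self.qc) - qc_fields
        if bad:
            raise ValueError(f"unknown qc keys: {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            default = getattr(base, f.name)
            if f.name in data:
                val = data[f.name]
                if isinstance(default, dict) and isinstance(val, dict):
                    d = dict(default)
                    d.update(val)
                    val = d
                merged[f.name] = val
            else:
                merged[f.name] = default
        return cls(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
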