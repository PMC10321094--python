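"""Variant-level gene-set enrichment with a label-permutation null.

Genes are scored by the best (minimum) association p-value over their mapped
SNPs and ranked by ``-log10(p)``. For each pathway a weighted running-sum
enrichment score (ES) is computed over the ranked list; significance comes
from re-running the *same* association engine on label-permuted phenotypes,
giving per-pathway null ES vectors. The normalized score is a z-score of the
observed ES against its null, the nominal p-value uses the add-one permutation
estimator, and Benjamini-Hochberg FDR is applied across pathways.

Because label permutation must leave the statistic exchangeable, the observed
and permuted runs always use the identical engine: either the full mixed-model
scan (``engine='mlma'``) or the fast vectorised linear score test
(``engine='fast'``), never a mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import (
    MixedLinearAssociation,
    linear_score_pvalues,
)
from .genotypes import GenotypeMatrix


# ------------------------------------------------------------------ pathways

@dataclass
class PathwayDB:
    """Named gene sets (GMT semantics): pathway name -> member gene ids."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def size_filter(self, universe, min_size: int = 20, max_size: int = 500
                    ) -> "PathwayDB":
        """Keep pathways whose membership *within the scored universe* is
        between ``min_size`` and ``max_size`` inclusive."""
        universe = set(universe)
        kept = {
            name: genes
            for name, genes in self.sets.items()
            if min_size <= len(genes & universe) <= max_size
        }
        return PathwayDB(kept, {k: self.descriptions.get(k, "") for k in kept})


# --------------------------------------------------------------- gene scores

def score_genes(assoc_table: pd.DataFrame, snp_gene_map: pd.DataFrame) -> pd.DataFrame:
    """Best-SNP gene scores: per gene, the minimum association p over its SNPs.

    SNPs without a p-value (e.g. monomorphic) are skipped. Returns a frame
    with ``gene_id, p, stat`` where ``stat = -log10(p)``.
    """
    assoc = assoc_table[["snp_id", "p"]].dropna(subset=["p"])
    merged = snp_gene_map.merge(assoc, on="snp_id", how="inner")
    if merged.empty:
        raise ValueError("no overlap between the SNP-gene map and association results")
    scores = merged.groupby("gene_id", sort=True)["p"].min().reset_index()
    # floor protects against underflowed p = 0 producing an infinite statistic
    scores["stat"] = -np.log10(scores["p"].clip(lower=1e-300))
    return scores


def _ranked(scores: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking: decreasing stat, ties broken by gene id."""
    return scores.sort_values(["stat", "gene_id"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)


def enrichment_score(
    scores: pd.DataFrame, gene_set, weight_exponent: float = 1.0
):
    """Running-sum enrichment score and leading edge for one gene set.

    Walking down the ranked list, set members increment the sum by
    ``|stat|^weight / sum_hits |stat|^weight`` and non-members decrement it by
    ``1 / (N - N_hits)``; the ES is the signed maximum deviation from zero.
    The leading edge comprises the set members at or before the position of
    the maximum deviation (for a positive ES; at or after it for a negative
    one).
    """
    ranked = _ranked(scores)
    member = ranked["gene_id"].isin(set(gene_set)).to_numpy()
    n_hit = int(member.sum())
    n_total = len(ranked)
    if n_hit == 0:
        raise ValueError("no gene-set member has a score")
    if n_hit == n_total:
        raise ValueError("gene set equals the scored universe; ES undefined")
    stat = np.abs(ranked["stat"].to_numpy())
    hit_w = stat**weight_exponent
    denom = hit_w[member].sum()
    inc = np.where(member, np.where(denom > 0, hit_w / max(denom, 1e-300), 0.0),
                   -1.0 / (n_total - n_hit))
    walk = np.cumsum(inc)
    arg = int(np.argmax(np.abs(walk)))
    es = float(walk[arg])
    if es >= 0:
        leading = ranked.loc[: arg, "gene_id"][member[: arg + 1]].tolist()
    else:
        leading = ranked.loc[arg:, "gene_id"][member[arg:]].tolist()
    return es, leading


def _es_for_pathways(scores: pd.DataFrame, pathways: PathwayDB,
                     weight_exponent: float) -> dict:
    return {
        name: enrichment_score(scores, genes, weight_exponent)[0]
        for name, genes in pathways.sets.items()
    }


def normalize_and_test(es: float, null_es: np.ndarray):
    """Z-score normalization and add-one permutation p for one pathway.

    ``NES = (ES - mean(null)) / SD(null)``; ``p = (1 + #{null >= ES}) /
    (1 + n_perm)``. A degenerate null (zero SD) yields a missing NES.
    """
    null_es = np.asarray(null_es, dtype=float)
    mu = null_es.mean()
    sd = null_es.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(mu)):  # constant null up to round-off
        warnings.warn("degenerate permutation null (zero SD); NES undefined")
        nes = np.nan
    else:
        nes = (es - mu) / sd
    p = (1.0 + np.sum(null_es >= es)) / (1.0 + null_es.size)
    return nes, p


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values across tested pathways."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


# ------------------------------------------------------------------ the model

class VariantSetEnrichment:
    """GSEA-style pathway enrichment of GWAS signal, statsmodels-flavoured.

    Parameters
    ----------
    pheno
        Prepared phenotype table with ``label`` in {poor, good, unassigned}.
    G
        Post-QC genotypes for the same cohort.
    snp_gene_map
        Frame ``snp_id, gene_id, evidence`` from the mapping stage.
    pathways
        :class:`PathwayDB` of candidate gene sets.
    n_perm
        Number of label permutations for the null (>= 1; fewer than 10 makes
        the NES unstable and triggers a warning).
    engine
        ``'mlma'`` for the full LOCO mixed model or ``'fast'`` for the plain
        linear score test; observed and permuted runs share the engine.
    """

    def __init__(
        self,
        pheno: pd.DataFrame,
        G: GenotypeMatrix,
        snp_gene_map: pd.DataFrame,
        pathways: PathwayDB,
        n_perm: int = 100,
        weight_exponent: float = 1.0,
        engine: str = "fast",
        min_size: int = 20,
        max_size: int = 500,
        seed: int | None = None,
        covariates=None,
    ):
        if n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if n_perm < 10:
            warnings.warn("fewer than 10 permutations: NES will be unstable")
        if engine not in ("mlma", "fast"):
            raise ValueError("engine must be 'mlma' or 'fast'")
        labeled = pheno[pheno["label"].isin(["poor", "good"])]
        if labeled.empty:
            raise ValueError("phenotype has no labeled (poor/good) individuals")
        ids = dict(zip(labeled["individual_id"], labeled["label"]))
        keep = np.array([i in ids for i in G.individuals])
        self.G = G.take_individuals(keep)
        self.y = np.array(
            [1.0 if ids[i] == "good" else 0.0 for i in self.G.individuals]
        )
        self.snp_gene_map = snp_gene_map
        self.pathways = pathways
        self.n_perm = int(n_perm)
        self.weight_exponent = float(weight_exponent)
        self.engine = engine
        self.min_size = min_size
        self.max_size = max_size
        self.seed = seed
        self.covariates = covariates

    # -- engines ---------------------------------------------------------

    def _assoc_pvalues(self, y: np.ndarray) -> pd.DataFrame:
        if self.engine == "mlma":
            res = MixedLinearAssociation(
                y, self.G, covariates=self.covariates
            ).fit()
            return res.table[["snp_id", "p"]]
        P = linear_score_pvalues(y[:, None], self.G)
        return pd.DataFrame({"snp_id": self.G.snp_ids, "p": P[:, 0]})

    def _gene_scores(self, assoc: pd.DataFrame) -> pd.DataFrame:
        return score_genes(assoc, self.snp_gene_map)

    def permutation_null(self, pathways: PathwayDB) -> pd.DataFrame:
        """Per-pathway null ES vectors from label-permuted reruns.

        Fully reproducible from the model's seed; rows are pathways, columns
        permutation indices.
        """
        rng = np.random.default_rng(self.seed)
        names = list(pathways.sets)
        null = np.empty((len(names), self.n_perm))
        if self.engine == "fast":
            Y = np.column_stack(
                [rng.permutation(self.y) for _ in range(self.n_perm)]
            )
            P = linear_score_pvalues(Y, self.G)
            snp_ids = self.G.snp_ids
            for k in range(self.n_perm):
                assoc = pd.DataFrame({"snp_id": snp_ids, "p": P[:, k]})
                scores = self._gene_scores(assoc)
                for i, name in enumerate(names):
                    null[i, k] = enrichment_score(
                        scores, pathways.sets[name], self.weight_exponent
                    )[0]
        else:
            for k in range(self.n_perm):
                y_perm = rng.permutation(self.y)
                scores = self._gene_scores(self._assoc_pvalues(y_perm))
                for i, name in enumerate(names):
                    null[i, k] = enrichment_score(
                        scores, pathways.sets[name], self.weight_exponent
                    )[0]
        return pd.DataFrame(null, index=names)

    # -- fit -------------------------------------------------------------

    def fit(self) -> "EnrichmentResults":
        observed_assoc = self._assoc_pvalues(self.y)
        scores = self._gene_scores(observed_assoc)
        pathways = self.pathways.size_filter(
            scores["gene_id"], self.min_size, self.max_size
        )
        if len(pathways) == 0:
            raise ValueError(
                f"no pathway has {self.min_size}-{self.max_size} scored genes"
            )
        observed = {}
        leading = {}
        for name, genes in pathways.sets.items():
            es, le = enrichment_score(scores, genes, self.weight_exponent)
            observed[name] = es
            leading[name] = le
        null = self.permutation_null(pathways)
        names = list(pathways.sets)
        nes = np.empty(len(names))
        pval = np.empty(len(names))
        for i, name in enumerate(names):
            nes[i], pval[i] = normalize_and_test(
                observed[name], null.loc[name].to_numpy()
            )
        qval = bh_qvalues(pval)
        universe = set(scores["gene_id"])
        table = pd.DataFrame(
            {
                "pathway": names,
                "size": [len(pathways.sets[n] & universe) for n in names],
                "es": [observed[n] for n in names],
                "nes": nes,
                "p": pval,
                "q": qval,
                "leading_edge": [",".join(leading[n]) for n in names],
            }
        ).sort_values("nes", ascending=False, kind="mergesort").reset_index(drop=True)
        return EnrichmentResults(
            table=table, null_es=null, gene_scores=scores, model=self
        )


@dataclass
class EnrichmentResults:
    """Per-pathway ES/NES/p/q, leading edges, and the permutation null."""

    table: pd.DataFrame
    null_es: pd.DataFrame
    gene_scores: pd.DataFrame
    model: VariantSetEnrichment | None = field(default=None, repr=False)

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        """Pathways called at FDR ``q_max``; only positive enrichment is called."""
        t = self.table
        return t[(t["q"] <= q_max) & (t["es"] > 0)].reset_index(drop=True)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Variant-level gene-set enrichment",
            "=" * 46,
            f"pathways tested: {len(t)}    permutations: {self.null_es.shape[1]}"
            f"    scored genes: {len(self.gene_scores)}",
            f"significant at q<=0.05 (positive ES): {len(self.significant())}",
            "",
            "top pathways by NES:",
        ]
        top = t.head(5)[["pathway", "size", "es", "nes", "p", "q"]]
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def run_enrichment(
    pheno: pd.DataFrame,
    G: GenotypeMatrix,
    snp_gene_map: pd.DataFrame,
    pathways: PathwayDB,
    **kwargs,
) -> EnrichmentResults:
    """One-call wrapper around :class:`VariantSetEnrichment`."""
    return VariantSetEnrichment(pheno, G, snp_gene_map, pathways, **kwargs).fit()
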