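"""Multi-evidence SNP-to-gene mapping.

Each SNP is linked to genes through up to three evidence channels:

* **eQTL** — a SNP/gene expression association, retained only when the SNP lies
  in open chromatin of the relevant tissue;
* **HiC** — chromatin-contact pairs whose enhancer side overlaps a known
  enhancer and whose promoter side overlaps a strand-aware promoter window
  (250 bp upstream to 500 bp downstream of a TSS);
* **positional** — nearest protein-coding gene when the distance to its
  transcription start or end site is at most 60 kb.

Functional evidence takes priority: a SNP with any eQTL or Hi-C link is never
also mapped positionally. A SNP may map to several genes, and to the same gene
through both eQTL and Hi-C.

Gene tables use 1-based inclusive ``start``/``end`` coordinates with ``strand``
in ``{+,-}``; the TSS is ``start`` on the plus strand and ``end`` on the minus
strand. Interval sets (open chromatin, enhancers, Hi-C anchors) are 0-based
half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    as_interval_frame,
    intervals_overlap_any,
    merge_intervals,
    points_in_intervals,
)

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "symbol", "biotype", "chrom", "strand", "start", "end"]
MAP_COLUMNS = ["snp_id", "gene_id", "evidence"]

#: Mnemonics of the Roadmap core 15-state chromatin model, state 1..15.
CHROMATIN_STATE_LABELS = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)
ENHANCER_STATE_LABELS = frozenset({"Enh", "EnhG"})
OPEN_CHROMATIN_MAX_STATE = 7


def gene_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a gene-model table, adding ``tss``/``tes`` columns."""
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table lacks columns: {missing}")
    df = df.copy().reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] > df["end"]).any():
        raise ValueError("gene with start > end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    plus = df["strand"] == "+"
    df["tss"] = np.where(plus, df["start"], df["end"])
    df["tes"] = np.where(plus, df["end"], df["start"])
    return df


@dataclass
class AnnotationBundle:
    """Everything SNP-to-gene mapping consumes.

    ``open_chromatin`` and ``enhancers`` are 0-based half-open interval frames;
    ``eqtls`` has columns ``snp_id, gene_id, tissue``; ``hic`` has columns
    ``chrom_a, start_a, end_a, chrom_b, start_b, end_b, orientation`` where
    orientation is ``enh_prom`` (A = enhancer side), ``prom_enh`` or empty
    (sides inferred by overlap).
    """

    genes: pd.DataFrame
    open_chromatin: pd.DataFrame
    enhancers: pd.DataFrame
    eqtls: pd.DataFrame
    hic: pd.DataFrame
    state_table: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.genes = gene_table(self.genes)
        self.open_chromatin = as_interval_frame(self.open_chromatin)
        self.enhancers = as_interval_frame(self.enhancers)

    def protein_coding_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["biotype"] == "protein_coding"].reset_index(
            drop=True
        )


def derive_regions(state_table: pd.DataFrame):
    """Split a chromatin-state segmentation into open-chromatin and enhancer sets.

    Open chromatin comprises intervals whose core 15-state value is <= 7;
    enhancers are intervals labeled ``Enh`` or ``EnhG``. Both are returned
    merged. Rows with labels outside the 15-state vocabulary are ignored for
    the label-based enhancer rule, with a warning.
    """
    required = {"chrom", "start", "end", "state_value", "state_label"}
    missing = required - set(state_table.columns)
    if missing:
        raise ValueError(f"state table lacks columns: {sorted(missing)}")
    known = state_table["state_label"].isin(CHROMATIN_STATE_LABELS)
    if not known.all():
        bad = sorted(state_table.loc[~known, "state_label"].unique())
        warnings.warn(f"ignoring unknown chromatin-state labels: {bad}")
    open_rows = state_table[state_table["state_value"] <= OPEN_CHROMATIN_MAX_STATE]
    enh_rows = state_table[known & state_table["state_label"].isin(ENHANCER_STATE_LABELS)]
    return merge_intervals(open_rows), merge_intervals(enh_rows)


def map_eqtl(
    snps: pd.DataFrame, eqtls: pd.DataFrame, open_chromatin: pd.DataFrame
) -> pd.DataFrame:
    """eQTL evidence: keep records whose SNP lies in open chromatin.

    ``snps`` needs columns ``snp_id, chrom, pos`` (1-based). Records naming
    SNPs absent from the table are skipped and counted.
    """
    eqtls = eqtls.copy()
    pos = snps.set_index("snp_id")[["chrom", "pos"]]
    known = eqtls["snp_id"].isin(pos.index)
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.warning("map_eqtl: skipped %d eQTL records with unknown SNPs", n_skipped)
    eqtls = eqtls[known]
    if eqtls.empty or open_chromatin.empty:
        return pd.DataFrame(columns=MAP_COLUMNS)
    loc = pos.loc[eqtls["snp_id"]]
    inside = points_in_intervals(
        loc["chrom"].to_numpy(), loc["pos"].to_numpy(), open_chromatin
    )
    kept = eqtls[inside]
    out = kept[["snp_id", "gene_id"]].copy()
    out["evidence"] = "eQTL"
    return out.drop_duplicates().reset_index(drop=True)


def _promoter_windows(genes: pd.DataFrame, upstream: int, downstream: int) -> pd.DataFrame:
    """Strand-aware TSS windows as 0-based half-open intervals.

    The window covers ``upstream`` bp 5' of the TSS through ``downstream`` bp
    3' of it (TSS base included), in transcription orientation.
    """
    plus = (genes["strand"] == "+").to_numpy()
    tss = genes["tss"].to_numpy()
    lo = np.where(plus, tss - upstream, tss - downstream)
    hi = np.where(plus, tss + downstream, tss + upstream)
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(lo - 1, 0),  # 1-based inclusive -> 0-based half-open
            "end": hi,
        }
    )


def annotate_hic_promoters(
    hic: pd.DataFrame, genes: pd.DataFrame, promoter_halfwidth: int = 2000
) -> pd.DataFrame:
    """Promoter-anchor annotation: which genes' TSS +/- halfwidth each anchor hits.

    Both anchors of every interaction are tested. Returns a long frame with
    columns ``interaction, anchor ('A'|'B'), gene_id``.
    """
    genes = gene_table(genes) if "tss" not in genes.columns else genes
    windows = _promoter_windows(genes, promoter_halfwidth, promoter_halfwidth)
    rows = []
    for anchor, (c, s, e) in {
        "A": ("chrom_a", "start_a", "end_a"),
        "B": ("chrom_b", "start_b", "end_b"),
    }.items():
        for i, rec in hic.iterrows():
            hit = windows[
                (windows["chrom"] == rec[c])
                & (windows["start"] < rec[e])
                & (windows["end"] > rec[s])
            ]
            for g in hit["gene_id"]:
                rows.append((i, anchor, g))
    return pd.DataFrame(rows, columns=["interaction", "anchor", "gene_id"])


def _anchor_frames(hic: pd.DataFrame):
    a = hic[["chrom_a", "start_a", "end_a"]].rename(
        columns={"chrom_a": "chrom", "start_a": "start", "end_a": "end"}
    )
    b = hic[["chrom_b", "start_b", "end_b"]].rename(
        columns={"chrom_b": "chrom", "start_b": "start", "end_b": "end"}
    )
    return a.reset_index(drop=True), b.reset_index(drop=True)


def map_hic(
    snps: pd.DataFrame,
    hic: pd.DataFrame,
    enhancers: pd.DataFrame,
    genes: pd.DataFrame,
    snp_side: str = "promoter",
    promoter_upstream: int = 250,
    promoter_downstream: int = 500,
) -> pd.DataFrame:
    """Hi-C evidence: enhancer-promoter contacts assign contacted genes to SNPs.

    An interaction survives when its enhancer side overlaps a known enhancer;
    the contacted gene is the one whose strand-aware promoter window
    (``promoter_upstream`` bp 5' to ``promoter_downstream`` bp 3' of the TSS)
    overlaps the promoter side. SNPs overlapping the ``snp_side`` anchor
    (``promoter`` by default, ``enhancer`` selectable) receive the gene link.
    """
    if snp_side not in ("promoter", "enhancer"):
        raise ValueError("snp_side must be 'promoter' or 'enhancer'")
    if hic.empty:
        return pd.DataFrame(columns=MAP_COLUMNS)
    genes = gene_table(genes) if "tss" not in genes.columns else genes
    windows = _promoter_windows(genes, promoter_upstream, promoter_downstream)
    a, b = _anchor_frames(hic)

    a_is_enh = intervals_overlap_any(a, enhancers) if len(enhancers) else np.zeros(len(a), bool)
    b_is_enh = intervals_overlap_any(b, enhancers) if len(enhancers) else np.zeros(len(b), bool)
    orientation = hic.get("orientation", pd.Series([""] * len(hic))).fillna("")

    n_dropped = 0
    records = []
    for i in range(len(hic)):
        orient = orientation.iloc[i]
        if orient == "enh_prom":
            enh, prom, enh_ok = a.iloc[i], b.iloc[i], a_is_enh[i]
        elif orient == "prom_enh":
            enh, prom, enh_ok = b.iloc[i], a.iloc[i], b_is_enh[i]
        elif a_is_enh[i] and not b_is_enh[i]:
            enh, prom, enh_ok = a.iloc[i], b.iloc[i], True
        elif b_is_enh[i] and not a_is_enh[i]:
            enh, prom, enh_ok = b.iloc[i], a.iloc[i], True
        else:
            # ambiguous or no enhancer overlap: cannot orient -> contributes nothing
            n_dropped += 1
            continue
        if not enh_ok:
            n_dropped += 1
            continue
        hit = windows[
            (windows["chrom"] == prom["chrom"])
            & (windows["start"] < prom["end"])
            & (windows["end"] > prom["start"])
        ]
        if hit.empty:
            n_dropped += 1
            continue
        anchor = prom if snp_side == "promoter" else enh
        in_anchor = snps[
            (snps["chrom"] == anchor["chrom"])
            & (snps["pos"] - 1 >= anchor["start"])
            & (snps["pos"] - 1 < anchor["end"])
        ]
        for snp_id in in_anchor["snp_id"]:
            for g in hit["gene_id"]:
                records.append((snp_id, g, "HiC"))
    if n_dropped:
        logger.info("map_hic: %d interactions contributed no gene link", n_dropped)
    out = pd.DataFrame(records, columns=MAP_COLUMNS)
    return out.drop_duplicates().reset_index(drop=True)


def map_positional(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 60_000,
    mode: str = "nearest",
) -> pd.DataFrame:
    """Positional evidence: genes within ``max_dist`` bp of the SNP.

    Distance is 0 inside the gene body, otherwise the smaller of the distances
    to the transcription start and end sites. ``mode='nearest'`` keeps every
    gene attaining the minimum distance (so co-nearest ties and all genes whose
    body contains the SNP are retained); ``mode='all'`` keeps every gene within
    ``max_dist``.
    """
    if mode not in ("nearest", "all"):
        raise ValueError("mode must be 'nearest' or 'all'")
    genes = gene_table(genes) if "tss" not in genes.columns else genes
    records = []
    for chrom, snp_grp in snps.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        pos = snp_grp["pos"].to_numpy()[:, None]
        start = g["start"].to_numpy()[None, :]
        end = g["end"].to_numpy()[None, :]
        tss = g["tss"].to_numpy()[None, :]
        tes = g["tes"].to_numpy()[None, :]
        inside = (pos >= start) & (pos <= end)
        dist = np.minimum(np.abs(pos - tss), np.abs(pos - tes))
        dist = np.where(inside, 0, dist)
        if mode == "nearest":
            dmin = dist.min(axis=1)
            keep = (dist == dmin[:, None]) & (dmin[:, None] <= max_dist)
        else:
            keep = dist <= max_dist
        snp_ids = snp_grp["snp_id"].to_numpy()
        gene_ids = g["gene_id"].to_numpy()
        si, gi = np.nonzero(keep)
        records.extend(zip(snp_ids[si], gene_ids[gi]))
    out = pd.DataFrame(records, columns=["snp_id", "gene_id"])
    out["evidence"] = "positional"
    return out.drop_duplicates().reset_index(drop=True)


def integrate(
    eqtl_map: pd.DataFrame, hic_map: pd.DataFrame, pos_map: pd.DataFrame
) -> pd.DataFrame:
    """Combine channels with functional priority.

    eQTL and Hi-C records are unioned; positional records are kept only for
    SNPs with neither kind of functional evidence.
    """
    functional = pd.concat([eqtl_map, hic_map], ignore_index=True)
    has_functional = set(functional["snp_id"])
    pos_only = pos_map[~pos_map["snp_id"].isin(has_functional)]
    out = pd.concat([functional, pos_only], ignore_index=True)
    out = out.drop_duplicates(subset=MAP_COLUMNS).reset_index(drop=True)
    validate_map(out)
    return out


def validate_map(snp_gene_map: pd.DataFrame) -> None:
    """Assert the priority invariant: no SNP mixes positional and functional evidence."""
    by_snp = snp_gene_map.groupby("snp_id")["evidence"].agg(set)
    mixed = by_snp[by_snp.apply(lambda s: "positional" in s and len(s) > 1)]
    if len(mixed):
        raise AssertionError(
            f"SNPs with both positional and functional evidence: {list(mixed.index)[:5]}"
        )


def build_snp_gene_map(
    snps: pd.DataFrame,
    bundle: AnnotationBundle,
    max_dist: int = 60_000,
    positional_mode: str = "nearest",
    hic_snp_side: str = "promoter",
) -> pd.DataFrame:
    """Run the full multi-evidence mapping against protein-coding genes."""
    genes = bundle.protein_coding_genes()
    coding = set(genes["gene_id"])
    eqtls = bundle.eqtls[bundle.eqtls["gene_id"].isin(coding)]
    e = map_eqtl(snps, eqtls, bundle.open_chromatin)
    h = map_hic(snps, bundle.hic, bundle.enhancers, genes, snp_side=hic_snp_side)
    p = map_positional(snps, genes, max_dist=max_dist, mode=positional_mode)
    return integrate(e, h, p)
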