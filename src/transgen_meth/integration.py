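"""Methylation-expression integration.

Maintained promoter DMCs map to genes via the TSS±window annotation; the
offspring brain differential-expression table is filtered at the study's
thresholds (fold change >= 2, p < 0.05) and the two gene sets are
intersected, with an upper-tail hypergeometric p for the overlap given the
shared gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError
from .methylome import GeneModel, annotate_sites
from .stats import hypergeom_upper_tail


@dataclass
class OverlapResult:
    universe_size: int
    set_meth_size: int
    set_de_size: int
    overlap_size: int
    hypergeometric_p: float
    overlap_genes: tuple

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "set_meth_size": self.set_meth_size,
            "set_de_size": self.set_de_size,
            "overlap_size": self.overlap_size,
            "hypergeometric_p": self.hypergeometric_p,
            "overlap_genes": list(self.overlap_genes),
        }


def filter_de(
    table: pd.DataFrame,
    min_fc: float = 2.0,
    max_p: float = 0.05,
    direction: str = "up",
) -> set:
    """Genes passing the DE filter: fold change >= min_fc (inclusive) and p < max_p.

    ``direction="up"`` selects fold_change >= min_fc (higher in the
    reference group, here Non-addict); ``"down"`` selects
    fold_change <= 1/min_fc; ``"both"`` is their union.
    """
    if len(table) == 0:
        return set()
    fc = table["fold_change"].to_numpy(dtype=np.float64)
    if (fc <= 0).any():
        raise FormatError("fold_change must be strictly positive")
    p = table["p_value"].to_numpy(dtype=np.float64)
    if direction == "up":
        keep = fc >= min_fc
    elif direction == "down":
        keep = fc <= 1.0 / min_fc
    elif direction == "both":
        keep = (fc >= min_fc) | (fc <= 1.0 / min_fc)
    else:
        raise DomainError(f"unknown direction {direction!r}")
    keep &= p < max_p
    return set(table.loc[keep, "gene_id"].astype(str))


def maintained_promoter_genes(
    maintained_sites: pd.DataFrame,
    gm: GeneModel,
    window: int = 2000,
    include_gene_body: bool = False,
) -> set:
    """Genes whose promoter (TSS±window) contains a maintained DMC.

    With ``include_gene_body=True``, exonic/intronic maintained CpGs also
    map to their gene.
    """
    if len(maintained_sites) == 0:
        return set()
    ann = annotate_sites(maintained_sites[["chrom", "pos"]].reset_index(drop=True), gm, window)
    keep = ann["element"] == "promoter"
    if include_gene_body:
        keep |= ann["element"].isin(["exon", "intron"])
    return set(ann.loc[keep, "gene_id"])


def overlap_enrichment(meth_genes: set, de_genes: set, universe: set) -> OverlapResult:
    """Overlap of methylation- and expression-derived gene sets.

    p is the upper-tail hypergeometric probability of an overlap at least
    this large when |de| genes are drawn from the universe containing
    |meth| marked genes.
    """
    meth_genes, de_genes, universe = set(meth_genes), set(de_genes), set(universe)
    stray = (meth_genes | de_genes) - universe
    if stray:
        raise DomainError(f"genes outside universe: {sorted(stray)[:10]}")
    overlap = meth_genes & de_genes
    p = hypergeom_upper_tail(len(overlap), len(universe), len(meth_genes), len(de_genes))
    return OverlapResult(
        universe_size=len(universe),
        set_meth_size=len(meth_genes),
        set_de_size=len(de_genes),
        overlap_size=len(overlap),
        hypergeometric_p=float(p),
        overlap_genes=tuple(sorted(overlap)),
    )
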