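"""Pathway-restricted polygenic risk scores with per-iteration FDR control.

Variants are assigned to genes positionally (distance strictly below a 10 kb
window by default), genes to pathways through gene-set libraries (GMT-style).
For every iteration — a (sex, p-value threshold, library) cell — each
pathway's variant set is scored with the genome-wide PRS machinery restricted
to that set, the score is tested against hospitalisation by age-corrected
logistic regression, and the iteration's p-values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import SeparationError
from .prs import PrsConfig, associate_prs, compute_prs, ld_clump, select_variants
from .simulate import GeneSetLibrary, GenotypeMatrix

__all__ = [
    "SnpGeneMap",
    "PprsConfig",
    "map_snps_to_genes",
    "build_pathway_variant_sets",
    "run_pprs_scan",
    "bh_fdr",
]

logger = logging.getLogger(__name__)


@dataclass
class SnpGeneMap:
    """Positional variant-to-gene assignment.

    A variant maps to a gene iff the distance from its position to the gene
    interval [start, end] (1-based inclusive; 0 inside the gene) is strictly
    less than ``window_bp``. A variant may map to several genes.
    """

    variant_to_genes: dict[str, frozenset[str]]
    window_bp: int
    n_unmapped: int

    def genes_to_variants(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for vid, genes in self.variant_to_genes.items():
            for g in genes:
                inv.setdefault(g, set()).add(vid)
        return inv


@dataclass(frozen=True)
class PprsConfig:
    """Pathway-scan options on top of the genome-wide PRS configuration."""

    prs: PrsConfig = field(default_factory=PrsConfig)
    mapping_window_bp: int = 10_000
    min_variants: int = 1
    fdr_scope: str = "cell"  # "cell" = per (sex, threshold, library); "library"
    clump_within_pathway: bool = False

    def __post_init__(self) -> None:
        if self.fdr_scope not in ("cell", "library"):
            raise ValueError("fdr_scope must be 'cell' or 'library'")
        if self.mapping_window_bp <= 0:
            raise ValueError("mapping_window_bp must be positive")


def map_snps_to_genes(
    variants: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 10_000
) -> SnpGeneMap:
    """Assign variants to genes within a strict positional window.

    The distance from position p to gene interval [s, e] is
    max(0, s - p, p - e); the variant maps iff that distance < ``window_bp``.
    Variants on chromosomes absent from the annotation stay unmapped and are
    counted.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    mapping: dict[str, frozenset[str]] = {}
    ann_by_chrom = dict(tuple(annotation.groupby("chrom", sort=False)))
    for chrom, var_grp in variants.groupby("chrom", sort=False):
        genes = ann_by_chrom.get(chrom)
        if genes is None:
            continue
        pos = var_grp["pos"].to_numpy()[:, None]
        start = genes["start"].to_numpy()[None, :]
        end = genes["end"].to_numpy()[None, :]
        dist = np.maximum(0, np.maximum(start - pos, pos - end))
        hits = dist < window_bp
        gene_ids = genes["gene_id"].to_numpy()
        vids = var_grp["id"].to_numpy()
        for i in np.flatnonzero(hits.any(axis=1)):
            mapping[vids[i]] = frozenset(gene_ids[hits[i]])
    n_unmapped = len(variants) - len(mapping)
    return SnpGeneMap(variant_to_genes=mapping, window_bp=window_bp, n_unmapped=n_unmapped)


def build_pathway_variant_sets(
    snp_map: SnpGeneMap,
    library: GeneSetLibrary,
    variants: pd.DataFrame,
    min_variants: int = 1,
) -> dict[str, list[str]]:
    """Per-pathway variant id lists from a thresholded (and clumped) subset.

    A pathway's set is the union over its member genes of mapped variants
    present in ``variants``; a variant enters a pathway once however many of
    the pathway's genes it maps to. Pathways with fewer than ``min_variants``
    variants are excluded (logged).
    """
    subset_ids = set(variants["id"])
    gene_to_vars = snp_map.genes_to_variants()
    order = pd.Series(np.arange(len(variants)), index=variants["id"])
    out: dict[str, list[str]] = {}
    n_excluded = 0
    for pathway, genes in library.pathways.items():
        vids: set[str] = set()
        for g in genes:
            vids |= gene_to_vars.get(g, set()) & subset_ids
        if len(vids) < min_variants:
            n_excluded += 1
            continue
        out[pathway] = sorted(vids, key=lambda v: int(order[v]))
    if n_excluded:
        logger.info(
            "library %s: %d/%d pathways excluded (< %d variants)",
            library.library_name, n_excluded, len(library.pathways), min_variants,
        )
    if not out and library.pathways:
        logger.warning(
            "library %s: no pathway retains any thresholded variant",
            library.library_name,
        )
    return out


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{k >= i} p_(k) * m / k, capped at 1. Adjusted values are
    monotone in the same order as the raw p and never smaller than them.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_pprs_scan(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    phenotypes: pd.DataFrame,
    annotation: pd.DataFrame,
    libraries: list[GeneSetLibrary],
    config: PprsConfig = PprsConfig(),
    sexes: tuple[str, ...] = ("male", "female"),
) -> pd.DataFrame:
    """Full pathway-PRS scan over (sex x threshold x library) iterations.

    Per iteration: build each pathway's variant set from the thresholded
    (clumped genome-wide by default) summary statistics, score it in
    sum-calculation mode, regress hospitalisation on the standardised score
    plus age at event within the sex stratum, and BH-adjust the iteration's
    p-values ("cell" scope; "library" scope pools an entire library's rows
    across sexes and thresholds instead). Pathway regressions that fail are
    flagged and excluded from the FDR family. Iterations with no eligible
    pathway are skipped with a warning.
    """
    snp_map = map_snps_to_genes(
        genotypes.variants, annotation, window_bp=config.mapping_window_bp
    )
    rows: list[dict[str, object]] = []
    for threshold in config.prs.p_thresholds:
        thresholded = select_variants(sumstats, threshold)
        if config.prs.clump_enabled and not config.clump_within_pathway:
            scored = ld_clump(
                thresholded, genotypes, config.prs.clump_r2, config.prs.clump_window_bp
            )
        else:
            scored = thresholded
        for library in libraries:
            var_sets = build_pathway_variant_sets(
                snp_map, library, scored, config.min_variants
            )
            if not var_sets:
                logger.warning(
                    "iteration (threshold=%g, library=%s): no eligible pathway; skipped",
                    threshold, library.library_name,
                )
                continue
            for sex in sexes:
                for pathway, vids in var_sets.items():
                    sub = scored[scored["id"].isin(vids)]
                    if config.clump_within_pathway and config.prs.clump_enabled:
                        sub = ld_clump(
                            sub, genotypes, config.prs.clump_r2,
                            config.prs.clump_window_bp,
                        )
                    prs = compute_prs(genotypes, sub, config.prs, threshold=threshold)
                    genes_hit = {
                        g
                        for v in prs.variant_ids
                        for g in snp_map.variant_to_genes.get(v, ())
                        if g in library.pathways[pathway]
                    }
                    row: dict[str, object] = {
                        "library": library.library_name,
                        "pathway": pathway,
                        "sex": sex,
                        "threshold": threshold,
                        "n_variants": prs.n_variants_used,
                        "n_genes_hit": len(genes_hit),
                    }
                    try:
                        assoc = associate_prs(prs, phenotypes, sex)
                        row.update(
                            beta=assoc.beta, se=assoc.se, p=assoc.p, flag=""
                        )
                    except (SeparationError, ValueError) as exc:
                        row.update(beta=np.nan, se=np.nan, p=np.nan, flag=str(exc))
                    rows.append(row)

    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_fdr"] = np.nan
    group_cols = (
        ["sex", "threshold", "library"] if config.fdr_scope == "cell" else ["library"]
    )
    for _, idx in table.groupby(group_cols, sort=False).indices.items():
        ok = table.loc[idx, "p"].notna()
        sel = np.asarray(idx)[ok.to_numpy()]
        if len(sel):
            table.loc[sel, "p_fdr"] = bh_fdr(table.loc[sel, "p"].to_numpy())
    return table
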