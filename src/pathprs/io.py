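"""File formats: VCF, dosage/phenotype/annotation TSV, GMT, summary statistics.

Internal coordinates are 1-based inclusive (the VCF convention) everywhere;
the BED-like annotation export converts to 0-based half-open at the boundary
and says so in a header comment. Genotype VCFs are diploid, unphased, GT-only;
dosages count copies of the ALT allele, which is recorded as the coded
(effect) allele.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneSetLibrary, GenotypeMatrix

__all__ = [
    "write_vcf",
    "write_dosage_tsv",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_annotation_bed",
    "read_annotation_bed",
    "write_gmt",
    "read_gmt",
    "write_sumstats",
    "read_sumstats",
    "write_ld_scores",
    "read_ld_scores",
    "plot_prevalence",
]

logger = logging.getLogger(__name__)

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


# ---------------------------------------------------------------------------
# genotypes


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write diploid unphased GT-only VCF; sex is kept in ##SAMPLE lines."""
    path = Path(path)
    variants = genotypes.variants
    samples = genotypes.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pathprs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in variants["chrom"].unique():
            length = int(variants.loc[variants["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for _, row in samples.iterrows():
            fh.write(f"##SAMPLE=<ID={row['individual_id']},Sex={row['sex']}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples["individual_id"])
            + "\n"
        )
        gts = np.empty(genotypes.dosages.shape, dtype=object)
        for code, s in _GT_CODE.items():
            gts[genotypes.dosages == code] = s
        for j in range(genotypes.n_variants):
            v = variants.iloc[j]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['other_allele']}\t"
                f"{v['coded_allele']}\t.\tPASS\t.\tGT\t" + "\t".join(gts[:, j]) + "\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    sex_by_id = {
        m.group(1): m.group(2)
        for m in re.finditer(r"##SAMPLE=<ID=([^,>]+),Sex=([^,>]+)>", vcf.raw_header)
    }
    rows, dosage_cols = [], []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record not supported: record {i} at "
                f"{rec.CHROM}:{rec.POS} (ALT={','.join(rec.ALT)})"
            )
        gt = np.asarray(rec.genotype.array())
        if gt.shape[1] != 3:  # two allele columns + phase column
            raise ValueError(
                f"mixed or non-diploid ploidy at record {i} ({rec.CHROM}:{rec.POS})"
            )
        alleles = gt[:, :2]
        missing = (alleles < 0).any(axis=1)
        dos = alleles.clip(min=0).sum(axis=1).astype(np.int8)
        dos[missing] = -1
        if (alleles > 1).any():
            raise ValueError(
                f"allele index > 1 at record {i} ({rec.CHROM}:{rec.POS}); "
                "multi-allelic genotypes are not supported"
            )
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.ALT[0], rec.REF))
        dosage_cols.append(dos)
    variants = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "coded_allele", "other_allele"]
    )
    dosages = (
        np.stack(dosage_cols, axis=1) if dosage_cols else np.empty((len(sample_ids), 0), np.int8)
    )
    samples = pd.DataFrame(
        {
            "individual_id": sample_ids,
            "sex": [sex_by_id.get(s, "unknown") for s in sample_ids],
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Plain dosage TSV (variants x individuals) plus a .samples.tsv sidecar."""
    path = Path(path)
    df = genotypes.variants[
        ["id", "chrom", "pos", "coded_allele", "other_allele"]
    ].copy()
    mat = pd.DataFrame(
        genotypes.dosages.T, columns=genotypes.samples["individual_id"]
    )
    pd.concat([df.reset_index(drop=True), mat], axis=1).to_csv(path, sep="\t", index=False)
    genotypes.samples.to_csv(path.with_suffix(path.suffix + ".samples.tsv"), sep="\t", index=False)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "coded_allele", "other_allele"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing metadata columns: {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=np.int8).T
    sidecar = path.with_suffix(path.suffix + ".samples.tsv")
    if sidecar.exists():
        samples = pd.read_csv(sidecar, sep="\t")
    else:
        samples = pd.DataFrame({"individual_id": sample_ids, "sex": "unknown"})
    return GenotypeMatrix(dosages=dosages, variants=df[meta_cols].copy(), samples=samples)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only diploid VCF (.vcf/.vcf.gz) or a plain dosage TSV."""
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


# ---------------------------------------------------------------------------
# phenotypes, annotation, gene sets


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("sars_cov2_positive", "hospitalized"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(bool)
    return df


def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """BED-like export: 0-based half-open intervals (internal is 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED); internal storage is 1-based inclusive\n")
        fh.write("chrom\tstart\tend\tgene_id\n")
        for _, r in annotation.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['gene_id']}\n")


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start": df["start"] + 1,
            "end": df["end"],
        }
    )
    return out


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in library.pathways.items():
            fh.write(name + "\t" + library.library_name + "\t" + "\t".join(sorted(genes)) + "\n")


def read_gmt(path: str | Path, library_name: str | None = None) -> GeneSetLibrary:
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line in {path.name}: {line[:80]!r}")
            pathways[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GeneSetLibrary(library_name=library_name or path.stem, pathways=pathways)


# ---------------------------------------------------------------------------
# summary statistics / LD scores

_SUMSTAT_HEADER = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "Z"]
_RENAME = {
    "SNP": "id", "CHR": "chrom", "BP": "pos", "A1": "effect_allele",
    "A2": "other_allele", "BETA": "beta", "SE": "se", "P": "p", "N": "n", "Z": "z",
}


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    """Fixed-header TSV: SNP CHR BP A1 A2 BETA SE P N Z."""
    inv = {v: k for k, v in _RENAME.items()}
    out = sumstats.rename(columns=inv)
    out[[c for c in _SUMSTAT_HEADER if c in out.columns]].to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistic TSV; tolerates extra columns and gzip."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"CHR": str})
    required = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file missing columns: {missing}")
    keep = [c for c in _SUMSTAT_HEADER if c in df.columns]
    out = df[keep].rename(columns=_RENAME)
    if "z" not in out.columns:
        out["z"] = out["beta"] / out["se"]
    if "n" not in out.columns:
        out["n"] = np.nan
    return out[["id", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "se", "p", "z", "n"]]


def write_ld_scores(ld: pd.DataFrame, path: str | Path) -> None:
    out = ld.rename(columns={"id": "SNP", "chrom": "CHR", "pos": "BP", "l2": "L2"})
    out[["SNP", "CHR", "BP", "L2"]].to_csv(path, sep="\t", index=False)


def read_ld_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    return df.rename(columns={"SNP": "id", "CHR": "chrom", "BP": "pos", "L2": "l2"})


# ---------------------------------------------------------------------------
# plotting


def plot_prevalence(
    table_34: pd.DataFrame, table_4: pd.DataFrame, path: str | Path
) -> None:
    """Two-panel bar plot of severe-balding prevalence by age group,
    hospitalised men vs the general male population, one panel per severity
    definition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, table, title in (
        (axes[0], table_34, "severe = patterns 3+4"),
        (axes[1], table_4, "severe = pattern 4"),
    ):
        x = np.arange(len(table))
        ax.bar(x - 0.2, table["prev_hospitalized"], width=0.4, label="hospitalized")
        ax.bar(x + 0.2, table["prev_general"], width=0.4, label="general population")
        ax.set_xticks(x, table["age_bin"], rotation=45)
        ax.set_title(title)
        ax.set_xlabel("age group")
    axes[0].set_ylabel("prevalence of severe AGA")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
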