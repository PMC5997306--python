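"""Readers and writers for the tabular formats used across the pipeline.

Tab-separated tables carry a header line. VCF input goes through cyvcf2:
per-bulk read counts come from per-sample AD fields (two samples = two
bulks) and genotype matrices from GT fields. Candidate regions are written
as BED, converting the package's 1-based half-open window coordinates to
BED's 0-based half-open convention (start-1, end-1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bsaqtl.simulate import F2Population

__all__ = [
    "read_bulk_counts",
    "write_bulk_counts",
    "read_bulk_counts_vcf",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_genotype_matrix_vcf",
    "read_trait_table",
    "write_trait_table",
    "write_windows",
    "write_regions_bed",
    "write_phenotypes",
]

COUNT_COLUMNS = ["chrom", "pos", "ref_count", "alt_count", "depth"]


def write_bulk_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def read_bulk_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(COUNT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"counts table lacks columns {sorted(missing)}")
    if "depth" not in df.columns:
        df["depth"] = df["ref_count"] + df["alt_count"]
    return df


def read_bulk_counts_vcf(path, samples: tuple[str, str] | None = None):
    """Two per-bulk count tables from a VCF with per-sample AD fields.

    Returns ``(counts_first, counts_second)`` in the order of ``samples``
    (default: the first two samples in the header). Multi-allelic records
    use the first alternative allele's depth.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    if samples is None:
        samples = tuple(names[:2])
    idx = [names.index(s) for s in samples]
    rows: list[list] = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            continue
        rec = [v.CHROM, v.POS]
        for i in idx:
            ref, alt = int(ad[i][0]), int(ad[i][1])
            ref, alt = max(ref, 0), max(alt, 0)  # cyvcf2 encodes missing as negative
            rec.extend([ref, alt])
        rows.append(rec)
    cols = ["chrom", "pos", "ref_0", "alt_0", "ref_1", "alt_1"]
    df = pd.DataFrame(rows, columns=cols)
    out = []
    for i in range(2):
        c = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos"],
                "ref_count": df[f"ref_{i}"],
                "alt_count": df[f"alt_{i}"],
            }
        )
        c["depth"] = c["ref_count"] + c["alt_count"]
        out.append(c)
    return out[0], out[1]


def write_genotype_matrix(pop: F2Population, path, ids: list | None = None) -> None:
    """Individuals x markers dosage matrix as TSV (markers chrom:pos columns)."""
    m = pop.genetic_map.markers
    cols = [f"{c}:{p}" for c, p in zip(m["chrom"], m["pos"])]
    df = pd.DataFrame(pop.genotypes, columns=cols)
    df.insert(0, "individual", ids if ids is not None else np.arange(pop.n))
    df.to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path) -> pd.DataFrame:
    """Accessions x SNPs dosage matrix from TSV (first column = identifier)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_genotype_matrix_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage matrix (accessions x SNPs) plus SNP info from VCF GT fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, info = [], []
    for v in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = v.gt_types.astype(float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        dosages.append(col)
        info.append({"snp": v.ID or f"{v.CHROM}:{v.POS}", "chrom": v.CHROM, "pos": v.POS})
    info_df = pd.DataFrame(info)
    G = pd.DataFrame(
        np.column_stack(dosages) if dosages else np.empty((len(samples), 0)),
        index=samples,
        columns=info_df["snp"] if len(info_df) else None,
    )
    return G, info_df


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "trait", "condition", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table lacks columns {sorted(missing)}")
    return df


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_phenotypes(phenotypes: np.ndarray, path, trait: str = "trait") -> None:
    pd.DataFrame(
        {"individual": np.arange(len(phenotypes)), "trait": trait, "value": phenotypes}
    ).to_csv(path, sep="\t", index=False)


def write_windows(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Candidate regions as BED3+ (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"] - 1,
            "end": regions["end"] - 1,
            "name": [f"region_{i + 1}" for i in range(len(regions))],
            "score": regions["peak_delta"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False, float_format="%.4f")
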