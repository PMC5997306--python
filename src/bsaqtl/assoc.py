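"""GWAS post-processing: scan, thresholding, clumping, QTL flags.

The single-marker scan is deliberately plain ordinary-least-squares
plumbing (phenotype on allele dosage, one SNP at a time) so the
post-processing chain can run end to end on synthetic data; it does not
correct for kinship or population structure the way a mixed linear model
would. The downstream steps are the contract of this module: a p <= 1e-4
significance threshold, single-linkage clumping of significant SNPs within
200 kb into QTL, four importance flags, and the peak-minus-one-log-unit
candidate-SNP window used for gene-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from bsaqtl.errors import DataError

__all__ = [
    "QtlRegion",
    "single_marker_scan",
    "significant_snps",
    "clump_qtl",
    "flag_important_qtl",
    "candidate_snp_set",
    "qtl_names",
]

P_FLOOR = 1e-300  # keeps -log10(p) finite on numerically perfect fits


def single_marker_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    info: pd.DataFrame | None = None,
    trait: str = "trait",
    condition: str = "stress",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-SNP OLS regression of phenotype on allele dosage.

    ``genotypes`` is accessions x SNPs with dosage codes 0/1/2 (NaN
    missing); ``info`` optionally supplies ``snp``, ``chrom``, ``pos``
    columns. Reports the F-test p-value, the allele effect signed with
    respect to the minor allele, the minor-allele frequency, and the
    variance explained (R^2). SNPs that are monomorphic or have fewer than
    ``min_n`` complete pairs come out missing.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if G.ndim != 2 or G.shape[0] != y.size:
        raise DataError("genotype matrix and phenotype length mismatch")
    mask = ~np.isnan(G) & ~np.isnan(y)[:, None]
    Gm = np.where(mask, G, 0.0)
    ym = np.where(mask, y[:, None], 0.0)
    n = mask.sum(axis=0).astype(float)
    sx = Gm.sum(axis=0)
    sy = ym.sum(axis=0)
    sxx = (Gm * Gm).sum(axis=0)
    syy = (ym * ym).sum(axis=0)
    sxy = (Gm * ym).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        cov = n * sxy - sx * sy
        slope = cov / vx
        r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), np.nan)
        df = n - 2
        f_stat = r2 / (1.0 - r2) * df
        p = stats.f.sf(f_stat, 1, df)
        p = np.where(np.isposinf(f_stat), 0.0, p)
        freq = sx / (2.0 * n)
    bad = (n < min_n) | (vx <= 0)
    flip = freq > 0.5
    maf = np.where(flip, 1.0 - freq, freq)
    effect = np.where(flip, -slope, slope)
    p = np.maximum(p, P_FLOOR)
    for arr in (p, maf, effect, r2):
        arr[bad] = np.nan
    out = pd.DataFrame(
        {
            "snp": info["snp"].to_numpy() if info is not None and "snp" in info else np.arange(G.shape[1]),
            "chrom": info["chrom"].to_numpy() if info is not None else "chr0",
            "pos": info["pos"].to_numpy() if info is not None else np.arange(1, G.shape[1] + 1),
            "trait": trait,
            "condition": condition,
            "n": n.astype(int),
            "maf": maf,
            "effect": effect,
            "p": p,
            "r2": r2,
        }
    )
    out["neg_log10_p"] = -np.log10(out["p"])
    return out


def significant_snps(table: pd.DataFrame, alpha: float = 1.0e-4) -> pd.DataFrame:
    """Records with p <= alpha (boundary inclusive); missing p drops out."""
    return table[table["p"] <= alpha].reset_index(drop=True)


@dataclass
class QtlRegion:
    """A clump of significant SNPs for one trait on one chromosome."""

    trait: str
    chrom: str
    start: int
    end: int
    members: pd.DataFrame = field(repr=False)

    @property
    def peak(self) -> pd.Series:
        """Minimum-p member; leftmost position on ties."""
        m = self.members.sort_values(["p", "pos"], kind="stable")
        return m.iloc[0]

    @property
    def conditions(self) -> set[str]:
        return set(self.members["condition"])


def clump_qtl(significant: pd.DataFrame, max_gap: int = 200_000) -> list[QtlRegion]:
    """Single-linkage chaining of significant SNPs into QTL.

    Consecutive SNPs on one chromosome at most ``max_gap`` bp apart join
    the same QTL; the region spans the outermost member positions. All
    records must belong to one trait (conditions may differ).
    """
    if len(significant) == 0:
        return []
    traits = set(significant["trait"])
    if len(traits) > 1:
        raise ValueError(f"clump one trait at a time, got {sorted(traits)}")
    trait = traits.pop()
    regions: list[QtlRegion] = []
    for chrom, grp in significant.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk in np.split(np.arange(len(grp)), breaks):
            members = grp.iloc[chunk].reset_index(drop=True)
            regions.append(
                QtlRegion(
                    trait=trait,
                    chrom=chrom,
                    start=int(members["pos"].min()),
                    end=int(members["pos"].max()),
                    members=members,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int, slop: int = 0) -> bool:
    return a_start <= b_end + slop and b_start <= a_end + slop


def flag_important_qtl(
    regions: list[QtlRegion],
    known_loci: list[tuple[str, int, int]] | None = None,
    near_bp: int = 300_000,
) -> pd.DataFrame:
    """Importance flags over QTL pooled across traits and conditions.

    Per region: ``multi_trait`` (bp-overlap with a QTL of another trait),
    ``both_conditions`` (significant under control and stress with the
    same peak effect sign), ``ratio_significant`` (significant for the
    stress/control ratio trait), ``near_known_locus`` (within ``near_bp``
    of a known locus interval). A region is ``important`` when at least
    two flags hold.
    """
    known_loci = known_loci or []
    rows = []
    for i, r in enumerate(regions):
        multi = any(
            o.trait != r.trait and o.chrom == r.chrom and _overlaps(r.start, r.end, o.start, o.end)
            for o in regions
        )
        both = False
        if {"control", "stress"}.issubset(r.conditions):
            signs = []
            for cond in ("control", "stress"):
                sub = r.members[r.members["condition"] == cond]
                best = sub.sort_values(["p", "pos"], kind="stable").iloc[0]
                signs.append(np.sign(best["effect"]))
            both = signs[0] == signs[1] != 0
        ratio = "ratio" in r.conditions
        near = any(
            r.chrom == chrom and _overlaps(r.start, r.end, s, e, slop=near_bp)
            for chrom, s, e in known_loci
        )
        flags = [multi, both, ratio, near]
        rows.append(
            {
                "trait": r.trait,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "peak_p": float(r.peak["p"]),
                "multi_trait": multi,
                "both_conditions": both,
                "ratio_significant": ratio,
                "near_known_locus": near,
                "important": sum(flags) >= 2,
            }
        )
    return pd.DataFrame(rows)


def candidate_snp_set(region: QtlRegion, window: float = 1.0) -> pd.DataFrame:
    """Members within ``window`` -log10(p) units of the region's peak.

    These are the SNPs carried into gene-level (non-synonymous/haplotype)
    analysis; the boundary is inclusive.
    """
    peak_score = float(region.members["neg_log10_p"].max())
    keep = region.members["neg_log10_p"] >= peak_score - window
    return region.members[keep].reset_index(drop=True)


def qtl_names(regions: list[QtlRegion]) -> list[str]:
    """Trait+chromosome names with a/b suffixes by position order (qSdw3a style)."""

    def chrom_tag(chrom: str) -> str:
        digits = "".join(ch for ch in chrom if ch.isdigit())
        return digits or chrom

    base = [f"q{r.trait.capitalize()}{chrom_tag(r.chrom)}" for r in regions]
    names = []
    for i, b in enumerate(base):
        dup = [j for j, bb in enumerate(base) if bb == b]
        if len(dup) == 1:
            names.append(b)
        else:
            order = sorted(dup, key=lambda j: regions[j].start)
            names.append(b + "abcdefgh"[order.index(i)])
    return names
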