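"""Candidate-gene analysis: variant filters, haplotypes, ANOVA, codon effects.

Given a genotype matrix over a candidate gene's SNPs, the pipeline filters
variants by missingness and minor-allele frequency, groups inbred
accessions into haplotypes by their joint allele string over the selected
(typically non-synonymous) SNPs, compares trait means across the major
haplotypes with one-way ANOVA plus a Tukey compact letter display, and
annotates individual substitutions at codon level against a gene model.
A 2^-ddCt utility covers qPCR relative-expression worked examples.

Genotype codes throughout: 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternative, NaN = missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from bsaqtl.errors import ConfigurationError, DataError

__all__ = [
    "GeneModel",
    "VariantEffect",
    "HaplotypeGroup",
    "HaplotypeAnova",
    "filter_variants",
    "build_haplotypes",
    "major_haplotypes",
    "haplotype_anova",
    "annotate_variant",
    "relative_expression",
    "synthetic_al_transporter_gene",
]


@dataclass
class GeneModel:
    """Exon/CDS structure of one gene plus its coding sequence.

    ``exons`` and ``cds`` are 1-based inclusive genomic intervals in
    ascending genomic order; ``cds_seq`` is the spliced coding sequence on
    the coding strand, 5'->3' from the A of ATG.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    cds_seq: str = field(repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ConfigurationError(f"strand must be + or -, got {self.strand!r}")
        for intervals, what in ((self.exons, "exons"), (self.cds, "CDS")):
            prev_end = 0
            for s, e in intervals:
                if s > e or s <= prev_end:
                    raise ConfigurationError(f"{what} not ordered/non-overlapping")
                prev_end = e
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if cds_len != len(self.cds_seq):
            raise ConfigurationError("CDS intervals and sequence length differ")
        if cds_len % 3 != 0:
            raise ConfigurationError("CDS length not divisible by 3")
        if not self.cds_seq.upper().startswith("ATG"):
            raise ConfigurationError("CDS does not start with ATG")

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS coordinate of a genomic position, or None outside the CDS."""
        offset = 0
        intervals = self.cds if self.strand == "+" else list(reversed(self.cds))
        for s, e in intervals:
            if s <= pos <= e:
                within = (pos - s + 1) if self.strand == "+" else (e - pos + 1)
                return offset + within
            offset += e - s + 1
        return None

    @classmethod
    def from_gff3(cls, gff_path: str, fasta_path: str, gene_id: str) -> "GeneModel":
        """Build a model from a GFF3 annotation and a genome FASTA."""
        import gffutils
        from pyfaidx import Fasta

        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        gene = db[gene_id]
        exons = sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        if not exons:
            exons = list(cds)
        fa = Fasta(str(fasta_path))
        pieces = [str(fa[gene.seqid][s - 1 : e]) for s, e in cds]
        seq = "".join(pieces).upper()
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return cls(gene_id, gene.seqid, gene.strand, exons, cds, seq)


@dataclass
class VariantEffect:
    """Codon-level consequence of a single-nucleotide substitution."""

    cds_pos: int | None
    codon_index: int | None
    codon_pos: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    consequence: str


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def annotate_variant(
    model: GeneModel,
    position: int,
    ref: str,
    alt: str,
    coords: str = "genomic",
) -> VariantEffect:
    """Annotate a substitution against a gene model using the standard code.

    ``coords='genomic'`` positions are mapped into the CDS; for a
    minus-strand gene the ref/alt bases are complemented onto the coding
    strand first. ``coords='cds'`` positions count 1-based from the A of
    ATG with bases already on the coding strand. Positions outside the CDS
    are annotated ``non_coding``; a reference base that contradicts the
    model's sequence raises :class:`DataError`.
    """
    if coords == "genomic":
        cds_pos = model.genomic_to_cds(position)
        if cds_pos is None:
            return VariantEffect(None, None, None, None, None, None, None, "non_coding")
        if model.strand == "-":
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
    elif coords == "cds":
        if not 1 <= position <= len(model.cds_seq):
            return VariantEffect(None, None, None, None, None, None, None, "non_coding")
        cds_pos = position
    else:
        raise ValueError(f"coords must be 'genomic' or 'cds', got {coords!r}")

    ref, alt = ref.upper(), alt.upper()
    seq = model.cds_seq.upper()
    if seq[cds_pos - 1] != ref:
        raise DataError(
            f"reference base mismatch at CDS {cds_pos}: model has "
            f"{seq[cds_pos - 1]}, input says {ref}"
        )
    codon_index = (cds_pos - 1) // 3 + 1
    codon_pos = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = seq[start : start + 3]
    alt_codon = ref_codon[: codon_pos - 1] + alt + ref_codon[codon_pos:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "nonsense"
    else:
        consequence = "missense"
    return VariantEffect(
        cds_pos, codon_index, codon_pos, ref_codon, alt_codon, ref_aa, alt_aa, consequence
    )


def filter_variants(
    genotypes: pd.DataFrame, max_missing: float = 0.20, min_maf: float = 0.05
) -> pd.DataFrame:
    """Keep SNPs with missing rate <= max_missing and MAF >= min_maf.

    ``genotypes`` is accessions x SNPs with dosage codes; heterozygotes
    contribute one allele of each kind to the frequency.
    """
    G = genotypes.to_numpy(dtype=float)
    n_missing = np.isnan(G).sum(axis=0)
    miss_rate = n_missing / G.shape[0]
    n_called = G.shape[0] - n_missing
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(G, axis=0) / (2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (miss_rate <= max_missing) & (maf >= min_maf)
    keep &= n_called > 0
    return genotypes.loc[:, keep]


@dataclass
class HaplotypeGroup:
    """Accessions sharing one allele string over the selected SNPs."""

    haplotype: str
    members: list

    @property
    def n(self) -> int:
        return len(self.members)


def build_haplotypes(
    genotypes: pd.DataFrame,
    alleles: pd.DataFrame | None = None,
    het_as_missing: bool = True,
) -> list[HaplotypeGroup]:
    """Group complete-case accessions by their joint allele string.

    Accessions with any missing call — and, by default, any heterozygous
    call, appropriate for inbred accessions — are excluded. ``alleles``
    optionally maps each SNP column to ``ref``/``alt`` bases used to spell
    the haplotype; otherwise dosage digits are used. Groups are returned
    in descending size order (ties by haplotype string).
    """
    if genotypes.shape[1] == 0:
        raise ValueError("no SNPs selected for haplotype construction")
    G = genotypes.to_numpy(dtype=float)
    bad = np.isnan(G).any(axis=1)
    if het_as_missing:
        bad |= (G == 1).any(axis=1)
    complete = genotypes.index[~bad]
    Gc = G[~bad]
    groups: dict[str, list] = {}
    for acc, row in zip(complete, Gc):
        if alleles is not None:
            letters = [
                alleles.loc[snp, "alt"] if code == 2 else alleles.loc[snp, "ref"]
                if code == 0
                else "H"
                for snp, code in zip(genotypes.columns, row)
            ]
        else:
            letters = [str(int(code)) for code in row]
        groups.setdefault("".join(letters), []).append(acc)
    out = [HaplotypeGroup(h, members) for h, members in groups.items()]
    out.sort(key=lambda g: (-g.n, g.haplotype))
    return out


def major_haplotypes(groups: list[HaplotypeGroup], min_n: int = 10) -> list[HaplotypeGroup]:
    """Haplotype groups with strictly more than ``min_n`` members."""
    return [g for g in groups if g.n > min_n]


def _letter_display(names: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-absorb compact letter display from significant pairs."""
    classes: list[set[str]] = [set(names)]
    for a, b in different:
        for cls in [c for c in classes if a in c and b in c]:
            classes.remove(cls)
            classes.extend([cls - {a}, cls - {b}])
        # absorb classes contained in another
        classes = [c for c in classes if c and not any(c < d for d in classes)]
    # stable letter order: by best (first) member appearance
    classes.sort(key=lambda c: min(names.index(m) for m in c))
    letters = {name: "" for name in names}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for name in names:
            if name in cls:
                letters[name] += letter
    return letters


@dataclass
class HaplotypeAnova:
    f: float
    p: float
    means: dict[str, float]
    counts: dict[str, int]
    letters: dict[str, str]


def haplotype_anova(
    groups: list[HaplotypeGroup],
    trait: pd.Series,
    alpha: float = 0.01,
) -> HaplotypeAnova:
    """One-way fixed-effects ANOVA of a trait across haplotype groups.

    ``trait`` is indexed by accession; accessions without a trait value are
    dropped. Pairwise Tukey HSD comparisons at ``alpha`` yield compact
    letter groupings (groups sharing a letter do not differ significantly).
    Requires at least two groups with two or more phenotyped members and a
    non-degenerate trait.
    """
    samples, names = [], []
    for g in groups:
        vals = trait.reindex(g.members).dropna().to_numpy(dtype=float)
        if vals.size >= 2:
            samples.append(vals)
            names.append(g.haplotype)
    if len(samples) < 2:
        raise ValueError("need >= 2 haplotype groups with >= 2 phenotyped members")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise ValueError("trait has zero variance across haplotype groups")
    f, p = stats.f_oneway(*samples)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
    order = sorted(range(len(names)), key=lambda i: -np.mean(samples[i]))
    ordered_names = [names[i] for i in order]
    different: set[tuple[str, str]] = set()
    if len(names) >= 2:
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            if bool(row["reject"]):
                different.add((str(row["group1"]), str(row["group2"])))
                different.add((str(row["group2"]), str(row["group1"])))
    letters = _letter_display(ordered_names, different)
    return HaplotypeAnova(
        f=float(f),
        p=float(p),
        means={n: float(np.mean(s)) for n, s in zip(names, samples)},
        counts={n: int(len(s)) for n, s in zip(names, samples)},
        letters=letters,
    )


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """qPCR fold change by the 2^-ddCt method.

    ddCt = (Ct_target,sample - Ct_ref,sample) -
    (Ct_target,calibrator - Ct_ref,calibrator).
    """
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))


def synthetic_al_transporter_gene(seed: int = 2018) -> GeneModel:
    """Synthetic stand-in for a 13-exon, minus-strand Al-transporter gene.

    Deterministically generates a 4069 bp gene with 13 exons whose spliced
    CDS encodes 554 amino acids (plus stop), with codon 104 fixed to GCC
    (Ala) so that the middle base — CDS position 311 from the A of ATG —
    recreates the worked missense example (GCC -> GAC, Ala -> Asp). The
    sequence is synthetic: only the structure (exon count, lengths, strand,
    the codon-104 context) mirrors the real gene.
    """
    rng = np.random.default_rng(seed)
    codons = [
        c
        for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
        if c not in ("TAA", "TAG", "TGA", "ATG")
    ]
    n_codons = 555  # 554 residues + stop
    body = rng.choice(codons, size=n_codons)
    body[0] = "ATG"
    body[103] = "GCC"  # codon 104
    body[-1] = "TGA"
    cds_seq = "".join(body)  # 1665 bp, coding strand

    exon_lengths = [128] * 12 + [129]  # sums to 1665
    intron_lengths = [201] * 4 + [200] * 8  # sums to 2404 -> gene span 4069
    start = 1_000_001
    cds = []
    g = start
    for i, el in enumerate(exon_lengths):
        cds.append((g, g + el - 1))
        g += el
        if i < len(intron_lengths):
            g += intron_lengths[i]
    return GeneModel(
        gene_id="synthetic_nramp_al_transporter",
        chrom="chr2",
        strand="-",
        exons=list(cds),
        cds=cds,
        cds_seq=cds_seq,
    )
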