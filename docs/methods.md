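# Methods

## The mapping problem

A major locus segregates in an F2 between two inbred parents: PR (tolerant,
carrying reference-like alleles throughout) and PS (susceptible, carrying
the alternative allele at every polymorphic site). Susceptibility is
recessive: only PS/PS homozygotes lose the major-effect amount of the
trait. Pooled sequencing of the two phenotypic extremes turns linkage into
allele-frequency skew: the susceptible bulk is almost pure PS/PS near the
locus (SNP-index → 1 with alt = PS allele), while the tolerant bulk is a
2:1 mixture of heterozygotes and PR/PS homozygote-free genotypes
(SNP-index → 1/3). Away from the locus both bulks are random samples of
the F2 and the expected index is 0.5.

## Simulator

Meiosis follows the Haldane model: crossovers form a Poisson process on the
cM scale, so the recombination fraction between adjacent markers d cM
apart is r = (1 − e^(−2d/100))/2 and gametes are generated as two-state
Markov chains along each chromosome (no interference). An F2 individual is
the sum of two independent gametes; genotype codes count PS alleles
(0/1/2).

The phenotype is `baseline − effect·I + polygenic + noise`, with I the
recessive indicator (code 2) or the additive dosage/2. The polygenic term
sums Gaussian effects over 40 evenly spread non-causal markers and is
empirically rescaled so its population standard deviation equals
`polygenic_sd`. Defaults — effect 6, polygenic sd 1, noise sd 1, baseline
10 (trait units, e.g. cm of root length under stress) — put roughly
three-quarters of the phenotypic variance on the major locus and produce
the continuous, weakly bimodal F2 distribution the design assumes.
Study-scale defaults elsewhere follow the experimental design: F2 of
~300–330, 20-individual extreme bulks, mean pooled depth 20×.

Pooled reads: per site the true alternative frequency f is the mean
genotype code over the bulk divided by two; depth ~ Poisson(mean depth);
alternative count ~ Binomial(depth, f(1−ε) + (1−f)ε) for base error ε.
Depth-0 draws are recorded and treated as missing. One seed feeds
independent `SeedSequence` substreams for meiosis, phenotype and each
bulk's reads, so every downstream number is reproducible bit for bit.

What the simulator does not emulate: read alignment and mapping artefacts,
base-quality structure, indels and multi-allelic sites, segregation
distortion, uneven marker density, and residual heterozygosity in the
parents. Passing tests therefore demonstrate the statistics are computed
correctly under the idealised sampling model, not that real libraries are
free of alignment bias.

## ΔSNP-index orientation and two-sided calling

Δ is defined as index(BR) − index(BS), BR being the resistant bulk. With
the alternative allele fixed to the susceptible parent and susceptibility
recessive, the causal locus appears as a *negative* Δ (BR ≈ 1/3, BS ≈ 1).
In published data the sign depends on which parent happens to differ from
the reference genome at each site. Fixed-threshold region calling
therefore accepts `two_sided=True` to scan |Δ|; CI-mode calling is
two-sided by construction.

## Site filters

A site is removed iff (index < 0.3 in both bulks) or (depth < 7× in either
bulk) or (index missing in either bulk). The both-bulk reading of the
index clause discards sites that look like shared sequencing error while
keeping genuinely divergent sites that are low in only one bulk; the depth
clause applies per bulk. Each removal is logged with its reason(s).

## Windows and permutation intervals

Windows are half-open [start, start + window) anchored at start = 1 + j·step
(defaults 1 Mb / 1 kb), emitted out to the chromosome end (or last site),
with plain averages over contained non-missing sites; empty windows are
reported missing and split region runs. Window means are computed by prefix
sums, so profiles and permutation replicates cost O(sites + windows).

The permutation null redraws each site's alternative counts
Binomial(observed depth, 0.5) independently in both bulks — the F2
expectation with no selected locus, conditioned on the observed depths —
and windows each replicate exactly like the observed data (1000 replicates,
95% empirical quantiles per window by default; a pooled genome-wide
interval is available). Two-bulk counts admit no exchangeable labels
within a site, which is why the null is simulated rather than shuffled.
This null captures read-sampling noise but not the pooling variance of a
finite bulk, whose allele-frequency deviations are also correlated along
the chromosome; an optional `bulk_size` argument adds per-site binomial
bulk-composition resampling, but no per-site null can model the linkage
correlation. Consequently the CI is calibrated against read noise (the
test suite verifies ~5% exceedance when the generative truth matches the
null) and is anti-conservative against chromosome-scale bulk-composition
drift — one reason the fixed |Δ| ≥ 0.5 rule on 1 Mb means, far above read
noise, is the primary calling criterion.

Region calls report maximal runs of qualifying consecutive windows, the
leftmost maximal window as peak, and plain means of the window means per
bulk. BED output converts the 1-based half-open spans to BED's 0-based
half-open convention.

## Association post-processing

The per-SNP scan is ordinary least squares of phenotype on allele dosage
(closed form, F-test with 1 df), reporting the effect signed with respect
to the minor allele, MAF, and R². It deliberately omits kinship/PC
correction — the scan exists as plumbing so thresholding (p ≤ 1×10⁻⁴,
boundary inclusive), 200 kb single-linkage clumping, importance flags
(multi-trait overlap; control+stress with equal effect sign;
ratio-significant; near a known locus; "important" = any two), and the
peak−1 −log₁₀(p) candidate-SNP window can run end to end on synthetic
data. P-values are floored at 1e-300 so −log₁₀(p) stays finite on
numerically perfect fits. Both inclusive boundaries (p ≤ α, ≥ peak−1) are
deliberate: deterministic and conservative toward retention.

## Phenotyping pipeline order

Outlier trimming (|v − mean| ≤ 3·sd computed once per trait × condition
across accessions, boundary kept, no re-iteration) is applied to raw
replicate values; replicates are then averaged; derived traits (SWC from
averaged SFW/SDW, stress tolerance index from averaged stress/control)
come last. Trimming before averaging lets a single aberrant replicate be
dropped without discarding the accession.

## Haplotype analysis

Variant filters: missing rate ≤ 20% and MAF ≥ 5%, with heterozygotes
contributing one allele of each kind. Haplotypes are exact allele strings
over the selected (typically non-synonymous) SNPs; accessions with missing
— and, by default, heterozygous — calls are excluded, reflecting inbred
material. "Major" haplotypes have strictly more than 10 members. Group
trait means are compared by one-way fixed-effects ANOVA; pairwise Tukey
HSD at α = 0.01 (configurable) feeds an insert-absorb compact letter
display.

## Variant annotation

Gene models carry 1-based inclusive exon/CDS intervals in genomic order
plus the spliced coding sequence (must start ATG, length divisible by 3);
they load from GFF3 + FASTA or are constructed directly. Genomic positions
map into CDS coordinates; on minus-strand genes the input ref/alt bases
are complemented onto the coding strand before comparison, which is what
reconciles a genomic G→T call with a GCC→GAC codon change. Consequences
are synonymous / missense / nonsense by the standard genetic code;
positions outside the CDS annotate as non-coding, and a reference-base
mismatch is a hard data error. The bundled
`synthetic_al_transporter_gene()` is a synthetic stand-in — 13 exons,
minus strand, 554 residues, 4069 bp span, codon 104 fixed to GCC — built
so the codon-level worked example is reproducible without genome data.

## LOD scan

Single-marker regression LOD on genotype-class means:
LOD = (n/2)·log₁₀(RSS₀/RSS₁), with RSS₁ from the three class means
(additive + dominance) and RSS₀ from the grand mean; markers lacking two
classes with ≥2 members are missing, constant phenotypes give 0, perfect
class separation gives +inf. Interval mapping is intentionally out of
scope: with a dense validation panel the peak marker is the inference.
Selective genotyping of extremes inflates LOD; values are for ranking and
are documented as such, not bias-corrected.

## Problem sizes in the test and acceptance suites

Simulated experiments run on two 40 Mb chromosomes (rice-like 4 cM/Mb)
with 200–800 markers per chromosome, window steps of 10–100 kb, 300–330
individuals, bulks of 20, depth 20×, and 40-seed replication for recovery
properties — small enough to execute in seconds while leaving dozens of
sites per window and clear recombination structure. Two deliberate
configuration choices in those checks: the unlinked-chromosome calibration
of the mean SNP-index sets the polygenic sd to zero so the second
chromosome truly carries no causal variation (and averages 48 replicate
experiments, since a single 20-individual bulk's chromosome-average allele
frequency has ~0.05 Monte Carlo sd); and the LOD validation panel spaces
its 11 markers ~1 Mb (4 cM) apart, because markers much closer than the
recombination resolution of 186 extremes are statistically
indistinguishable from the causal one, making "the peak lands at the
nearest marker" ill-posed at denser spacing.

## Known limitations

- The permutation CI does not model linked bulk-composition drift (above).
- The OLS scan is uncorrected for population structure; on structured
  panels its p-values are anti-conservative and only the post-processing
  contract should be relied on.
- The 1:2:1-based null and the read model assume diploid biparental F2
  material; other designs (backcross, RILs, multi-parent) are out of scope.
- Haplotype letter displays use the naive insert-absorb algorithm, which
  can emit more letters than the minimal display for many groups.
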