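"""Simulation of an F2 biparental cross and pooled short-read allele counts.

The simulator produces the statistical structure that bulked-segregant
(QTL-seq) mapping assumes: two fully homozygous inbred parents (PR, the
tolerant parent, carries the reference-like allele everywhere; PS, the
susceptible parent, the alternative allele), an F2 generation formed from
independent recombinant gametes, a continuous phenotype controlled by one
major locus plus polygenic background and noise, extreme-phenotype bulks,
and per-site read counts from pooled sequencing of each bulk.

Genotype codes: 0 = homozygous PR, 1 = heterozygous, 2 = homozygous PS.
Crossovers follow a Haldane (no-interference) model: recombination
probability between adjacent markers d cM apart is (1 - exp(-2d/100))/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bsaqtl.errors import ConfigurationError

__all__ = [
    "GeneticMap",
    "TraitModel",
    "ReadModel",
    "F2Population",
    "simulate_f2",
    "simulate_phenotype",
    "select_bulks",
    "simulate_bulk_reads",
    "simulate_bsa_experiment",
]


@dataclass
class GeneticMap:
    """A genetic map: chromosome sizes plus marker positions in bp and cM.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs.
    markers
        DataFrame with columns ``chrom``, ``pos`` (1-based bp) and ``cm``.
        Positions must be strictly increasing and cM positions
        non-decreasing within each chromosome.
    """

    chromosomes: list[tuple[str, int]]
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if not lengths:
            raise ConfigurationError("map must contain at least one chromosome")
        for name, length in lengths.items():
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has length {length} <= 0")
        required = {"chrom", "pos", "cm"}
        if not required.issubset(self.markers.columns):
            raise ConfigurationError(f"markers need columns {sorted(required)}")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ConfigurationError(f"marker chromosome {chrom!r} not in map")
            pos = grp["pos"].to_numpy()
            cm = grp["cm"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(f"positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ConfigurationError(f"cM positions decrease on {chrom}")
            if pos[0] < 1 or pos[-1] > lengths[chrom]:
                raise ConfigurationError(f"marker outside chromosome {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 2,
        length_bp: int = 40_000_000,
        n_markers: int = 200,
        cm_per_mb: float = 4.0,
    ) -> "GeneticMap":
        """Evenly spaced markers on equal-sized chromosomes.

        The default 4 cM/Mb is the genome-wide average for rice
        (~1500 cM over ~370 Mb).
        """
        chroms = [(f"chr{i + 1}", length_bp) for i in range(n_chromosomes)]
        frames = []
        pos = np.linspace(1, length_bp, n_markers).round().astype(np.int64)
        pos = np.unique(pos)
        for name, _ in chroms:
            frames.append(
                pd.DataFrame(
                    {"chrom": name, "pos": pos, "cm": pos * cm_per_mb / 1e6}
                )
            )
        return cls(chroms, pd.concat(frames, ignore_index=True))


@dataclass
class TraitModel:
    """Genetic architecture of a simulated quantitative trait.

    The major locus sits at a map marker; under ``recessive`` mode only
    homozygous-PS individuals (code 2) lose ``major_effect`` trait units,
    matching a recessive susceptibility allele carried by PS. The polygenic
    term is a sum of small additive marker effects rescaled to
    ``polygenic_sd`` trait units.
    """

    causal_chrom: str = "chr1"
    causal_pos: int = 20_000_000
    mode: str = "recessive"
    major_effect: float = 6.0
    polygenic_sd: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("recessive", "additive"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.polygenic_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")


@dataclass
class ReadModel:
    """Pooled-sequencing read model: Poisson depth, symmetric base error."""

    mean_depth: float = 20.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must be in [0, 0.5)")


@dataclass
class F2Population:
    """Simulated F2 genotypes (individuals x markers) on a genetic map."""

    genetic_map: GeneticMap
    genotypes: np.ndarray  # int8, codes 0/1/2

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def marker_index(self, chrom: str, pos: int) -> int:
        m = self.genetic_map.markers
        hits = np.flatnonzero((m["chrom"] == chrom) & (m["pos"] == pos))
        if hits.size == 0:
            raise ConfigurationError(f"no marker at {chrom}:{pos}")
        return int(hits[0])


def _simulate_gametes(gmap: GeneticMap, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Parental-origin matrix (n_gametes x markers), entries 0 (PR) / 1 (PS)."""
    out = np.empty((n_gametes, gmap.n_markers), dtype=np.int8)
    col = 0
    for _, grp in gmap.markers.groupby("chrom", sort=False):
        m = len(grp)
        d = np.diff(grp["cm"].to_numpy())
        # Haldane: no crossover interference
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        start = rng.integers(0, 2, size=(n_gametes, 1))
        if m > 1:
            switch = rng.random((n_gametes, m - 1)) < r
            phase = np.cumsum(np.concatenate([start, switch], axis=1), axis=1) % 2
        else:
            phase = start
        out[:, col : col + m] = phase.astype(np.int8)
        col += m
    return out


def simulate_f2(gmap: GeneticMap, n: int, seed: int | np.random.SeedSequence = 0) -> F2Population:
    """Simulate ``n`` F2 individuals, each the union of two independent gametes.

    Each gamete is a recombinant mosaic of the two parental chromosomes with
    crossovers placed by the Haldane model on the cM scale. Genotype code is
    the number of PS alleles (0/1/2). Fully reproducible for a fixed seed.
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return F2Population(gmap, np.empty((0, gmap.n_markers), dtype=np.int8))
    gametes = _simulate_gametes(gmap, 2 * n, rng)
    geno = gametes[:n] + gametes[n:]
    return F2Population(gmap, geno.astype(np.int8))


def simulate_phenotype(
    pop: F2Population,
    model: TraitModel,
    seed: int | np.random.SeedSequence = 0,
    n_background: int = 40,
) -> np.ndarray:
    """Continuous phenotype: baseline - major effect + polygenic + noise.

    ``recessive`` mode subtracts ``major_effect`` only for genotype code 2
    (homozygous PS); ``additive`` mode subtracts proportionally to PS allele
    dosage. The polygenic term sums Gaussian effects at ``n_background``
    evenly spread non-causal markers, empirically rescaled so its standard
    deviation over the population equals ``polygenic_sd``.
    """
    if pop.n == 0:
        raise ConfigurationError("population is empty")
    causal = pop.marker_index(model.causal_chrom, model.causal_pos)
    rng = np.random.default_rng(seed)
    g_causal = pop.genotypes[:, causal].astype(float)
    if model.mode == "recessive":
        trigger = (g_causal == 2).astype(float)
    else:
        trigger = g_causal / 2.0

    poly = np.zeros(pop.n)
    if model.polygenic_sd > 0:
        candidates = np.setdiff1d(np.arange(pop.genotypes.shape[1]), [causal])
        if candidates.size:
            take = min(n_background, candidates.size)
            idx = candidates[np.linspace(0, candidates.size - 1, take).round().astype(int)]
            beta = rng.normal(size=idx.size)
            raw = (pop.genotypes[:, idx].astype(float) - 1.0) @ beta
            sd = raw.std()
            if sd > 0:
                poly = raw * (model.polygenic_sd / sd)
    noise = rng.normal(0.0, model.noise_sd, size=pop.n) if model.noise_sd > 0 else 0.0
    return model.baseline - model.major_effect * trigger + poly + noise


def select_bulks(phenotypes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the k largest (high bulk) and k smallest (low bulk) phenotypes.

    Ties are broken by ascending individual index; the bulks are disjoint.
    Returns ``(high, low)``.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    n = phenotypes.size
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds population size {n}")
    order = np.argsort(phenotypes, kind="stable")
    low = np.sort(order[:k])
    high = np.sort(order[n - k :]) if k else np.array([], dtype=np.intp)
    return high, low


def simulate_bulk_reads(
    pop: F2Population,
    bulk: np.ndarray,
    model: ReadModel,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Pooled read counts for one bulk at every map marker.

    At each site the true alternative-allele frequency is the mean genotype
    code over the bulk divided by 2; depth is Poisson(mean_depth) and the
    alternative count Binomial(depth, f(1-e) + (1-f)e) with base error e.
    Sites drawn at depth 0 keep a row with depth 0 (treated as missing
    downstream).
    """
    bulk = np.asarray(bulk, dtype=np.intp)
    if bulk.size == 0:
        raise ValueError("bulk is empty")
    rng = np.random.default_rng(seed)
    f = pop.genotypes[bulk].mean(axis=0) / 2.0
    depth = rng.poisson(model.mean_depth, size=f.size)
    p = f * (1.0 - model.error_rate) + (1.0 - f) * model.error_rate
    alt = rng.binomial(depth, p)
    m = pop.genetic_map.markers
    return pd.DataFrame(
        {
            "chrom": m["chrom"].to_numpy(),
            "pos": m["pos"].to_numpy(),
            "ref_count": depth - alt,
            "alt_count": alt,
            "depth": depth,
        }
    )


def simulate_bsa_experiment(
    gmap: GeneticMap,
    trait: TraitModel,
    reads: ReadModel,
    n: int = 330,
    k: int = 20,
    seed: int | np.random.SeedSequence = 0,
):
    """One full bulked-segregant experiment from a single seed.

    Simulates the F2, the phenotype, selects k-individual extreme bulks, and
    sequences both pools. The seed is split into independent substreams for
    meiosis, phenotype, and each bulk's reads, so fixing it fixes every
    downstream number. Returns ``(pop, phen, high, low, counts_high,
    counts_low)`` where the high bulk holds the k largest phenotypes.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_meiosis, s_phen, s_high, s_low = ss.spawn(4)
    pop = simulate_f2(gmap, n, s_meiosis)
    phen = simulate_phenotype(pop, trait, s_phen)
    high, low = select_bulks(phen, k)
    counts_high = simulate_bulk_reads(pop, high, reads, s_high)
    counts_low = simulate_bulk_reads(pop, low, reads, s_low)
    return pop, phen, high, low, counts_high, counts_low
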