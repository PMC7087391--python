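"""Forward-in-time simulation of genotypes and an additive quantitative trait.

The generator emulates the classical drift design used to benchmark
whole-genome regression: a small founder population is mated at random for
many non-overlapping generations so that linkage disequilibrium accrues
through drift, then a single expansion generation produces the analysis
cohort.  A random subset of loci act as QTL with normal effects, rescaled so
that the additive genetic variance of the final generation hits an exact
target, and phenotypes are formed by adding independent normal residuals to
reach a prescribed narrow-sense heritability.

Founders are synthetic: per-locus allele frequencies are drawn
Uniform(0.05, 0.95) and haplotype alleles Bernoulli(freq) independently per
locus.  Recombination follows a no-interference model with a
Poisson(chromosome length in Morgans) crossover count per meiosis and
uniformly placed crossovers; there is no mutation and no selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimConfig",
    "GenotypeData",
    "TraitData",
    "Population",
    "simulate_base_population",
    "random_mating",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "make_dataset",
    "simulate_dataset",
    "SimulatedDataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated breeding experiment.

    Defaults are the benchmark design: 100 founders, 100 generations of
    random mating at constant size, one expansion generation to 60,000
    individuals genotyped at ~42,000 markers, 5% of loci as QTL, genetic
    variance scaled to 1.0, heritability 0.3, and a 50,000/10,000
    train/test split.
    """

    n_founders: int = 100
    n_generations: int = 100
    n_final: int = 60_000
    p_loci: int = 42_000
    n_chromosomes: int = 10
    chromosome_length: float = 1.0  # Morgans
    qtl_fraction: float = 0.05
    target_genetic_variance: float = 1.0
    heritability: float = 0.3
    n_train: int = 50_000
    n_test: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.p_loci < 1:
            raise ValueError("need at least 2 founders and 1 locus")
        if self.n_final < 1:
            raise ValueError("n_final must be positive")
        if not 0.0 < self.qtl_fraction < 1.0:
            raise ValueError("qtl_fraction must be in (0, 1)")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if self.n_train + self.n_test > self.n_final:
            raise ValueError("n_train + n_test exceeds n_final")
        if self.n_chromosomes < 1 or self.chromosome_length < 0:
            raise ValueError("invalid genome configuration")


@dataclass
class GenotypeData:
    """An n x p matrix of additive marker codes (0/1/2 counts, or centered).

    ``kept_loci`` indexes the retained columns in the coordinate system of
    the original locus set, so QTL indices remain interpretable after
    monomorphic-locus removal.
    """

    ids: np.ndarray
    X: np.ndarray
    allele_freq: np.ndarray
    centered: bool = False
    kept_loci: np.ndarray | None = None
    col_means: np.ndarray | None = None
    marker_names: list[str] | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def centered_copy(self, means: np.ndarray | None = None) -> "GenotypeData":
        """Return a centered copy; ``means`` defaults to this matrix's column means.

        Passing training-set means centers a test matrix consistently with
        the training data.
        """
        if self.centered:
            raise ValueError("genotype matrix is already centered")
        m = self.X.mean(axis=0) if means is None else np.asarray(means, float)
        return replace(
            self,
            X=np.asarray(self.X, float) - m,
            centered=True,
            col_means=m,
        )


@dataclass
class TraitData:
    """Phenotypes plus simulation ground truth for one cohort."""

    y: np.ndarray
    bv: np.ndarray
    qtl_idx: np.ndarray
    qtl_effects: np.ndarray
    sigma2_e_sim: float

    def subset(self, idx: np.ndarray) -> "TraitData":
        return TraitData(self.y[idx], self.bv[idx],
                         self.qtl_idx, self.qtl_effects, self.sigma2_e_sim)


@dataclass
class Population:
    """Haplotypes of one generation: array (n_individuals, 2, p_loci) of 0/1.

    ``chrom_bounds`` gives the half-open slice of loci on each chromosome;
    ``positions`` the genetic-map position (Morgans) of every locus within
    its chromosome.  Loci are evenly spaced by construction.
    """

    haplotypes: np.ndarray
    chrom_bounds: list[tuple[int, int]]
    positions: np.ndarray
    chromosome_length: float
    founder_freq: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def p(self) -> int:
        return self.haplotypes.shape[2]

    def genotypes(self) -> np.ndarray:
        """0/1/2 allele counts, shape (n, p)."""
        return self.haplotypes.sum(axis=1, dtype=np.int64)


def _genome_layout(p_loci: int, n_chrom: int, length: float):
    """Split p loci as evenly as possible over chromosomes; evenly spaced map."""
    base, extra = divmod(p_loci, n_chrom)
    sizes = [base + (1 if c < extra else 0) for c in range(n_chrom)]
    bounds, pos, start = [], [], 0
    for m in sizes:
        bounds.append((start, start + m))
        if m:
            pos.append((np.arange(m) + 0.5) / m * length)
        start += m
    return bounds, np.concatenate(pos) if pos else np.empty(0)


def simulate_base_population(cfg: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Create founder haplotypes in linkage equilibrium.

    Per-locus founder allele frequencies are Uniform(0.05, 0.95); each of the
    2 * n_founders haplotype alleles at a locus is Bernoulli(freq).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    bounds, pos = _genome_layout(cfg.p_loci, cfg.n_chromosomes, cfg.chromosome_length)
    freq = rng.uniform(0.05, 0.95, size=cfg.p_loci)
    hap = (rng.random((cfg.n_founders, 2, cfg.p_loci)) < freq).astype(np.uint8)
    return Population(hap, bounds, pos, cfg.chromosome_length, founder_freq=freq)


def _gamete(hap_pair: np.ndarray, pop: Population, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, p) parental haplotype pair."""
    out = np.empty(pop.p, dtype=np.uint8)
    L = pop.chromosome_length
    for start, stop in pop.chrom_bounds:
        if stop == start:
            continue
        first = rng.integers(2)
        k = rng.poisson(L) if L > 0 else 0
        if k:
            cuts = np.sort(rng.uniform(0.0, L, size=k))
            src = (first + np.searchsorted(cuts, pop.positions[start:stop])) % 2
            seg = hap_pair[:, start:stop]
            out[start:stop] = np.where(src == 0, seg[0], seg[1])
        else:
            out[start:stop] = hap_pair[first, start:stop]
    return out


def _mate_generation(pop: Population, n_offspring: int, rng: np.random.Generator) -> Population:
    parents = rng.integers(0, pop.size, size=(n_offspring, 2))
    hap = np.empty((n_offspring, 2, pop.p), dtype=np.uint8)
    for i in range(n_offspring):
        hap[i, 0] = _gamete(pop.haplotypes[parents[i, 0]], pop, rng)
        hap[i, 1] = _gamete(pop.haplotypes[parents[i, 1]], pop, rng)
    return replace(pop, haplotypes=hap)


def random_mating(
    pop: Population,
    n_generations: int,
    final_size: int,
    rng: np.random.Generator,
) -> GenotypeData:
    """Random mating at constant size, then one expansion generation.

    Runs ``n_generations`` discrete generations keeping the population size
    fixed; if ``final_size`` differs from the current size, one additional
    generation of random mating produces ``final_size`` offspring.  With
    ``n_generations=0`` and ``final_size`` equal to the founder count the
    founders are returned unchanged.
    """
    if pop.size < 1:
        raise ValueError("empty population")
    if final_size < 1:
        raise ValueError("final_size must be >= 1")
    for _ in range(n_generations):
        pop = _mate_generation(pop, pop.size, rng)
    if final_size != pop.size:
        pop = _mate_generation(pop, final_size, rng)
    X = pop.genotypes()
    freq = X.mean(axis=0) / 2.0
    ids = np.array([f"id{i:06d}" for i in range(X.shape[0])])
    return GenotypeData(ids=ids, X=X.astype(np.float64), allele_freq=freq,
                        centered=False, kept_loci=np.arange(X.shape[1]))


def assign_qtl_effects(
    G: GenotypeData,
    qtl_fraction: float,
    target_var: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick QTL among segregating loci and scale their N(0,1) effects.

    The number of QTL is round(qtl_fraction * number of segregating loci).
    Raw effects are standard normal and then multiplied by one scalar so that
    the population variance (denominator n) of X_qtl @ effects over this
    generation equals ``target_var`` exactly.
    """
    seg = np.flatnonzero((G.allele_freq > 0.0) & (G.allele_freq < 1.0))
    if seg.size == 0:
        raise ValueError("no segregating locus available for QTL assignment")
    n_qtl = int(round(qtl_fraction * seg.size))
    n_qtl = max(n_qtl, 1)
    qtl_idx = np.sort(rng.choice(seg, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    bv_raw = G.X[:, qtl_idx] @ effects
    v = bv_raw.var()  # population variance, denominator n
    if v <= 0.0:
        raise ValueError("selected QTL carry zero genetic variance; cannot scale")
    effects = effects * np.sqrt(target_var / v)
    return qtl_idx, effects


def simulate_phenotypes(
    bv: np.ndarray,
    heritability: float,
    rng: np.random.Generator,
    qtl_idx: np.ndarray | None = None,
    qtl_effects: np.ndarray | None = None,
) -> TraitData:
    """Add iid normal residuals so that h2 = var(bv) / (var(bv) + sigma2_e)."""
    if not 0.0 < heritability < 1.0:
        raise ValueError("heritability must be in (0, 1)")
    vg = bv.var()
    if vg <= 0.0:
        raise ValueError("breeding values have zero variance")
    sigma2_e = vg * (1.0 - heritability) / heritability
    y = bv + rng.normal(0.0, np.sqrt(sigma2_e), size=bv.shape[0])
    return TraitData(
        y=y,
        bv=np.asarray(bv, float),
        qtl_idx=qtl_idx if qtl_idx is not None else np.empty(0, dtype=int),
        qtl_effects=qtl_effects if qtl_effects is not None else np.empty(0),
        sigma2_e_sim=float(sigma2_e),
    )


def make_dataset(
    G: GenotypeData,
    T: TraitData,
    n_train: int,
    n_test: int,
    rng: np.random.Generator,
) -> tuple[tuple[GenotypeData, TraitData], tuple[GenotypeData, TraitData]]:
    """Disjoint random train/test split with training-based filtering/centering.

    Loci monomorphic in the training set are dropped from both sets; both
    genotype matrices are centered with training column means.
    """
    n = G.n
    if n_train + n_test > n:
        raise ValueError("n_train + n_test exceeds cohort size")
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:n_train + n_test]

    Xtr = G.X[tr]
    freq_tr = Xtr.mean(axis=0) / 2.0
    keep = np.flatnonzero((freq_tr > 0.0) & (freq_tr < 1.0))
    means = Xtr[:, keep].mean(axis=0)

    def _geno(idx: np.ndarray) -> GenotypeData:
        return GenotypeData(
            ids=G.ids[idx],
            X=np.asarray(G.X[np.ix_(idx, keep)], float) - means,
            allele_freq=freq_tr[keep],
            centered=True,
            kept_loci=(G.kept_loci[keep] if G.kept_loci is not None else keep),
            col_means=means,
        )

    return (_geno(tr), T.subset(tr)), (_geno(te), T.subset(te))


@dataclass
class SimulatedDataset:
    """Train/test genotypes and traits plus the QTL truth used to build them."""

    train: tuple[GenotypeData, TraitData]
    test: tuple[GenotypeData, TraitData]
    full_genotypes: GenotypeData
    full_trait: TraitData
    config: SimConfig


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """End-to-end simulation: founders -> drift -> QTL -> phenotypes -> split.

    All randomness derives from ``cfg.seed`` through independent child
    streams, so an identical configuration reproduces the dataset bit for
    bit.
    """
    ss = np.random.SeedSequence(cfg.seed)
    r_base, r_mate, r_qtl, r_phen, r_split = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    pop = simulate_base_population(cfg, r_base)
    G = random_mating(pop, cfg.n_generations, cfg.n_final, r_mate)
    qtl_idx, effects = assign_qtl_effects(
        G, cfg.qtl_fraction, cfg.target_genetic_variance, r_qtl
    )
    bv = G.X[:, qtl_idx] @ effects
    T = simulate_phenotypes(bv, cfg.heritability, r_phen,
                            qtl_idx=qtl_idx, qtl_effects=effects)
    train, test = make_dataset(G, T, cfg.n_train, cfg.n_test, r_split)
    return SimulatedDataset(train=train, test=test, full_genotypes=G,
                            full_trait=T, config=cfg)
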