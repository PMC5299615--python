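"""Forward-in-time gene-dropping simulator (drift + recombination + mutation).

A monoecious random-mating population of Ne breeding individuals (2 Ne
haplotypes) is evolved for a configurable number of generations under the
standard neutral drift model: each offspring draws two parents uniformly
with replacement (selfing allowed), each transmitted gamete recombines
with a Poisson(chr_length) crossover count at uniform positions (Haldane,
no interference), and every site mutates (allele flip) independently at
the per-generation mutation rate.

Founder haplotypes start every site at allele frequency 0.5; the
subsequent generations of drift establish the equilibrium LD pattern and
allele-frequency spectrum that the closed-form Me theory assumes.  After
the last breeding generation, discovery and target samples are produced
as freshly bred offspring of the final population ("expansion sampling"),
so sample sizes may exceed Ne.

Phenotypes are built from a random causal subset of sites passing a MAF
filter: standardized causal dosages times normal effects, rescaled so the
causal variance is ``h2_sim`` of the total phenotypic variance, plus a
normal residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import GenotypeMatrix

__all__ = ["GenedropConfig", "GenedropResult", "simulate_genedrop", "run_genedrop"]


@dataclass(frozen=True)
class GenedropConfig:
    Ne: int = 100
    generations: int = 200
    n_sites: int = 2000
    n_chr: int = 1
    chr_length: float = 1.0
    mutation_rate: float = 1e-8
    maf_min: float = 0.01
    n_discovery: int = 500
    n_target: int = 250
    n_causal: int = 500
    h2_sim: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0.0 < self.h2_sim < 1.0:
            raise ValueError("h2_sim must be in (0, 1)")
        if self.n_causal > self.n_sites * self.n_chr:
            raise ValueError("n_causal exceeds total number of sites")


@dataclass
class GenedropResult:
    """Observed-genotype matrices cover every site passing the MAF filter;
    ``causal_sites``/``observed_sites`` index into the original site grid."""

    discovery: GenotypeMatrix
    target: GenotypeMatrix
    phenotypes: np.ndarray  # discovery phenotypes
    g_true_discovery: np.ndarray
    g_true_target: np.ndarray
    observed_sites: np.ndarray = field(default=None)  # type: ignore[assignment]
    causal_sites: np.ndarray = field(default=None)  # type: ignore[assignment]


def _gametes(
    haps: np.ndarray, parents: np.ndarray, chr_length: float, rng: np.random.Generator
) -> np.ndarray:
    """One recombined gamete per parent index, for one chromosome.

    ``haps`` has shape (n_individuals, 2, n_sites); sites are equally
    spaced over [0, chr_length].
    """
    n_sites = haps.shape[2]
    pos = np.linspace(0.0, chr_length, n_sites) if n_sites > 1 else np.zeros(1)
    out = np.empty((parents.size, n_sites), dtype=haps.dtype)
    n_cx = rng.poisson(chr_length, size=parents.size)
    starts = rng.integers(0, 2, size=parents.size)
    for g, (p, k, s) in enumerate(zip(parents, n_cx, starts)):
        if k == 0:
            out[g] = haps[p, s]
            continue
        cx = np.sort(rng.uniform(0.0, chr_length, size=k))
        which = (s + np.searchsorted(cx, pos, side="right")) % 2
        out[g] = np.where(which == 0, haps[p, 0], haps[p, 1])
    return out


def _mutate(gametes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0.0:
        return
    n_mut = rng.binomial(gametes.size, rate)
    if n_mut == 0:
        return
    flat = rng.choice(gametes.size, size=n_mut, replace=False)
    idx = np.unravel_index(flat, gametes.shape)
    gametes[idx] ^= 1


def _breed(
    haps: list[np.ndarray], n_offspring: int, cfg: GenedropConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Produce ``n_offspring`` individuals; chromosomes assort independently."""
    n_parents = haps[0].shape[0]
    p1 = rng.integers(0, n_parents, size=n_offspring)
    p2 = rng.integers(0, n_parents, size=n_offspring)
    offspring = []
    for chrom in haps:
        g1 = _gametes(chrom, p1, cfg.chr_length, rng)
        g2 = _gametes(chrom, p2, cfg.chr_length, rng)
        _mutate(g1, cfg.mutation_rate, rng)
        _mutate(g2, cfg.mutation_rate, rng)
        offspring.append(np.stack([g1, g2], axis=1))
    return offspring


def run_genedrop(
    cfg: GenedropConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Evolve the breeding population; returns per-chromosome haplotypes.

    Each returned array has shape (Ne, 2, n_sites) with 0/1 alleles.
    """
    haps = [
        rng.integers(0, 2, size=(cfg.Ne, 2, cfg.n_sites), dtype=np.int8)
        for _ in range(cfg.n_chr)
    ]
    for _ in range(cfg.generations):
        haps = _breed(haps, cfg.Ne, cfg, rng)
    return haps


def simulate_genedrop(
    cfg: GenedropConfig, rng: np.random.Generator | None = None
) -> GenedropResult:
    """Run the full gene-dropping workflow: drift, sampling, phenotypes."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    haps = run_genedrop(cfg, rng)
    n_sample = cfg.n_discovery + cfg.n_target
    sample = _breed(haps, n_sample, cfg, rng)
    # dosage matrix over all sites, chromosomes concatenated
    dosages = np.concatenate([chrom.sum(axis=1) for chrom in sample], axis=1).astype(float)

    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    eligible = np.flatnonzero(maf > cfg.maf_min)
    if eligible.size < cfg.n_causal:
        raise RuntimeError(
            f"only {eligible.size} sites pass the MAF filter; "
            f"{cfg.n_causal} causal sites requested"
        )
    causal = np.sort(rng.choice(eligible, size=cfg.n_causal, replace=False))

    p = freq[causal]
    Z = (dosages[:, causal] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    beta = rng.standard_normal(cfg.n_causal)
    g = Z @ beta
    g *= np.sqrt(cfg.h2_sim) / g.std()
    residual = rng.standard_normal(n_sample) * np.sqrt(1.0 - cfg.h2_sim)
    y = g + residual

    ids = [f"ind{k + 1}" for k in range(n_sample)]
    snp_ids = [f"snp{k + 1}" for k in eligible]
    d = slice(0, cfg.n_discovery)
    t = slice(cfg.n_discovery, n_sample)
    discovery = GenotypeMatrix(dosages[d, :][:, eligible], ids[d], snp_ids)
    target = GenotypeMatrix(dosages[t, :][:, eligible], ids[t], snp_ids)
    return GenedropResult(
        discovery=discovery,
        target=target,
        phenotypes=y[d],
        g_true_discovery=g[d],
        g_true_target=g[t],
        observed_sites=eligible,
        causal_sites=causal,
    )
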