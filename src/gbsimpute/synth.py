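"""Synthetic GBS-like read-count data with known truth.

Genotypes come from a founder-haplotype mosaic: a small pool of founder
haplotypes is drawn site by site from an allele-frequency spectrum, and
each sample carries two haplotypes stitched together from whole founder
blocks.  Crossovers happen only at block boundaries (every ``block_len``
sites) with probability ``recomb_rate * block_len`` per boundary, so LD
is strong within blocks and decays across them — the structure LD-kNN
imputation relies on.  Fewer founders and longer blocks mean stronger LD.

Reads mimic genotyping-by-sequencing output: per-entry depth is Poisson
or (default) negative-binomial — the latter's overdispersion produces
both the many near-zero depths and the occasional very deep genotypes
seen in real GBS — optionally zero-inflated, and the ALT read count is
binomial with success probability e, 0.5 or 1 - e for genotypes 0, 1, 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vcf_io import ReadCountMatrix, Site

__all__ = ["SimConfig", "simulate_truth", "simulate_reads", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    maf_spectrum is the (low, high) range of a uniform distribution for
    the founder ALT-allele frequency per site.  depth_model is "poisson"
    or "negbin"; dispersion is the negative-binomial size parameter
    (smaller = heavier tail).  zero_inflation is the fraction of entries
    forced to depth 0 on top of the depth model, mimicking restriction
    fragments absent from a library.
    """

    n_samples: int = 200
    n_sites: int = 1000
    n_founders: int = 4
    block_len: int = 50
    recomb_rate: float = 0.01
    maf_spectrum: tuple[float, float] = (0.1, 0.5)
    mean_depth: float = 4.0
    depth_model: str = "negbin"
    dispersion: float = 0.3
    zero_inflation: float = 0.1
    e: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_model not in ("poisson", "negbin"):
            raise ValueError("depth_model must be 'poisson' or 'negbin'")


def simulate_truth(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw founder haplotypes and mosaic diploid genotypes.

    Returns ``(genotypes, founders)``: genotypes is (n_samples, n_sites)
    with values in {0, 1, 2}; founders is (n_founders, n_sites) binary.
    With recomb_rate = 0 every haplotype is a whole founder copy.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freqs = rng.uniform(*config.maf_spectrum, size=config.n_sites)
    founders = (rng.random((config.n_founders, config.n_sites)) < freqs).astype(np.int8)

    n_blocks = -(-config.n_sites // config.block_len)
    switch_p = min(1.0, config.recomb_rate * config.block_len)
    n_haps = 2 * config.n_samples
    # founder index per (haplotype, block): Markov chain over blocks
    choice = np.empty((n_haps, n_blocks), dtype=np.int64)
    choice[:, 0] = rng.integers(config.n_founders, size=n_haps)
    for blk in range(1, n_blocks):
        switch = rng.random(n_haps) < switch_p
        fresh = rng.integers(config.n_founders, size=n_haps)
        choice[:, blk] = np.where(switch, fresh, choice[:, blk - 1])
    per_site = np.repeat(choice, config.block_len, axis=1)[:, :config.n_sites]
    haps = founders[per_site, np.arange(config.n_sites)]
    genotypes = (haps[0::2] + haps[1::2]).astype(np.int8)
    return genotypes, founders


def simulate_reads(truth: np.ndarray, config: SimConfig,
                   rng: np.random.Generator | None = None) -> ReadCountMatrix:
    """Draw read counts for a genotype matrix under the depth/error model."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    truth = np.asarray(truth)
    shape = truth.shape
    if config.depth_model == "poisson":
        depth = rng.poisson(config.mean_depth, size=shape)
    else:
        r = config.dispersion
        p = r / (r + config.mean_depth)
        depth = rng.negative_binomial(r, p, size=shape)
    if config.zero_inflation > 0:
        depth[rng.random(shape) < config.zero_inflation] = 0
    p_alt = np.array([config.e, 0.5, 1.0 - config.e])[truth]
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    n_samples, n_sites = shape
    samples = [f"sample{i:04d}" for i in range(n_samples)]
    sites = [Site(f"snp{j:05d}", "1", j + 1, "A", "C") for j in range(n_sites)]
    return ReadCountMatrix(samples, sites, ref, alt)


def simulate_dataset(config: SimConfig):
    """Convenience: (read-count matrix, true genotypes, founders)."""
    rng = np.random.default_rng(config.seed)
    truth, founders = simulate_truth(config, rng)
    matrix = simulate_reads(truth, config, rng)
    return matrix, truth, founders
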