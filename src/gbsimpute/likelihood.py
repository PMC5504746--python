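"""Genotype inference from allelic read counts.

Given ``r_R`` reference and ``r_A`` alternate reads at a biallelic site, the
likelihood of each diploid genotype g (the count of ALT alleles, g in
{0, 1, 2}) is a binomial probability with success rate determined by the
genotype and a per-read error rate ``e``:

    L_0 = Binom(r_R; r_R + r_A, 1 - e)
    L_1 = Binom(r_R; r_R + r_A, 0.5)
    L_2 = Binom(r_A; r_R + r_A, 1 - e)

Normalising the three likelihoods yields the *inferred* genotype
distribution; its argmax is the inferred genotype.  This is the same
read-count model used by common GBS SNP-calling pipelines.

All heavy lifting is done in log space so depths in the hundreds do not
underflow before normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "ErrorModel",
    "genotype_likelihoods",
    "infer_distribution",
    "infer_distribution_matrix",
    "inferred_genotype",
    "inferred_genotype_matrix",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-read sequencing error rate.

    The default of 0.01 is the conventional choice for GBS read data.
    """

    e: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.e < 0.5:
            raise ValueError(f"error rate must lie in (0, 0.5), got {self.e}")


def _log_likelihoods(r_ref, r_alt, e: float):
    """Stacked log-likelihoods, shape (..., 3)."""
    r_ref = np.asarray(r_ref)
    r_alt = np.asarray(r_alt)
    n = r_ref + r_alt
    l0 = binom.logpmf(r_ref, n, 1.0 - e)
    l1 = binom.logpmf(r_ref, n, 0.5)
    l2 = binom.logpmf(r_alt, n, 1.0 - e)
    return np.stack([l0, l1, l2], axis=-1)


def genotype_likelihoods(r_ref: int, r_alt: int, model: ErrorModel = ErrorModel()):
    """Binomial likelihood of each genotype for one read-count pair.

    Returns the linear-space triple ``(L0, L1, L2)``.  With zero reads all
    three likelihoods are 1 (an empty binomial is certain).
    """
    if r_ref < 0 or r_alt < 0:
        raise ValueError("read counts must be non-negative")
    return np.exp(_log_likelihoods(r_ref, r_alt, model.e))


def infer_distribution(r_ref: int, r_alt: int, model: ErrorModel = ErrorModel()):
    """Normalised genotype probabilities from one read-count pair.

    The heterozygote likelihood is strictly positive for every count pair,
    so the normalising constant never vanishes.
    """
    if r_ref < 0 or r_alt < 0:
        raise ValueError("read counts must be non-negative")
    ll = _log_likelihoods(r_ref, r_alt, model.e)
    ll -= ll.max(axis=-1, keepdims=True)
    lin = np.exp(ll)
    return lin / lin.sum(axis=-1, keepdims=True)


def infer_distribution_matrix(ref, alt, model: ErrorModel = ErrorModel()):
    """Vectorised :func:`infer_distribution` over count arrays.

    ``ref`` and ``alt`` may have any matching shape; the result gains a
    trailing axis of length 3.
    """
    ll = _log_likelihoods(ref, alt, model.e)
    ll -= ll.max(axis=-1, keepdims=True)
    lin = np.exp(ll)
    return lin / lin.sum(axis=-1, keepdims=True)


def inferred_genotype(dist) -> int:
    """Most probable genotype; ties break to the lowest genotype index."""
    return int(np.argmax(dist))


def inferred_genotype_matrix(ref, alt, model: ErrorModel = ErrorModel()):
    """Argmax genotype per entry (ties to the lowest index), vectorised."""
    return np.argmax(infer_distribution_matrix(ref, alt, model), axis=-1).astype(np.int8)
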