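"""Final genotype calling: blend inferred and imputed probabilities.

The called distribution is the convex combination

    p_g^c = w * p_g^imputed + (1 - w) * p_g^inferred

with a single weight w per dataset, found by exhaustive scan of the grid
{0, 0.01, ..., 1.00} for the value maximising calling accuracy on a set
of masked training genotypes.  The scan is exhaustive rather than
hill-climbing because accuracy as a function of w need not be unimodal.
Only entries at or below the read-depth threshold d are blended; with
more reads than d the inferred distribution is used unchanged.
"""

from __future__ import annotations

import numpy as np

from .likelihood import ErrorModel, infer_distribution
from .vcf_io import ReadCountMatrix

__all__ = ["W_GRID", "combine", "call_genotype", "optimize_w", "scan_w_accuracy"]

# 101-point weight grid; includes both pure-inference (0) and pure-imputation (1)
W_GRID = np.round(np.arange(0, 101) / 100.0, 2)


def combine(inferred: np.ndarray, imputed: np.ndarray, w: float) -> np.ndarray:
    """Convex combination of the two genotype distributions."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    return w * np.asarray(imputed) + (1.0 - w) * np.asarray(inferred)


def call_genotype(matrix: ReadCountMatrix, a: int, b: int, d: int,
                  imputed: np.ndarray | None, w: float,
                  model: ErrorModel = ErrorModel()) -> np.ndarray:
    """Called distribution for sample ``b`` at site ``a``.

    Entries with depth > d keep the inferred distribution; the rest blend
    the inferred and imputed distributions with weight ``w``.
    """
    r_ref = int(matrix.ref[b, a])
    r_alt = int(matrix.alt[b, a])
    inferred = infer_distribution(r_ref, r_alt, model)
    if r_ref + r_alt > d:
        return inferred
    if imputed is None:
        raise ValueError("entry at or below the depth threshold needs an imputed distribution")
    return combine(inferred, imputed, w)


def scan_w_accuracy(inferred: np.ndarray, imputed: np.ndarray, known: np.ndarray,
                    blend: np.ndarray | None = None,
                    w_grid: np.ndarray = W_GRID) -> np.ndarray:
    """Calling accuracy at every grid weight.

    ``inferred``/``imputed`` are (n, 3) distributions for n masked
    genotypes, ``known`` the true genotypes.  Rows where ``blend`` is
    False (reduced depth above the threshold) are always called from the
    inferred distribution alone, so they contribute a constant term.
    """
    inferred = np.asarray(inferred, float)
    imputed = np.asarray(imputed, float)
    known = np.asarray(known)
    n = len(known)
    if n == 0:
        raise ValueError("w training mask is empty")
    if blend is None:
        blend = np.ones(n, dtype=bool)
    fixed_correct = int(np.sum(np.argmax(inferred[~blend], axis=1) == known[~blend]))
    inf_b, imp_b, known_b = inferred[blend], imputed[blend], known[blend]
    acc = np.empty(len(w_grid))
    for i, w in enumerate(w_grid):
        called = np.argmax(w * imp_b + (1.0 - w) * inf_b, axis=1)
        acc[i] = (fixed_correct + int(np.sum(called == known_b))) / n
    return acc


def optimize_w(inferred: np.ndarray, imputed: np.ndarray, known: np.ndarray,
               blend: np.ndarray | None = None) -> float:
    """Exhaustive 101-point scan for the accuracy-maximising weight.

    Ties break to the smallest w, i.e. toward read-count evidence when the
    training data are indifferent.
    """
    acc = scan_w_accuracy(inferred, imputed, known, blend)
    return float(W_GRID[int(np.argmax(acc))])
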