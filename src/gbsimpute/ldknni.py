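"""LD-kNN imputation over unordered biallelic markers.

To impute the genotype of sample ``b`` at SNP ``a``, the algorithm

1. finds the ``l`` SNPs in highest linkage disequilibrium (squared Pearson
   correlation, r^2) with ``a``,
2. measures a Manhattan distance from ``b`` to every other sample over
   those ``l`` SNPs,
3. takes the ``k`` nearest samples that have a known genotype at ``a`` and
   scores each genotype g by the inverse-distance-weighted count

       c_g = sum_{s in N} I(h(s, a) = g) / d_l(b, s)

   which, normalised, is the imputed genotype distribution.

No marker order and no reference panel are needed; LD is estimated from
the data themselves.  Distances use only LD sites at which both samples
are non-missing and are rescaled to ``l`` sites, with a +1 offset so the
inverse weights stay finite; a pair sharing no usable LD site sits at the
maximal distance 1 + 2l.  All tie-breaks go to the lowest index, making
runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import ErrorModel, inferred_genotype_matrix
from .vcf_io import ReadCountMatrix

__all__ = [
    "MISSING",
    "KnnParams",
    "LDNeighbourTable",
    "ImputationImpossibleError",
    "known_genotype_matrix",
    "pairwise_ld",
    "ld_matrix",
    "build_neighbour_table",
    "sample_distance",
    "distances_to_all",
    "impute_distribution",
    "impute_site",
    "optimize_k_l",
]

MISSING = np.int8(-1)

DEFAULT_K_GRID = tuple(range(1, 11))
DEFAULT_L_GRID = (2, 4, 8, 16, 32)


class ImputationImpossibleError(RuntimeError):
    """No other sample has a known genotype at the target site."""


@dataclass(frozen=True)
class KnnParams:
    """Number of neighbours ``k`` and of LD sites ``l``."""

    k: int
    l: int

    def __post_init__(self) -> None:
        if self.k < 1 or self.l < 1:
            raise ValueError("k and l must be positive")


@dataclass
class LDNeighbourTable:
    """Per site, the ``l`` other sites with highest r^2 (non-increasing).

    ``neighbours[a]`` lists site indices, ``r2[a]`` the matching r^2
    values.  r^2 ties are broken by the lower site index.
    """

    neighbours: np.ndarray  # (n_sites, l) int
    r2: np.ndarray  # (n_sites, l) float

    @property
    def l(self) -> int:
        return self.neighbours.shape[1]


def known_genotype_matrix(matrix: ReadCountMatrix, d: int,
                          model: ErrorModel = ErrorModel()) -> np.ndarray:
    """Inferred genotypes where read depth exceeds ``d``; MISSING elsewhere."""
    geno = inferred_genotype_matrix(matrix.ref, matrix.alt, model)
    geno[matrix.depth() <= d] = MISSING
    return geno


def pairwise_ld(genotypes: np.ndarray, a: int, b: int) -> float:
    """r^2 between sites ``a`` and ``b`` over mutually non-missing samples.

    Returns 0 when fewer than two complete pairs exist or either site is
    constant on the complete pairs.
    """
    ga, gb = genotypes[:, a], genotypes[:, b]
    ok = (ga != MISSING) & (gb != MISSING)
    n = int(ok.sum())
    if n < 2:
        return 0.0
    x = ga[ok].astype(np.int64)
    y = gb[ok].astype(np.int64)
    # integer sums keep this bit-identical to the matmul route in
    # ld_matrix (exact in float64 for realistic sample counts)
    sx, sy = int(x.sum()), int(y.sum())
    sxy = int((x * y).sum())
    sxx, syy = int((x * x).sum()), int((y * y).sum())
    cov = float(n * sxy - sx * sy)
    denom = float(n * sxx - sx * sx) * float(n * syy - sy * sy)
    if denom <= 0:
        return 0.0
    return float(min(cov * cov / denom, 1.0))


def ld_matrix(genotypes: np.ndarray) -> np.ndarray:
    """All-pairs r^2 with pairwise-complete samples, computed by matmuls.

    Degenerate pairs (fewer than 2 complete observations, or a constant
    site) get r^2 = 0.  The diagonal is set to 0 so a site is never its
    own LD neighbour.
    """
    known = (genotypes != MISSING)
    g = np.where(known, genotypes, 0).astype(np.float64)
    m = known.astype(np.float64)
    n = m.T @ m
    sx = g.T @ m
    sxy = g.T @ g
    sxx = (g * g).T @ m
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx * sx
        # same op order as pairwise_ld so both routes round identically
        denom = varx * varx.T
        r2 = np.where((n >= 2) & (denom > 0), cov * cov / denom, 0.0)
    np.clip(r2, 0.0, 1.0, out=r2)
    np.fill_diagonal(r2, 0.0)
    return r2


def build_neighbour_table(genotypes: np.ndarray, l: int,
                          r2: np.ndarray | None = None) -> LDNeighbourTable:
    """Top-``l`` LD partners of every site, ties broken by lower index."""
    n_sites = genotypes.shape[1]
    if l > n_sites - 1:
        raise ValueError(f"l={l} exceeds number of other sites ({n_sites - 1})")
    if r2 is None:
        r2 = ld_matrix(genotypes)
    idx = np.arange(n_sites)
    neighbours = np.empty((n_sites, l), dtype=np.int64)
    vals = np.empty((n_sites, l), dtype=np.float64)
    for a in range(n_sites):
        row = r2[a].copy()
        row[a] = -np.inf  # exclude self
        order = np.lexsort((idx, -row))[:l]
        neighbours[a] = order
        vals[a] = r2[a, order]
    return LDNeighbourTable(neighbours, vals)


def _distances(gl: np.ndarray, gb: np.ndarray, l: int) -> np.ndarray:
    """Distances from genotype-row ``gb`` to every row of ``gl`` (both over
    the l LD sites), applying the missing-data rescaling."""
    usable = (gl != MISSING) & (gb != MISSING)[None, :]
    diffs = np.abs(gl.astype(np.int64) - gb.astype(np.int64)) * usable
    n_usable = usable.sum(axis=1)
    manh = diffs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 + manh * (l / n_usable)
    dist[n_usable == 0] = 1.0 + 2.0 * l
    return dist


def distances_to_all(genotypes: np.ndarray, table: LDNeighbourTable, a: int, b: int,
                     l: int | None = None) -> np.ndarray:
    """Distance from sample ``b`` to every sample, for imputing site ``a``.

    Uses the top ``l`` LD sites of ``a`` (defaults to the table width).
    Entry ``b`` itself is returned too; callers exclude it.
    """
    l = table.l if l is None else l
    lsites = table.neighbours[a, :l]
    gl = genotypes[:, lsites]
    return _distances(gl, genotypes[b, lsites], l)


def sample_distance(genotypes: np.ndarray, table: LDNeighbourTable, a: int,
                    b: int, s: int, l: int | None = None) -> float:
    """Distance between samples ``b`` and ``s`` for imputing site ``a``.

    Manhattan distance over the l LD sites of ``a`` where both samples are
    non-missing, rescaled to l sites, plus 1; maximal (1 + 2l) when no LD
    site is usable.
    """
    if s == b:
        raise ValueError("distance requires two distinct samples")
    l = table.l if l is None else l
    lsites = table.neighbours[a, :l]
    gl = genotypes[np.array([s]), :][:, lsites]
    return float(_distances(gl, genotypes[b, lsites], l)[0])


def _weighted_vote(order: np.ndarray, dist: np.ndarray, geno_at_a: np.ndarray,
                   k: int) -> np.ndarray:
    """Inverse-distance genotype scores over the first min(k, n) neighbours."""
    top = order[:k]
    c = np.zeros(3)
    np.add.at(c, geno_at_a[top], 1.0 / dist[top])
    return c


def _eligible_order(genotypes: np.ndarray, dist: np.ndarray, a: int, b: int) -> np.ndarray:
    """Eligible neighbour indices sorted by (distance, sample index)."""
    eligible = np.flatnonzero(genotypes[:, a] != MISSING)
    eligible = eligible[eligible != b]
    if eligible.size == 0:
        raise ImputationImpossibleError(
            f"no sample has a known genotype at site index {a}"
        )
    return eligible[np.lexsort((eligible, dist[eligible]))]


def impute_distribution(genotypes: np.ndarray, table: LDNeighbourTable,
                        params: KnnParams, a: int, b: int) -> np.ndarray:
    """Imputed genotype distribution for sample ``b`` at site ``a``.

    Votes among the ``k`` nearest samples with a known genotype at ``a``
    (fewer if fewer exist), weighted by inverse distance, then normalises.
    """
    dist = distances_to_all(genotypes, table, a, b, params.l)
    order = _eligible_order(genotypes, dist, a, b)
    c = _weighted_vote(order, dist, genotypes[:, a], params.k)
    return c / c.sum()


def impute_site(genotypes: np.ndarray, table: LDNeighbourTable, params: KnnParams,
                a: int, targets: np.ndarray) -> np.ndarray:
    """Imputed distributions for several samples at one site, shape (t, 3)."""
    out = np.empty((len(targets), 3))
    for i, b in enumerate(targets):
        out[i] = impute_distribution(genotypes, table, params, a, int(b))
    return out


def optimize_k_l(genotypes: np.ndarray, training, k_grid=DEFAULT_K_GRID,
                 l_grid=DEFAULT_L_GRID, table: LDNeighbourTable | None = None) -> KnnParams:
    """Pick (k, l) maximising imputation accuracy on masked training genotypes.

    ``training`` is a sequence of (site, sample, known_genotype) triples.
    The grids are clipped to the data size; accuracy ties break to the
    smaller l, then the smaller k.  A shared neighbour table of width
    max(l_grid) may be passed in; smaller l values reuse its prefix
    columns because rows are sorted by decreasing r^2.
    """
    training = list(training)
    if not training:
        raise ValueError("k/l training mask is empty")
    n_samples, n_sites = genotypes.shape
    k_grid = sorted({k for k in k_grid if 1 <= k <= n_samples - 1})
    l_grid = sorted({l for l in l_grid if 1 <= l <= n_sites - 1})
    if not k_grid or not l_grid:
        raise ValueError("empty k or l grid after clipping to the data size")
    if table is None or table.l < max(l_grid):
        table = build_neighbour_table(genotypes, max(l_grid))
    correct = {(k, l): 0 for k in k_grid for l in l_grid}
    for a, b, known in training:
        for l in l_grid:
            dist = distances_to_all(genotypes, table, a, b, l)
            order = _eligible_order(genotypes, dist, a, b)
            for k in k_grid:
                c = _weighted_vote(order, dist, genotypes[:, a], k)
                if int(np.argmax(c)) == known:
                    correct[(k, l)] += 1
    best = max(correct, key=lambda kl: (correct[kl], -kl[1], -kl[0]))
    return KnnParams(k=best[0], l=best[1])
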