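"""Dataset filters: minor allele frequency, Hardy-Weinberg, missingness.

Two pre-filters (MAF, HWE) run once per analysis on genotypes inferred at
a fixed depth; the missingness filter runs once per *case*, where a case
is one (read-depth threshold d, SNP missingness, sample missingness)
combination.  A genotype counts as non-missing for the missingness filter
iff its read depth exceeds d; sites are filtered before samples, and the
order matters (the sample fractions are recomputed on the reduced site
set).  Every filter logs how many sites/samples it removed so the final
dataset size reconciles with the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .likelihood import ErrorModel, inferred_genotype_matrix
from .vcf_io import ReadCountMatrix

__all__ = [
    "CaseSpec",
    "FilteredDataset",
    "EmptyDatasetError",
    "maf_filter",
    "hwe_filter",
    "hwe_exact_pvalue",
    "missingness_filter",
    "apply_prefilters",
]


class EmptyDatasetError(RuntimeError):
    """Filtering removed every site or every sample."""

    def __init__(self, message: str, provenance=None):
        super().__init__(message)
        self.provenance = provenance or []


@dataclass(frozen=True)
class CaseSpec:
    """One candidate filtering regime.

    d is the read-depth threshold (depth > d counts as non-missing and is
    genotyped by inference alone); snp_miss and sample_miss are the
    maximum tolerated missing fractions.  The remaining fields configure
    the pre-filters.  hwe_error is carried for forward compatibility with
    error-aware HWE variants but does not enter the exact test.
    """

    d: int
    snp_miss: float
    sample_miss: float
    maf_min: float = 0.05
    maf_depth: int = 8
    hwe_alpha: float = 0.01
    hwe_error: float = 0.01

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("depth threshold d must be >= 1")
        if not 0 < self.snp_miss <= 1 or not 0 < self.sample_miss <= 1:
            raise ValueError("missingness thresholds must lie in (0, 1]")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")

    @property
    def label(self) -> str:
        """Case label in 'd/miss' form, e.g. '8/0.2'."""
        if self.snp_miss == self.sample_miss:
            return f"{self.d}/{self.snp_miss:g}"
        return f"{self.d}/{self.snp_miss:g}/{self.sample_miss:g}"

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "CaseSpec":
        parts = label.split("/")
        if len(parts) == 2:
            return cls(d=int(parts[0]), snp_miss=float(parts[1]),
                       sample_miss=float(parts[1]), **kwargs)
        if len(parts) == 3:
            return cls(d=int(parts[0]), snp_miss=float(parts[1]),
                       sample_miss=float(parts[2]), **kwargs)
        raise ValueError(f"cannot parse case label {label!r}")


@dataclass
class FilteredDataset:
    """A filtered matrix plus an audit trail of what each filter removed.

    site_index / sample_index map the retained rows and columns back to
    the matrix the first filter saw.
    """

    matrix: ReadCountMatrix
    site_index: np.ndarray
    sample_index: np.ndarray
    provenance: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def kept_sites(self) -> int:
        return self.matrix.n_sites

    @property
    def kept_samples(self) -> int:
        return self.matrix.n_samples


def _chain(parent: FilteredDataset | None, matrix: ReadCountMatrix,
           keep_sites: np.ndarray, keep_samples: np.ndarray,
           steps: list[tuple[str, str, int]]) -> FilteredDataset:
    sub = matrix.subset(sample_idx=keep_samples, site_idx=keep_sites)
    if parent is None:
        return FilteredDataset(sub, keep_sites, keep_samples, steps)
    return FilteredDataset(
        sub,
        parent.site_index[keep_sites],
        parent.sample_index[keep_samples],
        parent.provenance + steps,
    )


def maf_filter(matrix: ReadCountMatrix, maf_min: float, maf_depth: int,
               model: ErrorModel = ErrorModel(),
               parent: FilteredDataset | None = None) -> FilteredDataset:
    """Drop sites whose minor allele frequency falls below ``maf_min``.

    The allele frequency is computed from genotypes inferred at entries
    with depth >= ``maf_depth``; sites with fewer than two such genotypes
    are dropped too (no frequency can be estimated).
    """
    if maf_depth < 1:
        raise ValueError("maf_depth must be >= 1")
    geno = inferred_genotype_matrix(matrix.ref, matrix.alt, model).astype(float)
    qual = matrix.depth() >= maf_depth
    n_qual = qual.sum(axis=0)
    alt_freq = np.where(qual, geno, 0.0).sum(axis=0) / np.maximum(2 * n_qual, 1)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = (n_qual >= 2) & (maf >= maf_min)
    keep_sites = np.flatnonzero(keep)
    steps = [("maf", "sites", int(matrix.n_sites - keep_sites.size))]
    return _chain(parent, matrix, keep_sites, np.arange(matrix.n_samples), steps)


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value for one site.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count is

        P(n_ab) = N! / (n_aa! n_ab! n_bb!) * 2^n_ab * n_A! n_B! / (2N)!

    and the p-value is the total probability of all configurations no more
    likely than the observed one.  Fewer than two genotypes: returns 1.
    """
    n = n_aa + n_ab + n_bb
    if n < 2:
        return 1.0
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    lg = math.lgamma
    logp = np.array([
        lg(n + 1) - lg(h + 1) - lg(r + 1) - lg(c + 1) + h * math.log(2)
        for h, r, c in zip(hets, homr, homc)
    ])
    logp += lg(rare + 1) + lg(2 * n - rare + 1) - lg(2 * n + 1)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(matrix: ReadCountMatrix, alpha: float, error_rate: float, depth: int,
               model: ErrorModel = ErrorModel(),
               parent: FilteredDataset | None = None) -> FilteredDataset:
    """Drop sites that deviate from Hardy-Weinberg equilibrium.

    Genotype counts come from inferred genotypes at entries with
    depth >= ``depth``.  The per-site exact test is Bonferroni-corrected:
    a site is removed when p < alpha / (number of sites tested).  Sites
    with fewer than two genotyped samples are not tested (kept).
    ``error_rate`` is accepted for interface stability; the exact test
    does not use it.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    geno = inferred_genotype_matrix(matrix.ref, matrix.alt, model)
    qual = matrix.depth() >= depth
    counts = np.stack(
        [((geno == g) & qual).sum(axis=0) for g in (0, 1, 2)], axis=1
    )
    testable = counts.sum(axis=1) >= 2
    n_tested = int(testable.sum())
    keep = np.ones(matrix.n_sites, dtype=bool)
    if n_tested:
        threshold = alpha / n_tested
        for j in np.flatnonzero(testable):
            if hwe_exact_pvalue(*counts[j]) < threshold:
                keep[j] = False
    keep_sites = np.flatnonzero(keep)
    steps = [("hwe", "sites", int(matrix.n_sites - keep_sites.size))]
    return _chain(parent, matrix, keep_sites, np.arange(matrix.n_samples), steps)


def missingness_filter(matrix: ReadCountMatrix, d: int, snp_miss: float,
                       sample_miss: float,
                       parent: FilteredDataset | None = None) -> FilteredDataset:
    """Per-case missingness filter: sites first, then samples.

    An entry is missing iff depth <= d.  Sites whose missing fraction
    exceeds ``snp_miss`` are removed first; sample missing fractions are
    then recomputed on the surviving sites, and samples above
    ``sample_miss`` are removed.
    """
    if not 0 < snp_miss <= 1 or not 0 < sample_miss <= 1:
        raise ValueError("missingness thresholds must lie in (0, 1]")
    missing = matrix.depth() <= d
    site_frac = missing.mean(axis=0)
    keep_sites = np.flatnonzero(site_frac <= snp_miss)
    prov = [("snp_missingness", "sites", int(matrix.n_sites - keep_sites.size))]
    if keep_sites.size == 0:
        raise EmptyDatasetError(
            f"SNP missingness <= {snp_miss} at d={d} removed every site",
            (parent.provenance if parent else []) + prov,
        )
    sample_frac = missing[:, keep_sites].mean(axis=1)
    keep_samples = np.flatnonzero(sample_frac <= sample_miss)
    prov.append(("sample_missingness", "samples", int(matrix.n_samples - keep_samples.size)))
    if keep_samples.size == 0:
        raise EmptyDatasetError(
            f"sample missingness <= {sample_miss} at d={d} removed every sample",
            (parent.provenance if parent else []) + prov,
        )
    return _chain(parent, matrix, keep_sites, keep_samples, prov)


def apply_prefilters(matrix: ReadCountMatrix, case: CaseSpec,
                     model: ErrorModel = ErrorModel()) -> FilteredDataset:
    """MAF then HWE pre-filter, sharing one audit trail."""
    after_maf = maf_filter(matrix, case.maf_min, case.maf_depth, model)
    return hwe_filter(after_maf.matrix, case.hwe_alpha, case.hwe_error,
                      case.maf_depth, model, parent=after_maf)
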