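"""Accuracy estimation by read-count masking, and case comparison.

The pipeline's quality is estimated without any external truth: genotypes
with a high read depth (>= 30 by default) are treated as *known* — their
inferred genotype is taken as truth — and a sample of them has reads
removed at random until the depth matches a draw from the dataset's own
low-depth (<= d_a) depth distribution.  The pipeline then re-calls each
down-sampled genotype with every other masked genotype left untouched,
and accuracy is the fraction of masked genotypes called back to their
known value.  Matching the masked depths to the empirical distribution
makes accuracies comparable across depth thresholds d.

The masked set is split into three disjoint partitions: one to optimise
the imputation parameters (k, l), one to optimise the calling weight w,
and one held-out test partition on which accuracy and a MAF-centred
correlation are reported.

A *case* is one (d, missingness) filter combination; sweeping cases
yields a table of dataset size versus accuracy from which the
non-dominated ("good") cases are picked: a case is good when no other
case has at least as many SNPs and samples and a higher accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import caller
from .filters import CaseSpec, EmptyDatasetError, missingness_filter
from .ldknni import (DEFAULT_K_GRID, DEFAULT_L_GRID, KnnParams,
                     build_neighbour_table, impute_distribution,
                     known_genotype_matrix, optimize_k_l)
from .likelihood import ErrorModel, infer_distribution_matrix
from .vcf_io import ReadCountMatrix

__all__ = [
    "EvalConfig",
    "MaskedGenotype",
    "CaseResult",
    "MaskingError",
    "EvaluationImpossibleError",
    "CaseSkipped",
    "empirical_depth_distribution",
    "draw_masked_set",
    "correlation_metric",
    "evaluate_case",
    "good_cases",
]

PARTITIONS = ("kl_train", "w_train", "test")


class MaskingError(RuntimeError):
    """Not enough high-depth genotypes to build the masked set."""


class EvaluationImpossibleError(RuntimeError):
    """No entries at or below d_a: no depth distribution to match."""


class CaseSkipped(RuntimeError):
    """A case could not be evaluated; carries the reason."""

    def __init__(self, label: str, reason: str):
        super().__init__(f"case {label}: {reason}")
        self.label = label
        self.reason = reason


@dataclass(frozen=True)
class EvalConfig:
    """Masking and optimisation settings.

    n_mask masked genotypes are drawn once from entries with depth >=
    known_depth, down-sampled to depths <= d_a, and split into the
    k/l-training, w-training and test partitions in the given
    proportions.  d_a should equal the largest depth threshold under
    comparison so every case is judged on the same depth mix.
    """

    n_mask: int = 10_000
    d_a: int = 8
    known_depth: int = 30
    seed: int = 0
    split: tuple[float, float, float] = (0.4, 0.3, 0.3)
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    l_grid: tuple[int, ...] = DEFAULT_L_GRID
    min_masked: int = 30

    def __post_init__(self) -> None:
        if self.n_mask < 1:
            raise ValueError("n_mask must be >= 1")
        if self.d_a >= self.known_depth:
            raise ValueError("d_a must be below known_depth")
        if abs(sum(self.split) - 1.0) > 1e-9 or any(s <= 0 for s in self.split):
            raise ValueError("split must be three positive fractions summing to 1")


@dataclass(frozen=True)
class MaskedGenotype:
    """One deliberately down-sampled high-confidence genotype."""

    site: int
    sample: int
    original: tuple[int, int]
    reduced: tuple[int, int]
    known_genotype: int
    partition: str

    @property
    def reduced_depth(self) -> int:
        return self.reduced[0] + self.reduced[1]


@dataclass(frozen=True)
class CaseResult:
    """Per-case dataset size, optimised parameters and quality metrics."""

    case: CaseSpec
    n_sites: int
    n_samples: int
    k: int
    l: int
    w: float
    accuracy: float
    correlation: float
    accuracy_inferred_only: float
    accuracy_imputed_only: float
    n_test: int = 0
    provenance: tuple = ()
    # training-partition accuracies from the w scan: at the chosen w and
    # at the two grid endpoints (pure inference, pure imputation)
    w_train_accuracy: float = float("nan")
    w_train_accuracy_inferred: float = float("nan")
    w_train_accuracy_imputed: float = float("nan")

    @property
    def label(self) -> str:
        return self.case.label

    def metric(self, name: str = "accuracy") -> float:
        if name not in ("accuracy", "correlation"):
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)


def empirical_depth_distribution(matrix: ReadCountMatrix, d_a: int) -> np.ndarray:
    """Frequency of each depth 0..d_a among entries with depth <= d_a."""
    depth = matrix.depth()
    low = depth[depth <= d_a]
    if low.size == 0:
        raise EvaluationImpossibleError(f"no entries with depth <= {d_a}")
    counts = np.bincount(low, minlength=d_a + 1).astype(float)
    return counts / counts.sum()


def _partition_sizes(n: int, split) -> tuple[int, int, int]:
    n_kl = max(0, min(int(round(split[0] * n)), n - 2))
    n_w = max(0, min(int(round(split[1] * n)), n - n_kl - 1))
    return n_kl, n_w, n - n_kl - n_w


def draw_masked_set(matrix: ReadCountMatrix, dist: np.ndarray,
                    config: EvalConfig,
                    model: ErrorModel = ErrorModel()) -> list[MaskedGenotype]:
    """Sample and down-sample n_mask known genotypes, depth-matched.

    Entries are chosen uniformly without replacement from those with depth
    >= known_depth.  For each, a target depth is drawn from ``dist`` and
    individual reads are removed uniformly at random until the target
    remains — so the surviving REF count is hypergeometric given the
    original counts and the target.  Fully reproducible from the seed.
    """
    depth = matrix.depth()
    eligible = np.flatnonzero(depth >= config.known_depth)
    if eligible.size < config.n_mask:
        raise MaskingError(
            f"need {config.n_mask} genotypes with depth >= {config.known_depth}, "
            f"only {eligible.size} available"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(eligible, size=config.n_mask, replace=False)
    targets = rng.choice(len(dist), size=config.n_mask, p=dist)
    rows, cols = np.unravel_index(chosen, depth.shape)
    known = np.argmax(
        infer_distribution_matrix(matrix.ref[rows, cols], matrix.alt[rows, cols], model),
        axis=-1,
    )
    n_kl, n_w, _ = _partition_sizes(config.n_mask, config.split)
    out: list[MaskedGenotype] = []
    for i in range(config.n_mask):
        rr, ra = int(matrix.ref[rows[i], cols[i]]), int(matrix.alt[rows[i], cols[i]])
        t = int(targets[i])
        red_r = int(rng.hypergeometric(rr, ra, t)) if t > 0 else 0
        part = PARTITIONS[0] if i < n_kl else PARTITIONS[1] if i < n_kl + n_w else PARTITIONS[2]
        out.append(MaskedGenotype(
            site=int(cols[i]), sample=int(rows[i]),
            original=(rr, ra), reduced=(red_r, t - red_r),
            known_genotype=int(known[i]), partition=part,
        ))
    return out


def correlation_metric(known, called, site_means) -> float:
    """Pearson correlation of known vs called genotypes, both centred by
    the per-site mean genotype to alleviate MAF effects.

    Returns 0 when either centred vector has no variance or fewer than
    two pairs are given.
    """
    known = np.asarray(known, float)
    called = np.asarray(called, float)
    site_means = np.asarray(site_means, float)
    if known.size < 2:
        raise ValueError("correlation needs at least two pairs")
    x = known - site_means
    y = called - site_means
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _case_rng_seed(config: EvalConfig, case: CaseSpec) -> tuple[int, ...]:
    return (config.seed, case.d, int(round(case.snp_miss * 1000)),
            int(round(case.sample_miss * 1000)))


def evaluate_case(matrix: ReadCountMatrix, case: CaseSpec, config: EvalConfig,
                  model: ErrorModel = ErrorModel(),
                  masked: list[MaskedGenotype] | None = None) -> CaseResult:
    """Filter, optimise (k, l, w) and score one case.

    ``matrix`` should already be pre-filtered (MAF/HWE).  ``masked`` is a
    master masked set drawn on that matrix; entries falling outside the
    case's retained sites/samples are dropped and the survivors are
    re-partitioned with a case-specific seed.  If omitted, a fresh masked
    set is drawn.

    Each masked genotype is evaluated with only itself down-sampled: the
    known-genotype matrix and the LD neighbour table are built from the
    unmasked counts, which a single masked low-depth genotype cannot
    affect (it is excluded as its own neighbour, and its own site is
    never one of its LD sites).
    """
    try:
        fd = missingness_filter(matrix, case.d, case.snp_miss, case.sample_miss)
    except EmptyDatasetError as exc:
        raise CaseSkipped(case.label, str(exc)) from exc
    sub = fd.matrix

    if masked is None:
        dist = empirical_depth_distribution(matrix, config.d_a)
        masked = draw_masked_set(matrix, dist, config, model)

    site_pos = {int(orig): new for new, orig in enumerate(fd.site_index)}
    sample_pos = {int(orig): new for new, orig in enumerate(fd.sample_index)}
    entries = [
        (m, site_pos[m.site], sample_pos[m.sample])
        for m in masked
        if m.site in site_pos and m.sample in sample_pos
    ]
    if len(entries) < config.min_masked:
        raise CaseSkipped(
            case.label,
            f"only {len(entries)} masked genotypes fall inside the filtered dataset "
            f"(minimum {config.min_masked})",
        )

    rng = np.random.default_rng(_case_rng_seed(config, case))
    order = rng.permutation(len(entries))
    n_kl, n_w, n_test = _partition_sizes(len(entries), config.split)
    kl_idx = order[:n_kl]
    w_idx = order[n_kl:n_kl + n_w]
    test_idx = order[n_kl + n_w:]

    genotypes = known_genotype_matrix(sub, case.d, model)
    l_grid = sorted({l for l in config.l_grid if 1 <= l <= sub.n_sites - 1})
    k_grid = sorted({k for k in config.k_grid if 1 <= k <= sub.n_samples - 1})
    if not l_grid or not k_grid:
        raise CaseSkipped(case.label, "dataset too small for the k/l grids")
    table = build_neighbour_table(genotypes, max(l_grid))

    kl_training = [(entries[i][1], entries[i][2], entries[i][0].known_genotype)
                   for i in kl_idx]
    params = optimize_k_l(genotypes, kl_training, k_grid, l_grid, table)

    def _dists(idx):
        """(inferred, imputed, known, blend) arrays for a partition."""
        inferred = np.empty((len(idx), 3))
        imputed = np.empty((len(idx), 3))
        known = np.empty(len(idx), dtype=int)
        blend = np.empty(len(idx), dtype=bool)
        for row, i in enumerate(idx):
            m, a, b = entries[i]
            inferred[row] = infer_distribution_matrix(
                np.array(m.reduced[0]), np.array(m.reduced[1]), model)
            blend[row] = m.reduced_depth <= case.d
            imputed[row] = (impute_distribution(genotypes, table, params, a, b)
                            if blend[row] else inferred[row])
            known[row] = m.known_genotype
        return inferred, imputed, known, blend

    acc_train = caller.scan_w_accuracy(*_dists(w_idx))
    w_star = float(caller.W_GRID[int(np.argmax(acc_train))])

    inf_t, imp_t, known_t, blend_t = _dists(test_idx)
    acc = caller.scan_w_accuracy(inf_t, imp_t, known_t, blend_t,
                                 w_grid=np.array([w_star, 0.0, 1.0]))
    called = np.where(
        blend_t,
        np.argmax(w_star * imp_t + (1 - w_star) * inf_t, axis=1),
        np.argmax(inf_t, axis=1),
    )
    col_known = np.ma.masked_equal(genotypes, -1)
    site_means_all = col_known.mean(axis=0).filled(0.0)
    site_means = np.array([site_means_all[entries[i][1]] for i in test_idx])
    corr = correlation_metric(known_t, called, site_means)

    return CaseResult(
        case=case,
        n_sites=sub.n_sites,
        n_samples=sub.n_samples,
        k=params.k,
        l=params.l,
        w=w_star,
        accuracy=float(acc[0]),
        correlation=corr,
        accuracy_inferred_only=float(acc[1]),
        accuracy_imputed_only=float(acc[2]),
        n_test=len(test_idx),
        provenance=tuple(fd.provenance),
        w_train_accuracy=float(acc_train.max()),
        w_train_accuracy_inferred=float(acc_train[0]),
        w_train_accuracy_imputed=float(acc_train[-1]),
    )


def good_cases(results: list[CaseResult], metric: str = "accuracy") -> list[CaseResult]:
    """Cases not dominated by any other case.

    A case is dominated when another case has at least as many SNPs, at
    least as many samples, and a strictly higher value of ``metric``.
    Input order is preserved.
    """
    if not results:
        raise ValueError("no case results to compare")
    keep = []
    for r in results:
        dominated = any(
            o.n_sites >= r.n_sites and o.n_samples >= r.n_samples
            and o.metric(metric) > r.metric(metric)
            for o in results
        )
        if not dominated:
            keep.append(r)
    return keep
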