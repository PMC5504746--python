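"""Model/Results interface over the calling + imputation pipeline.

:class:`GenotypeCallingModel` is built from a read-count matrix (or a
VCF) and one filtering case; ``fit()`` optimises the imputation
parameters (k, l) and the calling weight w on masked high-depth
genotypes and returns a :class:`GenotypeCallingResults` carrying the
estimates, the held-out accuracy and correlation, and a ``summary()``
table.  ``results.call()`` then applies the fitted parameters to every
retained genotype, and ``results.to_vcf()`` writes the called dataset.
"""

from __future__ import annotations

import numpy as np

from . import filters, vcf_io
from .caller import combine
from .evaluation import CaseResult, EvalConfig, MaskedGenotype, evaluate_case
from .filters import CaseSpec, FilteredDataset
from .ldknni import (ImputationImpossibleError, KnnParams,
                     build_neighbour_table, impute_distribution,
                     known_genotype_matrix)
from .likelihood import ErrorModel, infer_distribution_matrix
from .vcf_io import ReadCountMatrix

__all__ = ["GenotypeCallingModel", "GenotypeCallingResults"]


class GenotypeCallingModel:
    """Genotype calling + LD-kNN imputation for one filtering case.

    Parameters
    ----------
    matrix
        Multi-sample read counts (REF, ALT) at biallelic SNPs.
    case
        Depth threshold and missingness/pre-filter settings.
    eval_config
        Masking and optimisation settings; defaults are suitable for
        datasets with thousands of high-depth genotypes.
    error_model
        Per-read error rate for the binomial likelihoods.
    prefilter
        Apply the MAF and HWE pre-filters before fitting.  Pass False if
        ``matrix`` is already pre-filtered (e.g. inside a case sweep).
    """

    def __init__(self, matrix: ReadCountMatrix, case: CaseSpec,
                 eval_config: EvalConfig | None = None,
                 error_model: ErrorModel | None = None,
                 prefilter: bool = True):
        self.case = case
        self.eval_config = eval_config or EvalConfig()
        self.error_model = error_model or ErrorModel()
        self.raw = matrix
        if prefilter:
            self.prefiltered = filters.apply_prefilters(matrix, case, self.error_model)
        else:
            self.prefiltered = FilteredDataset(
                matrix, np.arange(matrix.n_sites), np.arange(matrix.n_samples))
        self.matrix = self.prefiltered.matrix

    @classmethod
    def from_vcf(cls, path, case: CaseSpec, **kwargs) -> "GenotypeCallingModel":
        return cls(vcf_io.read_vcf(path), case, **kwargs)

    def fit(self, masked: list[MaskedGenotype] | None = None) -> "GenotypeCallingResults":
        """Optimise k, l and w and estimate held-out accuracy."""
        result = evaluate_case(self.matrix, self.case, self.eval_config,
                               self.error_model, masked=masked)
        return GenotypeCallingResults(self, result)

    def results_from_params(self, k: int, l: int, w: float,
                            **metrics) -> "GenotypeCallingResults":
        """Results object from externally supplied parameters.

        Used to re-apply a case whose parameters were fitted in an
        earlier sweep; accuracy metrics default to NaN unless given.
        """
        nan = float("nan")
        result = CaseResult(
            case=self.case, n_sites=0, n_samples=0, k=k, l=l, w=w,
            accuracy=metrics.get("accuracy", nan),
            correlation=metrics.get("correlation", nan),
            accuracy_inferred_only=metrics.get("accuracy_inferred_only", nan),
            accuracy_imputed_only=metrics.get("accuracy_imputed_only", nan),
        )
        return GenotypeCallingResults(self, result)


class GenotypeCallingResults:
    """Fitted parameters, quality estimates, and genotype calling."""

    def __init__(self, model: GenotypeCallingModel, result: CaseResult):
        self.model = model
        self.result = result
        self.params = KnnParams(result.k, result.l)
        self.w = result.w
        self.accuracy = result.accuracy
        self.correlation = result.correlation
        self.accuracy_inferred_only = result.accuracy_inferred_only
        self.accuracy_imputed_only = result.accuracy_imputed_only
        self.n_uncallable = 0  # sites imputed from inference alone (no known neighbour)

    def call(self) -> tuple[FilteredDataset, np.ndarray]:
        """Call every genotype retained by the case's missingness filter.

        Returns the filtered dataset and an (n_samples, n_sites, 3) array
        of called probability triples: the inferred distribution where
        depth exceeds d, otherwise the w-weighted blend of inferred and
        imputed distributions.  A site where no sample clears the depth
        threshold after sample filtering cannot be imputed; such entries
        keep their inferred distribution and are tallied in
        ``n_uncallable``.
        """
        model = self.model
        case = model.case
        fd = filters.missingness_filter(model.matrix, case.d, case.snp_miss,
                                        case.sample_miss,
                                        parent=model.prefiltered)
        sub = fd.matrix
        genotypes = known_genotype_matrix(sub, case.d, model.error_model)
        l = min(self.params.l, sub.n_sites - 1)
        table = build_neighbour_table(genotypes, l)
        params = KnnParams(self.params.k, l)
        calls = infer_distribution_matrix(sub.ref, sub.alt, model.error_model)
        depth = sub.depth()
        self.n_uncallable = 0
        for a in range(sub.n_sites):
            targets = np.flatnonzero(depth[:, a] <= case.d)
            for b in targets:
                try:
                    imputed = impute_distribution(genotypes, table, params, a, int(b))
                except ImputationImpossibleError:
                    self.n_uncallable += 1
                    continue
                calls[b, a] = combine(calls[b, a], imputed, self.w)
        return fd, calls

    def to_vcf(self, path, meta: dict | None = None) -> FilteredDataset:
        """Call all genotypes and write them to a VCF at ``path``."""
        fd, calls = self.call()
        info = {
            "case": self.model.case.label,
            "k": self.params.k,
            "l": self.params.l,
            "w": self.w,
        }
        info.update(meta or {})
        vcf_io.write_vcf(fd.matrix, calls, path, meta=info)
        return fd

    def summary(self) -> str:
        """Plain-text summary of the fitted case."""
        r = self.result
        lines = [
            "Genotype calling results",
            "=" * 40,
            f"case (d/missingness):    {r.label}",
            f"SNPs retained:           {r.n_sites}",
            f"samples retained:        {r.n_samples}",
            f"neighbours k:            {r.k}",
            f"LD sites l:              {r.l}",
            f"calling weight w:        {r.w:.2f}",
            f"accuracy (test):         {r.accuracy:.4f}",
            f"correlation (test):      {r.correlation:.4f}",
            f"accuracy, inferred only: {r.accuracy_inferred_only:.4f}",
            f"accuracy, imputed only:  {r.accuracy_imputed_only:.4f}",
            f"test genotypes:          {r.n_test}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<GenotypeCallingResults case={self.result.label} "
                f"k={self.params.k} l={self.params.l} w={self.w:.2f} "
                f"accuracy={self.accuracy:.4f}>")
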