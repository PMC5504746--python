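"""Two-phase workflow: sweep filter cases, then call a chosen case.

Phase 1 (:func:`run_accuracy_phase`) reads the input VCF, applies the
MAF/HWE pre-filters once, draws one master masked set, evaluates every
(depth, missingness) case on it and writes a summary table with a
good-case (Pareto) flag per row.  Phase 2 (:func:`run_call_phase`) takes
a case label chosen from that table, re-applies its filters and the
parameters fitted in phase 1, and writes the fully called VCF.  All
randomness flows from the configured seed, so both phases are
byte-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters, vcf_io
from .evaluation import (CaseSkipped, EvalConfig, draw_masked_set,
                         empirical_depth_distribution, evaluate_case,
                         good_cases)
from .filters import CaseSpec
from .likelihood import ErrorModel
from .model import GenotypeCallingModel

__all__ = ["RunConfig", "parse_config", "run_accuracy_phase", "run_call_phase"]

SUMMARY_COLUMNS = [
    "case", "status", "n_sites", "n_samples", "k", "l", "w",
    "accuracy", "correlation", "accuracy_inferred_only",
    "accuracy_imputed_only", "n_test", "good", "reason",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one run, normally parsed from a flat key=value file.

    The default grids sweep depth thresholds 2..8 against missingness
    thresholds 0.1..0.7 (applied to SNPs and samples alike), i.e. 49
    cases.  ``metric`` chooses whether good-case dominance uses accuracy
    or the MAF-centred correlation; both are always reported.
    """

    input_vcf: str = ""
    out_dir: str = "."
    depth_grid: tuple[int, ...] = tuple(range(2, 9))
    miss_grid: tuple[float, ...] = tuple(np.round(np.arange(1, 8) * 0.1, 1))
    maf_min: float = 0.05
    maf_depth: int = 8
    hwe_alpha: float = 0.01
    hwe_error: float = 0.01
    error_rate: float = 0.01
    metric: str = "accuracy"
    eval: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if not self.depth_grid or not self.miss_grid:
            raise ValueError("depth and missingness grids must be non-empty")
        if self.metric not in ("accuracy", "correlation"):
            raise ValueError("metric must be 'accuracy' or 'correlation'")

    def case(self, d: int, miss: float) -> CaseSpec:
        return CaseSpec(d=d, snp_miss=miss, sample_miss=miss,
                        maf_min=self.maf_min, maf_depth=self.maf_depth,
                        hwe_alpha=self.hwe_alpha, hwe_error=self.hwe_error)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


_EVAL_KEYS = {"n_mask": int, "d_a": int, "known_depth": int, "seed": int,
              "min_masked": int}
_RUN_KEYS = {"input_vcf": str, "out_dir": str, "maf_min": float,
             "maf_depth": int, "hwe_alpha": float, "hwe_error": float,
             "error_rate": float, "metric": str}


def parse_config(path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file.

    Grid keys (``depth_grid``, ``miss_grid``, ``k_grid``, ``l_grid``)
    take comma-separated values; ``#`` starts a comment.
    """
    run_kwargs: dict = {}
    eval_kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _RUN_KEYS:
            run_kwargs[key] = _RUN_KEYS[key](value)
        elif key in _EVAL_KEYS:
            eval_kwargs[key] = _EVAL_KEYS[key](value)
        elif key == "depth_grid":
            run_kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key == "miss_grid":
            run_kwargs[key] = tuple(float(v) for v in value.split(","))
        elif key == "k_grid":
            eval_kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key == "l_grid":
            eval_kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key == "split":
            eval_kwargs[key] = tuple(float(v) for v in value.split(","))
        else:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
    return RunConfig(eval=EvalConfig(**eval_kwargs), **run_kwargs)


def _write_log(config: RunConfig, out_dir: Path, phase: str, extra: dict) -> None:
    from . import __version__

    lines = [f"phase={phase}", f"version={__version__}",
             f"seed={config.eval.seed}",
             f"config_hash={config.config_hash()}", f"config={config!r}"]
    lines += [f"{k}={v}" for k, v in extra.items()]
    (out_dir / f"{phase}.log").write_text("\n".join(lines) + "\n")


def run_accuracy_phase(config: RunConfig,
                       matrix: vcf_io.ReadCountMatrix | None = None) -> pd.DataFrame:
    """Evaluate every (depth, missingness) case and write the summary.

    Writes ``summary.tsv`` (one row per case, good-case flag included),
    ``audit.tsv`` (per-filter removal counts) and ``accuracy.log`` under
    the output directory, and returns the summary as a DataFrame.  Cases
    whose filtered dataset is empty or retains too few masked genotypes
    are reported as skipped with the reason.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix = vcf_io.read_vcf(config.input_vcf)
    model = ErrorModel(config.error_rate)
    base_case = config.case(config.depth_grid[0], config.miss_grid[0])
    pre = filters.apply_prefilters(matrix, base_case, model)
    dist = empirical_depth_distribution(pre.matrix, config.eval.d_a)
    master = draw_masked_set(pre.matrix, dist, config.eval, model)

    rows = []
    audit = [("prefilter", name, dim, removed) for name, dim, removed in pre.provenance]
    results = {}
    for d in config.depth_grid:
        for miss in config.miss_grid:
            case = config.case(d, miss)
            try:
                res = evaluate_case(pre.matrix, case, config.eval, model, masked=master)
            except CaseSkipped as exc:
                rows.append({"case": case.label, "status": "skipped",
                             "reason": exc.reason})
                continue
            results[case.label] = res
            audit += [(case.label, name, dim, removed)
                      for name, dim, removed in res.provenance]
            rows.append({
                "case": res.label, "status": "ok", "n_sites": res.n_sites,
                "n_samples": res.n_samples, "k": res.k, "l": res.l, "w": res.w,
                "accuracy": res.accuracy, "correlation": res.correlation,
                "accuracy_inferred_only": res.accuracy_inferred_only,
                "accuracy_imputed_only": res.accuracy_imputed_only,
                "n_test": res.n_test, "reason": "",
            })
    if not results:
        raise RuntimeError("every case was skipped; nothing to summarise")
    good = {r.label for r in good_cases(list(results.values()), config.metric)}
    for row in rows:
        row["good"] = int(row["case"] in good) if row["status"] == "ok" else 0

    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(out_dir / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(audit, columns=["case", "filter", "dimension", "removed"]).to_csv(
        out_dir / "audit.tsv", sep="\t", index=False)
    _write_log(config, out_dir, "accuracy", {
        "n_input_sites": matrix.n_sites, "n_input_samples": matrix.n_samples,
        "n_dropped_records": matrix.n_dropped_sites,
        "n_prefiltered_sites": pre.matrix.n_sites,
        "n_cases_ok": len(results), "n_cases_skipped": len(rows) - len(results),
    })
    return df


def run_call_phase(config: RunConfig, case_label: str,
                   matrix: vcf_io.ReadCountMatrix | None = None) -> Path:
    """Apply one swept case's filters and fitted parameters; write the VCF.

    ``case_label`` must be an evaluated (non-skipped) row of the phase-1
    summary; its k, l and w are reused, not re-optimised.
    """
    out_dir = Path(config.out_dir)
    summary_path = out_dir / "summary.tsv"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"no summary at {summary_path}; run the accuracy phase first")
    df = pd.read_csv(summary_path, sep="\t", dtype={"case": str})
    ok = df[df["status"] == "ok"]
    match = ok[ok["case"] == case_label]
    if match.empty:
        raise ValueError(
            f"unknown case {case_label!r}; evaluated cases: "
            + ", ".join(ok["case"].tolist()))
    row = match.iloc[0]
    case = CaseSpec.from_label(case_label, maf_min=config.maf_min,
                               maf_depth=config.maf_depth,
                               hwe_alpha=config.hwe_alpha,
                               hwe_error=config.hwe_error)
    if matrix is None:
        matrix = vcf_io.read_vcf(config.input_vcf)
    model = GenotypeCallingModel(matrix, case,
                                 eval_config=config.eval,
                                 error_model=ErrorModel(config.error_rate))
    results = model.results_from_params(int(row["k"]), int(row["l"]),
                                        float(row["w"]))
    out_vcf = out_dir / f"called_{case_label.replace('/', '_')}.vcf"
    fd = results.to_vcf(out_vcf, meta={"seed": config.eval.seed})
    depth = fd.matrix.depth()
    n_total = depth.size
    n_blend = int((depth <= case.d).sum())
    _write_log(config, out_dir, "call", {
        "case": case_label, "output": out_vcf.name,
        "n_sites": fd.matrix.n_sites, "n_samples": fd.matrix.n_samples,
        "n_inferred_only": n_total - n_blend, "n_combined": n_blend,
        "n_uncallable": results.n_uncallable,
    })
    return out_vcf
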