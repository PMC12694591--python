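"""End-to-end differential abundance analysis and performance scoring.

The analysis runs, per study: (1) library-size and prevalence filters;
(2) covariate encoding and centering; (3) an unrestricted Gehan AFT fit
for every taxon; (4) the (spatial) median of the fitted interest
coefficients as the compositional null reference; (5) a restricted
score test per taxon of H0 "this taxon's interest coefficients equal
the reference"; (6) Benjamini-Hochberg adjustment of the per-taxon
p-values.

Coefficients are reported on the log relative-abundance scale: a
positive ``beta.x`` means the covariate increases the taxon's relative
abundance.  (Internally the AFT response is the *negative* log relative
abundance, so fitted values are negated on output.)
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .censoring import CountTable, filter_samples, filter_taxa, to_censored, zero_fraction
from .exceptions import CaftError, DesignError, NotEstimableError
from .gehan import DesignMatrix, SolverOptions, fit_restricted, fit_unrestricted
from .inference import ContrastSpec, interest_contrast, score_test
from .reference import CoefficientPanel, build_null_rhs
from .simulate import SimTruth

__all__ = [
    "RunConfig",
    "CaftResultTable",
    "PerformanceSummary",
    "bh_adjust",
    "encode_covariates",
    "run_caft",
    "replicate_metrics",
    "evaluate_performance",
]

log = logging.getLogger("caft")


@dataclass
class RunConfig:
    """Tunable settings of one analysis run.

    Defaults follow the package's documented pipeline: samples with
    library size strictly below ``min_library`` are removed first, then
    taxa present in fewer than ``min_presence_frac`` of the surviving
    samples; library sizes keep the pre-filter sequencing depths unless
    ``recompute_library_sizes`` is set.
    """

    min_library: int = 3000
    library_exclude_at_threshold: bool = False
    min_presence_frac: float = 0.10
    filter_order: str = "samples_first"  # or "taxa_first"
    recompute_library_sizes: bool = False
    fdr_threshold: float = 0.05
    variance_estimator: str = "rank"
    count_unconverged_in_bh: bool = False
    solver: SolverOptions = field(default_factory=SolverOptions)
    reference: str = "median"  # "mode" reserved, not implemented

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise CaftError("fdr_threshold must be in (0, 1)")
        if self.variance_estimator != "rank":
            raise CaftError("only the rank variance estimator is implemented")
        if self.reference != "median":
            raise CaftError("only the median reference is implemented")
        if self.filter_order not in ("samples_first", "taxa_first"):
            raise CaftError("filter_order must be 'samples_first' or 'taxa_first'")

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["solver"] = asdict(self.solver)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        solver = payload.pop("solver", None)
        cfg = cls(**payload)
        if solver is not None:
            cfg.solver = SolverOptions(**solver)
        return cfg


@dataclass
class CaftResultTable:
    """Per-taxon results plus run metadata.

    ``table`` columns: taxon_id, beta.<name>..., stat, df, pvalue,
    qvalue, detected, n_present, converged.  ``reference`` holds the
    null value (log-abundance scale) used as the right-hand side of
    every test.
    """

    table: pd.DataFrame
    reference: np.ndarray
    interest: Sequence[str]
    adjust: Sequence[str]
    config: RunConfig
    metadata: dict = field(default_factory=dict)

    def detected_taxa(self) -> list:
        return self.table.loc[self.table["detected"], "taxon_id"].tolist()


@dataclass
class PerformanceSummary:
    """Replicate-averaged operating characteristics."""

    type_i_error: float
    fdr_empirical: float
    sensitivity: float
    n_replicates: int
    alpha: float
    fdr_target: float


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def encode_covariates(
    metadata: pd.DataFrame,
    interest: Sequence[str],
    adjust: Sequence[str] = (),
) -> DesignMatrix:
    """Numeric, centered design from a metadata frame.

    Numeric columns are used as-is; two-level columns are coded 0/1 by
    sorted level order (logged, since the coefficient sign depends on
    it); columns with more levels expand to treatment-coded dummies
    against the first sorted level.  All columns are centered.
    """
    interest, adjust = list(interest), list(adjust)
    if set(interest) & set(adjust):
        raise CaftError("interest and adjustment covariates must be disjoint")
    cols, names, interest_idx = [], [], []
    for name in interest + adjust:
        if name not in metadata.columns:
            raise CaftError(f"covariate {name!r} missing from metadata")
        col = metadata[name]
        if col.isna().any():
            raise CaftError(f"covariate {name!r} has missing values")
        if pd.api.types.is_numeric_dtype(col):
            block = {name: col.to_numpy(dtype=float)}
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise DesignError(f"covariate {name!r} is constant")
            if len(levels) == 2:
                log.info("covariate %r coded %s=0, %s=1", name, levels[0], levels[1])
                block = {name: (col.astype(str) == levels[1]).to_numpy(dtype=float)}
            else:
                log.info("covariate %r expanded to dummies against level %s", name, levels[0])
                block = {
                    f"{name}[{lev}]": (col.astype(str) == lev).to_numpy(dtype=float)
                    for lev in levels[1:]
                }
        for cname, values in block.items():
            if name in interest:
                interest_idx.append(len(names))
            names.append(cname)
            cols.append(values - values.mean())
    X = np.column_stack(cols)
    return DesignMatrix(X=X, covariate_names=names, interest_indices=interest_idx)


def _align_metadata(table: CountTable, metadata: pd.DataFrame, sample_id_column: Optional[str]) -> pd.DataFrame:
    meta = metadata.set_index(sample_id_column) if sample_id_column else metadata
    meta.index = meta.index.astype(str)
    wanted = pd.Index(np.asarray(table.sample_ids, dtype=str))
    missing = wanted.difference(meta.index)
    if len(missing):
        raise CaftError(f"metadata missing {len(missing)} sample(s), e.g. {missing[0]!r}")
    extra = meta.index.difference(wanted)
    if len(extra):
        log.warning("metadata has %d sample(s) not in the count table; ignoring", len(extra))
    return meta.loc[wanted]


def run_caft(
    table: CountTable,
    metadata: pd.DataFrame,
    interest: Sequence[str],
    adjust: Sequence[str] = (),
    config: Optional[RunConfig] = None,
    sample_id_column: Optional[str] = None,
) -> CaftResultTable:
    """Full analysis of one study.  See the module docstring."""
    config = config or RunConfig()
    t0 = time.time()

    if config.filter_order == "samples_first":
        table = filter_samples(table, config.min_library, config.library_exclude_at_threshold)
        table = filter_taxa(table, config.min_presence_frac, config.recompute_library_sizes)
    else:
        table = filter_taxa(table, config.min_presence_frac, config.recompute_library_sizes)
        table = filter_samples(table, config.min_library, config.library_exclude_at_threshold)
    log.info(
        "after filtering: %d samples, %d taxa, zero fraction %.1f%%",
        table.n_samples, table.n_taxa, 100 * zero_fraction(table),
    )
    if table.n_taxa < 3:
        raise CaftError("fewer than 3 taxa survive filtering")

    meta = _align_metadata(table, metadata, sample_id_column)
    design = encode_covariates(meta, interest, adjust)

    taxa = [to_censored(table, t) for t in table.taxon_ids]
    fits = []
    for tx in taxa:
        try:
            fits.append(fit_unrestricted(tx, design, options=config.solver))
        except NotEstimableError:
            fits.append(None)
    betas = np.array(
        [f.beta_hat if f is not None else np.full(design.n_covariates, np.nan) for f in fits]
    )
    flags = np.array([f is not None and f.converged for f in fits])
    panel = CoefficientPanel(betas=betas, fitted_flags=flags, taxon_ids=table.taxon_ids)

    base = interest_contrast(design.n_covariates, design.interest_indices)
    contrast = build_null_rhs(panel, base)
    log.info("null reference (log-abundance scale): %s", -contrast.b)

    rows = []
    for tx, fit in zip(taxa, fits):
        if fit is None or not fit.converged:
            rows.append((tx, fit, None))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rfit = fit_restricted(tx, design, contrast, options=config.solver)
            res = score_test(tx, design, contrast, restricted_fit=rfit)
        rows.append((tx, fit, res))

    pvals = np.array([r.p_value if r is not None else np.nan for _, _, r in rows])
    if config.count_unconverged_in_bh:
        ok = np.isfinite(pvals)
        q = np.full_like(pvals, np.nan)
        if ok.sum():
            m = len(pvals)
            order = np.argsort(pvals[ok])
            ranked = pvals[ok][order] * m / (np.arange(ok.sum()) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            qq = np.empty(ok.sum())
            qq[order] = np.minimum(ranked, 1.0)
            q[ok] = qq
    else:
        q = bh_adjust(pvals)

    records = []
    for (tx, fit, res), p, qv in zip(rows, pvals, q):
        rec = {"taxon_id": tx.taxon_id}
        beta = -fit.beta_hat if fit is not None else np.full(design.n_covariates, np.nan)
        for name, val in zip(design.covariate_names, beta):
            rec[f"beta.{name}"] = val
        rec["stat"] = res.statistic if res is not None else np.nan
        rec["df"] = res.df if res is not None else pd.NA
        rec["pvalue"] = p
        rec["qvalue"] = qv
        rec["detected"] = bool(np.isfinite(qv) and qv <= config.fdr_threshold)
        rec["n_present"] = int((tx.delta == 1).sum())
        rec["converged"] = bool(fit is not None and fit.converged)
        records.append(rec)
    result = pd.DataFrame.from_records(records)
    log.info(
        "tested %d taxa, %d detected at FDR %.2f (%.2f s)",
        int(np.isfinite(pvals).sum()), int(result["detected"].sum()),
        config.fdr_threshold, time.time() - t0,
    )
    return CaftResultTable(
        table=result,
        reference=-contrast.b,
        interest=list(interest),
        adjust=list(adjust),
        config=config,
        metadata={
            "n_samples": table.n_samples,
            "n_taxa": table.n_taxa,
            "zero_fraction": zero_fraction(table),
            "config_hash": config.digest(),
        },
    )


def replicate_metrics(
    results: CaftResultTable,
    truth: SimTruth,
    alpha: float = 0.05,
    fdr_target: float = 0.05,
    interest_truth: str = "x1",
) -> dict:
    """Operating characteristics of one replicate against ground truth.

    ``type_i_error`` is the fraction of analyzed x1-null taxa with
    ``p <= alpha``; ``fdp`` the false-discovery proportion among BH
    detections at ``fdr_target`` (0 when nothing is detected);
    ``sensitivity`` the fraction of analyzed x1-causal taxa detected.
    """
    tab = results.table
    analyzed = tab[np.isfinite(tab["pvalue"].to_numpy(dtype=float))]
    causal = truth.causal_x1 if interest_truth == "x1" else truth.causal_x2
    is_causal = analyzed["taxon_id"].isin(causal).to_numpy()
    p = analyzed["pvalue"].to_numpy(dtype=float)
    q = analyzed["qvalue"].to_numpy(dtype=float)
    n_null = int((~is_causal).sum())
    type_i = float((p[~is_causal] <= alpha).mean()) if n_null else 0.0
    det = q <= fdr_target
    fdp = float((det & ~is_causal).sum() / det.sum()) if det.sum() else 0.0
    n_causal = int(is_causal.sum())
    sens = float((det & is_causal).sum() / n_causal) if n_causal else 0.0
    return {"type_i_error": type_i, "fdp": fdp, "sensitivity": sens,
            "n_null": n_null, "n_causal": n_causal}


def evaluate_performance(
    replicates,
    alpha: float = 0.05,
    fdr_target: float = 0.05,
) -> PerformanceSummary:
    """Average :func:`replicate_metrics` over ``(results, truth)`` pairs."""
    metrics = [replicate_metrics(r, t, alpha, fdr_target) for r, t in replicates]
    if not metrics:
        raise CaftError("no replicates to evaluate")
    return PerformanceSummary(
        type_i_error=float(np.mean([m["type_i_error"] for m in metrics])),
        fdr_empirical=float(np.mean([m["fdp"] for m in metrics])),
        sensitivity=float(np.mean([m["sensitivity"] for m in metrics])),
        n_replicates=len(metrics),
        alpha=alpha,
        fdr_target=fdr_target,
    )
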