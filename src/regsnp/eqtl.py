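"""eQTL association, cross-dataset support counting and case-control DE.

The association model is an additive ordinary-least-squares regression of
expression on genotype dosage (optionally with covariates); per-variant
support counts how many independent eQTL datasets show a nominally
significant association; case-control differential expression is a
per-gene Welch t-test on log2(x+1) with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, UndefinedAssociationError
from .formats import MISSING

__all__ = ["EqtlResult", "SupportSummary", "DeResult", "eqtl_association",
           "cross_dataset_support", "case_control_de"]


@dataclass(frozen=True)
class EqtlResult:
    variant: str
    gene_id: str
    dataset: str
    beta: float
    se: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class SupportSummary:
    variant: str
    n_datasets_significant: int
    genes: tuple[str, ...]


@dataclass(frozen=True)
class DeResult:
    gene_id: str
    log_fold_change: float
    pvalue: float
    qvalue: float
    significant: bool


def eqtl_association(dosages: np.ndarray, expression: np.ndarray,
                     covariates: np.ndarray | None = None,
                     variant: str = ".", gene_id: str = ".",
                     dataset: str = ".") -> EqtlResult:
    """OLS of expression on dosage (plus covariates); two-sided t-test on beta.

    Missing dosages (MISSING code or NaN) and NaN expression values are
    dropped pairwise-complete before fitting.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    if d.shape != y.shape:
        raise InputError("dosage and expression lengths differ")
    keep = (d != MISSING) & ~np.isnan(d) & ~np.isnan(y)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != d.shape[0]:
            cov = cov.T
        keep &= ~np.isnan(cov).any(axis=1)
    d, y = d[keep], y[keep]
    if np.ptp(d) == 0:
        raise UndefinedAssociationError("constant dosage: association undefined")

    if covariates is None:
        if d.size < 3:
            raise InputError("need at least 3 complete samples")
        res = stats.linregress(d, y)
        return EqtlResult(variant, gene_id, dataset, float(res.slope),
                          float(res.stderr), float(res.pvalue), int(d.size))

    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([d, cov[keep]]))
    fit = sm.OLS(y, X).fit()
    return EqtlResult(variant, gene_id, dataset, float(fit.params[1]),
                      float(fit.bse[1]), float(fit.pvalues[1]), int(d.size))


def cross_dataset_support(results: list[EqtlResult], alpha: float = 0.05
                          ) -> tuple[list[SupportSummary], dict[int, list[str]]]:
    """Per-SNP count of datasets with any significant gene association.

    Returns the per-variant summaries and nested tiers: tiers[k] lists the
    variants significant in at least k datasets (k = 1..n_datasets).
    """
    datasets = sorted({r.dataset for r in results})
    by_var: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for r in results:
        if r.pvalue < alpha:
            by_var[r.variant][r.dataset].add(r.gene_id)
    all_vars = sorted({r.variant for r in results})
    summaries = []
    for v in all_vars:
        sig = by_var.get(v, {})
        genes = sorted({g for gs in sig.values() for g in gs})
        summaries.append(SupportSummary(v, len(sig), tuple(genes)))
    tiers = {k: [s.variant for s in summaries if s.n_datasets_significant >= k]
             for k in range(1, len(datasets) + 1)}
    return summaries, tiers


def case_control_de(expression: np.ndarray, labels: np.ndarray,
                    gene_ids: list[str] | None = None,
                    alpha_q: float = 0.05) -> list[DeResult]:
    """Per-gene Welch t-test on log2(x+1) between cases and controls with BH.

    ``expression`` is genes x samples; ``labels`` is 1/True for cases. The
    log fold change is the case-minus-control difference of mean log2(x+1).
    """
    X = np.asarray(expression, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if X.ndim != 2 or X.shape[1] != lab.size:
        raise InputError("expression must be genes x samples matching labels")
    if lab.sum() < 2 or (~lab).sum() < 2:
        raise InputError("need at least 2 samples per group")
    L = np.log2(X + 1.0)
    cases, ctrls = L[:, lab], L[:, ~lab]
    t, p = stats.ttest_ind(cases, ctrls, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    lfc = cases.mean(axis=1) - ctrls.mean(axis=1)
    rej, q, _, _ = multipletests(p, alpha=alpha_q, method="fdr_bh")
    ids = gene_ids if gene_ids is not None else [f"gene_{i}" for i in range(len(p))]
    return [DeResult(ids[i], float(lfc[i]), float(p[i]), float(q[i]), bool(rej[i]))
            for i in range(len(p))]
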