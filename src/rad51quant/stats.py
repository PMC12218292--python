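"""Pairwise strain comparisons via binomial logistic regression with FDR.

For a pair of strains the binary response ``condition`` indicates which
strain a cell comes from, and three logit models test whether image
features discriminate the strains:

* M1: condition ~ 1 + hasFilament + batch              (all cells)
* M2: condition ~ 1 + filamentLength + filamentIntensity + batch
      (Simple cells only — the only cells carrying those features)
* M3: condition ~ 1 + spotIntensity + batch            (Foci cells only)

Batch enters as a categorical fixed effect absorbing session-level
intensity differences.  Each coefficient of interest is tested with a
Wald t-statistic (estimate / SE against a t distribution with residual
degrees of freedom; a normal reference is available), and all p-values of
a comparison set are jointly corrected with the Benjamini-Hochberg false
discovery rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "TestResult",
    "MODELS",
    "fit_pair_model",
    "fdr_adjust",
    "compare_all",
    "category_proportions",
    "significance_stars",
]


@dataclass(frozen=True)
class ModelSpec:
    """One of the three logistic models tested per strain pair."""

    model_id: str
    predictors: tuple           # continuous/binary cell features, batch added separately
    subset_category: str | None = None  # restrict to cells of this category

    @property
    def terms_of_interest(self) -> tuple:
        return self.predictors


MODELS = {
    "M1": ModelSpec("M1", ("hasFilament",)),
    "M2": ModelSpec("M2", ("filamentLength", "filamentIntensity"), subset_category="Simple"),
    "M3": ModelSpec("M3", ("spotIntensity",), subset_category="Foci"),
}


@dataclass
class TestResult:
    """One tested coefficient of one model for one strain pair."""

    pair: tuple
    model_id: str
    term: str
    estimate: float
    se: float
    t: float
    p: float          # NaN when the fit was flagged
    q: float = np.nan
    flag: str = ""    # "", "separation", "no_fit:<reason>", "batch_dropped"

    def to_row(self) -> dict:
        return {
            "strain_a": self.pair[0], "strain_b": self.pair[1],
            "model": self.model_id, "term": self.term,
            "estimate": self.estimate, "se": self.se, "t": self.t,
            "p": self.p, "q": self.q, "flag": self.flag,
            "stars": significance_stars(self.q),
        }


def significance_stars(q: float) -> str:
    if not np.isfinite(q):
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def _design_matrix(sub: pd.DataFrame, predictors: tuple) -> tuple[np.ndarray, list, str]:
    """Intercept + predictors + batch dummies (first level dropped).

    Returns (X, column names, flag) where flag notes a dropped batch term
    when all cells share one batch.
    """
    columns = [np.ones(len(sub))]
    names = ["Intercept"]
    for term in predictors:
        columns.append(sub[term].to_numpy(dtype=float))
        names.append(term)
    flag = ""
    levels = sorted(sub["batch"].astype(str).unique())
    if len(levels) > 1:
        for level in levels[1:]:
            columns.append((sub["batch"].astype(str) == level).to_numpy(dtype=float))
            names.append(f"batch[{level}]")
    else:
        flag = "batch_dropped"
    return np.column_stack(columns), names, flag


def fit_pair_model(
    records: pd.DataFrame,
    pair: tuple,
    spec: ModelSpec,
    use_t: bool = True,
) -> list[TestResult]:
    """Fit one logit model for one strain pair; test the terms of interest.

    Cells with missing model predictors are dropped (M2 thereby uses
    Simple cells only and M3 Foci cells only).  Complete separation or
    non-convergence yields flagged results with missing p rather than a
    silent NaN.
    """
    import statsmodels.api as sm

    strain_a, strain_b = pair
    sub = records[records["strain"].isin(pair)].copy()
    if spec.subset_category is not None:
        sub = sub[sub["category"] == spec.subset_category]
    needed = list(spec.predictors)
    sub = sub.dropna(subset=needed + ["category"])
    counts = sub["strain"].value_counts()
    if counts.get(strain_a, 0) < 2 or counts.get(strain_b, 0) < 2:
        return [
            TestResult(pair, spec.model_id, term, np.nan, np.nan, np.nan, np.nan,
                       flag="no_fit:too_few_cells")
            for term in spec.terms_of_interest
        ]
    y = (sub["strain"] == strain_b).to_numpy(dtype=float)
    X, names, flag = _design_matrix(sub, spec.predictors)

    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation / non-convergence is detected and flagged below
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = np.asarray(fit.params), np.asarray(fit.bse)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        params = np.full(X.shape[1], np.nan)
        bse = np.full(X.shape[1], np.nan)
        converged = False

    separated = (
        not converged
        or not np.all(np.isfinite(bse))
        or float(np.nanmax(np.abs(params))) > 25.0
    )
    df_resid = len(sub) - X.shape[1]
    results = []
    for term in spec.terms_of_interest:
        j = names.index(term)
        if separated or df_resid <= 0:
            results.append(TestResult(pair, spec.model_id, term,
                                      float(params[j]), float(bse[j]), np.nan, np.nan,
                                      flag="separation"))
            continue
        est, se = float(params[j]), float(bse[j])
        tval = est / se
        if use_t:
            p = 2.0 * sps.t.sf(abs(tval), df_resid)
        else:
            p = 2.0 * sps.norm.sf(abs(tval))
        results.append(TestResult(pair, spec.model_id, term, est, se,
                                  float(tval), float(p), flag=flag))
    return results


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values, capped
    at 1; order-preserving.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_all(
    records: pd.DataFrame,
    pairs: list,
    specs: list | None = None,
    use_t: bool = True,
) -> pd.DataFrame:
    """All (pair, model, term) Wald tests with a joint BH correction.

    One row per tested coefficient, in deterministic (pair, model, term)
    order.  Flagged fits keep their rows with missing p and are excluded
    from the BH input; their count can be read off the ``flag`` column.
    """
    specs = specs if specs is not None else [MODELS["M1"], MODELS["M2"], MODELS["M3"]]
    strains = set(records["strain"].unique())
    for pair in pairs:
        unknown = set(pair) - strains
        if unknown:
            raise ValueError(f"pair {pair} references unknown strain(s) {sorted(unknown)}")
    all_results: list[TestResult] = []
    for pair in pairs:
        for spec in sorted(specs, key=lambda s: s.model_id):
            all_results.extend(fit_pair_model(records, tuple(pair), spec, use_t=use_t))
    ps = np.array([r.p for r in all_results], dtype=float)
    ok = np.isfinite(ps)
    if ok.any():
        qs = fdr_adjust(ps[ok])
        it = iter(qs)
        for r, valid in zip(all_results, ok):
            r.q = float(next(it)) if valid else np.nan
    return pd.DataFrame([r.to_row() for r in all_results])


def all_pairs(strains) -> list:
    """All unordered strain pairs, in sorted order."""
    return list(itertools.combinations(sorted(strains), 2))


def category_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-strain category fractions and cell counts (the pie-chart table).

    Cells with a missing category (failed analyses) are excluded; the
    fractions of each strain sum to 1.
    """
    from .quantify import CATEGORIES

    usable = records.dropna(subset=["category"])
    rows = []
    for strain, group in usable.groupby("strain", sort=True):
        n = len(group)
        if n == 0:
            continue
        row = {"strain": strain, "n": n}
        for cat in CATEGORIES:
            row[cat] = float((group["category"] == cat).sum() / n)
        rows.append(row)
    return pd.DataFrame(rows)
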