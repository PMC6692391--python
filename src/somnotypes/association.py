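"""Phenotype coding, risk-allele orientation, GRS, association tests, meta.

The genetic-risk-score stage follows the standard weighted-allele-count
construction: score_i = sum_j w_j * dosage_ij with weights taken from the
discovery scan, after all variants are oriented to the sleepiness-increasing
allele.  Association testing is ordinary least squares for quantitative traits
and maximum-likelihood logistic regression (IRLS) for binary traits, with
covariate adjustment.  Cohort-level p-values are combined with Fisher's
method, and Bonferroni flags implement the per-table multiple-testing rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "MetaResult",
    "encode_phenotypes",
    "orient_to_risk_allele",
    "build_z_matrix",
    "GeneticRiskScore",
    "compute_grs",
    "assoc_linear",
    "assoc_logistic",
    "fisher_meta",
    "bonferroni_flag",
]


# ---------------------------------------------------------------------------
# phenotype coding

_MISSING = {"do not know", "prefer not to answer", ""}
_SLEEPINESS = {"never/rarely": 1, "sometimes": 2, "often": 3,
               "all of the time": 4}
_INSOMNIA = {"never/rarely": 0, "sometimes": 0, "usually": 1}
_CHRONOTYPE = {
    "definitely an evening person": 1,
    "more an evening than a morning person": 2,
    "more a morning than an evening person": 3,
    "definitely a morning person": 4,
}
_NAPS = {"never/rarely": 1, "sometimes": 2, "usually": 3}


def _map_categorical(series: pd.Series, mapping: dict, name: str) -> pd.Series:
    s = series.astype("string").str.strip().str.lower()
    out = s.map(mapping)
    unknown = s.notna() & out.isna() & ~s.isin(_MISSING)
    if unknown.any():
        bad = sorted(s[unknown].unique())
        raise ValueError(f"unknown {name} categories: {bad}")
    return out.astype(float)


def encode_phenotypes(raw: pd.DataFrame) -> pd.DataFrame:
    """Code survey responses into analysis phenotypes.

    Recognised input columns (all optional): ``sleepiness``, ``insomnia``,
    ``chronotype``, ``naps`` (categorical text) and ``sleep_duration_h``
    (numeric).  Sleepiness becomes a continuous 1-4 severity score; frequent
    insomnia cases are the "usually" responders; short sleep is duration
    < 7 h and long sleep > 8 h, both contrasted against the inclusive 7-8 h
    control band (the opposite extreme is set missing).  "Do not know" /
    "prefer not to answer" are set missing; unknown categories raise.
    """
    out = pd.DataFrame(index=raw.index)
    if "sleepiness" in raw:
        out["sleepiness_score"] = _map_categorical(
            raw["sleepiness"], _SLEEPINESS, "sleepiness")
    if "sleep_duration_h" in raw:
        dur = pd.to_numeric(raw["sleep_duration_h"], errors="coerce")
        out["sleep_duration_h"] = dur
        short = pd.Series(np.nan, index=raw.index)
        short[dur < 7] = 1.0
        short[(dur >= 7) & (dur <= 8)] = 0.0
        long = pd.Series(np.nan, index=raw.index)
        long[dur > 8] = 1.0
        long[(dur >= 7) & (dur <= 8)] = 0.0
        out["short_sleep"] = short
        out["long_sleep"] = long
    if "insomnia" in raw:
        out["insomnia_case"] = _map_categorical(
            raw["insomnia"], _INSOMNIA, "insomnia")
    if "chronotype" in raw:
        out["chronotype"] = _map_categorical(
            raw["chronotype"], _CHRONOTYPE, "chronotype")
    if "naps" in raw:
        out["naps"] = _map_categorical(raw["naps"], _NAPS, "naps")
    for cov in ("age", "sex", "array", "bmi"):
        if cov in raw:
            out[cov] = pd.to_numeric(raw[cov], errors="coerce")
    pcs = [c for c in raw.columns if c.upper().startswith("PC")]
    for c in pcs:
        out[c] = pd.to_numeric(raw[c], errors="coerce")
    return out


# ---------------------------------------------------------------------------
# risk-allele orientation and z-matrix assembly


def _align_alleles(base: pd.DataFrame, other: pd.DataFrame):
    """Align ``other`` to ``base``'s effect allele on shared SNPs.

    Returns the aligned table (betas/z negated and EAF complemented where the
    allele pair was swapped) and the list of SNPs dropped for allele
    mismatch.
    """
    shared = base.index.intersection(other.index)
    o = other.loc[shared].copy()
    b = base.loc[shared]
    same = (o["EA"] == b["EA"]) & (o["OA"] == b["OA"])
    swapped = (o["EA"] == b["OA"]) & (o["OA"] == b["EA"])
    dropped = list(shared[~(same | swapped)])
    _flip_rows(o, swapped)
    o.loc[swapped, ["EA", "OA"]] = b.loc[swapped, ["EA", "OA"]].to_numpy()
    return o.loc[same | swapped], dropped


def _flip_rows(table: pd.DataFrame, mask) -> None:
    """In-place allele flip: negate effects, complement the frequency."""
    for col in ("BETA", "Z"):
        if col in table:
            table.loc[mask, col] = -table.loc[mask, col]
    if "EAF" in table:
        table.loc[mask, "EAF"] = 1.0 - table.loc[mask, "EAF"]


def orient_to_risk_allele(sleepiness: pd.DataFrame,
                          others: dict[str, pd.DataFrame] | None = None):
    """Orient all effects to the sleepiness-increasing (risk) allele.

    ``sleepiness`` and each companion table are summary-statistics frames
    indexed by SNP with columns EA, OA, BETA, SE (optionally EAF, Z, P).
    Wherever the sleepiness beta is negative the allele pair is swapped and
    every table's effect at that SNP is negated in tandem (EAF complemented).
    Companion rows whose alleles match neither orientation are dropped and
    logged.  Returns ``(oriented_sleepiness, oriented_others, dropped_log)``.
    """
    base = sleepiness.copy()
    flip = base["BETA"] < 0
    aligned: dict[str, pd.DataFrame] = {}
    dropped_log: dict[str, list] = {}
    for trait, table in (others or {}).items():
        o, dropped = _align_alleles(base, table)
        if dropped:
            logger.warning("%s: dropped %d SNP(s) with mismatched alleles: %s",
                           trait, len(dropped), dropped)
            dropped_log[trait] = dropped
        f = flip.reindex(o.index, fill_value=False)
        _flip_rows(o, f)
        o.loc[f, ["EA", "OA"]] = o.loc[f, ["OA", "EA"]].to_numpy()
        aligned[trait] = o
    _flip_rows(base, flip)
    base.loc[flip, ["EA", "OA"]] = base.loc[flip, ["OA", "EA"]].to_numpy()
    return base, aligned, dropped_log


def build_z_matrix(oriented: dict[str, pd.DataFrame],
                   trait_order: list[str]) -> pd.DataFrame:
    """Assemble the locus x trait z-score matrix (z = beta / SE).

    Columns follow ``trait_order``; loci missing from any trait table are
    excluded with a logged warning.
    """
    loci = None
    for trait in trait_order:
        idx = oriented[trait].index
        loci = idx if loci is None else loci.intersection(idx)
    all_loci = pd.Index([])
    for trait in trait_order:
        all_loci = all_loci.union(oriented[trait].index)
    missing = all_loci.difference(loci)
    if len(missing):
        logger.warning("excluding %d locus/loci missing from some trait "
                       "table: %s", len(missing), list(missing))
    cols = {}
    for trait in trait_order:
        t = oriented[trait].loc[loci]
        cols[trait] = (t["Z"] if "Z" in t and t["Z"].notna().all()
                       else t["BETA"] / t["SE"])
    return pd.DataFrame(cols, index=loci)


# ---------------------------------------------------------------------------
# genetic risk score


class GeneticRiskScore(BaseEstimator, TransformerMixin):
    """Weighted allele-count genetic risk score.

    ``transform`` maps a person x variant dosage frame (effect-allele counts
    in [0, 2]) to ``score_i = sum_j w_j * dosage_ij``.  Missing dosages are
    imputed with the per-variant mean learned at ``fit`` (equivalently 2*EAF
    under Hardy-Weinberg); the imputation count is logged.

    Parameters
    ----------
    weights : pandas.Series
        Per-variant effect estimates from the discovery scan, indexed by
        variant ID and aligned to the risk allele.
    """

    def __init__(self, weights: pd.Series | None = None):
        self.weights = weights

    def fit(self, X: pd.DataFrame, y=None):
        if self.weights is None:
            raise ValueError("weights must be provided")
        w = pd.Series(self.weights, dtype=float)
        shared = X.columns.intersection(w.index)
        if len(shared) == 0:
            raise ValueError("dosage matrix and weights share no variants")
        if len(shared) < len(w):
            logger.warning("%d weighted variant(s) absent from dosages",
                           len(w) - len(shared))
        self.variants_ = shared
        self.weights_ = w.loc[shared]
        self.impute_means_ = X[shared].mean(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        D = X[self.variants_].astype(float)
        if ((D < -1e-9) | (D > 2 + 1e-9)).any().any():
            raise ValueError("dosages must lie in [0, 2]")
        n_missing = int(D.isna().sum().sum())
        if n_missing:
            logger.info("mean-imputing %d missing dosage value(s)", n_missing)
            D = D.fillna(self.impute_means_)
        return pd.Series(D.to_numpy() @ self.weights_.to_numpy(),
                         index=X.index, name="grs")


def compute_grs(dosages: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Per-individual weighted allele-count score (see GeneticRiskScore)."""
    return GeneticRiskScore(weights).fit(dosages).transform(dosages)


# ---------------------------------------------------------------------------
# association tests


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    n: int
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def _design(x, covariates) -> np.ndarray:
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C.reshape(-1, 1)
        x = np.hstack([x, C])
    return sm.add_constant(x, has_constant="add")


def assoc_linear(y, x, covariates=None) -> AssocResult:
    """OLS of ``y`` on ``x`` adjusting for covariates; two-sided t-test p."""
    y = np.asarray(y, dtype=float)
    if np.ptp(np.asarray(x, dtype=float)) == 0:
        raise ValueError("predictor is constant")
    X = _design(x, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    return AssocResult(beta=float(fit.params[1]), se=float(fit.bse[1]),
                       p=float(fit.pvalues[1]), n=int(fit.nobs))


def assoc_logistic(case_status, x, covariates=None, tol: float = 1e-8,
                   maxiter: int = 50) -> AssocResult:
    """Maximum-likelihood logistic regression via IRLS.

    Reports the log-odds ``beta`` with a normal-approximation two-sided p,
    plus OR = exp(beta) with its 95% CI ``exp(beta +/- 1.96 se)``.
    """
    y = np.asarray(case_status, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("case_status must contain both classes coded 0/1")
    X = _design(x, covariates)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
        tol=tol, maxiter=maxiter)
    if not fit.converged:
        raise RuntimeError("logistic fit did not converge "
                           "(possible separation)")
    beta, se = float(fit.params[1]), float(fit.bse[1])
    z = beta / se
    return AssocResult(
        beta=beta, se=se, p=float(2 * stats.norm.sf(abs(z))), n=int(fit.nobs),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
    )


# ---------------------------------------------------------------------------
# meta-analysis and multiple testing


@dataclass
class MetaResult:
    fisher_statistic: float
    df: int
    p: float


def fisher_meta(p_values) -> MetaResult:
    """Fisher's combined probability test over cohort p-values.

    X = -2 * sum(ln p_k) ~ chi-square with 2K degrees of freedom under the
    null.  Zero p-values are rejected: floor them explicitly (e.g. at machine
    epsilon) before calling if that is the intended behaviour.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor zeros explicitly")
    X = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return MetaResult(fisher_statistic=X, df=df,
                      p=float(stats.chi2.sf(X, df)))


def bonferroni_flag(p: float, m_tests: int) -> bool:
    """True when ``p`` survives Bonferroni correction for ``m_tests`` tests."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return bool(p < 0.05 / m_tests)
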