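"""Two-sample summary-level Mendelian randomization.

Given per-SNP effects of J instruments on an exposure (gamma_j, se) and on an
outcome (Gamma_j, se) from non-overlapping GWAS, the inverse-variance-weighted
(IVW) estimator combines the per-SNP Wald ratios beta_j = Gamma_j / gamma_j
with first-order weights w_j = gamma_j^2 / se_Gamma_j^2:

    beta_IVW = sum(w_j beta_j) / sum(w_j),   SE = (sum w_j)^(-1/2)

which assumes no horizontal pleiotropy.  Cochran's Q about the IVW slope
diagnoses heterogeneity; when it signals pleiotropy, MR-Egger on the radial
scale (regressing beta_j * sqrt(w_j) on sqrt(w_j) with a free intercept)
re-estimates the slope while absorbing directional pleiotropy into the
intercept, with Rucker's Q as the corresponding fit statistic.  Instrument
strength is summarised by the mean F statistic and by I^2_GX (the
regression-dilution diagnostic for MR-Egger).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "MrEstimate",
    "HeterogeneityStats",
    "harmonize",
    "wald_weights",
    "ivw",
    "radial_egger",
    "instrument_strength",
    "mr_analyze",
    "IVWEstimator",
    "RadialEggerEstimator",
]

_Z975 = 1.959963984540054
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


@dataclass
class HeterogeneityStats:
    cochran_q: float | None = None
    cochran_df: int | None = None
    cochran_p: float | None = None
    rucker_q: float | None = None
    rucker_df: int | None = None
    rucker_p: float | None = None
    mean_f: float | None = None
    i2_gx: float | None = None


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
              ) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect alleles.

    Both tables are summary-statistics frames with columns SNP, EA, OA, BETA,
    SE (optionally EAF).  Outcome betas are negated (and EAF complemented)
    where the allele pair is swapped, including strand-complement matches.
    Palindromic variants (A/T or C/G) with exposure EAF inside
    ``palindromic_eaf_window`` are dropped, as are unresolvable allele pairs;
    drops are logged.  Returns an instrument frame with columns
    beta_exposure/se_exposure/beta_outcome/se_outcome keyed by SNP.
    """
    e = exposure.set_index("SNP") if "SNP" in exposure.columns else exposure
    o = outcome.set_index("SNP") if "SNP" in outcome.columns else outcome
    shared = e.index.intersection(o.index)
    if len(shared) == 0:
        raise ValueError("no shared variants between exposure and outcome")
    rows, dropped = [], []
    lo, hi = palindromic_eaf_window
    for snp in shared:
        ee, oo = e.loc[snp], o.loc[snp]
        ea, oa = ee["EA"], ee["OA"]
        if _is_palindromic(ea, oa):
            eaf = ee.get("EAF", np.nan)
            if not np.isfinite(eaf) or lo <= eaf <= hi:
                dropped.append((snp, "palindromic"))
                continue
        flip = None
        if (oo["EA"], oo["OA"]) == (ea, oa):
            flip = False
        elif (oo["EA"], oo["OA"]) == (oa, ea):
            flip = True
        elif not _is_palindromic(ea, oa):
            cea, coa = _COMPLEMENT.get(oo["EA"]), _COMPLEMENT.get(oo["OA"])
            if (cea, coa) == (ea, oa):
                flip = False
            elif (cea, coa) == (oa, ea):
                flip = True
        if flip is None:
            dropped.append((snp, "allele mismatch"))
            continue
        bo = -float(oo["BETA"]) if flip else float(oo["BETA"])
        row = {"SNP": snp, "EA": ea, "OA": oa,
               "beta_exposure": float(ee["BETA"]),
               "se_exposure": float(ee["SE"]),
               "beta_outcome": bo, "se_outcome": float(oo["SE"])}
        if "EAF" in e.columns:
            row["EAF"] = float(ee["EAF"])
        if "EAF" in o.columns:
            row["EAF_outcome"] = (1.0 - float(oo["EAF"]) if flip
                                  else float(oo["EAF"]))
        rows.append(row)
    if dropped:
        logger.warning("harmonization dropped %d variant(s): %s",
                       len(dropped), dropped)
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# estimators


def wald_weights(instruments: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios and first-order IVW weights.

    ratio_j = beta_outcome / beta_exposure;
    w_j = beta_exposure^2 / se_outcome^2.  SNPs with a zero exposure effect
    are excluded with a log entry.
    """
    inst = instruments.copy()
    zero = inst["beta_exposure"] == 0
    if zero.any():
        logger.warning("excluding %d SNP(s) with zero exposure effect",
                       int(zero.sum()))
        inst = inst.loc[~zero]
    inst["ratio"] = inst["beta_outcome"] / inst["beta_exposure"]
    inst["weight"] = inst["beta_exposure"] ** 2 / inst["se_outcome"] ** 2
    return inst


def ivw(instruments: pd.DataFrame) -> tuple[MrEstimate, HeterogeneityStats]:
    """Fixed-effect inverse-variance-weighted estimate with Cochran's Q."""
    inst = instruments if "weight" in instruments.columns \
        else wald_weights(instruments)
    r = inst["ratio"].to_numpy(dtype=float)
    w = inst["weight"].to_numpy(dtype=float)
    if r.size < 2:
        raise ValueError("IVW needs at least 2 instruments")
    if w.sum() <= 0:
        raise ValueError("all IVW weights are zero")
    beta = float((w * r).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    q = float((w * (r - beta) ** 2).sum())
    df = r.size - 1
    z = beta / se
    est = MrEstimate(method="IVW", beta=beta, se=se,
                     ci_low=beta - _Z975 * se, ci_high=beta + _Z975 * se,
                     p=float(2 * stats.norm.sf(abs(z))))
    het = HeterogeneityStats(cochran_q=q, cochran_df=df,
                             cochran_p=float(stats.chi2.sf(q, df)))
    return est, het


def radial_egger(instruments: pd.DataFrame
                 ) -> tuple[MrEstimate, HeterogeneityStats]:
    """MR-Egger regression on the radial plot scale.

    Least squares of ratio_j * sqrt(w_j) on sqrt(w_j) with a free intercept:
    the slope is the pleiotropy-adjusted causal estimate and the intercept the
    directional-pleiotropy term.  Rucker's Q is the residual sum of squares
    (df = J - 2); standard errors carry a multiplicative overdispersion factor
    max(1, sqrt(Q_R / (J - 2))).
    """
    inst = instruments if "weight" in instruments.columns \
        else wald_weights(instruments)
    r = inst["ratio"].to_numpy(dtype=float)
    x = np.sqrt(inst["weight"].to_numpy(dtype=float))
    if r.size < 3:
        raise ValueError("radial MR-Egger needs at least 3 instruments")
    if np.ptp(x) == 0:
        raise ValueError("collinear radial design: all sqrt-weights equal")
    y = r * x
    X = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    q = float(resid @ resid)
    df = r.size - 2
    phi = max(1.0, np.sqrt(q / df))
    cov_unit = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov_unit)) * phi
    intercept, slope = float(coef[0]), float(coef[1])
    se_i, se_s = float(se[0]), float(se[1])
    est = MrEstimate(
        method="radial-Egger", beta=slope, se=se_s,
        ci_low=slope - _Z975 * se_s, ci_high=slope + _Z975 * se_s,
        p=float(2 * stats.norm.sf(abs(slope / se_s))),
        intercept=intercept, intercept_se=se_i,
        intercept_p=float(2 * stats.norm.sf(abs(intercept / se_i))),
    )
    het = HeterogeneityStats(rucker_q=q, rucker_df=df,
                             rucker_p=float(stats.chi2.sf(q, df)))
    return est, het


def instrument_strength(instruments: pd.DataFrame) -> tuple[float, float]:
    """Mean F statistic and I^2_GX instrument-strength diagnostics.

    F_j = gamma_j^2 / se_gamma_j^2.  I^2_GX = max(0, (Q_GX - (J-1)) / Q_GX)
    with Q_GX the precision-weighted heterogeneity of the exposure effects
    about their 1/se^2-weighted mean; values near 1 indicate MR-Egger is
    safe from regression dilution.
    """
    g = instruments["beta_exposure"].to_numpy(dtype=float)
    s = instruments["se_exposure"].to_numpy(dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 instruments")
    mean_f = float(np.mean(g ** 2 / s ** 2))
    w = 1.0 / s ** 2
    gbar = float((w * g).sum() / w.sum())
    q_gx = float((w * (g - gbar) ** 2).sum())
    i2 = max(0.0, (q_gx - (g.size - 1)) / q_gx) if q_gx > 0 else 0.0
    return mean_f, i2


def mr_analyze(exposure: pd.DataFrame, outcome: pd.DataFrame,
               alpha_threshold: float = 0.003,
               heterogeneity_alpha: float = 0.05,
               reverse: bool = False) -> dict:
    """Full forward (and optionally reverse) two-sample MR report.

    Harmonize -> Wald ratios/weights -> IVW + Cochran's Q; when Q signals
    heterogeneity (p < ``heterogeneity_alpha``) the radial MR-Egger
    sensitivity analysis is added.  ``alpha_threshold`` is the
    multiple-comparison significance level for the IVW p-value.  With
    ``reverse=True`` the same pipeline is run with the tables swapped and
    attached under ``"reverse"``.
    """
    inst = wald_weights(harmonize(exposure, outcome))
    est, het = ivw(inst)
    het.mean_f, het.i2_gx = instrument_strength(inst)
    egger = None
    if het.cochran_p is not None and het.cochran_p < heterogeneity_alpha:
        egger, egger_het = radial_egger(inst)
        het.rucker_q = egger_het.rucker_q
        het.rucker_df = egger_het.rucker_df
        het.rucker_p = egger_het.rucker_p
    report = {
        "ivw": est,
        "egger": egger,
        "heterogeneity": het,
        "n_snps": int(len(inst)),
        "n_dropped": len(inst.attrs.get("dropped", [])),
        "significant": bool(est.p < alpha_threshold),
        "alpha_threshold": alpha_threshold,
    }
    if reverse:
        report["reverse"] = mr_analyze(
            outcome, exposure, alpha_threshold, heterogeneity_alpha)
    return report


# ---------------------------------------------------------------------------
# estimator classes


class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted MR as a scikit-learn style estimator.

    ``fit`` takes an instrument frame (columns beta_exposure, se_exposure,
    beta_outcome, se_outcome) and exposes estimate_, se_, ci_, pvalue_,
    cochran_q_, q_pvalue_, mean_f_, i2_gx_, n_snps_.
    """

    def fit(self, X: pd.DataFrame, y=None):
        inst = wald_weights(X)
        est, het = ivw(inst)
        self.estimate_, self.se_, self.pvalue_ = est.beta, est.se, est.p
        self.ci_ = (est.ci_low, est.ci_high)
        self.cochran_q_ = het.cochran_q
        self.q_df_ = het.cochran_df
        self.q_pvalue_ = het.cochran_p
        self.mean_f_, self.i2_gx_ = instrument_strength(inst)
        self.n_snps_ = int(len(inst))
        return self


class RadialEggerEstimator(BaseEstimator):
    """Radial MR-Egger as a scikit-learn style estimator.

    Adds intercept_, intercept_se_, intercept_pvalue_ (directional
    pleiotropy) and rucker_q_ to the IVW-style attributes.
    """

    def fit(self, X: pd.DataFrame, y=None):
        inst = wald_weights(X)
        est, het = radial_egger(inst)
        self.estimate_, self.se_, self.pvalue_ = est.beta, est.se, est.p
        self.ci_ = (est.ci_low, est.ci_high)
        self.intercept_ = est.intercept
        self.intercept_se_ = est.intercept_se
        self.intercept_pvalue_ = est.intercept_p
        self.rucker_q_ = het.rucker_q
        self.rucker_df_ = het.rucker_df
        self.rucker_pvalue_ = het.rucker_p
        self.mean_f_, self.i2_gx_ = instrument_strength(inst)
        self.n_snps_ = int(len(inst))
        return self
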