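"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its config (seed included) and returns
the simulated data together with the ground truth needed to score the
downstream stage: planted sleep windows for the actigraphy detector, the true
genetic risk score and effect for association testing, planted subtype labels
for the locus clustering, and the true causal slope / pleiotropy for the
Mendelian-randomization estimators.

What is emulated -- and what is not -- is documented in docs/methods.md; in
short, traces are z-angle level processes (not raw sub-second waveforms),
genotypes are Hardy-Weinberg draws without linkage disequilibrium, and MR
instruments satisfy the InSIDE condition unless explicitly violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .actigraphy import AccelEpochSeries

__all__ = [
    "AccelSimConfig",
    "CohortSimConfig",
    "ZMatrixSimConfig",
    "MrSimConfig",
    "gen_accel_trace",
    "gen_cohort",
    "gen_locus_z_matrix",
    "gen_mr_instruments",
    "Z_COLUMNS",
    "PROPENSITY_TEMPLATE",
]

#: fixed trait order of the locus x trait z-matrix
Z_COLUMNS = ["z_efficiency", "z_duration", "z_bouts", "z_insomnia"]
#: sign pattern of a sleep-propensity locus: higher efficiency, longer
#: duration, fewer bouts, fewer insomnia symptoms
PROPENSITY_TEMPLATE = np.array([1.0, 1.0, -1.0, -1.0])


# ---------------------------------------------------------------------------
# accelerometer traces


@dataclass
class AccelSimConfig:
    """Multi-day z-angle trace with one planted nocturnal sleep window per day.

    Onset/wake are minutes from the analysis-day start (noon); the default
    window is 23:00-07:00.  ``angle_noise_sd`` is per-epoch measurement noise
    on the sleep posture angle; daytime wrist movement is always present
    (``daytime_jitter_sd``) so movement and non-movement are distinguishable.
    """

    n_days: int = 7
    epoch_seconds: float = 5.0
    sleep_onset_min: float = 660.0   # 23:00
    sleep_wake_min: float = 1140.0   # 07:00
    angle_noise_sd: float = 1.0
    n_posture_changes_in_sleep: int = 2
    daytime_nap: tuple[float, float] | None = None  # minutes from noon
    daytime_jitter_sd: float = 20.0
    daytime_posture_change_min: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sleep_onset_min >= self.sleep_wake_min:
            raise ValueError("sleep onset must precede wake")
        if self.sleep_wake_min - self.sleep_onset_min <= 30:
            raise ValueError("planted sleep window must exceed 30 min")
        if self.sleep_wake_min > 1440:
            raise ValueError("sleep window must lie within the noon-to-noon day")
        sec = self.epoch_seconds
        for minutes in (self.sleep_onset_min, self.sleep_wake_min):
            if abs((minutes * 60.0) % sec) > 1e-9:
                raise ValueError("window bounds must be multiples of the epoch")
        if self.n_posture_changes_in_sleep < 0:
            raise ValueError("n_posture_changes_in_sleep must be >= 0")


def gen_accel_trace(cfg: AccelSimConfig):
    """Simulate a trace; returns ``(AccelEpochSeries, truth)``.

    ``truth`` maps day index to the planted ``(onset_epoch, wake_epoch)``
    (absolute, half-open) and carries any nap windows under ``"naps"``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_day = int(round(86400.0 / cfg.epoch_seconds))
    n = n_day * cfg.n_days
    to_ep = lambda minutes: int(round(minutes * 60.0 / cfg.epoch_seconds))

    # waking baseline: piecewise-constant posture + per-epoch wrist jitter
    seg = max(1, to_ep(cfg.daytime_posture_change_min))
    n_seg = n // seg + 1
    levels = np.repeat(rng.uniform(-45.0, 45.0, size=n_seg), seg)[:n]
    z = levels + rng.normal(0.0, cfg.daytime_jitter_sd, size=n)
    activity = np.clip(rng.normal(30.0, 10.0, size=n), 0.0, None)

    windows: dict[int, tuple[int, int]] = {}
    naps: list[tuple[int, int]] = []

    def plant_still(a: int, b: int, base_angle: float, n_changes: int):
        # the epoch before onset already holds the sleep posture, so the
        # z-angle change at the onset epoch itself is zero
        zz = np.full(b - a + 1, base_angle)
        if n_changes:
            at = np.sort(rng.choice(np.arange(60, b - a - 60), size=n_changes,
                                    replace=False))
            for t in at:
                zz[t + 1:] += rng.uniform(10.0, 40.0) * rng.choice([-1.0, 1.0])
        if cfg.angle_noise_sd > 0:
            zz += rng.normal(0.0, cfg.angle_noise_sd, size=zz.size)
        z[a - 1:b] = zz
        activity[a:b] = np.clip(rng.normal(1.0, 0.5, size=b - a), 0.0, None)

    for day in range(cfg.n_days):
        a = day * n_day + to_ep(cfg.sleep_onset_min)
        b = day * n_day + to_ep(cfg.sleep_wake_min)
        plant_still(a, b, rng.uniform(-30.0, 30.0),
                    cfg.n_posture_changes_in_sleep)
        windows[day] = (a, b)
        if cfg.daytime_nap is not None:
            na = day * n_day + to_ep(cfg.daytime_nap[0])
            nb = day * n_day + to_ep(cfg.daytime_nap[1])
            plant_still(na, nb, rng.uniform(-30.0, 30.0), 0)
            naps.append((na, nb))

    np.clip(z, -90.0, 90.0, out=z)
    trace = AccelEpochSeries(
        person_id=f"sim{cfg.seed}",
        epoch_seconds=cfg.epoch_seconds,
        start_time=pd.Timestamp("2015-06-01 12:00:00"),
        z_angle=z,
        activity=activity,
    )
    return trace, {"windows": windows, "naps": naps}


# ---------------------------------------------------------------------------
# genotype cohorts


@dataclass
class CohortSimConfig:
    """Hardy-Weinberg cohort with a planted GRS -> trait effect.

    Genotypes are per-variant Binomial(2, MAF) dosages; the quantitative trait
    is ``grs_effect * GRS + N(0, noise_sd)`` and the binary trait uses a
    logistic link whose intercept is solved numerically so the expected
    prevalence equals ``baseline_prevalence``.
    """

    n_individuals: int = 5000
    n_variants: int = 42
    maf_vector: np.ndarray | None = None      # default U(0.08, 0.49)
    weight_vector: np.ndarray | None = None   # default U(0.01, 0.03)
    grs_effect: float = 1.0
    trait_type: str = "quantitative"
    baseline_prevalence: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError("trait_type must be 'quantitative' or 'binary'")
        rng = np.random.default_rng(self.seed + 982451653 % (2**31))
        if self.maf_vector is None:
            self.maf_vector = rng.uniform(0.08, 0.49, size=self.n_variants)
        self.maf_vector = np.asarray(self.maf_vector, dtype=float)
        if self.weight_vector is None:
            self.weight_vector = rng.uniform(0.01, 0.03, size=self.n_variants)
        self.weight_vector = np.asarray(self.weight_vector, dtype=float)
        if len(self.maf_vector) != self.n_variants or \
                len(self.weight_vector) != self.n_variants:
            raise ValueError("maf/weight vectors must have n_variants entries")
        if np.any(self.maf_vector <= 0) or np.any(self.maf_vector > 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0, 1)")


def gen_cohort(cfg: CohortSimConfig):
    """Simulate genotypes + phenotypes; returns ``(dosages, phenotypes, truth)``.

    ``dosages`` is a person x variant DataFrame of {0,1,2} counts of the
    effect allele; ``phenotypes`` holds the trait plus age/sex covariates
    (independent of the trait); ``truth`` carries the true GRS, weights and
    effect size.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_variants
    G = rng.binomial(2, cfg.maf_vector, size=(n, m)).astype(float)
    grs = G @ cfg.weight_vector
    eta = cfg.grs_effect * grs

    if cfg.trait_type == "quantitative":
        y = eta + rng.normal(0.0, cfg.noise_sd, size=n)
    else:
        def excess(b0):
            return float(np.mean(expit(b0 + eta))) - cfg.baseline_prevalence
        b0 = brentq(excess, -30.0, 30.0)
        y = rng.binomial(1, expit(b0 + eta)).astype(float)

    ids = [f"I{i:05d}" for i in range(n)]
    variants = [f"rs{j + 1:04d}" for j in range(m)]
    dosages = pd.DataFrame(G, index=pd.Index(ids, name="person_id"),
                           columns=variants)
    pheno = pd.DataFrame({
        "person_id": ids,
        "trait": y,
        "age": rng.uniform(40, 69, size=n).round(0),
        "sex": rng.binomial(1, 0.5, size=n),
    }).set_index("person_id")
    truth = {
        "grs": pd.Series(grs, index=dosages.index, name="grs"),
        "weights": pd.Series(cfg.weight_vector, index=variants, name="weight"),
        "grs_effect": cfg.grs_effect,
        "maf": pd.Series(cfg.maf_vector, index=variants, name="maf"),
    }
    return dosages, pheno, truth


# ---------------------------------------------------------------------------
# locus x trait z-matrices


@dataclass
class ZMatrixSimConfig:
    """Locus x 4-trait z-matrix with two planted sign-pattern clusters.

    Propensity loci follow ``mean_abs_z * (+,+,-,-)`` over (efficiency,
    duration, bouts, insomnia); fragmentation loci the inverse; outliers draw
    a random sign pattern that matches neither template.  Defaults mirror the
    two final subtype clusters (10 + 27 loci) plus 5 off-pattern loci for a
    42-locus input.
    """

    n_propensity: int = 10
    n_fragmentation: int = 27
    n_outliers: int = 5
    mean_abs_z: float = 3.0
    z_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_propensity, self.n_fragmentation, self.n_outliers) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_propensity + self.n_fragmentation < 2:
            raise ValueError("need at least 2 clustered loci")


def gen_locus_z_matrix(cfg: ZMatrixSimConfig):
    """Simulate a z-matrix; returns ``(DataFrame, labels)``.

    ``labels`` is a Series over loci: ``'propensity'``, ``'fragmentation'``
    or ``'outlier'``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, labels = [], []
    for _ in range(cfg.n_propensity):
        rows.append(cfg.mean_abs_z * PROPENSITY_TEMPLATE)
        labels.append("propensity")
    for _ in range(cfg.n_fragmentation):
        rows.append(-cfg.mean_abs_z * PROPENSITY_TEMPLATE)
        labels.append("fragmentation")
    for _ in range(cfg.n_outliers):
        while True:  # any sign pattern except the two templates
            signs = rng.choice([-1.0, 1.0], size=4)
            if abs(signs @ PROPENSITY_TEMPLATE) < 4:
                break
        rows.append(cfg.mean_abs_z * signs)
        labels.append("outlier")
    X = np.array(rows) + rng.normal(0.0, cfg.z_noise_sd, size=(len(rows), 4))
    loci = [f"L{i + 1:03d}" for i in range(len(rows))]
    Z = pd.DataFrame(X, index=pd.Index(loci, name="locus"), columns=Z_COLUMNS)
    return Z, pd.Series(labels, index=Z.index, name="subtype")


# ---------------------------------------------------------------------------
# MR instrument sets


@dataclass
class MrSimConfig:
    """Paired exposure/outcome instrument effects with a planted causal slope.

    ``gamma`` draws the true SNP -> exposure effects; observed exposure and
    outcome effects add estimation noise at the given SEs; the pleiotropy term
    alpha is zero (``none``), mean-zero (``balanced``) or has nonzero mean
    (``directional``), independent of gamma unless ``inside_violation``.
    Defaults emulate a BMI-sized instrument set acting on a very large
    outcome GWAS: J=77 with effect/SE scales solving mean F ~ 33,
    I^2_GX ~ 0.89 and an IVW standard error near 0.005 around a small
    positive causal slope.
    """

    n_instruments: int = 77
    true_beta: float = 0.018
    gamma_mean: float = 0.0174
    gamma_sd: float = 0.010
    se_exposure: float = 0.0035
    se_outcome: float = 0.0009
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_instruments < 3:
            raise ValueError("need at least 3 instruments")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError("SEs must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy_mode must be none|balanced|directional")


def gen_mr_instruments(cfg: MrSimConfig):
    """Simulate an instrument set; returns ``(DataFrame, truth)``."""
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_instruments
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=J)
    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(J)
    else:
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, cfg.pleiotropy_sd, size=J)
        if cfg.inside_violation:
            alpha = alpha + 0.5 * (gamma - gamma.mean())
    beta_exp = gamma + rng.normal(0.0, cfg.se_exposure, size=J)
    beta_out = cfg.true_beta * gamma + alpha + \
        rng.normal(0.0, cfg.se_outcome, size=J)
    alleles = rng.choice(["A", "C", "G"], size=J)  # non-palindromic pairs
    other = np.where(alleles == "A", "G", "T")
    inst = pd.DataFrame({
        "SNP": [f"rs{j + 1:05d}" for j in range(J)],
        "EA": alleles,
        "OA": other,
        "EAF": rng.uniform(0.1, 0.9, size=J),
        "beta_exposure": beta_exp,
        "se_exposure": np.full(J, cfg.se_exposure),
        "beta_outcome": beta_out,
        "se_outcome": np.full(J, cfg.se_outcome),
    })
    truth = {"beta": cfg.true_beta, "gamma": gamma, "alpha": alpha}
    return inst, truth
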