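"""Two-sample Mendelian-randomization estimators and diagnostics.

Implements the Wald ratio, fixed/multiplicative-random-effects IVW,
MR-Egger regression, the weighted median, Cochran's Q heterogeneity test,
and a simulation-based outlier screen (global residual-sum-of-squares test
plus leave-one-out outlier flagging), together with the method-selection
policy: Wald ratio for a single instrument, IVW otherwise, with MR-Egger
and weighted median attached as sensitivity analyses from three
instruments upward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPair, InstrumentSet


class MRError(ValueError):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate with normal-theory odds-ratio CI.

    ``beta`` is on the outcome scale (log-odds for binary outcomes), and
    ``or_``/``ci_low``/``ci_high`` apply exp() uniformly.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        z975 = stats.norm.ppf(0.975)
        self.or_ = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - z975 * self.se))
        self.ci_high = float(np.exp(self.beta + z975 * self.se))


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class PleiotropyResult:
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    outlier_ids: list[str] = field(default_factory=list)
    global_pval: float | None = None


@dataclass
class MRReport:
    exposure_id: str
    outcome_id: str
    primary: MREstimate
    sensitivity: list[MREstimate]
    heterogeneity: HeterogeneityResult | None
    pleiotropy: PleiotropyResult | None
    f_mean: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready table, one row per method."""
        rows = []
        for est in [self.primary, *self.sensitivity]:
            rows.append({
                "exposure": self.exposure_id,
                "outcome": self.outcome_id,
                "method": est.method,
                "nsnp": est.n_snp,
                "b": est.beta,
                "se": est.se,
                "pval": est.pval,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "Q": self.heterogeneity.Q if self.heterogeneity else np.nan,
                "Q_pval": self.heterogeneity.pval if self.heterogeneity else np.nan,
                "egger_intercept": (self.pleiotropy.egger_intercept
                                    if self.pleiotropy and self.pleiotropy.egger_intercept is not None
                                    else np.nan),
                "intercept_pval": (self.pleiotropy.intercept_pval
                                   if self.pleiotropy and self.pleiotropy.intercept_pval is not None
                                   else np.nan),
            })
        return pd.DataFrame(rows)


def _two_sided_normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    First-order delta-method se is se_out/|beta_exp|; the second-order
    option adds the exposure-uncertainty term
    beta_out^2 * se_exp^2 / beta_exp^4.
    """
    if pair.beta_exp == 0:
        raise MRError("Wald ratio undefined: exposure beta is zero")
    beta = pair.beta_out / pair.beta_exp
    var = pair.se_out**2 / pair.beta_exp**2
    if second_order:
        var += pair.beta_out**2 * pair.se_exp**2 / pair.beta_exp**4
    se = float(np.sqrt(var))
    return MREstimate("wald_ratio", float(beta), se, _two_sided_normal_p(beta / se), 1)


def ivw(instruments: InstrumentSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 instruments.

    Equivalent to a zero-intercept regression of outcome betas on exposure
    betas with weights 1/se_out^2.  The ``random`` model applies the
    multiplicative random-effects inflation max(1, sqrt(Q/(n-1))) to the
    fixed-effect se.
    """
    if instruments.n_snp < 2:
        raise MRError("IVW requires >= 2 instruments; use wald_ratio for a single instrument")
    if model not in ("fixed", "random"):
        raise MRError(f"unknown IVW model {model!r}")
    bx, _, by, sy = instruments.beta_arrays()
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by) / denom)
    se = float(np.sqrt(1.0 / denom))
    method = "ivw_fixed"
    if model == "random":
        q = cochran_q(instruments, beta).Q
        se *= max(1.0, float(np.sqrt(q / (instruments.n_snp - 1))))
        method = "ivw_random"
    return MREstimate(method, beta, se, _two_sided_normal_p(beta / se), instruments.n_snp)


def mr_egger(instruments: InstrumentSet) -> tuple[MREstimate, PleiotropyResult]:
    """Egger regression: weighted fit of beta_out = a + b*beta_exp.

    Pairs are oriented so every exposure beta is positive before fitting
    (the intercept is only interpretable under a fixed orientation).
    Inference uses a t reference with n_snp - 2 df.
    """
    if instruments.n_snp < 3:
        raise MRError("MR-Egger requires >= 3 instruments")
    bx, _, by, sy = instruments.beta_arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    import statsmodels.api as sm

    fit = sm.WLS(by, X, weights=w).fit()
    df = instruments.n_snp - 2
    # statsmodels WLS normalizes by residual MSE already (t inference on df)
    a, b = fit.params
    se_a, se_b = fit.bse
    p_b = float(2 * stats.t.sf(abs(b / se_b), df))
    p_a = float(2 * stats.t.sf(abs(a / se_a), df))
    slope = MREstimate("egger_slope", float(b), float(se_b), p_b, instruments.n_snp)
    intercept = PleiotropyResult(
        egger_intercept=float(a), intercept_se=float(se_a), intercept_pval=p_a
    )
    return slope, intercept


def _ratio_estimates(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order delta-method variances."""
    bx, sx, by, sy = instruments.beta_arrays()
    ratios = by / bx
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    return ratios, var


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    below = np.searchsorted(cum, 0.5, side="right") - 1
    if below < 0:
        return float(r[0])
    if below >= len(r) - 1:
        return float(r[-1])
    # linear interpolation between adjacent ordered ratios
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + frac * (r[below + 1] - r[below]))


def weighted_median(instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap se.

    Per-SNP ratios are weighted by their inverse first-order variances; the
    estimate is where the cumulative weight crosses 1/2, interpolating
    between adjacent ordered ratios.  The se is the standard deviation of
    the estimate over ``n_boot`` parametric resamples of the instrument
    effects.
    """
    if instruments.n_snp < 3:
        raise MRError("weighted median requires >= 3 instruments")
    ratios, var = _ratio_estimates(instruments)
    point = _weighted_median_point(ratios, 1.0 / var)

    rng = np.random.default_rng(seed)
    bx, sx, by, sy = instruments.beta_arrays()
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        r = bys / bxs
        v = sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4
        boots[i] = _weighted_median_point(r, 1.0 / v)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", point, se,
                      _two_sided_normal_p(point / se if se > 0 else np.inf),
                      instruments.n_snp)


def cochran_q(instruments: InstrumentSet, beta_ref: float) -> HeterogeneityResult:
    """Cochran's Q about ``beta_ref`` over per-SNP Wald ratios."""
    if instruments.n_snp < 2:
        raise MRError("Cochran's Q requires >= 2 instruments")
    ratios, var = _ratio_estimates(instruments)
    q = float(np.sum((ratios - beta_ref) ** 2 / var))
    df = instruments.n_snp - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def _ivw_beta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    w = 1.0 / sy**2
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def outlier_screen(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PleiotropyResult:
    """Simulation-based pleiotropy outlier screen.

    Global test: the observed weighted residual sum of squares about the
    IVW fit is compared with its parametric Monte-Carlo null (instrument
    effects resampled under the fitted homogeneous model).  Per-SNP test:
    each instrument's leave-one-out residual contribution is compared with
    its simulated distribution; ids with Bonferroni-corrected p < ``alpha``
    are flagged.  Outlier flagging needs >= 4 instruments; the global test
    runs from 2 upward.  Egger-intercept fields are attached when >= 3
    instruments are available.
    """
    n = instruments.n_snp
    result = PleiotropyResult()
    if n < 2:
        return result
    bx, sx, by, sy = instruments.beta_arrays()
    rng = np.random.default_rng(seed)
    beta_hat = _ivw_beta(bx, by, sy)

    def rss_and_contrib(bxa, bya):
        contrib = np.empty(len(bxa))
        for j in range(len(bxa)):
            mask = np.arange(len(bxa)) != j
            b_loo = _ivw_beta(bxa[mask], bya[mask], sy[mask])
            contrib[j] = (bya[j] - b_loo * bxa[j]) ** 2 / sy[j] ** 2
        return float(np.sum(contrib)), contrib

    obs_rss, obs_contrib = rss_and_contrib(bx, by)
    sim_rss = np.empty(n_sim)
    sim_contrib = np.empty((n_sim, n))
    for s in range(n_sim):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(beta_hat * bxs, sy)
        sim_rss[s], sim_contrib[s] = rss_and_contrib(bxs, bys)
    result.global_pval = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))

    if n >= 4:
        per_snp_p = (np.sum(sim_contrib >= obs_contrib, axis=0) + 1) / (n_sim + 1)
        flagged = np.where(per_snp_p * n < alpha)[0]
        result.outlier_ids = [instruments.pairs[int(j)].variant_id for j in flagged]
    else:
        import warnings

        warnings.warn("outlier flagging skipped: fewer than 4 instruments", stacklevel=2)

    if n >= 3:
        _, egger_int = mr_egger(instruments)
        result.egger_intercept = egger_int.egger_intercept
        result.intercept_se = egger_int.intercept_se
        result.intercept_pval = egger_int.intercept_pval
    return result


def run_mr(
    instruments: InstrumentSet,
    ivw_model: str = "auto",
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    run_outlier_screen: bool = True,
) -> MRReport:
    """Apply the method-selection policy and assemble a full report.

    One instrument: Wald ratio, no sensitivity analyses.  Two: IVW only.
    Three or more: IVW primary with Egger and weighted-median sensitivity
    estimates.  ``ivw_model='auto'`` uses fixed-effect IVW, switching to
    the multiplicative random-effects se when Cochran's Q has p < 0.05.
    """
    if instruments.n_snp == 0:
        raise MRError("no instruments available")
    if instruments.n_snp == 1:
        primary = wald_ratio(instruments.pairs[0])
        return MRReport(instruments.exposure_id, instruments.outcome_id,
                        primary, [], None, None, instruments.f_mean)

    fixed = ivw(instruments, "fixed")
    het = cochran_q(instruments, fixed.beta)
    if ivw_model == "auto":
        model = "random" if het.pval < 0.05 else "fixed"
    else:
        model = ivw_model
    primary = ivw(instruments, model)

    sensitivity: list[MREstimate] = []
    pleio: PleiotropyResult | None = None
    if instruments.n_snp >= 3:
        slope, pleio = mr_egger(instruments)
        sensitivity = [slope, weighted_median(instruments, n_boot=n_boot, seed=seed)]
        if run_outlier_screen:
            screen = outlier_screen(instruments, n_sim=n_sim, seed=seed)
            pleio.outlier_ids = screen.outlier_ids
            pleio.global_pval = screen.global_pval
    return MRReport(instruments.exposure_id, instruments.outcome_id,
                    primary, sensitivity, het, pleio, instruments.f_mean)
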