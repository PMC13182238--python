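"""Summary-data-based MR (SMR) and the HEIDI linkage test.

SMR links a molecular QTL (eQTL/pQTL/mQTL) to a trait through the top cis
variant: the test statistic T = z_x^2 z_y^2 / (z_x^2 + z_y^2) is referred
to a 1-df chi-square, and the effect is the ratio b = beta_GWAS/beta_QTL.

A significant SMR signal is compatible with a shared causal variant
(causality or vertical pleiotropy) but also with linkage between two
distinct causal variants.  HEIDI (heterogeneity in dependent instruments)
separates the two: under a single shared causal variant, the SMR ratio
estimated at every SNP in LD with the top SNP has the same expectation, so
the deviations d_i = b_i - b_top are jointly mean-zero.  The test
statistic sums squared standardized deviations, whose null distribution is
a weighted sum of 1-df chi-squares; its tail is evaluated by moment
matching on the leading moments of the eigenvalue spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPair, LDMatrix
from .tiering import bh_adjust


class SMRError(ValueError):
    pass


@dataclass
class SMRResult:
    """Per-gene SMR + HEIDI outcome (one top cis-QTL per gene)."""

    gene_id: str
    probe_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_smr_fdr: float | None = None
    p_heidi: float | None = None
    n_heidi_snps: int = 0


def smr_test(top_pair: HarmonizedPair) -> tuple[float, float, float]:
    """SMR ratio, its se, and the chi-square(1) p at the top cis-QTL.

    Returns ``(b_smr, se_smr, p_smr)`` where
    T = z_x^2 z_y^2 / (z_x^2 + z_y^2) with z_x the QTL z and z_y the GWAS z,
    b = beta_GWAS / beta_QTL, and se = |b| * sqrt(1/z_x^2 + 1/z_y^2).
    """
    if top_pair.beta_exp == 0:
        raise SMRError("SMR undefined: QTL beta is zero")
    z_x = top_pair.beta_exp / top_pair.se_exp
    z_y = top_pair.beta_out / top_pair.se_out
    if z_x == 0:
        raise SMRError("SMR undefined: QTL z is zero")
    b = top_pair.beta_out / top_pair.beta_exp
    if z_y == 0:
        t = 0.0
        se = np.inf
    else:
        t = (z_x**2 * z_y**2) / (z_x**2 + z_y**2)
        se = abs(b) * np.sqrt(1.0 / z_x**2 + 1.0 / z_y**2)
    p = float(stats.chi2.sf(t, df=1))
    return float(b), float(se), p


def _smr_ratio_cov(pairs: list[HarmonizedPair], r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ratios b_i and their covariance, propagated from LD by the delta method.

    Under the null of one shared causal variant, marginal-effect estimates
    at SNPs i, j correlate as r_ij within each trait; the QTL and GWAS
    samples are independent, so
    cov(b_i, b_j) ~ [r_ij se_yi se_yj + b_i b_j r_ij se_xi se_xj] / (bx_i bx_j).
    """
    bx = np.array([p.beta_exp for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    b = by / bx
    outer_bx = np.outer(bx, bx)
    cov = (r * np.outer(sy, sy) + np.outer(b, b) * r * np.outer(sx, sx)) / outer_bx
    return b, cov


def satterthwaite_p(t: float, eigenvalues: np.ndarray) -> float:
    """Tail probability of sum(lambda_k chi2_1) at ``t`` by two-moment matching.

    The mixture is approximated by a*chi2_nu with a = sum(l^2)/sum(l) and
    nu = sum(l)^2 / sum(l^2).  Exact when all eigenvalues are equal; for
    strongly unequal spectra prefer :func:`weighted_chisq_sf`.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    s1, s2 = float(np.sum(lam)), float(np.sum(lam**2))
    a = s2 / s1
    nu = s1**2 / s2
    return float(stats.chi2.sf(t / a, nu))


def _liu_sf(t: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang (noncentral chi-square) moment-matched tail."""
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    c4 = float(np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = a**2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2 * (df + 2 * delta))
    t_std = (t - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(t_std, df, delta))
    return float(stats.chi2.sf(t_std, df))


def weighted_chisq_sf(t: float, eigenvalues: np.ndarray) -> float:
    """Tail probability of sum(lambda_k chi2_1) at ``t``.

    Evaluates Imhof's characteristic-function inversion integral
    numerically (exact up to quadrature error), falling back to a
    moment-matched noncentral chi-square if the quadrature misbehaves.
    Spectra with one dominant eigenvalue -- common for HEIDI deviation
    vectors under strong LD -- are handled accurately.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if t <= 0:
        return 1.0
    from scipy.integrate import quad

    def integrand(u: float) -> float:
        theta = 0.5 * float(np.sum(np.arctan(lam * u))) - 0.5 * t * u
        log_rho = 0.25 * float(np.sum(np.log1p((lam * u) ** 2)))
        return float(np.sin(theta) * np.exp(-log_rho) / u)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            val, err = quad(integrand, 0, np.inf, limit=400)
        if err > 1e-4:
            raise RuntimeError("quadrature error too large")
        return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))
    except Exception:
        return _liu_sf(t, lam)


def heidi_test(
    region_pairs: list[HarmonizedPair],
    ld: LDMatrix,
    top_id: str,
    z_min: float = 3.16,
    r2_low: float = 0.05,
    r2_high: float = 0.9,
    max_snps: int = 20,
) -> tuple[float | None, int, float | None]:
    """HEIDI test for heterogeneity of SMR ratios across the cis region.

    Candidate SNPs have |z_QTL| >= ``z_min`` and r-squared with the top SNP
    in [``r2_low``, ``r2_high``], capped at ``max_snps`` by descending
    |z_QTL|.  Returns ``(T_heidi, n_used, p_heidi)``; the p-value is
    missing when fewer than 3 candidates are available.
    """
    by_id = {p.variant_id: p for p in region_pairs}
    if top_id not in by_id:
        raise SMRError(f"top SNP {top_id} not present in region pairs")
    top = by_id[top_id]

    candidates = []
    for p in region_pairs:
        if p.variant_id == top_id:
            continue
        z = abs(p.beta_exp / p.se_exp)
        r2 = ld.r_between(p.variant_id, top_id) ** 2
        if z >= z_min and r2_low <= r2 <= r2_high:
            candidates.append((z, p))
    candidates.sort(key=lambda t: (-t[0], t[1].variant_id))
    candidates = [p for _, p in candidates[:max_snps]]
    n_used = len(candidates)
    if n_used < 3:
        return None, n_used, None

    ordered = [top, *candidates]
    ids = [p.variant_id for p in ordered]
    r = np.array([[ld.r_between(i, j) for j in ids] for i in ids])
    b, cov = _smr_ratio_cov(ordered, r)

    m = n_used
    d = b[1:] - b[0]
    # cov(d_i, d_j) = cov(b_i,b_j) - cov(b_i,b_top) - cov(b_j,b_top) + var(b_top)
    vd = cov[1:, 1:] - cov[1:, [0]] - cov[[0], 1:] + cov[0, 0]
    sd = np.sqrt(np.diag(vd))
    z_d = d / sd
    t_heidi = float(np.sum(z_d**2))
    corr = vd / np.outer(sd, sd)
    eigenvalues = np.linalg.eigvalsh((corr + corr.T) / 2)
    p_heidi = weighted_chisq_sf(t_heidi, eigenvalues)
    return t_heidi, m, p_heidi


def smr_with_heidi(
    gene_id: str,
    region_pairs: list[HarmonizedPair],
    ld: LDMatrix,
    top_id: str | None = None,
    **heidi_kwargs,
) -> SMRResult:
    """Run SMR at the top cis-QTL (largest |z_QTL| unless given) plus HEIDI."""
    if not region_pairs:
        raise SMRError("empty region")
    if top_id is None:
        top_id = max(region_pairs, key=lambda p: abs(p.beta_exp / p.se_exp)).variant_id
    top = next(p for p in region_pairs if p.variant_id == top_id)
    b, se, p = smr_test(top)
    _, n_used, p_heidi = heidi_test(region_pairs, ld, top_id, **heidi_kwargs)
    return SMRResult(gene_id, top_id, b, se, p, p_heidi=p_heidi, n_heidi_snps=n_used)


def smr_fdr(results: list[SMRResult]) -> list[SMRResult]:
    """Benjamini-Hochberg adjustment of SMR p-values across genes.

    Applied within one analysis (one tissue/cohort) at a time; fills
    ``p_smr_fdr`` in place and returns the list.
    """
    if not results:
        raise SMRError("no SMR results to adjust")
    q = bh_adjust([r.p_smr for r in results])
    for r, qv in zip(results, q):
        r.p_smr_fdr = qv
    return results


def results_to_frame(results: list[SMRResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene_id, "probe_snp": r.probe_snp, "b_smr": r.b_smr,
        "se_smr": r.se_smr, "p_smr": r.p_smr, "p_smr_fdr": r.p_smr_fdr,
        "p_heidi": r.p_heidi, "n_heidi_snps": r.n_heidi_snps,
    } for r in results])
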