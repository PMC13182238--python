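"""Synthetic GWAS summary statistics with known ground truth.

Summary statistics are simulated directly from the multivariate-normal
model of marginal z statistics: for a region with LD correlation matrix R
and joint (per-standardized-genotype) causal effects lambda, the marginal
z vector has mean sqrt(n) * R * lambda and covariance R.  Betas and
standard errors are back-transformed to the per-allele scale through the
allele frequency (se = 1 / sqrt(2 maf (1-maf) n)).  This emulates the
statistical shape of eQTL/pQTL and disease-GWAS inputs (binary traits are
treated on the log-odds scale with effective-n scaling) without
simulating individual-level genotypes.

Scenario presets cover the configurations the analysis stages must
distinguish: a causal exposure->outcome effect, directional pleiotropy
(constant offset on every instrument's outcome effect), a single causal
variant shared by two traits, linkage between two distinct causal
variants, an exposure->mediator->outcome chain, and the null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, SummaryStatSet, make_sumstats


class SimulationError(ValueError):
    pass


@dataclass
class ReferencePanel:
    """LD-correlated variant panel used to simulate marginal statistics."""

    variant_ids: list[str]
    positions: np.ndarray
    mafs: np.ndarray
    ld: LDMatrix
    n_ref: int | None

    @property
    def m(self) -> int:
        return len(self.variant_ids)


@dataclass
class SimulationConfig:
    """Scenario description; ``seed`` is mandatory for reproducibility."""

    scenario: str
    seed: int
    # instrument-level (no-LD) scenarios
    m_snps: int = 100
    m_causal: int = 20
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    n_mediator: int = 100_000
    beta_xy: float = 0.2
    lambda_low: float = 0.03
    lambda_high: float = 0.06
    pleiotropy_offset: float = 0.0
    # LD panel
    rho: float = 0.0
    n_ref: int | None = None
    maf_range: tuple = (0.05, 0.5)
    spacing_bp: int = 5000
    # region (shared/linkage) scenarios
    causal_index: int | None = None
    linkage_lag: int = 5
    lambda_exp: float = 0.15
    lambda_out: float = 0.036
    # mediation chain
    beta_xm: float = 0.3
    beta_my: float = 0.5
    direct_effect: float = 0.1

    def __post_init__(self) -> None:
        valid = {"causal", "pleiotropy", "linkage", "shared", "mediation", "null"}
        if self.scenario not in valid:
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.m_causal > self.m_snps:
            raise SimulationError("m_causal cannot exceed m_snps")


def _nearest_psd(r: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh((r + r.T) / 2)
    repaired = (vecs * np.clip(vals, 0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.linalg.norm(repaired - r, "fro"))


def simulate_panel(
    m_snps: int,
    n_ref: int | None = 2000,
    rho: float = 0.8,
    maf_range: tuple = (0.05, 0.5),
    seed: int = 0,
    spacing_bp: int = 5000,
) -> ReferencePanel:
    """Reference panel with AR(1)-like LD, r_ij = rho^|i-j|.

    When ``n_ref`` is given, the LD matrix is the empirical correlation of
    ``n_ref`` simulated haplotype dosage vectors (finite-sample noise);
    ``n_ref=None`` returns the analytic AR(1) matrix.  Deterministic under
    ``seed``.
    """
    if not (0 <= rho < 1):
        raise SimulationError(f"rho must be in [0, 1), got {rho}")
    if m_snps < 1:
        raise SimulationError("m_snps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(m_snps)
    r_true = rho ** np.abs(idx[:, None] - idx[None, :])
    if n_ref is None:
        r = r_true
    else:
        chol = np.linalg.cholesky(r_true + 1e-12 * np.eye(m_snps))
        haplos = rng.standard_normal((n_ref, m_snps)) @ chol.T
        r = np.corrcoef(haplos, rowvar=False) if m_snps > 1 else np.ones((1, 1))
    r, frob = _nearest_psd(r)
    if frob >= 1e-6:
        raise SimulationError(f"nearest-PSD repair moved LD matrix by {frob:.2e}")
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m_snps)
    ids = [f"rs{i + 1:05d}" for i in range(m_snps)]
    positions = 1 + idx * spacing_bp
    return ReferencePanel(ids, positions, mafs, LDMatrix(ids, r), n_ref)


def simulate_gwas(
    panel: ReferencePanel,
    true_joint_effects: np.ndarray,
    n: int,
    seed: int = 0,
    trait_id: str = "trait",
    trait_type: str = "quantitative",
    marginal_offset: np.ndarray | None = None,
) -> SummaryStatSet:
    """Marginal summary statistics for one trait over the panel.

    ``true_joint_effects`` are per-standardized-genotype joint effects
    (log-odds for binary traits, with ``n`` an effective sample size).
    ``marginal_offset`` adds a constant to the emitted per-allele beta of
    selected SNPs after the draw (used for directional pleiotropy);
    p-values are recomputed from the offset betas.
    """
    if n <= 1:
        raise SimulationError("sample size must exceed 1")
    lam = np.asarray(true_joint_effects, dtype=float)
    if lam.shape != (panel.m,):
        raise SimulationError("effect vector length must match panel size")
    rng = np.random.default_rng(seed)
    r = panel.ld.r
    mean_z = np.sqrt(n) * (r @ lam)
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(panel.m))
    z = mean_z + chol @ rng.standard_normal(panel.m)

    scale = 1.0 / np.sqrt(2.0 * panel.mafs * (1.0 - panel.mafs))
    se = scale / np.sqrt(n)
    beta = z * se
    if marginal_offset is not None:
        beta = beta + np.asarray(marginal_offset, dtype=float)
    from scipy import stats

    pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    df = pd.DataFrame({
        "variant_id": panel.variant_ids,
        "chrom": "1",
        "pos": panel.positions,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": panel.mafs,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": n,
    })
    return make_sumstats(df, trait_id=trait_id, trait_type=trait_type)


@dataclass
class ScenarioBundle:
    """Simulated inputs plus the serialized ground truth."""

    exposure: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDMatrix
    panel: ReferencePanel
    truth: dict
    mediator: SummaryStatSet | None = None

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, default=float)


def _child_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(k)]


def make_scenario(config: SimulationConfig) -> ScenarioBundle:
    """Build the full input bundle for one scenario configuration."""
    if config.scenario in ("shared", "linkage"):
        return _make_region_scenario(config)
    if config.scenario == "mediation":
        return _make_mediation_scenario(config)
    return _make_instrument_scenario(config)


def _make_instrument_scenario(config: SimulationConfig) -> ScenarioBundle:
    """causal / pleiotropy / null: independent instruments, no LD."""
    s_panel, s_lam, s_exp, s_out = _child_seeds(config.seed, 4)
    panel = simulate_panel(config.m_snps, n_ref=config.n_ref, rho=config.rho,
                           maf_range=config.maf_range, seed=s_panel,
                           spacing_bp=config.spacing_bp)
    rng = np.random.default_rng(s_lam)
    causal_idx = rng.choice(config.m_snps, size=config.m_causal, replace=False)
    lam_x = np.zeros(config.m_snps)
    signs = rng.choice([-1.0, 1.0], size=config.m_causal)
    lam_x[causal_idx] = signs * rng.uniform(config.lambda_low, config.lambda_high,
                                            size=config.m_causal)
    beta_xy = 0.0 if config.scenario == "null" else config.beta_xy
    lam_y = beta_xy * lam_x

    offset = None
    if config.scenario == "pleiotropy" and config.pleiotropy_offset != 0.0:
        # directional pleiotropy is constant relative to the
        # exposure-increasing allele, hence signed with the exposure effect
        offset = np.zeros(config.m_snps)
        offset[causal_idx] = config.pleiotropy_offset * signs

    exposure = simulate_gwas(panel, lam_x, config.n_exposure, seed=s_exp,
                             trait_id="exposure")
    outcome = simulate_gwas(panel, lam_y, config.n_outcome, seed=s_out,
                            trait_id="outcome", trait_type="binary",
                            marginal_offset=offset)
    truth = {
        "scenario": config.scenario,
        "causal_ids": [panel.variant_ids[i] for i in sorted(causal_idx)],
        "beta_xy": beta_xy,
        "pleiotropy_offset": config.pleiotropy_offset if config.scenario == "pleiotropy" else 0.0,
        "config": asdict(config),
    }
    return ScenarioBundle(exposure, outcome, panel.ld, panel, truth)


def _make_region_scenario(config: SimulationConfig) -> ScenarioBundle:
    """shared / linkage: one cis region with LD, strong QTL + GWAS signals."""
    s_panel, s_exp, s_out = _child_seeds(config.seed, 3)
    rho = config.rho if config.rho > 0 else 0.9
    n_ref = config.n_ref if config.n_ref is not None else 5000
    panel = simulate_panel(config.m_snps, n_ref=n_ref, rho=rho,
                           maf_range=config.maf_range, seed=s_panel,
                           spacing_bp=config.spacing_bp)
    ci = config.causal_index if config.causal_index is not None else config.m_snps // 2
    lam_x = np.zeros(config.m_snps)
    lam_x[ci] = config.lambda_exp
    lam_y = np.zeros(config.m_snps)
    if config.scenario == "shared":
        cj = ci
    else:
        cj = min(ci + config.linkage_lag, config.m_snps - 1)
    lam_y[cj] = config.lambda_out
    exposure = simulate_gwas(panel, lam_x, config.n_exposure, seed=s_exp,
                             trait_id="eqtl")
    outcome = simulate_gwas(panel, lam_y, config.n_outcome, seed=s_out,
                            trait_id="gwas", trait_type="binary")
    truth = {
        "scenario": config.scenario,
        "causal_id_exposure": panel.variant_ids[ci],
        "causal_id_outcome": panel.variant_ids[cj],
        "ld_between_causals": float(panel.ld.r[ci, cj]),
        "config": asdict(config),
    }
    return ScenarioBundle(exposure, outcome, panel.ld, panel, truth)


def _make_mediation_scenario(config: SimulationConfig) -> ScenarioBundle:
    """Exposure -> mediator -> outcome chain on disjoint instrument sets."""
    s_panel, s_lam, s_x, s_m, s_y = _child_seeds(config.seed, 5)
    m_half = config.m_causal
    m_total = 2 * m_half
    panel = simulate_panel(m_total, n_ref=config.n_ref, rho=0.0,
                           maf_range=config.maf_range, seed=s_panel,
                           spacing_bp=config.spacing_bp)
    rng = np.random.default_rng(s_lam)
    lam_a = rng.uniform(config.lambda_low, config.lambda_high, size=m_half)
    lam_b = rng.uniform(config.lambda_low, config.lambda_high, size=m_half)
    idx_a = np.arange(m_half)            # exposure instruments
    idx_b = np.arange(m_half, m_total)   # mediator's own instruments

    lam_x = np.zeros(m_total)
    lam_x[idx_a] = lam_a
    lam_m = np.zeros(m_total)
    lam_m[idx_a] = config.beta_xm * lam_a
    lam_m[idx_b] = lam_b
    total = config.beta_xm * config.beta_my + config.direct_effect
    lam_y = np.zeros(m_total)
    lam_y[idx_a] = total * lam_a
    lam_y[idx_b] = config.beta_my * lam_b

    exposure = simulate_gwas(panel, lam_x, config.n_exposure, seed=s_x, trait_id="exposure")
    mediator = simulate_gwas(panel, lam_m, config.n_mediator, seed=s_m, trait_id="mediator")
    outcome = simulate_gwas(panel, lam_y, config.n_outcome, seed=s_y,
                            trait_id="outcome", trait_type="binary")
    truth = {
        "scenario": "mediation",
        "beta_xm": config.beta_xm,
        "beta_my": config.beta_my,
        "direct_effect": config.direct_effect,
        "beta_total": total,
        "indirect": config.beta_xm * config.beta_my,
        "proportion": config.beta_xm * config.beta_my / total,
        "exposure_instrument_ids": [panel.variant_ids[i] for i in idx_a],
        "mediator_instrument_ids": [panel.variant_ids[i] for i in idx_b],
        "config": asdict(config),
    }
    return ScenarioBundle(exposure, outcome, panel.ld, panel, truth, mediator=mediator)
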