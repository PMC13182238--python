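"""Bayesian colocalization with Wakefield approximate Bayes factors.

Two traits measured over a shared region are compared under five
hypotheses: no association (H0), association with trait 1 only (H1),
trait 2 only (H2), both traits through distinct causal variants (H3), and
both traits through one shared causal variant (H4).  Per-SNP evidence is
the Wakefield approximate Bayes factor computed from the marginal beta and
se with a normal prior of variance ``w`` on the true effect.  Hypothesis
mass is accumulated in log space with log-sum-exp stabilization; the H3
cross-term uses complementary sums to limit cancellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import SummaryStatSet


class ColocError(ValueError):
    pass


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of causal configurations.

    ``p1``/``p2`` are the priors that a SNP is causal for trait 1/2 only;
    ``p12`` that it is causal for both.  Defaults follow the standard
    single-causal-variant colocalization convention.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ColocError("priors must satisfy 0 < p12 <= min(p1, p2) < 1")


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    n_snps: int
    priors: ColocPriors
    grade: str  # strong | moderate | none

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def to_dict(self) -> dict:
        d = {f"pp{i}": float(self.pp[i]) for i in range(5)}
        d.update(n_snps=self.n_snps, grade=self.grade,
                 priors={"p1": self.priors.p1, "p2": self.priors.p2, "p12": self.priors.p12})
        return d


def wakefield_labf(beta: float, se: float, w: float = 0.04) -> float:
    """Log approximate Bayes factor for a single marginal association.

    With V = se^2 and z = beta/se:
    labf = 0.5 * [ln(V/(V+w)) + z^2 * w/(V+w)].
    ``w`` is the prior variance of the true effect (default 0.2^2).
    """
    if se <= 0:
        raise ColocError("se must be positive")
    if w <= 0:
        raise ColocError("prior variance w must be positive")
    v = se**2
    z = beta / se
    return 0.5 * (np.log(v / (v + w)) + z**2 * w / (v + w))


def classify_coloc(pp4: float) -> str:
    """Evidence grade from the shared-variant posterior.

    Strong for PP4 > 0.8; moderate (printed "Weak" in some report styles)
    for 0.5 < PP4 <= 0.8; none otherwise.  Boundaries are strict.
    """
    if not (0 <= pp4 <= 1):
        raise ColocError(f"PP4 must be a probability, got {pp4}")
    if pp4 > 0.8:
        return "strong"
    if pp4 > 0.5:
        return "moderate"
    return "none"


def coloc_abf(
    trait1: SummaryStatSet | pd.DataFrame,
    trait2: SummaryStatSet | pd.DataFrame,
    priors: ColocPriors | None = None,
    w1: float = 0.04,
    w2: float = 0.04,
) -> ColocResult:
    """Posterior probabilities PP0-PP4 over the shared-variant set.

    The analysis is restricted to variants present in both traits (matched
    on variant_id).  Effects must already refer to a consistent allele per
    variant; sign is irrelevant since only z^2 enters the Bayes factors.
    """
    priors = priors or ColocPriors()
    df1 = trait1.records if isinstance(trait1, SummaryStatSet) else trait1
    df2 = trait2.records if isinstance(trait2, SummaryStatSet) else trait2
    merged = df1.merge(df2, on="variant_id", suffixes=("_1", "_2"))
    n = len(merged)
    if n == 0:
        raise ColocError("traits share no variants")

    labf1 = np.array([wakefield_labf(b, s, w1) for b, s in zip(merged["beta_1"], merged["se_1"])])
    labf2 = np.array([wakefield_labf(b, s, w2) for b, s in zip(merged["beta_2"], merged["se_2"])])

    lsum1 = logsumexp(labf1)
    lsum2 = logsumexp(labf2)
    lsum12 = logsumexp(labf1 + labf2)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(priors.p1) + lsum1
    lh[2] = np.log(priors.p2) + lsum2
    # H3: sum over i != j of ABF1_i * ABF2_j = S1*S2 - S12
    both = lsum1 + lsum2
    if n == 1 or lsum12 >= both:
        if n > 1 and lsum12 > both + 1e-9:
            warnings.warn("negative H3 mass from floating cancellation; clamped to 0", stacklevel=2)
        lh[3] = -np.inf
    else:
        with np.errstate(divide="ignore"):
            lh[3] = np.log(priors.p1) + np.log(priors.p2) + both + np.log1p(-np.exp(lsum12 - both))
    lh[4] = np.log(priors.p12) + lsum12

    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp, n, priors, classify_coloc(float(pp[4])))
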