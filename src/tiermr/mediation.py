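"""Two-step mediation MR: indirect effects, delta-method SEs, proportions.

A mediation chain X -> M -> Y is quantified by the product of the
exposure->mediator and mediator->outcome causal estimates.  The indirect
effect's standard error comes from the (first-order) delta method; the
mediation proportion is the indirect effect divided by the total
exposure->outcome effect, reported as a percentage.  Batch screening
gates mediators on a BH-FDR-significant first leg and a nominally
significant second leg before combining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MRReport
from .tiering import bh_adjust


class MediationError(ValueError):
    pass


@dataclass
class MediationResult:
    mediator_id: str
    beta_xm: float
    se_xm: float
    beta_my: float
    se_my: float
    beta_total: float
    se_total: float
    indirect: float
    se_indirect: float
    z: float
    pval: float
    proportion: float | None  # fraction of the total effect; None if total == 0
    proportion_note: str = ""

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion


def two_step_mediation(
    beta_xm: float, se_xm: float,
    beta_my: float, se_my: float,
    beta_total: float, se_total: float,
    mediator_id: str = "",
    second_order: bool = False,
) -> MediationResult:
    """Combine the two legs into an indirect effect and mediation proportion.

    indirect = beta_xm * beta_my;
    se_indirect = sqrt(beta_my^2 se_xm^2 + beta_xm^2 se_my^2), with the
    ``second_order`` flag adding the se_xm^2 * se_my^2 cross term.
    Proportions outside [0, 1] or with sign opposite to the total effect
    are reported verbatim and flagged in ``proportion_note``.
    """
    for name, se in (("se_xm", se_xm), ("se_my", se_my), ("se_total", se_total)):
        if se <= 0:
            raise MediationError(f"{name} must be positive")
    indirect = beta_xm * beta_my
    var = beta_my**2 * se_xm**2 + beta_xm**2 * se_my**2
    if second_order:
        var += se_xm**2 * se_my**2
    se_ind = float(np.sqrt(var))
    z = indirect / se_ind if se_ind > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se_ind > 0 else 1.0

    note = ""
    if beta_total == 0:
        proportion = None
        note = "total effect is zero; proportion undefined"
    else:
        proportion = indirect / beta_total
        if indirect != 0 and np.sign(indirect) != np.sign(beta_total):
            note = "indirect and total effects have opposite signs"
        elif abs(proportion) > 1:
            note = "proportion exceeds 100%"
    return MediationResult(mediator_id, beta_xm, se_xm, beta_my, se_my,
                           beta_total, se_total, indirect, se_ind,
                           float(z), p, proportion, note)


def proportion_ci(result: MediationResult, level: float = 0.95) -> tuple[float, float]:
    """Delta-method confidence interval for the mediation proportion.

    Treats the three inputs (beta_xm, beta_my, beta_total) as independent
    estimates; the gradient of (xm*my)/total propagates their variances.
    """
    if result.proportion is None:
        raise MediationError("proportion undefined for zero total effect")
    bx, by, bt = result.beta_xm, result.beta_my, result.beta_total
    g = np.array([by / bt, bx / bt, -bx * by / bt**2])
    v = np.array([result.se_xm**2, result.se_my**2, result.se_total**2])
    se = float(np.sqrt(np.sum(g**2 * v)))
    zq = stats.norm.ppf(0.5 + level / 2)
    return result.proportion - zq * se, result.proportion + zq * se


def _primary(report: MRReport) -> tuple[float, float, float]:
    est = report.primary
    return est.beta, est.se, est.pval


def screen_mediators(
    xm_reports: dict[str, MRReport],
    my_reports: dict[str, MRReport],
    total: MRReport,
    fdr_q: float = 0.05,
    step2_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Batch mediation screen over many candidate mediators.

    Step 1 keeps mediators whose exposure->mediator p-value survives BH-FDR
    at ``fdr_q``; step 2 additionally requires a nominally significant
    mediator->outcome leg (p < ``step2_alpha``).  Survivors enter
    :func:`two_step_mediation`; the table is sorted by |proportion|
    descending.  Returns ``(table, summary_counts)``.
    """
    ids = [m for m in xm_reports if m in my_reports]
    if not ids:
        return _empty_table(), {"n_candidates": 0, "n_step1": 0, "n_step2": 0}
    p_xm = [xm_reports[m].primary.pval for m in ids]
    q_xm = bh_adjust(p_xm)
    q_by_id = dict(zip(ids, q_xm))

    step1 = [m for m in ids if q_by_id[m] < fdr_q]
    step2 = [m for m in step1 if my_reports[m].primary.pval < step2_alpha]

    bt, st, _ = _primary(total)
    rows = []
    for m in step2:
        bxm, sxm, pxm = _primary(xm_reports[m])
        bmy, smy, pmy = _primary(my_reports[m])
        res = two_step_mediation(bxm, sxm, bmy, smy, bt, st, mediator_id=m)
        rows.append({
            "mediator": m, "b_xm": bxm, "se_xm": sxm, "p_xm": pxm, "q_xm": q_by_id[m],
            "b_my": bmy, "se_my": smy, "p_my": pmy, "b_total": bt,
            "indirect": res.indirect, "se_indirect": res.se_indirect,
            "p_indirect": res.pval,
            "proportion_pct": res.proportion_pct, "note": res.proportion_note,
        })
    table = pd.DataFrame(rows) if rows else _empty_table()
    if len(table):
        table = table.reindex(
            table["proportion_pct"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    summary = {"n_candidates": len(ids), "n_step1": len(step1), "n_step2": len(step2)}
    return table, summary


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "mediator", "b_xm", "se_xm", "p_xm", "q_xm", "b_my", "se_my", "p_my",
        "b_total", "indirect", "se_indirect", "p_indirect", "proportion_pct", "note",
    ])
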