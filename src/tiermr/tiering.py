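"""Evidence-matrix construction and tiered causal-gene classification.

Evidence from SMR/HEIDI (discovery, whole blood, and a replication
cohort), two-sample MR against two outcome cohorts, and colocalization is
reduced to a gene x criterion boolean matrix.  Genes satisfying all nine
criteria are Tier 1, genes satisfying at least four are Tier 2, genes
satisfying exactly three are Tier 3, and anything weaker is unclassified.

The strict variant of the Tier-2 rule ("more than four") is selectable;
the default inclusive rule (>= 4) is the one consistent with published
tier tables in which genes with exactly four satisfied criteria appear as
Tier 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests


class TieringError(ValueError):
    pass


@dataclass(frozen=True)
class CriterionSpec:
    """One evidence criterion: a numeric column compared against a threshold.

    ``requires`` names a prerequisite criterion that must itself be
    satisfied: a non-significant HEIDI test only counts as evidence for a
    shared causal variant where the paired SMR association exists at all,
    so each HEIDI criterion lists its SMR partner as a prerequisite.
    """

    name: str
    source: str  # smr_p_fdr | heidi_p | mr_p | coloc_pp4
    column: str
    threshold: float
    direction: str  # "below" | "above"
    requires: str | None = None

    def satisfied(self, value: float | None) -> bool:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return False
        if self.direction == "below":
            return value < self.threshold
        if self.direction == "above":
            return value > self.threshold
        raise TieringError(f"unknown direction {self.direction!r}")


#: the nine default criteria: three SMR/HEIDI pairs (discovery cis-eQTL,
#: whole-blood eQTL, replication cohort), two MR p-values, and PP4 > 0.5
DEFAULT_CRITERIA: list[CriterionSpec] = [
    CriterionSpec("discovery cis pSMR-FDR", "smr_p_fdr", "smr_disc_psmr_fdr", 0.05, "below"),
    CriterionSpec("discovery cis pHEIDI", "heidi_p", "smr_disc_pheidi", 0.05, "above",
                  requires="discovery cis pSMR-FDR"),
    CriterionSpec("whole-blood pSMR-FDR", "smr_p_fdr", "smr_blood_psmr_fdr", 0.05, "below"),
    CriterionSpec("whole-blood pHEIDI", "heidi_p", "smr_blood_pheidi", 0.05, "above",
                  requires="whole-blood pSMR-FDR"),
    CriterionSpec("replication cis pSMR-FDR", "smr_p_fdr", "smr_rep_psmr_fdr", 0.05, "below"),
    CriterionSpec("replication pHEIDI", "heidi_p", "smr_rep_pheidi", 0.05, "above",
                  requires="replication cis pSMR-FDR"),
    CriterionSpec("MR discovery p", "mr_p", "mr_disc_p", 0.05, "below"),
    CriterionSpec("MR replication p", "mr_p", "mr_rep_p", 0.05, "below"),
    CriterionSpec("coloc PP4", "coloc_pp4", "coloc_pp4", 0.5, "above"),
]


@dataclass
class EvidenceMatrix:
    genes: list[str]
    criteria: list[CriterionSpec]
    values: pd.DataFrame  # gene x criterion-name numeric values (NaN = missing)
    satisfied: pd.DataFrame  # gene x criterion-name booleans

    def n_satisfied(self) -> pd.Series:
        return self.satisfied.sum(axis=1).astype(int)


@dataclass
class TierAssignment:
    gene: str
    n_satisfied: int
    tier: str  # tier1 | tier2 | tier3 | unclassified


def build_matrix(per_gene_values: pd.DataFrame, criteria: list[CriterionSpec] | None = None) -> EvidenceMatrix:
    """Evaluate every criterion for every gene.

    ``per_gene_values`` must have a ``gene`` column plus one numeric column
    per criterion source; missing values (NaN) never satisfy a criterion.
    """
    criteria = list(criteria) if criteria is not None else list(DEFAULT_CRITERIA)
    names = [c.name for c in criteria]
    if len(set(names)) != len(names):
        raise TieringError("criterion names must be unique")
    missing = [c.column for c in criteria if c.column not in per_gene_values.columns]
    if missing:
        raise TieringError(f"criterion source columns absent from input: {missing}")
    genes = list(per_gene_values["gene"])
    values = pd.DataFrame(
        {c.name: pd.to_numeric(per_gene_values[c.column], errors="coerce").to_numpy()
         for c in criteria},
        index=genes,
    )
    satisfied = pd.DataFrame(
        {c.name: [c.satisfied(v) for v in values[c.name]] for c in criteria},
        index=genes,
    )
    by_name = {c.name: c for c in criteria}
    for c in criteria:
        if c.requires is not None:
            if c.requires not in by_name:
                raise TieringError(f"criterion {c.name!r} requires unknown {c.requires!r}")
            satisfied[c.name] &= satisfied[c.requires]
    return EvidenceMatrix(genes, criteria, values, satisfied)


def assign_tiers(
    matrix: EvidenceMatrix,
    tier2_min: int = 4,
    tier3_exact: int = 3,
    tier2_strict: bool = False,
) -> list[TierAssignment]:
    """Assign tier labels from satisfied-criterion counts.

    Tier 1 requires every criterion; Tier 2 requires at least ``tier2_min``
    (strictly more when ``tier2_strict``); Tier 3 requires exactly
    ``tier3_exact``.  Output is sorted by (tier, descending count, gene).
    """
    if tier2_min <= tier3_exact and not tier2_strict:
        raise TieringError("tier2_min must exceed tier3_exact")
    n_crit = len(matrix.criteria)
    counts = matrix.n_satisfied()
    out = []
    for gene in matrix.genes:
        n = int(counts[gene])
        if n == n_crit:
            tier = "tier1"
        elif (n > tier2_min) if tier2_strict else (n >= tier2_min):
            tier = "tier2"
        elif n == tier3_exact:
            tier = "tier3"
        else:
            tier = "unclassified"
        out.append(TierAssignment(gene, n, tier))
    out.sort(key=lambda t: (t.tier, -t.n_satisfied, t.gene))
    return out


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving and monotone."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise TieringError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


# ---------------------------------------------------------------------------
# packaged evidence-matrix fixture (published PDR candidate-gene table)
# ---------------------------------------------------------------------------

_CELL_RE = re.compile(r"^\s*(?:(?:Weak|Strong|Moderate)\s*\(\s*)?([0-9.eE+-]+)\s*\)?\s*(√|×)?\s*$")


def parse_evidence_cell(cell: str) -> tuple[float | None, bool | None]:
    """Parse a printed evidence cell into (value, printed mark).

    Handles plain numerics ("1.88E-02"), graded colocalization entries
    ("Weak (0.67)", "Strong (0.86)"), "No" for missing, and trailing
    check/cross marks.
    """
    cell = str(cell).strip()
    mark = None
    if cell.endswith("√"):
        mark = True
    elif cell.endswith("×"):
        mark = False
    body = cell.rstrip("√×").strip()
    if body.lower() in ("no", "na", "", "nan"):
        return None, mark
    m = _CELL_RE.match(body)
    if not m:
        raise TieringError(f"unparseable evidence cell: {cell!r}")
    return float(m.group(1)), mark


def load_pdr_evidence_table(path=None) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Load the packaged PDR candidate-gene evidence table.

    Returns ``(values, printed_marks, printed_category)``: numeric values
    per gene and criterion column (NaN for "No"), the printed check/cross
    marks as booleans, and the printed tier category per gene.
    """
    if path is None:
        ref = resources.files("tiermr.data").joinpath("pdr_evidence_matrix.tsv")
        with resources.as_file(ref) as p:
            raw = pd.read_csv(p, sep="\t")
    else:
        raw = pd.read_csv(path, sep="\t")
    crit_cols = [c.column for c in DEFAULT_CRITERIA]
    values = {"gene": raw["gene"]}
    marks = {}
    for col in crit_cols:
        parsed = [parse_evidence_cell(v) for v in raw[col]]
        values[col] = [v for v, _ in parsed]
        marks[col] = [m for _, m in parsed]
    values_df = pd.DataFrame(values)
    marks_df = pd.DataFrame(marks, index=list(raw["gene"]))
    category = pd.Series(list(raw["category"]), index=list(raw["gene"]))
    return values_df, marks_df, category


def load_criteria_config(path) -> tuple[list[CriterionSpec], dict]:
    """Load criteria plus tier-rule parameters from a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    criteria = [CriterionSpec(**c) for c in cfg.get("criteria", [])]
    tier_rule = cfg.get("tier_rule", {})
    return criteria or list(DEFAULT_CRITERIA), tier_rule


def render_report(matrix: EvidenceMatrix, tiers: list[TierAssignment], fmt: str = "tsv") -> str:
    """Serialize the evidence matrix and tier labels.

    ``tsv`` emits one row per gene with value|mark cells, the satisfied
    count and the tier; ``text`` emits an aligned human-readable table.
    Ordering follows the tier assignment (deterministic).
    """
    rows = []
    for t in tiers:
        row: dict = {"gene": t.gene}
        for c in matrix.criteria:
            v = matrix.values.loc[t.gene, c.name]
            mark = "√" if matrix.satisfied.loc[t.gene, c.name] else "×"
            row[c.name] = ("No" if pd.isna(v) else f"{v:.3g}") + f" {mark}"
        row["n_satisfied"] = t.n_satisfied
        row["tier"] = t.tier
        rows.append(row)
    df = pd.DataFrame(rows)
    if fmt == "tsv":
        return df.to_csv(sep="\t", index=False)
    if fmt == "text":
        return df.to_string(index=False)
    raise TieringError(f"unknown report format {fmt!r}")


def tiers_from_report_tsv(text: str) -> list[TierAssignment]:
    """Re-read a rendered TSV report back into tier assignments (round-trip)."""
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t")
    return [TierAssignment(r["gene"], int(r["n_satisfied"]), r["tier"]) for _, r in df.iterrows()]
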