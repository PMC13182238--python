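"""GWAS summary-statistic containers, I/O, harmonization and instrument selection.

The basic unit is a per-variant marginal association record (effect allele,
other allele, effect-allele frequency, beta, standard error, p-value, sample
size).  A :class:`SummaryStatSet` holds one trait's records; an
:class:`LDMatrix` carries the pairwise correlation structure of a reference
panel needed for clumping and region-level tests.

Two-sample analyses require the exposure and outcome effects to refer to the
same effect allele.  :func:`harmonize` aligns the two traits per variant,
flipping signs for swapped alleles, resolving strand complements, and
dropping palindromic (A/T, C/G) variants whose allele frequency is too close
to 0.5 to orient reliably.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order used by readers/writers
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: default mapping from on-disk column names to canonical field names
DEFAULT_COLUMN_MAP = {
    "SNP": "variant_id", "CHR": "chrom", "POS": "pos", "EA": "effect_allele",
    "OA": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "pval", "N": "n",
}

MANDATORY_FIELDS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval"]


class SumstatsError(ValueError):
    """Raised for malformed summary-statistic inputs or configuration."""


class HarmonizationAction(str, Enum):
    KEPT = "kept"
    SIGN_FLIPPED = "sign_flipped"
    STRAND_FLIPPED = "strand_flipped"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_MISMATCH = "dropped_mismatch"

    def is_kept(self) -> bool:
        return self in (
            HarmonizationAction.KEPT,
            HarmonizationAction.SIGN_FLIPPED,
            HarmonizationAction.STRAND_FLIPPED,
        )


@dataclass
class SummaryStatSet:
    """One trait's per-variant marginal associations.

    ``records`` is a DataFrame with the canonical columns; ``variant_id``
    values are unique within a set.  Effect sizes for binary traits are
    log-odds on the additive per-allele scale.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SumstatsError(f"unknown trait_type {self.trait_type!r}")
        if self.records["variant_id"].duplicated().any():
            dups = self.records.loc[self.records["variant_id"].duplicated(), "variant_id"]
            raise SumstatsError(f"duplicate variant_id values: {sorted(set(dups))[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, variant_id: str) -> pd.Series:
        hit = self.records[self.records["variant_id"] == variant_id]
        if hit.empty:
            raise KeyError(variant_id)
        return hit.iloc[0]

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStatSet":
        ids = set(variant_ids)
        sub = self.records[self.records["variant_id"].isin(ids)].reset_index(drop=True)
        return SummaryStatSet(self.trait_id, self.trait_type, sub)


@dataclass
class LDMatrix:
    """Symmetric pairwise-correlation matrix over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise SumstatsError("LD matrix shape does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise SumstatsError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise SumstatsError("LD matrix diagonal is not 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r_between(self, id1: str, id2: str) -> float:
        """Pairwise r; variants absent from the panel are treated as r=0."""
        i = self._index.get(id1)
        j = self._index.get(id2)
        if i is None or j is None:
            logger.warning("variant pair (%s, %s) absent from LD matrix; assuming r=0", id1, id2)
            return 0.0
        return float(self.r[i, j])

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


@dataclass
class HarmonizedPair:
    """Exposure/outcome effect pair aligned to a shared effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    pval_out: float
    eaf_exp: float | None
    eaf_out: float | None
    action: HarmonizationAction
    pos: int | None = None
    chrom: str | None = None


@dataclass
class InstrumentSet:
    """Harmonized instruments surviving selection, clumping and F filtering."""

    exposure_id: str
    outcome_id: str
    pairs: list[HarmonizedPair]
    f_per_snp: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.f_per_snp and self.pairs:
            self.f_per_snp = [instrument_f(p) for p in self.pairs]

    @property
    def f_mean(self) -> float:
        return float(np.mean(self.f_per_snp)) if self.f_per_snp else float("nan")

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def beta_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([p.beta_exp for p in self.pairs])
        sx = np.array([p.se_exp for p in self.pairs])
        by = np.array([p.beta_out for p in self.pairs])
        sy = np.array([p.se_out for p in self.pairs])
        return bx, sx, by, sy


def instrument_f(pair: HarmonizedPair) -> float:
    """Per-instrument strength as the squared exposure z statistic."""
    return (pair.beta_exp / pair.se_exp) ** 2


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_id: str | None = None,
    sep: str = "\t",
) -> SummaryStatSet:
    """Read a delimited summary-statistic table into a validated set.

    ``column_map`` maps on-disk column names to canonical field names
    (defaults to the SNP/CHR/POS/EA/OA/EAF/BETA/SE/P/N convention).  Rows
    violating record invariants (non-positive se, p outside (0,1], invalid
    or identical alleles) are dropped and counted in ``n_dropped``.
    """
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    try:
        raw = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SumstatsError(f"empty summary-statistic file: {path}") from exc
    if raw.empty:
        raise SumstatsError(f"summary-statistic file has no data rows: {path}")

    present = {src: dst for src, dst in cmap.items() if src in raw.columns}
    missing = [f for f in MANDATORY_FIELDS if f not in present.values()]
    if missing:
        raise SumstatsError(f"missing mandatory columns for fields: {missing}")

    df = raw.rename(columns=present)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS].copy()
    return make_sumstats(df, trait_id=trait_id or str(path), trait_type=trait_type)


def make_sumstats(df: pd.DataFrame, trait_id: str, trait_type: str = "quantitative") -> SummaryStatSet:
    """Validate a canonical-column DataFrame, dropping invalid rows with a tally."""
    df = df.copy()
    for col in ("eaf", "beta", "se", "pval", "n", "pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    ok = (
        df["variant_id"].notna()
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    eaf_bad = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    ok &= ~eaf_bad
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d invalid rows for trait %s", n_dropped, trait_id)
    clean = df[ok].reset_index(drop=True)
    out = SummaryStatSet(trait_id=trait_id, trait_type=trait_type, records=clean)
    out.n_dropped = n_dropped
    return out


def write_sumstats(sset: SummaryStatSet, path, sep: str = "\t") -> None:
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    sset.records.rename(columns=inv).to_csv(path, sep=sep, index=False)


def read_ld_matrix(path, sep: str = "\t") -> LDMatrix:
    """Read an LD matrix from a square TSV (ids as header row and first column)
    or a long-format triplet table with columns id1, id2, r."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if set(df.columns[:2]) >= {"id2", "r"} or list(df.columns) == ["id2", "r"]:
        # long format read with id1 as index
        long = df.reset_index()
        long.columns = ["id1", "id2", "r"]
        ids = sorted(set(long["id1"]) | set(long["id2"]))
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for _, row in long.iterrows():
            i, j = idx[row["id1"]], idx[row["id2"]]
            r[i, j] = r[j, i] = row["r"]
        return LDMatrix(ids, r)
    return LDMatrix([str(c) for c in df.index], df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def _row_to_pair(erow, orow, beta_out, eaf_out, action) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=erow["variant_id"],
        beta_exp=float(erow["beta"]), se_exp=float(erow["se"]), pval_exp=float(erow["pval"]),
        beta_out=float(beta_out), se_out=float(orow["se"]), pval_out=float(orow["pval"]),
        eaf_exp=None if pd.isna(erow["eaf"]) else float(erow["eaf"]),
        eaf_out=eaf_out,
        action=action,
        pos=None if pd.isna(erow.get("pos")) else int(erow["pos"]),
        chrom=None if pd.isna(erow.get("chrom")) else str(erow["chrom"]),
    )


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele, per shared variant.

    Resolution order for non-palindromic variants: direct allele match
    (kept); swapped alleles (outcome beta sign flipped, eaf -> 1-eaf);
    strand complement, possibly swapped (strand_flipped, sign flipped if the
    complemented alleles are swapped); anything else is dropped_mismatch.

    Palindromic variants (A/T or C/G) cannot be strand-resolved from the
    alleles alone: they are dropped when either trait's eaf is missing or
    within ``palindrome_eaf_window`` of 0.5, and otherwise oriented by
    whether the two eafs fall on the same side of 0.5.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise SumstatsError("harmonize requires non-empty exposure and outcome sets")

    out_by_id = {r["variant_id"]: r for _, r in outcome.records.iterrows()}
    pairs: list[HarmonizedPair] = []
    n_shared = 0
    for _, erow in exposure.records.iterrows():
        orow = out_by_id.get(erow["variant_id"])
        if orow is None:
            continue
        n_shared += 1
        pairs.append(_harmonize_one(erow, orow, palindrome_eaf_window))
    if n_shared == 0:
        warnings.warn("no shared variants between exposure and outcome", stacklevel=2)
    return pairs


def _harmonize_one(erow, orow, window: float) -> HarmonizedPair:
    ea_x, oa_x = erow["effect_allele"], erow["other_allele"]
    ea_y, oa_y = orow["effect_allele"], orow["other_allele"]
    beta_y = float(orow["beta"])
    eaf_y = None if pd.isna(orow["eaf"]) else float(orow["eaf"])
    eaf_x = None if pd.isna(erow["eaf"]) else float(erow["eaf"])

    if _is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return _row_to_pair(erow, orow, beta_y, eaf_y, HarmonizationAction.DROPPED_MISMATCH)
        if eaf_x is None or eaf_y is None:
            return _row_to_pair(erow, orow, beta_y, eaf_y, HarmonizationAction.DROPPED_PALINDROMIC)
        if abs(eaf_x - 0.5) <= window or abs(eaf_y - 0.5) <= window:
            return _row_to_pair(erow, orow, beta_y, eaf_y, HarmonizationAction.DROPPED_PALINDROMIC)
        # orient by allele frequency: the effect allele is the one whose
        # frequency falls on the same side of 0.5 in both traits
        aligned = eaf_y if ea_y == ea_x else 1.0 - eaf_y
        signed = beta_y if ea_y == ea_x else -beta_y
        if (eaf_x - 0.5) * (aligned - 0.5) > 0:
            action = HarmonizationAction.KEPT if ea_y == ea_x else HarmonizationAction.SIGN_FLIPPED
            return _row_to_pair(erow, orow, signed, aligned, action)
        return _row_to_pair(erow, orow, -signed, 1.0 - aligned, HarmonizationAction.SIGN_FLIPPED)

    if (ea_y, oa_y) == (ea_x, oa_x):
        return _row_to_pair(erow, orow, beta_y, eaf_y, HarmonizationAction.KEPT)
    if (ea_y, oa_y) == (oa_x, ea_x):
        flipped_eaf = None if eaf_y is None else 1.0 - eaf_y
        return _row_to_pair(erow, orow, -beta_y, flipped_eaf, HarmonizationAction.SIGN_FLIPPED)

    cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return _row_to_pair(erow, orow, beta_y, eaf_y, HarmonizationAction.STRAND_FLIPPED)
    if (cea, coa) == (oa_x, ea_x):
        flipped_eaf = None if eaf_y is None else 1.0 - eaf_y
        return _row_to_pair(erow, orow, -beta_y, flipped_eaf, HarmonizationAction.STRAND_FLIPPED)

    return _row_to_pair(erow, orow, beta_y, eaf_y, HarmonizationAction.DROPPED_MISMATCH)


# ---------------------------------------------------------------------------
# clumping and instrument selection
# ---------------------------------------------------------------------------

def clump(
    records: SummaryStatSet,
    ld: LDMatrix,
    r2_max: float = 0.01,
    window_kb: int = 10_000,
) -> list[str]:
    """Greedy LD clumping: retain p-value-sorted variants whose r-squared with
    every already-retained variant within the window stays below ``r2_max``.

    Ties on p-value break lexicographically on variant_id, making the
    retained set invariant to input row order.  Positions are 1-based and
    the window is the closed interval |pos difference| <= window_kb * 1000.
    """
    if not (0 < r2_max <= 1):
        raise SumstatsError(f"r2_max must be in (0, 1], got {r2_max}")
    df = records.records
    order = df.sort_values(["pval", "variant_id"], kind="mergesort")
    retained: list[tuple[str, float]] = []  # (id, pos)
    for _, row in order.iterrows():
        vid = row["variant_id"]
        pos = float(row["pos"]) if not pd.isna(row["pos"]) else np.nan
        independent = True
        for rid, rpos in retained:
            if not (np.isnan(pos) or np.isnan(rpos)):
                if abs(pos - rpos) > window_kb * 1000:
                    continue
            if ld.r_between(vid, rid) ** 2 >= r2_max:
                independent = False
                break
        if independent:
            retained.append((vid, pos))
    return [vid for vid, _ in retained]


def select_instruments(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_max: float = 0.01,
    window_kb: int = 10_000,
    palindrome_eaf_window: float = 0.08,
    f_min: float | None = 10.0,
) -> InstrumentSet:
    """Full instrument-selection chain for two-sample MR.

    Exposure variants passing ``p_threshold`` are LD-clumped, harmonized
    against the outcome, and screened for instrument strength (per-SNP
    F = (beta/se)^2, instruments with F <= ``f_min`` removed when ``f_min``
    is set).  An empty result is returned (with a warning) when nothing
    survives.
    """
    sig = exposure.records[exposure.records["pval"] < p_threshold]
    if sig.empty:
        warnings.warn("no valid instruments: no exposure variant passes the p threshold", stacklevel=2)
        return InstrumentSet(exposure.trait_id, outcome.trait_id, [])
    sig_set = SummaryStatSet(exposure.trait_id, exposure.trait_type, sig.reset_index(drop=True))
    kept_ids = clump(sig_set, ld, r2_max=r2_max, window_kb=window_kb)
    clumped = sig_set.subset(kept_ids)
    pairs = harmonize(clumped, outcome, palindrome_eaf_window=palindrome_eaf_window)
    kept = [p for p in pairs if p.action.is_kept()]
    if f_min is not None:
        kept = [p for p in kept if instrument_f(p) > f_min]
    if not kept:
        warnings.warn("no valid instruments after harmonization/F filtering", stacklevel=2)
    return InstrumentSet(exposure.trait_id, outcome.trait_id, kept)
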