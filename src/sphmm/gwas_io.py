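"""Reading, harmonising, filtering and LD-pruning GWAS summary statistics.

The downstream mixture model assumes a set of (nearly) independent SNPs,
each carrying a log-odds-ratio estimate under the additive allele-dosage
model and the variance of that estimate.  This module turns heterogeneous
consortium summary files into that object: a :class:`SummaryTable` of
validated records, optionally re-oriented so effects refer to the derived
allele, restricted to a reference panel, and thinned by random LD pruning
until no retained pair exceeds an r-squared threshold.

All readers accept tab-, comma- or whitespace-delimited text with a header
row; a ``column_map`` names the relevant columns, so no particular
consortium dialect is assumed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "SummaryTable",
    "LdTable",
    "PrunedSet",
    "DropReport",
    "GwasFormatError",
    "EmptyInputError",
    "read_summary_table",
    "read_ld_table",
    "read_panel",
    "read_allele_map",
    "harmonize_to_derived",
    "filter_to_panel",
    "ld_prune",
    "count_significant",
]


class GwasFormatError(ValueError):
    """A summary-statistics file does not expose the required columns."""


class EmptyInputError(ValueError):
    """An operation produced (or received) zero usable SNP records."""


# canonical internal column order
_COLS = ["snp_id", "effect_allele", "other_allele", "beta_hat", "var_hat", "p_value", "maf"]

# column_map that reads back a table written by SummaryTable.to_tsv
INTERNAL_COLUMN_MAP = {
    "snp": "snp_id",
    "a1": "effect_allele",
    "a2": "other_allele",
    "beta": "beta_hat",
    "var": "var_hat",
    "maf": "maf",
}

# accepted role aliases for column_map keys
_ROLE_ALIASES = {
    "snp": "snp",
    "snp_id": "snp",
    "id": "snp",
    "a1": "effect_allele",
    "effect_allele": "effect_allele",
    "a2": "other_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "or": "or",
    "odds_ratio": "or",
    "se": "se",
    "var": "var",
    "p": "p",
    "pvalue": "p",
    "p_value": "p",
    "frq": "maf",
    "maf": "maf",
    "freq": "maf",
}


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's association summary.

    ``beta_hat`` is the estimated log odds ratio per copy of
    ``effect_allele`` (genotype dosage 0/1/2), ``var_hat`` the variance of
    that estimate.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_hat: float
    var_hat: float
    p_value: float | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta_hat):
            raise ValueError(f"{self.snp_id}: beta_hat must be finite")
        if not (np.isfinite(self.var_hat) and self.var_hat > 0):
            raise ValueError(f"{self.snp_id}: var_hat must be positive and finite")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")


@dataclass
class SummaryTable:
    """An ordered collection of SNP records plus study sample sizes."""

    df: pd.DataFrame
    n_cases: int
    n_controls: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        missing = [c for c in _COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SummaryTable frame missing columns: {missing}")
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in SummaryTable")
        self.df = self.df.reset_index(drop=True)

    @property
    def m(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    @property
    def y(self) -> np.ndarray:
        """Vector of log-OR estimates, in table order."""
        return self.df["beta_hat"].to_numpy(float)

    @property
    def v(self) -> np.ndarray:
        """Vector of estimate variances, in table order."""
        return self.df["var_hat"].to_numpy(float)

    @property
    def records(self) -> Iterator[SnpRecord]:
        for row in self.df.itertuples(index=False):
            yield SnpRecord(
                snp_id=row.snp_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta_hat=row.beta_hat,
                var_hat=row.var_hat,
                p_value=None if pd.isna(row.p_value) else row.p_value,
                maf=None if pd.isna(row.maf) else row.maf,
            )

    def subset_ids(self, ids: Iterable[str]) -> "SummaryTable":
        """Restrict to ``ids``, preserving table order."""
        keep = set(ids)
        sub = self.df[self.df["snp_id"].isin(keep)].reset_index(drop=True)
        return replace(self, df=sub)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class DropReport:
    """Counts of records dropped by an I/O or harmonisation step, by reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int) -> None:
        if n:
            self.counts[reason] = self.counts.get(reason, 0) + int(n)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_dict(self) -> dict:
        return {"total_dropped": self.total, "by_reason": dict(self.counts)}

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class LdTable:
    """Symmetric pairwise r-squared table.

    An absent pair is treated as independent (r² below any threshold of
    interest); self-pairs are ignored.
    """

    pairs: pd.DataFrame  # columns: snp_a, snp_b, r2

    def __post_init__(self) -> None:
        df = self.pairs
        need = {"snp_a", "snp_b", "r2"}
        if not need.issubset(df.columns):
            raise ValueError(f"LdTable frame needs columns {sorted(need)}")
        if ((df["r2"] < 0) | (df["r2"] > 1)).any():
            raise ValueError("r2 values must lie in [0, 1]")
        self.pairs = df[df["snp_a"] != df["snp_b"]].reset_index(drop=True)

    def neighbors_above(self, r2_threshold: float, universe: set[str] | None = None) -> dict[str, set[str]]:
        """Adjacency (both directions) restricted to pairs with r² > threshold."""
        df = self.pairs[self.pairs["r2"] > r2_threshold]
        if universe is not None:
            df = df[df["snp_a"].isin(universe) & df["snp_b"].isin(universe)]
        adj: dict[str, set[str]] = {}
        for a, b in zip(df["snp_a"], df["snp_b"]):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj


@dataclass
class PrunedSet:
    """A SummaryTable thinned so no retained pair exceeds ``r2_threshold``."""

    table: SummaryTable
    r2_threshold: float
    seed: int
    n_input: int

    @property
    def m(self) -> int:
        return self.table.m

    @property
    def y(self) -> np.ndarray:
        return self.table.y

    @property
    def v(self) -> np.ndarray:
        return self.table.v

    @property
    def snp_ids(self) -> list[str]:
        return self.table.snp_ids


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _normalize_column_map(column_map: Mapping[str, str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for role, col in column_map.items():
        key = _ROLE_ALIASES.get(role.lower())
        if key is None:
            raise GwasFormatError(f"unknown column role {role!r}")
        out[key] = col
    return out


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str],
    n_cases: int,
    n_controls: int,
    provenance: str | None = None,
) -> tuple[SummaryTable, DropReport]:
    """Parse a delimited summary-statistics file into a :class:`SummaryTable`.

    ``column_map`` maps roles to header names; required roles are ``snp``,
    ``a1``, ``a2`` and an effect column (``beta`` or ``or``), plus at least
    one of ``var``, ``se``, ``p``.  When several uncertainty columns are
    present the least derived wins: var > se > p.  An odds-ratio column is
    converted via the natural log.  Rows violating record invariants are
    dropped and tallied in the returned :class:`DropReport`.
    """
    roles = _normalize_column_map(column_map)
    need = {"snp", "effect_allele", "other_allele"}
    if not need.issubset(roles):
        raise GwasFormatError(f"column_map must name roles {sorted(need)}")
    if "beta" not in roles and "or" not in roles:
        raise GwasFormatError("column_map must name a 'beta' or 'or' column")
    if not ({"var", "se", "p"} & roles.keys()):
        raise GwasFormatError("column_map must name at least one of var/se/p")

    raw = pd.read_csv(path, sep=_sniff_sep(path), dtype={roles["snp"]: str}, float_precision="round_trip")
    # mapped-but-absent columns: fatal for identity/effect roles, tolerated
    # for optional extras (maf, redundant uncertainty columns)
    absent = {role: col for role, col in roles.items() if col not in raw.columns}
    hard = [col for role, col in absent.items() if role in need]
    effect_roles = [r for r in ("beta", "or") if r in roles]
    if all(r in absent for r in effect_roles):
        hard.extend(absent[r] for r in effect_roles)
    if hard:
        raise GwasFormatError(f"{path}: missing columns {sorted(set(hard))}")
    for role in absent:
        if role not in need:
            roles.pop(role)
    if not ({"var", "se", "p"} & roles.keys()):
        raise GwasFormatError(f"{path}: no variance/SE/p column present")

    report = DropReport()
    df = pd.DataFrame(
        {
            "snp_id": raw[roles["snp"]].astype(str),
            "effect_allele": raw[roles["effect_allele"]].astype(str).str.upper(),
            "other_allele": raw[roles["other_allele"]].astype(str).str.upper(),
        }
    )
    if "beta" in roles:
        beta = pd.to_numeric(raw[roles["beta"]], errors="coerce")
    else:
        orr = pd.to_numeric(raw[roles["or"]], errors="coerce")
        beta = np.log(orr.where(orr > 0))
    df["beta_hat"] = beta

    p_col = pd.to_numeric(raw[roles["p"]], errors="coerce") if "p" in roles else None
    var = pd.Series(np.nan, index=raw.index)
    bad_p = pd.Series(False, index=raw.index)
    if "var" in roles:
        var = pd.to_numeric(raw[roles["var"]], errors="coerce")
    elif "se" in roles:
        var = pd.to_numeric(raw[roles["se"]], errors="coerce") ** 2
    else:
        # variance implied by (beta, p): var = (beta / z)^2 with z the
        # two-sided normal quantile; undefined when p is 0/1 or beta is 0
        usable = (p_col > 0) & (p_col < 1) & beta.notna() & (beta != 0)
        z = pd.Series(np.nan, index=raw.index)
        z[usable] = stats.norm.isf(p_col[usable] / 2.0)
        var = (beta / z) ** 2
        bad_p = p_col.notna() & beta.notna() & ~usable
    df["var_hat"] = var
    df["p_value"] = p_col if p_col is not None else np.nan
    if "maf" in roles:
        df["maf"] = pd.to_numeric(raw[roles["maf"]], errors="coerce")
    else:
        df["maf"] = np.nan

    bad_alleles = (
        (df["effect_allele"] == df["other_allele"])
        | (df["effect_allele"].str.len() != 1)
        | (df["other_allele"].str.len() != 1)
    )
    bad_beta = ~np.isfinite(df["beta_hat"])
    bad_var = ~(np.isfinite(df["var_hat"]) & (df["var_hat"] > 0))
    dup = df["snp_id"].duplicated()

    report.add("invalid_alleles", int(bad_alleles.sum()))
    report.add("undefined_p_variance", int((bad_p & ~bad_alleles).sum()))
    report.add("nonfinite_beta", int((bad_beta & ~bad_alleles & ~bad_p).sum()))
    report.add(
        "nonpositive_variance",
        int((bad_var & ~bad_beta & ~bad_alleles & ~bad_p).sum()),
    )
    bad = bad_alleles | bad_beta | bad_var | bad_p
    report.add("duplicate_snp_id", int((dup & ~bad).sum()))
    bad |= dup

    df = df[~bad].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no usable SNP records after validation")
    if report.total:
        log.info("read_summary_table: dropped %d rows: %s", report.total, report.counts)
    table = SummaryTable(
        df=df[_COLS],
        n_cases=n_cases,
        n_controls=n_controls,
        provenance=provenance or str(path),
    )
    return table, report


def read_ld_table(path: str | Path) -> LdTable:
    """Read a pairwise LD table.

    Accepts a 3-column delimited file (id_a, id_b, r2, with or without a
    header) and the whitespace-separated pairwise-LD report dialect with
    SNP_A / SNP_B / R2 header columns.
    """
    sep = _sniff_sep(path)
    head = pd.read_csv(path, sep=sep, nrows=1)
    cols_upper = {c.upper(): c for c in head.columns}
    if {"SNP_A", "SNP_B", "R2"}.issubset(cols_upper):
        df = pd.read_csv(path, sep=sep, dtype={cols_upper["SNP_A"]: str, cols_upper["SNP_B"]: str}, float_precision="round_trip")
        df = df.rename(
            columns={cols_upper["SNP_A"]: "snp_a", cols_upper["SNP_B"]: "snp_b", cols_upper["R2"]: "r2"}
        )[["snp_a", "snp_b", "r2"]]
        return LdTable(pairs=df)
    # plain 3-column: detect header by whether the third field parses as float
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    if first.shape[1] < 3:
        raise GwasFormatError(f"{path}: LD table needs at least 3 columns")
    try:
        float(first.iloc[0, 2])
        header = None
    except (TypeError, ValueError):
        header = 0
    df = pd.read_csv(path, sep=sep, header=header, dtype={0: str, 1: str}, float_precision="round_trip")
    df = df.iloc[:, :3]
    df.columns = ["snp_a", "snp_b", "r2"]
    df["snp_a"] = df["snp_a"].astype(str)
    df["snp_b"] = df["snp_b"].astype(str)
    df["r2"] = pd.to_numeric(df["r2"])
    return LdTable(pairs=df)


def read_panel(path: str | Path) -> set[str]:
    """Read a one-id-per-line SNP panel list (first token per line)."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        tok = line.replace(",", " ").split()
        if tok:
            ids.add(tok[0])
    return ids


def read_allele_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read an ancestral/derived allele map: lines of ``id ancestral derived``."""
    out: dict[str, tuple[str, str]] = {}
    for line in Path(path).read_text().splitlines():
        tok = line.replace(",", "\t").split()
        if not tok:
            continue
        if len(tok) < 3:
            raise GwasFormatError(f"{path}: allele map line needs 3 fields: {line!r}")
        if tok[0].lower() in {"snp", "snp_id", "id"}:  # header
            continue
        out[tok[0]] = (tok[1].upper(), tok[2].upper())
    return out


def harmonize_to_derived(
    table: SummaryTable, allele_map: Mapping[str, tuple[str, str]]
) -> tuple[SummaryTable, DropReport]:
    """Re-sign effects so the effect allele is the derived allele.

    ``allele_map`` gives (ancestral, derived) per SNP.  Records already
    oriented to the derived allele pass through; records oriented to the
    ancestral allele have their sign flipped and alleles swapped; records
    absent from the map or inconsistent with it are dropped and counted.
    """
    df = table.df
    anc = df["snp_id"].map(lambda s: allele_map.get(s, (None, None))[0])
    der = df["snp_id"].map(lambda s: allele_map.get(s, (None, None))[1])
    in_map = anc.notna()
    ok = in_map & (df["effect_allele"] == der) & (df["other_allele"] == anc)
    flip = in_map & (df["effect_allele"] == anc) & (df["other_allele"] == der)
    inconsistent = in_map & ~ok & ~flip

    report = DropReport()
    report.add("not_in_allele_map", int((~in_map).sum()))
    report.add("alleles_inconsistent_with_map", int(inconsistent.sum()))

    out = df[ok | flip].copy()
    fl = flip[ok | flip]
    out.loc[fl, "beta_hat"] = -out.loc[fl, "beta_hat"]
    swapped = out.loc[fl, ["other_allele", "effect_allele"]].to_numpy()
    out.loc[fl, ["effect_allele", "other_allele"]] = swapped
    if len(out) == 0:
        raise EmptyInputError("no SNPs left after allele harmonisation")
    if report.total:
        log.info("harmonize_to_derived: dropped %d rows: %s", report.total, report.counts)
    return replace(table, df=out.reset_index(drop=True)), report


def filter_to_panel(table: SummaryTable, panel_ids: Iterable[str]) -> SummaryTable:
    """Restrict the table to SNPs on a reference panel, preserving order."""
    out = table.subset_ids(panel_ids)
    if out.m == 0:
        raise EmptyInputError("no SNPs overlap the reference panel")
    return out


def ld_prune(
    table: SummaryTable | PrunedSet,
    ld: LdTable,
    r2_threshold: float = 0.1,
    seed: int = 0,
) -> PrunedSet:
    """Random LD pruning to a nearly independent SNP set.

    Repeatedly draw one SNP uniformly at random from the remaining
    candidates (irrespective of association strength), retain it, and
    remove all candidates in LD (r² > threshold) with it, until no
    candidates remain.  Processing a uniformly random permutation with a
    greedy skip is distributionally identical and runs in linear time.
    Deterministic given ``seed``.
    """
    if not (0 < r2_threshold < 1):
        raise ValueError("r2_threshold must lie in (0, 1)")
    base = table.table if isinstance(table, PrunedSet) else table
    ids = base.snp_ids
    adj = ld.neighbors_above(r2_threshold, universe=set(ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    removed: set[str] = set()
    retained: set[str] = set()
    for i in order:
        sid = ids[i]
        if sid in removed:
            continue
        retained.add(sid)
        removed.update(adj.get(sid, ()))
    pruned = base.subset_ids(retained)
    log.info("ld_prune: retained %d of %d SNPs at r2 > %.3g (seed %d)", pruned.m, len(ids), r2_threshold, seed)
    return PrunedSet(table=pruned, r2_threshold=r2_threshold, seed=seed, n_input=len(ids))


def count_significant(data: PrunedSet | SummaryTable, p_c: float) -> int:
    """Count SNPs whose two-sided normal p-value reaches ``p_c``.

    Implemented on the z scale (|β̂|/√V̂ ≥ z_c) for numerical robustness at
    genome-wide thresholds.
    """
    if not (0 < p_c <= 1):
        raise ValueError("p_c must lie in (0, 1]")
    y = data.y
    v = data.v
    z_c = stats.norm.isf(p_c / 2.0)
    return int(np.count_nonzero(np.abs(y) / np.sqrt(v) >= z_c))
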