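"""Data model and I/O for GWAS summary statistics and LD reference information.

Every downstream stage (instrument selection, harmonisation, estimation,
screening) consumes the containers defined here:

* :class:`TraitMeta` — trait-level metadata (id, name, sample size, type).
* :class:`SummaryStats` — one trait's per-variant association table.
* :class:`LDReference` — block-diagonal pairwise r² with explicit allele
  phase, so proxy substitution knows which proxy allele tracks the index
  variant's effect allele.

Only biallelic SNVs with single-character A/C/G/T alleles are modelled;
indels and multi-allelic rows are rejected at validation.  Positions are
1-based and clumping distance is measured as the absolute base-pair
difference on the same chromosome.

The on-disk dialect is an uncompressed, unquoted, UTF-8 TSV with header
columns ``SNP CHR BP EA OA EAF BETA SE P N`` ('.' or empty for missing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical internal column order for a summary-statistics table
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

_FILE_TO_INTERNAL = {
    "SNP": "variant_id", "CHR": "chrom", "BP": "pos", "EA": "effect_allele",
    "OA": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "pvalue", "N": "n",
}
_INTERNAL_TO_FILE = {v: k for k, v in _FILE_TO_INTERNAL.items()}
_MANDATORY = ["SNP", "EA", "OA", "BETA", "SE", "P"]


class SummaryStatsFormatError(ValueError):
    """A summary-statistics file violates the expected TSV dialect."""


class EmptyInputError(ValueError):
    """An input file or table contains no usable rows."""


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one GWAS trait.

    ``trait_type`` controls effect-size presentation downstream: continuous
    exposures additionally report OR = exp(beta) per 1 SD of exposure change,
    binary exposures report beta only.
    """

    trait_id: str
    trait_name: str
    sample_size: int
    trait_type: str = "continuous"
    batch: str = ""
    population: str = "EUR"

    def __post_init__(self):
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary/continuous, got {self.trait_type!r}")


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or G/C variants read the same on both strands."""
    return COMPLEMENT.get(ea) == oa


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    """Drop rows violating the per-variant invariants; count reasons.

    Invariants: single-character A/C/G/T alleles, effect != other allele,
    se > 0, 0 < p <= 1, 0 < eaf < 1 when present, positive integer n when
    present, unique variant_id.
    """
    df = df.copy()
    drops: Counter = Counter()

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        bad = mask.fillna(True) if mask.dtype == object else mask
        n = int(bad.sum())
        if n:
            drops[reason] += n
            df = df[~bad]

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    _drop(~(df["effect_allele"].isin(ALLELES) & df["other_allele"].isin(ALLELES)),
          "non_snv_allele")
    _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    for col in ("beta", "se", "pvalue", "eaf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    _drop(df["beta"].isna(), "missing_beta")
    _drop(~(df["se"] > 0), "nonpositive_se")
    _drop(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "invalid_pvalue")
    _drop(df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "invalid_eaf")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    _drop(df["n"].notna() & ~(df["n"] > 0), "nonpositive_n")
    _drop(df["variant_id"].duplicated(keep="first"), "duplicate_variant_id")
    return df.reset_index(drop=True), drops


class SummaryStats:
    """One trait's validated per-variant association table plus metadata.

    Wraps a :class:`pandas.DataFrame` with columns :data:`COLUMNS` and keeps
    a ``variant_id -> row namedtuple`` index for fast single-variant access.
    """

    def __init__(self, meta: TraitMeta, table: pd.DataFrame, *, validate: bool = True):
        table = table.copy()
        for col in COLUMNS:
            if col not in table.columns:
                table[col] = np.nan if col in ("eaf", "n", "pos") else ""
        table = table[COLUMNS]
        if validate:
            table, self.drop_log = validate_records(table)
        else:
            self.drop_log = Counter()
        self.meta = meta
        self.table = table.reset_index(drop=True)
        self._index = {row.variant_id: row for row in self.table.itertuples(index=False)}

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str):
        """Row namedtuple for one variant (KeyError if absent)."""
        return self._index[variant_id]

    @property
    def ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        keep = set(variant_ids)
        sub = self.table[self.table["variant_id"].isin(keep)]
        return SummaryStats(self.meta, sub, validate=False)


def read_summary_stats(path: str | Path, meta: TraitMeta) -> SummaryStats:
    """Read a summary-statistics TSV; invalid rows are dropped and counted.

    Raises :class:`SummaryStatsFormatError` naming the first missing
    mandatory column, :class:`EmptyInputError` for an empty file.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "."],
                          keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    for col in _MANDATORY:
        if col not in raw.columns:
            raise SummaryStatsFormatError(f"{path}: missing mandatory column {col!r}")
    if len(raw) == 0:
        raise EmptyInputError(f"{path} has a header but no data rows")
    raw = raw.rename(columns=_FILE_TO_INTERNAL)
    for col in COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    raw["pos"] = pd.to_numeric(raw["pos"], errors="coerce")
    raw["chrom"] = raw["chrom"].fillna("")
    return SummaryStats(meta, raw[COLUMNS])


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write the canonical TSV dialect (round-trips through the reader)."""
    out = stats.table.rename(columns=_INTERNAL_TO_FILE)
    out = out[[_INTERNAL_TO_FILE[c] for c in COLUMNS]]
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def write_results_table(records: Sequence, path: str | Path) -> None:
    """Write a homogeneous collection of result dataclasses/mappings as TSV.

    Columns follow the first record's field order deterministically.  An
    empty collection produces a header-only file when the element schema is
    unknown, so the output is still machine-readable.
    """
    path = Path(path)
    rows: list[dict] = []
    for rec in records:
        if is_dataclass(rec):
            rows.append(_flatten(asdict(rec)))
        elif isinstance(rec, Mapping):
            rows.append(_flatten(dict(rec)))
        else:
            raise TypeError(f"unsupported record type {type(rec)!r}")
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", na_values=["."])


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(dict(v), prefix=f"{key}."))
        elif isinstance(v, (list, tuple, set, frozenset)):
            out[key] = ";".join(str(x) for x in sorted(v, key=str)) if isinstance(v, (set, frozenset)) \
                else ";".join(str(x) for x in v)
        else:
            out[key] = v
    return out


class LDReference:
    """Block-diagonal LD: pairwise r² within blocks, 0 across blocks.

    ``phase`` records, for each correlated pair, which allele of one variant
    co-occurs with which allele of the other — required for proxy
    substitution (the proxy allele tracking the index effect allele stands
    in for it).
    """

    def __init__(self, blocks: Mapping[str, int] | None = None):
        self.blocks: dict[str, int] = dict(blocks or {})
        self._r2: dict[tuple[str, str], float] = {}
        self._phase: dict[tuple[str, str], tuple[str, str]] = {}

    def add_pair(self, a: str, allele_a: str, b: str, allele_b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        self._r2[(a, b)] = r2
        self._r2[(b, a)] = r2
        self._phase[(a, b)] = (allele_a, allele_b)
        self._phase[(b, a)] = (allele_b, allele_a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get((a, b), 0.0)

    def phase(self, a: str, b: str) -> tuple[str, str] | None:
        """(allele of a, co-occurring allele of b) or None if uncorrelated."""
        return self._phase.get((a, b))

    def partners(self, a: str) -> list[tuple[str, float]]:
        """All variants with recorded nonzero r² to ``a``."""
        return [(b, r) for (x, b), r in self._r2.items() if x == a]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.blocks

    def write(self, pairs_path: str | Path, blocks_path: str | Path) -> None:
        rows = []
        for (a, b), r2 in sorted(self._r2.items()):
            if a < b:  # each unordered pair once
                pa, pb = self._phase[(a, b)]
                rows.append((a, pa, b, pb, r2))
        pd.DataFrame(rows, columns=["variant_a", "allele_a", "variant_b",
                                    "allele_b", "r2"]).to_csv(
            pairs_path, sep="\t", index=False)
        pd.DataFrame(sorted(self.blocks.items()),
                     columns=["variant_id", "block"]).to_csv(
            blocks_path, sep="\t", index=False)

    @classmethod
    def read(cls, pairs_path: str | Path, blocks_path: str | Path) -> "LDReference":
        blocks = pd.read_csv(blocks_path, sep="\t", dtype={"variant_id": str})
        ld = cls(dict(zip(blocks["variant_id"], blocks["block"].astype(int))))
        pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
        for row in pairs.itertuples(index=False):
            ld.add_pair(row.variant_a, row.allele_a, row.variant_b,
                        row.allele_b, float(row.r2))
        return ld
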