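"""Significance filtering, lead-SNP selection and functional-rank
prioritization.

Functional ranks follow the RegulomeDB convention: a digit category 1-7,
categories 1 and 2 (and some others) subdivided by a letter a-f.  Lower
ranks indicate higher regulatory probability, so "1a" outranks "1b"
outranks "2a" ... outranks "7".  Variants without a rank sort after all
ranked variants — unranked is not evidence of non-function, but it
cannot outrank evidence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .sumstats import EmptyInputError, LocusTable, SumstatsError

__all__ = [
    "RankKey",
    "filter_significant",
    "lead_variant",
    "merge_functional_ranks",
    "prioritize",
    "read_rank_map",
    "DEFAULT_SCREEN_THRESHOLD",
    "GENOME_WIDE_THRESHOLD",
]

#: Screening threshold used to call a locus's susceptibility variants.
DEFAULT_SCREEN_THRESHOLD = 1e-8
#: Conventional genome-wide significance threshold.
GENOME_WIDE_THRESHOLD = 5e-8

_RANK_RE = re.compile(r"^([1-7])([a-f]?)$")


@dataclass(frozen=True, order=True)
class RankKey:
    """Parsed functional rank with a strict total order.

    Ordering: category ascending, then subcategory letter ascending,
    with a bare digit sorting after its lettered peers is *not* the
    convention — a bare category ("7") has no letter and compares as
    letter-less, i.e. before "7a" would; in practice bare digits only
    occur for categories without subdivisions, so the order over valid
    strings is the familiar "1a" < "1b" < ... < "2a" < ... < "7".
    """

    category: int
    subcategory: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.category <= 7):
            raise SumstatsError(f"rank category {self.category} outside 1-7")
        if self.subcategory and self.subcategory not in "abcdef":
            raise SumstatsError(f"bad rank subcategory {self.subcategory!r}")

    @classmethod
    def parse(cls, text: str) -> "RankKey":
        m = _RANK_RE.match(text.strip().lower())
        if not m:
            raise SumstatsError(f"unparseable functional rank {text!r}")
        return cls(category=int(m.group(1)), subcategory=m.group(2))

    def __str__(self) -> str:
        return f"{self.category}{self.subcategory}"

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.category, self.subcategory)


def filter_significant(
    table: LocusTable, threshold: float = DEFAULT_SCREEN_THRESHOLD
) -> LocusTable:
    """Keep records with p strictly below ``threshold`` (order preserved).

    Idempotent, and monotone in the threshold: a larger threshold keeps
    a superset.
    """
    if not (0.0 < threshold < 1.0):
        raise SumstatsError(f"threshold {threshold} outside (0, 1)")
    kept = tuple(
        r for r in table.records if r.p is not None and r.p < threshold
    )
    return LocusTable(kept, region=table.region)


def lead_variant(table: LocusTable) -> str:
    """rsid of the minimum-p record.

    Ties break by larger |z| (stronger Wald evidence), then smaller
    position.
    """
    if len(table) == 0:
        raise EmptyInputError("cannot pick a lead variant from an empty table")
    recs = [r for r in table.records if r.p is not None]
    if not recs:
        raise EmptyInputError("no records carry a p-value")

    def key(r):
        z = r.z
        return (r.p, -(abs(z) if z is not None else 0.0), r.pos)

    return min(recs, key=key).rsid


def merge_functional_ranks(
    table: LocusTable, ranks: Mapping[str, str]
) -> tuple[LocusTable, list[tuple[str, str]]]:
    """Populate ``functional_rank`` from an rsid -> rank-string mapping.

    Unknown rsids in the mapping are ignored; unparseable rank strings
    are rejected per-row and returned as (rsid, reason) pairs.  The
    table is otherwise unchanged.
    """
    rejected: list[tuple[str, str]] = []
    valid: dict[str, str] = {}
    for rsid, text in ranks.items():
        try:
            valid[rsid] = str(RankKey.parse(text))
        except SumstatsError as exc:
            rejected.append((rsid, str(exc)))
    new = tuple(
        replace(r, functional_rank=valid[r.rsid]) if r.rsid in valid else r
        for r in table.records
    )
    return LocusTable(new, region=table.region), rejected


def prioritize(table: LocusTable) -> pd.DataFrame:
    """Ordered variant report: rank sort-key ascending, then p ascending.

    Missing ranks sort last.  Emits rsid, pos, p, -log10(p), rank and
    the eQTL flag.
    """
    rows = []
    for r in table.records:
        key = (
            RankKey.parse(r.functional_rank).sort_key
            if r.functional_rank
            else (8, "")  # past every valid category
        )
        rows.append(
            {
                "rsid": r.rsid,
                "pos": r.pos,
                "p": r.p,
                "neglog10p": r.neglog10p(),
                "rank": r.functional_rank or "NA",
                "eqtl": bool(r.eqtl_flag) if r.eqtl_flag is not None else False,
                "_key": key,
                "_p": r.p if r.p is not None else math.inf,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["_key", "_p"], kind="stable").drop(
            columns=["_key", "_p"]
        ).reset_index(drop=True)
    return df


def read_rank_map(path: str | Path) -> dict[str, str]:
    """2-column TSV (rsid, rank) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    a, b = df.columns[:2]
    return dict(zip(df[a], df[b]))
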