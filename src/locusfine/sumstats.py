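"""Per-variant GWAS summary statistics: records, locus tables, I/O and
z/p/beta conversions.

A :class:`VariantRecord` carries one SNP's marginal association summary
(effect size ``beta`` in trait-SD units, its standard error ``se``, the
two-sided p-value, minor allele frequency and sample size) plus optional
functional annotations.  A :class:`LocusTable` is an ordered, validated
collection of records for one genomic region.

Conversions between the (beta, se), z and p representations are
underflow-safe: -log10(p) is always computed through the logarithm of the
normal survival function, so loci with |z| well beyond 38 (where the
double-precision p underflows to 0) remain finite and accurate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VariantRecord",
    "LocusTable",
    "ValidationFailure",
    "DEFAULT_COLUMN_MAP",
    "read_sumstats",
    "write_sumstats",
    "write_validation_report",
    "z_from_beta_se",
    "z_from_p",
    "p_from_z",
    "neglog10p_from_z",
    "fold_maf",
]

_LN10 = math.log(10.0)

#: Default mapping of logical field name -> file column name (GWAS convention).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "maf": "MAF",
    "n": "N",
    "functional_rank": "RANK",
    "eqtl_flag": "EQTL",
}

_OPTIONAL_FIELDS = {"effect_allele", "other_allele", "beta", "se", "p", "maf",
                    "n", "functional_rank", "eqtl_flag"}
_REQUIRED_FIELDS = {"rsid", "chrom", "pos"}


class SumstatsError(ValueError):
    """Base error for summary-statistic handling."""


class ConfigurationError(SumstatsError):
    """A mapped column is absent from the file header."""


class EmptyInputError(SumstatsError):
    """No valid records survived validation."""


@dataclass(frozen=True)
class ValidationFailure:
    """One rejected input row and the reason it failed."""

    rsid: str
    reason: str


def fold_maf(maf: float) -> float:
    """Fold an allele frequency onto the minor side, (0, 0.5].

    Idempotent: folding twice equals folding once.
    """
    if not (0.0 < maf < 1.0):
        raise SumstatsError(f"allele frequency {maf} outside (0, 1)")
    return maf if maf <= 0.5 else 1.0 - maf


@dataclass(frozen=True)
class VariantRecord:
    """Summary statistics and annotations for one SNP.

    ``pos`` is the 1-based genomic coordinate (hg38 convention for the
    study data this package targets).  ``beta`` is the per-allele effect
    in trait-SD units and ``se`` its standard error; ``V = se**2`` is the
    variance term entering the approximate Bayes factor.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str | None = None
    other_allele: str | None = None
    beta: float | None = None
    se: float | None = None
    p: float | None = None
    maf: float | None = None
    n: float | None = None
    functional_rank: str | None = None
    eqtl_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SumstatsError(f"{self.rsid}: position {self.pos} < 1")
        if self.se is not None and not self.se > 0:
            raise SumstatsError(f"{self.rsid}: nonpositive SE")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise SumstatsError(f"{self.rsid}: p {self.p} outside (0, 1]")
        if self.maf is not None:
            object.__setattr__(self, "maf", fold_maf(self.maf))

    @property
    def z(self) -> float | None:
        """Wald statistic beta/se, or signed z recovered from p when beta
        is absent but a sign is derivable; None when neither works."""
        if self.beta is not None and self.se is not None:
            return z_from_beta_se(self.beta, self.se)
        return None

    def neglog10p(self) -> float | None:
        """-log10 of the two-sided p, preferring the underflow-safe route
        through z when beta/se are available."""
        z = self.z
        if z is not None:
            return neglog10p_from_z(z)
        if self.p is not None:
            return -math.log10(self.p) if self.p > 0 else math.inf
        return None


@dataclass(frozen=True)
class LocusTable:
    """Ordered collection of :class:`VariantRecord` for one region.

    Invariants enforced at construction: unique rsids, a single
    chromosome, records sorted by ascending position.  ``region`` is the
    0-based half-open internal representation (external files stay
    1-based).
    """

    records: tuple[VariantRecord, ...]
    region: tuple[str, int, int] = field(default=("", 0, 0))

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.records, key=lambda r: (r.pos, r.rsid)))
        object.__setattr__(self, "records", recs)
        rsids = [r.rsid for r in recs]
        if len(set(rsids)) != len(rsids):
            dup = sorted({x for x in rsids if rsids.count(x) > 1})
            raise SumstatsError(f"duplicate rsids: {dup}")
        chroms = {r.chrom for r in recs}
        if len(chroms) > 1:
            raise SumstatsError(f"records span multiple chromosomes: {sorted(chroms)}")
        if recs and self.region == ("", 0, 0):
            chrom = recs[0].chrom
            object.__setattr__(
                self, "region", (chrom, recs[0].pos - 1, recs[-1].pos)
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rsid: str) -> VariantRecord:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(rsid)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def to_dataframe(self):
        """Records as a pandas DataFrame in locus order."""
        import pandas as pd

        return pd.DataFrame([vars(r) | {} for r in self.records])

    def subset(self, rsids: Iterable[str]) -> "LocusTable":
        keep = set(rsids)
        return LocusTable(tuple(r for r in self.records if r.rsid in keep))


# ---------------------------------------------------------------------------
# scalar conversions


def z_from_beta_se(beta: float, se: float) -> float:
    """Wald statistic z = beta / se; requires se > 0."""
    if not se > 0:
        raise SumstatsError(f"nonpositive SE {se}")
    return beta / se


def z_from_p(p: float, sign: int = 1) -> float:
    """Signed z with two-sided p-value ``p``; |z| = Phi^-1(1 - p/2)."""
    if not (0.0 < p <= 1.0):
        raise SumstatsError(f"p {p} outside (0, 1]")
    if sign not in (-1, 1):
        raise SumstatsError(f"sign must be +1 or -1, got {sign}")
    return sign * float(stats.norm.isf(p / 2.0))


def p_from_z(z: float) -> float:
    """Two-sided p-value 2*Phi(-|z|); underflows to 0 for |z| > ~38."""
    return float(2.0 * stats.norm.sf(abs(z)))


def neglog10p_from_z(z: float) -> float:
    """-log10 of the two-sided normal p-value, finite for any finite z.

    Evaluated as -(log 2 + log Phi(-|z|)) / log 10 through the normal
    log-survival function, which stays accurate far past the point where
    the p-value itself underflows (|z| ~ 38, p ~ 1e-317).
    """
    if not math.isfinite(z):
        raise SumstatsError(f"non-finite z {z}")
    if z == 0.0:
        return 0.0
    logp = math.log(2.0) + float(stats.norm.logsf(abs(z)))
    return -logp / _LN10


# ---------------------------------------------------------------------------
# file I/O

_FLOAT_FIELDS = ("beta", "se", "p", "maf", "n")


def _parse_row(
    row: Mapping[str, str], colmap: Mapping[str, str]
) -> VariantRecord:
    kwargs: dict = {}
    for logical, column in colmap.items():
        raw = row.get(column)
        if raw is None or raw == "" or raw.upper() in ("NA", "NAN", "."):
            if logical in _REQUIRED_FIELDS:
                raise SumstatsError(f"missing {logical}")
            continue
        if logical == "pos":
            kwargs["pos"] = int(raw)
        elif logical in _FLOAT_FIELDS:
            kwargs[logical] = float(raw)
        elif logical == "eqtl_flag":
            kwargs["eqtl_flag"] = raw.strip().lower() in ("1", "true", "yes", "t")
        else:
            kwargs[logical] = raw.strip()
    return VariantRecord(**kwargs)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> tuple[LocusTable, list[ValidationFailure]]:
    """Read a delimited summary-statistics file into a validated table.

    Rows violating record invariants (nonpositive SE, p outside (0,1],
    position < 1, bad frequency) are rejected individually; the reasons
    come back as a list of :class:`ValidationFailure` alongside the table.
    Frequencies above 0.5 are folded to the minor allele.

    Raises :class:`ConfigurationError` if a mapped column is absent and
    :class:`EmptyInputError` if no row validates.
    """
    explicit = column_map is not None
    colmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        # an explicitly supplied map must match the header exactly; the
        # default map only insists on the identifying columns
        missing = [
            c for k, c in colmap.items()
            if c not in header and (explicit or k in _REQUIRED_FIELDS)
        ]
        if missing:
            raise ConfigurationError(
                f"mapped columns absent from header of {path}: {missing}"
            )
        # optional logical fields silently drop out when their column is absent
        colmap = {k: c for k, c in colmap.items() if c in header}
        records: list[VariantRecord] = []
        failures: list[ValidationFailure] = []
        for row in reader:
            rsid = row.get(colmap.get("rsid", ""), "?")
            try:
                records.append(_parse_row(row, colmap))
            except (SumstatsError, ValueError) as exc:
                reason = str(exc)
                if "nonpositive SE" in reason:
                    reason = "nonpositive SE"
                failures.append(ValidationFailure(rsid=rsid, reason=reason))
    if not records:
        raise EmptyInputError(f"no valid records in {path}")
    return LocusTable(tuple(records)), failures


def _format_value(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_sumstats(
    table: LocusTable,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> None:
    """Write a table as delimited text that round-trips through
    :func:`read_sumstats` to an equal table (floats via repr)."""
    colmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(list(colmap.values()))
        for rec in table.records:
            writer.writerow([_format_value(getattr(rec, k)) for k in colmap])


def write_validation_report(
    failures: Sequence[ValidationFailure], path: str | Path
) -> None:
    """Validation failures as a 2-column TSV (rsid, reason)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rsid", "reason"])
        for f in failures:
            writer.writerow([f.rsid, f.reason])


def harmonize_alleles(
    rec: VariantRecord, effect_allele: str, other_allele: str
) -> VariantRecord:
    """Align a record to a reference allele pair.

    Exact match passes through; a swapped pair flips the sign of beta.
    Anything else (including ambiguous strand flips) is rejected —
    harmonization here is deliberately minimal and safe.
    """
    if rec.effect_allele == effect_allele and rec.other_allele == other_allele:
        return rec
    if rec.effect_allele == other_allele and rec.other_allele == effect_allele:
        beta = None if rec.beta is None else -rec.beta
        return replace(
            rec, effect_allele=effect_allele, other_allele=other_allele, beta=beta
        )
    raise SumstatsError(
        f"{rec.rsid}: alleles {rec.effect_allele}/{rec.other_allele} do not "
        f"match {effect_allele}/{other_allele} by identity or swap"
    )
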