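"""Linkage-disequilibrium structure for a locus.

LD comes in two shapes here: a full symmetric correlation matrix of
signed r (unit diagonal, entries in [-1, 1], NaN where a pair is missing
from the reference panel), or a lead-relative r-squared vector such as an
LDlink export.  Signed r is the stored quantity for matrices — the
simulator needs it — and r-squared is derived on demand.

Binning follows the r-squared strata used to summarise a locus around
its lead SNP.  Two presets ship:

``counts``
    [0, 0.2), [0.2, 0.5), [0.5, 0.8), [0.8, 1.0] — the strata used for
    counting high/moderate/lower/low-LD variants.  The literature
    convention writes the top stratum as "r2 > 0.8" while the next is
    "0.5 <= r2 < 0.8", which leaves r2 = 0.8 unassigned; a partition must
    be exhaustive, so 0.8 goes to the top bin.

``decay``
    [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0] — the
    equal-width strata used for the association-decay analysis.

Variants with missing r-squared (absent from the panel) are excluded
from every bin and reported separately, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LDInfo",
    "BinSpec",
    "BinAssignment",
    "BIN_PRESETS",
    "lead_r2",
    "assign_bins",
    "read_ld_matrix",
    "read_ld_long",
    "read_lead_r2",
    "write_ld_matrix",
]


class LDError(ValueError):
    pass


@dataclass(frozen=True)
class LDInfo:
    """LD for an ordered set of variants.

    ``kind`` is ``"matrix"`` (signed r, symmetric, unit diagonal, NaN
    allowed off-diagonal) or ``"lead_vector"`` (per-variant r-squared to
    a named lead, NaN allowed).  ``ids`` gives the rsid order and must
    match the LocusTable the LD describes.
    """

    kind: str
    ids: tuple[str, ...]
    matrix: np.ndarray | None = None
    lead_vector: np.ndarray | None = None
    lead: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("matrix", "lead_vector"):
            raise LDError(f"unknown LDInfo kind {self.kind!r}")
        m = len(self.ids)
        if self.kind == "matrix":
            if self.matrix is None:
                raise LDError("matrix kind requires a matrix")
            R = np.asarray(self.matrix, dtype=float)
            if R.shape != (m, m):
                raise LDError(f"matrix shape {R.shape} does not match {m} ids")
            mask = ~np.isnan(R)
            both = mask & mask.T
            if not np.allclose(R[both], R.T[both], atol=1e-10):
                raise LDError("matrix not symmetric within 1e-10")
            diag = np.diag(R)
            if not np.allclose(diag[~np.isnan(diag)], 1.0, atol=1e-10):
                raise LDError("matrix diagonal must be 1 where present")
            finite = R[mask]
            if np.any(np.abs(finite) > 1.0 + 1e-10):
                raise LDError("correlation entries must lie in [-1, 1]")
            object.__setattr__(self, "matrix", R)
        else:
            if self.lead_vector is None or self.lead is None:
                raise LDError("lead_vector kind requires lead_vector and lead")
            v = np.asarray(self.lead_vector, dtype=float)
            if v.shape != (m,):
                raise LDError(f"vector length {v.shape} does not match {m} ids")
            finite = v[~np.isnan(v)]
            if np.any((finite < -1e-12) | (finite > 1.0 + 1e-12)):
                raise LDError("r2 values must lie in [0, 1]")
            if self.lead not in self.ids:
                raise LDError(f"lead {self.lead!r} not among ids")
            li = self.ids.index(self.lead)
            if not np.isclose(v[li], 1.0, atol=1e-10):
                raise LDError("lead_vector must be 1 at the lead")
            object.__setattr__(self, "lead_vector", v)

    @property
    def m(self) -> int:
        return len(self.ids)

    def index_of(self, rsid: str) -> int:
        try:
            return self.ids.index(rsid)
        except ValueError:
            raise LDError(f"unknown variant {rsid!r}") from None


def lead_r2(ld: LDInfo, lead: str) -> np.ndarray:
    """Per-variant r-squared to ``lead``; NaN preserved for missing pairs.

    Matrix inputs are squared from signed r; lead-vector inputs pass
    through (their stored lead must match).
    """
    if ld.kind == "lead_vector":
        if lead != ld.lead:
            raise LDError(
                f"lead-relative LD is stored for {ld.lead!r}, not {lead!r}"
            )
        return ld.lead_vector.copy()
    i = ld.index_of(lead)
    r2 = ld.matrix[i, :] ** 2
    r2[i] = 1.0
    return r2


@dataclass(frozen=True)
class BinSpec:
    """Half-open r-squared strata partitioning [0, 1].

    ``edges`` are strictly increasing breakpoints starting at 0 and
    ending at 1; bin k is [edges[k], edges[k+1]), except the last which
    closes at 1.  Every r2 in [0, 1] therefore falls in exactly one bin.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) < 2 or e[0] != 0.0 or e[-1] != 1.0:
            raise LDError("edges must start at 0 and end at 1")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise LDError("edges must be strictly increasing")
        if len(self.labels) != len(e) - 1:
            raise LDError("need exactly one label per bin")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def nbins(self) -> int:
        return len(self.labels)

    def bin_index(self, r2: float) -> int:
        if not (0.0 <= r2 <= 1.0):
            raise LDError(f"r2 {r2} outside [0, 1]")
        # np.searchsorted with side='right' gives the half-open convention;
        # r2 == 1 belongs to the last (closed) bin
        k = int(np.searchsorted(self.edges, r2, side="right")) - 1
        return min(k, self.nbins - 1)

    def midpoints(self) -> list[float]:
        return [(a + b) / 2.0 for a, b in zip(self.edges, self.edges[1:])]


BIN_PRESETS: dict[str, BinSpec] = {
    "counts": BinSpec(
        edges=(0.0, 0.2, 0.5, 0.8, 1.0),
        labels=("r2<0.2", "0.2-0.5", "0.5-0.8", "0.8-1.0"),
    ),
    "decay": BinSpec(
        edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
        labels=("r2<0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", "0.8-1.0"),
    ),
}


@dataclass(frozen=True)
class BinAssignment:
    """Per-variant labels plus per-bin counts; missing r2 is counted in
    ``excluded`` and labelled "NA"."""

    spec: BinSpec
    labels: tuple[str, ...]
    counts: dict
    excluded: int


def assign_bins(r2: Sequence[float], spec: BinSpec) -> BinAssignment:
    """Assign each r-squared value to its stratum.

    NaN values (variant absent from the panel) are excluded from the
    counts and reported via ``excluded``; counts over all bins sum to the
    number of non-missing values.
    """
    arr = np.asarray(r2, dtype=float)
    labels: list[str] = []
    counts = {lab: 0 for lab in spec.labels}
    excluded = 0
    for v in arr:
        if np.isnan(v):
            labels.append("NA")
            excluded += 1
            continue
        lab = spec.labels[spec.bin_index(float(v))]
        labels.append(lab)
        counts[lab] += 1
    return BinAssignment(
        spec=spec, labels=tuple(labels), counts=counts, excluded=excluded
    )


# ---------------------------------------------------------------------------
# file formats


def read_ld_matrix(path: str | Path) -> LDInfo:
    """Square delimited text with an rsid header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise LDError("matrix row and column rsids differ")
    return LDInfo(kind="matrix", ids=ids, matrix=df.to_numpy(dtype=float))


def read_ld_long(path: str | Path, ids: Sequence[str]) -> LDInfo:
    """Long-format pairwise file (rsid1, rsid2, r) densified to a matrix.

    Unlisted pairs are missing (NaN), not zero — an LDlink-style export
    only reports computable pairs.
    """
    ids = tuple(ids)
    pos = {s: i for i, s in enumerate(ids)}
    m = len(ids)
    R = np.full((m, m), np.nan)
    np.fill_diagonal(R, 1.0)
    df = pd.read_csv(path, sep="\t")
    a_col, b_col, r_col = df.columns[:3]
    for a, b, r in zip(df[a_col], df[b_col], df[r_col]):
        if a in pos and b in pos:
            R[pos[a], pos[b]] = R[pos[b], pos[a]] = float(r)
    return LDInfo(kind="matrix", ids=ids, matrix=R)


def read_lead_r2(path: str | Path, lead: str) -> LDInfo:
    """2-column TSV (rsid, r2) of lead-relative r-squared values."""
    df = pd.read_csv(path, sep="\t")
    rs_col, r2_col = df.columns[:2]
    ids = tuple(str(s) for s in df[rs_col])
    return LDInfo(
        kind="lead_vector",
        ids=ids,
        lead_vector=df[r2_col].to_numpy(dtype=float),
        lead=lead,
    )


def write_ld_matrix(ld: LDInfo, path: str | Path) -> None:
    if ld.kind != "matrix":
        raise LDError("only matrix-kind LDInfo can be written as a matrix")
    df = pd.DataFrame(ld.matrix, index=list(ld.ids), columns=list(ld.ids))
    df.to_csv(path, sep="\t")
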