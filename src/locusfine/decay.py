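"""LD-stratified association-signal decay.

For a locus dominated by one causal variant, association strength at a
tag falls off with its LD to the causal site: the expected z-score of a
variant with correlation r to the causal variant is r times the causal
non-centrality.  Stratifying variants by lead-relative r-squared and
averaging -log10(p) per stratum therefore exposes whether the signal
decays with LD (one causal signal) or not (multiple independent hits).

Means here are arithmetic means of -log10(p), not -log10 of the mean p.
Displayed values round to one decimal; full precision is retained in
the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ld import BinSpec, LDError, assign_bins
from .sumstats import LocusTable

__all__ = [
    "DecayBin",
    "DecayTable",
    "decay_table",
    "gw_sig_count_by_bin",
    "regional_plot_data",
]

GENOME_WIDE_P = 5e-8
SCREEN_P = 1e-8


@dataclass(frozen=True)
class DecayBin:
    label: str
    r2_low: float
    r2_high: float
    count: int
    mean_neglog10p: float  # NaN when the bin is empty


@dataclass(frozen=True)
class DecayTable:
    """Per-bin decay summary, ordered by descending r-squared.

    ``monotone`` is True when the means strictly decrease across the
    nonempty bins as the interval midpoint decreases (vacuously True
    with fewer than two nonempty bins).
    """

    bins: tuple[DecayBin, ...]
    excluded: int
    monotone: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": [b.label for b in self.bins],
                "r2_low": [b.r2_low for b in self.bins],
                "r2_high": [b.r2_high for b in self.bins],
                "count": [b.count for b in self.bins],
                "mean_neglog10p": [b.mean_neglog10p for b in self.bins],
            }
        )

    def rounded_means(self) -> list[float]:
        """Means at report precision (1 decimal), NaN for empty bins."""
        return [round(b.mean_neglog10p, 1) for b in self.bins]


def _aligned_neglog10p(table: LocusTable, r2: Sequence[float]) -> np.ndarray:
    arr = np.asarray(r2, dtype=float)
    if arr.shape != (len(table),):
        raise LDError(
            f"r2 vector length {arr.shape} does not match {len(table)} records"
        )
    nlp = np.array(
        [r.neglog10p() if r.neglog10p() is not None else np.nan
         for r in table.records]
    )
    return nlp


def decay_table(
    table: LocusTable,
    r2: Sequence[float],
    spec: BinSpec,
    include_lead: bool = True,
) -> DecayTable:
    """Mean -log10(p) per r-squared stratum, descending r-squared.

    Variants with missing r-squared are excluded (count reported).
    ``include_lead=False`` drops the variant(s) at r2 == 1 from the top
    bin, for sensitivity to the lead's own extreme p-value.
    """
    arr = np.asarray(r2, dtype=float)
    nlp = _aligned_neglog10p(table, arr)
    if not include_lead:
        keep = ~(arr == 1.0)
        arr = np.where(keep, arr, np.nan)
    assignment = assign_bins(arr, spec)
    labels = np.asarray(assignment.labels)

    bins: list[DecayBin] = []
    # iterate strata from the top (highest r2) down
    for k in reversed(range(spec.nbins)):
        lab = spec.labels[k]
        mask = labels == lab
        vals = nlp[mask]
        vals = vals[~np.isnan(vals)]
        mean = float(vals.mean()) if vals.size else float("nan")
        bins.append(
            DecayBin(
                label=lab,
                r2_low=spec.edges[k],
                r2_high=spec.edges[k + 1],
                count=int(mask.sum()),
                mean_neglog10p=mean,
            )
        )
    means = [b.mean_neglog10p for b in bins if b.count > 0]
    monotone = all(a > b for a, b in zip(means, means[1:]))
    return DecayTable(
        bins=tuple(bins), excluded=assignment.excluded, monotone=monotone
    )


def gw_sig_count_by_bin(
    table: LocusTable,
    r2: Sequence[float],
    spec: BinSpec,
    threshold: float = GENOME_WIDE_P,
) -> dict:
    """Count of variants with p strictly below ``threshold`` per stratum.

    The comparison uses -log10(p) computed from z where available, so
    underflowed p-values still count correctly.
    """
    if not (0.0 < threshold < 1.0):
        raise LDError(f"threshold {threshold} outside (0, 1)")
    arr = np.asarray(r2, dtype=float)
    nlp = _aligned_neglog10p(table, arr)
    assignment = assign_bins(arr, spec)
    labels = np.asarray(assignment.labels)
    cut = -np.log10(threshold)
    counts = {}
    for k in reversed(range(spec.nbins)):
        lab = spec.labels[k]
        mask = (labels == lab) & (nlp > cut)
        counts[lab] = int(mask.sum())
    return counts


def regional_plot_data(
    table: LocusTable,
    r2: Sequence[float],
    spec: BinSpec,
    lead: str | None = None,
) -> pd.DataFrame:
    """Per-variant export for a regional association plot.

    One row per variant sorted by position: pos, -log10(p), r-squared,
    bin label ("lead" for the lead variant, "NA" when r-squared is
    missing) and a lead flag.  The two reference significance thresholds
    travel in ``DataFrame.attrs`` for the plotting layer.
    """
    arr = np.asarray(r2, dtype=float)
    nlp = _aligned_neglog10p(table, arr)
    assignment = assign_bins(arr, spec)
    labels = list(assignment.labels)
    rsids = table.rsids
    if lead is not None:
        for i, s in enumerate(rsids):
            if s == lead:
                labels[i] = "lead"
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "pos": [r.pos for r in table.records],
            "neglog10p": nlp,
            "r2": arr,
            "bin": labels,
            "is_lead": [s == lead for s in rsids],
        }
    ).sort_values("pos", kind="stable").reset_index(drop=True)
    df.attrs["screen_threshold_p"] = SCREEN_P
    df.attrs["genome_wide_threshold_p"] = GENOME_WIDE_P
    return df
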