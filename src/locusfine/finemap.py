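"""Single-causal-variant fine-mapping from summary statistics.

The model is Wakefield's approximate Bayes factor.  For one variant with
estimated effect beta-hat, standard error se (V = se^2) and a normal
prior N(0, W) on the true effect, the Bayes factor in favour of
association is

    ABF = sqrt(V / (V + W)) * exp( z^2 / 2 * W / (V + W) )

with z = beta-hat / se.  We work with its natural log,

    log ABF = 1/2 * [ ln(1 - r) + r * z^2 ],    r = W / (V + W),

where r in [0, 1) is the shrinkage factor.  Note Wakefield's original
ABF favours the null; this module stores the association-direction
log-BF (the reciprocal), because normalising to posterior inclusion
probabilities requires evidence *for* association.

Under a single-causal-variant assumption with per-variant prior causal
weights w_i, the posterior inclusion probability is

    PIP_i = w_i * ABF_i / sum_j w_j * ABF_j,

computed via log-sum-exp so arbitrarily large log-ABFs do not overflow.
The level-alpha credible set is the smallest prefix of variants, taken
in descending PIP order, whose cumulative PIP strictly exceeds alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import LocusTable, VariantRecord, neglog10p_from_z, z_from_beta_se

__all__ = [
    "PriorSpec",
    "FinemapResult",
    "FinemapError",
    "ZScaleWarning",
    "log_abf",
    "pips",
    "credible_set",
    "finemap_locus",
    "write_finemap_tsv",
]


class FinemapError(ValueError):
    pass


class ZScaleWarning(UserWarning):
    """Raised when V is taken as 1 because only z (not beta/se) is known;
    W is then interpreted on the z scale, which changes its meaning."""


@dataclass(frozen=True)
class PriorSpec:
    """Prior for the causal-effect model.

    W is the prior variance of the causal effect on the beta scale
    (default 0.04, i.e. prior SD 0.2 trait-SD units — a typical
    quantitative-trait effect scale).  ``pi`` holds optional per-variant
    prior causal weights; None means uniform over the locus.
    """

    W: float = 0.04
    pi: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.W < 0:
            raise FinemapError(f"prior variance W must be >= 0, got {self.W}")
        if self.pi is not None:
            arr = np.asarray(self.pi, dtype=float)
            if np.any(arr < 0) or not np.any(arr > 0):
                raise FinemapError("priors must be nonnegative, not all zero")
            object.__setattr__(self, "pi", tuple(float(x) for x in arr))


def log_abf(z: float, se: float, W: float) -> float:
    """Natural-log approximate Bayes factor for association.

    With V = se^2 and shrinkage r = W/(V+W):
    log ABF = 1/2 [ln(1-r) + r z^2].  W = 0 forces BF = 1 (log 0).
    Finite for every finite z.
    """
    if not se > 0:
        raise FinemapError(f"nonpositive SE {se}")
    if W < 0:
        raise FinemapError(f"negative prior variance {W}")
    if W == 0.0:
        return 0.0
    V = se * se
    r = W / (V + W)
    # ln(1-r) written as ln(V/(V+W)) to stay accurate when r -> 1
    return 0.5 * (math.log(V / (V + W)) + r * z * z)


def pips(labf: Sequence[float], prior: Sequence[float] | None = None) -> np.ndarray:
    """Posterior inclusion probabilities from per-variant log-ABFs.

    PIP_i = w_i exp(labf_i) / sum_j w_j exp(labf_j), evaluated with
    max-subtraction so log-ABFs of any magnitude normalise without
    overflow.  The result sums to 1 within 1e-12.
    """
    arr = np.asarray(labf, dtype=float)
    if arr.size == 0:
        raise FinemapError("empty log-ABF vector")
    if prior is None:
        logw = np.zeros_like(arr)
    else:
        w = np.asarray(prior, dtype=float)
        if w.shape != arr.shape:
            raise FinemapError("prior weights misaligned with log-ABFs")
        if np.any(w < 0) or not np.any(w > 0):
            raise FinemapError("priors must be nonnegative, not all zero")
        with np.errstate(divide="ignore"):
            logw = np.log(w)
    logpost = arr + logw
    out = np.exp(logpost - logsumexp(logpost))
    return out / out.sum()  # renormalise away the last ulp


def credible_set(
    pip: Sequence[float],
    level: float = 0.95,
    p: Sequence[float] | None = None,
    pos: Sequence[int] | None = None,
    ids: Sequence[str] | None = None,
) -> list[int]:
    """Indices of the minimal credible set at ``level``.

    Variants are ranked by PIP descending; ties break by smaller p, then
    smaller position, then lexicographic rsid, so output order is fully
    deterministic.  The returned prefix is the shortest whose cumulative
    PIP is strictly greater than ``level``.
    """
    if not (0.0 < level < 1.0):
        raise FinemapError(f"credible level {level} outside (0, 1)")
    arr = np.asarray(pip, dtype=float)
    m = arr.size
    if m == 0:
        raise FinemapError("empty PIP vector")
    pvals = np.asarray(p, dtype=float) if p is not None else np.full(m, np.nan)
    posns = np.asarray(pos) if pos is not None else np.arange(m)
    names = list(ids) if ids is not None else [""] * m

    def key(i: int):
        pv = pvals[i]
        return (-arr[i], pv if not np.isnan(pv) else np.inf, posns[i], names[i])

    order = sorted(range(m), key=key)
    cum = 0.0
    chosen: list[int] = []
    for i in order:
        chosen.append(i)
        cum += arr[i]
        if cum > level:
            return chosen
    return chosen  # total mass <= level only if pips do not sum to 1


@dataclass(frozen=True)
class FinemapResult:
    """Fine-mapping output for one locus.

    Per-variant arrays are aligned to ``rsids``.  ``credible_set`` lists
    member rsids in descending-PIP order; ``credible_mass`` is their
    cumulative PIP (> ``level`` by construction whenever PIPs sum to 1).
    """

    rsids: tuple[str, ...]
    z: np.ndarray
    V: np.ndarray
    shrinkage: np.ndarray
    labf: np.ndarray
    pip: np.ndarray
    in_credible_set: np.ndarray
    level: float
    credible_set: tuple[str, ...]
    credible_mass: float
    W: float
    excluded: tuple[str, ...] = ()
    z_scale: bool = False

    @property
    def top_variant(self) -> str:
        return self.rsids[int(np.argmax(self.pip))]

    def to_dataframe(self):
        import pandas as pd

        order = np.argsort(-self.pip, kind="stable")
        rank = np.empty(len(self.rsids), dtype=int)
        rank[order] = np.arange(1, len(self.rsids) + 1)
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "z": self.z,
                "labf": self.labf,
                "pip": self.pip,
                "cum_pip_rank": rank,
                "in_credible_set": self.in_credible_set.astype(int),
            }
        )


def finemap_locus(
    table: LocusTable,
    prior: PriorSpec | None = None,
    level: float = 0.95,
) -> FinemapResult:
    """Fine-map one locus under the single-causal-variant ABF model.

    Records lacking both (beta, se) are excluded from the normalisation
    and reported in ``FinemapResult.excluded``; if a record carries only
    a p-value there is no safe scale for V, so it cannot enter (the sign
    and scale of beta are never invented).

    If *no* record has a usable se but z-scores are recoverable, V would
    have to be taken as 1 with W on the z scale; callers wanting that
    must set it up explicitly — here it raises unless every record has
    beta/se.
    """
    prior = prior or PriorSpec()
    usable: list[VariantRecord] = []
    excluded: list[str] = []
    for rec in table.records:
        if rec.beta is not None and rec.se is not None:
            usable.append(rec)
        else:
            excluded.append(rec.rsid)
    if not usable:
        raise FinemapError("no records with usable beta/se to fine-map")

    z = np.array([z_from_beta_se(r.beta, r.se) for r in usable])
    V = np.array([r.se**2 for r in usable])
    W = prior.W
    shrink = W / (V + W) if W > 0 else np.zeros_like(V)
    labf = np.array([log_abf(zi, r.se, W) for zi, r in zip(z, usable)])

    if prior.pi is not None:
        if len(prior.pi) == len(table.records):
            keep = [i for i, r in enumerate(table.records) if r.rsid not in excluded]
            w = np.asarray(prior.pi)[keep]
        elif len(prior.pi) == len(usable):
            w = np.asarray(prior.pi)
        else:
            raise FinemapError("prior weight vector misaligned with locus")
    else:
        w = None

    pip = pips(labf, w)
    pvec = np.array([r.p if r.p is not None else np.nan for r in usable])
    posv = np.array([r.pos for r in usable])
    ids = [r.rsid for r in usable]
    cs_idx = credible_set(pip, level, p=pvec, pos=posv, ids=ids)
    in_set = np.zeros(len(usable), dtype=bool)
    in_set[cs_idx] = True
    return FinemapResult(
        rsids=tuple(ids),
        z=z,
        V=V,
        shrinkage=shrink,
        labf=labf,
        pip=pip,
        in_credible_set=in_set,
        level=level,
        credible_set=tuple(ids[i] for i in cs_idx),
        credible_mass=float(pip[cs_idx].sum()),
        W=W,
        excluded=tuple(excluded),
    )


def finemap_zscores(
    z: Sequence[float],
    W: float,
    level: float = 0.95,
    ids: Sequence[str] | None = None,
) -> FinemapResult:
    """Fine-map from z-scores alone, taking V = 1.

    W is then interpreted on the z scale rather than the beta scale —
    a different prior.  A :class:`ZScaleWarning` is always emitted.
    """
    warnings.warn(
        "fine-mapping from z-scores alone: V taken as 1, prior variance W "
        "interpreted on the z scale",
        ZScaleWarning,
        stacklevel=2,
    )
    z = np.asarray(z, dtype=float)
    names = tuple(ids) if ids is not None else tuple(
        f"var{i}" for i in range(z.size)
    )
    labf = np.array([log_abf(zi, 1.0, W) for zi in z])
    pip = pips(labf)
    cs_idx = credible_set(pip, level, ids=list(names))
    in_set = np.zeros(z.size, dtype=bool)
    in_set[cs_idx] = True
    V = np.ones_like(z)
    shrink = np.full_like(z, W / (1.0 + W)) if W > 0 else np.zeros_like(z)
    return FinemapResult(
        rsids=names,
        z=z,
        V=V,
        shrinkage=shrink,
        labf=labf,
        pip=pip,
        in_credible_set=in_set,
        level=level,
        credible_set=tuple(names[i] for i in cs_idx),
        credible_mass=float(pip[cs_idx].sum()),
        W=W,
        z_scale=True,
    )


def write_finemap_tsv(
    result: FinemapResult, table: LocusTable, path: str | Path
) -> None:
    """Fine-mapping output TSV: rsid, pos, z, labf, pip, cum_pip_rank,
    in_credible_set, sorted by position."""
    df = result.to_dataframe()
    posmap = {r.rsid: r.pos for r in table.records}
    df.insert(1, "pos", [posmap.get(s, -1) for s in df["rsid"]])
    df.to_csv(path, sep="\t", index=False)
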