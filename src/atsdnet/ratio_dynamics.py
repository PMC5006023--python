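"""Feature ratios, Chebyshev effective ranges, and the non-overlapping ratio.

The central statistic of the package.  For an ordered feature pair
``(f_i, f_j)`` with ``i < j`` in canonical order, the per-sample ratio
``r_ijt = f_it / f_jt`` is summarised at each time point by an *effective
range*: an interval ``[u - h, u + h]`` around the sample mean ``u`` whose
half-width ``h = 2 * p_t * gamma * sigma`` derives from the sample standard
deviation ``sigma`` via the Chebyshev coefficient ``gamma = 1.732``
(``sqrt(3)``), guaranteeing that at least two thirds of the population lies
inside the range.  ``p_t`` is the sample probability of the time point
within the two-point window that a network is built from; with equal sample
sets at both points ``p_t = 0.5`` and the range reduces to ``u +/- gamma *
sigma``.

The change of a ratio's effective range between adjacent time points falls
into one of four cases: *upshift* (both bounds strictly increase),
*downshift* (both strictly decrease), *nested* (one range contained in the
other) or *identical*.  Only up/downshifts carry a signed **non-overlapping
ratio**::

    |NOR| = (L1 + L2 - 2*O) / (L1 + L2)

with ``L1``/``L2`` the range lengths and ``O`` the overlap length; the sign
is positive for an upshift and negative for a downshift.  ``|NOR| = 1``
iff the ranges are disjoint; nested/identical changes have no NOR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Mapping

import numpy as np

from .data_model import TimeSeriesDataset
from .errors import InsufficientDataError

#: Chebyshev coefficient sqrt(3): at least 1 - 1/gamma^2 = 2/3 of the
#: population falls within u +/- gamma*sigma.
GAMMA = 1.732

#: Default edge threshold on |NOR|.
TAU = 0.85

ChangeCase = Literal["upshift", "downshift", "nested", "identical"]


def sample_probability(n_t: int, n_t1: int) -> float:
    """Sample probability of time point ``T_t`` in a two-point network.

    ``p_t = n_t / (n_t + n_t1)`` where ``n_t`` and ``n_t1`` are the sample
    counts at the two adjacent time points the network is built from.
    Equal counts give 0.5.
    """
    if n_t < 1 or n_t1 < 1:
        raise InsufficientDataError(f"sample counts must be >= 1, got {n_t}, {n_t1}")
    return n_t / (n_t + n_t1)


@dataclass(frozen=True)
class EffectiveRange:
    """Chebyshev effective range of one feature ratio at one time point."""

    mean: float
    sd: float
    floor: float
    ceiling: float
    p: float
    n: int

    @property
    def length(self) -> float:
        return self.ceiling - self.floor

    @property
    def degenerate(self) -> bool:
        """Zero-variance range collapsed to a point."""
        return self.length == 0.0


def effective_range(
    values: np.ndarray, p: float, gamma: float = GAMMA, ddof: int = 0
) -> EffectiveRange:
    """Effective range ``u -/+ 2*p*gamma*sigma`` of ratio samples at one time point.

    ``sigma`` uses the population divisor ``n`` by default (``ddof=0``),
    matching a sum over the ``n`` repeated time-series measures without a
    finite-sample correction.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 2:
        raise InsufficientDataError(f"need >= 2 samples for an effective range, got {arr.size}")
    if not 0 < p < 1:
        raise ValueError(f"sample probability p must be in (0,1), got {p}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    u = float(arr.mean())
    sd = float(arr.std(ddof=ddof))
    half = 2.0 * p * gamma * sd
    return EffectiveRange(mean=u, sd=sd, floor=u - half, ceiling=u + half, p=p, n=arr.size)


def classify_change(a: EffectiveRange, b: EffectiveRange) -> ChangeCase:
    """Classify the change of an effective range from ``a`` (T_t) to ``b`` (T_t+1).

    Degenerate (point) ranges fall out of the same rules: two equal points
    are identical, a separated point pair is an up/downshift, and a point
    inside the other range is nested.
    """
    if b.floor == a.floor and b.ceiling == a.ceiling:
        return "identical"
    if b.floor > a.floor and b.ceiling > a.ceiling:
        return "upshift"
    if b.floor < a.floor and b.ceiling < a.ceiling:
        return "downshift"
    return "nested"


@dataclass(frozen=True)
class NorValue:
    """Signed non-overlapping ratio between two effective ranges.

    ``value`` is a signed real in [-1, 1] for up/downshifts and ``None``
    for nested/identical changes, which carry no NOR.
    """

    value: float | None
    case: ChangeCase
    L1: float
    L2: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def nor(a: EffectiveRange, b: EffectiveRange) -> NorValue:
    """Non-overlapping ratio of the change from range ``a`` to range ``b``.

    ``|NOR| = (L1 + L2 - 2*O) / (L1 + L2)`` with overlap
    ``O = max(0, min(ceilings) - max(floors))``; the sign is +1 for an
    upshift and -1 for a downshift.  Two separated zero-length ranges are
    fully disjoint, hence ``|NOR| = 1``.
    """
    case = classify_change(a, b)
    L1 = a.length
    L2 = b.length
    if case in ("nested", "identical"):
        return NorValue(value=None, case=case, L1=L1, L2=L2)
    overlap = max(0.0, min(a.ceiling, b.ceiling) - max(a.floor, b.floor))
    total = L1 + L2
    magnitude = 1.0 if total == 0.0 else (total - 2.0 * overlap) / total
    sign = 1.0 if case == "upshift" else -1.0
    return NorValue(value=sign * magnitude, case=case, L1=L1, L2=L2)


@dataclass(frozen=True)
class RatioSeries:
    """Per-sample values of one ordered feature ratio, grouped by time point."""

    i: str
    j: str
    values: Mapping[int, np.ndarray]
    flipped: bool = False  # True if the request arrived in (j, i) orientation


def ratio_series(
    ds: TimeSeriesDataset,
    i: str | int,
    j: str | int,
    group: str | None = None,
) -> RatioSeries:
    """Per-sample ratio ``f_i / f_j`` at each time point.

    The orientation is canonicalised to ``i < j`` in the dataset's feature
    order; a request in the opposite orientation returns the canonical
    series with ``flipped=True``.
    """
    names = ds.feature_names
    ii = names.index(i) if isinstance(i, str) else int(i)
    jj = names.index(j) if isinstance(j, str) else int(j)
    if ii == jj:
        raise ValueError(f"a ratio needs two distinct features, got {names[ii]!r} twice")
    flipped = ii > jj
    if flipped:
        ii, jj = jj, ii
    X = ds.abundance.to_numpy(dtype=float)
    values: dict[int, np.ndarray] = {}
    for t in sorted(set(ds.meta["time"])):
        m = ds.mask(time=t, group=group)
        values[t] = X[m, ii] / X[m, jj]
    return RatioSeries(i=names[ii], j=names[jj], values=values, flipped=flipped)


def canonical_pairs(features: list[str]) -> Iterator[tuple[str, str]]:
    """All C(m, 2) ordered pairs (i < j) in canonical feature order."""
    for a in range(len(features)):
        for b in range(a + 1, len(features)):
            yield features[a], features[b]


def pairwise_nor(
    Xa: np.ndarray,
    Xb: np.ndarray,
    p_a: float,
    gamma: float = GAMMA,
    ddof: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised NOR for every canonical feature pair between two time points.

    ``Xa``/``Xb`` are the (samples x features) abundance matrices at ``T_t``
    and ``T_t+1``; ``p_a`` is the sample probability of ``T_t`` (the second
    point gets ``1 - p_a``).  Returns ``(i_idx, j_idx, nor_values)`` over
    the flattened upper triangle; undefined (nested/identical) cases are
    NaN.  Agrees exactly with the scalar :func:`nor` path.
    """
    m = Xa.shape[1]
    if Xa.shape[0] < 2 or Xb.shape[0] < 2:
        raise InsufficientDataError("need >= 2 samples at both time points")
    i_idx, j_idx = np.triu_indices(m, k=1)
    Ra = Xa[:, i_idx] / Xa[:, j_idx]
    Rb = Xb[:, i_idx] / Xb[:, j_idx]
    p_b = 1.0 - p_a

    ua, sa = Ra.mean(axis=0), Ra.std(axis=0, ddof=ddof)
    ub, sb = Rb.mean(axis=0), Rb.std(axis=0, ddof=ddof)
    fa, ca = ua - 2 * p_a * gamma * sa, ua + 2 * p_a * gamma * sa
    fb, cb = ub - 2 * p_b * gamma * sb, ub + 2 * p_b * gamma * sb

    up = (fb > fa) & (cb > ca)
    down = (fb < fa) & (cb < ca)
    L1, L2 = ca - fa, cb - fb
    total = L1 + L2
    overlap = np.maximum(0.0, np.minimum(ca, cb) - np.maximum(fa, fb))
    with np.errstate(invalid="ignore", divide="ignore"):
        magnitude = np.where(total > 0, (total - 2 * overlap) / np.where(total > 0, total, 1.0), 1.0)
    values = np.full(i_idx.shape, np.nan)
    values[up] = magnitude[up]
    values[down] = -magnitude[down]
    return i_idx, j_idx, values


def range_table(
    ds: TimeSeriesDataset,
    features: list[str] | None = None,
    gamma: float = GAMMA,
    group: str | None = "model",
) -> "pd.DataFrame":
    """Audit dump: (pair, t, u, sigma, floor, ceiling, case, NOR) tuples.

    One row per canonical pair and adjacent time-point transition, using
    the sample probabilities of the corresponding two-point window.
    """
    import pandas as pd

    features = features or ds.feature_names
    probs = {}
    for t in range(1, ds.n_timepoints):
        n_a = int(ds.mask(time=t, group=group).sum())
        n_b = int(ds.mask(time=t + 1, group=group).sum())
        probs[t] = sample_probability(n_a, n_b)
    rows = []
    for fi, fj in canonical_pairs(features):
        rs = ratio_series(ds, fi, fj, group=group)
        for t in range(1, ds.n_timepoints):
            p_a = probs[t]
            a = effective_range(rs.values[t], p=p_a, gamma=gamma)
            b = effective_range(rs.values[t + 1], p=1 - p_a, gamma=gamma)
            nv = nor(a, b)
            rows.append(
                {
                    "pair": f"{fi}/{fj}",
                    "t": t,
                    "u_t": a.mean,
                    "sd_t": a.sd,
                    "floor_t": a.floor,
                    "ceiling_t": a.ceiling,
                    "u_t1": b.mean,
                    "sd_t1": b.sd,
                    "floor_t1": b.floor,
                    "ceiling_t1": b.ceiling,
                    "case": nv.case,
                    "nor": nv.value if nv.defined else np.nan,
                }
            )
    return pd.DataFrame(rows)
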