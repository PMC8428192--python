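"""Heart rate fragmentation (HRF) metrics: PIP, PNNSS, PNNLS.

Fragmentation quantifies anomalously frequent reversals in the sign of heart
rate acceleration — variability that does not arise from respiratory vagal
modulation.  Successive NN-interval differences (dNN_i = NN_i − NN_{i−1})
are symbolized on a ternary alphabet using the resolution of the source ECG
as the no-change quantum q = n/SF (seconds):

* −1 (HR acceleration):  dNN ≤ −q
* +1 (HR deceleration):  dNN ≥ +q
*  0 (no change):        −q < dNN < q

Differences are only taken between consecutive intervals inside the same
contiguous run; ectopic-adjacent boundaries contribute nothing.

Three indices summarise the symbol stream:

* PIP — percentage of inflection points: sign transitions between adjacent
  symbols, both "hard" (−1↔+1) and "soft" (to/from 0), over all evaluated
  within-run symbol pairs.
* PNNLS — percentage of dNN intervals lying in accelerative/decelerative
  (nonzero-sign) segments of length ≥ 3, relative to ALL dNN intervals.
* PNNSS — percentage of dNN intervals in nonzero-sign segments of length
  < 3, relative to dNN intervals in nonzero-sign segments of any length.

Higher PIP and PNNSS, and lower PNNLS, indicate more fragmented dynamics.
Undefined metrics (empty denominators) are reported as NaN, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .nn_io import NNSeries

__all__ = [
    "DeltaSymbolSeries",
    "FragmentationResult",
    "symbolize",
    "count_inflections",
    "pip",
    "segment_decompose",
    "pnnls",
    "pnnss",
    "compute_fragmentation",
]

# relative slack when comparing a float dNN against the quantum, so that a
# difference mathematically equal to n/SF (always the case for grid-quantized
# NN values) is classified as +/-1 despite round-off
_REL_TOL = 1e-9


@dataclass
class DeltaSymbolSeries:
    """Ternary symbolization of successive NN differences.

    ``symbols`` take values in {−1, 0, +1}; ``run_id`` marks the contiguous
    run each symbol was computed in; ``quantum_ms`` is n/SF expressed in ms.
    """

    symbols: np.ndarray
    run_id: np.ndarray
    n: int
    sampling_frequency: float

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        self.run_id = np.asarray(self.run_id, dtype=int)
        if self.symbols.shape != self.run_id.shape:
            raise ValueError("symbols and run_id must have equal length")
        if self.symbols.size and not np.isin(self.symbols, (-1, 0, 1)).all():
            raise ValueError("symbols must be in {-1, 0, +1}")
        if self.n < 1 or self.sampling_frequency <= 0:
            raise ValueError("need n >= 1 and positive sampling frequency")

    @property
    def quantum_ms(self) -> float:
        return 1000.0 * self.n / self.sampling_frequency

    def __len__(self) -> int:
        return self.symbols.size

    def run_slices(self) -> list[slice]:
        if len(self) == 0:
            return []
        bounds = np.flatnonzero(np.diff(self.run_id)) + 1
        edges = [0, *bounds.tolist(), len(self)]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class FragmentationResult:
    """PIP/PNNSS/PNNLS (%) plus the underlying counts.

    Percentages are NaN when their denominator is empty.
    """

    pip_pct: float
    pnnss_pct: float
    pnnls_pct: float
    n_delta_total: int
    n_pairs_evaluated: int
    n_inflection_hard: int
    n_inflection_soft: int
    n_delta_in_nonzero_segments: int
    n_delta_in_long_segments: int
    n_delta_in_short_segments: int
    n: int = 1
    sampling_frequency: float = 256.0
    denominator_convention: str = "within-run adjacent symbol pairs"

    def to_dict(self) -> dict:
        return asdict(self)


def symbolize(nn: NNSeries, n: int = 1) -> DeltaSymbolSeries:
    """Symbolize successive NN differences on {−1, 0, +1}.

    The no-change band is (−n/SF, n/SF); boundary values, which arise
    exactly for ECG-grid-quantized intervals, count as acceleration or
    deceleration per the non-strict inequalities.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    quantum = 1000.0 * n / nn.sampling_frequency  # ms
    thr = quantum * (1.0 - _REL_TOL)
    symbols: list[np.ndarray] = []
    run_ids: list[np.ndarray] = []
    for sl in nn.run_slices():
        seg = nn.intervals[sl]
        if seg.size < 2:
            continue
        d = np.diff(seg)
        s = np.where(d >= thr, 1, np.where(d <= -thr, -1, 0))
        symbols.append(s)
        run_ids.append(np.full(s.size, nn.run_id[sl][0]))
    if symbols:
        sym = np.concatenate(symbols)
        rid = np.concatenate(run_ids)
    else:
        sym = np.empty(0, dtype=int)
        rid = np.empty(0, dtype=int)
    return DeltaSymbolSeries(sym, rid, n=n, sampling_frequency=nn.sampling_frequency)


def count_inflections(sym: DeltaSymbolSeries) -> tuple[int, int, int]:
    """Count (hard, soft, evaluated-pair) over within-run adjacent symbol pairs.

    A pair (s_i, s_{i+1}) is a hard inflection if the symbols are opposite
    nonzero signs, soft if exactly one is 0, and no inflection when equal
    (including the 0,0 pair).
    """
    hard = soft = pairs = 0
    for sl in sym.run_slices():
        s = sym.symbols[sl]
        if s.size < 2:
            continue
        a, b = s[:-1], s[1:]
        pairs += a.size
        hard += int(np.sum(a * b == -1))
        soft += int(np.sum((a == 0) ^ (b == 0)))
    return hard, soft, pairs


def pip(sym: DeltaSymbolSeries) -> float:
    """Percentage of inflection points over evaluated symbol pairs."""
    hard, soft, pairs = count_inflections(sym)
    if pairs == 0:
        warnings.warn("PIP undefined: no within-run symbol pairs", stacklevel=2)
        return float("nan")
    return 100.0 * (hard + soft) / pairs


def segment_decompose(sym: DeltaSymbolSeries) -> list[tuple[int, int]]:
    """Maximal same-symbol segments as (sign, length), per contiguous run.

    A segment's length is the number of dNN intervals (symbols) it contains;
    segments never cross run boundaries.  Zero-symbol stretches are reported
    with sign 0.
    """
    out: list[tuple[int, int]] = []
    for sl in sym.run_slices():
        s = sym.symbols[sl]
        if s.size == 0:
            continue
        change = np.flatnonzero(np.diff(s)) + 1
        edges = [0, *change.tolist(), s.size]
        out.extend((int(s[a]), b - a) for a, b in zip(edges[:-1], edges[1:]))
    return out


def pnnls(sym: DeltaSymbolSeries) -> float:
    """Percentage of dNN intervals in nonzero segments of length ≥ 3,
    over the total number of dNN intervals."""
    total = len(sym)
    if total == 0:
        warnings.warn("PNNLS undefined: no dNN intervals", stacklevel=2)
        return float("nan")
    long_count = sum(L for sign, L in segment_decompose(sym) if sign != 0 and L >= 3)
    return 100.0 * long_count / total

def pnnss(sym: DeltaSymbolSeries) -> float:
    """Percentage of dNN intervals in nonzero segments of length < 3, over
    dNN intervals in nonzero segments of any length."""
    segs = [(sign, L) for sign, L in segment_decompose(sym) if sign != 0]
    denom = sum(L for _, L in segs)
    if denom == 0:
        warnings.warn(
            "PNNSS undefined: no accelerative/decelerative segments", stacklevel=2
        )
        return float("nan")
    short = sum(L for _, L in segs if L < 3)
    return 100.0 * short / denom


def compute_fragmentation(nn: NNSeries, n: int = 1) -> FragmentationResult:
    """Compute PIP, PNNSS and PNNLS with their underlying counts.

    Counts are pooled across runs (no per-run averaging) so that each
    subject contributes one value per metric.
    """
    sym = symbolize(nn, n=n)
    hard, soft, pairs = count_inflections(sym)
    segs = segment_decompose(sym)
    nz = [(s, L) for s, L in segs if s != 0]
    n_nonzero = sum(L for _, L in nz)
    n_long = sum(L for _, L in nz if L >= 3)
    n_short = n_nonzero - n_long
    total = len(sym)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pip_pct = pip(sym)
        pnnss_pct = pnnss(sym)
        pnnls_pct = pnnls(sym)
    return FragmentationResult(
        pip_pct=pip_pct,
        pnnss_pct=pnnss_pct,
        pnnls_pct=pnnls_pct,
        n_delta_total=total,
        n_pairs_evaluated=pairs,
        n_inflection_hard=hard,
        n_inflection_soft=soft,
        n_delta_in_nonzero_segments=n_nonzero,
        n_delta_in_long_segments=n_long,
        n_delta_in_short_segments=n_short,
        n=n,
        sampling_frequency=nn.sampling_frequency,
    )
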