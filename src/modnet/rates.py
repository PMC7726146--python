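"""Binned firing rates, smoothing, and Pearson correlation connectivity.

The functional-connectivity measure is the Pearson correlation between
binned, Gaussian-smoothed firing-rate histograms (100 ms bins, 5-bin
kernel by default), computed over all electrode pairs that pass the
activity filter (> 0.05 Hz).  Within-module ("intra-CC") and
between-module ("inter-CC") means summarize the matrix against a module
map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import ModuleMap, RecordingSession, SpikeTrain, ValidationError

__all__ = [
    "RateHistogram",
    "CorrelationMatrix",
    "CCSummary",
    "bin_rates",
    "smooth_rates",
    "gaussian_kernel",
    "active_filter",
    "pearson_matrix",
    "session_matrix",
    "cc_summary",
]

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_KERNEL_BINS = 5
DEFAULT_KERNEL_SIGMA = 1.25  # bins; 5-bin support covers +/- 2 sigma
DEFAULT_MIN_RATE = 0.05


@dataclass
class RateHistogram:
    """Per-electrode firing rate per time bin (Hz)."""

    electrode_id: str
    bin_width: float
    rates: np.ndarray
    t_start: float = 0.0
    smoothed: bool = False
    kernel_bins: int = 0

    @property
    def n_bins(self) -> int:
        return int(self.rates.size)

    def spike_count(self) -> float:
        """Total count implied by the rates (conserved by smoothing)."""
        return float(np.sum(self.rates) * self.bin_width)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients between electrodes' rate histograms.

    Entries for zero-variance channels are NaN and are excluded from all
    summaries; ``valid`` marks electrodes with defined correlations.
    """

    electrode_ids: list[str]
    matrix: np.ndarray
    valid: np.ndarray = field(default=None)  # bool per electrode

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = ~np.all(np.isnan(self.matrix), axis=1)

    def value(self, a: str, b: str) -> float:
        i, j = self.electrode_ids.index(a), self.electrode_ids.index(b)
        return float(self.matrix[i, j])


@dataclass
class CCSummary:
    """Intra-/inter-module means of a correlation matrix.

    ``intra_per_module`` maps each module with >= 2 active electrodes to
    the mean of its within-module off-diagonal coefficients; modules with
    fewer electrodes appear in ``undefined_modules``.  ``inter_per_pair``
    maps unordered module pairs; pairs involving control electrodes are
    summarized separately in ``control_mean``.
    """

    intra_per_module: dict[str, float]
    inter_per_pair: dict[tuple[str, str], float]
    intra_overall: float
    inter_overall: float
    control_cross_mean: float  # pairs of one control + one network electrode
    control_intra_mean: float  # pairs within the control group
    undefined_modules: list[str]


def bin_rates(train: SpikeTrain, bin_width: float = DEFAULT_BIN_WIDTH) -> RateHistogram:
    """Bin a spike train into a firing-rate histogram.

    Bins are half-open ``[a, b)`` of width ``bin_width`` starting at
    ``t_start``; the number of bins is ``floor(duration / bin_width)`` so
    a trailing partial bin is dropped.  Rate = count / bin_width.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    n_bins = int(math.floor(train.duration / bin_width + 1e-9))
    if n_bins < 1:
        raise ValidationError(
            f"bin_width {bin_width} exceeds recording duration {train.duration}"
        )
    # floor of the scaled time keeps bins half-open; the 1e-9 snap places
    # spikes at exact decimal edges (unrepresentable in binary) into the
    # bin they open rather than the one they close
    idx = np.floor((train.timestamps - train.t_start) / bin_width + 1e-9).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return RateHistogram(train.electrode_id, bin_width, counts / bin_width, train.t_start)


def gaussian_kernel(kernel_bins: int = DEFAULT_KERNEL_BINS, sigma: float = DEFAULT_KERNEL_SIGMA) -> np.ndarray:
    """Discrete Gaussian kernel over ``kernel_bins`` bins, sum 1."""
    if kernel_bins < 1 or kernel_bins % 2 == 0:
        raise ValidationError("kernel_bins must be odd and >= 1")
    half = kernel_bins // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_rates(
    hist: RateHistogram,
    kernel_bins: int = DEFAULT_KERNEL_BINS,
    sigma: float = DEFAULT_KERNEL_SIGMA,
) -> RateHistogram:
    """Smooth a rate histogram with a discrete Gaussian kernel.

    At the edges the kernel is renormalized over the in-range bins (no
    zero padding), so the total spike count is conserved exactly.
    """
    k = gaussian_kernel(kernel_bins, sigma)
    half = kernel_bins // 2
    r = hist.rates
    n = r.size
    if half == 0:
        out = r.copy()
    elif n >= k.size:
        # each source bin's mass is redistributed over its in-range
        # neighbours with the kernel renormalized to those bins, so the
        # total count is conserved exactly at the edges; w[i] is the
        # kernel mass source bin i can place in range (symmetric kernel)
        w = np.convolve(np.ones(n), k, mode="same")
        out = np.convolve(r / w, k, mode="same")
    else:
        out = np.zeros(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            kk = k[lo - i + half : hi - i + half]
            out[lo:hi] += r[i] * kk / kk.sum()
    return RateHistogram(
        hist.electrode_id, hist.bin_width, out, hist.t_start, True, kernel_bins
    )


def active_filter(
    session: RecordingSession, min_rate: float = DEFAULT_MIN_RATE
) -> list[str]:
    """Electrodes whose mean firing rate is strictly greater than ``min_rate`` Hz."""
    return [
        eid
        for eid in session.electrode_ids
        if session.trains[eid].mean_rate > min_rate
    ]


def pearson_matrix(histograms: list[RateHistogram]) -> CorrelationMatrix:
    """Pearson correlation matrix over a list of rate histograms.

    All histograms must share the same bin grid.  Zero-variance channels
    yield NaN rows/columns (kept in the matrix, flagged via ``valid``).
    """
    if len(histograms) < 1:
        raise ValidationError("need at least one histogram")
    grids = {(h.bin_width, h.n_bins, round(h.t_start, 9)) for h in histograms}
    if len(grids) != 1:
        raise ValidationError(f"histograms on mismatched bin grids: {grids}")
    if histograms[0].n_bins < 2:
        raise ValidationError("need >= 2 bins for correlation")
    data = np.vstack([h.rates for h in histograms])
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(data)
    mat = np.atleast_2d(mat)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan
    np.fill_diagonal(mat, np.where(sd > 0, 1.0, np.nan))
    ids = [h.electrode_id for h in histograms]
    return CorrelationMatrix(ids, mat, sd > 0)


def session_matrix(
    session: RecordingSession,
    bin_width: float = DEFAULT_BIN_WIDTH,
    kernel_bins: int = DEFAULT_KERNEL_BINS,
    sigma: float = DEFAULT_KERNEL_SIGMA,
    min_rate: float = DEFAULT_MIN_RATE,
    smooth: bool = True,
) -> CorrelationMatrix:
    """Activity-filter, bin, smooth and correlate a whole session."""
    active = active_filter(session, min_rate)
    if len(active) < 2:
        raise ValidationError("fewer than two active electrodes")
    hists = [bin_rates(session.trains[e], bin_width) for e in active]
    if smooth:
        hists = [smooth_rates(h, kernel_bins, sigma) for h in hists]
    return pearson_matrix(hists)


def _pair_mean(values: list[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def cc_summary(matrix: CorrelationMatrix, mmap: ModuleMap) -> CCSummary:
    """Summarize a correlation matrix into intra- and inter-CC means.

    Only unordered off-diagonal pairs enter the means; NaN (zero
    variance) entries are excluded rather than treated as zero.  Pairs
    that involve a control electrode are pooled into ``control_mean``.
    """
    ids = matrix.electrode_ids
    unmapped = [e for e in ids if mmap.module_of(e) is None and e not in mmap.excluded]
    if unmapped:
        raise ValidationError(f"electrodes not covered by module map: {unmapped}")
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    control_cross: list[float] = []
    control_intra: list[float] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if a in mmap.excluded or b in mmap.excluded:
                continue
            ma, mb = mmap.module_of(a), mmap.module_of(b)
            v = float(matrix.matrix[i, j])
            if mmap.is_control(a) and mmap.is_control(b):
                control_intra.append(v)
            elif mmap.is_control(a) or mmap.is_control(b):
                control_cross.append(v)
            elif ma == mb:
                intra.setdefault(ma, []).append(v)
            else:
                inter.setdefault(tuple(sorted((ma, mb))), []).append(v)
    intra_per_module = {m: _pair_mean(v) for m, v in intra.items()}
    undefined = [
        m for m in mmap.modules
        if m not in intra or math.isnan(intra_per_module.get(m, math.nan))
    ]
    return CCSummary(
        intra_per_module={m: v for m, v in intra_per_module.items() if not math.isnan(v)},
        inter_per_pair={p: _pair_mean(v) for p, v in inter.items()},
        intra_overall=_pair_mean([v for vs in intra.values() for v in vs]),
        inter_overall=_pair_mean([v for vs in inter.values() for v in vs]),
        control_cross_mean=_pair_mean(control_cross),
        control_intra_mean=_pair_mean(control_intra),
        undefined_modules=undefined,
    )
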