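"""Graph Fourier analysis of region time series and the structural decoupling index.

A region-by-time activity matrix is a time-indexed family of graph signals.
Projecting each time sample onto the connectome's Laplacian eigenbasis (the
graph Fourier transform, GFT) gives per-eigenmode coefficients; their
time-averaged squares form the graph power spectral density (graph PSD).
The eigenmode axis is split at the median-energy cutoff C — the smallest
number of low-frequency modes holding at least half the total energy — into
a structurally *coupled* (low graph frequency) and a *decoupled* (high graph
frequency) component via ideal complementary filters.  The structural
decoupling index (SDI) at a region is

    SDI[n] = log2( ||decoupled[n, :]||_1 / ||coupled[n, :]||_1 ),

so positive values mean activity there escapes the structural scaffold and
negative values mean it rides the smooth harmonics of the connectome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph import (
    GraphSpectrum,
    StructuralConnectome,
    eigendecompose,
    normalized_laplacian,
    warn_if_degenerate_cutoff,
)

__all__ = [
    "RegionTimeSeries",
    "GraphCoefficients",
    "GraphPsd",
    "SdiMap",
    "TimeResolvedSdi",
    "gft",
    "igft",
    "graph_psd",
    "median_split_cutoff",
    "graph_filter_split",
    "compute_sdi",
    "sdi_pipeline",
    "time_resolved_sdi",
    "temporal_fluctuation",
    "decile_bin_maps",
    "ZeroNormWarning",
]

#: an l1 norm below this is treated as numerically zero for log-ratios
ZERO_NORM_FLOOR = 1e-300


class ZeroNormWarning(UserWarning):
    """A region's coupled or decoupled component has (numerically) zero norm."""


@dataclass
class RegionTimeSeries:
    """Region x time activity matrix with its sampling rate and labels.

    ``signal_kind`` distinguishes raw activity from band-passed signals and
    band envelopes produced by :mod:`neurogsp.prep`.
    """

    values: np.ndarray
    sampling_rate: float
    subject_id: str = "unknown"
    condition: str = "unknown"
    signal_kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be a (regions, samples) matrix, T >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def replace_values(self, values: np.ndarray, *, sampling_rate: float | None = None,
                       signal_kind: str | None = None) -> "RegionTimeSeries":
        return RegionTimeSeries(
            values=values,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            subject_id=self.subject_id,
            condition=self.condition,
            signal_kind=self.signal_kind if signal_kind is None else signal_kind,
        )


@dataclass
class GraphCoefficients:
    """GFT coefficients: eigenmodes x time samples."""

    values: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.values.shape[0]


@dataclass
class GraphPsd:
    """Per-eigenmode signal power (time-averaged squared GFT coefficients)."""

    power: np.ndarray
    normalization: str = "none"  # "none" | "l2"


@dataclass
class SdiMap:
    """Per-region log2 decoupled/coupled ratio for one subject and condition."""

    sdi: np.ndarray
    cutoff_C: int
    subject_id: str = "unknown"
    condition: str = "unknown"
    band: str = "raw"


@dataclass
class TimeResolvedSdi:
    """SDI per region and per non-overlapping window, with per-window cutoffs."""

    sdi: np.ndarray  # (regions, windows)
    window_seconds: float
    per_window_cutoffs: np.ndarray
    subject_id: str = "unknown"
    condition: str = "unknown"
    band: str = "raw"

    @property
    def n_windows(self) -> int:
        return self.sdi.shape[1]


def _check_match(spectrum: GraphSpectrum, n_regions: int) -> None:
    if spectrum.n_modes != n_regions:
        raise ValueError(
            f"spectrum has {spectrum.n_modes} modes but signal has "
            f"{n_regions} regions"
        )


def gft(spectrum: GraphSpectrum, ts: RegionTimeSeries) -> GraphCoefficients:
    """Graph Fourier transform: project each time sample onto the eigenbasis.

    ``coefficients = U^T @ values``.  Because U is orthonormal, the per-sample
    l2 norm is preserved (Parseval).
    """
    _check_match(spectrum, ts.n_regions)
    return GraphCoefficients(values=spectrum.eigenvectors.T @ ts.values)


def igft(spectrum: GraphSpectrum, coeffs: GraphCoefficients,
         template: RegionTimeSeries | None = None) -> RegionTimeSeries:
    """Inverse GFT: ``values = U @ coefficients``; exact inverse of :func:`gft`."""
    _check_match(spectrum, coeffs.n_modes)
    values = spectrum.eigenvectors @ coeffs.values
    if template is not None:
        return template.replace_values(values)
    return RegionTimeSeries(values=values, sampling_rate=1.0)


def graph_psd(coeffs: GraphCoefficients, normalize: bool = False) -> GraphPsd:
    """Graph PSD: mean over time of squared coefficients, per eigenmode.

    With ``normalize=True`` every time sample's coefficient vector is
    l2-normed first, which puts subjects with different overall signal power
    on a common scale — useful only for group-average displays, never for
    per-subject cutoff selection.
    """
    vals = coeffs.values
    if vals.shape[1] < 1:
        raise ValueError("cannot compute a PSD from an empty time axis")
    if normalize:
        norms = np.linalg.norm(vals, axis=0, keepdims=True)
        norms = np.where(norms == 0, 1.0, norms)
        vals = vals / norms
    return GraphPsd(
        power=np.mean(vals**2, axis=1),
        normalization="l2" if normalize else "none",
    )


def median_split_cutoff(psd: GraphPsd) -> int:
    """Number C of low-frequency eigenmodes holding half of the total energy.

    C is the smallest 1-based count such that the cumulative power of modes
    ``1..C`` reaches half the total.  It is clipped to ``[1, N-1]`` so both
    spectral halves remain non-empty.
    """
    power = psd.power
    total = power.sum()
    if total <= 0:
        raise ValueError("zero total spectral power; cutoff undefined")
    cum = np.cumsum(power)
    c = int(np.searchsorted(cum, total / 2.0) + 1)
    return int(np.clip(c, 1, len(power) - 1))


def graph_filter_split(
    spectrum: GraphSpectrum, ts: RegionTimeSeries, cutoff: int
) -> tuple[RegionTimeSeries, RegionTimeSeries]:
    """Ideal complementary low-/high-graph-frequency filtering.

    The coupled part keeps the first ``cutoff`` eigenmodes, the decoupled
    part the remaining ``N - cutoff``; by construction the two components
    add back to the input exactly and their energies partition the total.
    """
    _check_match(spectrum, ts.n_regions)
    n = spectrum.n_modes
    if not 1 <= cutoff <= n - 1:
        raise ValueError(f"cutoff must be in [1, {n - 1}], got {cutoff}")
    warn_if_degenerate_cutoff(spectrum, cutoff)
    u = spectrum.eigenvectors
    coeffs = u.T @ ts.values
    low = u[:, :cutoff] @ coeffs[:cutoff]
    high = u[:, cutoff:] @ coeffs[cutoff:]
    return ts.replace_values(low), ts.replace_values(high)


def compute_sdi(
    coupled: RegionTimeSeries, decoupled: RegionTimeSeries, cutoff: int
) -> SdiMap:
    """Per-region log2 ratio of decoupled to coupled l1 norms.

    Regions where either component's l1 norm underflows get a non-finite SDI
    and a :class:`ZeroNormWarning`; no epsilon is injected, since that would
    silently bias the log-ratio.
    """
    if coupled.values.shape != decoupled.values.shape:
        raise ValueError("coupled/decoupled shapes differ")
    norm_c = np.sum(np.abs(coupled.values), axis=1)
    norm_d = np.sum(np.abs(decoupled.values), axis=1)
    bad = (norm_c < ZERO_NORM_FLOOR) | (norm_d < ZERO_NORM_FLOOR)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} region(s) have a zero-norm component; "
            "their SDI is non-finite",
            ZeroNormWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        sdi = np.log2(norm_d / norm_c)
    sdi[bad & (norm_d < ZERO_NORM_FLOOR) & (norm_c >= ZERO_NORM_FLOOR)] = -np.inf
    sdi[bad & (norm_c < ZERO_NORM_FLOOR) & (norm_d >= ZERO_NORM_FLOOR)] = np.inf
    sdi[bad & (norm_c < ZERO_NORM_FLOOR) & (norm_d < ZERO_NORM_FLOOR)] = np.nan
    return SdiMap(
        sdi=sdi,
        cutoff_C=cutoff,
        subject_id=coupled.subject_id,
        condition=coupled.condition,
        band=_band_of(coupled),
    )


def _band_of(ts: RegionTimeSeries) -> str:
    kind = ts.signal_kind
    if "(" in kind and kind.endswith(")"):
        return kind[kind.index("(") + 1 : -1]
    return "raw"


def _sdi_from_spectrum(spectrum: GraphSpectrum, ts: RegionTimeSeries) -> SdiMap:
    coeffs = gft(spectrum, ts)
    cutoff = median_split_cutoff(graph_psd(coeffs))
    coupled, decoupled = graph_filter_split(spectrum, ts, cutoff)
    return compute_sdi(coupled, decoupled, cutoff)


def sdi_pipeline(connectome: StructuralConnectome, ts: RegionTimeSeries) -> SdiMap:
    """Static SDI for one subject/condition.

    Composition: eigendecompose the connectome's normalized Laplacian, GFT
    the signal, pick the median-energy cutoff from this subject's own PSD
    (the cutoff is subject-specific by design), split, and take the log2
    l1-norm ratio.  Deterministic: repeated runs are bit-identical.
    """
    if connectome.n_regions != ts.n_regions:
        raise ValueError("connectome and time series region counts differ")
    spectrum = eigendecompose(normalized_laplacian(connectome))
    return _sdi_from_spectrum(spectrum, ts)


def time_resolved_sdi(
    connectome: StructuralConnectome,
    ts: RegionTimeSeries,
    window_seconds: float = 1.0,
    spectrum: GraphSpectrum | None = None,
) -> TimeResolvedSdi:
    """SDI in consecutive non-overlapping windows with per-window cutoffs.

    Windows are aligned to sample 0; the window length in samples is
    ``round(window_seconds * sampling_rate)`` and a trailing partial window
    is discarded.  Each window gets its own local PSD, cutoff, filtering,
    and l1 norms, yielding a coupling time course per region.
    """
    win = int(round(window_seconds * ts.sampling_rate))
    if win < 1:
        raise ValueError("window shorter than one sample")
    n_windows = ts.n_samples // win
    if n_windows < 1:
        raise ValueError(
            f"need at least {win} samples for one {window_seconds}-s window, "
            f"got {ts.n_samples}"
        )
    if spectrum is None:
        spectrum = eigendecompose(normalized_laplacian(connectome))
    sdi = np.empty((ts.n_regions, n_windows))
    cutoffs = np.empty(n_windows, dtype=int)
    for w in range(n_windows):
        chunk = ts.replace_values(ts.values[:, w * win : (w + 1) * win])
        local = _sdi_from_spectrum(spectrum, chunk)
        sdi[:, w] = local.sdi
        cutoffs[w] = local.cutoff_C
    return TimeResolvedSdi(
        sdi=sdi,
        window_seconds=window_seconds,
        per_window_cutoffs=cutoffs,
        subject_id=ts.subject_id,
        condition=ts.condition,
        band=_band_of(ts),
    )


def temporal_fluctuation(
    tr: TimeResolvedSdi, low_pct: float = 20.0, high_pct: float = 20.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-region std of the SDI time course plus low/high percentile masks.

    Returns ``(std_map, low_mask, high_mask)``: the low mask selects regions
    at or below the ``low_pct`` linear-interpolation percentile of the std
    distribution (temporally stable coupling), the high mask those at or
    above the ``100 - high_pct`` percentile (strong temporal fluctuation).
    """
    if tr.n_windows < 2:
        raise ValueError("temporal fluctuation needs at least 2 windows")
    std_map = np.std(tr.sdi, axis=1, ddof=0)
    lo_thr = np.percentile(std_map, low_pct)
    hi_thr = np.percentile(std_map, 100.0 - high_pct)
    return std_map, std_map <= lo_thr, std_map >= hi_thr


def decile_bin_maps(sdi_map: SdiMap) -> np.ndarray:
    """Partition regions into 10 binary masks by SDI decile.

    Mask 0 holds the lowest decile (strongest coupling), mask 9 the highest
    (strongest decoupling).  The masks are pairwise disjoint and cover every
    region; ties are resolved by stable region order so the split is
    deterministic.
    """
    sdi = sdi_map.sdi
    if not np.all(np.isfinite(sdi)):
        raise ValueError("decile binning requires finite SDI values")
    n = len(sdi)
    order = np.argsort(sdi, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    deciles = np.minimum(ranks * 10 // n, 9)
    masks = np.zeros((10, n), dtype=bool)
    for d in range(10):
        masks[d] = deciles == d
    return masks
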