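"""Inter-modification spacing and periodicity in the 0-200 bp band.

Distances between *adjacent* (nearest-neighbor consecutive) calls are
histogrammed per contig — on the same strand or ignoring strand — and
compared against matched random-site controls (the same number of sites
drawn uniformly from eligible bases of the same type).  Periodicity is
read off the squared DFT magnitude of the detrended histogram: a 10 bp
helical-turn comb and a ~175 bp nucleosome-repeat peak are the two
signals of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_core import (
    MOD_CLASS_BASE,
    ConfigError,
    GenomeSeq,
    ModscapeError,
    ModTable,
)
from .synthetic_data import eligible_positions

STRAND_MODES = ("same_strand", "either_strand")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def adjacent_distances(mods: ModTable, mod_class: str,
                       strand_mode: str = "same_strand",
                       pool: bool = False) -> list[int]:
    """Distances between consecutive calls within contigs.

    ``same_strand``: differences of consecutive positions per
    (contig, strand).  ``either_strand``: per contig ignoring strand;
    two strands at one position yield a recorded 0.
    """
    if strand_mode not in STRAND_MODES:
        raise ConfigError(f"unknown strand_mode {strand_mode!r}")
    sub = mods.filter(mod_class, pool=pool)
    groups: dict[tuple, list[int]] = {}
    for c in sub:
        key = (c.contig, c.strand) if strand_mode == "same_strand" \
            else (c.contig,)
        groups.setdefault(key, []).append(c.pos)
    out: list[int] = []
    for pos in groups.values():
        arr = np.sort(np.asarray(pos, dtype=np.int64))
        out.extend(int(d) for d in np.diff(arr))
    return out


def control_distances(genome: GenomeSeq, mods: ModTable, mod_class: str,
                      n_replicates: int, seed: int,
                      strand_mode: str = "same_strand",
                      pool: bool = False) -> list[list[int]]:
    """Adjacent distances between matched random same-base sites.

    Per replicate, the same number of positions as real calls is drawn
    uniformly without replacement from eligible target-base positions on
    each (contig, strand) stream, then adjacent distances are taken under
    the requested strand mode.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if strand_mode not in STRAND_MODES:
        raise ConfigError(f"unknown strand_mode {strand_mode!r}")
    sub = mods.filter(mod_class, pool=pool)
    base = MOD_CLASS_BASE[mod_class]
    counts: dict[tuple[str, str], int] = {}
    for c in sub:
        counts[(c.contig, c.strand)] = counts.get((c.contig, c.strand), 0) + 1
    eligible: dict[tuple[str, str], np.ndarray] = {}
    for (contig, strand), n in counts.items():
        eligible[(contig, strand)] = eligible_positions(genome, base,
                                                        contig)[strand]
        if n > len(eligible[(contig, strand)]):
            raise ModscapeError(
                f"more calls ({n}) than eligible positions on "
                f"{contig}:{strand}")
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_replicates):
        groups: dict[tuple, list[np.ndarray]] = {}
        for (contig, strand), n in counts.items():
            pick = rng.choice(eligible[(contig, strand)], size=n,
                              replace=False)
            key = (contig, strand) if strand_mode == "same_strand" \
                else (contig,)
            groups.setdefault(key, []).append(pick)
        dists: list[int] = []
        for parts in groups.values():
            arr = np.sort(np.concatenate(parts))
            dists.extend(int(d) for d in np.diff(arr))
        replicates.append(dists)
    return replicates


# ---------------------------------------------------------------------------
# Histogram
# ---------------------------------------------------------------------------


@dataclass
class DistanceHistogram:
    """Counts of adjacent distances 1..max_d plus overflow/zero tallies."""

    max_d: int
    counts: np.ndarray  # counts[d-1] = multiplicity of distance d
    n_pairs: int
    n_overflow: int
    n_zero: int
    strand_mode: str = "same_strand"

    def count_at(self, d: int) -> int:
        return int(self.counts[d - 1])


def histogram(distances: Sequence[int], max_d: int = 200,
              strand_mode: str = "same_strand") -> DistanceHistogram:
    """Histogram distances into 1..max_d; 0s and >max_d are tallied apart."""
    if max_d < 1:
        raise ConfigError("max_d must be >= 1")
    arr = np.asarray(list(distances), dtype=np.int64)
    if (arr < 0).any():
        raise ConfigError("negative distance")
    n_zero = int((arr == 0).sum())
    n_overflow = int((arr > max_d).sum())
    in_range = arr[(arr >= 1) & (arr <= max_d)]
    counts = np.bincount(in_range, minlength=max_d + 1)[1:]
    return DistanceHistogram(max_d, counts.astype(np.int64), len(arr),
                             n_overflow, n_zero, strand_mode)


# ---------------------------------------------------------------------------
# Periodogram
# ---------------------------------------------------------------------------


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    n = len(x)
    h = window // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


@dataclass
class Periodogram:
    """Squared DFT magnitude of a (detrended) distance histogram."""

    periods: np.ndarray  # bp, for frequency indices 1..N//2
    power: np.ndarray  # aligned with `periods`
    power_full: np.ndarray  # full spectrum, indices 0..N-1 (Parseval-complete)
    detrended: np.ndarray
    band: tuple[float, float]
    dominant_period: Optional[float]


def periodogram(hist: DistanceHistogram, detrend_window: int = 20,
                band: tuple[float, float] = (5.0, 20.0),
                detrend: bool = True,
                range_max: Optional[int] = 100) -> Periodogram:
    """DFT power spectrum of the distance histogram.

    The histogram's monotone decay dominates low frequencies, so counts
    are detrended by subtracting a centered moving average (width
    ``detrend_window``, shrinking at the edges) before the FFT;
    ``detrend=False`` gives the raw-counts spectrum.  Helical-turn
    periodicity is a short-range phenomenon, so only distances up to
    ``range_max`` bp (default 100) enter the transform — this keeps the
    nucleosome-repeat peak, which generally shares no phase with the
    helical comb, from biasing the band-limited argmax; pass None to use
    the full histogram.  The dominant period is the power argmax within
    ``band`` (bp); an empty histogram yields dominant_period None.
    """
    x = hist.counts.astype(float)
    if range_max is not None and range_max < len(x):
        x = x[:range_max]
    N = len(x)
    if detrend:
        if N < 2 * detrend_window:
            raise ConfigError("histogram shorter than 2 x detrend_window")
        x = x - _moving_average(x, detrend_window)
    spec = np.fft.fft(x)
    power_full = np.abs(spec) ** 2
    j = np.arange(1, N // 2 + 1)
    periods = N / j
    power = power_full[1: N // 2 + 1]
    dominant: Optional[float] = None
    if hist.counts.sum() > 0:
        # zero-padded transform interpolates the spectrum so the peak is
        # localized off the coarse N-point frequency grid
        n_fft = max(1024, 8 * N)
        fine = np.abs(np.fft.fft(x, n_fft)[1: n_fft // 2 + 1]) ** 2
        fine_periods = n_fft / np.arange(1, n_fft // 2 + 1)
        in_band = (fine_periods >= band[0]) & (fine_periods <= band[1])
        if in_band.any():
            idx = np.flatnonzero(in_band)[np.argmax(fine[in_band])]
            dominant = float(fine_periods[idx])
    return Periodogram(periods, power, power_full, x, band, dominant)


# ---------------------------------------------------------------------------
# Nucleosome-scale peak
# ---------------------------------------------------------------------------


@dataclass
class NucleosomePeak:
    """Observed/control enrichment peak in the nucleosome-repeat band."""

    peak_distance: Optional[int]
    enrichment: Optional[float]
    ratio: np.ndarray  # per-distance smoothed observed/control ratio
    control_floored: bool  # True where epsilon flooring was needed in band


def nucleosome_peak(hist: DistanceHistogram,
                    control_hists: Sequence[DistanceHistogram],
                    window: int = 10,
                    band: tuple[int, int] = (100, 200),
                    epsilon: float = 1e-9) -> NucleosomePeak:
    """Peak of smoothed observed/control distance enrichment in 100-200 bp.

    Observed and mean-control counts are smoothed with a centered moving
    average of ``window`` bp; the control is floored at ``epsilon`` (with
    a flag) where it is zero.  Returns peak None when the control has no
    mass anywhere in the band.
    """
    if not control_hists:
        raise ConfigError("at least one control histogram required")
    if any(h.max_d != hist.max_d for h in control_hists):
        raise ConfigError("control histograms have different max_d")
    obs = _moving_average(hist.counts.astype(float), window)
    ctrl_mean = np.mean([h.counts for h in control_hists], axis=0)
    ctrl = _moving_average(ctrl_mean, window)
    d = np.arange(1, hist.max_d + 1)
    in_band = (d >= band[0]) & (d <= band[1])
    if not in_band.any():
        raise ConfigError("band outside histogram range")
    if ctrl[in_band].sum() == 0:
        return NucleosomePeak(None, None,
                              np.full(hist.max_d, np.nan), True)
    floored = bool((ctrl[in_band] <= 0).any())
    ratio = obs / np.maximum(ctrl, epsilon)
    idx = np.flatnonzero(in_band)[np.argmax(ratio[in_band])]
    return NucleosomePeak(int(d[idx]), float(ratio[idx]), ratio, floored)
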