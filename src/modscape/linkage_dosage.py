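"""Coverage-based X/autosome contig classification and dosage comparison.

In a male XO insect the X is haploid while autosomes are diploid, so
X-linked contigs sit at half the autosomal depth.  Contigs are windowed,
per-window *median* depth is taken (robust to repeat-driven spikes), the
diploid peak is estimated as the majority mode of window medians, and a
contig is called X-linked when more than a threshold fraction (default
80%) of its windows fall in a haploid band around half the peak.

The dosage-compensation check compares per-gene log2(male/female)
abundance ratios between X-linked and autosomal genes: without
compensation the X distribution is centred near -1; with compensation
the two distributions coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io_core import (
    ConfigError,
    CoverageTrack,
    ExpressionTable,
    GenomeSeq,
    ModscapeError,
)


class EstimationError(ModscapeError):
    """Coverage peak estimation failed (e.g. all-zero depth)."""


# ---------------------------------------------------------------------------
# Coverage windows
# ---------------------------------------------------------------------------


@dataclass
class ContigCoverageProfile:
    contig: str
    window_bp: int
    medians: np.ndarray  # per-window median depth
    fraction_in_haploid_band: Optional[float] = None

    @property
    def n_windows(self) -> int:
        return len(self.medians)


def _weighted_median(depths: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median of a step function's per-base depth."""
    order = np.argsort(depths, kind="stable")
    d, w = depths[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    return float(d[np.searchsorted(cum, half, side="left")])


def coverage_profile(track: CoverageTrack,
                     genome: Union[GenomeSeq, dict[str, int]],
                     window_bp: int = 10_000) -> list[ContigCoverageProfile]:
    """Per-window median depth over the coverage step function.

    Windows tile each contig; a final partial window is kept if it spans
    at least half a window, else it is merged into the previous one.
    Bases not covered by any step count as depth 0; a contig absent from
    the track yields zero-depth windows with a warning.
    """
    if window_bp < 100:
        raise ConfigError("window_bp must be >= 100")
    lengths = genome.lengths if isinstance(genome, GenomeSeq) else dict(genome)
    profiles = []
    for contig, length in lengths.items():
        steps = track.contig_steps(contig)
        # window boundaries with the partial-window rule
        bounds = list(range(0, length, window_bp)) + [length]
        if len(bounds) > 2 and bounds[-1] - bounds[-2] < window_bp / 2:
            del bounds[-2]
        medians = []
        for ws, we in zip(bounds[:-1], bounds[1:]):
            depths, weights = [], []
            covered = 0
            for s in steps:
                lo, hi = max(s.start, ws), min(s.end, we)
                if lo < hi:
                    depths.append(s.depth)
                    weights.append(hi - lo)
                    covered += hi - lo
            if covered < we - ws:
                depths.append(0.0)
                weights.append(we - ws - covered)
            medians.append(_weighted_median(np.asarray(depths),
                                            np.asarray(weights, dtype=float)))
        profiles.append(ContigCoverageProfile(contig, window_bp,
                                              np.asarray(medians)))
    return profiles


def estimate_diploid_peak(profiles: Sequence[ContigCoverageProfile]) -> float:
    """Majority mode of window-median depths, as a histogram bin center.

    Assumes autosomal (diploid) sequence dominates the window population.
    Bin width is max(1, m/100) with m an initial median-based guess; ties
    resolve to the lower mode.
    """
    medians = np.concatenate([p.medians for p in profiles])
    if len(medians) < 10:
        raise ConfigError("need at least 10 windows")
    if medians.max() <= 0:
        raise EstimationError("all-zero coverage")
    guess = float(np.median(medians[medians > 0]))
    binw = max(1.0, guess / 100.0)
    edges = np.arange(0.0, medians.max() + 2 * binw, binw)
    counts, edges = np.histogram(medians, bins=edges)
    i = int(np.argmax(counts))  # first (= lowest) maximal bin
    return float((edges[i] + edges[i + 1]) / 2.0)


@dataclass
class LinkageCall:
    """Per-contig X/autosomal assignment from haploid-band occupancy."""

    calls: dict[str, str]  # contig -> 'X' | 'autosomal'
    diploid_peak: float
    haploid_band: tuple[float, float]  # absolute depths
    threshold: float
    fractions: dict[str, float] = field(default_factory=dict)


def classify_contigs(profiles: Sequence[ContigCoverageProfile],
                     diploid_peak: float,
                     band: tuple[float, float] = (0.35, 0.65),
                     threshold: float = 0.8) -> LinkageCall:
    """Call a contig X-linked when > ``threshold`` of its windows sit in
    the haploid band (``band`` x diploid peak, inclusive)."""
    if diploid_peak <= 0:
        raise ConfigError("diploid_peak must be > 0")
    if not (0 < threshold <= 1) or band[0] >= band[1]:
        raise ConfigError("bad band or threshold")
    lo, hi = band[0] * diploid_peak, band[1] * diploid_peak
    calls, fractions = {}, {}
    for p in profiles:
        in_band = (p.medians >= lo) & (p.medians <= hi)
        frac = float(in_band.mean()) if p.n_windows else 0.0
        p.fraction_in_haploid_band = frac
        fractions[p.contig] = frac
        calls[p.contig] = "X" if frac > threshold else "autosomal"
    return LinkageCall(calls, diploid_peak, (lo, hi), threshold, fractions)


# ---------------------------------------------------------------------------
# Dosage compensation
# ---------------------------------------------------------------------------


@dataclass
class DosageResult:
    ratios: dict[str, np.ndarray]  # class -> log2(male/female) ratios
    medians: dict[str, float]
    pseudocount: float
    rank_sum_stat: Optional[float]
    p: Optional[float]
    ks_stat: Optional[float] = None
    ks_p: Optional[float] = None
    skipped: bool = False  # a class had < 2 genes; comparison not run
    n_excluded: int = 0


def dosage_ratios(expression: ExpressionTable, linkage: dict[str, str],
                  pseudocount: float = 1.0,
                  min_abundance: float = 1.0) -> DosageResult:
    """Compare male/female log2 abundance ratios between X and autosomes.

    ``linkage`` maps gene id to 'X' or 'autosomal'.  Genes whose larger
    abundance is below ``min_abundance`` are excluded; ratios use a
    pseudocount to stay finite.  The two classes are compared with a
    two-sided rank-sum (Mann-Whitney) test plus a Kolmogorov-Smirnov
    statistic for the distribution-equality claim.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    ratios: dict[str, list[float]] = {"X": [], "autosomal": []}
    n_excluded = 0
    for gene, (male, female, _contig) in expression.items():
        cls = linkage.get(gene)
        if cls not in ratios:
            continue
        if max(male, female) < min_abundance:
            n_excluded += 1
            continue
        ratios[cls].append(math.log2((male + pseudocount) /
                                     (female + pseudocount)))
    arrays = {k: np.asarray(v) for k, v in ratios.items()}
    medians = {k: float(np.median(v)) if len(v) else math.nan
               for k, v in arrays.items()}
    if any(len(v) < 2 for v in arrays.values()):
        return DosageResult(arrays, medians, pseudocount, None, None,
                            skipped=True, n_excluded=n_excluded)
    u = stats.mannwhitneyu(arrays["X"], arrays["autosomal"],
                           alternative="two-sided")
    ks = stats.ks_2samp(arrays["X"], arrays["autosomal"])
    return DosageResult(arrays, medians, pseudocount, float(u.statistic),
                        float(u.pvalue), float(ks.statistic),
                        float(ks.pvalue), n_excluded=n_excluded)


def gene_linkage_from_contigs(expression: ExpressionTable,
                              contig_class: dict[str, str]) -> dict[str, str]:
    """Map genes to X/autosomal through their contig of origin."""
    out = {}
    for gene, (_m, _f, contig) in expression.items():
        cls = contig_class.get(contig)
        if cls is not None:
            out[gene] = cls
    return out
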