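"""Per-6-mer nanopore current-shift detection against a pore model.

Native event current means are compared per 6-mer with the expected
pore-model Gaussian: the mean shift (delta, in pA), a z-score of that
shift, and a one-sample Kolmogorov-Smirnov statistic with its asymptotic
p-value.  A k-mer is called *shifted* when its BH-adjusted KS p-value
clears alpha AND the absolute mean shift clears an effect-size floor —
a concrete, reproducible decision rule for distributions that do not
conform to their model.  Sub-motifs (e.g. GAG, GCG trimers) enriched in
the shifted set are scored with the same standardized-residual formula
as the modification-context analysis, pooled over all offsets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .io_core import ConfigError, EventTable, KmerModel
from .kmer_context import EnrichmentResult, enrichment_from_counts

logger = logging.getLogger("modscape")


@dataclass
class KmerShiftResult:
    kmer: str
    n_events: int
    native_mean: float
    native_sd: float
    model_mean: float
    model_sd: float
    delta_mean: float  # native - model, pA
    z: float  # delta / (model_sd / sqrt(n))
    ks_stat: float
    p: float  # asymptotic one-sample KS p-value
    q: Optional[float] = None
    flagged: bool = False
    low_coverage: bool = False


def _ks_one_sample_normal(x: np.ndarray, mean: float, sd: float
                          ) -> tuple[float, float]:
    """One-sample KS statistic vs N(mean, sd) with asymptotic p-value."""
    n = len(x)
    cdf = special.ndtr((np.sort(x) - mean) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    d = max(d_plus, d_minus)
    p = float(special.kolmogorov(math.sqrt(n) * d))
    return float(d), min(max(p, 0.0), 1.0)


def kmer_shift_stats(events: EventTable, model: KmerModel,
                     min_events: int = 50) -> list[KmerShiftResult]:
    """Compare each 6-mer's native events with its expected model Gaussian.

    K-mers absent from the model are skipped with a logged tally; k-mers
    with fewer than ``min_events`` events are reported with a
    low-coverage marker and are never flagged.
    """
    if min_events < 10:
        raise ConfigError("min_events must be >= 10")
    results = []
    n_skipped = 0
    for kmer in sorted(events.table):
        if kmer not in model:
            n_skipped += 1
            continue
        x = events[kmer]
        n = len(x)
        mean, sd = model[kmer]
        native_mean = float(np.mean(x))
        native_sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        delta = native_mean - mean
        z = delta / (sd / math.sqrt(n))
        ks_stat, p = _ks_one_sample_normal(x, mean, sd)
        results.append(KmerShiftResult(kmer, n, native_mean, native_sd,
                                       mean, sd, delta, z, ks_stat, p,
                                       low_coverage=n < min_events))
    if n_skipped:
        logger.warning("kmer_shift_stats: %d k-mer(s) absent from model",
                       n_skipped)
    return results


def shifted_kmer_set(results: Sequence[KmerShiftResult], alpha: float = 0.01,
                     min_abs_shift: float = 1.0) -> set[str]:
    """K-mers flagged as shifted: BH-adjusted p <= alpha and |delta| >=
    ``min_abs_shift`` pA (low-coverage k-mers never qualify)."""
    if not results:
        return set()
    from .feature_enrichment import bh_adjust

    testable = [r for r in results if not r.low_coverage]
    if not testable:
        return set()
    q = bh_adjust([r.p for r in testable])
    out = set()
    for r, qv in zip(testable, q):
        r.q = float(qv)
        r.flagged = bool(qv <= alpha and abs(r.delta_mean) >= min_abs_shift)
        if r.flagged:
            out.add(r.kmer)
    return out


def _submotif_counts(kmers: Sequence[str], m: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for kmer in kmers:
        for i in range(len(kmer) - m + 1):
            sub = kmer[i: i + m]
            counts[sub] = counts.get(sub, 0) + 1
    return counts


def submotif_enrichment(shifted: set[str], universe: Sequence[str],
                        m: int = 3) -> Optional[EnrichmentResult]:
    """Standardized-residual enrichment of m-mers within shifted 6-mers.

    Every m-mer window (all offsets) inside the shifted set is counted
    against the same windows over the whole modeled universe; residuals
    use the offset-free variant of the context-enrichment formula.
    Returns None for an empty shifted set.
    """
    if not (1 <= m <= 6):
        raise ConfigError("m must be in 1..6")
    if not shifted:
        return None
    missing = set(shifted) - set(universe)
    if missing:
        raise ConfigError(f"shifted k-mers outside universe: "
                          f"{sorted(missing)[:3]}")
    obs = _submotif_counts(sorted(shifted), m)
    bg = _submotif_counts(list(universe), m)
    return enrichment_from_counts(obs, bg, k=m)
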