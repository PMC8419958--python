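"""Binomial enrichment/depletion of modifications in genomic features.

Each feature class is tested with an exact two-sided binomial model: the
success probability is the fraction of eligible target bases (both
strands) inside the merged intervals of the class, and the observed
count is the number of calls falling inside.  Fold = observed/expected;
two-sided p-values come from minimum-likelihood summation, and q-values
from Benjamini-Hochberg across classes or repeat families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    MOD_CLASS_BASE,
    ConfigError,
    ExpressionTable,
    FeatureSet,
    GenomeSeq,
    Interval,
    ModTable,
    encode,
)


# ---------------------------------------------------------------------------
# Interval plumbing
# ---------------------------------------------------------------------------


def merge_intervals(features: FeatureSet) -> dict[str, np.ndarray]:
    """Merge overlapping intervals per contig -> array of (start, end)."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in features:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged = {}
    for contig, spans in by_contig.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = np.asarray(out, dtype=np.int64)
    return merged


def _positions_inside(merged: dict[str, np.ndarray], contig: str,
                      pos: int) -> bool:
    spans = merged.get(contig)
    if spans is None or len(spans) == 0:
        return False
    i = int(np.searchsorted(spans[:, 0], pos, side="right")) - 1
    return i >= 0 and pos < spans[i, 1]


def _group_positions(calls) -> dict[str, np.ndarray]:
    by_contig: dict[str, list[int]] = {}
    for c in calls:
        by_contig.setdefault(c.contig, []).append(c.pos)
    return {k: np.asarray(v, dtype=np.int64) for k, v in by_contig.items()}


def _count_inside(merged: dict[str, np.ndarray],
                  positions: dict[str, np.ndarray]) -> int:
    """Vectorized count of positions falling in merged (disjoint) spans."""
    total = 0
    for contig, pos in positions.items():
        spans = merged.get(contig)
        if spans is None or len(spans) == 0:
            continue
        i = np.searchsorted(spans[:, 0], pos, side="right") - 1
        ok = (i >= 0) & (pos < spans[np.clip(i, 0, None), 1])
        total += int(ok.sum())
    return total


def eligible_base_count(genome: GenomeSeq, features: FeatureSet,
                        target_base: str) -> tuple[int, int]:
    """(eligible bases inside merged features, eligible genome-wide).

    Both strands are counted: an A contributes on the plus strand where
    the forward letter is A and on the minus strand where it is T, so the
    both-strand count in a region is #base + #complement.
    """
    if target_base not in "AC":
        raise ConfigError("target_base must be A or C")
    code = int(encode(target_base)[0])
    comp = 3 - code
    merged = merge_intervals(features)
    eligible_in = 0
    eligible_total = 0
    for contig, _seq in genome.items():
        enc = genome.encoded(contig)
        eligible_total += int(((enc == code) | (enc == comp)).sum())
        for s, e in merged.get(contig, ()):  # merged spans are disjoint
            seg = enc[s:e]
            eligible_in += int(((seg == code) | (seg == comp)).sum())
    return eligible_in, eligible_total


# ---------------------------------------------------------------------------
# Binomial test
# ---------------------------------------------------------------------------


@dataclass
class FeatureEnrichment:
    feature_type: str
    eligible_in: int
    eligible_total: int
    observed: int
    n_total: int
    expected: float
    fold: float
    p: float
    q: Optional[float] = None


def binomial_feature_test(mods: ModTable, genome: GenomeSeq,
                          features: FeatureSet, feature_type: str,
                          mod_class: str, pool: bool = False,
                          strand_matched: bool = False
                          ) -> Optional[FeatureEnrichment]:
    """Exact two-sided binomial enrichment of one feature class.

    Membership is strand-agnostic by default (the test concerns genomic
    regions, not strand-matched features); ``strand_matched`` restricts
    observed calls to those whose strand equals the interval strand.
    Returns None when there are no calls of the class.
    """
    sub = mods.filter(mod_class, pool=pool)
    n_total = len(sub)
    if n_total == 0:
        return None
    fsub = features.of_type(feature_type)
    base = MOD_CLASS_BASE[mod_class]
    eligible_in, eligible_total = eligible_base_count(genome, fsub, base)
    if eligible_total == 0:
        raise ConfigError("no eligible bases in genome")
    if strand_matched:
        observed = 0
        for s in "+-":
            merged_s = merge_intervals(
                FeatureSet([iv for iv in fsub if iv.strand == s]))
            observed += _count_inside(
                merged_s, _group_positions(c for c in sub if c.strand == s))
    else:
        merged = merge_intervals(fsub)
        observed = _count_inside(merged, _group_positions(sub))
    p_success = eligible_in / eligible_total
    expected = n_total * p_success
    fold = observed / expected if expected > 0 else math.inf
    if p_success in (0.0, 1.0):
        pval = 1.0 if observed == expected else 0.0
    else:
        pval = stats.binomtest(observed, n_total, p_success,
                               alternative="two-sided").pvalue
    return FeatureEnrichment(feature_type, eligible_in, eligible_total,
                             observed, n_total, expected, fold, float(pval))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ConfigError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def feature_class_table(mods: ModTable, genome: GenomeSeq,
                        features: FeatureSet, mod_class: str,
                        feature_types: Optional[Sequence[str]] = None,
                        pool: bool = False) -> pd.DataFrame:
    """Binomial test per feature class with BH adjustment across classes."""
    if feature_types is None:
        feature_types = features.types()
    results = []
    for ftype in feature_types:
        r = binomial_feature_test(mods, genome, features, ftype, mod_class,
                                  pool=pool)
        if r is not None:
            results.append(r)
    if not results:
        return pd.DataFrame()
    q = bh_adjust([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
    return pd.DataFrame([vars(r) for r in results])


def per_family_fold(mods: ModTable, genome: GenomeSeq,
                    repeat_features: FeatureSet, mod_class: str,
                    min_eligible: int = 100, pool: bool = False,
                    family_of: Callable[[Interval], str] = lambda iv:
                    iv.id.split(":")[0]) -> tuple[pd.DataFrame, list[str]]:
    """One binomial test per repeat family; BH across tested families.

    Families with fewer than ``min_eligible`` eligible bases are excluded
    from testing and returned separately.
    """
    sub = mods.filter(mod_class, pool=pool)
    n_total = len(sub)
    base = MOD_CLASS_BASE[mod_class]
    by_family: dict[str, list[Interval]] = {}
    for iv in repeat_features:
        by_family.setdefault(family_of(iv), []).append(iv)
    code = int(encode(base)[0])
    comp = 3 - code
    eligible_total = 0
    for contig, _seq in genome.items():
        enc = genome.encoded(contig)
        eligible_total += int(((enc == code) | (enc == comp)).sum())
    positions = _group_positions(sub)
    rows, excluded = [], []
    for family in sorted(by_family):
        fset = FeatureSet(by_family[family])
        merged = merge_intervals(fset)
        eligible_in = 0
        for contig in merged:
            enc = genome.encoded(contig)
            for s, e in merged[contig]:
                seg = enc[s:e]
                eligible_in += int(((seg == code) | (seg == comp)).sum())
        if eligible_in < min_eligible:
            excluded.append(family)
            continue
        observed = _count_inside(merged, positions)
        p_success = eligible_in / eligible_total
        expected = n_total * p_success
        fold = observed / expected if expected > 0 else math.inf
        pval = stats.binomtest(observed, n_total, p_success,
                               alternative="two-sided").pvalue if n_total else 1.0
        rows.append({"family": family, "eligible_in": eligible_in,
                     "observed": observed, "expected": expected,
                     "fold": fold, "p": float(pval)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df, excluded


# ---------------------------------------------------------------------------
# Promoters and expression strata
# ---------------------------------------------------------------------------


def derive_promoters(features: FeatureSet, genome: GenomeSeq,
                     upstream: int = 500) -> FeatureSet:
    """Fixed strand-aware windows upstream of gene starts, clipped to contigs."""
    out = []
    for iv in features.of_type("gene"):
        if iv.strand == "-":
            s, e = iv.end, min(iv.end + upstream, genome.lengths[iv.contig])
        else:
            s, e = max(iv.start - upstream, 0), iv.start
        if s < e:
            out.append(Interval(iv.contig, s, e, iv.strand, "promoter",
                                f"{iv.id}_prom"))
    return FeatureSet(out)


def expression_strata(expression: ExpressionTable,
                      thresholds: tuple[float, float] = (0.1, 10.0)
                      ) -> dict[str, str]:
    """Classify genes as unexpressed/low/high from male-sample abundance."""
    t_un, t_high = thresholds
    if t_un >= t_high:
        raise ConfigError("t_unexpressed must be < t_high")
    out = {}
    for gene, (male, _female, _contig) in expression.items():
        if male <= t_un:
            out[gene] = "unexpressed"
        elif male >= t_high:
            out[gene] = "high"
        else:
            out[gene] = "low"
    return out
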