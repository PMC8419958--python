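"""Position-specific k-mer context statistics for modified bases.

The central comparison: the distribution of k-mers carrying a specific
modification at a fixed offset versus the genome-wide distribution of
k-mers with the target base at that offset.  Per-k-mer enrichment is
expressed as chi-square standardized residuals — how many standard
deviations each observed count sits from its expectation — plus a
dimensionless rate ratio (context modification rate over the bare-base
rate).  Enriched k-mer sets feed a position weight matrix builder.

Context extraction is call-strand-relative: a minus-strand call's
context is the reverse complement of the forward-strand window, so the
modified base occupies the same offset in every extracted k-mer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    MOD_CLASS_BASE,
    ConfigError,
    GenomeSeq,
    ModscapeError,
    ModTable,
    encode,
)


class UndefinedRatioError(ModscapeError):
    """A rate ratio has a zero denominator (k-mer absent from genome)."""


# ---------------------------------------------------------------------------
# Encoded-window machinery
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _kmer_code(kmer: str) -> int:
    enc = encode(kmer)
    if (enc > 3).any():
        raise ConfigError(f"k-mer {kmer!r} not over ACGT")
    code = 0
    for c in enc:
        code = code * 4 + int(c)
    return code


def _rc_enc(enc: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded array (N stays N)."""
    return np.where(enc == 4, 4, 3 - enc)[::-1]


def _window_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all length-k windows and a validity mask (no N)."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    code = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        seg = enc[j: m + j]
        code = code * 4 + seg
        ok &= seg < 4
    return code, ok


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


@dataclass
class KmerCountTable:
    """Counts of k-mers with a fixed target base at a fixed offset."""

    k: int
    target_base: str
    offset: int
    counts: dict[str, int]
    dropped: int = 0

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def compatible(self, other: "KmerCountTable") -> bool:
        return (self.k, self.target_base, self.offset) == \
            (other.k, other.target_base, other.offset)


def background_kmer_counts(genome: GenomeSeq, k: int, target_base: str,
                           offset: int) -> KmerCountTable:
    """Genome-wide k-mer counts with ``target_base`` at ``offset``.

    Both strands are scanned (the minus strand as the reverse complement
    of each contig); windows containing N or truncated at contig ends are
    excluded, so the total equals the number of eligible target-base
    positions.
    """
    if not (1 <= k <= 9):
        raise ConfigError("k must be in 1..9")
    if not (0 <= offset < k):
        raise ConfigError("offset out of range")
    if target_base not in "AC":
        raise ConfigError("target_base must be A or C")
    target = int(encode(target_base)[0])
    acc = np.zeros(4 ** k, dtype=np.int64)
    for name, _seq in genome.items():
        enc = genome.encoded(name)
        for strand_enc in (enc, _rc_enc(enc)):
            codes, ok = _window_codes(strand_enc, k)
            if len(codes) == 0:
                continue
            at_off = strand_enc[offset: offset + len(codes)]
            sel = ok & (at_off == target)
            if sel.any():
                acc += np.bincount(codes[sel], minlength=4 ** k)
    counts = {_decode(int(c), k): int(acc[c]) for c in np.flatnonzero(acc)}
    return KmerCountTable(k, target_base, offset, counts)


def modified_kmer_counts(mods: ModTable, genome: GenomeSeq, k: int,
                         offset: int, mod_class: str,
                         pool: bool = False) -> KmerCountTable:
    """K-mer contexts of all calls of one class, strand-resolved.

    A minus-strand call contributes the reverse complement of its
    forward-strand window, so the called base sits at ``offset`` in the
    emitted k-mer.  Contexts running off a contig end or containing N are
    excluded and tallied in ``dropped``.
    """
    if mod_class not in MOD_CLASS_BASE:
        raise ConfigError(f"unknown mod_class {mod_class!r}")
    if not (0 <= offset < k):
        raise ConfigError("offset out of range")
    target_base = MOD_CLASS_BASE[mod_class]
    sub = mods.filter(mod_class, pool=pool)
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    acc = np.zeros(4 ** k, dtype=np.int64)
    dropped = 0
    by_group: dict[tuple[str, str], list[int]] = {}
    for c in sub:
        by_group.setdefault((c.contig, c.strand), []).append(c.pos)
    for (contig, strand), pos_list in by_group.items():
        enc = genome.encoded(contig)
        n = len(enc)
        pos = np.asarray(pos_list, dtype=np.int64)
        if strand == "+":
            start = pos - offset
        else:
            start = pos - (k - 1 - offset)
        in_range = (start >= 0) & (start + k <= n)
        dropped += int((~in_range).sum())
        start = start[in_range]
        if len(start) == 0:
            continue
        win = enc[start[:, None] + np.arange(k)]
        if strand == "-":
            win = np.where(win == 4, 4, 3 - win)[:, ::-1]
        ok = (win < 4).all(axis=1)
        dropped += int((~ok).sum())
        win = win[ok]
        if len(win):
            codes = win @ pows
            acc += np.bincount(codes, minlength=4 ** k)
    counts = {_decode(int(c), k): int(acc[c]) for c in np.flatnonzero(acc)}
    return KmerCountTable(k, target_base, offset, counts, dropped=dropped)


# ---------------------------------------------------------------------------
# Standardized residuals
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Per-k-mer observed/expected counts, residuals and rate ratios."""

    k: int
    target_base: str
    offset: int
    n_mod: int
    obs: dict[str, int]
    expected: dict[str, float]
    proportion: dict[str, float]
    residual: dict[str, Optional[float]]  # None where E=0 and O=0
    rate_ratio: dict[str, float]
    chi_square: float
    variant: str = "haberman"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in sorted(self.obs, key=lambda w: (-(self.residual[w]
                                                  if self.residual[w] is not None
                                                  else -math.inf), w)):
            rows.append({"kmer": w, "obs": self.obs[w],
                         "expected": self.expected[w],
                         "proportion": self.proportion[w],
                         "residual": self.residual[w],
                         "rate_ratio": self.rate_ratio[w]})
        return pd.DataFrame(rows)

    def top_kmer(self) -> Optional[str]:
        ranked = select_enriched_kmers(self, "top_n", 1)
        return ranked[0] if ranked else None


def enrichment_from_counts(obs_counts: dict[str, int],
                           bg_counts: dict[str, int], *, k: int,
                           target_base: str = "*", offset: int = -1,
                           variant: str = "haberman") -> EnrichmentResult:
    """Residuals/ratios from raw observed and background count dicts.

    Backs :func:`standardized_residuals`; also usable offset-free (e.g.
    sub-motif counts pooled over all offsets), flagged by ``offset=-1``.
    """
    if variant not in ("haberman", "pearson"):
        raise ConfigError(f"unknown variant {variant!r}")
    bg_total = sum(bg_counts.values())
    if bg_total <= 0:
        raise ConfigError("background counts are empty")
    n_mod = sum(obs_counts.values())
    kmers = sorted(set(obs_counts) | set(bg_counts))
    obs_d, exp_d, prop_d, res_d, rr_d = {}, {}, {}, {}, {}
    chi2 = 0.0
    overall_rate = n_mod / bg_total
    for w in kmers:
        O = obs_counts.get(w, 0)
        b = bg_counts.get(w, 0)
        p = b / bg_total
        E = n_mod * p
        obs_d[w], exp_d[w], prop_d[w] = O, E, p
        if E > 0:
            chi2 += (O - E) ** 2 / E
            denom = math.sqrt(E * (1 - p)) if variant == "haberman" \
                else math.sqrt(E)
            res_d[w] = (O - E) / denom if denom > 0 else (
                0.0 if O == E else math.inf)
        else:
            res_d[w] = math.inf if O > 0 else None
        if b > 0 and overall_rate > 0:
            rr_d[w] = (O / b) / overall_rate
        else:
            rr_d[w] = math.inf if O > 0 else math.nan
    return EnrichmentResult(k, target_base, offset, n_mod,
                            obs_d, exp_d, prop_d, res_d, rr_d, chi2, variant)


def standardized_residuals(obs: KmerCountTable, bg: KmerCountTable,
                           variant: str = "haberman") -> EnrichmentResult:
    """Chi-square standardized residuals of observed vs background k-mers.

    With p_w = bg_w / bg_total and E_w = N p_w, the default residual is
    the adjusted goodness-of-fit form r_w = (O_w - E_w)/sqrt(E_w (1-p_w)),
    whose scale is standard deviations from expectation; ``variant=
    "pearson"`` gives the plain (O_w - E_w)/sqrt(E_w).  Also reports the
    goodness-of-fit chi-square sum of (O-E)^2/E.
    """
    if not obs.compatible(bg):
        raise ConfigError("obs and bg tables have mismatched (k, base, offset)")
    return enrichment_from_counts(obs.counts, bg.counts, k=obs.k,
                                  target_base=obs.target_base,
                                  offset=obs.offset, variant=variant)


def rate_ratio(mods: ModTable, genome: GenomeSeq, kmer: str, offset: int,
               mod_class: str, pool: bool = False) -> float:
    """Modification rate of a k-mer context over the bare target-base rate.

    rho = (modified occurrences of kmer / genome occurrences of kmer)
        / (modified target bases / genome target bases), both strands.
    """
    if mod_class not in MOD_CLASS_BASE:
        raise ConfigError(f"unknown mod_class {mod_class!r}")
    base = MOD_CLASS_BASE[mod_class]
    k = len(kmer)
    if not (0 <= offset < k) or kmer[offset] != base:
        raise ConfigError(
            f"offset base of {kmer!r} must be {base} for {mod_class}")
    bg_k = background_kmer_counts(genome, k, base, offset)
    n_kmer = bg_k.counts.get(kmer, 0)
    if n_kmer == 0:
        raise UndefinedRatioError(f"{kmer!r} absent from genome")
    obs_k = modified_kmer_counts(mods, genome, k, offset, mod_class, pool=pool)
    m_kmer = obs_k.counts.get(kmer, 0)
    bg_b = background_kmer_counts(genome, 1, base, 0)
    n_base = bg_b.total
    m_base = modified_kmer_counts(mods, genome, 1, 0, mod_class, pool=pool).total
    if m_base == 0:
        raise UndefinedRatioError("no modified target bases")
    return (m_kmer / n_kmer) / (m_base / n_base)


def select_enriched_kmers(result: EnrichmentResult, mode: str,
                          value) -> list[str]:
    """K-mers ranked by descending residual (lexicographic tie-break)."""
    scored = [(w, r) for w, r in result.residual.items() if r is not None]
    scored.sort(key=lambda t: (-t[1], t[0]))
    if mode == "top_n":
        return [w for w, _ in scored[: int(value)]]
    if mode == "residual_threshold":
        return [w for w, r in scored if r >= value]
    raise ConfigError(f"unknown selection mode {mode!r}")


# ---------------------------------------------------------------------------
# Position weight matrix
# ---------------------------------------------------------------------------


@dataclass
class PWM:
    """Column-stochastic base-probability matrix with information content."""

    probs: np.ndarray  # shape (k, 4), columns over A,C,G,T
    information: np.ndarray  # bits per column, in [0, 2]

    @property
    def k(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(_BASES))
        df["information_bits"] = self.information
        df.index.name = "position"
        return df


def build_pwm(kmers: Sequence[str], weights: Optional[Sequence[float]] = None,
              pseudocount: float = 0.0) -> PWM:
    """Weighted position probability matrix from equal-length k-mers."""
    if not kmers:
        raise ConfigError("no k-mers given")
    k = len(kmers[0])
    if any(len(w) != k for w in kmers):
        raise ConfigError("k-mers have mixed lengths")
    if weights is None:
        weights = np.ones(len(kmers))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(kmers) or (weights < 0).any():
        raise ConfigError("bad weights")
    mat = np.zeros((k, 4))
    for w, wt in zip(kmers, weights):
        enc = encode(w)
        if (enc > 3).any():
            raise ConfigError(f"k-mer {w!r} not over ACGT")
        mat[np.arange(k), enc] += wt
    mat += pseudocount
    totals = mat.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ConfigError("zero total weight")
    probs = mat / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PWM(probs, np.clip(info, 0.0, 2.0))


# ---------------------------------------------------------------------------
# Genome composition and summary tables
# ---------------------------------------------------------------------------


def genome_trimer_depletion(genome: GenomeSeq,
                            trimer: str) -> tuple[float, float, float]:
    """Observed vs composition-expected frequency of a trimer, both strands.

    Expected frequency is the product of mononucleotide frequencies
    (order-0 background); the ratio observed/expected below 1 indicates
    genomic depletion (e.g. GCG loss through 5mC deamination).
    """
    if len(trimer) != 3 or set(trimer) - set(_BASES):
        raise ConfigError(f"bad trimer {trimer!r}")
    mono = np.zeros(4, dtype=np.int64)
    tri_count = 0
    total_windows = 0
    code = _kmer_code(trimer)
    for name, _seq in genome.items():
        enc = genome.encoded(name)
        for strand_enc in (enc, _rc_enc(enc)):
            valid = strand_enc[strand_enc < 4]
            mono += np.bincount(valid, minlength=4)
            codes, ok = _window_codes(strand_enc, 3)
            total_windows += int(ok.sum())
            tri_count += int((codes[ok] == code).sum())
    if total_windows == 0:
        raise UndefinedRatioError("no valid trimer windows")
    obs_freq = tri_count / total_windows
    f = mono / mono.sum()
    exp_freq = float(np.prod([f[int(c)] for c in encode(trimer)]))
    return obs_freq, exp_freq, obs_freq / exp_freq if exp_freq > 0 else math.inf


@dataclass
class FrequencySummary:
    """Methylation-fraction summary over calls that carry a fraction."""

    mod_class: str
    n: int
    exceeding: dict[float, float]  # threshold -> fraction of sites above it
    hist_counts: np.ndarray
    bin_edges: np.ndarray


def methylation_frequency_summary(mods: ModTable, mod_class: str,
                                  thresholds: Sequence[float] = (0.5, 0.8),
                                  pool: bool = False
                                  ) -> Optional[FrequencySummary]:
    """Fraction of sites whose methylation fraction exceeds each threshold.

    Only calls with a fraction present are used (absent is missing, not
    zero).  Returns None when no call of the class carries a fraction.
    """
    fracs = np.array([c.frac for c in mods.filter(mod_class, pool=pool)
                      if c.frac is not None])
    if len(fracs) == 0:
        return None
    exceeding = {float(t): float((fracs > t).mean()) for t in thresholds}
    edges = np.arange(0.0, 1.0 + 0.05, 0.05)
    counts, edges = np.histogram(fracs, bins=edges)
    return FrequencySummary(mod_class, len(fracs), exceeding, counts, edges)


def modification_rate_table(mods: ModTable, genome: GenomeSeq,
                            contexts: Sequence[tuple[str, int]] = (
                                ("A", 0), ("C", 0), ("CG", 0), ("GAG", 1),
                                ("GCG", 1)),
                            mod_classes: Optional[Sequence[str]] = None,
                            pool: bool = False) -> pd.DataFrame:
    """Per-context modification rates (modified / total occurrences).

    Contexts are (k-mer, offset of the called base); CpG is the 2-mer CG
    at offset 0, counted on each strand.  One row per (class, context).
    """
    if mod_classes is None:
        mod_classes = sorted({c.mod_class for c in mods})
    rows = []
    bg_cache: dict[tuple, KmerCountTable] = {}
    for mod_class in mod_classes:
        base = MOD_CLASS_BASE[mod_class]
        for kmer, offset in contexts:
            if not (0 <= offset < len(kmer)):
                raise ConfigError(f"bad offset for context {kmer!r}")
            if kmer[offset] != base:
                continue  # context not applicable to this class's base
            key = (len(kmer), base, offset)
            if key not in bg_cache:
                bg_cache[key] = background_kmer_counts(genome, *key)
            bg = bg_cache[key]
            n_occ = bg.counts.get(kmer, 0) if len(kmer) > 1 else bg.total
            obs = modified_kmer_counts(mods, genome, len(kmer), offset,
                                       mod_class, pool=pool)
            n_mod = obs.counts.get(kmer, 0) if len(kmer) > 1 else obs.total
            rate = n_mod / n_occ if n_occ > 0 else math.nan
            rows.append({"mod_class": mod_class, "context": kmer,
                         "offset": offset, "n_occurrences": n_occ,
                         "n_modified": n_mod, "rate": rate})
    return pd.DataFrame(rows)
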