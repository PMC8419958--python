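"""Seeded synthetic-data generator with complete ground truth.

Every generator is a pure function of (config, seed): the same inputs
produce byte-identical outputs.  The generator emulates the data shapes
the analyses consume — a gnat-sized AT-rich genome, motif-driven and
nucleosome-phased modification calls, haploid/diploid coverage mixtures,
sex-split expression tables, and per-6-mer nanopore event samples — and
records every planted call and label in a :class:`SimTruth` so recovery
tests can score against known truth.

The distributional choices (log-normal expression baselines, Beta
methylation fractions, negative-binomial depth) are test scaffolding:
they give each analysis stage realistic structure but are not estimates
from any real dataset.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_core import (
    MOD_CLASS_BASE,
    ConfigError,
    CoverageStep,
    CoverageTrack,
    EventTable,
    ExpressionTable,
    FeatureSet,
    GenomeSeq,
    Interval,
    KmerModel,
    ModCall,
    ModTable,
    encode,
    revcomp,
)

# ---------------------------------------------------------------------------
# Configuration records
# ---------------------------------------------------------------------------


@dataclass
class MotifSpec:
    """One motif to plant: e.g. GAGG with the A at offset 1 called as 6mA."""

    motif: str
    modified_offset: int
    mod_class: str
    per_site_probability: float
    frac_alpha: Optional[float] = None
    frac_beta: Optional[float] = None

    def __post_init__(self):
        if set(self.motif) - set("ACGT"):
            raise ConfigError(f"motif {self.motif!r} not over ACGT")
        if not (0 <= self.modified_offset < len(self.motif)):
            raise ConfigError("modified_offset outside motif")
        if not (0.0 <= self.per_site_probability <= 1.0):
            raise ConfigError("per_site_probability outside [0,1]")
        base = MOD_CLASS_BASE.get(self.mod_class)
        if base is None:
            raise ConfigError(f"unknown mod_class {self.mod_class!r}")
        if self.motif[self.modified_offset] != base:
            raise ConfigError(
                f"motif base {self.motif[self.modified_offset]!r} incompatible "
                f"with mod_class {self.mod_class}")
        if self.frac_alpha is None or self.frac_beta is None:
            # high-frequency mode for identified classes, broad for generic
            if self.mod_class in ("6mA", "4mC", "5mC"):
                self.frac_alpha, self.frac_beta = 8.0, 2.0
            else:
                self.frac_alpha, self.frac_beta = 2.0, 2.0


@dataclass
class PeriodicSpec:
    """Nucleosome-phased lattice of modification sites.

    Each array is a run of ``span_periods + 1`` lattice points spaced
    ``helical_period`` bp (both endpoints always called, interior points
    with ``fill_prob``); consecutive arrays are placed so the gap between
    the last call of one and the first of the next is
    ``nucleosome_repeat`` bp.  ``span_periods = 0`` gives one call per
    array, i.e. a pure nucleosome-repeat ladder.
    """

    helical_period: int = 10
    nucleosome_repeat: int = 175
    jitter_sd: float = 0.0
    span_periods: int = 16
    fill_prob: float = 0.5

    def __post_init__(self):
        if self.helical_period >= self.nucleosome_repeat:
            raise ConfigError("helical_period must be < nucleosome_repeat")
        if self.jitter_sd < 0 or not (0 <= self.fill_prob <= 1):
            raise ConfigError("bad periodic_spec")
        if self.span_periods < 0:
            raise ConfigError("span_periods must be >= 0")


@dataclass
class PloidySpec:
    haploid_depth: float = 20.0
    n_haploid_contigs: int = 10
    n_diploid_contigs: int = 40
    dispersion: float = math.inf  # NB size parameter; inf = Poisson

    def __post_init__(self):
        if self.haploid_depth <= 0:
            raise ConfigError("haploid_depth must be > 0")


@dataclass
class ExpressionSpec:
    n_genes: int = 2000
    x_fraction: float = 0.2
    compensated: bool = True
    biological_cv: float = 0.2
    baseline_meanlog: float = math.log(200.0)
    baseline_sdlog: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.x_fraction < 1.0):
            raise ConfigError("x_fraction must be in (0,1)")
        if self.biological_cv < 0:
            raise ConfigError("biological_cv must be >= 0")


@dataclass
class SignalSpec:
    shift: float = 2.0
    shifted_kmers: frozenset = frozenset()
    events_per_kmer: int = 200

    def __post_init__(self):
        if self.events_per_kmer < 1:
            raise ConfigError("events_per_kmer must be >= 1")
        self.shifted_kmers = frozenset(self.shifted_kmers)


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 1_000_000
    gc: float = 0.38
    n_contigs: int = 1
    motif_spec: Sequence[MotifSpec] = ()
    background_rate: float = 0.0
    periodic_spec: Optional[PeriodicSpec] = None
    n_arrays: int = 500
    ploidy_spec: PloidySpec = field(default_factory=PloidySpec)
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    signal_spec: SignalSpec = field(default_factory=SignalSpec)

    def __post_init__(self):
        if not (0.0 <= self.gc <= 1.0):
            raise ConfigError("gc outside [0,1]")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ConfigError("background_rate outside [0,1]")
        if self.genome_length < 1 or self.n_contigs < 1:
            raise ConfigError("genome_length and n_contigs must be >= 1")


@dataclass
class SimTruth:
    """Ground truth emitted by the generators.

    ``planted_calls`` records every call as
    (contig, pos, strand, mod_class, origin) with origin in
    {motif, background, periodic}.
    """

    planted_calls: list = field(default_factory=list)
    contig_ploidy: dict = field(default_factory=dict)
    gene_class: dict = field(default_factory=dict)
    shifted_kmers: set = field(default_factory=set)

    def to_json(self, path) -> None:
        obj = {
            "planted_calls": [list(t) for t in self.planted_calls],
            "contig_ploidy": self.contig_ploidy,
            "gene_class": self.gene_class,
            "shifted_kmers": sorted(self.shifted_kmers),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(planted_calls=[tuple(t) for t in obj["planted_calls"]],
                   contig_ploidy=obj["contig_ploidy"],
                   gene_class=obj["gene_class"],
                   shifted_kmers=set(obj["shifted_kmers"]))

    def merge(self, other: "SimTruth") -> "SimTruth":
        return SimTruth(self.planted_calls + other.planted_calls,
                        {**self.contig_ploidy, **other.contig_ploidy},
                        {**self.gene_class, **other.gene_class},
                        self.shifted_kmers | other.shifted_kmers)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def gen_genome(genome_length: int, gc: float = 0.38, n_contigs: int = 1,
               seed: int = 0) -> GenomeSeq:
    """i.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not (0.0 <= gc <= 1.0):
        raise ConfigError("gc outside [0,1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    per = genome_length // n_contigs
    sizes = [per] * n_contigs
    sizes[-1] += genome_length - per * n_contigs
    contigs = []
    for i, size in enumerate(sizes):
        codes = rng.choice(4, size=size, p=probs)
        contigs.append((f"contig_{i + 1}", alphabet[codes].tobytes().decode()))
    return GenomeSeq(contigs)


# ---------------------------------------------------------------------------
# Motif occurrence scanning (shared with analyses via simple helpers)
# ---------------------------------------------------------------------------


def _forward_occurrences(enc: np.ndarray, motif: str) -> np.ndarray:
    """Start positions of exact forward-strand motif matches."""
    m = encode(motif)
    L = len(m)
    if len(enc) < L:
        return np.empty(0, dtype=np.int64)
    hit = enc[: len(enc) - L + 1] == m[0]
    for j in range(1, L):
        hit &= enc[j: len(enc) - L + 1 + j] == m[j]
    return np.flatnonzero(hit).astype(np.int64)


def motif_call_sites(genome: GenomeSeq, motif: str,
                     modified_offset: int) -> list[tuple[str, int, str]]:
    """All (contig, pos, strand) sites where the motif's modified base sits.

    Both strands are scanned: a minus-strand occurrence is an occurrence
    of the motif's reverse complement on the forward axis, and yields a
    minus-strand call at the complementary base.
    """
    L = len(motif)
    sites = []
    for name, _seq in genome.items():
        enc = genome.encoded(name)
        for start in _forward_occurrences(enc, motif):
            sites.append((name, int(start) + modified_offset, "+"))
        for start in _forward_occurrences(enc, revcomp(motif)):
            sites.append((name, int(start) + (L - 1 - modified_offset), "-"))
    return sites


def eligible_positions(genome: GenomeSeq, base: str,
                       contig: str) -> dict[str, np.ndarray]:
    """Positions of ``base`` per strand on one contig (forward axis).

    On the minus strand the base sits opposite its complement, so minus
    eligibility is where the forward letter is the complement of ``base``.
    """
    enc = genome.encoded(contig)
    code = encode(base)[0]
    comp_code = 3 - code
    return {"+": np.flatnonzero(enc == code).astype(np.int64),
            "-": np.flatnonzero(enc == comp_code).astype(np.int64)}


# ---------------------------------------------------------------------------
# Planting modification calls
# ---------------------------------------------------------------------------


def plant_motif_mods(genome: GenomeSeq, motif_spec: Sequence[MotifSpec],
                     background_rate: float = 0.0,
                     seed: int = 0) -> tuple[ModTable, SimTruth]:
    """Plant motif-driven calls plus a uniform background of spurious calls.

    Each motif occurrence (either strand) is modified independently with
    its per-site probability; methylation fractions are Beta draws.
    Background calls land uniformly on eligible bases of the same class
    that are not already called.  Overlapping occurrences are collapsed to
    the ModTable uniqueness invariant (one call per site/strand/class).
    """
    rng = np.random.default_rng(seed)
    calls: dict[tuple, ModCall] = {}
    truth = SimTruth()

    for spec in motif_spec:
        base = MOD_CLASS_BASE[spec.mod_class]
        sites = motif_call_sites(genome, spec.motif, spec.modified_offset)
        take = rng.random(len(sites)) < spec.per_site_probability
        for (contig, pos, strand), t in zip(sites, take):
            if not t:
                continue
            key = (contig, pos, strand, spec.mod_class)
            if key in calls:
                continue
            frac = float(rng.beta(spec.frac_alpha, spec.frac_beta))
            calls[key] = ModCall(contig, pos, strand, base, spec.mod_class,
                                 coverage=25, score=50.0, frac=frac)
            truth.planted_calls.append((contig, pos, strand,
                                        spec.mod_class, "motif"))

    if background_rate > 0:
        classes = sorted({s.mod_class for s in motif_spec}) or ["6mA"]
        for mod_class in classes:
            base = MOD_CLASS_BASE[mod_class]
            a, b = (8.0, 2.0) if mod_class in ("6mA", "4mC", "5mC") else (2.0, 2.0)
            for contig, _ in genome.items():
                for strand, pos_arr in eligible_positions(genome, base,
                                                          contig).items():
                    hit = pos_arr[rng.random(len(pos_arr)) < background_rate]
                    for pos in hit:
                        key = (contig, int(pos), strand, mod_class)
                        if key in calls:
                            continue
                        frac = float(rng.beta(a, b))
                        calls[key] = ModCall(contig, int(pos), strand, base,
                                             mod_class, coverage=25,
                                             score=30.0, frac=frac)
                        truth.planted_calls.append(
                            (contig, int(pos), strand, mod_class, "background"))

    return ModTable(calls.values()), truth


def plant_periodic_mods(genome: GenomeSeq, periodic_spec: PeriodicSpec,
                        n_arrays: int, seed: int = 0,
                        mod_class: str = "6mA") -> tuple[ModTable, SimTruth]:
    """Plant nucleosome-phased calls on a helical lattice.

    Each array is a short run of sites at multiples of ``helical_period``
    (endpoints always called, interior points with ``fill_prob``), each
    position jittered by a rounded Gaussian; arrays are laid along each
    contig so that the gap from the last call of one array to the first
    of the next is ``nucleosome_repeat`` bp.  All calls are on the plus
    strand, and the genome base at each planted site is rewritten to the
    class's canonical base so the call set stays consistent with the
    sequence.
    """
    spec = periodic_spec
    rng = np.random.default_rng(seed)
    base = MOD_CLASS_BASE[mod_class]
    span = spec.span_periods * spec.helical_period
    stride = spec.nucleosome_repeat + span  # first-call-to-first-call
    margin = int(4 * spec.jitter_sd) + 2
    calls: dict[tuple, ModCall] = {}
    truth = SimTruth()
    placed = 0
    for contig, seq in genome.items():
        if placed >= n_arrays:
            break
        length = len(seq)
        anchor = margin
        if anchor + span + margin >= length:
            continue  # contig too short for one array
        while placed < n_arrays and anchor + span + margin < length:
            lattice = {0, spec.span_periods}
            lattice.update(k for k in range(1, spec.span_periods)
                           if rng.random() < spec.fill_prob)
            for k in sorted(lattice):
                pos = anchor + k * spec.helical_period
                if spec.jitter_sd > 0:
                    pos += int(round(rng.normal(0.0, spec.jitter_sd)))
                pos = min(max(pos, 0), length - 1)
                key = (contig, pos, "+", mod_class)
                if key in calls:
                    continue
                if genome.base_at(contig, pos, "+") != base:
                    genome.set_base(contig, pos, base)
                calls[key] = ModCall(contig, pos, "+", base, mod_class,
                                     coverage=25, score=50.0)
                truth.planted_calls.append((contig, pos, "+", mod_class,
                                            "periodic"))
            anchor += stride
            placed += 1
    return ModTable(calls.values()), truth


def background_rate_for_rate_ratio(genome: GenomeSeq, motif: str,
                                   modified_offset: int,
                                   per_site_probability: float,
                                   target_ratio: float,
                                   mod_class: str = "6mA") -> float:
    """Background rate b such that the expected k-mer/base rate ratio hits
    ``target_ratio`` when the motif is planted at ``per_site_probability``.

    With f the fraction of eligible bases sitting in motif context, the
    expected ratio is (p+b)/(f*p + b); solving for b gives
    b = p*(1 - target*f)/(target - 1).
    """
    base = MOD_CLASS_BASE[mod_class]
    n_motif = len(motif_call_sites(genome, motif, modified_offset))
    n_base = 0
    for contig, _ in genome.items():
        pos = eligible_positions(genome, base, contig)
        n_base += len(pos["+"]) + len(pos["-"])
    f = n_motif / n_base
    if target_ratio <= 1:
        raise ConfigError("target_ratio must exceed 1")
    b = per_site_probability * (1 - target_ratio * f) / (target_ratio - 1)
    if b < 0:
        raise ConfigError("target_ratio unreachable with this probability")
    return b


# ---------------------------------------------------------------------------
# Coverage, expression, events
# ---------------------------------------------------------------------------


def gen_coverage(contigs: Sequence[tuple[str, int]], ploidy_spec: PloidySpec,
                 window: int = 1000, seed: int = 0
                 ) -> tuple[CoverageTrack, SimTruth]:
    """Windowed depth: negative binomial around λ (haploid) or 2λ (diploid).

    ``contigs`` is a list of (name, length); the first
    ``n_haploid_contigs`` after a seeded shuffle are haploid.  Infinite
    dispersion gives the Poisson limit.
    """
    spec = ploidy_spec
    rng = np.random.default_rng(seed)
    names = [n for n, _ in contigs]
    if contigs and len(contigs) != spec.n_haploid_contigs + spec.n_diploid_contigs:
        raise ConfigError("contig count does not match ploidy_spec")
    order = rng.permutation(len(names))
    haploid = {names[i] for i in order[: spec.n_haploid_contigs]}
    steps, truth = [], SimTruth()
    for name, length in contigs:
        ploidy = "haploid" if name in haploid else "diploid"
        truth.contig_ploidy[name] = ploidy
        mean = spec.haploid_depth * (1 if ploidy == "haploid" else 2)
        starts = np.arange(0, length, window)
        n_win = len(starts)
        if math.isinf(spec.dispersion):
            depths = rng.poisson(mean, size=n_win)
        else:
            r = spec.dispersion
            depths = rng.negative_binomial(r, r / (r + mean), size=n_win)
        for s, d in zip(starts, depths):
            steps.append(CoverageStep(name, int(s), int(min(s + window, length)),
                                      float(d)))
    return CoverageTrack(steps), truth


def gen_expression(expression_spec: ExpressionSpec, seed: int = 0,
                   x_contig: str = "chrX", autosome_contig: str = "chr2"
                   ) -> tuple[ExpressionTable, SimTruth]:
    """Male/female abundances with optional loss of X dosage compensation.

    Baselines are log-normal; the female abundance is the baseline, the
    male abundance is the baseline — halved for X genes when compensation
    is off — times a log-normal noise term with median 1 and the
    configured biological CV.  In the uncompensated case the median X
    log2(male/female) ratio is therefore -1.
    """
    spec = expression_spec
    rng = np.random.default_rng(seed)
    n = spec.n_genes
    n_x = int(round(n * spec.x_fraction))
    is_x = np.zeros(n, dtype=bool)
    is_x[rng.permutation(n)[:n_x]] = True
    sigma = math.sqrt(math.log(1.0 + spec.biological_cv ** 2))
    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=n)
    noise_m = rng.lognormal(0.0, sigma, size=n) if sigma > 0 else np.ones(n)
    factor = np.where(is_x & (not spec.compensated), 0.5, 1.0)
    rows, truth = {}, SimTruth()
    for i in range(n):
        gene = f"gene_{i + 1:05d}"
        contig = x_contig if is_x[i] else autosome_contig
        rows[gene] = (float(baseline[i] * factor[i] * noise_m[i]),
                      float(baseline[i]), contig)
        truth.gene_class[gene] = "X" if is_x[i] else "autosomal"
    return ExpressionTable(rows), truth


def gen_pore_model(seed: int = 0) -> KmerModel:
    """Synthetic pore model over all 4096 6-mers (not a real pore model).

    Means are spread over a realistic ionic-current range (~60-120 pA)
    and per-k-mer sds over 1-2.5 pA, deterministically from the seed.
    """
    rng = np.random.default_rng(seed)
    kmers = ["".join(t) for t in itertools.product("ACGT", repeat=6)]
    means = rng.uniform(60.0, 120.0, size=len(kmers))
    sds = rng.uniform(1.0, 2.5, size=len(kmers))
    return KmerModel({k: (float(m), float(s))
                      for k, m, s in zip(kmers, means, sds)})


def kmers_containing(submotif: str, k: int = 6) -> frozenset:
    """All k-mers containing ``submotif`` at any offset."""
    out = set()
    for kmer in ("".join(t) for t in itertools.product("ACGT", repeat=k)):
        if submotif in kmer:
            out.add(kmer)
    return frozenset(out)


def gen_events(model: KmerModel, signal_spec: SignalSpec,
               seed: int = 0) -> tuple[EventTable, SimTruth]:
    """Sample event current means: N(mean, sd), +shift for shifted k-mers."""
    spec = signal_spec
    unknown = spec.shifted_kmers - set(model.table)
    if unknown:
        raise ConfigError(f"shifted k-mers not in model: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    table = {}
    for kmer in sorted(model.table):
        mean, sd = model[kmer]
        if kmer in spec.shifted_kmers:
            mean += spec.shift
        table[kmer] = rng.normal(mean, sd, size=spec.events_per_kmer)
    truth = SimTruth(shifted_kmers=set(spec.shifted_kmers))
    return EventTable(table), truth


# ---------------------------------------------------------------------------
# Feature annotation scaffolding
# ---------------------------------------------------------------------------


def gen_features(genome: GenomeSeq, gene_every: int = 5000,
                 gene_len: int = 2000, promoter_len: int = 500,
                 n_repeat_families: int = 5, repeats_per_family: int = 20,
                 repeat_len: int = 300, seed: int = 0) -> FeatureSet:
    """Simple gene/exon/intron/promoter/repeat annotation over a genome.

    Genes are tiled at a fixed spacing with a two-exon structure and a
    fixed upstream promoter; repeat copies from a few families are
    scattered in intergenic space.
    """
    rng = np.random.default_rng(seed)
    intervals = []
    gi = 0
    for contig, seq in genome.items():
        length = len(seq)
        start = promoter_len
        while start + gene_len < length:
            gi += 1
            gid = f"gene{gi:05d}"
            exon1 = gene_len // 3
            intron = gene_len // 3
            intervals.append(Interval(contig, start, start + gene_len, "+",
                                      "gene", gid))
            intervals.append(Interval(contig, start - promoter_len, start, "+",
                                      "promoter", f"{gid}_prom"))
            intervals.append(Interval(contig, start, start + exon1, "+",
                                      "exon", f"{gid}_e1"))
            intervals.append(Interval(contig, start + exon1,
                                      start + exon1 + intron, "+",
                                      "intron", f"{gid}_i1"))
            intervals.append(Interval(contig, start + exon1 + intron,
                                      start + gene_len, "+",
                                      "exon", f"{gid}_e2"))
            start += gene_every
        # intergenic repeats
        for fam in range(n_repeat_families):
            for rep in range(repeats_per_family):
                s = int(rng.integers(0, max(1, length - repeat_len)))
                intervals.append(Interval(contig, s, s + repeat_len, ".",
                                          "repeat",
                                          f"fam{fam + 1}:{contig}:{s}"))
    return FeatureSet(intervals)
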