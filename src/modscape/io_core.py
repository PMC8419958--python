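"""Domain types and format I/O shared by every analysis stage.

All internal coordinates are 0-based half-open; conversion to and from
1-based formats (GFF3) happens only at the parse/serialize boundary.
Strand-specific records carry the *canonical base on the called strand*:
for a minus-strand call the ``base`` field is the complement of the
forward-strand letter, computed once at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("modscape")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class ModscapeError(Exception):
    """Base class for all package errors."""


class FormatError(ModscapeError):
    """A file does not conform to its declared format."""


class ValidationError(ModscapeError):
    """Parsed data violate a domain invariant."""


class ConfigError(ModscapeError):
    """Invalid configuration or argument."""


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: base -> integer code used for vectorized k-mer work (N and ambiguity = 4)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

_IUPAC = set("ACGTNRYSWKMBDHV")
_AMBIG = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0, C=1, G=2, T=3, other=4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Modification-class vocabulary
# ---------------------------------------------------------------------------

#: canonical called-strand base for each modification class
MOD_CLASS_BASE = {"modA": "A", "6mA": "A", "modC": "C", "4mC": "C", "5mC": "C"}

#: generic classes pool their identified subclasses when requested
CLASS_POOL = {
    "modA": ("modA", "6mA"),
    "modC": ("modC", "4mC", "5mC"),
    "6mA": ("6mA",),
    "4mC": ("4mC",),
    "5mC": ("5mC",),
}

_GFF_TYPE_TO_CLASS = {"m6A": "6mA", "m4C": "4mC", "m5C": "5mC"}
_CLASS_TO_GFF_TYPE = {"6mA": "m6A", "4mC": "m4C", "5mC": "m5C",
                      "modA": "modified_base", "modC": "modified_base"}


# ---------------------------------------------------------------------------
# GenomeSeq
# ---------------------------------------------------------------------------


class GenomeSeq:
    """An ordered set of named contig sequences with a soft-mask track.

    Sequences are stored uppercase over {A,C,G,T,N}; the original
    lowercase (soft-masked) state is kept as a per-base boolean flag.
    """

    def __init__(self, contigs: Iterable[tuple[str, str]],
                 masks: Optional[dict[str, np.ndarray]] = None):
        self._seqs: dict[str, str] = {}
        self._masks: dict[str, np.ndarray] = {}
        self._enc_cache: dict[str, np.ndarray] = {}
        self.n_ambiguous = 0
        for name, seq in contigs:
            if not name:
                raise FormatError("empty contig name")
            if name in self._seqs:
                raise FormatError(f"duplicate contig name: {name!r}")
            if len(seq) == 0:
                raise FormatError(f"empty sequence for contig {name!r}")
            bad = set(seq.upper()) - _IUPAC
            if bad:
                raise FormatError(
                    f"non-IUPAC character(s) {sorted(bad)} in contig {name!r}")
            mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) >= ord("a")
            up = seq.upper()
            # ambiguity codes other than N carry no usable context; fold to N
            n_amb = sum(up.count(c) for c in _AMBIG)
            if n_amb:
                self.n_ambiguous += n_amb
                up = "".join("N" if c in _AMBIG else c for c in up)
            self._seqs[name] = up
            if masks is not None and name in masks:
                mask = np.asarray(masks[name], dtype=bool)
            self._masks[name] = mask

    # -- accessors ---------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def seq(self, name: str) -> str:
        return self._seqs[name]

    def mask(self, name: str) -> np.ndarray:
        return self._masks[name]

    def encoded(self, name: str) -> np.ndarray:
        """Cached uint8 encoding of a contig (A=0,C=1,G=2,T=3,N=4)."""
        enc = self._enc_cache.get(name)
        if enc is None:
            enc = encode(self._seqs[name])
            self._enc_cache[name] = enc
        return enc

    def base_at(self, contig: str, pos: int, strand: str = "+") -> str:
        """Strand-resolved base: the complement on the minus strand."""
        b = self._seqs[contig][pos]
        return b if strand == "+" else b.translate(_COMP)

    def set_base(self, contig: str, pos: int, base: str) -> None:
        """Overwrite one forward-strand base (used by synthetic planting)."""
        s = self._seqs[contig]
        self._seqs[contig] = s[:pos] + base + s[pos + 1:]
        self._enc_cache.pop(contig, None)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())


# ---------------------------------------------------------------------------
# ModCall / ModTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModCall:
    """One strand-specific per-base modification call (0-based pos)."""

    contig: str
    pos: int
    strand: str
    base: str
    mod_class: str
    coverage: int = 0
    score: float = 0.0
    frac: Optional[float] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        if self.mod_class not in MOD_CLASS_BASE:
            raise ValidationError(f"unknown mod_class {self.mod_class!r}")
        if self.base != MOD_CLASS_BASE[self.mod_class]:
            raise ValidationError(
                f"base {self.base!r} incompatible with class {self.mod_class}")
        if self.coverage < 0 or self.score < 0:
            raise ValidationError("negative coverage or score")
        if self.frac is not None and not (0.0 <= self.frac <= 1.0):
            raise ValidationError(f"frac {self.frac} outside [0,1]")

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.strand)


class ModTable:
    """Sorted, de-duplicated collection of :class:`ModCall` records."""

    def __init__(self, calls: Iterable[ModCall], dropped: Optional[dict] = None):
        calls = sorted(calls, key=lambda c: (c.contig, c.pos, c.strand, c.mod_class))
        seen = set()
        for c in calls:
            k = (c.contig, c.pos, c.strand, c.mod_class)
            if k in seen:
                raise ValidationError(f"duplicate call {k}")
            seen.add(k)
        self.calls: list[ModCall] = calls
        #: tallies of records dropped at parse/validate time, by reason
        self.dropped: dict[str, int] = dict(dropped or {})

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[ModCall]:
        return iter(self.calls)

    def filter(self, mod_class: str, pool: bool = False) -> "ModTable":
        """Calls of one class; ``pool=True`` lets modA/modC absorb subclasses."""
        if mod_class not in CLASS_POOL:
            raise ConfigError(f"unknown mod_class {mod_class!r}")
        classes = set(CLASS_POOL[mod_class]) if pool else {mod_class}
        return ModTable([c for c in self.calls if c.mod_class in classes],
                        dropped=self.dropped)

    def validate_against(self, genome: GenomeSeq) -> "ModTable":
        """Check coordinates and strand-resolved bases against a genome.

        Calls at N positions are dropped (context undefined); a base
        mismatch raises, since it indicates corrupted input.
        """
        kept, n_dropped = [], 0
        for c in self.calls:
            if c.contig not in genome:
                raise ValidationError(f"contig {c.contig!r} not in genome")
            if not (0 <= c.pos < genome.lengths[c.contig]):
                raise ValidationError(
                    f"pos {c.pos} outside contig {c.contig!r}")
            b = genome.base_at(c.contig, c.pos, c.strand)
            if b == "N":
                n_dropped += 1
                continue
            if b != c.base:
                raise ValidationError(
                    f"call base {c.base} != genome base {b} at "
                    f"{c.contig}:{c.pos}:{c.strand}")
            kept.append(c)
        dropped = dict(self.dropped)
        if n_dropped:
            dropped["n_base"] = dropped.get("n_base", 0) + n_dropped
            logger.warning("dropped %d call(s) at N bases", n_dropped)
        return ModTable(kept, dropped=dropped)

    def positions(self, contig: str, strand: Optional[str] = None) -> np.ndarray:
        """Sorted positions on one contig, optionally one strand."""
        pos = [c.pos for c in self.calls
               if c.contig == contig and (strand is None or c.strand == strand)]
        return np.asarray(sorted(pos), dtype=np.int64)


# ---------------------------------------------------------------------------
# FeatureSet / CoverageTrack / ExpressionTable / KmerModel / EventTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with a type label and id."""

    contig: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    feature_type: str
    id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.id!r}: start {self.start} >= end {self.end}")
        if self.strand not in "+-.":
            raise FormatError(f"bad strand {self.strand!r}")


class FeatureSet:
    """Flat list of typed intervals (gene/exon/intron/promoter/repeat...)."""

    def __init__(self, intervals: Iterable[Interval]):
        self.intervals = sorted(intervals,
                                key=lambda i: (i.contig, i.start, i.end, i.id))

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def of_type(self, feature_type: str) -> "FeatureSet":
        return FeatureSet([i for i in self.intervals
                           if i.feature_type == feature_type])

    def types(self) -> list[str]:
        return sorted({i.feature_type for i in self.intervals})

    def validate_against(self, genome: GenomeSeq) -> None:
        for iv in self.intervals:
            if iv.contig not in genome:
                raise ValidationError(f"contig {iv.contig!r} not in genome")
            if iv.end > genome.lengths[iv.contig]:
                raise ValidationError(
                    f"interval {iv.id!r} exceeds contig {iv.contig!r}")


@dataclass(frozen=True)
class CoverageStep:
    contig: str
    start: int
    end: int
    depth: float

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError("coverage step start >= end")
        if self.depth < 0:
            raise ValidationError("negative depth")


class CoverageTrack:
    """Per-contig step function of read depth (0-based half-open)."""

    def __init__(self, steps: Iterable[CoverageStep]):
        self.steps = sorted(steps, key=lambda s: (s.contig, s.start))
        prev: dict[str, int] = {}
        for s in self.steps:
            if s.start < prev.get(s.contig, 0):
                raise ValidationError(
                    f"overlapping coverage steps on {s.contig!r}")
            prev[s.contig] = s.end

    def __len__(self):
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def contig_steps(self, contig: str) -> list[CoverageStep]:
        return [s for s in self.steps if s.contig == contig]


class ExpressionTable:
    """Per-gene abundances for male and female samples, with contig of origin."""

    def __init__(self, rows: dict[str, tuple[float, float, str]]):
        for g, (m, f, _c) in rows.items():
            if not (np.isfinite(m) and np.isfinite(f)):
                raise ValidationError(f"non-finite abundance for {g!r}")
            if m < 0 or f < 0:
                raise ValidationError(f"negative abundance for {g!r}")
        self.rows = dict(rows)

    def __len__(self):
        return len(self.rows)

    def items(self):
        return self.rows.items()


class KmerModel:
    """Expected nanopore ionic current per 6-mer: (mean pA, sd pA)."""

    K = 6

    def __init__(self, table: dict[str, tuple[float, float]]):
        for kmer, (mean, sd) in table.items():
            if len(kmer) != self.K or set(kmer) - set("ACGT"):
                raise ValidationError(f"bad model k-mer {kmer!r}")
            if sd <= 0:
                raise ValidationError(f"sd <= 0 for {kmer!r}")
            if not (np.isfinite(mean) and np.isfinite(sd)):
                raise ValidationError(f"non-finite model row {kmer!r}")
        self.table = dict(table)

    def __len__(self):
        return len(self.table)

    def __contains__(self, kmer):
        return kmer in self.table

    def __getitem__(self, kmer):
        return self.table[kmer]


class EventTable:
    """Observed event current means per 6-mer."""

    def __init__(self, table: dict[str, Iterable[float]]):
        self.table = {}
        for kmer, vals in table.items():
            if len(kmer) != 6 or set(kmer) - set("ACGT"):
                raise ValidationError(f"bad event k-mer {kmer!r}")
            arr = np.asarray(list(vals), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite event for {kmer!r}")
            self.table[kmer] = arr

    def __len__(self):
        return len(self.table)

    def __contains__(self, kmer):
        return kmer in self.table

    def __getitem__(self, kmer):
        return self.table[kmer]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genome(path) -> GenomeSeq:
    """Read a FASTA genome; duplicate headers and non-IUPAC bases are errors."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSeq(records)


def write_genome(genome: GenomeSeq, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            mask = genome.mask(name)
            if mask.any():
                chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                chars[mask] += 32  # lowercase soft-masked bases
                seq = chars.tobytes().decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _parse_gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_modcalls(path, dialect: str = "kineticsTools",
                  genome: Optional[GenomeSeq] = None) -> ModTable:
    """Read per-base modification calls.

    ``kineticsTools`` dialect: GFF3 with feature types ``modified_base``,
    ``m6A``, ``m4C``, ``m5C``; 1-based coordinates are converted to
    0-based; ``modified_base`` records are assigned to modA/modC from the
    strand-resolved genome base (or the center of the ``context``
    attribute), and records at other bases are dropped with a logged count.
    ``tsv`` dialect: tab table ``contig pos strand base mod_class coverage
    score frac`` with 0-based positions.
    """
    calls: list[ModCall] = []
    dropped: dict[str, int] = {}

    def drop(reason: str):
        dropped[reason] = dropped.get(reason, 0) + 1

    if dialect == "kineticsTools":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                contig, _src, ftype, start, end, score, strand, _phase, attrs = cols
                if strand not in "+-":
                    raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
                if ftype not in ("modified_base", "m6A", "m4C", "m5C"):
                    drop("unknown_type")
                    continue
                pos = int(start) - 1
                if int(end) != int(start):
                    raise FormatError(f"{path}:{lineno}: multi-base mod record")
                a = _parse_gff_attrs(attrs)
                coverage = int(float(a.get("coverage", 0)))
                frac = float(a["frac"]) if "frac" in a else None
                if ftype in _GFF_TYPE_TO_CLASS:
                    mod_class = _GFF_TYPE_TO_CLASS[ftype]
                    base = MOD_CLASS_BASE[mod_class]
                else:
                    # modified_base: infer the called-strand base
                    if genome is not None:
                        if contig not in genome or not (
                                0 <= pos < genome.lengths[contig]):
                            raise ValidationError(
                                f"{path}:{lineno}: position outside genome")
                        base = genome.base_at(contig, pos, strand)
                    elif "context" in a:
                        ctx = a["context"]
                        base = ctx[len(ctx) // 2]
                    else:
                        drop("no_base_info")
                        continue
                    if base == "A":
                        mod_class = "modA"
                    elif base == "C":
                        mod_class = "modC"
                    else:
                        drop("non_AC_base")
                        continue
                calls.append(ModCall(contig, pos, strand, base, mod_class,
                                     coverage, float(score) if score != "." else 0.0,
                                     frac))
    elif dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["contig", "pos", "strand", "base", "mod_class",
                        "coverage", "score", "frac"]
            if header != expected:
                raise FormatError(f"{path}: bad TSV header {header}")
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                c = line.rstrip("\n").split("\t")
                if len(c) != 8:
                    raise FormatError(f"{path}:{lineno}: expected 8 columns")
                frac = float(c[7]) if c[7] not in ("", ".") else None
                calls.append(ModCall(c[0], int(c[1]), c[2], c[3], c[4],
                                     int(c[5]), float(c[6]), frac))
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")

    for reason, n in dropped.items():
        logger.info("read_modcalls: dropped %d record(s): %s", n, reason)
    table = ModTable(calls, dropped=dropped)
    if genome is not None:
        table = table.validate_against(genome)
    return table


def write_modcalls(table: ModTable, path, dialect: str = "kineticsTools") -> None:
    with open(path, "w") as fh:
        if dialect == "kineticsTools":
            fh.write("##gff-version 3\n")
            for c in table:
                ftype = _CLASS_TO_GFF_TYPE[c.mod_class]
                attrs = [f"coverage={c.coverage}", f"context={c.base}"]
                if c.frac is not None:
                    attrs.append(f"frac={c.frac!r}")
                fh.write("\t".join([c.contig, "modscape", ftype,
                                    str(c.pos + 1), str(c.pos + 1),
                                    repr(c.score), c.strand, ".",
                                    ";".join(attrs)]) + "\n")
        elif dialect == "tsv":
            fh.write("contig\tpos\tstrand\tbase\tmod_class\tcoverage\tscore\tfrac\n")
            for c in table:
                frac = repr(c.frac) if c.frac is not None else ""
                fh.write(f"{c.contig}\t{c.pos}\t{c.strand}\t{c.base}\t"
                         f"{c.mod_class}\t{c.coverage}\t{c.score!r}\t{frac}\n")
        else:
            raise ConfigError(f"unknown dialect {dialect!r}")


def read_intervals(path, fmt: Optional[str] = None,
                   default_type: str = "region") -> FeatureSet:
    """Read BED6 (0-based half-open) or GFF3 (1-based closed) intervals.

    GFF3 feature type comes from column 3 and the id from the ID/Name
    attribute; BED has no type column, so ``default_type`` is used.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if fmt == "bed":
                    contig, start, end = cols[0], int(cols[1]), int(cols[2])
                    name = cols[3] if len(cols) > 3 else f"feat{lineno}"
                    strand = cols[5] if len(cols) > 5 else "."
                    ftype = cols[6] if len(cols) > 6 else default_type
                    intervals.append(Interval(contig, start, end, strand,
                                              ftype, name))
                elif fmt == "gff3":
                    if len(cols) != 9:
                        raise FormatError("expected 9 GFF3 columns")
                    contig, _src, ftype, start, end, _score, strand, _ph, attrs = cols
                    a = _parse_gff_attrs(attrs)
                    fid = a.get("ID", a.get("Name", f"feat{lineno}"))
                    intervals.append(Interval(contig, int(start) - 1, int(end),
                                              strand if strand in "+-" else ".",
                                              ftype, fid))
                else:
                    raise ConfigError(f"unknown format {fmt!r}")
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return FeatureSet(intervals)


def write_intervals(features: FeatureSet, path, fmt: str = "bed") -> None:
    with open(path, "w") as fh:
        if fmt == "bed":
            for iv in features:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t"
                         f"{iv.strand}\t{iv.feature_type}\n")
        elif fmt == "gff3":
            fh.write("##gff-version 3\n")
            for iv in features:
                fh.write("\t".join([iv.contig, "modscape", iv.feature_type,
                                    str(iv.start + 1), str(iv.end), ".",
                                    iv.strand, ".", f"ID={iv.id}"]) + "\n")
        else:
            raise ConfigError(f"unknown format {fmt!r}")


def read_coverage(path) -> CoverageTrack:
    """Read a bedGraph file into a CoverageTrack."""
    steps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                steps.append(CoverageStep(cols[0], int(cols[1]), int(cols[2]),
                                          float(cols[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return CoverageTrack(steps)


def write_coverage(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for s in track:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{float(s.depth)!r}\n")


def read_expression(path) -> ExpressionTable:
    """Read a TSV ``gene_id male female contig`` expression table."""
    rows = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "male", "female", "contig"]:
            raise FormatError(f"{path}: bad header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            gene, male, female, contig = cols
            if gene in rows:
                raise ValidationError(f"{path}:{lineno}: duplicate gene {gene!r}")
            rows[gene] = (float(male), float(female), contig)
    return ExpressionTable(rows)


def write_expression(table: ExpressionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmale\tfemale\tcontig\n")
        for gene, (m, f, c) in table.items():
            fh.write(f"{gene}\t{float(m)!r}\t{float(f)!r}\t{c}\n")


def read_kmer_model(path) -> KmerModel:
    """Read a TSV pore model ``kmer mean sd``."""
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("kmer"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                table[cols[0]] = (float(cols[1]), float(cols[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return KmerModel(table)


def write_kmer_model(model: KmerModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tmean\tsd\n")
        for kmer in sorted(model.table):
            mean, sd = model.table[kmer]
            fh.write(f"{kmer}\t{float(mean)!r}\t{float(sd)!r}\n")


def read_events(path) -> EventTable:
    """Read a TSV event table ``kmer event_mean`` (one row per event)."""
    table: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("kmer"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                table.setdefault(cols[0], []).append(float(cols[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return EventTable(table)


def write_events(events: EventTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tevent_mean\n")
        for kmer in sorted(events.table):
            for v in events.table[kmer]:
                fh.write(f"{kmer}\t{float(v)!r}\n")
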