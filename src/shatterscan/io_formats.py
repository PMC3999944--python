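"""Input file formats, domain types and configuration.

Structural-variant calls arrive as simple tab-delimited tables, one
dialect per SV class:

``.spt``  translocations -- source chromosome, source start/end,
          destination chromosome, destination start/end, call quality.
``.spc``  copy-number variants -- chromosome, start, end, copy number,
          call quality.
``.spl``  loss-of-heterozygosity segments -- chromosome, start, end,
          call quality.

Short insertions are read from VCF (v4.0 or later); only CHROM, POS,
REF and ALT are used and only records where an ALT allele extends REF
as a prefix (a sequence insertion) are retained.

All coordinates are 1-based, fully closed intervals.  Chromosome labels
are matched after stripping an optional ``chr`` prefix, so ``chr8`` and
``8`` refer to the same chromosome.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "InputFormatError",
    "ConfigError",
    "GenomeModel",
    "TranslocationCall",
    "CNVCall",
    "LOHCall",
    "InsertionCall",
    "WeightConfig",
    "ScanConfig",
    "read_genome",
    "write_genome",
    "read_translocations",
    "read_cnvs",
    "read_loh",
    "read_insertions_vcf",
    "write_translocations",
    "write_cnvs",
    "write_loh",
    "write_insertions_vcf",
    "load_config",
    "write_config",
]


class InputFormatError(ValueError):
    """A malformed row or value in an input file (reported with its line)."""


class ConfigError(ValueError):
    """Invalid weight or scan configuration."""


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix from a chromosome label."""
    if label.lower().startswith("chr"):
        return label[3:]
    return label


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths: the coordinate frame.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs in the order they should
        be reported.  Names must be unique (after ``chr``-stripping) and
        lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        if not self.chromosomes:
            raise ValueError("genome model must contain at least one chromosome")
        index: dict[str, int] = {}
        for i, (name, length) in enumerate(self.chromosomes):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            key = normalize_chrom(name)
            if key in index:
                raise ValueError(f"duplicate chromosome label {name!r}")
            index[key] = i
        object.__setattr__(self, "_index", index)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __contains__(self, label: str) -> bool:
        return normalize_chrom(str(label)) in self._index  # type: ignore[attr-defined]

    def canonical(self, label: str) -> str:
        """Return the stored name for *label*, raising on unknown labels."""
        try:
            i = self._index[normalize_chrom(str(label))]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown chromosome {label!r}") from None
        return self.chromosomes[i][0]

    def length(self, label: str) -> int:
        return self.chromosomes[self.order(label)][1]

    def order(self, label: str) -> int:
        """Position of *label* in the genome ordering."""
        try:
            return self._index[normalize_chrom(str(label))]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown chromosome {label!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


def read_genome(path: str | Path) -> GenomeModel:
    """Read a two-column ``name<TAB>length`` chromosome table."""
    chroms: list[tuple[str, int]] = []
    for lineno, fields in _rows(path, 2):
        try:
            chroms.append((fields[0], int(fields[1])))
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: bad chromosome length {fields[1]!r}") from exc
    try:
        return GenomeModel(tuple(chroms))
    except ValueError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def write_genome(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# SV call records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranslocationCall:
    """A translocation between two chromosomes (or within one).

    ``src_start``..``src_end`` delimits the fragment on the source
    chromosome and ``dst_start``..``dst_end`` the matching fragment on
    the destination chromosome; each call therefore contributes four
    breakpoints.
    """

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    dst_end: int
    quality: float

    def __post_init__(self) -> None:
        if self.src_start > self.src_end:
            raise ValueError(f"source start {self.src_start} > end {self.src_end}")
        if self.dst_start > self.dst_end:
            raise ValueError(f"destination start {self.dst_start} > end {self.dst_end}")
        _check_quality(self.quality)


@dataclass(frozen=True)
class CNVCall:
    """A copy-number segment with its integer copy-number state."""

    chrom: str
    start: int
    end: int
    copy_number: int
    quality: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.copy_number < 0:
            raise ValueError(f"negative copy number {self.copy_number}")
        _check_quality(self.quality)


@dataclass(frozen=True)
class LOHCall:
    """A loss-of-heterozygosity segment."""

    chrom: str
    start: int
    end: int
    quality: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        _check_quality(self.quality)


@dataclass(frozen=True)
class InsertionCall:
    """A short sequence insertion at a single position."""

    chrom: str
    pos: int
    inserted_length: int

    def __post_init__(self) -> None:
        if self.inserted_length < 1:
            raise ValueError(f"inserted length must be >= 1, got {self.inserted_length}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


def _check_quality(q: float) -> None:
    if not (0.0 <= q <= 1.0) or math.isnan(q):
        raise ValueError(f"quality {q} outside [0, 1]")


# ---------------------------------------------------------------------------
# tab-delimited readers / writers
# ---------------------------------------------------------------------------

def _rows(path: str | Path, ncols: int) -> Iterator[tuple[int, list[str]]]:
    """Yield ``(lineno, fields)`` for data rows; '#' lines and blanks skipped."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise InputFormatError(
                    f"{path}:{lineno}: expected {ncols} tab-delimited columns, found {len(fields)}"
                )
            yield lineno, fields


def _parse_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise InputFormatError(f"{path}:{lineno}: non-integer {what} {value!r}") from None


def _parse_float(value: str, path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise InputFormatError(f"{path}:{lineno}: non-numeric {what} {value!r}") from None


def _canonical(label: str, genome: GenomeModel, path, lineno: int) -> str:
    try:
        return genome.canonical(label)
    except KeyError:
        raise InputFormatError(f"{path}:{lineno}: unknown chromosome {label!r}") from None


def read_translocations(
    path: str | Path, genome: GenomeModel, min_quality: float = 0.0
) -> list[TranslocationCall]:
    """Parse a 7-column ``.spt`` translocation file.

    Rows with quality below *min_quality* are excluded (and logged);
    any malformed row raises :class:`InputFormatError` with its line
    number.
    """
    calls: list[TranslocationCall] = []
    excluded = 0
    for lineno, f in _rows(path, 7):
        try:
            call = TranslocationCall(
                src_chrom=_canonical(f[0], genome, path, lineno),
                src_start=_parse_int(f[1], path, lineno, "source start"),
                src_end=_parse_int(f[2], path, lineno, "source end"),
                dst_chrom=_canonical(f[3], genome, path, lineno),
                dst_start=_parse_int(f[4], path, lineno, "destination start"),
                dst_end=_parse_int(f[5], path, lineno, "destination end"),
                quality=_parse_float(f[6], path, lineno, "quality"),
            )
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: {exc}") from None
        if call.quality < min_quality:
            excluded += 1
            logger.info("%s:%d: excluded translocation (quality %.3f < %.3f)",
                        path, lineno, call.quality, min_quality)
            continue
        calls.append(call)
    if excluded:
        logger.info("%s: excluded %d low-quality translocation calls", path, excluded)
    return calls


def read_cnvs(path: str | Path, genome: GenomeModel, min_quality: float = 0.0) -> list[CNVCall]:
    """Parse a 5-column ``.spc`` CNV file."""
    calls: list[CNVCall] = []
    excluded = 0
    for lineno, f in _rows(path, 5):
        try:
            call = CNVCall(
                chrom=_canonical(f[0], genome, path, lineno),
                start=_parse_int(f[1], path, lineno, "start"),
                end=_parse_int(f[2], path, lineno, "end"),
                copy_number=_parse_int(f[3], path, lineno, "copy number"),
                quality=_parse_float(f[4], path, lineno, "quality"),
            )
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: {exc}") from None
        if call.quality < min_quality:
            excluded += 1
            logger.info("%s:%d: excluded CNV (quality %.3f < %.3f)",
                        path, lineno, call.quality, min_quality)
            continue
        calls.append(call)
    if excluded:
        logger.info("%s: excluded %d low-quality CNV calls", path, excluded)
    return calls


def read_loh(path: str | Path, genome: GenomeModel, min_quality: float = 0.0) -> list[LOHCall]:
    """Parse a 4-column ``.spl`` LOH file."""
    calls: list[LOHCall] = []
    excluded = 0
    for lineno, f in _rows(path, 4):
        try:
            call = LOHCall(
                chrom=_canonical(f[0], genome, path, lineno),
                start=_parse_int(f[1], path, lineno, "start"),
                end=_parse_int(f[2], path, lineno, "end"),
                quality=_parse_float(f[3], path, lineno, "quality"),
            )
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: {exc}") from None
        if call.quality < min_quality:
            excluded += 1
            logger.info("%s:%d: excluded LOH (quality %.3f < %.3f)",
                        path, lineno, call.quality, min_quality)
            continue
        calls.append(call)
    if excluded:
        logger.info("%s: excluded %d low-quality LOH calls", path, excluded)
    return calls


def read_insertions_vcf(path: str | Path, genome: GenomeModel) -> list[InsertionCall]:
    """Extract short insertions from a VCF file.

    A record qualifies when an ALT allele is longer than REF and REF is
    a prefix of ALT; the inserted length is ``len(ALT) - len(REF)``.
    Multiallelic records contribute the first qualifying ALT allele
    only; all other records (SNVs, deletions, symbolic alleles) are
    ignored.
    """
    calls: list[InsertionCall] = []
    save = pysam.set_verbosity(0)  # silence undeclared-contig warnings
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                chrom = _canonical(rec.chrom, genome, path, "?")
                ref = rec.ref or ""
                for alt in rec.alts or ():
                    if alt is None or alt.startswith("<"):
                        continue
                    if len(alt) > len(ref) and alt.startswith(ref) and ref:
                        length = len(alt) - len(ref)
                        if rec.pos > genome.length(chrom):
                            raise InputFormatError(
                                f"{path}: insertion at {rec.chrom}:{rec.pos} beyond chromosome end"
                            )
                        calls.append(InsertionCall(chrom=chrom, pos=rec.pos, inserted_length=length))
                        break
    except (OSError, ValueError) as exc:
        if isinstance(exc, InputFormatError):
            raise
        raise InputFormatError(f"{path}: unparseable VCF ({exc})") from exc
    finally:
        pysam.set_verbosity(save)
    return calls


def write_translocations(calls: Iterable[TranslocationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.src_chrom}\t{c.src_start}\t{c.src_end}\t"
                     f"{c.dst_chrom}\t{c.dst_start}\t{c.dst_end}\t{c.quality:g}\n")


def write_cnvs(calls: Iterable[CNVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_number}\t{c.quality:g}\n")


def write_loh(calls: Iterable[LOHCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.quality:g}\n")


def write_insertions_vcf(
    calls: Iterable[InsertionCall], path: str | Path, genome: GenomeModel | None = None
) -> None:
    """Write insertions as minimal VCF v4.0 records (REF ``A``, ALT ``A`` + Ts)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.0\n")
        if genome is not None:
            for name, length in genome.chromosomes:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            alt = "A" + "T" * c.inserted_length
            fh.write(f"{c.chrom}\t{c.pos}\t.\tA\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Published hallmark weights derived by multi-criteria analysis.
DEFAULT_WEIGHTS = {
    "genome_localization": 0.1145,
    "chromosome_localization": 0.1697,
    "cnv": 0.2724,
    "translocation": 0.2724,
    "heterozygosity": 0.0648,
    "insertion": 0.0657,
    "tp53": 0.0406,
}

#: Names of the seven hallmarks, in reporting order.
HALLMARK_NAMES = tuple(DEFAULT_WEIGHTS)


@dataclass(frozen=True)
class WeightConfig:
    """The seven hallmark weights of the final weighted-sum score.

    Weights are non-negative and must sum to 1 within 0.001 (the
    published values are rounded to four decimals and literally sum to
    1.0001).
    """

    genome_localization: float = DEFAULT_WEIGHTS["genome_localization"]
    chromosome_localization: float = DEFAULT_WEIGHTS["chromosome_localization"]
    cnv: float = DEFAULT_WEIGHTS["cnv"]
    translocation: float = DEFAULT_WEIGHTS["translocation"]
    heterozygosity: float = DEFAULT_WEIGHTS["heterozygosity"]
    insertion: float = DEFAULT_WEIGHTS["insertion"]
    tp53: float = DEFAULT_WEIGHTS["tp53"]

    def __post_init__(self) -> None:
        for name in HALLMARK_NAMES:
            if getattr(self, name) < 0:
                raise ConfigError(f"weight {name} is negative")
        total = self.total
        if abs(total - 1.0) > 1e-3:
            raise ConfigError(f"hallmark weights sum to {total:.4f}, expected 1.000 +/- 0.001")

    @property
    def total(self) -> float:
        return sum(getattr(self, n) for n in HALLMARK_NAMES)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in HALLMARK_NAMES}


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds and sizes for the sliding-window scan and hallmark scores.

    Attributes
    ----------
    bin_size
        Width of a genome bin in bp.  Windows advance by one bin.
    window_size
        Window width in bins (default 10000 bins of 1000 bp = 10 Mbp).
    window_z_threshold
        A window is flagged when its breakpoint count is at least this
        many (population) standard deviations above the genome-wide
        window mean.
    significance_z_cutoff
        Values with a z-score above this cutoff count as significant
        when tallying copy-number states and translocation partners
        (default -2, dropping the low tail).
    outlier_z_cutoff
        Breakpoint separations with a z-score above this cutoff are
        dropped before computing the translocation spread (default 2,
        dropping the high tail).
    max_significant_partners
        If more than this many partner chromosomes share significant
        translocation counts with a region, the translocation score is 0.
    insertion_window
        Maximum distance in bp between a translocation breakpoint and a
        short insertion for the pair to count (inclusive).
    tp53_interval
        ``(chrom, start, end)`` of the TP53 locus used for annotation.
    normal_copy_number
        Baseline (diploid) copy-number state.
    min_quality
        Calls with quality below this are excluded at read time.
    call_threshold
        Final scores above this mark a region as a chromothripsis call.
    """

    bin_size: int = 1000
    window_size: int = 10_000
    window_z_threshold: float = 2.0
    significance_z_cutoff: float = -2.0
    outlier_z_cutoff: float = 2.0
    max_significant_partners: int = 8
    insertion_window: int = 10
    tp53_interval: tuple[str, int, int] = ("17", 7_570_000, 7_590_000)
    normal_copy_number: int = 2
    min_quality: float = 0.0
    call_threshold: float = 0.37

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ConfigError(f"bin_size must be >= 1, got {self.bin_size}")
        if self.window_size < 1:
            raise ConfigError(f"window_size must be >= 1, got {self.window_size}")
        if self.insertion_window < 0:
            raise ConfigError(f"insertion_window must be >= 0, got {self.insertion_window}")
        object.__setattr__(self, "tp53_interval", (str(self.tp53_interval[0]),
                                                   int(self.tp53_interval[1]),
                                                   int(self.tp53_interval[2])))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tp53_interval"] = list(self.tp53_interval)
        return d


def load_config(path: str | Path | None = None) -> tuple[WeightConfig, ScanConfig]:
    """Load ``weights:`` and ``scan:`` sections from a YAML file.

    Missing file or missing keys fall back to the defaults.
    """
    if path is None:
        return WeightConfig(), ScanConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a YAML mapping")
    wraw = raw.get("weights", {}) or {}
    sraw = dict(raw.get("scan", {}) or {})
    unknown = set(wraw) - set(HALLMARK_NAMES)
    if unknown:
        raise ConfigError(f"{path}: unknown weight names {sorted(unknown)}")
    allowed = {f.name for f in dataclasses.fields(ScanConfig)}
    unknown = set(sraw) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown scan options {sorted(unknown)}")
    if "tp53_interval" in sraw:
        sraw["tp53_interval"] = tuple(sraw["tp53_interval"])
    try:
        return WeightConfig(**wraw), ScanConfig(**sraw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_config(weights: WeightConfig, scan: ScanConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"weights": weights.as_dict(), "scan": scan.as_dict()},
                       fh, sort_keys=False)
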