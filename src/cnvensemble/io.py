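"""Readers and writers for caller-specific VCF/BED dialects.

Each supported caller emits structural-variant VCF with its own field
conventions; a :class:`DialectSpec` declares where the svtype, the end
coordinate, read-support counts, the adjusted p value and the genotype
live.  Readers normalize everything into :class:`~cnvensemble.model.CallSet`
objects (0-based half-open coordinates, ``chr`` prefix stripped) and
count records they skip (non-DEL/DUP types, unresolvable ends,
sub-minimum sizes).

Coordinate convention for symbolic SV records: internal
``start = POS`` and ``end = INFO/END`` (VCF POS is the base before the
event, so the affected bases are the 0-based half-open ``[POS, END)``),
giving ``length = END - POS``.  Writing inverts this exactly.

Support fractions for Delly-style records are computed as
``DV/(DV+DR)`` (paired-end) and ``RV/(RV+RR)`` (split-read); Manta-style
``PR``/``SR`` carry (ref, alt) count pairs and are converted the same
way.  When the reference-support count is absent the fraction is left
unset rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable

from cyvcf2 import VCF

from .exceptions import ConfigError, InputError
from .model import (
    DEFAULT_MIN_SIZE,
    CallSet,
    CnvCall,
    Genotype,
    GenomicInterval,
    SignalClass,
    SvType,
    Track,
    TrackRecord,
    normalize_chrom,
)

log = logging.getLogger(__name__)

# INFO keys used by the normalized VCF this package writes.
_INFO_CALLERS = "CALLERS"
_INFO_SRC = "SRC"
_INFO_PEF = "PEF"
_INFO_SRF = "SRF"
_INFO_PADJ = "PADJ"


@dataclass(frozen=True)
class DialectSpec:
    """Field mapping for one caller's VCF flavour.

    ``support_style`` selects how read support is extracted:

    - ``"delly"`` — FORMAT scalars DV/DR (discordant pairs) and RV/RR
      (split reads); fractions are alt/(alt+ref).
    - ``"manta"`` — FORMAT pairs PR/SR holding (ref, alt) counts.
    - ``"info"`` — precomputed fractions in INFO keys PEF/SRF.
    - ``None`` — no support information.

    ``adjusted_p_keys`` are INFO keys tried in order for the
    coverage-caller adjusted p value.
    """

    id: str
    signal_class: SignalClass = SignalClass.PAIRED_END
    support_style: str | None = None
    adjusted_p_keys: tuple[str, ...] = ()
    read_genotype: bool = True
    read_provenance: bool = False


DIALECTS: dict[str, DialectSpec] = {
    "delly": DialectSpec("delly", SignalClass.PAIRED_END, support_style="delly"),
    "manta": DialectSpec("manta", SignalClass.PAIRED_END, support_style="manta"),
    "cnvnator": DialectSpec(
        "cnvnator",
        SignalClass.COVERAGE,
        adjusted_p_keys=("natorP2", _INFO_PADJ),
        read_genotype=False,
    ),
    "erds": DialectSpec("erds", SignalClass.COVERAGE, read_genotype=False),
    "generic": DialectSpec(
        "generic",
        SignalClass.PAIRED_END,
        support_style="info",
        adjusted_p_keys=(_INFO_PADJ,),
        read_provenance=True,
    ),
}


@dataclass
class ReadReport:
    """Bookkeeping for one parse: accepted and skipped record counts."""

    path: str
    n_records: int = 0
    n_accepted: int = 0
    skipped: dict[str, int] = dc_field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def _svtype_of(variant) -> str | None:
    svtype = variant.INFO.get("SVTYPE")
    if svtype is None:
        alt = variant.ALT[0] if variant.ALT else ""
        if alt.startswith("<") and alt.endswith(">"):
            svtype = alt[1:-1]
    return svtype


def _end_of(variant) -> int | None:
    end = variant.INFO.get("END")
    if end is not None:
        return int(end)
    svlen = variant.INFO.get("SVLEN")
    if svlen is not None:
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        return variant.POS + abs(int(svlen))
    return None


def _fmt_scalar(variant, key: str, sidx: int) -> float | None:
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    v = arr[sidx]
    try:
        v = float(v[0]) if hasattr(v, "__len__") else float(v)
    except (TypeError, ValueError):
        return None
    if v < 0:  # cyvcf2 encodes missing ints as negative sentinels
        return None
    return v


def _fmt_pair(variant, key: str, sidx: int) -> tuple[float, float] | None:
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    row = arr[sidx]
    if not hasattr(row, "__len__") or len(row) < 2:
        return None
    ref, alt = float(row[0]), float(row[1])
    if ref < 0 or alt < 0:
        return None
    return ref, alt


def _fraction(alt: float | None, ref: float | None) -> float | None:
    if alt is None or ref is None or alt + ref <= 0:
        return None
    return alt / (alt + ref)


def _support_fields(variant, dialect: DialectSpec, sidx: int | None):
    pe = sr = None
    if dialect.support_style == "delly" and sidx is not None:
        pe = _fraction(_fmt_scalar(variant, "DV", sidx), _fmt_scalar(variant, "DR", sidx))
        sr = _fraction(_fmt_scalar(variant, "RV", sidx), _fmt_scalar(variant, "RR", sidx))
    elif dialect.support_style == "manta" and sidx is not None:
        pr = _fmt_pair(variant, "PR", sidx)
        srp = _fmt_pair(variant, "SR", sidx)
        pe = _fraction(pr[1], pr[0]) if pr else None
        sr = _fraction(srp[1], srp[0]) if srp else None
    elif dialect.support_style == "info":
        pe = variant.INFO.get(_INFO_PEF)
        sr = variant.INFO.get(_INFO_SRF)
        pe = float(pe) if pe is not None else None
        sr = float(sr) if sr is not None else None
    return pe, sr


def _genotype_of(variant, sidx: int) -> Genotype:
    alleles = variant.genotypes[sidx][:-1]
    if not alleles or any(a is None or a < 0 for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a > 0)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def _parse_sources(raw: str, chrom_style: str):
    out = []
    for entry in str(raw).split(","):
        caller, chrom, start, end = entry.split("|")
        out.append(
            (caller, GenomicInterval(normalize_chrom(chrom, chrom_style), int(start), int(end)))
        )
    return tuple(out)


def read_caller_vcf(
    path: str | Path,
    dialect: DialectSpec | str,
    sample: str | None = None,
    strict: bool = False,
    min_size: int = DEFAULT_MIN_SIZE,
    chrom_style: str = "strip",
) -> tuple[CallSet, ReadReport]:
    """Read one caller's VCF into a normalized CallSet.

    Only DEL and DUP records are kept; other SVTYPEs, records without a
    resolvable end and sub-``min_size`` events are skipped and counted
    (or abort the parse under ``strict``).
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ConfigError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    report = ReadReport(str(path))
    vcf = VCF(str(path))
    sidx: int | None = None
    if vcf.samples:
        if sample is not None:
            if sample not in vcf.samples:
                raise InputError(
                    f"sample {sample!r} absent from {path} (has {vcf.samples})"
                )
            sidx = vcf.samples.index(sample)
        elif len(vcf.samples) == 1:
            sidx = 0
    elif sample is None:
        sample = "unknown"

    calls: list[CnvCall] = []
    for variant in vcf:
        report.n_records += 1
        svtype = _svtype_of(variant)
        if svtype not in ("DEL", "DUP"):
            report.skip(f"svtype:{svtype}")
            continue
        end = _end_of(variant)
        if end is None:
            if strict:
                raise InputError(
                    f"{path}: record {variant.CHROM}:{variant.POS} has no END/SVLEN"
                )
            report.skip("no-end")
            continue
        start = variant.POS  # POS is the base before the event
        if end <= start:
            if strict:
                raise InputError(f"{path}: record {variant.CHROM}:{variant.POS} END <= POS")
            report.skip("bad-end")
            continue
        iv = GenomicInterval(normalize_chrom(variant.CHROM, chrom_style), start, end)
        if iv.length < min_size:
            report.skip("below-min-size")
            continue
        pe, sr = _support_fields(variant, dialect, sidx)
        adjusted_p = None
        for key in dialect.adjusted_p_keys:
            v = variant.INFO.get(key)
            if v is not None:
                adjusted_p = min(1.0, max(0.0, float(v)))
                break
        genotype = None
        if dialect.read_genotype and sidx is not None:
            genotype = _genotype_of(variant, sidx)
        sources: tuple = ()
        if dialect.read_provenance:
            raw = variant.INFO.get(_INFO_SRC)
            if raw is not None:
                sources = _parse_sources(raw, chrom_style)
        call = CnvCall(
            interval=iv,
            svtype=SvType(svtype),
            caller=dialect.id,
            sample=sample or (vcf.samples[sidx] if sidx is not None else "unknown"),
            pe_support_fraction=pe,
            sr_support_fraction=sr,
            adjusted_p=adjusted_p,
            genotype=genotype,
            sources=sources,
            id=variant.ID or "",
        )
        calls.append(call)
        report.n_accepted += 1
    if report.n_skipped:
        log.info("%s: skipped %d/%d records: %s", path, report.n_skipped,
                 report.n_records, report.skipped)
    sample_id = sample if sample is not None else (vcf.samples[sidx] if sidx is not None else "unknown")
    return CallSet.build(sample_id, dialect.id, calls), report


def read_bed_calls(
    path: str | Path,
    svtype_column: int | None = 3,
    sample: str = "unknown",
    origin: str = "bed",
    min_size: int = DEFAULT_MIN_SIZE,
    chrom_style: str = "strip",
) -> CallSet:
    """Read a BED3+ file (0-based half-open) of CNV calls.

    Column ``svtype_column`` (0-based index, default 3) must hold DEL or
    DUP; pass ``None`` for plain interval tracks read via
    :func:`read_track`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    calls: list[CnvCall] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise InputError(f"{path}:{lineno}: fewer than 3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-numeric coordinates")
        if end <= start:
            raise InputError(f"{path}:{lineno}: end <= start")
        svtype = SvType.DEL
        if svtype_column is not None:
            if len(cols) <= svtype_column:
                raise InputError(f"{path}:{lineno}: missing svtype column {svtype_column}")
            try:
                svtype = SvType(cols[svtype_column])
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: svtype must be DEL or DUP, got {cols[svtype_column]!r}"
                )
        iv = GenomicInterval(normalize_chrom(cols[0], chrom_style), start, end)
        calls.append(
            CnvCall(iv, svtype, origin, sample).validate_size(min_size)
        )
    return CallSet.build(sample, origin, calls)


def read_track(
    path: str | Path,
    name: str | None = None,
    chrom_style: str = "strip",
) -> Track:
    """Read a plain BED3+ interval track (blacklist, exons, repeats...)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise InputError(f"{path}:{lineno}: fewer than 3 columns")
        try:
            iv = GenomicInterval(normalize_chrom(cols[0], chrom_style), int(cols[1]), int(cols[2]))
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-numeric coordinates")
        records.append(TrackRecord(iv, name=cols[3] if len(cols) > 3 else None))
    return Track(records, name=name or path.stem)


def _max_af(value) -> float:
    # multi-allelic AF: keep the maximal component (matches the
    # "maximal allele frequency of overlaps" usage downstream)
    if isinstance(value, (tuple, list)):
        return float(max(value))
    if isinstance(value, str) and "," in value:
        return max(float(x) for x in value.split(","))
    return float(value)


def read_population_sv(
    path: str | Path,
    af_field: str | int = "AF",
    chrom_style: str = "strip",
) -> Track:
    """Read a population SV reference (gnomAD-SV style) with allele frequencies.

    VCF input: ``af_field`` is an INFO key (list-valued AF collapses to
    its maximum).  BED/TSV input: ``af_field`` is a 0-based column index
    (default column 4, after chrom/start/end/svtype).  Records without
    AF keep ``af=None``; if *no* record carries the field the
    configuration is considered wrong and a hard error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records: list[TrackRecord] = []
    n_af = 0
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        key = af_field if isinstance(af_field, str) else "AF"
        for variant in VCF(str(path)):
            svtype = _svtype_of(variant)
            if svtype not in ("DEL", "DUP"):
                continue
            end = _end_of(variant)
            if end is None or end <= variant.POS:
                continue
            raw = variant.INFO.get(key)
            af = None
            if raw is not None:
                af = _max_af(raw)
                n_af += 1
            records.append(
                TrackRecord(
                    GenomicInterval(normalize_chrom(variant.CHROM, chrom_style), variant.POS, end),
                    svtype=SvType(svtype),
                    af=af,
                )
            )
    else:
        col = af_field if isinstance(af_field, int) else 4
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise InputError(f"{path}:{lineno}: need chrom/start/end/svtype columns")
            try:
                iv = GenomicInterval(
                    normalize_chrom(cols[0], chrom_style), int(cols[1]), int(cols[2])
                )
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric coordinates")
            af = None
            if len(cols) > col and cols[col] not in (".", ""):
                af = _max_af(cols[col])
                n_af += 1
            records.append(TrackRecord(iv, svtype=SvType(cols[3]), af=af))
    if records and n_af == 0:
        raise InputError(
            f"{path}: AF field {af_field!r} present in no record — misconfigured reference"
        )
    return Track(records, name=path.stem)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=cnvensemble
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID={callers},Number=.,Type=String,Description="Callers supporting this record">
##INFO=<ID={src},Number=.,Type=String,Description="Source calls as caller|chrom|start|end">
##INFO=<ID={pef},Number=1,Type=Float,Description="Paired-end support fraction">
##INFO=<ID={srf},Number=1,Type=Float,Description="Split-read support fraction">
##INFO=<ID={padj},Number=1,Type=Float,Description="Adjusted p value">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _contig_lines(calls: Iterable[CnvCall]) -> list[str]:
    maxend: dict[str, int] = {}
    for c in calls:
        maxend[c.interval.chrom] = max(maxend.get(c.interval.chrom, 0), c.interval.end)
    return [f"##contig=<ID={chrom},length={end + 1}>" for chrom, end in sorted(maxend.items())]


def write_callset(
    calls: CallSet,
    path: str | Path,
    format: str = "vcf",
) -> Path:
    """Write a CallSet as VCF, BED or TSV.

    VCF is the lossless round-trip format: symbolic ALTs, INFO
    SVTYPE/END plus provenance (CALLERS, SRC) and quality fields; read
    back with the ``generic`` dialect it reproduces intervals, svtypes
    and provenance exactly.  A GT column is emitted only when some call
    carries a genotype; calls without one are then written as ``./.``
    and read back as the explicit MISSING genotype.  BED/TSV are documented lossy projections
    (BED: chrom, start, end, svtype, id, callers).
    """
    path = Path(path)
    format = format.lower()
    if format == "vcf":
        has_gt = any(c.genotype is not None for c in calls)
        lines = [_VCF_HEADER.format(
            callers=_INFO_CALLERS, src=_INFO_SRC, pef=_INFO_PEF, srf=_INFO_SRF, padj=_INFO_PADJ
        ).rstrip("\n")]
        lines.extend(_contig_lines(calls))
        header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if has_gt:
            header_cols += ["FORMAT", calls.sample]
        lines.append("\t".join(header_cols))
        for c in calls:
            iv = c.interval
            info = [
                f"SVTYPE={c.svtype.value}",
                f"END={iv.end}",
                f"SVLEN={-iv.length if c.svtype is SvType.DEL else iv.length}",
                f"{_INFO_CALLERS}={','.join(c.source_callers)}",
                f"{_INFO_SRC}="
                + ",".join(
                    f"{caller}|{s.chrom}|{s.start}|{s.end}" for caller, s in c.sources
                ),
            ]
            if c.pe_support_fraction is not None:
                info.append(f"{_INFO_PEF}={c.pe_support_fraction:.6g}")
            if c.sr_support_fraction is not None:
                info.append(f"{_INFO_SRF}={c.sr_support_fraction:.6g}")
            if c.adjusted_p is not None:
                info.append(f"{_INFO_PADJ}={c.adjusted_p:.6g}")
            row = [
                iv.chrom,
                str(iv.start),  # internal start == VCF POS
                c.id,
                "N",
                f"<{c.svtype.value}>",
                ".",
                "PASS",
                ";".join(info),
            ]
            if has_gt:
                row += ["GT", _GT_STRING[c.genotype or Genotype.MISSING]]
            lines.append("\t".join(row))
        path.write_text("\n".join(lines) + "\n")
    elif format == "bed":
        rows = [
            "\t".join(
                [
                    c.interval.chrom,
                    str(c.interval.start),
                    str(c.interval.end),
                    c.svtype.value,
                    c.id,
                    ",".join(c.source_callers),
                ]
            )
            for c in calls
        ]
        path.write_text("\n".join(rows) + ("\n" if rows else ""))
    elif format == "tsv":
        header = "\t".join(
            [
                "chrom", "start", "end", "id", "svtype", "caller", "sample",
                "pe_support_fraction", "sr_support_fraction", "adjusted_p",
                "genotype", "callers",
            ]
        )
        rows = [header]
        for c in calls:
            rows.append(
                "\t".join(
                    [
                        c.interval.chrom,
                        str(c.interval.start),
                        str(c.interval.end),
                        c.id,
                        c.svtype.value,
                        c.caller,
                        c.sample,
                        "" if c.pe_support_fraction is None else f"{c.pe_support_fraction:.6g}",
                        "" if c.sr_support_fraction is None else f"{c.sr_support_fraction:.6g}",
                        "" if c.adjusted_p is None else f"{c.adjusted_p:.6g}",
                        "" if c.genotype is None else c.genotype.value,
                        ",".join(c.source_callers),
                    ]
                )
            )
        path.write_text("\n".join(rows) + "\n")
    else:
        raise ConfigError(f"unknown output format {format!r} (vcf, bed, tsv)")
    return path
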