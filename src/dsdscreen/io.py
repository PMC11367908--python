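"""Readers and writers for the pipeline's file formats.

Small variants travel as VCF v4.x (annotation in the reserved INFO keys
``GENE``/``REGION``/``EFFECT``, genotypes in per-sample ``GT`` fields) or as a
headered TSV dialect; structural variants as a headered TSV or BEDPE.  All
tabular dialects round-trip: ``read(write(records)) == records``.

Genotype conventions on VCF read: ``0/0`` maps to ``absent``, ``./.`` to
``no_call``, any mix of reference and alternate alleles to ``het`` and an
all-alternate genotype to ``hom``.  Multi-allelic rows are split into one
record per alternate allele before keying, each inheriting the annotation.
TSV genotype codes are ``.`` (absent), ``het``, ``hom`` and ``nc`` (no call).

BEDPE coordinates (0-based half-open breakpoint intervals) are converted to
the package's 1-based inclusive convention on read and back on write.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .model import (
    AnnotatedSNV,
    Effect,
    GenePanel,
    GenotypeCall,
    Region,
    SVRecord,
    SVType,
)

__all__ = [
    "read_snv_table",
    "write_snv_table",
    "read_sv_table",
    "write_sv_table",
    "read_gene_panel",
]

logger = logging.getLogger(__name__)

_SNV_FIXED_COLS = ["chrom", "pos", "ref", "alt", "gene", "region", "effect"]
_SV_FIXED_COLS = ["sv_id", "type", "chrom", "start", "end", "genes"]

_TSV_GT = {
    ".": GenotypeCall.ABSENT,
    "het": GenotypeCall.HET,
    "hom": GenotypeCall.HOM,
    "nc": GenotypeCall.NO_CALL,
}
_GT_TSV = {v: k for k, v in _TSV_GT.items()}


def _parse_effect(text: str, where: str) -> Effect:
    try:
        return Effect(text)
    except ValueError:
        logger.warning("unknown effect %r at %s; recording effect=unknown", text, where)
        return Effect.UNKNOWN


def _parse_region(text: str, where: str) -> Region:
    try:
        return Region(text)
    except ValueError:
        logger.warning("unknown region %r at %s; recording region=other", text, where)
        return Region.OTHER


# ---------------------------------------------------------------------------
# small variants
# ---------------------------------------------------------------------------

def read_snv_table(
    path: str | Path,
    dialect: str = "tsv",
    samples: Sequence[str] | None = None,
) -> list[AnnotatedSNV]:
    """Read annotated small variants from ``path``.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` (headered TSV, columns ``chrom pos ref alt gene region
        effect <sample>...``) or ``"vcf"``.
    samples
        If given, the file's sample columns must be exactly this set;
        an unexpected sample column raises ``ValueError``.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_snv_tsv(path, samples)
    if dialect == "vcf":
        return _read_snv_vcf(path, samples)
    raise ValueError(f"unknown SNV dialect {dialect!r}")


def _read_snv_tsv(path: Path, samples: Sequence[str] | None) -> list[AnnotatedSNV]:
    records: list[AnnotatedSNV] = []
    with open(path, newline="") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file (header line required)")
        if header[: len(_SNV_FIXED_COLS)] != _SNV_FIXED_COLS:
            raise ValueError(
                f"{path}: header must start with {_SNV_FIXED_COLS}, got {header}"
            )
        sample_ids = header[len(_SNV_FIXED_COLS):]
        if samples is not None and set(sample_ids) != set(samples):
            unknown = set(sample_ids) - set(samples)
            raise ValueError(f"{path}: unexpected sample column(s) {sorted(unknown)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            where = f"{path}:{lineno}"
            try:
                genotypes = {}
                for sid, code in zip(sample_ids, row[len(_SNV_FIXED_COLS):]):
                    if code not in _TSV_GT:
                        raise ValueError(f"unknown genotype code {code!r}")
                    genotypes[sid] = _TSV_GT[code]
                rec = AnnotatedSNV(
                    chrom=row[0],
                    pos=int(row[1]),
                    ref=row[2],
                    alt=row[3],
                    gene=row[4].upper(),
                    region=_parse_region(row[5], where),
                    effect=_parse_effect(row[6], where),
                    genotypes=genotypes,
                )
            except ValueError as exc:
                raise ValueError(f"{where}: malformed row: {exc}") from exc
            records.append(rec)
    return records


def _split_gt(gt: tuple | None, alt_index: int) -> GenotypeCall:
    """Zygosity of one sample for one alternate allele of a (possibly
    multi-allelic) VCF row.  ``alt_index`` is 1-based over ALT alleles."""
    if gt is None or any(a is None for a in gt):
        return GenotypeCall.NO_CALL
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 0:
        return GenotypeCall.ABSENT
    if n_alt == len(gt):
        return GenotypeCall.HOM
    return GenotypeCall.HET


def _read_snv_vcf(path: Path, samples: Sequence[str] | None) -> list[AnnotatedSNV]:
    records: list[AnnotatedSNV] = []
    with pysam.VariantFile(str(path)) as vcf:
        file_samples = list(vcf.header.samples)
        if samples is not None and set(file_samples) != set(samples):
            unknown = set(file_samples) - set(samples)
            raise ValueError(f"{path}: unexpected sample(s) {sorted(unknown)}")
        declared = set(vcf.header.info)
        for rec in vcf:
            where = f"{path}:{rec.chrom}:{rec.pos}"
            def _info(key: str, default: str) -> str:
                if key not in declared:
                    return default
                return str(rec.info.get(key, default) or default)
            gene = _info("GENE", "").upper()
            region = _parse_region(_info("REGION", "other"), where)
            effect = _parse_effect(_info("EFFECT", "unknown"), where)
            alts = rec.alts or ()
            for i, alt in enumerate(alts, start=1):
                genotypes = {
                    sid: _split_gt(rec.samples[sid].get("GT"), i)
                    for sid in file_samples
                }
                records.append(
                    AnnotatedSNV(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=gene,
                        region=region,
                        effect=effect,
                        genotypes=genotypes,
                    )
                )
    return records


def write_snv_table(
    records: Sequence[AnnotatedSNV],
    path: str | Path,
    dialect: str = "tsv",
    samples: Sequence[str] | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write annotated small variants to ``path`` in ``dialect``.

    ``samples`` fixes the sample-column order; by default it is the union of
    sample ids over the records, in first-seen order.
    """
    path = Path(path)
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    if dialect == "tsv":
        with open(path, "w", newline="") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_SNV_FIXED_COLS + list(samples))
            for r in records:
                writer.writerow(
                    [r.chrom, r.pos, r.ref, r.alt, r.gene, r.region.value, r.effect.value]
                    + [_GT_TSV[r.genotypes.get(s, GenotypeCall.NO_CALL)] for s in samples]
                )
        return
    if dialect == "vcf":
        _write_snv_vcf(records, path, samples)
        return
    raise ValueError(f"unknown SNV dialect {dialect!r}")


_GT_VCF = {
    GenotypeCall.ABSENT: (0, 0),
    GenotypeCall.HET: (0, 1),
    GenotypeCall.HOM: (1, 1),
    GenotypeCall.NO_CALL: (None, None),
}


def _write_snv_vcf(records: Sequence[AnnotatedSNV], path: Path, samples: Sequence[str]) -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "dsdscreen")
    for key, desc in (
        ("GENE", "Gene symbol"),
        ("REGION", "Genomic region class"),
        ("EFFECT", "Coding effect class"),
    ):
        header.info.add(key, 1, "String", desc)
    header.formats.add("GT", 1, "String", "Genotype")
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            if r.gene:
                rec.info["GENE"] = r.gene
            rec.info["REGION"] = r.region.value
            rec.info["EFFECT"] = r.effect.value
            for s in samples:
                rec.samples[s]["GT"] = _GT_VCF[r.genotypes.get(s, GenotypeCall.NO_CALL)]
            vcf.write(rec)


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

def read_sv_table(
    path: str | Path,
    dialect: str = "tsv",
    samples: Sequence[str] | None = None,
) -> list[SVRecord]:
    """Read structural variants from a headered TSV or BEDPE file.

    TSV columns: ``sv_id type chrom start end genes <sample>...`` with genes
    semicolon-separated and presence flags 0/1.  BEDPE carries the two
    breakpoints as 0-based half-open intervals plus the same trailing columns
    after name/score/strands; a ``#``-prefixed header names the samples.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_sv_tsv(path, samples)
    if dialect == "bedpe":
        return _read_sv_bedpe(path, samples)
    raise ValueError(f"unknown SV dialect {dialect!r}")


def _parse_sv_row(
    sv_id: str, sv_type: str, chrom: str, start: str, end: str, genes: str,
    presence_flags: Sequence[str], sample_ids: Sequence[str], where: str,
) -> SVRecord:
    try:
        typ = SVType(sv_type)
    except ValueError:
        raise ValueError(f"{where}: unknown SV type {sv_type!r}")
    s, e = int(start), int(end)
    if e < s:
        raise ValueError(f"{where}: end ({e}) < start ({s})")
    presence = {}
    for sid, flag in zip(sample_ids, presence_flags):
        if flag not in ("0", "1"):
            raise ValueError(f"{where}: presence flag must be 0/1, got {flag!r}")
        presence[sid] = flag == "1"
    gene_set = frozenset(g for g in genes.split(";") if g)
    return SVRecord(sv_id=sv_id, sv_type=typ, chrom=chrom, start=s, end=e,
                    genes=gene_set, presence=presence)


def _read_sv_tsv(path: Path, samples: Sequence[str] | None) -> list[SVRecord]:
    records: list[SVRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file (header line required)")
        if header[: len(_SV_FIXED_COLS)] != _SV_FIXED_COLS:
            raise ValueError(f"{path}: header must start with {_SV_FIXED_COLS}")
        sample_ids = header[len(_SV_FIXED_COLS):]
        if samples is not None and set(sample_ids) != set(samples):
            unknown = set(sample_ids) - set(samples)
            raise ValueError(f"{path}: unexpected sample column(s) {sorted(unknown)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
            records.append(
                _parse_sv_row(row[0], row[1], row[2], row[3], row[4], row[5],
                              row[6:], sample_ids, f"{path}:{lineno}")
            )
    return records


_BEDPE_FIXED = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                "name", "score", "strand1", "strand2", "type", "genes"]


def _read_sv_bedpe(path: Path, samples: Sequence[str] | None) -> list[SVRecord]:
    records: list[SVRecord] = []
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: BEDPE input requires a '#'-prefixed header line")
        header = first.lstrip("#").strip().split("\t")
        if header[: len(_BEDPE_FIXED)] != _BEDPE_FIXED:
            raise ValueError(f"{path}: BEDPE header must start with {_BEDPE_FIXED}")
        sample_ids = header[len(_BEDPE_FIXED):]
        if samples is not None and set(sample_ids) != set(samples):
            unknown = set(sample_ids) - set(samples)
            raise ValueError(f"{path}: unexpected sample column(s) {sorted(unknown)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
            if row[0] != row[3]:
                raise ValueError(f"{path}:{lineno}: interchromosomal BEDPE rows unsupported")
            # breakpoint intervals (0-based half-open) -> 1-based inclusive span
            start = int(row[1]) + 1
            end = int(row[5])
            records.append(
                _parse_sv_row(row[6], row[10], row[0], str(start), str(end),
                              row[11], row[12:], sample_ids, f"{path}:{lineno}")
            )
    return records


def write_sv_table(
    records: Sequence[SVRecord],
    path: str | Path,
    dialect: str = "tsv",
    samples: Sequence[str] | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    path = Path(path)
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.presence:
                seen.setdefault(s)
        samples = list(seen)
    with open(path, "w", newline="") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if dialect == "tsv":
            writer.writerow(_SV_FIXED_COLS + list(samples))
            for r in records:
                writer.writerow(
                    [r.sv_id, r.sv_type.value, r.chrom, r.start, r.end,
                     ";".join(sorted(r.genes))]
                    + [int(r.present_in(s)) for s in samples]
                )
        elif dialect == "bedpe":
            fh.write("#" + "\t".join(_BEDPE_FIXED + list(samples)) + "\n")
            for r in records:
                writer.writerow(
                    [r.chrom, r.start - 1, r.start, r.chrom, r.end - 1, r.end,
                     r.sv_id, ".", "+", "+", r.sv_type.value,
                     ";".join(sorted(r.genes))]
                    + [int(r.present_in(s)) for s in samples]
                )
        else:
            raise ValueError(f"unknown SV dialect {dialect!r}")


def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a candidate-gene panel from a headered TSV (columns gene, note)."""
    entries: dict[str, str] = {}
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or "gene" not in reader.fieldnames:
            raise ValueError(f"{path}: panel file requires a 'gene' column")
        for row in reader:
            entries[row["gene"].upper()] = row.get("note", "") or ""
    return GenePanel(entries)
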