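"""Domain types for the XX DSD variant-screening pipeline.

The pipeline operates on three kinds of atoms: annotated small variants
(:class:`AnnotatedSNV`) with per-sample zygosity calls, structural variants
(:class:`SVRecord`) with per-sample presence flags, and candidate gene panels
(:class:`GenePanel`).  A run always involves one unaffected control female and
two or more affected (XX DSD) individuals, described by :class:`SampleRole`.

Coordinates are 1-based and inclusive throughout: an interval ``[start, end]``
spans ``end - start + 1`` bases.  This convention is what makes a deletion
recorded as 6:9669113-9669182 measure exactly 70 bp.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Role",
    "SampleRole",
    "GenotypeCall",
    "Region",
    "Effect",
    "SVType",
    "AnnotatedSNV",
    "SVRecord",
    "GenePanel",
    "variant_key",
    "assembly_n50",
]

_VALID_ALLELE = frozenset("ACGT")


class Role(str, enum.Enum):
    """Role of a sample in the trio design."""

    CONTROL_FEMALE = "control_female"
    AFFECTED = "affected"


@dataclass(frozen=True)
class SampleRole:
    sample_id: str
    role: Role

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


def check_roles(roles: Iterable[SampleRole]) -> tuple[str, list[str]]:
    """Validate a trio (or extended) design.

    Returns ``(control_id, affected_ids)``.  Exactly one control female and at
    least two affected samples are required; sample ids must be unique.
    """
    roles = list(roles)
    ids = [r.sample_id for r in roles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in roles")
    controls = [r.sample_id for r in roles if r.role is Role.CONTROL_FEMALE]
    affected = [r.sample_id for r in roles if r.role is Role.AFFECTED]
    if len(controls) != 1:
        raise ValueError(f"exactly one control_female required, got {len(controls)}")
    if len(affected) < 2:
        raise ValueError(f"at least two affected samples required, got {len(affected)}")
    return controls[0], affected


class GenotypeCall(str, enum.Enum):
    """Zygosity of one sample at one site-allele.

    ``ABSENT`` means the sample carries no copy of the alternate allele (it is
    homozygous reference there); ``NO_CALL`` means the genotype could not be
    determined and is deliberately distinct from ``ABSENT``.
    """

    ABSENT = "absent"
    HET = "het"
    HOM = "hom"
    NO_CALL = "no_call"


class Region(str, enum.Enum):
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UTR = "utr"
    SPLICING = "splicing"
    OTHER = "other"


class Effect(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    UNKNOWN = "unknown"


class SVType(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INVERSION = "inversion"


@dataclass
class AnnotatedSNV:
    """One annotated small variant with per-sample zygosity calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    region: Region = Region.OTHER
    effect: Effect = Effect.UNKNOWN
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_ALLELE:
                raise ValueError(f"{name} allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self)


def variant_key(v: AnnotatedSNV) -> tuple[str, int, str, str]:
    """Canonical site-allele identity: ``(chrom, pos, REF, ALT)``.

    Alleles are upper-cased; the key ignores annotation and genotype content,
    so two records with equal keys describe the same site-allele across
    samples (the unit of the trio screen's set algebra).
    """
    return (v.chrom, v.pos, v.ref.upper(), v.alt.upper())


@dataclass
class SVRecord:
    """One structural variant with per-sample presence flags."""

    sv_id: str
    sv_type: SVType
    chrom: str
    start: int
    end: int
    genes: frozenset[str] = frozenset()
    presence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start}) for {self.sv_id}")
        self.sv_type = SVType(self.sv_type)
        self.genes = frozenset(g.upper() for g in self.genes)

    @property
    def size(self) -> int:
        """Span in bp under the 1-based inclusive convention."""
        return self.end - self.start + 1

    def present_in(self, sample_id: str) -> bool:
        return bool(self.presence.get(sample_id, False))


@dataclass
class GenePanel:
    """A curated candidate-gene panel (symbols upper-cased, unique)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for gene, note in self.entries.items():
            g = gene.upper()
            if g in normalized:
                raise ValueError(f"duplicate gene symbol in panel: {g}")
            normalized[g] = note
        self.entries = normalized

    @classmethod
    def from_genes(cls, genes: Iterable[str], notes: Mapping[str, str] | None = None) -> "GenePanel":
        notes = notes or {}
        return cls({g: notes.get(g, "") for g in genes})

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.entries)


def assembly_n50(lengths: Iterable[int]) -> int:
    """N50 of a set of contig/scaffold lengths.

    The largest length L such that pieces of length >= L together cover at
    least half the assembly's total bases.  Computed by sorting descending and
    accumulating; permutation-invariant by construction.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("assembly_n50 requires a non-empty list of lengths")
    if lens[-1] <= 0:
        raise ValueError("contig lengths must be positive")
    total = sum(lens)
    half = total / 2
    acc = 0
    for n in lens:
        acc += n
        if acc >= half:
            return n
    raise AssertionError("unreachable")  # pragma: no cover
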