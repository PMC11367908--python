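"""Two-step structural-variant concordance screen and cohort SV burden.

Step A keeps SVs carried by the primary affected genome with no matching SV
in the control; step B keeps those that additionally match an SV carried by
the second affected genome.  "Matching" is policy-driven: the default
``gene_and_type`` mode requires the same SV type and an overlapping gene
annotation (the study criterion of same gene position and type), with
positional proximity as a guard; ``reciprocal_overlap`` is the standard
interval-based alternative for gene-sparse regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import SVRecord, SVType

__all__ = ["SVMatchPolicy", "SVBurden", "sv_match", "screen_step_a", "screen_step_b", "sv_burden"]


@dataclass(frozen=True)
class SVMatchPolicy:
    """How two SV records are decided to describe the same event.

    mode
        ``gene_and_type``: same type, shared gene symbol, and intervals that
        overlap or have nearest breakpoints within ``breakpoint_tolerance``.
        Records with empty gene sets (intergenic SVs) fall back to the
        positional test alone.
        ``reciprocal_overlap``: same type and chromosome with at least
        ``min_reciprocal_overlap`` of BOTH records covered by the overlap;
        inversions are instead matched on both breakpoints lying within
        ``breakpoint_tolerance`` (overlap fraction is uninformative for
        balanced events).
    """

    mode: str = "gene_and_type"
    min_reciprocal_overlap: float = 0.5
    breakpoint_tolerance: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in ("gene_and_type", "reciprocal_overlap"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if not (0 < self.min_reciprocal_overlap <= 1):
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")
        if self.breakpoint_tolerance <= 0:
            raise ValueError("breakpoint_tolerance must be positive")


def _overlap_bp(a: SVRecord, b: SVRecord) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def _breakpoints_near(a: SVRecord, b: SVRecord, tol: int) -> bool:
    return abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol


def _positional(a: SVRecord, b: SVRecord, tol: int) -> bool:
    if a.chrom != b.chrom:
        return False
    if _overlap_bp(a, b) >= 1:
        return True
    # disjoint intervals: nearest breakpoints within tolerance
    gap = max(a.start, b.start) - min(a.end, b.end)
    return gap <= tol


def sv_match(a: SVRecord, b: SVRecord, policy: SVMatchPolicy | None = None) -> bool:
    """Symmetric predicate: do ``a`` and ``b`` describe the same SV event?"""
    policy = policy or SVMatchPolicy()
    if a.sv_type is not b.sv_type:
        return False
    if policy.mode == "gene_and_type":
        if a.genes and b.genes:
            if not (a.genes & b.genes):
                return False
            return _positional(a, b, policy.breakpoint_tolerance)
        # intergenic route: the gene criterion is undefined, match on position
        return _positional(a, b, policy.breakpoint_tolerance)
    # reciprocal_overlap mode
    if a.chrom != b.chrom:
        return False
    if a.sv_type is SVType.INVERSION:
        return _breakpoints_near(a, b, policy.breakpoint_tolerance)
    ov = _overlap_bp(a, b)
    if ov < 1:
        return False
    return ov / a.size >= policy.min_reciprocal_overlap and ov / b.size >= policy.min_reciprocal_overlap


def _carried(svs: Iterable[SVRecord], sample_id: str) -> list[SVRecord]:
    return [s for s in svs if s.present_in(sample_id)]


def screen_step_a(
    svs: Sequence[SVRecord],
    control: str,
    affected: str,
    policy: SVMatchPolicy | None = None,
) -> list[SVRecord]:
    """SVs carried by ``affected`` with no matching SV carried by ``control``."""
    known = {s for rec in svs for s in rec.presence}
    for sid in (control, affected):
        if sid not in known:
            raise ValueError(f"unknown sample_id {sid!r}")
    policy = policy or SVMatchPolicy()
    control_svs = _carried(svs, control)
    return [
        rec for rec in _carried(svs, affected)
        if not any(sv_match(rec, c, policy) for c in control_svs)
    ]


def screen_step_b(
    step_a: Sequence[SVRecord],
    other_affected: Sequence[SVRecord],
    policy: SVMatchPolicy | None = None,
) -> list[SVRecord]:
    """Keep step-A survivors that match at least one SV of the second
    affected genome (concordance between the two affected individuals)."""
    policy = policy or SVMatchPolicy()
    return [
        rec for rec in step_a
        if any(sv_match(rec, o, policy) for o in other_affected)
    ]


@dataclass
class SVBurden:
    """Per-individual candidate-SV burden and its cohort summary."""

    per_individual: dict[str, int]
    exactly_one: int
    two_or_more: int
    zero: int
    #: individuals carrying only that SV and nothing else
    exclusive_carriers: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict[str, int]:
        return {"exactly_one": self.exactly_one, "two_or_more": self.two_or_more,
                "zero": self.zero}


def sv_burden(carriers: Mapping[str, set[str]], cohort_size: int) -> SVBurden:
    """Summarise how many candidate SVs each cohort member carries.

    ``carriers`` maps individual id to the set of candidate SV ids carried;
    individuals absent from the map carry none.
    """
    if len(carriers) > cohort_size:
        raise ValueError(
            f"cohort_size ({cohort_size}) smaller than number of individuals ({len(carriers)})"
        )
    per_individual = {ind: len(svs) for ind, svs in carriers.items()}
    exactly_one = sum(1 for n in per_individual.values() if n == 1)
    two_or_more = sum(1 for n in per_individual.values() if n >= 2)
    zero = cohort_size - exactly_one - two_or_more
    exclusive: dict[str, int] = {}
    for svs in carriers.values():
        if len(svs) == 1:
            (sv,) = svs
            exclusive[sv] = exclusive.get(sv, 0) + 1
    return SVBurden(per_individual=per_individual, exactly_one=exactly_one,
                    two_or_more=two_or_more, zero=zero, exclusive_carriers=exclusive)
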