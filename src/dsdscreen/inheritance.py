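"""Autosomal-recessive trio screen over nonsynonymous SNVs.

A candidate recessive variant for an XX DSD phenotype should be homozygous in
every affected individual while absent or heterozygous in the unaffected
control female.  The screen builds per-sample zygosity sets over
nonsynonymous variants and evaluates four criteria:

A. homozygous in every affected sample, absent from the control;
B. homozygous in the control, absent from every affected sample;
C. homozygous in every affected sample, heterozygous in the control;
D. heterozygous in the control, absent from every affected sample.

A and C are the recessive-model candidates; B and D are the mirrored
control-only patterns, reported separately.  The four result sets are
pairwise disjoint by construction (hom/het are disjoint within a sample and
presence/absence are complementary), so the screen total is the plain sum of
the four set sizes.

Missing genotypes (``no_call``) enter no set: they are treated as
unevaluable rather than as absence, and a count of affected no-calls is
logged per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    AnnotatedSNV,
    Effect,
    GenePanel,
    GenotypeCall,
    SampleRole,
    check_roles,
    variant_key,
)

__all__ = [
    "CRITERIA",
    "ZygositySets",
    "ScreenResult",
    "build_zygosity_sets",
    "screen_criterion",
    "screen_all",
    "filter_by_panel",
]

logger = logging.getLogger(__name__)

CRITERIA = ("A", "B", "C", "D")

VariantKey = tuple[str, int, str, str]

#: effects admitted to the screen by default; a wider filter (adding
#: stopgain/stoploss) can be requested explicitly.
DEFAULT_EFFECTS = frozenset({Effect.NONSYNONYMOUS})


@dataclass
class ZygositySets:
    """Per-sample variant-key sets over screened-effect variants.

    ``all_ns`` holds every key at which the sample carries the alternate
    allele (het or hom); ``hom_ns`` / ``het_ns`` partition it by zygosity.
    """

    control: str
    affected: list[str]
    all_ns: dict[str, set[VariantKey]] = field(default_factory=dict)
    hom_ns: dict[str, set[VariantKey]] = field(default_factory=dict)
    het_ns: dict[str, set[VariantKey]] = field(default_factory=dict)


def build_zygosity_sets(
    variants: Iterable[AnnotatedSNV],
    roles: Sequence[SampleRole],
    effects: frozenset[Effect] = DEFAULT_EFFECTS,
) -> ZygositySets:
    """Build the per-sample hom/het/all sets feeding the four criteria."""
    control, affected = check_roles(roles)
    sample_ids = [control] + affected
    sets = ZygositySets(
        control=control,
        affected=list(affected),
        all_ns={s: set() for s in sample_ids},
        hom_ns={s: set() for s in sample_ids},
        het_ns={s: set() for s in sample_ids},
    )
    n_affected_no_call = 0
    for v in variants:
        if v.effect not in effects:
            continue
        key = variant_key(v)
        for s in sample_ids:
            call = v.genotypes.get(s, GenotypeCall.NO_CALL)
            if call is GenotypeCall.NO_CALL:
                if s != control:
                    n_affected_no_call += 1
                continue
            if call is GenotypeCall.HOM:
                sets.hom_ns[s].add(key)
                sets.all_ns[s].add(key)
            elif call is GenotypeCall.HET:
                sets.het_ns[s].add(key)
                sets.all_ns[s].add(key)
    if n_affected_no_call:
        logger.info("screen: %d no_call genotypes in affected samples were "
                    "excluded as unevaluable", n_affected_no_call)
    return sets


def screen_criterion(sets: ZygositySets, criterion: str) -> set[VariantKey]:
    """Evaluate one criterion; with >2 affected samples the intersections run
    over all affected hom sets and the exclusions over the union of all
    affected all-sets (the trio is the two-affected special case)."""
    nf = sets.control
    hom_isect: set[VariantKey] = set.intersection(*(sets.hom_ns[a] for a in sets.affected))
    all_union: set[VariantKey] = set.union(*(sets.all_ns[a] for a in sets.affected))
    if criterion == "A":
        return hom_isect - sets.all_ns[nf]
    if criterion == "B":
        return sets.hom_ns[nf] - all_union
    if criterion == "C":
        return hom_isect & sets.het_ns[nf]
    if criterion == "D":
        return sets.het_ns[nf] - all_union
    raise ValueError(f"unknown criterion {criterion!r} (expected one of {CRITERIA})")


@dataclass
class ScreenResult:
    """Per-criterion key sets; ``total`` is the size of their disjoint union."""

    criteria: dict[str, set[VariantKey]]

    @property
    def total(self) -> int:
        return sum(len(s) for s in self.criteria.values())

    @property
    def union(self) -> set[VariantKey]:
        out: set[VariantKey] = set()
        for s in self.criteria.values():
            out |= s
        return out

    def counts(self) -> dict[str, int]:
        return {c: len(self.criteria[c]) for c in CRITERIA}


def screen_all(
    variants: Iterable[AnnotatedSNV],
    roles: Sequence[SampleRole],
    criteria: Sequence[str] = CRITERIA,
    effects: frozenset[Effect] = DEFAULT_EFFECTS,
) -> ScreenResult:
    """Run the recessive screen end to end over all requested criteria."""
    sets = build_zygosity_sets(variants, roles, effects=effects)
    return ScreenResult({c: screen_criterion(sets, c) for c in criteria})


def filter_by_panel(
    keys: set[VariantKey],
    variants: Iterable[AnnotatedSNV],
    panel: GenePanel,
) -> list[AnnotatedSNV]:
    """Keep variants whose key was selected and whose gene is on the panel,
    sorted by genomic position (numeric chromosomes before named ones)."""
    selected = [
        v for v in variants
        if variant_key(v) in keys and v.gene and v.gene.upper() in panel
    ]

    def _chrom_rank(chrom: str) -> tuple[int, int | str]:
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom)

    return sorted(selected, key=lambda v: (_chrom_rank(v.chrom), v.pos))
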