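"""Cohort validation statistics: genotype/allele frequencies, group-exclusive
genotypes, carrier prevalence and an optional allelic association test.

Genotype labels are unordered allele pairs.  When a locus declares its
reference/alternate allele pair, labels are printed reference-allele first
(TT, TC, CC for a T>C site); otherwise alleles are ordered lexicographically.
Frequencies are computed at full precision; display rounding is
round-half-even at three decimals, which reproduces the published convention
for values like 60/64 = 0.9375 -> 0.938.

Missing genotypes (both alleles empty) are excluded from the typed total
rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "CohortGenotypeTable",
    "FrequencyEntry",
    "genotype_frequencies",
    "allele_frequencies",
    "exclusivity_check",
    "carrier_prevalence",
    "association_test",
    "display_round",
]

logger = logging.getLogger(__name__)

GROUPS = ("affected", "control")

_COLUMNS = ["individual_id", "group", "locus_id", "allele1", "allele2"]


def display_round(x: float, ndigits: int = 3) -> float:
    """Round-half-even display rounding (computation keeps full precision)."""
    return round(x, ndigits)


@dataclass
class CohortGenotypeTable:
    """Long-format per-individual two-allele genotypes at validated loci.

    ``locus_alleles`` optionally declares the (reference, alternate) allele
    pair per locus; declared pairs fix genotype-label ordering and make
    zero-count genotype classes explicit in frequency output.
    """

    data: pd.DataFrame
    locus_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing column(s) {missing}")
        self.data = self.data[_COLUMNS].copy()
        self.data[["allele1", "allele2"]] = self.data[["allele1", "allele2"]].fillna("")
        dup = self.data.duplicated(subset=["individual_id", "locus_id"])
        if dup.any():
            raise ValueError("duplicate (individual_id, locus_id) rows in cohort table")
        bad = ~self.data["group"].isin(GROUPS)
        if bad.any():
            raise ValueError(f"unknown group label(s) {sorted(self.data.loc[bad, 'group'].unique())}")
        for locus, (a1, a2) in self.locus_alleles.items():
            sub = self.data[self.data["locus_id"] == locus]
            observed = set(sub["allele1"]) | set(sub["allele2"])
            extra = observed - {a1, a2, ""}
            if extra:
                raise ValueError(f"locus {locus}: allele(s) {sorted(extra)} outside declared pair ({a1},{a2})")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 locus_alleles: Mapping[str, tuple[str, str]] | None = None) -> "CohortGenotypeTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        return cls(df, dict(locus_alleles or {}))

    def to_tsv(self, path: str | Path, header_comments: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.data["locus_id"]))

    def _label(self, locus: str, a1: str, a2: str) -> str:
        """Canonical unordered genotype label (reference-first if declared)."""
        if locus in self.locus_alleles:
            ref, alt = self.locus_alleles[locus]
            order = {ref: 0, alt: 1}
            return "".join(sorted((a1, a2), key=lambda a: order.get(a, 2)))
        return "".join(sorted((a1, a2)))

    def genotype_labels(self, locus: str) -> list[str]:
        """All genotype labels for the locus's allele pair, homozygotes first
        in allele order then the heterozygote."""
        if locus in self.locus_alleles:
            alleles = list(self.locus_alleles[locus])
        else:
            sub = self.data[self.data["locus_id"] == locus]
            alleles = sorted(
                {a for a in pd.concat([sub["allele1"], sub["allele2"]]) if a}
            )
        labels = [a + a for a in alleles]
        for i, a in enumerate(alleles):
            for b in alleles[i + 1:]:
                labels.append(self._label(locus, a, b))
        return labels


@dataclass
class FrequencyEntry:
    """Genotype and allele counts/frequencies for one locus in one group."""

    locus_id: str
    group: str
    n_typed: int
    n_missing: int
    genotype_counts: dict[str, int]
    genotype_freqs: dict[str, float]
    allele_counts: dict[str, int]
    allele_freqs: dict[str, float]


def genotype_frequencies(table: CohortGenotypeTable, locus: str, group: str) -> FrequencyEntry:
    """Tabulate genotype counts and frequencies for one locus and group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    sub = table.data[(table.data["locus_id"] == locus) & (table.data["group"] == group)]
    if sub.empty:
        raise ValueError(f"no individuals of group {group!r} typed at locus {locus!r}")
    typed = sub[(sub["allele1"] != "") & (sub["allele2"] != "")]
    n_missing = len(sub) - len(typed)
    if n_missing:
        logger.info("locus %s group %s: %d missing genotypes excluded from n_typed",
                    locus, group, n_missing)
    n = len(typed)
    if n == 0:
        raise ValueError(f"zero typed individuals at locus {locus!r} in group {group!r}")
    counts = {label: 0 for label in table.genotype_labels(locus)}
    for a1, a2 in zip(typed["allele1"], typed["allele2"]):
        counts[table._label(locus, a1, a2)] = counts.get(table._label(locus, a1, a2), 0) + 1
    freqs = {g: c / n for g, c in counts.items()}
    entry = FrequencyEntry(
        locus_id=locus, group=group, n_typed=n, n_missing=n_missing,
        genotype_counts=counts, genotype_freqs=freqs,
        allele_counts={}, allele_freqs={},
    )
    entry.allele_freqs = allele_frequencies(entry)
    return entry


def allele_frequencies(entry: FrequencyEntry) -> dict[str, float]:
    """Allele frequencies from genotype counts:
    freq(x) = (2 * hom_x + het containing x) / (2 * n_typed)."""
    allele_counts: dict[str, int] = {}
    for label, c in entry.genotype_counts.items():
        a1, a2 = label[: len(label) // 2], label[len(label) // 2:]
        allele_counts[a1] = allele_counts.get(a1, 0) + c
        allele_counts[a2] = allele_counts.get(a2, 0) + c
    entry.allele_counts = allele_counts
    total = 2 * entry.n_typed
    return {a: c / total for a, c in allele_counts.items()}


def exclusivity_check(table: CohortGenotypeTable, locus: str) -> dict[str, set[str]]:
    """Partition observed genotype labels by group occurrence."""
    observed: dict[str, set[str]] = {}
    for group in GROUPS:
        entry = genotype_frequencies(table, locus, group)
        observed[group] = {g for g, c in entry.genotype_counts.items() if c > 0}
    return {
        "affected_only_genotypes": observed["affected"] - observed["control"],
        "control_only_genotypes": observed["control"] - observed["affected"],
        "shared": observed["affected"] & observed["control"],
    }


def carrier_prevalence(
    cn_genotypes: Mapping[str, int],
    groups: Mapping[str, str] | None = None,
    group: str | None = None,
) -> tuple[float, int, int]:
    """Fraction of individuals carrying at least one deleted allele.

    ``cn_genotypes`` maps individual id to the number of INTACT copies of the
    segment (0/1/2); an intact-copy count <= 1 means the individual carries
    the deletion on at least one chromosome.  Returns
    ``(fraction, n_carriers, n_total)``.
    """
    ids = list(cn_genotypes)
    if groups is not None and group is not None:
        ids = [i for i in ids if groups.get(i) == group]
    if not ids:
        raise ValueError("empty group for carrier_prevalence")
    for i in ids:
        if cn_genotypes[i] not in (0, 1, 2):
            raise ValueError(f"intact-copy count for {i} must be 0, 1 or 2")
    carriers = sum(1 for i in ids if cn_genotypes[i] <= 1)
    return carriers / len(ids), carriers, len(ids)


def association_test(table: CohortGenotypeTable, locus: str) -> dict[str, float]:
    """Fisher exact test on the 2x2 allele-count table (affected vs control).

    This is an extension beyond the published analysis, which reports
    frequencies only.  The odds ratio uses the Haldane-Anscombe correction
    (+0.5 to every cell) whenever any cell is zero, keeping it finite.
    """
    entries = {g: genotype_frequencies(table, locus, g) for g in GROUPS}
    alleles = sorted(set(entries["affected"].allele_counts) | set(entries["control"].allele_counts))
    if len(alleles) != 2:
        raise ValueError(f"association_test requires exactly two alleles, got {alleles}")
    counts = [[entries[g].allele_counts.get(a, 0) for a in alleles] for g in GROUPS]
    for j, a in enumerate(alleles):
        if counts[0][j] + counts[1][j] == 0:
            raise ValueError(f"allele {a} absent from both groups (degenerate table)")
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    a, b = counts[0]
    c, d = counts[1]
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return {"odds_ratio": (a * d) / (b * c), "p_value": float(p)}
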