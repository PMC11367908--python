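"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration (seed included) and
returns both the synthetic records and a planted-truth table, so every
pipeline stage can be tested by exact recovery with no external data.
Trio genotype patterns are planted to satisfy exactly one screen criterion
(or none, for the background classes); SV sets are planted into
concordant / affected-only / control-shared classes; cohort genotypes are
laid out to exact counts or sampled from configured frequencies; probe peaks
and Ct values get multiplicative log-normal and additive Gaussian noise
respectively — noise models that are simulation assumptions, since the
source assays publish none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortGenotypeTable
from .model import (
    AnnotatedSNV,
    Effect,
    GenotypeCall,
    Region,
    SVRecord,
    SVType,
    variant_key,
)
from .quantify import ExpressionRecord, PrimerPair, ProbeSignalTable, REFERENCE_PROBES

__all__ = [
    "TrioSimConfig",
    "SVSimConfig",
    "CohortSimConfig",
    "LocusSpec",
    "SignalSimConfig",
    "QpcrSimConfig",
    "AmpliconFixture",
    "generate_trio_snvs",
    "generate_sv_sets",
    "generate_cohort",
    "generate_cnvplex",
    "generate_qpcr",
    "generate_amplicon_fixture",
    "WWOX_FORWARD_PRIMER",
    "WWOX_REVERSE_PRIMER",
    "WWOX_WILDTYPE_PRODUCT",
    "WWOX_DELETION_SIZE",
]

#: published primer pair flanking the WWOX intron-5 deletion
WWOX_FORWARD_PRIMER = "ATCCTCGCAGGACACAGGAG"
WWOX_REVERSE_PRIMER = "TGTGTAGCGGCCTCCAGAAG"
#: wild-type product length and deletion size of that assay (bp)
WWOX_WILDTYPE_PRODUCT = 298
WWOX_DELETION_SIZE = 70

_BASES = np.array(list("ACGT"))

# genotype pattern per planted class: (control, first affected, other affected)
_CLASS_PATTERNS: dict[str, tuple[GenotypeCall, GenotypeCall, GenotypeCall]] = {
    "A": (GenotypeCall.ABSENT, GenotypeCall.HOM, GenotypeCall.HOM),
    "B": (GenotypeCall.HOM, GenotypeCall.ABSENT, GenotypeCall.ABSENT),
    "C": (GenotypeCall.HET, GenotypeCall.HOM, GenotypeCall.HOM),
    "D": (GenotypeCall.HET, GenotypeCall.ABSENT, GenotypeCall.ABSENT),
    "shared_hom": (GenotypeCall.HOM, GenotypeCall.HOM, GenotypeCall.HOM),
    "single_affected": (GenotypeCall.ABSENT, GenotypeCall.HOM, GenotypeCall.HET),
    "synonymous": (GenotypeCall.ABSENT, GenotypeCall.HOM, GenotypeCall.HOM),
    "intronic": (GenotypeCall.ABSENT, GenotypeCall.HOM, GenotypeCall.HOM),
}


@dataclass(frozen=True)
class TrioSimConfig:
    """Planted-class counts for the trio screen generator.

    ``kA..kD`` plant variants satisfying exactly the corresponding screen
    criterion; the background classes satisfy none (``shared_hom`` is
    homozygous everywhere, ``single_affected`` is discordant between the two
    affected genomes, ``synonymous``/``intronic`` fail the effect filter).
    """

    kA: int = 50
    kB: int = 30
    kC: int = 20
    kD: int = 10
    k_shared_hom: int = 100
    k_single_affected: int = 50
    k_synonymous: int = 40
    k_intronic: int = 200
    chromosomes: tuple[str, ...] = tuple(str(c) for c in range(1, 19))
    chrom_length: int = 100_000_000
    control: str = "NF"
    affected: tuple[str, ...] = ("D1", "D2")
    seed: int = 0

    def class_counts(self) -> dict[str, int]:
        return {
            "A": self.kA, "B": self.kB, "C": self.kC, "D": self.kD,
            "shared_hom": self.k_shared_hom,
            "single_affected": self.k_single_affected,
            "synonymous": self.k_synonymous,
            "intronic": self.k_intronic,
        }


def _draw_site(rng: np.random.Generator, chromosomes: Sequence[str],
               chrom_length: int, used: set[tuple[str, int]]) -> tuple[str, int]:
    for _ in range(1000):
        chrom = chromosomes[int(rng.integers(len(chromosomes)))]
        pos = int(rng.integers(1, chrom_length + 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos
    raise RuntimeError("position pool exhausted while planting variants")


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return str(_BASES[i]), str(_BASES[j])


def generate_trio_snvs(
    config: TrioSimConfig,
) -> tuple[list[AnnotatedSNV], dict[tuple, str]]:
    """Generate a trio SNV table with planted screen classes.

    Returns ``(records, truth)`` where ``truth`` maps each variant key to its
    planted class label (criterion letter or background class name).
    """
    for name, k in config.class_counts().items():
        if k < 0:
            raise ValueError(f"count for class {name} must be >= 0")
    rng = np.random.default_rng(config.seed)
    used: set[tuple[str, int]] = set()
    records: list[AnnotatedSNV] = []
    truth: dict[tuple, str] = {}
    for cls, count in config.class_counts().items():
        nf_gt, first_gt, rest_gt = _CLASS_PATTERNS[cls]
        for i in range(count):
            chrom, pos = _draw_site(rng, config.chromosomes, config.chrom_length, used)
            ref, alt = _draw_alleles(rng)
            if cls == "synonymous":
                region, effect = Region.EXONIC, Effect.SYNONYMOUS
            elif cls == "intronic":
                region, effect = Region.INTRONIC, Effect.UNKNOWN
            else:
                region, effect = Region.EXONIC, Effect.NONSYNONYMOUS
            genotypes = {config.control: nf_gt, config.affected[0]: first_gt}
            for a in config.affected[1:]:
                genotypes[a] = rest_gt
            rec = AnnotatedSNV(chrom=chrom, pos=pos, ref=ref, alt=alt,
                               gene=f"SIM{cls.upper()}{i:04d}",
                               region=region, effect=effect, genotypes=genotypes)
            records.append(rec)
            truth[variant_key(rec)] = cls
    records.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return records, truth


@dataclass(frozen=True)
class SVSimConfig:
    """Planted-class counts for the SV concordance generator."""

    n_concordant: int = 20
    n_affected_primary_only: int = 15
    n_control_shared: int = 10
    control: str = "NF"
    affected_primary: str = "D2"
    affected_secondary: str = "D1"
    spacing: int = 100_000  # keeps planted SVs from matching across classes
    seed: int = 0


def generate_sv_sets(config: SVSimConfig) -> tuple[list[SVRecord], dict[str, str]]:
    """Generate an SV table with concordant / primary-only / control-shared
    classes.  Each SV gets a unique synthetic gene symbol and intervals are
    spaced far beyond any breakpoint tolerance, so the only policy match for
    a planted SV is itself."""
    rng = np.random.default_rng(config.seed)
    types = [SVType.DELETION, SVType.DUPLICATION, SVType.INVERSION]
    plan = (
        [("concordant", {config.affected_primary: True, config.affected_secondary: True,
                         config.control: False})] * config.n_concordant
        + [("affected_primary_only", {config.affected_primary: True,
                                      config.affected_secondary: False,
                                      config.control: False})] * config.n_affected_primary_only
        + [("control_shared", {config.affected_primary: True,
                               config.affected_secondary: False,
                               config.control: True})] * config.n_control_shared
    )
    records: list[SVRecord] = []
    truth: dict[str, str] = {}
    for i, (label, presence) in enumerate(plan):
        chrom = str(1 + i % 18)
        start = 1 + (i // 18 + 1) * config.spacing + int(rng.integers(0, 1000))
        size = int(rng.integers(70, 5000))
        sv_id = f"sv{i:04d}"
        records.append(SVRecord(
            sv_id=sv_id, sv_type=types[i % 3], chrom=chrom,
            start=start, end=start + size - 1,
            genes=frozenset({f"SIMGENE{i:04d}"}), presence=dict(presence),
        ))
        truth[sv_id] = label
    return records, truth


@dataclass(frozen=True)
class LocusSpec:
    """One validated locus: reference/alternate alleles plus either exact
    per-group genotype counts or per-group genotype frequencies."""

    ref: str
    alt: str
    counts: Mapping[str, Mapping[str, int]] | None = None
    freqs: Mapping[str, Mapping[str, float]] | None = None

    def genotype_of(self, label: str) -> tuple[str, str]:
        half = len(label) // 2
        return label[:half], label[half:]


@dataclass(frozen=True)
class CohortSimConfig:
    loci: Mapping[str, LocusSpec] = field(default_factory=dict)
    n_affected: int = 32
    n_control: int = 32
    seed: int = 0


def generate_cohort(config: CohortSimConfig) -> tuple[CohortGenotypeTable, dict]:
    """Generate an affected/control cohort genotype table.

    Exact-count mode reproduces the configured genotype counts bit-exactly
    (genotypes laid out over a seeded permutation of individuals); sampling
    mode draws each individual's genotype from the configured frequencies.
    Returns the table plus the truth parameters per locus and group.
    """
    rng = np.random.default_rng(config.seed)
    group_sizes = {"affected": config.n_affected, "control": config.n_control}
    individuals = {
        g: [f"{'d' if g == 'affected' else 'c'}{i+1:03d}" for i in range(n)]
        for g, n in group_sizes.items()
    }
    rows = []
    truth: dict[str, dict] = {}
    for locus_id, spec in config.loci.items():
        if (spec.counts is None) == (spec.freqs is None):
            raise ValueError(f"locus {locus_id}: exactly one of counts/freqs required")
        truth[locus_id] = {}
        for group, inds in individuals.items():
            n = len(inds)
            order = list(rng.permutation(inds))
            if spec.counts is not None:
                counts = dict(spec.counts.get(group, {}))
                if sum(counts.values()) > n:
                    raise ValueError(
                        f"locus {locus_id} group {group}: counts exceed group size {n}")
                assigned: list[str] = []
                for label, c in counts.items():
                    assigned.extend([label] * c)
                # individuals beyond the configured counts are missing
                assigned.extend([""] * (n - len(assigned)))
                truth[locus_id][group] = {"counts": counts}
            else:
                freqs = dict(spec.freqs.get(group, {}))
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"locus {locus_id} group {group}: frequencies sum to {total}")
                labels = list(freqs)
                draws = rng.choice(len(labels), size=n, p=[freqs[l] for l in labels])
                assigned = [labels[d] for d in draws]
                truth[locus_id][group] = {"freqs": freqs}
            for ind, label in zip(order, assigned):
                a1, a2 = spec.genotype_of(label) if label else ("", "")
                rows.append({"individual_id": ind, "group": group,
                             "locus_id": locus_id, "allele1": a1, "allele2": a2})
    df = pd.DataFrame(rows, columns=["individual_id", "group", "locus_id", "allele1", "allele2"])
    df = df.sort_values(["locus_id", "group", "individual_id"], kind="stable").reset_index(drop=True)
    locus_alleles = {lid: (spec.ref, spec.alt) for lid, spec in config.loci.items()}
    return CohortGenotypeTable(df, locus_alleles), truth


@dataclass(frozen=True)
class SignalSimConfig:
    """Copy-number classes driving noisy ligation-probe peak signals.

    ``copies`` maps sample id -> probe id -> planted intact-copy count in
    {0, 1, 2, 3}.  Peaks get multiplicative log-normal noise of coefficient
    of variation ``cv`` (mean 1); a zero-copy sample still emits a small
    positive floor peak (0.02 x baseline) so every peak is positive.
    """

    copies: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    groups: Mapping[str, str] = field(default_factory=dict)
    cv: float = 0.10
    baseline: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for s, probes in self.copies.items():
            for p, c in probes.items():
                if c not in (0, 1, 2, 3):
                    raise ValueError(f"copies for {s}/{p} must be in 0..3, got {c}")


_ZERO_COPY_FLOOR = 0.02


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1 + cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2, sigma, size=size))


def generate_cnvplex(config: SignalSimConfig) -> tuple[ProbeSignalTable, dict[str, dict[str, int]]]:
    """Generate a probe peak-signal table from planted copy classes."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for sample in config.copies:
        group = config.groups.get(sample, "unknown")
        probes = config.copies[sample]
        target_ids = list(probes)
        factors = _lognormal_factor(rng, config.cv, len(target_ids) + len(REFERENCE_PROBES))
        for i, probe in enumerate(target_ids):
            copies = probes[probe]
            scale = _ZERO_COPY_FLOOR if copies == 0 else copies / 2.0
            rows.append({"sample_id": sample, "group": group, "probe_id": probe,
                         "peak_signal": config.baseline * scale * factors[i]})
        for j, probe in enumerate(REFERENCE_PROBES):
            rows.append({"sample_id": sample, "group": group, "probe_id": probe,
                         "peak_signal": config.baseline * factors[len(target_ids) + j]})
    table = ProbeSignalTable(pd.DataFrame(rows))
    truth = {s: dict(p) for s, p in config.copies.items()}
    return table, truth


@dataclass(frozen=True)
class QpcrSimConfig:
    """Group-structured Ct values around a shared reference-gene baseline.

    ``group_log2_fold`` gives each group's true log2 fold change relative to
    the calibrator group (fold 2**x corresponds to a ΔCt offset of -x).
    ``replicate_sd`` is the technical replicate standard deviation in Ct
    units, applied independently to every replicate of both genes.
    """

    gene: str = "IFITM1"
    group_log2_fold: Mapping[str, float] = field(default_factory=dict)
    calibrator_group: str = "normal_female"
    n_per_group: int = 3
    replicate_sd: float = 0.1
    reference_ct: float = 18.0
    base_dct: float = 5.0
    seed: int = 0


def generate_qpcr(config: QpcrSimConfig) -> tuple[list[ExpressionRecord], dict[str, float]]:
    """Generate triplicate Ct records; returns records plus true fold per group."""
    rng = np.random.default_rng(config.seed)
    groups = dict(config.group_log2_fold)
    groups.setdefault(config.calibrator_group, 0.0)
    records: list[ExpressionRecord] = []
    truth: dict[str, float] = {}
    for group, log2_fold in groups.items():
        truth[group] = 2.0 ** log2_fold
        for i in range(config.n_per_group):
            ref = config.reference_ct + rng.normal(0, config.replicate_sd, 3) \
                if config.replicate_sd > 0 else np.full(3, config.reference_ct)
            tgt_mean = config.reference_ct + config.base_dct - log2_fold
            tgt = tgt_mean + rng.normal(0, config.replicate_sd, 3) \
                if config.replicate_sd > 0 else np.full(3, tgt_mean)
            records.append(ExpressionRecord(
                individual_id=f"{group}_{i+1}", group=group, gene=config.gene,
                ct_target=tuple(float(x) for x in tgt),
                ct_reference=tuple(float(x) for x in ref),
            ))
    return records, truth


@dataclass
class AmpliconFixture:
    """Synthetic wild-type and deletion-allele templates for the WWOX
    intron-5 PCR assay, carrying the published primer pair."""

    wild_type: str
    deletion: str
    primers: PrimerPair
    deletion_interval: tuple[int, int]  # 1-based inclusive, on the wild type

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(">wild_type synthetic template, published primer sites, "
                     f"deletion interval {self.deletion_interval[0]}-{self.deletion_interval[1]}\n")
            fh.write(self.wild_type + "\n")
            fh.write(">deletion synthetic template with the 70 bp interval excised\n")
            fh.write(self.deletion + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def generate_amplicon_fixture(
    seed: int = 0,
    product_length: int = WWOX_WILDTYPE_PRODUCT,
    deletion_size: int = WWOX_DELETION_SIZE,
    flank: int = 60,
) -> AmpliconFixture:
    """Build templates on which the published primers amplify the published
    bands: ``product_length`` (298 bp) on the wild type and
    ``product_length - deletion_size`` (228 bp) on the deletion allele.

    The primer sites sit exactly ``product_length`` apart outer edge to outer
    edge with the deletion interval strictly between them; random filler is
    regenerated until neither primer site occurs anywhere else in either
    template.
    """
    from Bio.Seq import Seq

    fwd = WWOX_FORWARD_PRIMER
    rc_rev = str(Seq(WWOX_REVERSE_PRIMER).reverse_complement())
    interior = product_length - len(fwd) - len(rc_rev)
    if interior <= deletion_size:
        raise ValueError("product too short to contain the deletion interval")
    left_pad = (interior - deletion_size) // 2
    right_pad = interior - deletion_size - left_pad
    rng = np.random.default_rng(seed)
    for _ in range(100):
        del_block = _random_seq(rng, deletion_size)
        wild = (_random_seq(rng, flank) + fwd + _random_seq(rng, left_pad)
                + del_block + _random_seq(rng, right_pad) + rc_rev
                + _random_seq(rng, flank))
        del_start = flank + len(fwd) + left_pad + 1  # 1-based inclusive
        deletion = wild[: del_start - 1] + wild[del_start - 1 + deletion_size:]
        ok = all(tmpl.count(site) == 1
                 for tmpl in (wild, deletion) for site in (fwd, rc_rev))
        if ok:
            return AmpliconFixture(
                wild_type=wild, deletion=deletion,
                primers=PrimerPair(fwd, WWOX_REVERSE_PRIMER),
                deletion_interval=(del_start, del_start + deletion_size - 1),
            )
    raise RuntimeError("could not place unique primer sites (pathological seed)")
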