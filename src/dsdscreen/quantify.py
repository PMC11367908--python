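"""Ligation-probe copy-number quantification, in-silico PCR and qPCR analysis.

Copy number from multiplex ligation-probe peak signals follows the standard
MLPA-style two-stage normalisation: within a sample, the target peak is
divided by the arithmetic mean of the three reference-gene peaks (defaults
ACTB, COL10A1, GCG); across samples, that ratio is scaled so the median of
the control samples sits at two copies.  The control baseline is the median,
not the mean, so a single deletion carrier contaminating the control group
cannot shift the diploid anchor.

In-silico PCR predicts amplicon lengths by exact primer matching (the
forward primer on the given strand, the reverse primer as its reverse
complement downstream); product length is measured outer edge to outer edge,
1-based inclusive.  Relative expression uses the delta-delta-Ct method with
triplicate Ct values per individual and a configurable calibrator group.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "REFERENCE_PROBES",
    "ProbeSignalTable",
    "CNCall",
    "CopyClassThresholds",
    "PrimerPair",
    "ExpressionRecord",
    "DdctResult",
    "normalize_signal",
    "relative_copy_number",
    "classify_copy_class",
    "predict_amplicons",
    "sry_status",
    "ddct",
]

#: default internal reference controls of the ligation-probe assay
REFERENCE_PROBES = ("ACTB", "COL10A1", "GCG")

_VALID_BASES = frozenset("ACGT")


@dataclass
class ProbeSignalTable:
    """Per-sample fluorescent peak signals for target and reference probes."""

    data: pd.DataFrame
    reference_probes: tuple[str, ...] = REFERENCE_PROBES

    def __post_init__(self) -> None:
        required = ["sample_id", "group", "probe_id", "peak_signal"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"probe signal table missing column(s) {missing}")
        self.data = self.data[required].copy()
        self.data["peak_signal"] = self.data["peak_signal"].astype(float)
        if (self.data["peak_signal"] <= 0).any():
            raise ValueError("peak_signal values must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 reference_probes: Sequence[str] = REFERENCE_PROBES) -> "ProbeSignalTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df, tuple(reference_probes))

    def to_tsv(self, path: str | Path, header_comments: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    def group_of(self, sample_id: str) -> str:
        sub = self.data[self.data["sample_id"] == sample_id]
        return str(sub["group"].iloc[0])

    def peak(self, sample_id: str, probe_id: str) -> float:
        sub = self.data[(self.data["sample_id"] == sample_id)
                        & (self.data["probe_id"] == probe_id)]
        if sub.empty:
            raise KeyError(f"no peak for sample {sample_id!r}, probe {probe_id!r}")
        return float(sub["peak_signal"].iloc[0])


def normalize_signal(table: ProbeSignalTable, sample_id: str, probe_id: str) -> float:
    """Target peak over the arithmetic mean of the reference-probe peaks.

    Scale-invariant within a sample: multiplying every peak of the sample by
    k > 0 leaves the ratio unchanged.
    """
    target = table.peak(sample_id, probe_id)
    refs = []
    for rp in table.reference_probes:
        try:
            refs.append(table.peak(sample_id, rp))
        except KeyError:
            raise ValueError(f"sample {sample_id!r} is missing reference probe {rp!r}")
    return target / (sum(refs) / len(refs))


@dataclass(frozen=True)
class CopyClassThresholds:
    """Copy-unit boundaries for classifying a relative copy number (diploid
    reference = 2 copies): below ``zero_one`` -> 0 copies, up to ``one_two``
    -> 1, up to ``two_gain`` -> 2, at or above it -> gain."""

    zero_one: float = 0.5
    one_two: float = 1.5
    two_gain: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.zero_one < self.one_two < self.two_gain):
            raise ValueError("thresholds must be positive and increasing")


def classify_copy_class(relative_cn: float,
                        thresholds: CopyClassThresholds | None = None) -> str:
    """Bin a relative copy number into {'0', '1', '2', 'gain'}."""
    if relative_cn < 0:
        raise ValueError("relative copy number cannot be negative")
    t = thresholds or CopyClassThresholds()
    if relative_cn < t.zero_one:
        return "0"
    if relative_cn < t.one_two:
        return "1"
    if relative_cn < t.two_gain:
        return "2"
    return "gain"


@dataclass
class CNCall:
    sample_id: str
    probe_id: str
    normalized_signal: float
    relative_cn: float
    copy_class: str


def relative_copy_number(
    table: ProbeSignalTable,
    probe_id: str,
    controls: set[str],
    thresholds: CopyClassThresholds | None = None,
) -> dict[str, CNCall]:
    """Per-sample relative copy number at one target probe.

    ``relative_cn(s) = 2 * normalize_signal(s) / median over controls`` —
    the control group is thereby anchored at two copies (its median relative
    copy number is exactly 2 by construction).
    """
    if not controls:
        raise ValueError("relative_copy_number requires at least one control sample")
    norm = {s: normalize_signal(table, s, probe_id) for s in table.samples()}
    missing = controls - set(norm)
    if missing:
        raise ValueError(f"control sample(s) absent from table: {sorted(missing)}")
    baseline = statistics.median(norm[c] for c in controls)
    out = {}
    for s, v in norm.items():
        rel = 2.0 * v / baseline
        out[s] = CNCall(sample_id=s, probe_id=probe_id, normalized_signal=v,
                        relative_cn=rel,
                        copy_class=classify_copy_class(rel, thresholds))
    return out


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq or not set(seq.upper()) <= _VALID_BASES:
                raise ValueError(f"{name} primer must be a non-empty ACGT string, got {seq!r}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def predict_amplicons(template: str, primers: PrimerPair) -> list[int]:
    """Predicted PCR product lengths on ``template`` under exact matching.

    The forward primer is searched on the given strand; the reverse primer
    binds where its reverse complement occurs downstream.  Every pairing with
    the forward site starting before the reverse site is reported; product
    length spans outer edge to outer edge (1-based inclusive).  No binding
    site yields an empty list, not an error.
    """
    template = template.upper()
    if not set(template) <= _VALID_BASES:
        bad = sorted(set(template) - _VALID_BASES)
        raise ValueError(f"template contains non-ACGT character(s) {bad}")
    rc_reverse = str(Seq(primers.reverse).reverse_complement())
    fwd_sites = _find_all(template, primers.forward)
    rev_sites = _find_all(template, rc_reverse)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r >= f:
                end = r + len(rc_reverse)  # exclusive 0-based end
                products.append(end - f)
    return sorted(products)


def sry_status(bands: Mapping[str, bool]) -> str:
    """Interpret the duplex SRY/GAPDH sexing assay.

    The GAPDH band is the internal control: without it the assay is void
    regardless of the SRY lane.
    """
    if not bands.get("GAPDH", False):
        return "assay_failure"
    return "sry_positive" if bands.get("SRY", False) else "sry_negative"


# ---------------------------------------------------------------------------
# delta-delta-Ct expression analysis
# ---------------------------------------------------------------------------

EXPRESSION_GROUPS = ("normal_female", "xx_dsd", "normal_male")


@dataclass
class ExpressionRecord:
    """Triplicate Ct values for one individual, one target gene, with the
    reference gene (GAPDH) measured alongside."""

    individual_id: str
    group: str
    gene: str
    ct_target: tuple[float, float, float]
    ct_reference: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, cts in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if len(cts) != 3:
                raise ValueError(f"{name} must hold exactly three replicate Ct values")
            if any(c <= 0 for c in cts):
                raise ValueError(f"{name} Ct values must be positive")


@dataclass
class DdctResult:
    """Per-individual and per-group relative expression (fold changes)."""

    gene: str
    calibrator_group: str
    per_individual: pd.DataFrame  # individual_id, group, dct, ddct, fold
    group_mean_fold: dict[str, float]
    welch_p: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{"group": g, "mean_fold": f, "welch_p_vs_calibrator": self.welch_p.get(g)}
                for g, f in self.group_mean_fold.items()]
        return pd.DataFrame(rows)


def ddct(records: Sequence[ExpressionRecord], gene: str,
         calibrator_group: str = "normal_female",
         welch_test: bool = True) -> DdctResult:
    """Relative expression by the delta-delta-Ct method.

    ΔCt(i) = mean target Ct − mean reference Ct; ΔΔCt(i) = ΔCt(i) − mean
    calibrator ΔCt; fold(i) = 2^(−ΔΔCt(i)).  The calibrator group's mean
    ΔΔCt is zero by construction.  The optional Welch t-test on ΔCt between
    each group and the calibrator is an analysis extension, not part of the
    published method.
    """
    recs = [r for r in records if r.gene == gene]
    if not recs:
        raise ValueError(f"no expression records for gene {gene!r}")
    rows = []
    for r in recs:
        dct = statistics.fmean(r.ct_target) - statistics.fmean(r.ct_reference)
        rows.append({"individual_id": r.individual_id, "group": r.group, "dct": dct})
    df = pd.DataFrame(rows)
    cal = df[df["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no records for {gene!r}")
    cal_mean = cal["dct"].mean()
    df["ddct"] = df["dct"] - cal_mean
    df["fold"] = 2.0 ** (-df["ddct"])
    group_mean = {g: float(sub["fold"].mean()) for g, sub in df.groupby("group", sort=False)}
    welch_p: dict[str, float] = {}
    if welch_test:
        for g, sub in df.groupby("group", sort=False):
            if g == calibrator_group or len(sub) < 2 or len(cal) < 2:
                continue
            with warnings.catch_warnings():
                # zero replicate variance (e.g. noise-free simulations) is fine
                warnings.simplefilter("ignore", RuntimeWarning)
                t = stats.ttest_ind(sub["dct"], cal["dct"], equal_var=False)
            p = float(t.pvalue)
            welch_p[g] = p if math.isfinite(p) else float("nan")
    return DdctResult(gene=gene, calibrator_group=calibrator_group,
                      per_individual=df, group_mean_fold=group_mean, welch_p=welch_p)


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a qPCR Ct table (TSV columns: individual_id, group, gene,
    ct_target_1..3, ct_reference_1..3)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        records.append(ExpressionRecord(
            individual_id=str(row["individual_id"]), group=str(row["group"]),
            gene=str(row["gene"]),
            ct_target=(row["ct_target_1"], row["ct_target_2"], row["ct_target_3"]),
            ct_reference=(row["ct_reference_1"], row["ct_reference_2"], row["ct_reference_3"]),
        ))
    return records


def write_expression_table(records: Sequence[ExpressionRecord], path: str | Path,
                           header_comments: Iterable[str] = ()) -> None:
    rows = []
    for r in records:
        row = {"individual_id": r.individual_id, "group": r.group, "gene": r.gene}
        row.update({f"ct_target_{i+1}": c for i, c in enumerate(r.ct_target)})
        row.update({f"ct_reference_{i+1}": c for i, c in enumerate(r.ct_reference)})
        rows.append(row)
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.4f")
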