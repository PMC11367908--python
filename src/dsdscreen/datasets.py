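"""Shipped reference fixtures: the candidate gene panel, the 14-SV candidate
table and the cohort carrier table used for burden/prevalence summaries."""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .io import read_gene_panel, read_sv_table
from .model import GenePanel, SVRecord

__all__ = [
    "candidate_snp_panel",
    "candidate_sv_table",
    "cohort_sv_carriers",
    "data_path",
]


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("dsdscreen.data") / name) as p:
        return Path(p)


def candidate_snp_panel() -> GenePanel:
    """The 11-gene candidate panel behind the 27 validated SNPs."""
    return read_gene_panel(data_path("candidate_snp_panel.tsv"))


def candidate_sv_table() -> list[SVRecord]:
    """The 14 candidate structural variants (types, coordinates, genes)."""
    return read_sv_table(data_path("candidate_svs.tsv"), dialect="tsv")


def cohort_sv_carriers() -> dict[str, set[str]]:
    """Per-individual candidate-SV carrier sets for the 32 affected pigs."""
    carriers: dict[str, set[str]] = {}
    with open(data_path("cohort_sv_carriers.tsv"), newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            svs = {s for s in (row["svs"] or "").split(";") if s}
            carriers[row["individual_id"]] = svs
    return carriers
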