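import pytest

from dsdscreen.model import (
    AnnotatedSNV,
    Effect,
    GenotypeCall,
    Region,
    Role,
    SampleRole,
)

G = GenotypeCall


def make_snv(chrom, pos, nf, d1, d2, effect=Effect.NONSYNONYMOUS,
             region=Region.EXONIC, gene="", ref="A", alt="G"):
    return AnnotatedSNV(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, region=region,
        effect=effect, genotypes={"NF": nf, "D1": d1, "D2": d2},
    )


@pytest.fixture
def trio_roles():
    return [
        SampleRole("NF", Role.CONTROL_FEMALE),
        SampleRole("D1", Role.AFFECTED),
        SampleRole("D2", Role.AFFECTED),
    ]


@pytest.fixture
def toy_trio_table():
    """Six nonsynonymous variants covering each screen pattern:
    v1 -> A, v2 -> B, v3 -> C, v4 -> D, v5/v6 -> no criterion."""
    return [
        make_snv("1", 100, G.ABSENT, G.HOM, G.HOM),   # v1: A
        make_snv("1", 200, G.HOM, G.ABSENT, G.ABSENT),  # v2: B
        make_snv("1", 300, G.HET, G.HOM, G.HOM),      # v3: C
        make_snv("1", 400, G.HET, G.ABSENT, G.ABSENT),  # v4: D
        make_snv("1", 500, G.HOM, G.HOM, G.HOM),      # v5: shared hom
        make_snv("1", 600, G.ABSENT, G.HOM, G.HET),   # v6: discordant affected
    ]
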