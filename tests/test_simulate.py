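"""Generator contracts: determinism, planted-truth recovery, exact-count and
sampling-mode cohorts, noise-free signal and Ct generation."""

import math

import numpy as np
import pytest

from dsdscreen.cohort import genotype_frequencies
from dsdscreen.inheritance import screen_all
from dsdscreen.io import write_snv_table, write_sv_table
from dsdscreen.model import Role, SampleRole
from dsdscreen.quantify import ddct, predict_amplicons, relative_copy_number
from dsdscreen.simulate import (
    CohortSimConfig,
    LocusSpec,
    QpcrSimConfig,
    SignalSimConfig,
    SVSimConfig,
    TrioSimConfig,
    generate_amplicon_fixture,
    generate_cnvplex,
    generate_cohort,
    generate_qpcr,
    generate_sv_sets,
    generate_trio_snvs,
)


TRIO_ROLES = [SampleRole("NF", Role.CONTROL_FEMALE),
              SampleRole("D1", Role.AFFECTED), SampleRole("D2", Role.AFFECTED)]


class TestTrioGenerator:
    def test_zero_counts_give_empty_table(self):
        recs, truth = generate_trio_snvs(TrioSimConfig(
            kA=0, kB=0, kC=0, kD=0, k_shared_hom=0, k_single_affected=0,
            k_synonymous=0, k_intronic=0, seed=1))
        assert recs == [] and truth == {}

    def test_planted_recovery_is_exact(self):
        cfg = TrioSimConfig(kA=50, kB=30, kC=20, kD=10, k_shared_hom=100,
                            k_single_affected=50, k_synonymous=40,
                            k_intronic=200, seed=7)
        recs, truth = generate_trio_snvs(cfg)
        assert len(recs) == 500
        result = screen_all(recs, TRIO_ROLES)
        assert result.counts() == {"A": 50, "B": 30, "C": 20, "D": 10}
        # every planted variant recovered under exactly its class, and no
        # background variant recovered at all
        for key, cls in truth.items():
            for c in "ABCD":
                assert (key in result.criteria[c]) == (cls == c)

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_recovery_holds_for_any_seed(self, seed):
        cfg = TrioSimConfig(kA=5, kB=4, kC=3, kD=2, seed=seed)
        recs, _ = generate_trio_snvs(cfg)
        assert screen_all(recs, TRIO_ROLES).counts() == {"A": 5, "B": 4, "C": 3, "D": 2}

    def test_deterministic_byte_identical_output(self, tmp_path):
        cfg = TrioSimConfig(seed=42)
        paths = []
        for i in (1, 2):
            recs, _ = generate_trio_snvs(cfg)
            p = tmp_path / f"run{i}.tsv"
            write_snv_table(recs, p, samples=["NF", "D1", "D2"])
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestSVGenerator:
    def test_planted_counts(self):
        svs, truth = generate_sv_sets(SVSimConfig(seed=3))
        from dsdscreen.sv import screen_step_a, screen_step_b

        step_a = screen_step_a(svs, "NF", "D2")
        step_b = screen_step_b(step_a, [r for r in svs if r.present_in("D1")])
        assert (len(step_a), len(step_b)) == (35, 20)

    def test_zero_concordant_gives_empty_step_b(self):
        svs, _ = generate_sv_sets(SVSimConfig(n_concordant=0, seed=1))
        from dsdscreen.sv import screen_step_a, screen_step_b

        step_a = screen_step_a(svs, "NF", "D2")
        assert screen_step_b(step_a, [r for r in svs if r.present_in("D1")]) == []

    def test_deterministic_byte_identical_output(self, tmp_path):
        paths = []
        for i in (1, 2):
            svs, _ = generate_sv_sets(SVSimConfig(seed=9))
            p = tmp_path / f"run{i}.tsv"
            write_sv_table(svs, p, samples=["NF", "D1", "D2"])
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestCohortGenerator:
    def test_exact_mode_counts_reproduced_bit_exactly(self):
        cfg = CohortSimConfig(loci={
            "L": LocusSpec(ref="T", alt="C",
                           counts={"affected": {"TT": 28, "TC": 4},
                                   "control": {"CC": 32}})}, seed=5)
        table, _ = generate_cohort(cfg)
        e = genotype_frequencies(table, "L", "affected")
        assert e.genotype_counts == {"TT": 28, "TC": 4, "CC": 0}
        assert e.genotype_freqs == {"TT": 0.875, "TC": 0.125, "CC": 0.0}

    def test_counts_exceeding_group_size_rejected(self):
        cfg = CohortSimConfig(loci={
            "L": LocusSpec(ref="T", alt="C", counts={"affected": {"TT": 40}})},
            n_affected=32, seed=0)
        with pytest.raises(ValueError, match="exceed"):
            generate_cohort(cfg)

    def test_sampling_mode_degenerate_frequency(self):
        cfg = CohortSimConfig(loci={
            "L": LocusSpec(ref="T", alt="C", freqs={
                "affected": {"TT": 1.0}, "control": {"TT": 1.0}})}, seed=0)
        table, _ = generate_cohort(cfg)
        e = genotype_frequencies(table, "L", "affected")
        assert e.genotype_freqs["TT"] == 1.0

    @pytest.mark.parametrize("n", [32, 320, 3200])
    def test_sampling_mode_converges_to_configured_frequencies(self, n):
        freqs = {"TT": 0.6, "TC": 0.3, "CC": 0.1}
        cfg = CohortSimConfig(loci={
            "L": LocusSpec(ref="T", alt="C",
                           freqs={"affected": freqs, "control": freqs})},
            n_affected=n, n_control=n, seed=13)
        table, _ = generate_cohort(cfg)
        e = genotype_frequencies(table, "L", "affected")
        for g, p in freqs.items():
            tol = 3 * math.sqrt(p * (1 - p) / n)
            assert abs(e.genotype_freqs[g] - p) <= tol


class TestSignalGenerator:
    def _configs(self, cv, seed):
        copies = {f"d{i:02d}": {"probe": [0, 1, 2][i % 3]} for i in range(32)}
        copies.update({f"c{i:02d}": {"probe": 2} for i in range(32)})
        groups = {s: ("affected" if s.startswith("d") else "control") for s in copies}
        return SignalSimConfig(copies=copies, groups=groups, cv=cv, seed=seed)

    def test_noise_free_copies_recover_exactly(self):
        table, truth = generate_cnvplex(self._configs(cv=0.0, seed=0))
        calls = relative_copy_number(table, "probe",
                                     {s for s in truth if s.startswith("c")})
        for s, probes in truth.items():
            if probes["probe"] > 0:
                assert calls[s].relative_cn == pytest.approx(probes["probe"])

    def test_noisy_classification_recovers_at_least_99pct(self):
        table, truth = generate_cnvplex(self._configs(cv=0.10, seed=11))
        controls = {s for s in truth if s.startswith("c")}
        calls = relative_copy_number(table, "probe", controls)
        correct = sum(1 for s in truth
                      if calls[s].copy_class == str(truth[s]["probe"]))
        assert correct / len(truth) >= 0.99
        med = float(np.median([calls[c].relative_cn for c in controls]))
        assert med == pytest.approx(2.0)

    def test_zero_copy_floor_keeps_peaks_positive(self):
        table, _ = generate_cnvplex(self._configs(cv=0.10, seed=2))
        assert (table.data["peak_signal"] > 0).all()

    def test_invalid_copy_count_rejected(self):
        with pytest.raises(ValueError, match="0..3"):
            SignalSimConfig(copies={"s": {"p": 5}})


class TestQpcrGenerator:
    def test_noise_free_null_gives_fold_one(self):
        recs, _ = generate_qpcr(QpcrSimConfig(group_log2_fold={"xx_dsd": 0.0},
                                              replicate_sd=0.0, seed=1))
        out = ddct(recs, "IFITM1")
        assert all(f == pytest.approx(1.0) for f in out.group_mean_fold.values())

    def test_noise_free_offset_gives_exact_fold(self):
        recs, truth = generate_qpcr(QpcrSimConfig(group_log2_fold={"xx_dsd": 2.0},
                                                  replicate_sd=0.0, seed=1))
        out = ddct(recs, "IFITM1")
        assert truth["xx_dsd"] == 4.0
        assert out.group_mean_fold["xx_dsd"] == pytest.approx(4.0)


class TestAmpliconFixture:
    def test_published_band_sizes(self):
        fix = generate_amplicon_fixture(seed=0)
        assert predict_amplicons(fix.wild_type, fix.primers) == [298]
        assert predict_amplicons(fix.deletion, fix.primers) == [228]

    def test_band_difference_is_the_deletion_size(self):
        fix = generate_amplicon_fixture(seed=4)
        (wt,) = predict_amplicons(fix.wild_type, fix.primers)
        (dl,) = predict_amplicons(fix.deletion, fix.primers)
        assert wt - dl == 70

    def test_primer_sites_unique_and_interval_consistent(self):
        from Bio.Seq import Seq

        fix = generate_amplicon_fixture(seed=8)
        rc_rev = str(Seq(fix.primers.reverse).reverse_complement())
        for tmpl in (fix.wild_type, fix.deletion):
            assert tmpl.count(fix.primers.forward) == 1
            assert tmpl.count(rc_rev) == 1
        s, e = fix.deletion_interval
        assert e - s + 1 == 70
        excised = fix.wild_type[:s - 1] + fix.wild_type[e:]
        assert excised == fix.deletion

    def test_fasta_round_trip(self, tmp_path):
        from Bio import SeqIO

        fix = generate_amplicon_fixture(seed=0)
        path = tmp_path / "templates.fasta"
        fix.write_fasta(path)
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert seqs == {"wild_type": fix.wild_type, "deletion": fix.deletion}
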