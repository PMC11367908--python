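"""Copy-number quantification, in-silico PCR and delta-delta-Ct analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsdscreen.quantify import (
    CopyClassThresholds,
    ExpressionRecord,
    PrimerPair,
    ProbeSignalTable,
    classify_copy_class,
    ddct,
    normalize_signal,
    predict_amplicons,
    relative_copy_number,
    sry_status,
)
from dsdscreen.simulate import QpcrSimConfig, generate_qpcr


def signal_table(rows):
    return ProbeSignalTable(pd.DataFrame(
        rows, columns=["sample_id", "group", "probe_id", "peak_signal"]))


def sample_rows(sample, group, target, refs):
    rows = [(sample, group, "tgt", target)]
    rows += [(sample, group, p, r) for p, r in zip(("ACTB", "COL10A1", "GCG"), refs)]
    return rows


class TestNormalize:
    def test_equal_peaks_give_one(self):
        t = signal_table(sample_rows("s1", "affected", 700.0, (700, 700, 700)))
        assert normalize_signal(t, "s1", "tgt") == 1.0

    def test_halved_target(self):
        t = signal_table(sample_rows("s1", "affected", 500.0, (1000, 1000, 1000)))
        assert normalize_signal(t, "s1", "tgt") == 0.5

    def test_missing_reference_probe_named(self):
        rows = sample_rows("s1", "affected", 500.0, (1000, 1000, 1000))
        t = signal_table([r for r in rows if r[2] != "GCG"])
        with pytest.raises(ValueError, match="GCG"):
            normalize_signal(t, "s1", "tgt")

    @given(st.floats(10, 1e5), st.floats(10, 1e5), st.floats(10, 1e5),
           st.floats(10, 1e5), st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_oracle(self, tgt, r1, r2, r3, k):
        t1 = signal_table(sample_rows("s", "g", tgt, (r1, r2, r3)))
        tk = signal_table(sample_rows("s", "g", tgt * k, (r1 * k, r2 * k, r3 * k)))
        expected = tgt / ((r1 + r2 + r3) / 3)  # one-line independent recompute
        assert normalize_signal(t1, "s", "tgt") == pytest.approx(expected)
        assert normalize_signal(tk, "s", "tgt") == pytest.approx(expected)


class TestRelativeCopyNumber:
    def _table(self, targets):
        rows = []
        for sample, tgt in targets.items():
            group = "control" if sample.startswith("c") else "affected"
            rows += sample_rows(sample, group, tgt, (1000, 1000, 1000))
        return signal_table(rows)

    def test_sample_identical_to_controls_is_two_copies(self):
        t = self._table({"c1": 800.0, "c2": 800.0, "c3": 800.0, "s1": 800.0})
        calls = relative_copy_number(t, "tgt", {"c1", "c2", "c3"})
        assert calls["s1"].relative_cn == pytest.approx(2.0)
        assert calls["s1"].copy_class == "2"

    def test_halved_target_is_one_copy(self):
        t = self._table({"c1": 800.0, "c2": 800.0, "s1": 400.0})
        calls = relative_copy_number(t, "tgt", {"c1", "c2"})
        assert calls["s1"].relative_cn == pytest.approx(1.0)
        assert calls["s1"].copy_class == "1"

    def test_control_median_is_exactly_two(self):
        t = self._table({f"c{i}": 700.0 + 40 * i for i in range(6)})
        calls = relative_copy_number(t, "tgt", {f"c{i}" for i in range(6)})
        med = float(np.median([calls[f"c{i}"].relative_cn for i in range(6)]))
        assert med == pytest.approx(2.0)

    def test_empty_control_set_rejected(self):
        t = self._table({"s1": 500.0})
        with pytest.raises(ValueError, match="control"):
            relative_copy_number(t, "tgt", set())


class TestClassify:
    @pytest.mark.parametrize("cn,expected", [
        (0.0, "0"), (0.49, "0"), (0.5, "1"), (0.97, "1"), (1.49, "1"),
        (1.5, "2"), (2.0, "2"), (2.49, "2"), (2.5, "gain"), (4.0, "gain"),
    ])
    def test_default_thresholds(self, cn, expected):
        assert classify_copy_class(cn) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_copy_class(-0.1)

    def test_custom_thresholds(self):
        t = CopyClassThresholds(zero_one=0.3, one_two=1.2, two_gain=3.0)
        assert classify_copy_class(1.3, t) == "2"
        with pytest.raises(ValueError):
            CopyClassThresholds(zero_one=2.0, one_two=1.0, two_gain=3.0)


def brute_force_products(template, fwd, rc_rev):
    """Quadratic scan oracle for amplicon prediction."""
    out = []
    for i in range(len(template) - len(fwd) + 1):
        if template[i:i + len(fwd)] != fwd:
            continue
        for j in range(i, len(template) - len(rc_rev) + 1):
            if template[j:j + len(rc_rev)] == rc_rev:
                out.append(j + len(rc_rev) - i)
    return sorted(out)


class TestAmplicons:
    PRIMERS = PrimerPair("ATCCTCGCAGGACACAGGAG", "TGTGTAGCGGCCTCCAGAAG")

    def test_minimal_template(self):
        from Bio.Seq import Seq

        p = PrimerPair("A" * 20, "C" * 20)  # rc of reverse is G*20
        template = "A" * 20 + "T" * 10 + str(Seq("C" * 20).reverse_complement())
        assert predict_amplicons(template, p) == [50]

    def test_no_product_is_empty_not_error(self):
        assert predict_amplicons("ACGT" * 30, self.PRIMERS) == []

    def test_invalid_primer_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair("ACGN", "ACGT")

    def test_two_forward_sites_match_brute_force(self):
        from Bio.Seq import Seq

        fwd = "ACCGTACCGTAACCGGTTAA"
        rev = "TTGGCCAATTGGCCAATTGG"
        rc_rev = str(Seq(rev).reverse_complement())
        rng = np.random.default_rng(5)
        filler = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        template = fwd + filler + fwd + filler[::-1] + rc_rev + "ACGTAC"
        got = predict_amplicons(template, PrimerPair(fwd, rev))
        assert len(got) == 2
        assert got == brute_force_products(template, fwd, rc_rev)

    @given(st.integers(1, 120), st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_excision_shortens_products_by_exactly_d(self, d, seed):
        """Removing a d-bp interval strictly between the primer sites shortens
        every spanning product by exactly d (d=70 gives the 298->228 pair)."""
        from dsdscreen.simulate import generate_amplicon_fixture

        fix = generate_amplicon_fixture(seed=seed, deletion_size=d,
                                        product_length=160 + d)
        wt = predict_amplicons(fix.wild_type, fix.primers)
        cut = predict_amplicons(fix.deletion, fix.primers)
        assert wt == [160 + d]
        assert cut == [160]


class TestSryStatus:
    @pytest.mark.parametrize("bands,expected", [
        ({"GAPDH": True, "SRY": False}, "sry_negative"),
        ({"GAPDH": True, "SRY": True}, "sry_positive"),
        ({"GAPDH": False, "SRY": True}, "assay_failure"),
        ({"GAPDH": False, "SRY": False}, "assay_failure"),
    ])
    def test_duplex_interpretation(self, bands, expected):
        assert sry_status(bands) == expected


class TestDdct:
    def _record(self, ind, group, dct, gene="IFITM1"):
        return ExpressionRecord(individual_id=ind, group=group, gene=gene,
                                ct_target=(20.0 + dct,) * 3,
                                ct_reference=(20.0,) * 3)

    def test_calibrator_matching_individual_has_fold_one(self):
        recs = [self._record("a", "normal_female", 5.0),
                self._record("b", "xx_dsd", 5.0)]
        out = ddct(recs, "IFITM1")
        assert out.group_mean_fold["xx_dsd"] == pytest.approx(1.0)

    def test_ddct_minus_three_gives_fold_eight(self):
        recs = [self._record("a", "normal_female", 5.0),
                self._record("b", "xx_dsd", 2.0)]
        out = ddct(recs, "IFITM1")
        assert out.group_mean_fold["xx_dsd"] == pytest.approx(8.0)

    def test_calibrator_mean_ddct_zero_and_folds_positive(self):
        rng = np.random.default_rng(1)
        recs = [self._record(f"c{i}", "normal_female", float(d))
                for i, d in enumerate(rng.normal(5, 1, 5))]
        out = ddct(recs, "IFITM1")
        cal = out.per_individual[out.per_individual["group"] == "normal_female"]
        assert cal["ddct"].mean() == pytest.approx(0.0, abs=1e-12)
        assert (out.per_individual["fold"] > 0).all()

    def test_replicate_contract_enforced(self):
        with pytest.raises(ValueError, match="three replicate"):
            ExpressionRecord("a", "xx_dsd", "IFITM1", (20.0, 21.0), (20.0,) * 3)

    def test_missing_calibrator_rejected(self):
        recs = [self._record("b", "xx_dsd", 2.0)]
        with pytest.raises(ValueError, match="calibrator"):
            ddct(recs, "IFITM1")

    def test_simulated_fold_recovery(self):
        recs, truth = generate_qpcr(QpcrSimConfig(
            group_log2_fold={"xx_dsd": 2.0}, replicate_sd=0.1,
            n_per_group=3, seed=5))
        out = ddct(recs, "IFITM1")
        assert truth["xx_dsd"] == 4.0
        assert 3.2 <= out.group_mean_fold["xx_dsd"] <= 5.0
        assert "xx_dsd" in out.welch_p
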