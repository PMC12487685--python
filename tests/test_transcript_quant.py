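import numpy as np
import pandas as pd
import pytest

from calmkit.transcript_quant import (
    AlleleCount,
    allele_fractions,
    alt_fraction_from_fold,
    compute_fpkm,
    ddct_estimate,
    fpkm_table,
    mutant_transcript_share,
)


class TestComputeFpkm:
    @pytest.mark.parametrize(
        "count, length_kb, lib_m, expected",
        [(100, 2.0, 10.0, 5.0), (0, 1.5, 30.0, 0.0), (1, 1.0, 1.0, 1.0)],
    )
    def test_direct_arithmetic(self, count, length_kb, lib_m, expected):
        assert compute_fpkm(count, length_kb, lib_m) == pytest.approx(expected)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 5000, 200).astype(float)
        lengths = rng.uniform(0.3, 20.0, 200)
        lib = 37.5
        vec = compute_fpkm(counts, lengths, lib)
        oracle = np.array([c / (l * lib) for c, l in zip(counts, lengths)])
        assert np.max(np.abs(vec - oracle)) < 1e-12

    @pytest.mark.parametrize("length_kb, lib_m", [(0.0, 10.0), (2.0, 0.0), (-1.0, 10.0)])
    def test_rejects_degenerate_denominators(self, length_kb, lib_m):
        with pytest.raises(ValueError):
            compute_fpkm(10, length_kb, lib_m)

    def test_table_round_trip_identity(self):
        table = pd.DataFrame(
            {"gene": ["a", "b"], "count": [100, 40], "length_kb": [2.0, 0.5]}
        )
        out = fpkm_table(table, 10.0)
        # the defining identity fpkm * length * lib == count
        assert np.allclose(
            out["fpkm"] * out["length_kb"] * 10.0, out["count"], atol=1e-9
        )


class TestAlleleFractions:
    def test_balanced_counts(self):
        fr = allele_fractions(AlleleCount(50, 50))
        assert fr.ref_fraction == fr.alt_fraction == 0.5
        assert fr.ref_over_alt_fold == 1.0

    def test_fractions_sum_to_one(self):
        fr = allele_fractions(AlleleCount(117, 50))
        assert fr.ref_fraction + fr.alt_fraction == pytest.approx(1.0)

    def test_pure_alt(self):
        fr = allele_fractions(AlleleCount(0, 80))
        assert fr.alt_fraction == 1.0
        assert fr.ref_over_alt_fold == 0.0

    def test_zero_alt_flags_fold_undefined(self):
        fr = allele_fractions(AlleleCount(80, 0))
        assert not fr.fold_defined
        assert np.isinf(fr.ref_over_alt_fold)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            allele_fractions(AlleleCount(0, 0))

    def test_fold_2_34_gives_30_percent_mutant_allele(self):
        # a wild-type over mutant read excess of 2.34-fold corresponds to a
        # mutant allelic fraction of 1/3.34, i.e. ~30 %
        frac = alt_fraction_from_fold(2.34)
        assert frac == pytest.approx(1 / 3.34)
        assert round(100 * frac) == 30


class TestMutantTranscriptShare:
    @pytest.mark.parametrize(
        "alt_fraction, fpkm, expected",
        [
            (0.30, (34.8, 49.0, 41.4), 8.3),  # heterozygous LV
            (1.0, (34.2, 53.2, 35.7), 27.8),  # homozygous LV
            (0.0, (34.8, 49.0, 41.4), 0.0),
        ],
    )
    def test_share_of_total_calm_pool(self, alt_fraction, fpkm, expected):
        assert mutant_transcript_share(alt_fraction, fpkm) == expected

    def test_gene_shares_partition_the_pool(self):
        fpkm = (34.8, 49.0, 41.4)
        shares = [
            mutant_transcript_share(1.0, np.roll(fpkm, -i), ndigits=1)
            for i in range(3)
        ]
        assert abs(sum(shares) - 100.0) <= 0.05

    def test_monotone_in_alt_fraction_and_calm1_fpkm(self):
        base = mutant_transcript_share(0.3, (30.0, 50.0, 40.0), ndigits=None)
        assert mutant_transcript_share(0.4, (30.0, 50.0, 40.0), ndigits=None) > base
        assert mutant_transcript_share(0.3, (35.0, 50.0, 40.0), ndigits=None) > base

    def test_all_zero_fpkm_rejected(self):
        with pytest.raises(ValueError):
            mutant_transcript_share(0.3, (0.0, 0.0, 0.0))


def _ct_table(dct_target, dct_cal, target="atria", cal="LV", gene="Calm1"):
    rows = []
    for tissue, dcts in ((target, dct_target), (cal, dct_cal)):
        for d in dcts:
            rows.append({"gene": gene, "tissue": tissue, "ct": 20.0 + d, "ref_ct": 20.0})
    return pd.DataFrame(rows)


class TestDdctEstimate:
    def test_calibrator_identity(self):
        ct = _ct_table([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        est = ddct_estimate(ct, "Calm1", "atria", "LV", calibrator_fpkm=34.8)
        assert est.fold_change == pytest.approx(1.0)
        assert est.estimate == pytest.approx(34.8)

    def test_one_cycle_halving(self):
        ct = _ct_table([4.0], [3.0])
        est = ddct_estimate(ct, "Calm1", "atria", "LV", calibrator_fpkm=10.0)
        assert est.fold_change == pytest.approx(0.5)

    def test_known_fold_inversion(self):
        # a noiseless Ct table built from a known 3.4-fold difference
        fold = 3.4
        ct = _ct_table([2.0 - np.log2(fold)] * 3, [2.0] * 3)
        est = ddct_estimate(ct, "Calm1", "atria", "LV", calibrator_fpkm=1.0)
        assert est.estimate == pytest.approx(fold, abs=1e-12)

    def test_swapped_tissues_give_reciprocal_fold(self):
        ct = _ct_table([4.1, 3.9, 4.3], [2.9, 3.2, 3.1])
        a = ddct_estimate(ct, "Calm1", "atria", "LV", 1.0)
        b = ddct_estimate(ct, "Calm1", "LV", "atria", 1.0)
        assert a.fold_change * b.fold_change == pytest.approx(1.0, abs=1e-9)

    def test_margins_bracket_estimate(self):
        ct = _ct_table([4.1, 3.9, 4.3], [3.0, 3.1, 2.9])
        est = ddct_estimate(ct, "Calm1", "atria", "LV", 34.8)
        assert est.margin_low <= est.estimate <= est.margin_high
        # band follows the 2^-(ddCt -/+ SEM) convention
        assert est.margin_high == pytest.approx(2 ** (-(est.ddct - est.sem)) * 34.8)

    def test_missing_tissue_rejected(self):
        ct = _ct_table([3.0], [3.0])
        with pytest.raises(ValueError):
            ddct_estimate(ct, "Calm1", "RV", "LV", 1.0)
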