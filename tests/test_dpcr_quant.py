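"""Digital-PCR estimators: closed forms, CIs, multiplex classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapedit import dpcr_quant as dq
from hapedit import synthetic_data as sd
from hapedit.synthetic_data import simulate_multiplex_wells


def simulate_two_channel(n_partitions, copies_a, copies_b, seed, aliquot=True):
    """One reaction with two unlinked species (channels FAM / HEX)."""
    species = [
        sd.MoleculeSpecies("a", {"FAM"}, copies_a),
        sd.MoleculeSpecies("b", {"HEX"}, copies_b),
    ]
    if aliquot:
        species = sd.sample_aliquot(species, seed + 1)
    table, _ = sd.simulate_partitions(n_partitions, species, seed)
    return dq.PartitionCounts.from_table(table)


class TestPoissonLambda:
    def test_zero_positive_gives_zero(self):
        lam = dq.poisson_lambda(0, 10_000)
        assert lam.value == 0.0 and lam.se == 0.0

    def test_closed_form_example(self):
        lam = dq.poisson_lambda(1000, 20_000)
        assert lam.value == pytest.approx(-math.log(0.95), abs=1e-9)
        assert lam.value == pytest.approx(0.051293, abs=1e-6)

    def test_saturation_raises(self):
        with pytest.raises(dq.SaturationError, match="dilute"):
            dq.poisson_lambda(100, 100)

    def test_ci_calibration_at_lambda_03(self):
        """CI covers a true occupancy of 0.3 in ~95 of 100 seeded runs
        (aliquot-resampled molecule counts, multinomial loading)."""
        n, cover = 20_000, 0
        for s in range(100):
            rng = np.random.default_rng(900 + s)
            m = int(rng.poisson(0.3 * n))
            table, _ = sd.simulate_partitions(
                n, [sd.MoleculeSpecies("x", {"FAM"}, m)], seed=int(rng.integers(2**31))
            )
            lam = dq.poisson_lambda(int(table["FAM"].sum()), n)
            if lam.ci[0] <= 0.3 <= lam.ci[1]:
                cover += 1
        assert 90 <= cover <= 99


class TestGainOfSignal:
    def test_half_reference_occupancy_is_fifty_percent(self):
        # lambda_edit = lambda_ref / 2 exactly: the allele-specific ceiling
        n = 100_000
        p_ref = 1 - math.exp(-0.4)
        p_edit = 1 - math.exp(-0.2)
        q = dq.excision_frequency_gain(
            (round(p_edit * n), n), (round(p_ref * n), n)
        )
        assert q.frequency_pct == pytest.approx(50.0, abs=0.01)

    def test_closed_form_example(self):
        q = dq.excision_frequency_gain((500, 20_000), (2000, 20_000))
        assert q.frequency_pct == pytest.approx(
            100 * math.log(0.975) / math.log(0.9), abs=1e-9
        )
        assert q.frequency_pct == pytest.approx(24.03, abs=0.005)

    def test_zero_edit_positives_gives_zero(self):
        q = dq.excision_frequency_gain((0, 20_000), (2000, 20_000))
        assert q.frequency_pct == 0.0

    def test_zero_reference_raises(self):
        with pytest.raises(dq.UndefinedRatioError):
            dq.excision_frequency_gain((10, 100), (0, 100))

    def test_reference_copy_scaling(self):
        raw = dq.excision_frequency_gain((500, 20_000), (2000, 20_000))
        scaled = dq.excision_frequency_gain(
            (500, 20_000), (2000, 20_000), ref_copies_per_genome=4
        )
        assert scaled.frequency_pct == pytest.approx(2 * raw.frequency_pct)


class TestLossOfSignal:
    def test_intact_locus_is_zero(self):
        q = dq.excision_frequency_loss((3000, 20_000), (3000, 20_000))
        assert q.frequency_pct == 0.0

    def test_eighty_percent_ratio_is_twenty(self):
        n = 1_000_000
        p_int = 1 - math.exp(-0.4)
        p_ref = 1 - math.exp(-0.5)
        q = dq.excision_frequency_loss((round(p_int * n), n), (round(p_ref * n), n))
        assert q.frequency_pct == pytest.approx(20.0, abs=0.01)

    def test_negative_estimate_clamped_with_warning(self):
        q = dq.excision_frequency_loss((3100, 20_000), (3000, 20_000))
        assert q.frequency_pct == 0.0
        assert any("clamped" in w for w in q.warnings)

    def test_simulated_quarter_loss_recovered(self):
        n, G = 20_000, 5000
        ests = []
        for s in range(10):
            species = sd.sample_aliquot(
                [
                    sd.MoleculeSpecies("intact", {"FAM"}, round(0.75 * 2 * G)),
                    sd.MoleculeSpecies("ref", {"HEX"}, 2 * G),
                ],
                seed=300 + s,
            )
            table, _ = sd.simulate_partitions(n, species, seed=3000 + s)
            pc = dq.PartitionCounts.from_table(table)
            q = dq.excision_frequency_loss(pc.channel("FAM"), pc.channel("HEX"))
            ests.append(q.frequency_pct)
            se = (q.ci[1] - q.ci[0]) / (2 * dq.Z95)
            assert abs(q.frequency_pct - 25.0) < 3 * se
        assert abs(np.mean(ests) - 25.0) < 1.0


class TestInversion:
    def test_zero_positives(self):
        q = dq.inversion_frequency((0, 8500), (2000, 8500))
        assert q.frequency_pct == 0.0

    def test_half_reference_is_ceiling(self):
        n = 1_000_000
        q = dq.inversion_frequency(
            (round((1 - math.exp(-0.15)) * n), n), (round((1 - math.exp(-0.3)) * n), n)
        )
        assert q.frequency_pct == pytest.approx(50.0, abs=0.01)

    def test_ten_percent_recovery_simulation(self):
        n, G = 20_000, 5000
        pc = simulate_two_channel(n, round(0.1 * 2 * G), 2 * G, seed=17)
        q = dq.inversion_frequency(pc.channel("FAM"), pc.channel("HEX"))
        se = (q.ci[1] - q.ci[0]) / (2 * dq.Z95)
        assert abs(q.frequency_pct - 10.0) < 3 * se


class TestFractionalAbundance:
    def test_symmetric_counts_exactly_half(self):
        for mode in ("poisson", "raw"):
            fa = dq.fractional_abundance((1500, 20_000), (1500, 20_000), mode=mode)
            assert fa.fraction == 0.5

    def test_closed_form_example(self):
        fa = dq.fractional_abundance((1500, 20_000), (500, 20_000))
        la, lb = -math.log(1 - 0.075), -math.log(1 - 0.025)
        assert fa.fraction == pytest.approx(la / (la + lb), abs=1e-9)
        assert fa.fraction == pytest.approx(0.7548, abs=5e-4)

    def test_unedited_heterozygote_simulation_near_half(self):
        pc = simulate_two_channel(20_000, 5000, 5000, seed=23)
        fa = dq.fractional_abundance(pc.channel("FAM"), pc.channel("HEX"))
        assert fa.ci[0] <= 0.5 <= fa.ci[1]
        assert abs(fa.fraction - 0.5) < 0.02

    def test_both_empty_raises(self):
        with pytest.raises(dq.UndefinedRatioError):
            dq.fractional_abundance((0, 100), (0, 100))


class TestExpressionRatio:
    def test_equal_counts_unity_both_modes(self):
        assert dq.expression_ratio((500, 8500), (500, 8500)).frequency_pct == 1.0
        assert dq.expression_ratio(
            (500, 8500), (500, 8500), mode="poisson"
        ).frequency_pct == 1.0

    def test_closed_form_examples(self):
        raw = dq.expression_ratio((1000, 20_000), (4000, 20_000))
        assert raw.frequency_pct == pytest.approx(0.25)
        pois = dq.expression_ratio((1000, 20_000), (4000, 20_000), mode="poisson")
        assert pois.frequency_pct == pytest.approx(
            math.log(0.95) / math.log(0.8), abs=1e-9
        )
        assert pois.frequency_pct == pytest.approx(0.2299, abs=5e-4)

    def test_halved_copies_halve_poisson_ratio(self):
        full = simulate_two_channel(20_000, 6000, 6000, seed=31)
        half = simulate_two_channel(20_000, 3000, 6000, seed=37)
        r_full = dq.expression_ratio(
            full.channel("FAM"), full.channel("HEX"), mode="poisson"
        )
        r_half = dq.expression_ratio(
            half.channel("FAM"), half.channel("HEX"), mode="poisson"
        )
        se = (r_half.ci[1] - r_half.ci[0]) / (2 * dq.Z95)
        assert abs(r_half.frequency_pct - 0.5 * r_full.frequency_pct) < 3 * se

    def test_zero_housekeeping_raises(self):
        with pytest.raises(dq.UndefinedRatioError):
            dq.expression_ratio((100, 8500), (0, 8500))


class TestMultiplexClassify:
    def test_all_negative_single_class(self):
        table = pd.DataFrame(
            {"partition_id": range(5), "FAM": 0, "ROX": 0}
        )
        counts = dq.multiplex_classify(table)
        assert counts["NEG"] == 5
        assert sum(counts.values()) == 5

    def test_enumeration_of_all_signatures(self):
        rows = [
            {"partition_id": i, "FAM": i & 1, "VIC": (i >> 1) & 1, "ROX": (i >> 2) & 1}
            for i in range(8)
        ]
        counts = dq.multiplex_classify(pd.DataFrame(rows))
        assert set(counts.values()) == {1}
        assert len(counts) == 8

    def test_unknown_channel_rejected(self):
        table = pd.DataFrame({"partition_id": [0], "TAMRA": [1]})
        with pytest.raises(dq.DpcrError, match="TAMRA"):
            dq.multiplex_classify(table)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 200))
    def test_counts_conserved_on_random_tables(self, seed, n):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {
                "partition_id": np.arange(n),
                "FAM": rng.integers(0, 2, n),
                "VIC": rng.integers(0, 2, n),
                "ROX": rng.integers(0, 2, n),
                "CY5": rng.integers(0, 2, n),
            }
        )
        counts = dq.multiplex_classify(table)
        assert sum(counts.values()) == n
        pc = dq.PartitionCounts.from_table(table)
        for ch in ("FAM", "VIC", "ROX", "CY5"):
            assert pc.positive(ch) == int(table[ch].sum())


class TestMultiplexSpecificity:
    def test_arithmetic_example(self):
        counts = dq.PartitionCounts(
            {
                "ROX+FAM": 90, "VIC+ROX": 10, "FAM+VIC+ROX": 5,
                "CY5": 300, "NEG": 595,
            },
            channels=("FAM", "VIC", "ROX", "CY5"),
        )
        freq, spec = dq.multiplex_excision_specificity(counts)
        assert spec.target_fraction == pytest.approx(0.90)
        assert spec.excluded_triple_fraction == pytest.approx(5 / 105)
        assert not spec.warning

    def test_triple_warning_at_ten_percent(self):
        counts = dq.PartitionCounts(
            {"ROX+FAM": 80, "VIC+ROX": 8, "FAM+VIC+ROX": 12, "CY5": 100, "NEG": 800},
            channels=("FAM", "VIC", "ROX", "CY5"),
        )
        _, spec = dq.multiplex_excision_specificity(counts)
        assert spec.excluded_triple_fraction >= 0.10
        assert spec.warning

    def test_zero_edit_positive_frequency_and_specificity(self):
        counts = dq.PartitionCounts(
            {"FAM": 50, "VIC": 50, "CY5": 100, "NEG": 800},
            channels=("FAM", "VIC", "ROX", "CY5"),
        )
        freq = dq.multiplex_excision_frequency(counts)
        assert freq.frequency_pct == 0.0
        with pytest.raises(dq.UndefinedSpecificityError):
            dq.multiplex_excision_specificity(counts)

    def test_simulation_recovers_programmed_specificity(self):
        counts, truth = simulate_multiplex_wells(8500, 3, 700, 0.25, 0.92, seed=5)
        _, spec = dq.multiplex_excision_specificity(counts)
        assert abs(100 * spec.target_fraction
                   - 100 * truth.params["target_specificity"]) < 2.0
        assert spec.excluded_triple_fraction < 0.10

    def test_specificity_invariant_to_downsampling(self):
        counts, _ = simulate_multiplex_wells(8500, 3, 700, 0.25, 0.92, seed=6)
        _, full = dq.multiplex_excision_specificity(counts)
        halved = dq.PartitionCounts(
            {sig: n // 2 for sig, n in counts.class_counts.items()},
            channels=counts.channels,
        )
        _, sub = dq.multiplex_excision_specificity(halved)
        assert abs(sub.target_fraction - full.target_fraction) < 0.03


class TestEndToEndRecovery:
    def test_gain_and_loss_agree_on_same_truth(self):
        """Gain- and loss-of-signal estimates of the same simulated excision
        fraction agree within overlapping CIs (clean simulation: no large
        deletions disrupting either amplicon)."""
        n, G, f = 20_000, 5000, 0.25
        for s in range(5):
            species = sd.sample_aliquot(
                [
                    sd.MoleculeSpecies("junction", {"FAM"}, round(f * 2 * G)),
                    sd.MoleculeSpecies("intact", {"VIC"}, round((1 - f) * 2 * G)),
                    sd.MoleculeSpecies("ref", {"CY5"}, 2 * G),
                ],
                seed=500 + s,
            )
            table, _ = sd.simulate_partitions(n, species, seed=5000 + s)
            pc = dq.PartitionCounts.from_table(table)
            gain = dq.excision_frequency_gain(pc.channel("FAM"), pc.channel("CY5"))
            loss = dq.excision_frequency_loss(pc.channel("VIC"), pc.channel("CY5"))
            assert gain.ci[0] <= loss.ci[1] and loss.ci[0] <= gain.ci[1]

    def test_volume_invariance(self):
        """Frequencies are pure ratios: no partition-volume parameter enters
        any estimator (API carries none)."""
        q = dq.excision_frequency_gain((500, 20_000), (2000, 20_000))
        assert q.frequency_pct == pytest.approx(24.03, abs=0.005)

    def test_merge_wells_sums_class_counts(self):
        a = dq.PartitionCounts({"FAM": 10, "NEG": 90}, channels=("FAM",))
        b = dq.PartitionCounts({"FAM": 20, "NEG": 80}, channels=("FAM",))
        merged = dq.merge_wells([a, b])
        assert merged.class_counts == {"FAM": 30, "NEG": 170}
        assert merged.n_partitions == 200
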