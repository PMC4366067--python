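import math

import numpy as np
import pytest

from ploidosage.core import ExpressionTable, InvalidInputError
from ploidosage.qpcr import (
    estimate_transcriptome_size,
    livak_per_genome,
    one_sample_t,
    per_cell_ratio,
    read_qpcr_csv,
    size_ratio,
    tukey_outliers,
    write_qpcr_csv,
)
from ploidosage.simulate import (
    QpcrSimConfig,
    SimulationConfig,
    simulate_qpcr,
    target_expression_tables,
)

from conftest import make_plate
from oracles import t_two_sided_p

# the six per-gene relative transcriptome-size estimates of the study system
SIZE_COLUMN = [0.8, 0.9, 1.6, 0.9, 1.2, 0.8]


class TestLivak:
    def test_identical_cq_gives_ratio_one(self):
        plate = make_plate({"PA": 5.0, "PAA": 5.0})
        expr = livak_per_genome(plate, "rpl35")
        assert expr.ratio_per_genome == pytest.approx(1.0, abs=1e-12)

    def test_one_cycle_shift_halves_the_ratio(self):
        plate = make_plate({"PA": 5.0, "PAA": 6.0})
        assert livak_per_genome(plate, "rpl35").ratio_per_genome == pytest.approx(0.5)

    def test_fractional_ddcq(self):
        plate = make_plate({"PA": 5.00, "PAA": 5.32})
        expr = livak_per_genome(plate, "rpl35")
        assert expr.ratio_per_genome == pytest.approx(2.0 ** -0.32, rel=1e-9)
        assert expr.per_genomotype_mean_delta_cq["PAA"] == pytest.approx(5.32)

    def test_cq_shift_invariance(self):
        """Adding a constant to every Cq of a sample changes nothing."""
        plate = make_plate({"PA": 5.0, "PAA": 4.6})
        base = livak_per_genome(plate, "rpl35").ratio_per_genome
        for s in plate[:3]:
            s.wells = [
                type(w)(w.target, w.template, w.cq + 3.7, w.replicate) for w in s.wells
            ]
        shifted = livak_per_genome(plate, "rpl35").ratio_per_genome
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_missing_reference_target_names_sample_and_target(self):
        plate = make_plate({"PA": 5.0, "PAA": 5.0})
        plate[0].wells = [w for w in plate[0].wells if w.target != "eef1a"]
        with pytest.raises(InvalidInputError, match="eef1a"):
            livak_per_genome(plate, "rpl35")

    def test_missing_genomotype_raises(self):
        plate = make_plate({"PA": 5.0})
        with pytest.raises(InvalidInputError):
            livak_per_genome(plate, "rpl35")


class TestScalingOps:
    @pytest.mark.parametrize(
        "per_genome,expected", [(0.8, 1.2), (1.0, 1.5), (0.6, 0.9)]
    )
    def test_per_cell_triploid_over_diploid(self, per_genome, expected):
        assert per_cell_ratio(per_genome, 3, 2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cell,transcriptome,expected", [(1.2, 1.5, 0.8), (1.2, 1.0, 1.2), (0.7, 0.7, 1.0)]
    )
    def test_size_ratio(self, cell, transcriptome, expected):
        assert size_ratio(cell, transcriptome) == pytest.approx(expected)

    def test_size_ratio_round_trip(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cell, trans = rng.uniform(0.1, 5.0, size=2)
            assert size_ratio(cell, trans) * trans == pytest.approx(cell, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            per_cell_ratio(-1.0, 3, 2)
        with pytest.raises(InvalidInputError):
            size_ratio(1.0, 0.0)


class TestOneSampleT:
    def test_values_equal_to_null(self):
        t, df, p = one_sample_t([1.5, 1.5, 1.5], 1.5)
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_size_column_vs_one(self):
        t, df, p = one_sample_t(SIZE_COLUMN, 1.0)
        assert df == 5
        assert t == pytest.approx(0.26, abs=0.01)
        assert p == pytest.approx(0.81, abs=0.01)

    def test_size_column_vs_one_point_five(self):
        t, df, p = one_sample_t(SIZE_COLUMN, 1.5)
        assert t == pytest.approx(-3.64, abs=0.01)
        assert p == pytest.approx(0.015, abs=0.002)

    def test_zero_variance_off_null_warns(self):
        with pytest.warns(RuntimeWarning):
            t, df, p = one_sample_t([2.0, 2.0], 1.0)
        assert p == 0.0 and math.isinf(t)

    def test_single_value_raises(self):
        with pytest.raises(InvalidInputError):
            one_sample_t([1.0], 1.0)

    def test_matches_integration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            values = rng.normal(loc=rng.uniform(-1, 1), scale=rng.uniform(0.5, 2), size=n)
            null = float(rng.uniform(-1, 1))
            t, df, p = one_sample_t(values, null)
            assert p == pytest.approx(t_two_sided_p(t, df), abs=1e-6)


class TestTukeyOutliers:
    def test_published_size_column_keeps_1_6(self):
        flags = tukey_outliers(SIZE_COLUMN)
        assert not any(flags.values())

    def test_all_equal_values_unflagged(self):
        assert not any(tukey_outliers([1.0] * 6).values())

    def test_collapsed_fences_flag_extreme(self):
        flags = tukey_outliers([1, 1, 1, 1, 1, 10])
        assert flags[5] and not any(flags[i] for i in range(5))

    def test_too_few_values_raise(self):
        with pytest.raises(InvalidInputError):
            tukey_outliers([1.0, 2.0, 3.0])


class TestEstimateTranscriptomeSize:
    def test_per_cell_equal_per_transcriptome_gives_size_one(self):
        plate = make_plate({"PA": 5.0, "PAA": 5.0}, targets=("rpl35", "rpsa", "actb2", "rpl8"))
        # per-genome 1.0 -> per-cell 1.5; per-transcriptome 1.5 -> size exactly 1
        num = ExpressionTable.from_abundances(
            "paa", "PAA", {g: 15.0 for g in ("rpl35", "rpsa", "actb2", "rpl8")}
        )
        den = ExpressionTable.from_abundances(
            "pa", "PA", {g: 10.0 for g in ("rpl35", "rpsa", "actb2", "rpl8")}
        )
        est = estimate_transcriptome_size(plate, num, den, ["rpl35", "rpsa", "actb2", "rpl8"])
        for row in est.per_gene.values():
            assert row["size_ratio"] == pytest.approx(1.0, rel=1e-12)

    def test_missing_target_gene_names_it(self):
        plate = make_plate({"PA": 5.0, "PAA": 5.0})
        num = ExpressionTable.from_abundances("paa", "PAA", {"other": 1.0})
        den = ExpressionTable.from_abundances("pa", "PA", {"other": 1.0})
        with pytest.raises(InvalidInputError, match="rpl35"):
            estimate_transcriptome_size(plate, num, den, ["rpl35"])

    def test_simulated_plate_recovers_true_size(self):
        cfg = SimulationConfig(seed=21, qpcr=QpcrSimConfig(cq_noise_sd=0.0))
        plate = simulate_qpcr(cfg)
        num, den = target_expression_tables(cfg, true_size_ratio=1.0)
        est = estimate_transcriptome_size(
            plate, num, den, sorted(cfg.qpcr.true_per_genome_ratios)
        )
        assert est.mean_size == pytest.approx(1.0, rel=1e-9)
        for row in est.per_gene.values():
            assert row["size_ratio"] == pytest.approx(1.0, rel=1e-9)
        # a noiseless plate leaves essentially no variance, so the 1.5-fold
        # dosage-effect null is overwhelmingly rejected
        assert est.t_vs_dosage_effect[2] < 1e-6


class TestQpcrRoundTrip:
    def test_csv_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=4)
        plate = simulate_qpcr(cfg)
        path = tmp_path / "plate.csv"
        write_qpcr_csv(plate, path)
        back = read_qpcr_csv(path)
        assert len(back) == len(plate)
        assert back[0].sample_id == plate[0].sample_id
        orig = sorted((w.target, w.template, w.replicate, w.cq) for w in plate[3].wells)
        readback = sorted((w.target, w.template, w.replicate, w.cq) for w in back[3].wells)
        assert readback == orig  # %.17g round-trips doubles exactly


class TestParameterRecovery:
    @pytest.mark.parametrize("true_ratio", [0.5, 0.8, 1.0, 1.5])
    def test_median_livak_estimate_within_5pct(self, true_ratio):
        estimates = []
        for seed in range(60):
            cfg = SimulationConfig(
                seed=seed,
                qpcr=QpcrSimConfig(
                    cq_noise_sd=0.15, true_per_genome_ratios={"tgt": true_ratio}
                ),
            )
            plate = simulate_qpcr(cfg)
            estimates.append(livak_per_genome(plate, "tgt").ratio_per_genome)
        median = float(np.median(estimates))
        assert abs(median - true_ratio) / true_ratio < 0.05
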