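import itertools

import numpy as np
import pytest

from regdesign.ann import TrainedModel, TrainingConfig, predict_strength
from regdesign.design import (
    KeyPointSet,
    MutationEffect,
    classify_key_points,
    conservation_profile,
    design_by_keypoints,
    design_by_library,
    generate_insilico_library,
    mutation_type_counts,
    point_scan,
)
from regdesign.simulate import make_ground_truth


def zero_model(L):
    """Constant-output model: every sequence predicts the same strength."""
    return TrainedModel(
        hidden_weights=np.zeros((2, 4 * L)), hidden_bias=np.zeros(2),
        output_weights=np.zeros((1, 2)), output_bias=np.zeros(1),
        normalization_max=2.0, config=TrainingConfig(hidden_neurons=2),
        training_log=[0.0],
    )


@pytest.fixture(scope="module")
def planted20(planted_model_factory):
    gt = make_ground_truth(seed=31, L=20, n_positive_sites=4,
                           n_negative_sites=8)
    return gt, planted_model_factory(gt)


class TestPointScan:
    def test_three_effects_per_site(self, planted20):
        gt, model = planted20
        effects = point_scan(model, gt.wt_seq)
        assert len(effects) == 3 * 20
        positions = [e.position for e in effects]
        for p in range(1, 21):
            assert positions.count(p) == 3

    def test_l2_enumeration(self):
        model = zero_model(2)
        effects = point_scan(model, "AT")
        assert {(e.position, e.to_base) for e in effects} == {
            (1, "C"), (1, "G"), (1, "T"), (2, "A"), (2, "C"), (2, "G"),
        }
        assert all(e.from_base == "AT"[e.position - 1] for e in effects)

    def test_constant_model_all_zero_delta(self):
        model = zero_model(5)
        effects = point_scan(model, "ACGTA")
        assert all(e.delta_relative == 0.0 for e in effects)

    def test_length_mismatch_rejected(self, planted20):
        _, model = planted20
        with pytest.raises(ValueError, match="length"):
            point_scan(model, "ACGT")

    def test_deltas_match_planted_truth(self, planted20):
        gt, model = planted20
        effects = point_scan(model, gt.wt_seq)
        for e in effects:
            truth = gt.relative_effect(e.position, e.to_base)
            assert e.delta_relative == pytest.approx(truth, abs=1e-4)

    def test_224nt_scan_emits_672(self, planted_model_factory):
        gt = make_ground_truth(seed=5)
        model = planted_model_factory(gt)
        assert len(point_scan(model, gt.wt_seq)) == 672


class TestClassifyKeyPoints:
    def eff(self, pos, delta, to="G", frm="A"):
        return MutationEffect(position=pos, from_base=frm, to_base=to,
                              predicted_strength=1 + delta,
                              delta_relative=delta)

    def test_threshold_rule(self):
        effects = [self.eff(1, 0.25), self.eff(2, -0.30), self.eff(3, 0.05)]
        kps = classify_key_points(effects, wt_predicted=1.0)
        assert len(kps.positive_points) == 1
        assert len(kps.negative_points) == 1
        assert kps.positive_points[0].position == 1
        assert kps.negative_points[0].position == 2

    def test_threshold_is_inclusive(self):
        kps = classify_key_points([self.eff(1, 0.20)], wt_predicted=1.0)
        assert len(kps.positive_points) == 1
        kps = classify_key_points([self.eff(1, -0.20)], wt_predicted=1.0)
        assert len(kps.negative_points) == 1

    def test_empty_effects(self):
        kps = classify_key_points([], wt_predicted=1.0)
        assert len(kps) == 0

    def test_nonpositive_wt_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_key_points([], wt_predicted=0.0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            classify_key_points([], wt_predicted=1.0, threshold=0.0)

    def test_planted_site_recovery_on_exact_model(self, planted_model_factory):
        """Oracle model: every planted site with |effect| >= 0.3 is recovered."""
        gt = make_ground_truth(seed=41, L=60, n_positive_sites=6,
                               n_negative_sites=20)
        model = planted_model_factory(gt)
        effects = point_scan(model, gt.wt_seq)
        wt_pred = float(predict_strength(model, gt.wt_seq)[0])
        kps = classify_key_points(effects, wt_pred)
        found_pos = {(e.position, e.to_base) for e in kps.positive_points}
        found_neg = {(e.position, e.to_base) for e in kps.negative_points}
        planted = gt.planted_key_sites(min_effect=0.3)
        n_planted = len(planted["positive"]) + len(planted["negative"])
        n_found = len(set(map(tuple, planted["positive"])) & found_pos)
        n_found += len(set(map(tuple, planted["negative"])) & found_neg)
        assert n_planted > 0
        assert n_found / n_planted >= 0.90


class TestInsilicoLibrary:
    def test_mean_hamming_distance(self):
        wt = "ACGT" * 15  # L = 60
        n, rate = 2000, 0.20
        lib = generate_insilico_library(wt, n, rate, seed=0)
        assert len(lib) == n
        ham = np.array([sum(a != b for a, b in zip(wt, s)) for s in lib])
        se = np.sqrt(60 * rate * (1 - rate) / n)
        assert abs(ham.mean() - 60 * rate) <= 3 * se

    def test_tiny_rate_limit(self):
        wt = "ACGTACGTAC"
        lib = generate_insilico_library(wt, 5, 1e-9, seed=1)
        assert all(s == wt for s in lib)

    def test_seed_reproducibility(self):
        wt = "ACGTACGTAC"
        assert (generate_insilico_library(wt, 20, 0.3, seed=4)
                == generate_insilico_library(wt, 20, 0.3, seed=4))

    @pytest.mark.parametrize("rate", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_rate_rejected(self, rate):
        with pytest.raises(ValueError, match="mutation_rate"):
            generate_insilico_library("ACGT", 5, rate, seed=0)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError, match="n must"):
            generate_insilico_library("ACGT", 0, 0.2, seed=0)


class TestDesignByLibrary:
    def test_wt_found_when_targeting_wt_strength(self, planted20):
        gt, model = planted20
        wt_pred = float(predict_strength(model, gt.wt_seq)[0])
        result = design_by_library(model, gt.wt_seq, desired=wt_pred,
                                   tolerance=0.05, n=200, mutation_rate=0.2,
                                   seed=0, k=5)
        assert result.satisfied
        assert any(c.sequence == gt.wt_seq and not c.mutations
                   for c in result.candidates)

    def test_reachable_target_satisfied_or_flagged(self, planted20):
        gt, model = planted20
        result = design_by_library(model, gt.wt_seq, desired=2.50,
                                   tolerance=0.1, n=2000, mutation_rate=0.2,
                                   seed=1)
        assert result.candidates
        if result.satisfied:
            for c in result.candidates:
                assert abs(c.predicted_strength - 2.50) <= 0.1
        else:
            assert result.nearest_achieved is not None

    def test_target_beyond_training_max_rejected(self, planted20):
        gt, model = planted20
        assert model.normalization_max == pytest.approx(3.559)
        with pytest.raises(ValueError, match="maximum training strength"):
            design_by_library(model, gt.wt_seq, desired=4.0, tolerance=0.1,
                              n=10, mutation_rate=0.2, seed=0)

    def test_candidates_rescore_exactly(self, planted20):
        gt, model = planted20
        result = design_by_library(model, gt.wt_seq, desired=1.5,
                                   tolerance=0.5, n=500, mutation_rate=0.2,
                                   seed=3)
        for c in result.candidates:
            rescored = float(predict_strength(model, c.sequence)[0])
            assert rescored == c.predicted_strength

    def test_mutation_lists_are_correct(self, planted20):
        gt, model = planted20
        result = design_by_library(model, gt.wt_seq, desired=1.0,
                                   tolerance=1.0, n=100, mutation_rate=0.2,
                                   seed=4)
        for c in result.candidates:
            rebuilt = list(gt.wt_seq)
            for pos, frm, to in c.mutations:
                assert rebuilt[pos - 1] == frm
                rebuilt[pos - 1] = to
            assert "".join(rebuilt) == c.sequence


@pytest.fixture(scope="module")
def scan_kps(planted20):
    gt, model = planted20
    effects = point_scan(model, gt.wt_seq)
    wt_pred = float(predict_strength(model, gt.wt_seq)[0])
    return classify_key_points(effects, wt_pred, threshold=0.20)


class TestDesignByKeypoints:
    def test_beam_equals_brute_force(self, planted20, scan_kps):
        """Beam search vs independent exhaustive enumeration."""
        gt, model = planted20
        points = sorted(scan_kps.all_points(),
                        key=lambda e: (e.position, e.to_base))[:6]
        kps6 = KeyPointSet(
            positive_points=[e for e in points if e.delta_relative > 0],
            negative_points=[e for e in points if e.delta_relative < 0],
        )
        desired, max_mut = 1.8, 3

        # brute-force oracle: enumerate every valid combination directly
        best_gap = abs(float(predict_strength(model, gt.wt_seq)[0]) - desired)
        for r in range(1, max_mut + 1):
            for combo in itertools.combinations(points, r):
                if len({e.position for e in combo}) < len(combo):
                    continue
                seq = list(gt.wt_seq)
                for e in combo:
                    seq[e.position - 1] = e.to_base
                pred = float(predict_strength(model, "".join(seq))[0])
                best_gap = min(best_gap, abs(pred - desired))

        result = design_by_keypoints(model, gt.wt_seq, kps6, desired,
                                     tolerance=1.0, max_mutations=max_mut,
                                     beam_width=50, search="beam")
        beam_gap = abs(result.candidates[0].predicted_strength - desired)
        assert beam_gap == pytest.approx(best_gap, abs=1e-12)

    def test_single_mutation_reduces_to_best_effect(self, planted20, scan_kps):
        gt, model = planted20
        desired = 2.0
        result = design_by_keypoints(model, gt.wt_seq, scan_kps, desired,
                                     tolerance=1.0, max_mutations=1)
        wt_pred = float(predict_strength(model, gt.wt_seq)[0])
        gaps = [abs(e.predicted_strength - desired)
                for e in scan_kps.all_points()] + [abs(wt_pred - desired)]
        got = abs(result.candidates[0].predicted_strength - desired)
        assert got == pytest.approx(min(gaps), abs=1e-12)

    def test_positive_points_only_push_up(self, planted20, scan_kps):
        gt, model = planted20
        pos_only = KeyPointSet(positive_points=scan_kps.positive_points,
                               negative_points=[])
        if not pos_only.positive_points:
            pytest.skip("no positive key points in this planted model")
        wt_pred = float(predict_strength(model, gt.wt_seq)[0])
        result = design_by_keypoints(model, gt.wt_seq, pos_only,
                                     desired=gt.s_max, tolerance=5.0,
                                     max_mutations=3)
        for c in result.candidates:
            if c.mutations:
                assert c.predicted_strength >= wt_pred - 1e-9

    def test_at_most_one_mutation_per_position(self, planted20, scan_kps):
        gt, model = planted20
        result = design_by_keypoints(model, gt.wt_seq, scan_kps, desired=0.5,
                                     tolerance=5.0, max_mutations=4, k=20)
        for c in result.candidates:
            positions = [m[0] for m in c.mutations]
            assert len(positions) == len(set(positions))

    def test_unreachable_target_flagged_not_raised(self, planted20, scan_kps):
        gt, model = planted20
        result = design_by_keypoints(model, gt.wt_seq, scan_kps, desired=3.5,
                                     tolerance=1e-6, max_mutations=2)
        assert not result.satisfied
        assert result.nearest_achieved is not None

    def test_empty_keypoints_rejected(self, planted20):
        gt, model = planted20
        empty = KeyPointSet(positive_points=[], negative_points=[])
        with pytest.raises(ValueError, match="non-empty"):
            design_by_keypoints(model, gt.wt_seq, empty, 1.0, 0.1)

    def test_deterministic(self, planted20, scan_kps):
        gt, model = planted20
        kwargs = dict(desired=1.5, tolerance=1.0, max_mutations=3)
        r1 = design_by_keypoints(model, gt.wt_seq, scan_kps, **kwargs)
        r2 = design_by_keypoints(model, gt.wt_seq, scan_kps, **kwargs)
        assert ([c.sequence for c in r1.candidates]
                == [c.sequence for c in r2.candidates])


class TestConservationProfile:
    def test_identical_sequences_2_bits(self):
        profile = conservation_profile(["ACGT", "ACGT", "ACGT"])
        assert np.allclose(profile, 2.0)

    def test_uniform_column_0_bits(self):
        profile = conservation_profile(["A", "C", "G", "T"])
        assert profile[0] == pytest.approx(0.0)

    def test_half_half_column_1_bit(self):
        profile = conservation_profile(["AA", "AT", "TA", "TT"])
        assert np.allclose(profile, 1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            conservation_profile(["ACGT", "ACG"])

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            conservation_profile(["ACGT"])

    def test_values_bounded(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(10)]
        profile = conservation_profile(seqs)
        assert np.all(profile >= 0) and np.all(profile <= 2)


class TestMutationTypeCounts:
    def eff(self, frm, to, delta):
        return MutationEffect(position=1, from_base=frm, to_base=to,
                              predicted_strength=1 + delta, delta_relative=delta)

    def test_empty_set_all_zero(self):
        counts = mutation_type_counts(
            KeyPointSet(positive_points=[], negative_points=[])
        )
        assert counts["total"] == 0
        assert counts["negative"]["AT_to_GC"] == 0

    def test_hand_tally(self):
        kps = KeyPointSet(
            positive_points=[],
            negative_points=[self.eff("A", "G", -0.3), self.eff("T", "C", -0.4),
                             self.eff("A", "C", -0.5)],
        )
        counts = mutation_type_counts(kps)
        assert counts["negative"]["AT_to_GC"] == 3
        assert counts["negative"]["pairs"] == {"A>G": 1, "T>C": 1, "A>C": 1}

    def test_totals_conserved(self):
        kps = KeyPointSet(
            positive_points=[self.eff("G", "A", 0.5), self.eff("C", "T", 0.4)],
            negative_points=[self.eff("A", "G", -0.3)],
        )
        counts = mutation_type_counts(kps)
        assert counts["total"] == 3
        assert counts["positive"]["total"] == 2
        assert counts["positive"]["GC_to_AT"] == 2
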