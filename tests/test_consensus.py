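"""Standardization, calibration (PAVA), grouping and the consensus score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirconsensus.consensus import (
    CalibrationCurve,
    ConsensusGroup,
    StandardizedPrediction,
    calibration_curve,
    compute_cws,
    ensemble_scores,
    group_overlapping,
    rank_predictions,
    standardize,
)
from mirconsensus.engines.sites import TargetSite
from mirconsensus.fixtures import generate_score_benchmark, true_precision_above
from mirconsensus.sequence_space import GenomeInterval


def _site(engine="e1", mirna="m1", tx="t1", g0=100, g1=107, score=1.0, site_type="8mer",
          strand="+"):
    return TargetSite(
        engine=engine,
        mirna_id=mirna,
        transcript_id=tx,
        utr_start=0,
        utr_end=50,
        seed_start=5,
        seed_end=12,
        genomic_seed=GenomeInterval("c1", g0, g1, strand),
        site_type=site_type,
        raw_score=score,
    )


class TestStandardize:
    def test_one_two_three_gives_plus_minus_1_2247(self):
        sites = [_site(score=s) for s in (1.0, 2.0, 3.0)]
        preds = standardize({"e1": sites})["e1"]
        zs = [p.z for p in preds]
        assert zs == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_energy_orientation_flips_sign(self):
        # lower energy is better: -20 becomes the larger z
        sites = [_site(score=-20.0), _site(score=-10.0, g0=200, g1=207)]
        preds = standardize({"e1": sites}, {"e1": False})["e1"]
        assert [p.z for p in preds] == pytest.approx([1.0, -1.0])

    def test_constant_scores_error_names_engine(self):
        sites = [_site(score=2.0), _site(score=2.0)]
        with pytest.raises(ValueError, match="e1"):
            standardize({"e1": sites})

    def test_mean_zero_sd_one_on_pipeline_predictions(self, sites_by_engine):
        preds = standardize({e: s for e, s in sites_by_engine.items() if len(s) > 1})
        for engine, ps in preds.items():
            z = np.array([p.z for p in ps])
            assert abs(z.mean()) < 1e-9, engine
            assert abs(z.std() - 1.0) < 1e-9, engine


class TestCalibration:
    def test_hand_computed_pava_example(self):
        # scores [3,2,1], labels [T,F,T]:
        # raw W: s=3 -> 1.0, s=2 -> 0.5, s=1 -> 2/3; count weights (1,2,3)
        # PAVA pools (2/3 * 3 + 0.5 * 2) / 5 = 0.6
        curve = calibration_curve([3.0, 2.0, 1.0], [True, False, True])
        assert curve.weight_at(1.0) == pytest.approx(0.6)
        assert curve.weight_at(2.0) == pytest.approx(0.6)
        assert curve.weight_at(3.0) == pytest.approx(1.0)

    def test_all_validated_gives_unit_weights(self):
        curve = calibration_curve([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(curve.weights, 1.0)

    def test_none_validated_gives_floor(self):
        eps = 1e-6
        curve = calibration_curve([1.0, 2.0, 3.0], [False, False, False], eps=eps)
        assert np.allclose(curve.weights, eps)

    def test_curves_are_non_decreasing_and_idempotent(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=500)
        labels = rng.random(500) < 1 / (1 + np.exp(-scores))
        curve = calibration_curve(scores, labels)
        assert np.all(np.diff(curve.weights) >= -1e-12)
        # recalibrating the monotone curve is a fixed point
        refit = calibration_curve(curve.scores, curve.weights > 0.5)  # labels proxy
        assert np.all(np.diff(refit.weights) >= -1e-12)

    def test_recovery_within_5pc_of_generative_curve_at_deciles(self):
        df = generate_score_benchmark(
            10000, seed=42, engine_coeffs=(1.0,), noise_sd=1.0, label_slope=2.0
        )
        x = df["sim1"].to_numpy()
        curve = calibration_curve(x, df["label"].to_numpy())
        deciles = np.quantile(x, np.arange(0.05, 1.0, 0.1))
        big = generate_score_benchmark(
            400000, seed=999, engine_coeffs=(1.0,), noise_sd=1.0, label_slope=2.0
        )
        truth = true_precision_above(
            big["sim1"].to_numpy(), big["label"].to_numpy(), deciles
        )
        err = np.abs(curve.weights_at(deciles) - truth)
        assert err.max() <= 0.05, err


def _pred(site, z, oriented=None):
    return StandardizedPrediction(site=site, oriented_score=site.raw_score if oriented is None else oriented, z=z)


def _curve_for(engine, score, w):
    return CalibrationCurve(engine, np.array([score]), np.array([w]))


class TestCWS:
    def test_printed_equation_example(self):
        g = ConsensusGroup(
            mirna_id="m1", transcript_id="t1", gene_symbol="G", chrom="c1",
            strand="+", g_start=100, g_end=107,
            members=[
                _pred(_site(engine="e1", score=10.0), z=1.0),
                _pred(_site(engine="e2", score=20.0), z=2.0),
            ],
            agreement=2,
        )
        curves = {"e1": _curve_for("e1", 10.0, 0.2), "e2": _curve_for("e2", 20.0, 0.8)}
        assert compute_cws(g, curves) == pytest.approx(1.8)

    def test_single_member_reduces_to_z(self):
        g = ConsensusGroup(
            mirna_id="m", transcript_id="t", gene_symbol="G", chrom="c1",
            strand="+", g_start=0, g_end=7,
            members=[_pred(_site(score=5.0), z=-0.7)], agreement=1,
        )
        assert compute_cws(g, {"e1": _curve_for("e1", 5.0, 0.123)}) == pytest.approx(-0.7)

    def test_equal_weights_reduce_to_mean(self):
        members = [
            _pred(_site(engine=f"e{k}", score=1.0), z=z)
            for k, z in enumerate([0.5, 1.5, 2.5])
        ]
        g = ConsensusGroup(
            mirna_id="m", transcript_id="t", gene_symbol="G", chrom="c1",
            strand="+", g_start=0, g_end=7, members=members, agreement=3,
        )
        curves = {f"e{k}": _curve_for(f"e{k}", 1.0, 0.4) for k in range(3)}
        assert compute_cws(g, curves) == pytest.approx(np.mean([0.5, 1.5, 2.5]))

    @settings(derandomize=True, max_examples=100)
    @given(
        zs=st.lists(st.floats(-3, 3), min_size=1, max_size=5),
        ws=st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
    )
    def test_cws_is_convex_combination_of_member_z(self, zs, ws):
        members = [
            _pred(_site(engine=f"e{k}", score=float(k)), z=z) for k, z in enumerate(zs)
        ]
        g = ConsensusGroup(
            mirna_id="m", transcript_id="t", gene_symbol="G", chrom="c1",
            strand="+", g_start=0, g_end=7, members=members, agreement=len(members),
        )
        curves = {f"e{k}": _curve_for(f"e{k}", float(k), ws[k]) for k in range(len(zs))}
        cws = compute_cws(g, curves)
        assert min(zs) - 1e-9 <= cws <= max(zs) + 1e-9


class TestGrouping:
    def test_identical_intervals_same_type_exact_agreement(self):
        preds = [
            _pred(_site(engine="e1", g0=100, g1=107), z=0.1),
            _pred(_site(engine="e2", g0=100, g1=107), z=0.2),
        ]
        (g,) = group_overlapping(preds)
        assert g.agreement == 2
        assert g.agreement_exact is True

    def test_partial_overlap_groups_without_exact_agreement(self):
        preds = [
            _pred(_site(engine="e1", g0=100, g1=107), z=0.1),
            _pred(_site(engine="e2", g0=105, g1=112), z=0.2),
        ]
        (g,) = group_overlapping(preds)
        assert g.agreement == 2
        assert g.agreement_exact is False
        assert (g.g_start, g.g_end) == (100, 112)

    def test_same_interval_different_transcripts_stay_separate(self):
        preds = [
            _pred(_site(engine="e1", tx="t1"), z=0.1),
            _pred(_site(engine="e1", tx="t2"), z=0.2),
        ]
        groups = group_overlapping(preds)
        assert len(groups) == 2

    def test_non_overlapping_intervals_split(self):
        preds = [
            _pred(_site(engine="e1", g0=100, g1=107), z=0.1),
            _pred(_site(engine="e2", g0=107, g1=114), z=0.2),  # abutting, 0 bp overlap
        ]
        assert len(group_overlapping(preds)) == 2

    @settings(derandomize=True, max_examples=25)
    @given(perm=st.permutations(list(range(6))))
    def test_grouping_is_order_independent(self, perm):
        base = [
            _pred(_site(engine="e1", g0=100, g1=107), z=0.1),
            _pred(_site(engine="e2", g0=103, g1=110), z=0.4),
            _pred(_site(engine="e3", g0=109, g1=116), z=0.3),
            _pred(_site(engine="e1", g0=200, g1=207), z=0.2),
            _pred(_site(engine="e2", mirna="m2", g0=100, g1=107), z=0.5),
            _pred(_site(engine="e1", g0=300, g1=307, strand="+"), z=0.9),
        ]
        shuffled = [base[i] for i in perm]
        a = group_overlapping(base)
        b = group_overlapping(shuffled)
        key = lambda g: (g.mirna_id, g.transcript_id, g.g_start, g.g_end, g.agreement)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestRanking:
    def test_descending_cws_with_agreement_tie_break(self):
        def grp(cws, agreement, mirna="m"):
            g = ConsensusGroup(
                mirna_id=mirna, transcript_id="t", gene_symbol="G", chrom="c",
                strand="+", g_start=0, g_end=7, members=[], agreement=agreement,
            )
            g.cws = cws
            return g

        ranked = rank_predictions([grp(0.5, 1), grp(1.8, 1), grp(-0.2, 1)])
        assert [g.cws for g in ranked] == [1.8, 0.5, -0.2]
        ranked = rank_predictions([grp(1.0, 1, "b"), grp(1.0, 3, "a")])
        assert [g.agreement for g in ranked] == [3, 1]
        assert rank_predictions([]) == []


def test_consensus_groups_from_pipeline_have_valid_structure(consensus_run):
    groups, curves = consensus_run
    assert groups
    for g in groups:
        engines = [m.site.engine for m in g.members]
        assert len(engines) == len(set(engines))  # at most one member per engine
        assert g.agreement == len(g.members)
        zs = [m.z for m in g.members]
        assert min(zs) - 1e-9 <= g.cws <= max(zs) + 1e-9
        assert len(g.weights) == len(g.members)
        assert all(0 < w <= 1 for w in g.weights)
    for curve in curves.values():
        assert np.all(np.diff(curve.weights) >= -1e-12)
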