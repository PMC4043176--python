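"""Synthetic study generator and individual-consistency injection."""

import numpy as np
import pytest
from scipy import stats

from applause.event_data import write_bouts, read_bouts
from applause.simulator import sample_start_spreads
from applause.starting_models import GaussianStartParams, StartParams
from applause.stopping_models import GaussianStopParams, StopParams
from applause.synthetic_data import (
    StudyDesign,
    calibrate_consistency_effect,
    generate_study,
    inject_individual_consistency,
)
from conftest import BEST_FIT_START, BEST_FIT_STOP, RECOVERY_DESIGN, best_fit_study


def _median_cross_talk_rho(bouts):
    rhos = []
    groups = {}
    for b in bouts:
        groups.setdefault(b.group_id, []).append(b)
    for talks in groups.values():
        talks = sorted(talks, key=lambda b: b.talk_id)
        shared = sorted(
            {r.individual_id for r in talks[0].starters}
            & {r.individual_id for r in talks[1].starters}
        )
        s1 = [talks[0].record_of(i).start_time for i in shared]
        s2 = [talks[1].record_of(i).start_time for i in shared]
        rhos.append(stats.spearmanr(s1, s2).statistic)
    return float(np.median(rhos))


class TestGenerateStudy:
    def test_shape_and_schema(self):
        bouts = best_fit_study(seed=0, design=StudyDesign())
        assert len(bouts) == 12
        sizes = sorted(b.n for b in bouts)
        assert sizes == sorted([20, 20, 20, 18, 16, 13] * 2)
        non_starters = sum(1 for b in bouts for r in b.records if not r.is_starter)
        assert non_starters == 6  # 3 individuals x 2 talks
        for b in bouts:
            assert b.latency is not None and b.latency >= 0
            for r in b.starters:
                assert r.clap_times[0] == r.start_time
                assert r.clap_times[-1] == r.stop_time

    def test_seeded_determinism(self):
        a = best_fit_study(seed=4)
        b = best_fit_study(seed=4)
        assert a == b

    def test_roundtrips_through_event_data(self, tmp_path):
        bouts = best_fit_study(seed=6)
        path = write_bouts(bouts, tmp_path / "s.json")
        assert len(read_bouts(path)) == 12

    def test_linear_model_matches_simulator_start_law(self):
        """Global-rate generation and the dedicated simulator draw the
        start spread from the same distribution (two-sample KS)."""
        design = StudyDesign(group_sizes=(20,), n_non_starters=0)
        spreads = []
        for seed in range(250):
            bouts = generate_study(
                design, "L2", BEST_FIT_START, "G2+G3", BEST_FIT_STOP, seed=seed
            )
            starts = [r.start_time for r in bouts[0].starters]
            spreads.append(max(starts))
        fast = sample_start_spreads(2.15, 20, 4000, np.random.default_rng(99))
        assert stats.ks_2samp(spreads, fast).pvalue > 0.01

    def test_neighbour_model_spreads_through_adjacency(self):
        """Under a pure neighbour cue the second starter must always be a
        seat neighbour of the initiator."""
        design = StudyDesign(group_sizes=(16,), n_non_starters=0)
        for seed in range(10):
            bouts = generate_study(
                design, "L4", StartParams(lam4=3.0), "G2+G3", BEST_FIT_STOP, seed=seed
            )
            bout = bouts[0]
            nbrs = bout.neighbours()
            order = sorted(bout.starters, key=lambda r: r.start_time)
            assert order[1].individual_id in nbrs[order[0].individual_id]

    def test_gaussian_models_generate(self):
        design = StudyDesign(group_sizes=(13,), n_non_starters=0)
        bouts = generate_study(
            design,
            "G_start",
            GaussianStartParams(mu=1.5, sigma=0.5),
            "G_stop",
            GaussianStopParams(m=12.0, s=3.0),
            seed=1,
        )
        for b in bouts:
            assert min(r.start_time for r in b.starters) == 0.0

    def test_unstoppable_model_rejected_before_generation(self):
        with pytest.raises(ValueError, match="initiate stopping"):
            generate_study(
                RECOVERY_DESIGN,
                "L2",
                BEST_FIT_START,
                "G2",
                StopParams(gamma2=0.63),
                seed=0,
            )


class TestConsistencyInjection:
    def test_effect_one_makes_orders_identical(self):
        bouts = best_fit_study(seed=12)
        injected = inject_individual_consistency(bouts, 1.0, seed=0)
        assert _median_cross_talk_rho(injected) == pytest.approx(1.0)

    def test_effect_zero_leaves_orders_uncorrelated(self):
        rhos = [
            _median_cross_talk_rho(
                inject_individual_consistency(best_fit_study(seed=s), 0.0, seed=s)
            )
            for s in range(15)
        ]
        assert abs(np.mean(rhos)) < 0.15

    def test_group_level_curves_untouched(self):
        bouts = best_fit_study(seed=13)
        injected = inject_individual_consistency(bouts, 0.7, seed=3)
        for a, b in zip(bouts, injected):
            assert sorted(r.start_time for r in a.starters) == sorted(
                r.start_time for r in b.starters
            )
            assert sorted(r.stop_time for r in a.starters) == sorted(
                r.stop_time for r in b.starters
            )
            # identities keep their seats
            for r in a.records:
                rb = b.record_of(r.individual_id)
                assert (rb.seat_row, rb.seat_col) == (r.seat_row, r.seat_col)

    def test_invalid_effect_rejected(self):
        bouts = best_fit_study(seed=14)
        with pytest.raises(ValueError):
            inject_individual_consistency(bouts, 1.2, seed=0)

    def test_calibration_hits_observed_median_rho(self):
        """Calibrating the effect to the observed median rho = 0.53 then
        re-measuring over fresh studies lands within +-0.1."""
        effect = calibrate_consistency_effect(
            0.53, lambda s: best_fit_study(seed=s), n_studies=6, seed=0, iterations=7
        )
        rhos = [
            _median_cross_talk_rho(
                inject_individual_consistency(best_fit_study(seed=400 + s), effect, seed=s)
            )
            for s in range(40)
        ]
        assert np.median(rhos) == pytest.approx(0.53, abs=0.1)
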