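"""Block segmentation, bracketing, VPDB calibration, MAE, group stats."""

import math

import numpy as np
import pytest
from scipy import stats

from orbidelta.ratios import RatioSummary
from orbidelta.session import (
    Block,
    CalibrationConfig,
    SessionLayout,
    bracket_delta,
    combine_replicates,
    compare_groups,
    detect_plateau,
    from_vpdb,
    load_standards,
    mae,
    process_session,
    segment_blocks,
    to_vpdb,
)
from orbidelta.synth import SimConfig, simulate_session

from conftest import build_run


def make_block(role, t0, t1, ratio):
    summary = RatioSummary(ratio=ratio, sd=0.0, se=0.0, n=100, n_excluded=0,
                           shot_noise_rel=1e-4, method="ratio_of_sums")
    return Block(role=role, t_start=t0, t_end=t1, summary=summary)


def alternating_blocks(ratios):
    roles = ["reference" if i % 2 == 0 else "sample" for i in range(len(ratios))]
    return [make_block(r, 5.0 * i, 5.0 * (i + 1), x) for i, (r, x) in enumerate(zip(roles, ratios))]


class TestLayout:
    def test_default_dual_inlet_layout(self):
        layout = SessionLayout()
        assert layout.roles == ("R", "S", "R", "S", "R", "S", "R")
        assert layout.total_minutes == 35.0

    @pytest.mark.parametrize("roles", [("S", "R", "S"), ("R", "R", "S"), ("R", "S")])
    def test_invalid_role_sequences(self, roles):
        with pytest.raises(ValueError):
            SessionLayout(roles=roles)


class TestSegmentBlocks:
    def test_seven_blocks_with_alternating_roles(self):
        run = simulate_session(SimConfig(seed=5))
        blocks = segment_blocks(run)
        assert [b.role[0].upper() for b in blocks] == list("RSRSRSR")
        assert len(blocks) == 7
        for blk in blocks:
            # 5 min minus 2 x 30 s trim at 1 scan/s
            assert blk.n_scans == pytest.approx(240, abs=2)

    def test_boundary_scan_joins_later_block(self):
        """Half-open intervals: a scan exactly on a block boundary belongs
        to the following block."""
        n = 35 * 4  # 15 s period; scans land exactly on 5-min boundaries
        times = np.arange(n) * 0.25
        run = build_run(np.full(n, 1000.0), np.full(n, 170.0), times=times)
        blocks = segment_blocks(run, trim_seconds=0.0, min_scans=5)
        first = run.window(blocks[1].t_start, blocks[1].t_end)
        assert first.time_min[0] == pytest.approx(5.0)
        assert first.time_min[-1] == pytest.approx(9.75)

    def test_short_run_rejected(self):
        run = build_run(np.full(600, 1000.0), np.full(600, 170.0),
                        times=np.arange(600) / 60.0)  # 10 min
        with pytest.raises(ValueError, match="shorter"):
            segment_blocks(run)


class TestDetectPlateau:
    @staticmethod
    def trapezoid_run(ramp_min=1.0, top_min=10.0, period_s=1.0, tail_min=2.0):
        total = 2 * ramp_min + top_min + 2 * tail_min
        t = np.arange(0, total, period_s / 60.0)
        local = t - tail_min
        up = np.clip(local / ramp_min, 0, 1)
        down = np.clip((2 * ramp_min + top_min - local) / ramp_min, 0, 1)
        shape = np.clip(np.minimum(up, down), 0, None)
        tic = 1e6 * shape + 1.0
        s_m0 = 1000.0 * shape + 1e-6
        return build_run(s_m0, 0.17 * s_m0, tic=tic, times=t)

    def test_trapezoid_plateau_found_in_flat_top(self):
        run = self.trapezoid_run()
        lo, hi = detect_plateau(run, threshold=0.5, min_duration_min=1.0, trim_seconds=30.0)
        assert hi - lo >= 9.0
        assert lo >= 2.0 and hi <= 14.0
        tic = run.window(lo, hi).tic
        assert tic.min() >= 0.5 * np.median(tic)

    def test_constant_tic_keeps_whole_run_minus_trims(self):
        run = build_run(np.full(600, 1000.0), np.full(600, 170.0),
                        times=np.arange(600) / 60.0)
        lo, hi = detect_plateau(run, trim_seconds=30.0)
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(600 / 60.0 - 1 / 60.0 - 0.5, abs=0.02)

    def test_all_zero_tic_rejected(self):
        run = build_run(np.full(60, 1.0), np.full(60, 1.0), tic=np.zeros(60))
        with pytest.raises(ValueError):
            detect_plateau(run)


class TestBracketDelta:
    def test_identical_ratios_give_zero_delta(self):
        blocks = alternating_blocks([0.2] * 7)
        result = bracket_delta(blocks)
        assert result.delta_vs_std == pytest.approx(0.0, abs=1e-12)
        assert result.sd == pytest.approx(0.0, abs=1e-12)
        assert result.n == 3

    def test_permil_definition(self):
        """R_sample/R_ref = 1.001 everywhere is exactly +1 permil."""
        blocks = alternating_blocks([0.2, 0.2 * 1.001] * 3 + [0.2])
        for scheme in ("adjacent_mean", "interpolate"):
            result = bracket_delta(blocks, scheme)
            assert result.delta_vs_std == pytest.approx(1.0, rel=1e-9)

    def test_unbracketed_sample_rejected(self):
        blocks = alternating_blocks([0.2] * 7)[:-1]  # ends on a sample block
        with pytest.raises(ValueError, match="bracketed"):
            bracket_delta(blocks)

    def test_common_drift_cancels(self):
        """A 1%/h flux drift common to both isotopologues biases delta by
        less than 0.05 permil under either bracketing scheme."""
        cfg = SimConfig(delta_sample_vpdb=-30.0, poisson=False, noise_sigma=0.0,
                        drift="linear", drift_rate_per_hour=0.01, seed=0)
        run = simulate_session(cfg)
        truth = cfg.delta_sample_vs_std
        for scheme in ("adjacent_mean", "interpolate"):
            result = process_session(run, bracketing=scheme)
            assert abs(result.delta_vs_std - truth) < 0.05


class TestVpdbScale:
    def test_zero_sample_offset_is_the_standard_value(self):
        assert to_vpdb(0.0, CalibrationConfig(-27.8)) == pytest.approx(-27.8)

    def test_multiplicative_composition(self):
        """delta = -1.0 against a -27.8 standard lands at -28.7722 on the
        VPDB scale (exact composition, not a plain sum)."""
        assert to_vpdb(-1.0, CalibrationConfig(-27.8)) == pytest.approx(-28.7722, abs=1e-9)

    def test_round_trip_identity(self):
        cal = CalibrationConfig(-27.8)
        for d in (-35.0, -5.3, 0.0, 12.7):
            assert from_vpdb(to_vpdb(d, cal), cal) == pytest.approx(d, abs=1e-9)

    def test_chain_composition_associates(self):
        """Converting A->B then B->C equals converting A->C directly."""
        d_ab, d_bc = -27.8, 4.2
        d_ac = to_vpdb(d_ab, CalibrationConfig(d_bc))
        for ds in (-31.0, -1.0, 2.5):
            via_b = to_vpdb(to_vpdb(ds, CalibrationConfig(d_ab)), CalibrationConfig(d_bc))
            direct = to_vpdb(ds, CalibrationConfig(d_ac))
            assert via_b == pytest.approx(direct, abs=1e-9)


class TestMae:
    def test_zero_for_identical_vectors(self):
        report = mae([-29.5, -28.0], [-29.5, -28.0])
        assert report.mae == 0.0

    def test_sign_insensitive(self):
        assert mae([1.0, -1.0], [0.0, 0.0]).mae == pytest.approx(1.0)

    def test_dual_inlet_sodiated_standards_reproduce_published_mae(self):
        """The nine published dual-inlet [M+Na]+ residues average to 0.72
        permil in absolute value."""
        table = load_standards()
        rows = table[(table["method"] == "dual_inlet") & (table["adduct"] == "MNa")]
        report = mae(rows["expected_vpdb"] + rows["residue_printed"], rows["expected_vpdb"])
        assert round(report.mae, 2) == 0.72

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


class TestReplicates:
    def test_identical_values_have_zero_half_width(self):
        mean, sd, hw = combine_replicates([2.0] * 9)
        assert sd == 0.0 and hw == 0.0

    def test_two_point_closed_form(self):
        """{-1, 1}: SD = sqrt(2), so the 95% half-width is t(0.975, 1) x
        sqrt(2)/sqrt(2) = 12.706."""
        mean, sd, hw = combine_replicates([-1.0, 1.0])
        assert mean == 0.0
        assert sd == pytest.approx(math.sqrt(2.0))
        assert hw == pytest.approx(stats.t.ppf(0.975, 1), rel=1e-9)
        assert hw == pytest.approx(12.706, abs=5e-4)

    def test_interval_coverage_near_nominal(self):
        """t-based 95% intervals over nine Gaussian replicates cover the
        true mean in about 95% of 2000 seeded trials."""
        rng = np.random.default_rng(2024)
        n_sim, n_rep, truth = 2000, 9, -30.0
        covered = 0
        draws = rng.normal(truth, 0.5, (n_sim, n_rep))
        for row in draws:
            mean, _, hw = combine_replicates(row)
            covered += abs(mean - truth) <= hw
        assert covered / n_sim == pytest.approx(0.95, abs=0.015)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            combine_replicates([1.0])


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        stat, _, p = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert stat == 0.0 and p == 1.0

    def test_large_separation_is_significant(self):
        _, _, p = compare_groups([0.0, 0.0, 0.001], [10.0, 10.0, 10.001])
        assert p < 1e-6

    def test_matches_closed_form_welch(self):
        """Agreement with the Welch statistic computed from the textbook
        formulas (unequal variances, Welch-Satterthwaite df)."""
        a = np.array([-30.9, -30.7, -31.1])
        b = np.array([-30.1, -29.8, -30.3])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_direct = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_direct = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_direct = 2 * stats.t.sf(abs(t_direct), df_direct)
        stat, df, p = compare_groups(a, b)
        assert stat == pytest.approx(t_direct, abs=1e-4)
        assert df == pytest.approx(df_direct, abs=1e-4)
        assert p == pytest.approx(p_direct, abs=1e-4)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestStandardsDataset:
    def test_recomputed_residues_match_printed_except_std9(self):
        """Residues recomputed as measured minus expected equal the
        published residue column for standards 1-8 (dual-inlet [M+Na]+);
        standard 9 is documented as internally inconsistent."""
        table = load_standards()
        rows = table[(table["method"] == "dual_inlet") & (table["adduct"] == "MNa")]
        recomputed = (rows["delta_vpdb"] - rows["expected_vpdb"]).round(1)
        match = np.isclose(recomputed, rows["residue_printed"], atol=1e-9)
        assert match[rows["std"] <= 8].all()
        assert not match[rows["std"] == 9].any()
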