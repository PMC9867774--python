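"""Two-cell regimes, tissue phenotypes, sweeps, and run invariants.

The two-cell model's behavior is summarized by the late Hes1 amplitudes of
the two cells: "segregation" means they split into one high- and one
low-amplitude cell (amplitude ratio > 3), the low-Hes1 cell accumulating
Ptf1a (PAC identity) while the other keeps strong oscillation (BP).
"""

import numpy as np
import pytest

from notchsim import (
    RunConfig,
    run_tissue,
    run_two_cell,
    run_two_cell_delay_variant,
    sweep,
)
from notchsim.analysis import (
    DEFAULT_THRESHOLDS_3D,
    fate_proportions,
    oscillation_stats,
    phase_relation,
)
from notchsim.model import PerturbationSpec

WINDOW = (3200, 3600)


def late_amplitudes(ts):
    H = ts.var("H")
    return np.array(
        [oscillation_stats(ts.t, H[:, i], WINDOW).amplitude for i in range(ts.n_cells)]
    )


def segregated(ts):
    amps = late_amplitudes(ts)
    return amps.max() / max(amps.min(), 1e-9) > 3.0


def comparable_antiphase(ts, window):
    """Both cells oscillate with similar amplitude, in anti-phase."""
    H = ts.var("H")
    amps = [oscillation_stats(ts.t, H[:, i], window).amplitude for i in range(2)]
    if min(amps) <= 0:
        return False
    ratio = max(amps) / min(amps)
    return ratio < 2.0 and phase_relation(ts.t, H[:, 0], H[:, 1], window) < 0


def segregation_time(ts, ratio_thresh=3.0, width=400, step=100):
    """Center of the first sliding window where the amplitude ratio exceeds 3."""
    H = ts.var("H")
    for start in range(0, int(ts.t[-1]) - width + 1, step):
        win = (start, start + width)
        amps = [oscillation_stats(ts.t, H[:, i], win).amplitude for i in range(2)]
        if max(amps) / max(min(amps), 1e-9) > ratio_thresh:
            return start + width / 2
    return np.inf


class TestTwoCellRegimes:
    def test_medium_interactions_segregate_after_transient(self, twocell_wt):
        # medium trans (K2=0.5) and cis (gamma1=0.25): a transient progenitor
        # phase of comparable anti-phase oscillation, then fate segregation
        assert comparable_antiphase(twocell_wt, (200, 800))
        assert segregated(twocell_wt)
        # the low-amplitude cell accumulates Ptf1a
        amps = late_amplitudes(twocell_wt)
        P = twocell_wt.var("P")
        m = twocell_wt.t >= WINDOW[0]
        meanp = P[m].mean(axis=0)
        assert meanp[np.argmin(amps)] > 3 * meanp[np.argmax(amps)]

    @pytest.mark.parametrize("overrides", [{"K2": 0.15}, {"gamma1": 0.1}])
    def test_strong_trans_or_weak_cis_blocks_segregation(self, overrides):
        cfg = RunConfig(preset="table1_twocell").with_perturbation(
            PerturbationSpec(overrides=overrides)
        )
        ts = run_two_cell(cfg)
        assert not segregated(ts)
        # sustained anti-phase oscillation persists to the end of the run
        H = ts.var("H")
        assert phase_relation(ts.t, H[:, 0], H[:, 1], (3000, 3600)) < 0

    @pytest.mark.parametrize("overrides", [{"K2": 0.9}, {"gamma1": 0.4}])
    def test_weak_trans_or_strong_cis_segregate_earlier(self, overrides, twocell_wt):
        # weak trans bypasses the progenitor phase entirely; strong cis cuts
        # it short -- in both regimes the amplitudes diverge well before the
        # wild-type segregation time
        cfg = RunConfig(preset="table1_twocell").with_perturbation(
            PerturbationSpec(overrides=overrides)
        )
        ts = run_two_cell(cfg)
        assert segregated(ts)
        assert segregation_time(ts) < segregation_time(twocell_wt) - 100

    def test_identical_initial_states_never_diverge(self):
        from notchsim.simulate import _make_rhs, _neighbor_operator, _two_cell_graph
        from notchsim.dde import integrate
        from notchsim.model import ParameterSet

        params = ParameterSet.from_preset("table1_twocell")
        rhs = _make_rhs(_neighbor_operator(_two_cell_graph()), params, PerturbationSpec())
        y0 = np.tile([0.5, 1.1, 0.0, 1.0, 0.0], (2, 1))
        tr = integrate(rhs, y0, [params.tau0], 1200.0, 0.5)
        assert np.array_equal(tr.y[:, 0], tr.y[:, 1])


@pytest.fixture(scope="module")
def delay_runs():
    return {tau: run_two_cell_delay_variant(tau) for tau in (0.0, 10.0, 20.0)}


class TestDelayVariant:

    def test_zero_delay_reduces_to_jag1_deficient_model(self, delay_runs):
        cfg = RunConfig(preset="table1_twocell").with_perturbation("jag1_ko")
        ref = run_two_cell(cfg)
        assert np.array_equal(delay_runs[0.0].trajectory.y, ref.trajectory.y)

    def test_oscillation_death_near_10_min(self, delay_runs):
        base = late_amplitudes(delay_runs[0.0]).max()
        dead = late_amplitudes(delay_runs[10.0]).max()
        assert dead < 0.15 * base

    def test_large_delay_restores_in_phase_oscillation(self, delay_runs):
        ts = delay_runs[20.0]
        amps = late_amplitudes(ts)
        assert amps.min() > 0.3 * late_amplitudes(delay_runs[0.0]).max()
        H = ts.var("H")
        assert phase_relation(ts.t, H[:, 0], H[:, 1], (3000, 3600)) > 0


class TestNicdVariant:
    def test_fast_limit_matches_simplified_two_cell_model(self, twocell_wt):
        pert = PerturbationSpec(overrides={"tau_NICD": 2.0}, nicd_variant=True)
        ts = run_two_cell(RunConfig(preset="table1_twocell").with_perturbation(pert))
        ref = np.sort(late_amplitudes(twocell_wt))
        got = np.sort(late_amplitudes(ts))
        assert np.allclose(got, ref, rtol=0.15)

    def test_slow_nicd_shifts_transient_to_in_phase(self):
        scores = {}
        for tau_nicd in (10.0, 45.0):
            pert = PerturbationSpec(overrides={"tau_NICD": tau_nicd}, nicd_variant=True)
            ts = run_two_cell(RunConfig(preset="table1_twocell").with_perturbation(pert))
            H = ts.var("H")
            scores[tau_nicd] = phase_relation(ts.t, H[:, 0], H[:, 1], (200, 800))
        assert scores[10.0] < 0 < scores[45.0]


class TestTissuePhenotypes:
    def test_wild_type_bifurcates_into_amplitude_groups(self, wt_tissue, wt_fates):
        per = wt_fates.per_cell
        # both extreme fates well represented
        assert wt_fates.counts["BP"] > 0.3 * wt_fates.n_cells
        assert wt_fates.counts["PAC"] > 0.05 * wt_fates.n_cells
        # amplitude distribution is bimodal around the frozen band
        amps = per.hes1_amplitude.to_numpy()
        mid = (
            (amps > DEFAULT_THRESHOLDS_3D.theta_a_low)
            & (amps < DEFAULT_THRESHOLDS_3D.theta_a_high)
        ).mean()
        assert mid < 0.3

    def test_bifurcation_begins_late_in_interior(self, wt_tissue):
        # interior cells stay a homogeneous progenitor pool for ~10 h before
        # their Ptf1a levels diverge
        g = wt_tissue.graph
        surf = np.array(
            [
                any(g.cell_class[j] == "mesenchymal" for j in g.neighbors[c])
                for c in wt_tissue.cell_ids
            ]
        )
        P = wt_tissue.var("P")[:, ~surf]
        cv = P.std(axis=1) / np.clip(P.mean(axis=1), 1e-12, None)
        t = wt_tissue.t
        assert cv[np.searchsorted(t, 600.0)] < 0.5  # still homogeneous at 10 h
        assert cv[np.searchsorted(t, 1200.0)] > 0.5  # bifurcated by 20 h

    def test_neighbors_oscillate_antiphase_in_mpc_period(self, wt_tissue):
        H = wt_tissue.var("H")
        loc = {g: i for i, g in enumerate(wt_tissue.cell_ids)}
        scores = []
        for i, cid in enumerate(wt_tissue.cell_ids):
            for j in wt_tissue.graph.neighbors[cid]:
                if j in loc and loc[j] > i:
                    scores.append(
                        phase_relation(wt_tissue.t, H[:, i], H[:, loc[j]], (100, 600))
                    )
        scores = np.array(scores)
        assert scores.mean() < 0
        assert (scores < 0).mean() > 0.5

    def test_jag1_ko_traps_cells_in_mpc(self, graph0):
        ts = run_tissue(RunConfig(geometry_seed=0).with_perturbation("jag1_ko"), graph0)
        ft = fate_proportions(ts)
        assert ft.proportions["MPC"] > 0.5

    def test_dll1_ko_still_segregates(self, graph0):
        ts = run_tissue(RunConfig(geometry_seed=0).with_perturbation("dll1_ko"), graph0)
        ft = fate_proportions(ts)
        assert ft.proportions["MPC"] < 0.1
        assert ft.proportions["BP"] > 0.3
        assert ft.proportions["PAC"] > 0.1

    def test_surface_bias_and_equal_neighbor_control(self, wt_fates):
        per = wt_fates.per_cell
        pac_surface = per.loc[per.surface, "fate"].eq("PAC").mean()
        pac_interior = per.loc[~per.surface, "fate"].eq("PAC").mean()
        assert pac_surface > pac_interior + 0.1
        # equal-neighbor tissue: segregation without radial PAC enrichment
        # (bulk lateral inhibition needs a weaker Hes1 response, K2=0.2,
        # than the boundary-seeded wild-type pattern)
        cfg = RunConfig(
            geometry_seed=0, uniform_neighbors=12, initial_noise=0.01, noise_seed=1
        ).with_perturbation(PerturbationSpec(overrides={"K2": 0.2}))
        ts = run_tissue(cfg)
        ft = fate_proportions(ts)
        pac = (ft.per_cell.fate == "PAC").to_numpy()
        assert pac.sum() >= 5
        pos = ts.graph.positions
        r = np.linalg.norm(pos - pos.mean(axis=0), axis=1)
        outer = r > np.quantile(r, 0.6)
        assert pac[outer].mean() < pac[~outer].mean() + 0.1

    def test_type2_dll1_leaves_proportions_close_to_wild_type(self, graph0, wt_fates):
        ts = run_tissue(RunConfig(geometry_seed=0).with_perturbation("type2_dll1"), graph0)
        ft = fate_proportions(ts)
        for fate in ("MPC", "PAC", "BP"):
            assert abs(ft.proportions[fate] - wt_fates.proportions[fate]) < 0.08


@pytest.fixture(scope="module")
def ablation_runs(graph0):
    out = {}
    for name in ("no_cis_dll1", "no_trans_dll1", "jag1_cis_only", "jag1_trans_only"):
        ts = run_tissue(RunConfig(geometry_seed=0).with_perturbation(name), graph0)
        out[name] = (ts, fate_proportions(ts))
    return out


class TestAblationMatrix:

    @staticmethod
    def early_amplitude(ts):
        H = ts.var("H")
        return np.median(
            [
                oscillation_stats(ts.t, H[:, i], (200, 800)).amplitude
                for i in range(0, ts.n_cells, 4)
            ]
        )

    def test_dll1_channels_maintain_early_mpc(self, ablation_runs, wt_tissue):
        # removing either Dll1 channel disturbs the early progenitor phase
        # (amplitudes jump far above the wild-type intermediate level)
        wt_early = self.early_amplitude(wt_tissue)
        for name in ("no_cis_dll1", "no_trans_dll1"):
            assert self.early_amplitude(ablation_runs[name][0]) > 3 * wt_early

    def test_jag1_channels_spare_early_mpc(self, ablation_runs, wt_tissue):
        wt_early = self.early_amplitude(wt_tissue)
        for name in ("jag1_cis_only", "jag1_trans_only"):
            assert self.early_amplitude(ablation_runs[name][0]) < 2 * wt_early

    def test_jag1_cis_only_segregates_with_lower_amplitude(self, ablation_runs, wt_fates):
        ft = ablation_runs["jag1_cis_only"][1]
        assert abs(ft.proportions["MPC"] - wt_fates.proportions["MPC"]) < 0.1
        bp_amp = ft.per_cell.loc[ft.per_cell.fate == "BP", "hes1_amplitude"].median()
        wt_amp = wt_fates.per_cell.loc[
            wt_fates.per_cell.fate == "BP", "hes1_amplitude"
        ].median()
        assert bp_amp < wt_amp

    def test_jag1_trans_only_impairs_segregation(self, ablation_runs, wt_fates):
        ft = ablation_runs["jag1_trans_only"][1]
        assert ft.proportions["MPC"] > 1.5 * wt_fates.proportions["MPC"]
        assert ft.proportions["PAC"] < wt_fates.proportions["PAC"]


class TestSweeps:
    def test_gamma1_transition_to_bimodality(self, graph0):
        cfg = RunConfig(geometry_seed=0)
        res = sweep(cfg, "gamma1", [0.15, 0.35], graph=graph0)
        th = DEFAULT_THRESHOLDS_3D

        def midband(a):
            return ((a > th.theta_a_low) & (a < th.theta_a_high)).mean()

        # weak cis: unimodal intermediate amplitudes; strong cis: bimodal
        assert midband(res.amplitudes[0]) > 0.5
        assert midband(res.amplitudes[1]) < 0.1
        assert res.proportions("MPC")[0] > res.proportions("MPC")[1]

    def test_jag1_overexpression_rescues_low_cis(self, graph0):
        cfg = RunConfig(geometry_seed=0)
        rescued = run_tissue(cfg.with_perturbation("jag1_rescue"), graph0)
        broken = run_tissue(
            cfg.with_perturbation(
                PerturbationSpec(overrides={"gamma1": 0.2, "a_J": 0.0})
            ),
            graph0,
        )
        ft_rescued = fate_proportions(rescued)
        ft_broken = fate_proportions(broken)
        assert ft_rescued.proportions["MPC"] < 0.1
        assert ft_broken.proportions["MPC"] > 0.5

    def test_identity_timescale_reproduces_wild_type(self, graph0, wt_tissue):
        cfg = RunConfig(geometry_seed=0)
        res = sweep(cfg, "ptf1a_timescale", [1.0], graph=graph0)
        ref = fate_proportions(wt_tissue)
        assert res.fate_tables[0].proportions == ref.proportions

    def test_empty_value_list_rejected(self, graph0):
        with pytest.raises(ValueError):
            sweep(RunConfig(geometry_seed=0), "gamma1", [], graph=graph0)
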