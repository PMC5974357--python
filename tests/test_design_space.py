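"""Parameter sweeps and optimal-strategy maps."""

import numpy as np
import pytest

import spatialflux as sf
from spatialflux.core import Strategy
from spatialflux.design_space import kcat_E0
from spatialflux.errors import InvalidParameterError


class TestParamPaths:
    def test_resolve_and_set(self, pdu):
        assert sf.resolve_param(pdu, "conditions.S1_out") == 5.5e4
        out = sf.set_param(pdu, "enzyme2.k_cat", 110.0)
        assert out.enzyme2.k_cat == 110.0
        assert pdu.enzyme2.k_cat == 55.0

    def test_unresolvable_path(self, pdu):
        with pytest.raises(InvalidParameterError):
            sf.set_param(pdu, "enzyme3.k_cat", 1.0)
        with pytest.raises(InvalidParameterError):
            sf.set_param(pdu, "enzyme1.k_off", 1.0)
        with pytest.raises(InvalidParameterError):
            sf.set_param(pdu, "k_cat", 1.0)


class TestKcatE0:
    def test_identity(self, pdu):
        current = kcat_E0(pdu, 2)
        assert sf.kcatE0_path(pdu, 2, current) == pdu

    def test_doubling_doubles_vmax(self, pdu):
        out = sf.kcatE0_path(pdu, 2, 2 * kcat_E0(pdu, 2))
        assert out.vmax2 == pytest.approx(2 * pdu.vmax2, rel=1e-12)
        assert out.enzyme2.copies == pdu.enzyme2.copies  # scaled via k_cat only

    def test_matches_fold_change_on_kcat(self, pdu):
        via_path = sf.kcatE0_path(pdu, 1, 3.0 * kcat_E0(pdu, 1))
        via_fold = sf.apply_fold_change(pdu, "k_cat_E0_enzyme1", 3.0)
        assert via_path.enzyme1.k_cat == pytest.approx(
            via_fold.enzyme1.k_cat, rel=1e-12
        )

    def test_monotone_flux_response(self, pdu):
        # organelle flux responds monotonically over six decades of the
        # second enzyme's activity (the dashed-line slice of the design map)
        base = kcat_E0(pdu, 2)
        fluxes = [
            sf.solve_organized(sf.kcatE0_path(pdu, 2, base * f)).pathway_flux
            for f in np.logspace(-3, 3, 7)
        ]
        assert np.all(np.diff(fluxes) > 0)

    def test_invalid_enzyme_index(self, pdu):
        with pytest.raises(InvalidParameterError):
            sf.kcatE0_path(pdu, 3, 1.0)
        with pytest.raises(InvalidParameterError):
            sf.kcatE0_path(pdu, 2, 0.0)


class TestSweep1D:
    def test_degenerate_sweep_equals_compare(self, pdu):
        sw = sf.sweep_1d(pdu, "conditions.S1_out", [pdu.conditions.S1_out])
        comp = sf.compare_strategies(pdu, "max_flux")
        for s in Strategy:
            assert sw.flux[s][0] == pytest.approx(comp.values[s], rel=1e-12, abs=0.0)

    def test_pdu_strategy_ordering_along_substrate_ladder(self, pdu):
        sw = sf.sweep_1d(pdu, "conditions.S1_out", np.logspace(1, 5, 10))
        f_org = sw.flux[Strategy.ORGANELLE]
        f_sca = sw.flux[Strategy.SCAFFOLD]
        f_non = sw.flux[Strategy.NONE]
        assert np.all(np.diff(f_org) >= 0)
        assert np.all(f_org >= f_sca)
        assert np.all(f_sca >= f_non)
        assert all(sw.converged[s].all() for s in Strategy)

    def test_cell_radius_sweep_organelle_insensitive(self, pdu):
        sw = sf.sweep_1d(
            pdu, "geometry.R_b", [2.5e-5, 5e-5, 1e-4], strategies=[Strategy.ORGANELLE]
        )
        f = sw.flux[Strategy.ORGANELLE]
        assert (f.max() - f.min()) / f.min() < 0.05

    def test_frame_shape(self, pdu):
        sw = sf.sweep_1d(pdu, "conditions.S1_out", [1e3, 1e4])
        frame = sw.to_frame()
        assert len(frame) == 2
        assert "flux_organelle" in frame.columns


class TestStrategyMap:
    def test_single_cell_equals_compare(self, pdu):
        m = sf.optimal_strategy_map(
            pdu,
            ("enzyme2.kcat_E0", [kcat_E0(pdu, 2)]),
            ("conditions.S1_out", [pdu.conditions.S1_out]),
        )
        comp = sf.compare_strategies(pdu, "max_flux")
        assert m.best[0, 0] == comp.best.value
        for s in Strategy:
            assert m.flux[s][0, 0] == pytest.approx(comp.values[s], rel=1e-12, abs=0.0)

    def test_cells_match_recomputation(self, mev):
        xg = np.array([0.5, 2.0]) * kcat_E0(mev, 2)
        yg = np.array([5e2, 5e4])
        m = sf.optimal_strategy_map(mev, ("enzyme2.kcat_E0", xg), ("conditions.S1_out", yg))
        for i, yv in enumerate(yg):
            for j, xv in enumerate(xg):
                cell = sf.set_param(
                    sf.kcatE0_path(mev, 2, xv), "conditions.S1_out", yv
                )
                comp = sf.compare_strategies(cell, "max_flux")
                assert m.best[i, j] == comp.best.value

    def test_evaluation_order_invariance(self, pdu):
        xg = np.logspace(2, 4, 3)
        yg = np.logspace(3, 5, 2)
        m = sf.optimal_strategy_map(pdu, ("enzyme1.kcat_E0", xg), ("conditions.S1_out", yg))
        m_rev = sf.optimal_strategy_map(
            pdu, ("enzyme1.kcat_E0", xg[::-1]), ("conditions.S1_out", yg[::-1])
        )
        assert np.array_equal(m.best, m_rev.best[::-1, ::-1])

    def test_mevalonate_substrate_shift(self, mev):
        # at the baseline activity of the second enzyme: organelle optimal at
        # 50 mM substrate; at 0.5 mM the scaffold out-fluxes the organelle
        m = sf.optimal_strategy_map(
            mev,
            ("enzyme2.kcat_E0", [kcat_E0(mev, 2)]),
            ("conditions.S1_out", [5e2, 5e4]),
        )
        assert m.best[1, 0] == "organelle"
        assert m.flux[Strategy.SCAFFOLD][0, 0] > m.flux[Strategy.ORGANELLE][0, 0]
        assert m.best[0, 0] in ("scaffold", "none")

    def test_weak_kinetics_leakage_map_prefers_none(self, pdu):
        weak = sf.apply_fold_change(
            sf.apply_fold_change(pdu, "k_cat_E0_enzyme1", 1e-4),
            "k_cat_E0_enzyme2",
            1e-4,
        )
        m = sf.optimal_strategy_map(
            weak,
            ("enzyme1.kcat_E0", [kcat_E0(weak, 1)]),
            ("enzyme2.kcat_E0", [kcat_E0(weak, 2)]),
            objective="min_leakage",
        )
        assert m.best[0, 0] == "none"

    @pytest.mark.parametrize("preset_name", ["pdu", "mevalonate"])
    def test_organelle_beats_scaffold_on_an_up_set(self, preset_name):
        # along S_ext, the region where the organelle out-fluxes the scaffold
        # is an up-set: a single boundary, organelle favored above it
        spec = sf.preset(preset_name)
        sw = sf.sweep_1d(spec, "conditions.S1_out", np.logspace(1.5, 5, 8),
                         strategies=[Strategy.ORGANELLE, Strategy.SCAFFOLD])
        wins = sw.flux[Strategy.ORGANELLE] >= sw.flux[Strategy.SCAFFOLD]
        # once the organelle wins, it keeps winning at all larger S_ext
        assert np.all(wins[np.argmax(wins):]) or not wins.any()

    def test_long_format_frame(self, pdu):
        m = sf.optimal_strategy_map(
            pdu, ("enzyme1.kcat_E0", np.logspace(2, 4, 3)),
            ("conditions.S1_out", np.logspace(3, 5, 2)),
        )
        frame = m.to_frame()
        assert len(frame) == 6
        assert set(frame.columns) == {
            "x_value", "y_value", "best_strategy",
            "flux_organelle", "flux_scaffold", "flux_none",
            "leak_organelle", "leak_scaffold", "leak_none",
        }

    def test_plot_smoke(self, pdu):
        import matplotlib

        matplotlib.use("Agg")
        m = sf.optimal_strategy_map(
            pdu, ("enzyme1.kcat_E0", np.logspace(2, 4, 2)),
            ("conditions.S1_out", np.logspace(3, 5, 2)),
        )
        ax = m.plot()
        assert ax is not None
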