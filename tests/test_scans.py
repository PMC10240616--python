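"""Scan machinery: grids, transitions, uncertainty bands, 2D maps."""

import numpy as np
import pytest

import fuzzypolar as fp
from fuzzypolar.scans import ScanResult, _derive_transitions, find_transition

CFG = fp.SimulationConfig(t_max=100.0)


class TestGrid:
    def test_default_grid(self):
        grid = fp.make_grid()
        assert len(grid) == 41
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert np.allclose(np.diff(grid), 0.025)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            fp.make_grid(step=0.0)
        with pytest.raises(ValueError):
            fp.make_grid(0.5, 1.5)
        with pytest.raises(ValueError):
            fp.ScanSpec1D(scan_nodes=["A"], grid=np.array([0.2, 1.2]))
        with pytest.raises(ValueError):
            fp.ScanSpec1D(scan_nodes=[])


class TestTransitionExtraction:
    def test_threshold_with_uncertainty_band(self):
        grid = np.array([0.50, 0.525, 0.55, 0.575])
        labels = ["M0", "M0", "NoLabel", "M1a"]
        transitions, bands = _derive_transitions(grid, labels)
        assert transitions == [
            {
                "value": 0.575,
                "label_before": "M0",
                "label_after": "M1a",
                "uncertainty_band": [0.55],
            }
        ]
        assert bands == [(0.55, 0.55)]

    def test_constant_labels_yield_no_transition(self):
        transitions, bands = _derive_transitions(
            np.array([0.0, 0.5, 1.0]), ["M0", "M0", "M0"]
        )
        assert transitions == [] and bands == []

    def test_two_point_grid(self):
        transitions, _ = _derive_transitions(np.array([0.0, 1.0]), ["M0", "M1a"])
        assert transitions[0]["value"] == 1.0

    def test_find_transition_threshold_none_when_absent(self, mac_system, mac_markers):
        spec = fp.ScanSpec1D(scan_nodes=["IFNG"], grid=np.array([0.0, 0.1]))
        result = fp.dose_scan_1d(mac_system, spec, mac_markers, CFG)
        assert fp.find_transition_threshold(result, "M0", "M1a") is None


class TestDoseScan1D:
    def test_disconnected_input_stays_monocyte(self):
        net = fp.loads_network("X, input, -\nG, tf, 0\n")
        markers = fp.MarkerTable(entries=[("G", "M1")])
        system = fp.build_ode_system(net)
        spec = fp.ScanSpec1D(scan_nodes=["X"], grid=fp.make_grid(0, 1, 0.25))
        result = fp.dose_scan_1d(system, spec, markers, CFG)
        assert result.labels() == ["M0"] * 5
        assert result.transitions == []

    def test_rows_cover_grid_and_record_diagnostics(self, mac_system, mac_markers):
        grid = fp.make_grid(0.4, 0.6, 0.05)
        spec = fp.ScanSpec1D(scan_nodes=["IFNG"], grid=grid)
        result = fp.dose_scan_1d(mac_system, spec, mac_markers, CFG)
        assert [r.value for r in result.rows] == list(grid)
        frame = result.to_frame()
        assert {"value", "label", "distance", "residual", "converged"} <= set(
            frame.columns
        )
        assert frame.converged.all()

    def test_grid_order_invariance(self, mac_system, mac_markers):
        """Each grid point restarts from q0, so evaluation order is
        immaterial: a permuted grid yields identical per-value states."""
        values = np.array([0.3, 0.5, 0.7])
        perm = np.array([0.7, 0.3, 0.5])
        r1 = fp.dose_scan_1d(
            mac_system, fp.ScanSpec1D(["IFNG"], grid=values), mac_markers, CFG
        )
        r2 = fp.dose_scan_1d(
            mac_system, fp.ScanSpec1D(["IFNG"], grid=perm), mac_markers, CFG
        )
        by_value = {row.value: row for row in r2.rows}
        for row in r1.rows:
            other = by_value[row.value]
            assert row.label.label == other.label.label
            assert np.array_equal(row.state.q, other.state.q)

    def test_refinement_keeps_threshold_within_one_coarse_step(
        self, mac_system, mac_markers
    ):
        coarse = fp.dose_scan_1d(
            mac_system,
            fp.ScanSpec1D(["IFNG"], grid=fp.make_grid(0.3, 0.8, 0.05)),
            mac_markers,
            CFG,
        )
        fine = fp.dose_scan_1d(
            mac_system,
            fp.ScanSpec1D(["IFNG"], grid=fp.make_grid(0.3, 0.8, 0.025)),
            mac_markers,
            CFG,
        )
        t_coarse = fp.find_transition_threshold(coarse, "M0", "M1a")
        t_fine = fp.find_transition_threshold(fine, "M0", "M1a")
        assert t_coarse is not None and t_fine is not None
        assert abs(t_coarse - t_fine) <= 0.05 + 1e-12

    def test_no_spontaneous_polarization(self, mac_system, mac_markers):
        """All inputs at zero leave the monocyte unpolarized."""
        zero_inputs = {n: 0.0 for n in mac_system.network.input_nodes}
        spec = fp.ScanSpec1D(
            scan_nodes=["IFNG"], grid=np.array([0.0]), extra_clamps=zero_inputs
        )
        result = fp.dose_scan_1d(mac_system, spec, mac_markers, CFG)
        assert result.labels() == ["M0"]


class TestMicroenvironmentAndTgem:
    def test_degenerate_single_point_grid(self, mac_system, mac_markers):
        result = fp.microenvironment_scan(
            mac_system, ["IFNG", "IFNB"], "M1", mac_markers, CFG,
            grid=np.array([0.0]),
        )
        assert len(result.rows) == 1
        assert result.labels() == ["M1"]  # the M1 core self-sustains

    def test_m1_invariant_under_interferons(self, mac_system, mac_markers):
        result = fp.microenvironment_scan(
            mac_system, "pro-M1a", "M1", mac_markers, CFG,
            grid=fp.make_grid(0.0, 1.0, 0.1),
        )
        assert set(result.labels()) <= {"M1", "NoLabel"}
        assert result.labels()[0] == "M1" and result.labels()[-1] == "M1"

    def test_tgem_clamps_pin_marker_nodes(self, mac_system, mac_markers):
        result = fp.tgem_scan(
            mac_system, ["Hypoxia", "GCGCR"], mac_markers, CFG,
            grid=np.array([0.0, 0.5, 1.0]),
        )
        for row in result.rows:
            assert row.state["NFkB"] == 1.0
            assert row.state["HIF1a"] == 0.0
        assert all("M1" in label for label in result.labels())


class TestPhenotypeMap2D:
    def test_grid_arithmetic(self, mac_system, mac_markers):
        spec = fp.MapSpec2D(
            axis1=("STAT1", "initial_value", fp.make_grid(0, 1, 0.25)),
            axis2=("NFkB", "initial_value", fp.make_grid(0, 1, 0.5)),
        )
        result = fp.phenotype_map_2d(mac_system, spec, mac_markers, CFG)
        assert result.labels.shape == (5, 3)
        assert len(result.to_frame()) == 15

    def test_distinct_axes_required(self):
        with pytest.raises(ValueError):
            fp.MapSpec2D(
                axis1=("STAT1", "initial_value", np.array([0.0])),
                axis2=("STAT1", "clamp", np.array([0.0])),
            )

    def test_degenerate_axis_reproduces_1d_scan(self, mac_system, mac_markers):
        grid = fp.make_grid(0.4, 0.6, 0.05)
        spec2d = fp.MapSpec2D(
            axis1=("IFNG", "clamp", grid),
            axis2=("IL4e", "clamp", np.array([0.0])),
        )
        map_result = fp.phenotype_map_2d(mac_system, spec2d, mac_markers, CFG)
        scan = fp.dose_scan_1d(
            mac_system,
            fp.ScanSpec1D(["IFNG"], grid=grid, extra_clamps={"IL4e": 0.0}),
            mac_markers,
            CFG,
        )
        assert list(map_result.labels[:, 0]) == scan.labels()

    def test_disconnected_clamp_axis_gives_identical_rows(self, mac_markers):
        net = fp.loads_network(
            "X, input, -\nY, input, -\nG, tf, X\n"
        )
        markers = fp.MarkerTable(entries=[("G", "M1")])
        system = fp.build_ode_system(net)
        spec = fp.MapSpec2D(
            axis1=("X", "clamp", fp.make_grid(0, 1, 0.5)),
            axis2=("Y", "clamp", fp.make_grid(0, 1, 0.5)),
        )
        result = fp.phenotype_map_2d(system, spec, markers, CFG)
        for i in range(result.labels.shape[0]):
            assert len(set(result.labels[i, :])) == 1
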