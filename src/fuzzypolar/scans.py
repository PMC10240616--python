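"""Dose scans, microenvironment scans, constant perturbations, 2D maps.

Every experiment family shares one protocol: clamp a set of nodes to a grid
value (plus any constant extra clamps), integrate the fuzzy ODE system from
a fixed initial state, and label the resulting steady state. Each grid
point restarts from the same initial state — conditions are independent, so
scan rows can be evaluated in any order and no hysteresis is introduced by
the protocol itself (a continuation mode is available but off by default).

Transition thresholds are reported as the first grid value carrying the new
label; NoLabel rows between two definite labels belong to that transition
and are reported as its uncertainty band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .dynamics import (
    ClampSet,
    SimulationConfig,
    SteadyState,
    integrate_to_steady_state,
)
from .fuzzy import FuzzyODESystem
from .network import MarkerTable
from .phenotyping import PhenotypeLabel, distance_to_initial, label_state
from .synthetic import make_initial_state

__all__ = [
    "ScanSpec1D",
    "ScanRow",
    "ScanResult",
    "MapSpec2D",
    "Map2DResult",
    "dose_scan_1d",
    "microenvironment_scan",
    "tgem_scan",
    "phenotype_map_2d",
    "find_transition_threshold",
    "find_transition",
    "make_grid",
    "MICROENVIRONMENTS",
    "TGEM_CLAMPS",
]

#: Named microenvironments: extracellular nodes clamped jointly to the
#: common grid value.
MICROENVIRONMENTS: dict[str, tuple[str, ...]] = {
    "pro-M1a": ("IFNG", "IFNB"),
    "pro-M1": ("TNFAe", "IL1B"),
    "pro-M2a": ("IL4e", "TGFB"),
    "pro-M2b": ("IgG", "GCGCR"),
    "pro-M2c": ("IL10e", "MCSF", "IL6e"),
    "pro-M2d": ("A2a", "Hypoxia", "GCGCR"),
    # breast-cancer-associated combinations
    "bc-IgG-A2a": ("IgG", "A2a"),
    "bc-IL10-TGFB": ("IL10e", "TGFB"),
    "bc-storm": ("IL1B", "IL6e", "IFNG"),
    "bc-hypoxia": ("Hypoxia", "GCGCR"),
}

#: Constant perturbation defining the theoretically genetically modified
#: macrophage: NFkB permanently active, HIF1a permanently inactive.
TGEM_CLAMPS: dict[str, float] = {"NFkB": 1.0, "HIF1a": 0.0}


def make_grid(start: float = 0.0, stop: float = 1.0, step: float = 0.025) -> np.ndarray:
    """Inclusive clamp-value grid; default 0..1 in steps of 0.025."""
    if step <= 0:
        raise ValueError("step must be > 0")
    if not (0.0 <= start <= stop <= 1.0):
        raise ValueError("grid must lie within [0, 1]")
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    return np.clip(grid, 0.0, 1.0)


@dataclass
class ScanSpec1D:
    """One-dimensional dose scan specification.

    scan_nodes : nodes clamped together at the same grid value
    grid : clamp values (defaults to 0..1 step 0.025)
    q0 : initial state — a vector or a phenotype name ("M0", "M1", ...)
    extra_clamps : constant clamps applied at every grid point
    continuation : start each grid point from the previous point's steady
        state instead of from q0 (off by default; independent conditions)
    """

    scan_nodes: Sequence[str]
    grid: np.ndarray = field(default_factory=make_grid)
    q0: Union[str, Sequence[float]] = "M0"
    extra_clamps: ClampSet | Mapping[str, float] | None = None
    continuation: bool = False

    def __post_init__(self) -> None:
        if not self.scan_nodes:
            raise ValueError("scan_nodes must be nonempty")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or len(grid) == 0:
            raise ValueError("grid must be a nonempty 1D array")
        if grid.min() < 0 or grid.max() > 1:
            raise ValueError("grid values must lie in [0, 1]")
        self.grid = grid


@dataclass
class ScanRow:
    value: float
    state: SteadyState
    label: PhenotypeLabel
    distance: float

    @property
    def residual(self) -> float:
        return self.state.residual


@dataclass
class ScanResult:
    """Rows over the full grid plus derived transitions and NoLabel bands."""

    spec: ScanSpec1D
    rows: list[ScanRow]
    transitions: list[dict]
    uncertainty_bands: list[tuple[float, float]]

    def labels(self) -> list[str]:
        return [row.label.label for row in self.rows]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {
                "value": row.value,
                "label": row.label.label,
                "distance": row.distance,
                "residual": row.state.residual,
                "converged": row.state.converged,
            }
            for marker_name in row.state.names:
                rec[marker_name] = row.state[marker_name]
            records.append(rec)
        return pd.DataFrame(records)


def _derive_transitions(
    grid: np.ndarray, labels: list[str]
) -> tuple[list[dict], list[tuple[float, float]]]:
    transitions: list[dict] = []
    bands: list[tuple[float, float]] = []
    last_definite: str | None = None
    pending: list[float] = []
    band_start: float | None = None
    for value, label in zip(grid, labels):
        if label == "NoLabel":
            pending.append(float(value))
            if band_start is None:
                band_start = float(value)
            continue
        if band_start is not None:
            bands.append((band_start, pending[-1]))
            band_start = None
        if last_definite is not None and label != last_definite:
            transitions.append(
                {
                    "value": float(value),
                    "label_before": last_definite,
                    "label_after": label,
                    "uncertainty_band": list(pending),
                }
            )
        last_definite = label
        pending = []
    if band_start is not None:
        bands.append((band_start, pending[-1]))
    return transitions, bands


def dose_scan_1d(
    system: FuzzyODESystem,
    spec: ScanSpec1D,
    markers: MarkerTable,
    cfg: SimulationConfig | None = None,
) -> ScanResult:
    """Clamp the scan nodes to each grid value, integrate from q0, label.

    Non-convergence at a grid point is recorded in that row (label "Cyclic"
    or residual diagnostics), never fatal for the scan.
    """
    cfg = cfg or SimulationConfig()
    markers.validate_against(system.network)
    q0 = make_initial_state(system.network, spec.q0)
    extra = (
        spec.extra_clamps
        if isinstance(spec.extra_clamps, ClampSet)
        else ClampSet(dict(spec.extra_clamps or {}))
    )
    rows: list[ScanRow] = []
    q_start = q0
    for value in spec.grid:
        clamps = extra.merged({node: float(value) for node in spec.scan_nodes})
        state = integrate_to_steady_state(system, q_start, clamps, cfg)
        rows.append(
            ScanRow(
                value=float(value),
                state=state,
                label=label_state(state, markers),
                distance=distance_to_initial(state, q0, system.network),
            )
        )
        if spec.continuation:
            q_start = state.q
    transitions, bands = _derive_transitions(spec.grid, [r.label.label for r in rows])
    return ScanResult(spec=spec, rows=rows, transitions=transitions, uncertainty_bands=bands)


def microenvironment_scan(
    system: FuzzyODESystem,
    env_nodes: Sequence[str],
    q0: Union[str, Sequence[float]],
    markers: MarkerTable,
    cfg: SimulationConfig | None = None,
    grid: np.ndarray | None = None,
    extra_clamps: Mapping[str, float] | None = None,
) -> ScanResult:
    """Joint gradual increase of a named set of extracellular nodes.

    Identical contract to :func:`dose_scan_1d` with all environment nodes
    clamped to the common grid value; ``env_nodes`` may be a preset name
    from :data:`MICROENVIRONMENTS`.
    """
    if isinstance(env_nodes, str):
        env_nodes = MICROENVIRONMENTS[env_nodes]
    spec = ScanSpec1D(
        scan_nodes=list(env_nodes),
        grid=make_grid() if grid is None else grid,
        q0=q0,
        extra_clamps=extra_clamps,
    )
    return dose_scan_1d(system, spec, markers, cfg)


def tgem_scan(
    system: FuzzyODESystem,
    env_nodes: Sequence[str],
    markers: MarkerTable,
    cfg: SimulationConfig | None = None,
    grid: np.ndarray | None = None,
    q0: Union[str, Sequence[float]] = "M1",
    clamps: Mapping[str, float] | None = None,
) -> ScanResult:
    """Dose scan under the TGEM constant perturbation.

    The theoretically genetically modified macrophage holds NFkB clamped
    fully active and HIF1a fully inactive while an environment is scanned.
    """
    if isinstance(env_nodes, str):
        env_nodes = MICROENVIRONMENTS[env_nodes]
    spec = ScanSpec1D(
        scan_nodes=list(env_nodes),
        grid=make_grid() if grid is None else grid,
        q0=q0,
        extra_clamps=dict(clamps if clamps is not None else TGEM_CLAMPS),
    )
    return dose_scan_1d(system, spec, markers, cfg)


@dataclass
class MapSpec2D:
    """Two-axis phenotype-space map specification.

    Each axis is (node, role, grid) with role "initial_value" (the node's
    component of the initial state is set to the grid value) or "clamp"
    (the node is clamped). ``environment`` is a constant clamp set and
    ``q0`` the initial-state template the axes modify.
    """

    axis1: tuple[str, str, np.ndarray]
    axis2: tuple[str, str, np.ndarray]
    environment: ClampSet | Mapping[str, float] | None = None
    q0: Union[str, Sequence[float]] = "M0"

    def __post_init__(self) -> None:
        for node, role, grid in (self.axis1, self.axis2):
            if role not in ("initial_value", "clamp"):
                raise ValueError(f"axis role {role!r} invalid")
            grid = np.asarray(grid, dtype=float)
            if grid.min() < 0 or grid.max() > 1:
                raise ValueError("axis grid values must lie in [0, 1]")
        if self.axis1[0] == self.axis2[0]:
            raise ValueError("axes must reference distinct nodes")


@dataclass
class Map2DResult:
    spec: MapSpec2D
    labels: np.ndarray  # dtype=object, shape (len(grid1), len(grid2))
    states: list[list[SteadyState]]

    def to_frame(self) -> pd.DataFrame:
        n1, _, g1 = self.spec.axis1
        n2, _, g2 = self.spec.axis2
        records = []
        for i, v1 in enumerate(np.asarray(g1, dtype=float)):
            for j, v2 in enumerate(np.asarray(g2, dtype=float)):
                records.append(
                    {n1: float(v1), n2: float(v2), "label": self.labels[i, j]}
                )
        return pd.DataFrame(records)


def phenotype_map_2d(
    system: FuzzyODESystem,
    spec: MapSpec2D,
    markers: MarkerTable,
    cfg: SimulationConfig | None = None,
) -> Map2DResult:
    """Label matrix over a two-axis grid of initial values and/or clamps."""
    cfg = cfg or SimulationConfig()
    markers.validate_against(system.network)
    q_template = make_initial_state(system.network, spec.q0)
    env = (
        spec.environment
        if isinstance(spec.environment, ClampSet)
        else ClampSet(dict(spec.environment or {}))
    )
    idx = system.network.index
    node1, role1, grid1 = spec.axis1
    node2, role2, grid2 = spec.axis2
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    labels = np.empty((len(grid1), len(grid2)), dtype=object)
    states: list[list[SteadyState]] = []
    for i, v1 in enumerate(grid1):
        row_states: list[SteadyState] = []
        for j, v2 in enumerate(grid2):
            q0 = q_template.copy()
            cell_clamps: dict[str, float] = {}
            for node, role, value in ((node1, role1, v1), (node2, role2, v2)):
                if role == "clamp":
                    cell_clamps[node] = float(value)
                else:
                    q0[idx[node]] = float(value)
            state = integrate_to_steady_state(
                system, q0, env.merged(cell_clamps), cfg
            )
            labels[i, j] = label_state(state, markers).label
            row_states.append(state)
        states.append(row_states)
    return Map2DResult(spec=spec, labels=labels, states=states)


def find_transition(
    result: ScanResult, from_label: str, to_label: str
) -> dict | None:
    """First transition record matching (from_label -> to_label), or None."""
    for tr in result.transitions:
        if tr["label_before"] == from_label and tr["label_after"] == to_label:
            return tr
    return None


def find_transition_threshold(
    result: ScanResult, from_label: str, to_label: str
) -> float | None:
    """Smallest grid value whose label is ``to_label`` with the preceding
    definite label equal to ``from_label``; None when absent.

    NoLabel rows between the two labels are attributed to the transition;
    they are available as the record's ``uncertainty_band``.
    """
    tr = find_transition(result, from_label, to_label)
    return None if tr is None else tr["value"]
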