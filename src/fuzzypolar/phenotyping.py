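"""Steady-state phenotype labeling.

A marker transcription factor counts as *activated* when its steady-state
expression is >= 0.75 and *inactivated* when <= 0.25 (both inclusive). Any
marker strictly inside the intermediate band (0.25, 0.75) leaves the state
unlabelable ("NoLabel", the range of uncertainty). Otherwise the label is
the concatenation of the tags of all active markers in the canonical order
M1 < M1a < M2a < M2b < M2c < M2d; no active marker at all is the monocyte
"M0". States that never settled to a fixed point are labeled "Cyclic".

When both M1-family markers (NFkB -> M1 and STAT1 -> M1a) are active the
combined tag collapses to "M1": the two factors jointly define the classical
pro-inflammatory macrophage and the subtype distinction only applies when
one of them is specifically active. The collapse is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import StateClass, SteadyState
from .network import MarkerTable, NodeClass, RegulatoryNetwork

__all__ = [
    "ACTIVATION_THRESHOLD",
    "INACTIVATION_THRESHOLD",
    "PhenotypeLabel",
    "label_state",
    "distance_to_initial",
]

ACTIVATION_THRESHOLD = 0.75
INACTIVATION_THRESHOLD = 0.25


@dataclass(frozen=True)
class PhenotypeLabel:
    """Canonical label plus the set of active markers behind it."""

    label: str
    active_markers: frozenset[str] = frozenset()

    def __str__(self) -> str:
        return self.label

    def __eq__(self, other) -> bool:  # allow comparison against bare strings
        if isinstance(other, str):
            return self.label == other
        if isinstance(other, PhenotypeLabel):
            return (self.label, self.active_markers) == (
                other.label,
                other.active_markers,
            )
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.label)


def label_state(
    state: SteadyState,
    markers: MarkerTable,
    activation: float = ACTIVATION_THRESHOLD,
    inactivation: float = INACTIVATION_THRESHOLD,
    collapse_m1: bool = True,
) -> PhenotypeLabel:
    """Map a steady state to its phenotype label.

    The label is a pure function of the state vector and the marker table:
    marker-table row order never changes the result. A state not classified
    as a fixed point is labeled "Cyclic". A marker missing from the state
    vector raises ``KeyError``.
    """
    if state.classification is not StateClass.fixed_point:
        return PhenotypeLabel("Cyclic")
    active: set[str] = set()
    for marker, _tag in markers.entries:
        value = state[marker]  # KeyError when absent
        if value >= activation:
            active.add(marker)
        elif value <= inactivation:
            continue
        else:
            return PhenotypeLabel("NoLabel")
    if not active:
        return PhenotypeLabel("M0")
    tags = {markers.tag_of(m) for m in active}
    if collapse_m1 and "M1" in tags and "M1a" in tags:
        tags.discard("M1a")
    ordered = sorted(tags, key=markers.tag_order.index)
    return PhenotypeLabel("".join(ordered), frozenset(active))


def distance_to_initial(
    state: SteadyState,
    q0: np.ndarray,
    network: RegulatoryNetwork | None = None,
) -> float:
    """Euclidean distance between the steady state and the initial state.

    Computed over transcription-factor nodes only when a network is given
    (inputs are clamped, so their displacement is an artifact of the scan
    protocol rather than of the dynamics); over all components otherwise.
    """
    q0 = np.asarray(q0, dtype=float)
    if q0.shape != state.q.shape:
        raise ValueError(
            f"dimension mismatch: state {state.q.shape} vs q0 {q0.shape}"
        )
    delta = state.q - q0
    if network is not None:
        idx = [
            i
            for i, node in enumerate(network.nodes)
            if node.klass is NodeClass.transcription_factor
        ]
        delta = delta[idx]
    return float(np.linalg.norm(delta))


def difference_vector(state: SteadyState, q0: np.ndarray) -> dict[str, float]:
    """Per-node displacement q - q0, for recomputing any distance metric."""
    q0 = np.asarray(q0, dtype=float)
    return {n: float(d) for n, d in zip(state.names, state.q - q0)}
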