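"""Time-dependent fuzzy aggregation of optical flow over four spatial cells.

The flow field is divided into a 2x2 grid of cells (top-left, top-right,
bottom-left, bottom-right) over the moving person's bounding box.  Each
frame yields instantaneous triangular memberships from the location of the
flow maximum, scaled by each cell's share of the total flow energy.  A
temporal memory then aggregates them:

    mu(t) = mu(t - tau) + eta(t) * (1 - mu(t - tau))

for the winning cell, with a frame counter k since the last winner change,
capped at a memory horizon N; non-winning cells decay multiplicatively so a
sustained new winner can overtake.  Winner-takes-all defuzzification maps
the aggregated memberships to a limb group: lower (walking/jogging/running)
when the bottom cells dominate, upper (boxing/clapping/waving) when the top
cells do.  The memory is the stabiliser: one spurious frame cannot flip an
established winner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .motion_flow import FlowField, flow_energy

logger = logging.getLogger(__name__)

__all__ = [
    "CellGrid",
    "MembershipState",
    "divide_flow",
    "frame_membership",
    "update_membership",
    "defuzzify",
    "grid_from_flow",
    "grid_from_frame",
    "export_membership_trace",
    "LOWER_CLASSES",
    "UPPER_CLASSES",
]

#: cell order everywhere: 0 top-left, 1 top-right, 2 bottom-left, 3 bottom-right
LOWER_CLASSES = ("walking", "jogging", "running")
UPPER_CLASSES = ("boxing", "clapping", "waving")

DEFAULT_ETA = 0.15
DEFAULT_N = 25
DEFAULT_TAU = 1.0 / 25.0


@dataclass(frozen=True)
class CellGrid:
    """2x2 cell partition of rows [row0, row1) x cols [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self):
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("grid region must be non-empty")

    @property
    def row_mid(self) -> int:
        return (self.row0 + self.row1) // 2

    @property
    def col_mid(self) -> int:
        return (self.col0 + self.col1) // 2

    def cell_slices(self):
        rm, cm = self.row_mid, self.col_mid
        return [
            (slice(self.row0, rm), slice(self.col0, cm)),  # top-left
            (slice(self.row0, rm), slice(cm, self.col1)),  # top-right
            (slice(rm, self.row1), slice(self.col0, cm)),  # bottom-left
            (slice(rm, self.row1), slice(cm, self.col1)),  # bottom-right
        ]

    def cell_centers(self) -> np.ndarray:
        """(4, 2) array of (row, col) cell centres."""
        out = []
        for rs, cs in self.cell_slices():
            out.append([(rs.start + rs.stop - 1) / 2.0, (cs.start + cs.stop - 1) / 2.0])
        return np.array(out)


@dataclass
class MembershipState:
    """Aggregated memberships plus the temporal-memory bookkeeping."""

    mu: np.ndarray = field(default_factory=lambda: np.zeros(4))
    k: int = 0
    N: int = DEFAULT_N
    eta: float = DEFAULT_ETA
    tau: float = DEFAULT_TAU
    winner: int = -1  # -1: no winner seen yet

    def copy(self) -> "MembershipState":
        return replace(self, mu=self.mu.copy())


def grid_from_frame(frame: np.ndarray, threshold_frac: float = 0.25) -> CellGrid:
    """Person-box grid from intensity deviation against the background.

    Pixels deviating from the median intensity by more than
    ``threshold_frac`` of the maximum deviation delimit the figure.  Unlike
    a box thresholded on flow energy, this stays anchored to the whole body
    when only one limb group moves, so the 2x2 cells keep their upper/lower
    body meaning.  Falls back to the full frame for blank frames.
    """
    frame = np.asarray(frame, dtype=float)
    dev = np.abs(frame - np.median(frame))
    peak = dev.max()
    if peak <= 1e-9:
        return CellGrid(0, frame.shape[0], 0, frame.shape[1])
    mask = dev > threshold_frac * peak
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size < 2 or cols.size < 2:
        return CellGrid(0, frame.shape[0], 0, frame.shape[1])
    return CellGrid(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def grid_from_flow(flow: FlowField, threshold_frac: float = 0.1) -> CellGrid:
    """Bounding-box grid from thresholded flow energy.

    Pixels with energy above ``threshold_frac`` of the maximum define the
    person box; a degenerate (empty or all-static) field falls back to the
    full frame.
    """
    e = flow_energy(flow)
    peak = e.max()
    if peak <= 0:
        return CellGrid(0, e.shape[0], 0, e.shape[1])
    mask = e > threshold_frac * peak
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size < 2 or cols.size < 2:
        return CellGrid(0, e.shape[0], 0, e.shape[1])
    return CellGrid(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def divide_flow(flow: FlowField, grid: CellGrid) -> np.ndarray:
    """Per-cell summed flow energy (4-vector, cell order as above)."""
    e = flow_energy(flow)
    if grid.row1 > e.shape[0] or grid.col1 > e.shape[1]:
        raise ValueError("grid does not fit the flow field")
    return np.array([float(e[rs, cs].sum()) for rs, cs in grid.cell_slices()])


def frame_membership(
    cell_energies: np.ndarray, peak_location, grid: CellGrid
) -> np.ndarray:
    """Instantaneous memberships from the maximum-flow location.

    Triangular membership per cell: 1 at the cell centre, falling linearly
    to 0 at the opposite cell centre (separably in row and column), scaled
    by the cell's share of the total energy.  All-zero energies give
    all-zero memberships.
    """
    cell_energies = np.asarray(cell_energies, dtype=float)
    if np.any(cell_energies < 0):
        raise ValueError("cell energies must be non-negative")
    total = cell_energies.sum()
    if total <= 0:
        return np.zeros(4)
    share = cell_energies / total
    centers = grid.cell_centers()
    pr, pc = float(peak_location[0]), float(peak_location[1])
    dr = abs(centers[0, 0] - centers[2, 0])  # row distance to opposite cell
    dc = abs(centers[0, 1] - centers[1, 1])  # col distance to opposite cell
    dr = max(dr, 1e-9)
    dc = max(dc, 1e-9)
    mu = np.empty(4)
    for i in range(4):
        tri_r = max(0.0, 1.0 - abs(pr - centers[i, 0]) / dr)
        tri_c = max(0.0, 1.0 - abs(pc - centers[i, 1]) / dc)
        mu[i] = tri_r * tri_c * share[i]
    return mu


def update_membership(state: MembershipState, eta_t: np.ndarray) -> MembershipState:
    """One step of the temporal-memory recursion.

    The winning cell (argmax of ``eta_t``) is reinforced by
    ``mu += eta * (1 - mu)``; the other cells decay by ``(1 - eta_win)``.
    A winner change resets the frame counter k; once k reaches the memory
    horizon N the winner's membership is no longer incremented (the decay
    of the others still applies).  All-zero ``eta_t`` leaves memberships
    untouched and only advances k.
    """
    eta_t = np.asarray(eta_t, dtype=float)
    if eta_t.shape != (4,) or np.any(eta_t < 0) or np.any(eta_t > 1):
        raise ValueError("eta_t must be a 4-vector in [0, 1]")
    new = state.copy()
    if not np.any(eta_t > 0):
        new.k = min(state.k + 1, state.N)
        return new
    win = int(np.argmax(eta_t))
    if win != state.winner:
        new.winner = win
        new.k = 0
    else:
        new.k = min(state.k + 1, state.N)
    eta_w = float(eta_t[win])
    if new.k < new.N:
        new.mu[win] = new.mu[win] + eta_w * (1.0 - new.mu[win])
    for i in range(4):
        if i != win:
            new.mu[i] *= 1.0 - eta_w
    np.clip(new.mu, 0.0, 1.0, out=new.mu)
    return new


def export_membership_trace(states, path) -> None:
    """Write a sequence of MembershipState snapshots as a TSV table.

    Columns: frame, mu_C1..mu_C4, winner, group, confidence.
    """
    lines = ["frame\tmu_C1\tmu_C2\tmu_C3\tmu_C4\twinner\tgroup\tconfidence"]
    for t, st in enumerate(states):
        group, conf = defuzzify(st)
        mus = "\t".join(f"{m:.6f}" for m in st.mu)
        lines.append(f"{t}\t{mus}\t{st.winner}\t{group}\t{conf:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def defuzzify(state: MembershipState):
    """Winner-takes-all limb-group decision.

    Returns ``(group, confidence)`` with group in {"upper", "lower",
    "unknown"}.  Lower wins iff the best bottom-cell membership exceeds the
    best top-cell membership; confidence is the winning maximum over the sum
    of the two maxima.  An exact tie goes to "lower" at confidence 0.5; an
    all-zero state is "unknown" at confidence 0.
    """
    top = float(max(state.mu[0], state.mu[1]))
    bottom = float(max(state.mu[2], state.mu[3]))
    if top == 0.0 and bottom == 0.0:
        return "unknown", 0.0
    if bottom == top:
        logger.debug("defuzzify tie at mu=%s", state.mu)
        return "lower", 0.5
    if bottom > top:
        return "lower", bottom / (bottom + top)
    return "upper", top / (bottom + top)
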