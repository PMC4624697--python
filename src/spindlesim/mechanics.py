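"""Force assembly and the overdamped chromosome position update.

A chromosome moves according to the discretised overdamped equation
``r(t + dt) = r(t) + F_total * dt / eta`` where ``F_total`` is the sum of

* polar ejection forces: ``F_PEF`` along the plus-end direction of every MT
  crossing the arm cross-section within ``r_c`` of the chromosome centre;
* the lateral motor-group force on the current rail: ``+F_CENPE * u``
  (plus-end-ward) or ``-F_DYN * u`` (pole-ward), ``u`` the rail direction;
* end-on spring forces from attached MT tips.

There is no thermal noise term; all stochasticity enters through MT turnover
and attachment kinetics.  After the Euler step, positions outside the cortex
are projected radially back to the boundary (hard repulsion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attachments import end_on_spring_forces
from .geometry import _confine
from .params import ParameterSet
from .state import CENPE, DYNEIN, SimulationState


@dataclass
class ForceBreakdown:
    """Per-chromosome force contributions (pN), each of shape (n_c, 3)."""

    f_pef: np.ndarray
    f_lateral: np.ndarray
    f_spring: np.ndarray

    @property
    def f_total(self) -> np.ndarray:
        return self.f_pef + self.f_lateral + self.f_spring


def polar_ejection_force(state: SimulationState) -> np.ndarray:
    """Net PEF on each chromosome, shape (n_c, 3).

    Disk geometry (default): an MT contributes iff its segment crosses the
    plane through the chromosome centre perpendicular to x at a point within
    ``r_c`` of the centre; each crossing MT pushes with ``f_pef`` along its
    own direction (towards its plus end).
    """
    p = state.params
    out = np.zeros((state.n_c, 3))
    if state.n_mt == 0 or p.f_pef == 0.0:
        return out
    starts = state.mt_starts()
    if p.pef_geometry == "disk":
        dx = state.mt_dir[:, 0]
        safe_dx = np.where(dx == 0.0, np.inf, dx)
        # t_cross per (chromosome, MT): (x_ch - x_start) / dx
        t = (state.ch_pos[:, 0:1] - starts[None, :, 0]) / safe_dx[None, :]
        valid = (t > 0.0) & (t <= state.mt_len[None, :])
        hy = starts[None, :, 1] + t * state.mt_dir[None, :, 1]
        hz = starts[None, :, 2] + t * state.mt_dir[None, :, 2]
        d2 = (hy - state.ch_pos[:, 1:2]) ** 2 + (hz - state.ch_pos[:, 2:3]) ** 2
        crossing = valid & (d2 <= p.r_c * p.r_c)
    else:  # orientation-free spherical cross-section
        from .geometry import segment_point_distance
        crossing = np.stack([
            segment_point_distance(starts, state.mt_dir, state.mt_len,
                                   state.ch_pos[i]) <= p.r_c
            for i in range(state.n_c)
        ])
    out = p.f_pef * (crossing.astype(float) @ state.mt_dir)
    return out


def pef_crossing_counts(state: SimulationState) -> np.ndarray:
    """Number of MTs crossing each chromosome's arm cross-section."""
    p = state.params
    if state.n_mt == 0:
        return np.zeros(state.n_c, dtype=int)
    starts = state.mt_starts()
    counts = np.zeros(state.n_c, dtype=int)
    for i in range(state.n_c):
        from .geometry import arm_crossing_test
        mask = arm_crossing_test(starts, state.mt_dir, state.mt_len,
                                 state.ch_pos[i], p.r_c, p.pef_geometry)
        counts[i] = int(np.sum(mask))
    return counts


def lateral_motor_force(state: SimulationState) -> np.ndarray:
    """Motor-group force on each laterally linked chromosome, (n_c, 3).

    A motor group cannot walk past the end of its track: CENP-E stalls at
    the rail plus end (where it holds the chromosome for end-on conversion)
    and dynein stalls at the pole, so the transport force vanishes once the
    chromosome's projection onto the rail reaches the corresponding end.
    """
    p = state.params
    out = np.zeros((state.n_c, 3))
    linked = np.flatnonzero(state.ch_lateral >= 0)
    if linked.size == 0:
        return out
    rails = state.ch_lateral[linked]
    u = state.mt_dir[rails]
    proj = np.einsum("ij,ij->i",
                     state.ch_pos[linked] - state.pole_positions[state.mt_pole[rails]],
                     u)
    cenpe = state.ch_motor[linked] == CENPE
    sign = np.where(cenpe, p.f_cenpe, -p.f_dyn)
    stalled = np.where(cenpe, proj >= state.mt_len[rails], proj <= 0.0)
    out[linked] = np.where(stalled[:, None], 0.0, sign[:, None] * u)
    return out


def net_force(state: SimulationState) -> ForceBreakdown:
    """Assemble the three force contributions for every chromosome."""
    return ForceBreakdown(
        f_pef=polar_ejection_force(state),
        f_lateral=lateral_motor_force(state),
        f_spring=end_on_spring_forces(state),
    )


def advance_chromosomes(state: SimulationState, forces: ForceBreakdown,
                        dt: float) -> None:
    """Euler step of the overdamped equation of motion, then confinement."""
    p = state.params
    state.ch_pos += forces.f_total * (dt / p.eta_pn_s_per_um)
    _confine(state.ch_pos, state.geometry)
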