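"""Kinetochore--microtubule attachment lifecycle.

The motor program is deterministic: chromosomes starting inside the
interpolar shell (|r| < 0.45a) carry active CENP-E; peripheral chromosomes
carry kinetochore dynein, which transports them to the nearest pole, where
dynein is switched off (Aurora-A zone of radius ``delta_pole``) and CENP-E
takes over permanently.

Lateral attachments form when an MT passes within ``r_k`` of the kinetochore
sphere and serve as transport rails.  Dynein rides any MT; CENP-E requires a
long-lived rail (age > tau_MT, or a scaffold MT), which biases plate-ward
transport onto stable interpolar tracks.

End-on attachments form only while CENP-E is active (dynein-coated
kinetochores inhibit them): any MT tip within ``r_k`` of the chromosome
centre binds the kinetochore hemisphere it touches, if a slot is free.  The
coupling is a zero-rest-length spring of stiffness ``k_k``.  Attachments are
*stable* only for the amphitelic configuration (both kinetochores occupied,
attached MTs stemming from both poles); otherwise they are *unstable*.
Unstable attachments are slip bonds (detachment accelerates with load),
stable ones catch bonds (load suppresses detachment).
"""

from __future__ import annotations

import numpy as np

from .geometry import segment_point_distance
from .params import ParameterSet
from .state import (CENPE, DYNEIN, ST_NONE, ST_STABLE, ST_UNSTABLE,
                    SimulationState)


# ---------------------------------------------------------------------------
# motor program
# ---------------------------------------------------------------------------

def init_motor_program(state: SimulationState) -> None:
    """Set the initial motor per chromosome from the 0.45a interpolar shell."""
    r = np.linalg.norm(state.ch_pos, axis=1)
    inside = r < state.geometry.r_cenpe_shell
    state.ch_motor[:] = np.where(inside, CENPE, DYNEIN)


def update_motor_program(state: SimulationState) -> None:
    """Permanently switch dynein -> CENP-E for chromosomes arriving at a pole.

    The switch models Aurora-A inactivating dynein at the pole *and CENP-E
    taking over*; with CENP-E depleted there is nothing to replace dynein, so
    the switch does not occur and pole-bound chromosomes stay dynein-held
    (which is what traps them at the poles).
    """
    if state.params.f_cenpe == 0.0:
        return
    dyn = state.ch_motor == DYNEIN
    if not np.any(dyn):
        return
    d = np.linalg.norm(state.ch_pos[dyn, None, :] - state.pole_positions[None, :, :],
                       axis=2).min(axis=1)
    arrived = d < state.params.delta_pole
    if np.any(arrived):
        idx = np.flatnonzero(dyn)[arrived]
        state.ch_motor[idx] = CENPE
        # the dynein rail is released; CENP-E must find its own
        # (stable, centre-pointing) track
        state.ch_lateral[idx] = -1
        for i in idx:
            state.events.add(state.t, "motor_switch", chrom=int(i))


# ---------------------------------------------------------------------------
# stability classification and bond kinetics
# ---------------------------------------------------------------------------

def classify_stability(state: SimulationState) -> np.ndarray:
    """Per-chromosome stability class (ST_NONE / ST_UNSTABLE / ST_STABLE).

    Stable requires the amphitelic condition: both kinetochores end-on
    occupied *and* the union of attached MTs stems from both poles.
    """
    occ = state.pole_occupancy()            # (n_c, side, pole)
    per_side = occ.sum(axis=2)              # (n_c, 2)
    per_pole = occ.sum(axis=1)              # (n_c, 2)
    any_att = per_side.sum(axis=1) > 0
    stable = (per_side > 0).all(axis=1) & (per_pole > 0).all(axis=1)
    out = np.full(state.n_c, ST_NONE, dtype=np.int8)
    out[any_att & ~stable] = ST_UNSTABLE
    out[stable] = ST_STABLE
    return out


def detachment_rate(force, stability, p: ParameterSet):
    """Detachment rate (1/s): slip bond if unstable, catch bond if stable."""
    force = np.asarray(force, dtype=float)
    stability = np.asarray(stability)
    if np.any(stability == ST_NONE):
        raise ValueError("detachment rate undefined without an attachment")
    slip = p.p_detach_u0 * np.exp(force / p.f_detach_u)
    catch = p.p_detach_s0 * np.exp(-force / p.f_detach_s)
    return np.where(stability == ST_STABLE, catch, slip)


def detachment_probability(force, stability, p: ParameterSet, dt: float):
    """Per-step detachment probability, 1 - exp(-rate*dt)."""
    return -np.expm1(-detachment_rate(force, stability, p) * dt)


def end_on_tip_forces(state: SimulationState) -> np.ndarray:
    """Spring tension magnitude (pN) on every MT tip; zero if unattached."""
    f = np.zeros(state.n_mt)
    att = state.mt_attach_ch >= 0
    if np.any(att):
        tips = state.mt_tips()[att]
        stretch = np.linalg.norm(tips - state.ch_pos[state.mt_attach_ch[att]], axis=1)
        f[att] = state.params.k_k * stretch
    return f


def end_on_spring_forces(state: SimulationState) -> np.ndarray:
    """Net end-on spring force on each chromosome, shape (n_c, 3).

    Each attached MT pulls its chromosome towards the MT tip with force
    ``k_k * (tip - r)`` (zero rest length); the tip feels the equal and
    opposite tension.
    """
    out = np.zeros((state.n_c, 3))
    att = state.mt_attach_ch >= 0
    if np.any(att):
        ch = state.mt_attach_ch[att]
        vec = state.params.k_k * (state.mt_tips()[att] - state.ch_pos[ch])
        np.add.at(out, ch, vec)
    return out


# ---------------------------------------------------------------------------
# attachment formation
# ---------------------------------------------------------------------------

def form_end_on(state: SimulationState, tips=None) -> int:
    """Form new end-on attachments; returns the number formed.

    Only CENP-E chromosomes accept tips; each free MT tip within ``r_k`` of
    the chromosome centre occupies one slot on the hemisphere whose side
    (sign of the x-offset; ties to the MT's own pole) it touches, while
    slots remain (capacity ``n_k`` per kinetochore).  Chromosomes claim MTs
    in index order; an MT occupies at most one slot.
    """
    p = state.params
    cenpe = np.flatnonzero(state.ch_motor == CENPE)
    if cenpe.size == 0 or state.n_mt == 0:
        return 0
    # a tip released by a stochastic detachment may not rebind until its
    # refractory time has passed (its catastrophe carries it away first)
    free = (state.mt_attach_ch < 0) & (state.mt_refract_until <= state.t)
    if not np.any(free):
        return 0
    free_idx = np.flatnonzero(free)
    all_tips = state.mt_tips() if tips is None else tips
    tips = all_tips[free_idx]
    occ = state.slot_occupancy()
    formed = 0
    for ci in cenpe:
        if occ[ci, 0] >= p.n_k and occ[ci, 1] >= p.n_k:
            continue
        rel = tips - state.ch_pos[ci]
        near = np.einsum("ij,ij->i", rel, rel) <= p.r_k * p.r_k
        if not np.any(near):
            continue
        cand = np.flatnonzero(near)
        xoff = rel[cand, 0]
        side = (xoff > 0).astype(np.int8)
        tie = xoff == 0
        if np.any(tie):
            side[tie] = state.mt_pole[free_idx[cand[tie]]]
        for k, s in zip(cand, side):
            mt = free_idx[k]
            if state.mt_attach_ch[mt] >= 0:
                continue
            if occ[ci, s] >= p.n_k:
                continue
            state.mt_attach_ch[mt] = ci
            state.mt_attach_side[mt] = s
            occ[ci, s] += 1
            formed += 1
            state.events.add(state.t, "attach", mt=int(mt), chrom=int(ci),
                             side=int(s))
    return formed


def form_lateral(state: SimulationState, stable=None) -> int:
    """Form lateral transport links for unlinked chromosomes; returns count.

    Candidates are MTs passing within ``r_k`` of the chromosome centre.
    Dynein rides the nearest candidate regardless of age; CENP-E only rides
    long-lived, centre-pointing rails: scaffold MTs, or dynamic MTs older
    than ``tau_mt`` whose ray passes through the interpolar region (the
    detyrosinated subpopulation).  Lateral
    transport coexists with *unstable* end-on attachments (their slip bonds
    cannot hold against a motor group anyway); only stably bi-oriented
    chromosomes stop riding.  Ties on distance resolve to the smallest MT
    index (argmin convention).
    """
    p = state.params
    if state.n_mt == 0:
        return 0
    if stable is None:
        stable = classify_stability(state) == ST_STABLE
    need = np.flatnonzero((state.ch_lateral < 0) & ~stable)
    if need.size == 0:
        return 0
    starts = state.mt_starts()
    cenpe_ok = state.mt_scaffold.copy()
    if p.cenpe_rails == "aged_interpolar":
        cenpe_ok |= (state.mt_age() > p.tau_mt) & state.mt_interpolar
    cenpe_idx = np.flatnonzero(cenpe_ok)
    formed = 0
    for ci in need:
        if state.ch_motor[ci] == CENPE:
            cand = cenpe_idx
        else:
            cand = slice(None)
        dist = segment_point_distance(starts[cand], state.mt_dir[cand],
                                      state.mt_len[cand], state.ch_pos[ci])
        if dist.size == 0 or dist.min() > p.r_k:
            continue
        k = int(np.argmin(dist))
        mt = int(cenpe_idx[k]) if state.ch_motor[ci] == CENPE else k
        state.ch_lateral[ci] = mt
        formed += 1
        state.events.add(state.t, "lateral_attach", chrom=int(ci), mt=mt)
    return formed


def drop_stale_lateral(state: SimulationState) -> None:
    """Clear lateral links whose rail no longer passes the proximity test."""
    linked = np.flatnonzero(state.ch_lateral >= 0)
    if linked.size == 0:
        return
    mts = state.ch_lateral[linked]
    starts = state.pole_positions[state.mt_pole[mts]]
    d = segment_point_distance(starts, state.mt_dir[mts], state.mt_len[mts],
                               state.ch_pos[linked])
    stale = d > state.params.r_k
    if np.any(stale):
        for ci in linked[stale]:
            state.events.add(state.t, "lateral_detach", chrom=int(ci))
        state.ch_lateral[linked[stale]] = -1


# ---------------------------------------------------------------------------
# the parallel stochastic-event pass
# ---------------------------------------------------------------------------

def process_stochastic_events(state: SimulationState, dt: float,
                              search_attachments: bool = True) -> dict:
    """One parallel pass of all stochastic events, then attachment formation.

    All detachments, catastrophes, rescues and nucleations are sampled
    against the start-of-step state, then applied together; finally stale
    lateral links are dropped and new end-on / lateral attachments form.
    Returns the tip forces and stability masks computed at the start of the
    step, for reuse by the growth phase.
    """
    from . import mt_dynamics  # local import to avoid a cycle

    p = state.params
    tip_force = end_on_tip_forces(state)
    stability = classify_stability(state)

    # --- sample detachments (per attached MT, shared stability class)
    att = np.flatnonzero(state.mt_attach_ch >= 0)
    if att.size:
        st_att = stability[state.mt_attach_ch[att]]
        prob = detachment_probability(tip_force[att], st_att, p, dt)
        u = state.rngs["detachment"].random(att.size)
        fired = u < prob
        detach = att[fired]
        detach_stable = att[fired & (st_att == ST_STABLE)]
    else:
        detach = np.empty(0, dtype=np.int64)
        detach_stable = detach

    # --- sample instability switches
    cat, res = mt_dynamics.sample_switches(state, tip_force, dt)

    # --- apply
    state.mt_growing[cat] = False
    state.mt_growing[res] = True
    if detach.size:
        state.mt_attach_ch[detach] = -1
        state.events.add(state.t, "detach", count=int(detach.size))
    if detach_stable.size:
        # release of a *stabilised* attachment is an error-correction event:
        # it is depolymerisation-coupled (the freed tip catastrophes and
        # shrinks away; scaffold MTs stay static) with a short refractory
        # dead time, so a mislocated amphitelic lock genuinely dissolves
        # instead of rebinding the kinetochore it still touches.  Unstable
        # slip-bond releases keep their fast rebinding equilibrium.
        dyn_det = detach_stable[~state.mt_scaffold[detach_stable]]
        state.mt_growing[dyn_det] = False
        state.mt_refract_until[detach_stable] = state.t + p.attach_refractory
    state.events.add(state.t, "catastrophe", count=int(cat.sum()))
    state.events.add(state.t, "rescue", count=int(res.sum()))

    if not p.fixed_n_mode:
        mt_dynamics.nucleate(state, dt)
        # arrays may have grown; pad the cached start-of-step quantities
        grown = state.n_mt - tip_force.size
        if grown > 0:
            tip_force = np.concatenate([tip_force, np.zeros(grown)])

    # --- attachment formation on the post-event state; the geometric
    # searches may be run at a coarser cadence than the stochastic events
    drop_stale_lateral(state)
    tips_now = state.mt_tips()
    if search_attachments:
        form_end_on(state, tips=tips_now)
    stable_now = classify_stability(state) == ST_STABLE
    if search_attachments:
        form_lateral(state, stable=stable_now)

    # stably bi-oriented chromosomes are held by their k-fibres, not motors
    drop = (state.ch_lateral >= 0) & stable_now
    if np.any(drop):
        state.ch_lateral[drop] = -1

    # post-event tip forces and stability, reused by the growth phase
    stable_mask = np.zeros(state.n_mt, dtype=bool)
    post_force = np.zeros(state.n_mt)
    attached = state.mt_attach_ch >= 0
    if np.any(attached):
        stable_mask[attached] = stable_now[state.mt_attach_ch[attached]]
        stretch = np.linalg.norm(
            tips_now[attached] - state.ch_pos[state.mt_attach_ch[attached]],
            axis=1)
        post_force[attached] = p.k_k * stretch
    return {"tip_force": post_force, "stable_mask": stable_mask,
            "stability": stability}
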