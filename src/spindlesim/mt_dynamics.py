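"""Microtubule dynamic instability, nucleation and population kinetics.

Each non-scaffold MT switches stochastically between persistent growth and
shrinkage.  Both switching rates depend on the tension ``F`` transmitted
through an end-on kinetochore coupling (``F = 0`` for unattached MTs):

* catastrophe: ``p_cat = p_cat0 * exp(-F / F_cat)`` -- tension stabilises growth;
* rescue:      ``p_res = p_res0 * exp(+F / F_res)``.

Rates are converted to per-step probabilities as ``1 - exp(-rate * dt)``,
exact for an exponential waiting time within a step, so the scheme stays
correct for the large catastrophe rates explored in depolymerase-
overexpression sweeps.

In fixed-N mode a MT that shrinks back to the pole is immediately renucleated
in a fresh uniform direction so the population size is conserved; in
nucleation mode it is removed and new MTs appear from each pole as a Poisson
process of rate ``k_nucl``.  The deterministic mean of the nucleation-mode
population count follows the birth--death relaxation
``N(t) = (k_nucl / k_out) * (1 - exp(-k_out * t))``
with ``k_out`` the collapse rate per MT (inverse mean lifetime).
"""

from __future__ import annotations

import numpy as np

from .geometry import max_ray_length, uniform_directions
from .params import ParameterSet
from .state import SimulationState


def catastrophe_rate(force, p: ParameterSet):
    """Growth -> shrinkage switching rate (1/s), monotone decreasing in force."""
    return p.p_cat0 * np.exp(-np.asarray(force, dtype=float) / p.f_cat)


def rescue_rate(force, p: ParameterSet):
    """Shrinkage -> growth switching rate (1/s), monotone increasing in force."""
    return p.p_res0 * np.exp(np.asarray(force, dtype=float) / p.f_res)


def loaded_velocity(v0, force, f_sens):
    """Tip velocity (um/min) slowed exponentially by the tip load."""
    return v0 * np.exp(-np.asarray(force, dtype=float) / f_sens)


def event_probability(rate, dt: float):
    """Per-step probability of a rate process firing: 1 - exp(-rate*dt)."""
    return -np.expm1(-np.asarray(rate, dtype=float) * dt)


# ---------------------------------------------------------------------------
# closed-form population kinetics
# ---------------------------------------------------------------------------

def mean_mt_lifetime(p: ParameterSet) -> float:
    """Mean unloaded MT lifetime (s) from nucleation to collapse.

    For dynamic instability with growth speed v_g, shrinkage speed v_s,
    catastrophe rate k_c and rescue rate k_r (all unloaded, no boundary), the
    mean first-passage time back to zero length of an excursion that starts
    growing at zero length is ``(v_g + v_s) / (v_s k_c - v_g k_r)``, finite
    only in the bounded-growth regime ``v_s k_c > v_g k_r``.
    """
    drift = p.v_s_um_s * p.p_cat0 - p.v_g_um_s * p.p_res0
    if drift <= 0:
        raise ValueError("unbounded-growth regime: v_s*p_cat0 <= v_g*p_res0")
    return (p.v_g_um_s + p.v_s_um_s) / drift


def collapse_rate(p: ParameterSet) -> float:
    """Per-MT collapse rate k_out = 1 / mean lifetime (1/s)."""
    return 1.0 / mean_mt_lifetime(p)


def catastrophe_rate_for_collapse_rate(k_out: float, p: ParameterSet) -> float:
    """Invert the closed-form lifetime: p_cat0 giving the requested k_out.

    Used to reconstruct the catastrophe rate behind a measured per-MT
    turnover when only the population collapse rate is known.
    """
    if k_out <= 0:
        raise ValueError("k_out must be strictly positive")
    return (k_out * (p.v_g_um_s + p.v_s_um_s) + p.v_g_um_s * p.p_res0) / p.v_s_um_s


def expected_mt_count(k_nucl: float, k_out: float, t) -> np.ndarray:
    """Mean population size of the birth--death process at time t.

    ``k_nucl`` is the total nucleation rate feeding the counted population
    (per pole if a single pole is counted, twice that for the whole spindle).
    """
    if k_out <= 0:
        raise ValueError("k_out must be strictly positive")
    return k_nucl / k_out * -np.expm1(-k_out * np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def nucleate(state: SimulationState, dt: float) -> np.ndarray:
    """Add Poisson(k_nucl * dt) new zero-length growing MTs per pole."""
    p = state.params
    if p.k_nucl is None:
        raise RuntimeError("nucleate() requires nucleation mode (k_nucl set)")
    rng = state.rngs["nucleation"]
    counts = rng.poisson(p.k_nucl * dt, size=2)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    poles = np.repeat([0, 1], counts)
    dirs = uniform_directions(rng, total)
    idx = state.add_mts(poles, dirs)
    state.events.add(state.t, "nucleation", count=total)
    return idx


def sample_switches(state: SimulationState, tip_force: np.ndarray, dt: float):
    """Sample catastrophes and rescues for all dynamic MTs in parallel.

    Uses the start-of-step phases and forces; returns boolean masks
    ``(catastrophes, rescues)`` over the MT arrays.
    """
    p = state.params
    dynamic = ~state.mt_scaffold
    u = state.rngs["instability"].random(state.n_mt)
    loaded = tip_force > 0.0
    if loaded.any():
        p_cat = event_probability(catastrophe_rate(tip_force, p), dt)
        p_res = event_probability(rescue_rate(tip_force, p), dt)
    else:  # unloaded rates are uniform across the population
        p_cat = event_probability(p.p_cat0, dt)
        p_res = event_probability(p.p_res0, dt)
    cat = dynamic & state.mt_growing & (u < p_cat)
    res = dynamic & ~state.mt_growing & ~state.mt_no_rescue & (u < p_res)
    return cat, res


def advance_lengths(state: SimulationState, tip_force: np.ndarray,
                    stable_mask: np.ndarray, dt: float) -> np.ndarray:
    """Grow/shrink all MTs by one step; returns the collapse mask.

    Velocities are the unloaded values except for MTs held in *stable*
    end-on attachments, whose tip velocity is slowed exponentially by the
    spring tension.  A dynamic MT that grows into the cortex is clamped and
    undergoes an immediate contact-induced catastrophe: the envelope repels
    MTs, and this is also what makes the long-lived (CENP-E-eligible)
    subpopulation point across the cell rather than at the nearby cortex.
    """
    p = state.params
    v = np.where(state.mt_growing, p.v_g_um_s, -p.v_s_um_s)
    if stable_mask.any():
        sel = stable_mask
        slow = np.where(state.mt_growing[sel],
                        np.exp(-tip_force[sel] / p.f_g),
                        np.exp(-tip_force[sel] / p.f_s))
        v[sel] *= slow
    if state.mt_scaffold.any():
        v[state.mt_scaffold] = 0.0
    state.mt_len = state.mt_len + v * dt
    hit = (state.mt_len >= state.mt_maxlen) & ~state.mt_scaffold
    if np.any(hit):
        state.mt_len[hit] = state.mt_maxlen[hit]
        state.mt_growing[hit] = False
        if p.boundary_processive:
            # contact-induced catastrophes depolymerise processively: no
            # rescue until the MT has shrunk back to the pole
            state.mt_no_rescue[hit] = True
        state.events.add(state.t, "boundary_catastrophe", count=int(hit.sum()))
    collapsed = (state.mt_len <= 0.0) & ~state.mt_growing & ~state.mt_scaffold
    return collapsed


def handle_collapses(state: SimulationState, collapsed: np.ndarray) -> None:
    """Bookkeeping for MTs that shrank back to the pole.

    Records lifetimes, clears any attachment or lateral link carried by the
    collapsing MT, then either renucleates in place (fixed-N mode: same pole,
    new uniform direction, zero length, growing) or removes the MT
    (nucleation mode).
    """
    if not np.any(collapsed):
        return
    n = int(collapsed.sum())
    state.n_collapsed += n
    state.sum_lifetimes += float((state.t + state.params.dt
                                  - state.mt_birth[collapsed]).sum())
    state.events.add(state.t, "collapse", count=n)

    # detach and unlink
    state.mt_attach_ch[collapsed] = -1
    lat = state.ch_lateral
    linked = lat >= 0
    if np.any(linked):
        drop = collapsed[lat[linked]]
        if np.any(drop):
            idx = np.flatnonzero(linked)[drop]
            lat[idx] = -1

    if state.params.fixed_n_mode:
        rng = state.rngs["nucleation"]
        dirs = uniform_directions(rng, n)
        state.mt_dir[collapsed] = dirs
        state.mt_len[collapsed] = 0.0
        state.mt_growing[collapsed] = True
        state.mt_no_rescue[collapsed] = False
        state.mt_birth[collapsed] = state.t + state.params.dt
        state.mt_maxlen[collapsed] = max_ray_length(
            state.pole_positions[state.mt_pole[collapsed]], dirs, state.geometry)
        state.mt_interpolar[collapsed] = state._is_interpolar(
            state.mt_pole[collapsed], dirs)
        state.events.add(state.t, "renucleation", count=n)
    else:
        state.remove_mts(collapsed)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _scaffold_directions(state: SimulationState, pole: int, n: int) -> np.ndarray:
    """Directions for interpolar scaffold rails.

    Rejection-samples uniform directions until the ray (i) passes within the
    interpolar region (0.45a of the cell centre) and (ii) crosses the spindle
    midplane before leaving the cortex, so every scaffold rail can terminate
    past the midzone.
    """
    rng = state.rngs["init"]
    g = state.geometry
    origin = g.poles[pole]
    out = np.empty((0, 3))
    while out.shape[0] < n:
        cand = uniform_directions(rng, max(4 * n, 64))
        # perpendicular distance from the cell centre to each ray
        to_center = -origin
        t = cand @ to_center
        closest = origin[None, :] + t[:, None] * cand
        ok = (t > 0) & (np.linalg.norm(closest, axis=1) <= g.r_cenpe_shell)
        if np.any(ok):
            sel = cand[ok]
            t_mid = -origin[0] / sel[:, 0]
            maxlen = max_ray_length(
                np.broadcast_to(origin, (sel.shape[0], 3)), sel, g)
            sel = sel[t_mid < maxlen]
            out = np.concatenate([out, sel])
    return out[:n]


def init_scaffold(state: SimulationState) -> np.ndarray:
    """Create the stable interpolar scaffold (fixed-N mode).

    ``round(p_sc * n_mt)`` MTs, split evenly between the poles, are marked as
    scaffold: never switching phase and infinitely old, so they are always
    eligible as CENP-E transport rails.  Their directions aim through the
    interpolar region (rays passing within 0.45a of the cell centre) and, as
    for interpolar MTs of a real spindle, they terminate just past the
    midzone: each scaffold MT extends to the spindle midplane (x = 0) plus an
    antiparallel-overlap length drawn uniformly from
    ``[0, 2 * scaffold_overlap]``.  The overlapping plus ends of scaffold MTs
    from the two poles thus interdigitate around the future metaphase plate,
    which is what lets CENP-E deliver chromosomes there and what seeds
    bi-orientation.
    """
    p = state.params
    if not p.fixed_n_mode:
        raise RuntimeError("scaffold requires fixed-N mode")
    n_sc = int(round(p.p_sc * p.n_mt))
    if n_sc == 0:
        return np.empty(0, dtype=np.int64)
    per_pole = [n_sc // 2 + (n_sc % 2), n_sc // 2]
    rng = state.rngs["init"]
    idx_all = []
    for pole, k in enumerate(per_pole):
        if k == 0:
            continue
        dirs = _scaffold_directions(state, pole, k)
        start = state.pole_positions[np.full(k, pole)]
        t_mid = -start[:, 0] / dirs[:, 0]   # ray parameter at the midplane
        overlap = rng.uniform(0.0, 2.0 * p.scaffold_overlap, k)
        maxlen = max_ray_length(start, dirs, state.geometry)
        length = np.minimum(t_mid + overlap, maxlen)
        idx = state.add_mts(np.full(k, pole), dirs, length=length, growing=True,
                            scaffold=True, birth_time=-np.inf)
        idx_all.append(idx)
    return np.concatenate(idx_all) if idx_all else np.empty(0, dtype=np.int64)


def init_dynamic_mts(state: SimulationState) -> np.ndarray:
    """Create the dynamic (non-scaffold) MTs of a fixed-N spindle at length 0."""
    p = state.params
    n_sc = int(round(p.p_sc * p.n_mt))
    n_dyn = p.n_mt - n_sc
    if n_dyn <= 0:
        return np.empty(0, dtype=np.int64)
    rng = state.rngs["init"]
    poles = np.arange(n_dyn, dtype=np.int8) % 2
    dirs = uniform_directions(rng, n_dyn)
    return state.add_mts(poles, dirs)


def warmup_mts(state: SimulationState, duration: float | None = None) -> None:
    """Pre-equilibrate the MT population with no chromosome interactions.

    The congression run assumes an already-formed spindle; evolving the
    dynamic MTs alone for a few mean lifetimes before t = 0 produces
    steady-state lengths and realistic ages (so the CENP-E age filter has
    eligible rails at t = 0).  Birth times end up negative; the clock is
    reset to zero afterwards.
    """
    p = state.params
    dur = p.warmup if duration is None else duration
    if dur <= 0:
        return
    nsteps = int(round(dur / p.dt))
    zeros = np.zeros(state.n_mt)
    no_stable = np.zeros(state.n_mt, dtype=bool)
    for _ in range(nsteps):
        cat, res = sample_switches(state, zeros, p.dt)
        state.mt_growing[cat] = False
        state.mt_growing[res] = True
        collapsed = advance_lengths(state, zeros, no_stable, p.dt)
        handle_collapses(state, collapsed)
        state.t += p.dt
    # shift the clock so the run starts at t = 0 with realistic ages
    state.mt_birth -= state.t
    state.t = 0.0
    state.n_collapsed = 0
    state.sum_lifetimes = 0.0
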