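"""Scenario presets, the time-stepping main loop and ensemble orchestration.

Each step executes three phases in a fixed order, all stochastic events
sampled in parallel against the start-of-step state:

1. stochastic events (detachments, catastrophes, rescues, nucleations),
   followed by attachment bookkeeping and formation;
2. MT growth/shrinkage with cortex clamping and collapse handling;
3. chromosome force assembly, the overdamped position update, confinement
   and the motor-program update.

A run is bit-reproducible from its configuration and seed: all randomness
flows from per-subsystem streams spawned from the single run seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from . import attachments, mechanics, mt_dynamics
from .geometry import CellGeometry, sample_initial_chromosomes
from .observables import (RunSummary, first_passage, probability_curve,
                          median_time)
from .params import ParameterSet
from .state import SimulationState

#: scenario name -> parameter overrides (knockouts only zero the relevant force)
SCENARIOS: Dict[str, dict] = {
    "wt_scattered": {},
    "wt_interpolar": {},
    "ko_dynein": {"f_dyn": 0.0},
    "ko_cenpe": {"f_cenpe": 0.0},
    "ko_pef": {"f_pef": 0.0},
    "mt_density_sweep": {},
    "catastrophe_sweep": {},
    "nucleation_mode": {"k_nucl": 30.0, "n_c": 0, "p_sc": 0.0, "warmup": 0.0,
                        "p_cat0": None},  # p_cat0 filled in below
}

#: initial chromosome placement radius per scenario (None = nuclear 0.65a ball)
_INIT_RADIUS: Dict[str, Optional[str]] = {"wt_interpolar": "interpolar"}


def scenario_parameters(name: str, base: ParameterSet | None = None) -> ParameterSet:
    """Parameter set for a named scenario, starting from Table defaults.

    The nucleation-mode scenario reconstructs its catastrophe rate from the
    target per-MT collapse rate of 0.09/s via the closed-form lifetime (the
    corresponding p_cat0, about 0.206/s, lies inside the plausible 0.058-0.58
    range).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    p = base if base is not None else ParameterSet()
    overrides = dict(SCENARIOS[name])
    if name == "nucleation_mode":
        overrides["p_cat0"] = mt_dynamics.catastrophe_rate_for_collapse_rate(0.09, p)
    return p.replace(**overrides)


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    params: ParameterSet = field(default_factory=ParameterSet)
    scenario: str = "wt_scattered"
    seed: int = 0
    congression_deadline: float = 1.0e3   #: s
    biorientation_deadline: float = 1.0e5  #: s
    snapshot_every: float = 1.0           #: s, cadence of the MT-count series
    record_events: bool = False
    record_trajectory: bool = False
    trajectory_every: float = 10.0        #: s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["params"] = ParameterSet.from_dict(d["params"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class Simulation:
    """One simulated cell; owns the state and the main loop."""

    def __init__(self, config: RunConfig):
        self.config = config
        p = scenario_parameters(config.scenario, config.params)
        p.validate()
        self.params = p
        self.state = SimulationState(p, record_events=config.record_events)
        self.state.seed(config.seed)
        self.trajectory: List[dict] = []
        self._step_count = 0
        self._pef_cache: Optional[np.ndarray] = None
        self._init_state()

    # ------------------------------------------------------------------
    def _init_state(self) -> None:
        st = self.state
        p = self.params
        if p.fixed_n_mode:
            mt_dynamics.init_scaffold(st)
            mt_dynamics.init_dynamic_mts(st)
            mt_dynamics.warmup_mts(st)
        if p.n_c > 0:
            radius = (st.geometry.r_cenpe_shell
                      if _INIT_RADIUS.get(self.config.scenario) == "interpolar"
                      else None)
            st.ch_pos[:] = sample_initial_chromosomes(
                p.n_c, st.geometry, st.rngs["init"], radius=radius)
            attachments.init_motor_program(st)

    # ------------------------------------------------------------------
    # the three phases, split out so instrumentation can observe ordering
    def _phase_events(self) -> dict:
        search = self._step_count % self.params.interaction_every == 0
        return attachments.process_stochastic_events(
            self.state, self.params.dt, search_attachments=search)

    def _phase_mts(self, tip_force=None, stable_mask=None) -> None:
        st = self.state
        if tip_force is None:
            tip_force = attachments.end_on_tip_forces(st)
        if stable_mask is None:
            from .attachments import classify_stability
            from .state import ST_STABLE
            stable_mask = np.zeros(st.n_mt, dtype=bool)
            att = st.mt_attach_ch >= 0
            if np.any(att):
                stable_mask[att] = (classify_stability(st)[st.mt_attach_ch[att]]
                                    == ST_STABLE)
        collapsed = mt_dynamics.advance_lengths(st, tip_force, stable_mask,
                                                self.params.dt)
        mt_dynamics.handle_collapses(st, collapsed)

    def _phase_chromosomes(self) -> None:
        st = self.state
        if st.n_c == 0:
            return
        # PEF crossings are refreshed at the interaction cadence and held
        # constant in between (they decorrelate on the MT turnover timescale)
        if (self._pef_cache is None
                or self._step_count % self.params.interaction_every == 0):
            self._pef_cache = mechanics.polar_ejection_force(st)
        forces = mechanics.ForceBreakdown(
            f_pef=self._pef_cache,
            f_lateral=mechanics.lateral_motor_force(st),
            f_spring=attachments.end_on_spring_forces(st))
        mechanics.advance_chromosomes(st, forces, self.params.dt)
        attachments.update_motor_program(st)

    def step(self) -> None:
        info = self._phase_events()
        self._phase_mts(tip_force=info["tip_force"],
                        stable_mask=info["stable_mask"])
        self._phase_chromosomes()
        self._step_count += 1
        self.state.t += self.params.dt

    # ------------------------------------------------------------------
    def run(self, progress: Optional[Callable[[float], None]] = None) -> RunSummary:
        """Run until both events resolve or both deadlines pass."""
        cfg = self.config
        st = self.state
        p = self.params
        deadline = max(cfg.congression_deadline, cfg.biorientation_deadline)
        snap_steps = max(1, int(round(cfg.snapshot_every / p.dt)))
        traj_steps = max(1, int(round(cfg.trajectory_every / p.dt)))

        from .observables import biorientation_state, congression_state

        t_cong = math.nan
        t_bio = math.nan
        nmt_t: List[float] = [0.0]
        nmt_n: List[int] = [st.n_mt]
        self._record_trajectory()
        n_steps = 0
        track_ch = st.n_c > 0
        while True:
            cong_open = track_ch and math.isnan(t_cong) and st.t < cfg.congression_deadline
            bio_open = track_ch and math.isnan(t_bio) and st.t < cfg.biorientation_deadline
            if st.t >= deadline or (track_ch and not cong_open and not bio_open):
                break
            if not track_ch and st.t >= deadline:
                break
            self.step()
            n_steps += 1
            if cong_open and congression_state(st):
                t_cong = st.t
                st.events.add(st.t, "congression")
            if bio_open and biorientation_state(st):
                t_bio = st.t
                st.events.add(st.t, "biorientation")
            if n_steps % snap_steps == 0:
                nmt_t.append(st.t)
                nmt_n.append(st.n_mt)
            if cfg.record_trajectory and n_steps % traj_steps == 0:
                self._record_trajectory()
            if progress is not None:
                progress(st.t)

        congressed = not math.isnan(t_cong) and t_cong <= cfg.congression_deadline
        bioriented = not math.isnan(t_bio) and t_bio <= cfg.biorientation_deadline
        return RunSummary(
            seed=cfg.seed, scenario=cfg.scenario,
            congression_time=t_cong, congressed=congressed,
            biorientation_time=t_bio, bioriented=bioriented,
            congression_deadline=cfg.congression_deadline,
            biorientation_deadline=cfg.biorientation_deadline,
            nmt_times=np.asarray(nmt_t), nmt_counts=np.asarray(nmt_n),
            final_chromosomes=self._chromosome_frame(),
            n_steps=n_steps, n_collapsed=st.n_collapsed,
            sum_lifetimes=st.sum_lifetimes,
        )

    # ------------------------------------------------------------------
    def _record_trajectory(self) -> None:
        if not self.config.record_trajectory:
            return
        st = self.state
        occ = st.slot_occupancy()
        for i in range(st.n_c):
            self.trajectory.append({
                "t": st.t, "chromosome": i,
                "x": st.ch_pos[i, 0], "y": st.ch_pos[i, 1], "z": st.ch_pos[i, 2],
                "motor": int(st.ch_motor[i]),
                "n_end_on_left": int(occ[i, 0]), "n_end_on_right": int(occ[i, 1]),
            })

    def _chromosome_frame(self):
        import pandas as pd
        st = self.state
        occ = st.slot_occupancy()
        from .attachments import classify_stability
        stab = classify_stability(st)
        d_pole = np.linalg.norm(
            st.ch_pos[:, None, :] - st.pole_positions[None, :, :], axis=2
        ).min(axis=1) if st.n_c else np.empty(0)
        return pd.DataFrame({
            "x": st.ch_pos[:, 0], "y": st.ch_pos[:, 1], "z": st.ch_pos[:, 2],
            "motor": st.ch_motor, "stability": stab,
            "n_end_on_left": occ[:, 0], "n_end_on_right": occ[:, 1],
            "dist_to_pole": d_pole,
        })


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def run_single(config: RunConfig) -> RunSummary:
    """Execute one run from a config."""
    return Simulation(config).run()


def run_ensemble(config: RunConfig, n: int, base_seed: int | None = None
                 ) -> List[RunSummary]:
    """n independent runs with seeds base_seed + i (order-independent)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seed0 = config.seed if base_seed is None else base_seed
    out = []
    for i in range(n):
        cfg = dataclasses.replace(config, seed=seed0 + i)
        out.append(run_single(cfg))
    return out


def sweep(config: RunConfig, parameter: str, values: Sequence, n: int,
          base_seed: int | None = None):
    """Ensemble grid over one parameter; returns a tidy DataFrame.

    One row per value with congression / bi-orientation probabilities and
    median event times (NaN when the plateau stays below 1/2).
    """
    import pandas as pd
    rows = []
    seed0 = config.seed if base_seed is None else base_seed
    for j, v in enumerate(values):
        params = config.params.replace(**{parameter: v})
        cfg = dataclasses.replace(config, params=params)
        summaries = run_ensemble(cfg, n, base_seed=seed0 + 10_000 * j)
        pc = probability_curve(summaries, "congression")
        pb = probability_curve(summaries, "biorientation")
        rows.append({
            parameter: v, "n_runs": n,
            "p_congression": float(pc.probability[-1]) if pc.times.size else 0.0,
            "p_biorientation": float(pb.probability[-1]) if pb.times.size else 0.0,
            "t_half_congression": median_time(pc),
            "t_half_biorientation": median_time(pb),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nucleation-mode population ensemble (no chromosomes)
# ---------------------------------------------------------------------------

def mt_population_ensemble(k_nucl: float, t_end: float, n_runs: int,
                           base_seed: int = 0,
                           params: ParameterSet | None = None,
                           sample_every: float = 0.5):
    """Ensemble of chromosome-free nucleation-mode runs.

    Returns ``(times, counts, lifetime_stats)`` where ``counts`` has shape
    ``(n_runs, n_times)`` (total MT number, both poles) and
    ``lifetime_stats = (n_collapsed, total_lifetime)`` aggregates completed
    birth-to-collapse lifetimes over the ensemble.
    """
    base = params if params is not None else scenario_parameters("nucleation_mode")
    p = base.replace(k_nucl=k_nucl, n_c=0, p_sc=0.0, warmup=0.0)
    p.validate()
    every = max(1, int(round(sample_every / p.dt)))
    nsteps = int(round(t_end / p.dt))
    times = np.arange(0, nsteps + 1, every) * p.dt
    counts = np.zeros((n_runs, times.size), dtype=np.int64)
    n_coll, sum_life = 0, 0.0
    no_force = np.zeros(0)
    for r in range(n_runs):
        st = SimulationState(p).seed(base_seed + r)
        j = 0
        counts[r, 0] = 0
        for s in range(1, nsteps + 1):
            # chromosome-free stepping: births and switches, then growth
            mt_dynamics.nucleate(st, p.dt)
            zeros = np.zeros(st.n_mt)
            cat, res = mt_dynamics.sample_switches(st, zeros, p.dt)
            st.mt_growing[cat] = False
            st.mt_growing[res] = True
            collapsed = mt_dynamics.advance_lengths(
                st, zeros, np.zeros(st.n_mt, dtype=bool), p.dt)
            mt_dynamics.handle_collapses(st, collapsed)
            st.t += p.dt
            if s % every == 0:
                j += 1
                counts[r, j] = st.n_mt
        n_coll += st.n_collapsed
        sum_life += st.sum_lifetimes
    return times, counts, (n_coll, sum_life)
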