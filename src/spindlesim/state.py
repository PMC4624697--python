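"""Simulation state: record types and the vectorised array container.

Two representations coexist.  ``Microtubule``/``Chromosome``/``Kinetochore``
are plain dataclass records, convenient for building tiny deterministic test
states and for inspecting single agents.  The simulation itself operates on
``SimulationState``, a structure-of-arrays container in which all MTs (and
all chromosomes) live in flat numpy arrays so the per-step work vectorises.
``SimulationState.from_records`` / ``mt_record`` convert between the two.

Motor codes: 0 = dynein (poleward transport, end-on attachments inhibited),
1 = CENP-E (plate-ward transport on long-lived MTs, end-on permitted).
Stability codes: 0 = no end-on attachment, 1 = unstable, 2 = stable
(amphitelic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .geometry import CellGeometry, max_ray_length, uniform_directions
from .params import ParameterSet

DYNEIN, CENPE = 0, 1
ST_NONE, ST_UNSTABLE, ST_STABLE = 0, 1, 2
SIDE_LEFT, SIDE_RIGHT = 0, 1  # kinetochore hemisphere facing pole 0 / pole 1


@dataclass
class Microtubule:
    """A single MT: a straight ray from one pole."""

    pole: int
    direction: np.ndarray
    length: float = 0.0
    growing: bool = True
    scaffold: bool = False
    birth_time: float = 0.0
    #: chromosome index of the end-on attached kinetochore, or None
    end_on_chrom: Optional[int] = None
    end_on_side: Optional[int] = None


@dataclass
class Kinetochore:
    side: int
    capacity: int
    attached: set = field(default_factory=set)


@dataclass
class Chromosome:
    position: np.ndarray
    motor: int = DYNEIN
    lateral_mt: Optional[int] = None


class EventLog:
    """Append-only event record; disabled by default for large ensembles."""

    def __init__(self, enabled: bool = False):
        self.enabled = enabled
        self.records: List[tuple] = []

    def add(self, t: float, kind: str, **info):
        if self.enabled:
            self.records.append((round(t, 9), kind, tuple(sorted(info.items()))))

    def __len__(self):
        return len(self.records)


class SimulationState:
    """Vectorised container for the full spindle state at one instant.

    MT arrays (all length ``n_mt_alive``): ``mt_pole`` (int8), ``mt_dir``
    (n,3), ``mt_len``, ``mt_growing`` (bool), ``mt_scaffold`` (bool),
    ``mt_birth``, ``mt_maxlen`` (cached cortex clamp), ``mt_attach_ch``
    (int32, -1 = free) and ``mt_attach_side`` (int8).

    Chromosome arrays (length ``n_c``): ``ch_pos`` (n,3), ``ch_motor``
    (int8), ``ch_lateral`` (int32, -1 = none).
    """

    def __init__(self, params: ParameterSet, geometry: CellGeometry | None = None,
                 record_events: bool = False):
        self.params = params
        self.geometry = geometry if geometry is not None else CellGeometry(a=params.a)
        self.t = 0.0
        self.events = EventLog(record_events)

        n = 0
        self.mt_pole = np.zeros(n, dtype=np.int8)
        self.mt_dir = np.zeros((n, 3))
        self.mt_len = np.zeros(n)
        self.mt_growing = np.zeros(n, dtype=bool)
        self.mt_scaffold = np.zeros(n, dtype=bool)
        self.mt_birth = np.zeros(n)
        self.mt_maxlen = np.zeros(n)
        self.mt_attach_ch = np.zeros(n, dtype=np.int32)
        self.mt_attach_side = np.zeros(n, dtype=np.int8)
        self.mt_no_rescue = np.zeros(n, dtype=bool)
        self.mt_interpolar = np.zeros(n, dtype=bool)
        self.mt_refract_until = np.zeros(n)

        nc = params.n_c
        self.ch_pos = np.zeros((nc, 3))
        self.ch_motor = np.full(nc, DYNEIN, dtype=np.int8)
        self.ch_lateral = np.full(nc, -1, dtype=np.int32)

        # cumulative collapse statistics (for lifetime-based k_out estimates)
        self.n_collapsed = 0
        self.sum_lifetimes = 0.0

        self.rngs: dict[str, np.random.Generator] = {}

    # ------------------------------------------------------------------
    def seed(self, seed: int) -> "SimulationState":
        """Create the per-subsystem random streams from one seed.

        Separate streams for initial placement, nucleation (incl. MT
        directions), dynamic instability and detachment keep the chromosome-
        facing randomness insensitive to how many MT draws occur.
        """
        ss = np.random.SeedSequence(seed)
        keys = ("init", "nucleation", "instability", "detachment")
        for key, child in zip(keys, ss.spawn(len(keys))):
            self.rngs[key] = np.random.default_rng(child)
        return self

    @property
    def n_mt(self) -> int:
        return self.mt_len.size

    @property
    def n_c(self) -> int:
        return self.ch_pos.shape[0]

    @property
    def pole_positions(self) -> np.ndarray:
        return self.geometry.poles

    def mt_starts(self) -> np.ndarray:
        return self.pole_positions[self.mt_pole]

    def mt_tips(self) -> np.ndarray:
        return self.mt_starts() + self.mt_len[:, None] * self.mt_dir

    def mt_age(self) -> np.ndarray:
        return self.t - self.mt_birth

    # ------------------------------------------------------------------
    def add_mts(self, pole, direction, length=0.0, growing=True, scaffold=False,
                birth_time=None) -> np.ndarray:
        """Append MTs; returns their indices.  Computes the cortex clamp."""
        pole = np.atleast_1d(np.asarray(pole, dtype=np.int8))
        direction = np.atleast_2d(np.asarray(direction, dtype=float))
        k = pole.size
        length = np.broadcast_to(np.asarray(length, dtype=float), (k,))
        growing = np.broadcast_to(np.asarray(growing, dtype=bool), (k,))
        scaffold = np.broadcast_to(np.asarray(scaffold, dtype=bool), (k,))
        bt = self.t if birth_time is None else birth_time
        birth = np.broadcast_to(np.asarray(bt, dtype=float), (k,))
        maxlen = max_ray_length(self.pole_positions[pole], direction, self.geometry)
        interpolar = self._is_interpolar(pole, direction)

        idx = np.arange(self.n_mt, self.n_mt + k)
        self.mt_pole = np.concatenate([self.mt_pole, pole])
        self.mt_dir = np.concatenate([self.mt_dir, direction])
        self.mt_len = np.concatenate([self.mt_len, np.minimum(length, maxlen)])
        self.mt_growing = np.concatenate([self.mt_growing, growing])
        self.mt_scaffold = np.concatenate([self.mt_scaffold, scaffold])
        self.mt_birth = np.concatenate([self.mt_birth, birth])
        self.mt_maxlen = np.concatenate([self.mt_maxlen, maxlen])
        self.mt_attach_ch = np.concatenate(
            [self.mt_attach_ch, np.full(k, -1, dtype=np.int32)])
        self.mt_attach_side = np.concatenate(
            [self.mt_attach_side, np.zeros(k, dtype=np.int8)])
        self.mt_no_rescue = np.concatenate(
            [self.mt_no_rescue, np.zeros(k, dtype=bool)])
        self.mt_interpolar = np.concatenate([self.mt_interpolar, interpolar])
        self.mt_refract_until = np.concatenate(
            [self.mt_refract_until, np.zeros(k)])
        return idx

    def _is_interpolar(self, pole, direction) -> np.ndarray:
        """Does the ray pass through the interpolar region (0.45a of centre)?

        Centre-pointing MTs are the detyrosinated subpopulation CENP-E
        prefers as transport rails.
        """
        origin = self.pole_positions[pole]
        t = np.einsum("ij,ij->i", direction, -origin)
        closest = origin + t[:, None] * direction
        return (t > 0) & (np.linalg.norm(closest, axis=1)
                          <= self.geometry.r_cenpe_shell)

    def remove_mts(self, mask: np.ndarray) -> None:
        """Remove the masked MTs (nucleation mode) and remap all references."""
        if not np.any(mask):
            return
        keep = ~mask
        remap = np.full(self.n_mt, -1, dtype=np.int32)
        remap[keep] = np.arange(int(keep.sum()), dtype=np.int32)
        # chromosome lateral links onto removed MTs are cleared
        lat = self.ch_lateral
        linked = lat >= 0
        lat[linked] = remap[lat[linked]]
        for name in ("mt_pole", "mt_dir", "mt_len", "mt_growing", "mt_scaffold",
                     "mt_birth", "mt_maxlen", "mt_attach_ch", "mt_attach_side",
                     "mt_no_rescue", "mt_interpolar", "mt_refract_until"):
            setattr(self, name, getattr(self, name)[keep])

    # ------------------------------------------------------------------
    def slot_occupancy(self) -> np.ndarray:
        """End-on attachment counts per kinetochore, shape (n_c, 2)."""
        occ = np.zeros((self.n_c, 2), dtype=np.int64)
        att = self.mt_attach_ch >= 0
        if np.any(att):
            key = self.mt_attach_ch[att] * 2 + self.mt_attach_side[att]
            counts = np.bincount(key, minlength=self.n_c * 2)
            occ = counts.reshape(self.n_c, 2)
        return occ

    def pole_occupancy(self) -> np.ndarray:
        """End-on counts per (chromosome, kinetochore side, MT pole), (n_c,2,2)."""
        occ = np.zeros((self.n_c, 2, 2), dtype=np.int64)
        att = self.mt_attach_ch >= 0
        if np.any(att):
            key = (self.mt_attach_ch[att] * 4 + self.mt_attach_side[att] * 2
                   + self.mt_pole[att])
            counts = np.bincount(key, minlength=self.n_c * 4)
            occ = counts.reshape(self.n_c, 2, 2)
        return occ

    # ------------------------------------------------------------------
    def mt_record(self, i: int) -> Microtubule:
        return Microtubule(
            pole=int(self.mt_pole[i]), direction=self.mt_dir[i].copy(),
            length=float(self.mt_len[i]), growing=bool(self.mt_growing[i]),
            scaffold=bool(self.mt_scaffold[i]), birth_time=float(self.mt_birth[i]),
            end_on_chrom=int(self.mt_attach_ch[i]) if self.mt_attach_ch[i] >= 0 else None,
            end_on_side=int(self.mt_attach_side[i]) if self.mt_attach_ch[i] >= 0 else None,
        )

    def chromosome_record(self, i: int) -> Chromosome:
        lat = int(self.ch_lateral[i])
        return Chromosome(position=self.ch_pos[i].copy(), motor=int(self.ch_motor[i]),
                          lateral_mt=lat if lat >= 0 else None)

    @classmethod
    def from_records(cls, params: ParameterSet, mts: list, chromosomes: list,
                     geometry: CellGeometry | None = None, seed: int = 0,
                     record_events: bool = True) -> "SimulationState":
        """Build a state from explicit records (tiny deterministic fixtures)."""
        params = params.replace(n_c=len(chromosomes))
        st = cls(params, geometry=geometry, record_events=record_events).seed(seed)
        for m in mts:
            d = np.asarray(m.direction, dtype=float)
            d = d / np.linalg.norm(d)
            st.add_mts(m.pole, d, m.length, m.growing, m.scaffold, m.birth_time)
        for i, m in enumerate(mts):
            if m.end_on_chrom is not None:
                st.mt_attach_ch[i] = m.end_on_chrom
                st.mt_attach_side[i] = m.end_on_side
        for i, c in enumerate(chromosomes):
            st.ch_pos[i] = np.asarray(c.position, dtype=float)
            st.ch_motor[i] = c.motor
            st.ch_lateral[i] = -1 if c.lateral_mt is None else c.lateral_mt
        return st
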