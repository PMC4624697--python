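"""Tiny deterministic fixture states for tests and examples.

These builders produce fully specified states with a handful of MTs and
chromosomes so individual rules (attachment formation, stability
classification, force assembly) can be exercised against hand-computable
expectations.
"""

from __future__ import annotations

import numpy as np

from .params import ParameterSet
from .state import CENPE, DYNEIN, Chromosome, Microtubule, SimulationState

#: a small, fast parameter set used by most unit fixtures
TINY = ParameterSet(n_mt=4, n_c=1, p_sc=0.0, warmup=0.0)


def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def state_with(mts, chromosomes, params: ParameterSet | None = None,
               seed: int = 0) -> SimulationState:
    """Build a state from explicit MT / chromosome records."""
    p = params if params is not None else TINY
    return SimulationState.from_records(p, mts, chromosomes, seed=seed)


def centred_chromosome(motor: int = CENPE) -> Chromosome:
    return Chromosome(position=np.zeros(3), motor=motor)


def mt_towards(point, pole: int = 0, overshoot: float = 0.0,
               params: ParameterSet | None = None, **kw) -> Microtubule:
    """An MT from the given pole aimed at ``point``, tip at/behind/past it."""
    p = params if params is not None else TINY
    pole_pos = np.array([(-1 if pole == 0 else 1) * p.a / 2.0, 0.0, 0.0])
    vec = np.asarray(point, dtype=float) - pole_pos
    d = np.linalg.norm(vec)
    return Microtubule(pole=pole, direction=vec / d, length=d + overshoot, **kw)


def biorientable_pair(params: ParameterSet | None = None, offset: float = 0.1):
    """One centred chromosome with opposing MT tips at both kinetochores.

    The two MTs come from opposite poles; their tips sit symmetrically at
    ``+-offset`` along x from the chromosome centre, so attaching both
    yields the stable amphitelic configuration with balanced springs.
    """
    ch = centred_chromosome(motor=CENPE)
    mt0 = mt_towards([-offset, 0, 0], pole=0, params=params, birth_time=-1e3)
    mt1 = mt_towards([+offset, 0, 0], pole=1, params=params, birth_time=-1e3)
    return [mt0, mt1], [ch]
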