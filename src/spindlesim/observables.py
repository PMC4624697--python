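"""Run-level observables, ensemble statistics and the population-kinetics fit.

Congression is scored with a slab criterion: the cell is congressed when
every chromosome satisfies ``|x| <= eps * a`` (default ``eps = 0.1``, i.e. a
metaphase plate of half-width 1.5 um at the default cell size).  The cell is
bi-oriented when every chromosome is in the stable amphitelic attachment
class.  Both are first-passage events with explicit censoring at a deadline.

Ensemble probability curves are empirical CDFs of the uncensored event times
with *all* runs (censored included) in the denominator, matching the
"fraction of n independent runs" convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .mt_dynamics import expected_mt_count
from .state import ST_STABLE, SimulationState


@dataclass
class RunSummary:
    """Outcome of one simulated cell."""

    seed: int
    scenario: str = ""
    congression_time: float = math.nan   #: s; NaN if censored
    congressed: bool = False
    biorientation_time: float = math.nan
    bioriented: bool = False
    congression_deadline: float = math.nan
    biorientation_deadline: float = math.nan
    nmt_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    nmt_counts: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_chromosomes: Optional[object] = None   #: pandas DataFrame
    n_steps: int = 0
    n_collapsed: int = 0
    sum_lifetimes: float = 0.0


@dataclass
class ProbabilityCurve:
    """Empirical cumulative event-probability over an ensemble of runs."""

    times: np.ndarray
    probability: np.ndarray
    n_runs: int

    def __post_init__(self):
        p = np.asarray(self.probability)
        if np.any(np.diff(p) < 0) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("probability curve must be monotone in [0, 1]")


@dataclass
class KineticFit:
    """Result of fitting the birth--death relaxation to a mean MT count."""

    k_nucl_hat: float
    k_out_hat: float
    residual: float      #: RMS misfit / plateau (dimensionless)
    k_nucl_fixed: bool = True


# ---------------------------------------------------------------------------
# state predicates
# ---------------------------------------------------------------------------

def congression_state(state: SimulationState, eps: float | None = None) -> bool:
    """True iff every chromosome lies in the plate slab |x| <= eps*a."""
    e = state.params.congression_eps if eps is None else eps
    if e <= 0:
        raise ValueError("eps must be strictly positive")
    return bool(np.all(np.abs(state.ch_pos[:, 0]) <= e * state.geometry.a))


def biorientation_state(state: SimulationState) -> bool:
    """True iff every chromosome is stably (amphitelically) attached."""
    from .attachments import classify_stability
    return bool(np.all(classify_stability(state) == ST_STABLE))


def first_passage(times: Sequence[float], flags: Sequence[bool],
                  deadline: float) -> Tuple[float, bool]:
    """Earliest time the predicate holds; ``(nan, False)`` if censored."""
    if deadline <= 0:
        raise ValueError("deadline must be strictly positive")
    for t, ok in zip(times, flags):
        if t > deadline:
            break
        if ok:
            return float(t), True
    return math.nan, False


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------

def probability_curve(summaries: Sequence[RunSummary],
                      which: str = "congression") -> ProbabilityCurve:
    """Empirical CDF of event times; censored runs count in the denominator."""
    if len(summaries) == 0:
        raise ValueError("no runs")
    if which == "congression":
        times = [s.congression_time for s in summaries if s.congressed]
    elif which == "biorientation":
        times = [s.biorientation_time for s in summaries if s.bioriented]
    else:
        raise ValueError(f"unknown event {which!r}")
    n = len(summaries)
    ts = np.sort(np.asarray(times, dtype=float))
    prob = np.arange(1, ts.size + 1) / n
    return ProbabilityCurve(times=ts, probability=prob, n_runs=n)


def median_time(curve: ProbabilityCurve) -> Optional[float]:
    """Smallest t with P(event <= t) >= 1/2; None if the plateau is below 1/2."""
    hit = curve.probability >= 0.5
    if not np.any(hit):
        return None
    return float(curve.times[np.argmax(hit)])


def fit_kout(times: np.ndarray, mean_counts: np.ndarray, k_nucl: float,
             fix_k_nucl: bool = True) -> KineticFit:
    """Least-squares fit of the birth--death relaxation to a mean MT count.

    ``k_nucl`` is the total nucleation rate feeding the counted population
    (both poles if the count is spindle-wide).  With ``fix_k_nucl=True``
    (default) only ``k_out`` is free, which anchors the plateau at
    ``k_nucl / k_out``; otherwise both parameters are fitted.
    """
    times = np.asarray(times, dtype=float)
    mean_counts = np.asarray(mean_counts, dtype=float)
    if times.size < 10:
        raise ValueError("need at least 10 time points spanning the transient")
    plateau_guess = float(np.max(mean_counts))
    if plateau_guess <= 0:
        raise ValueError("mean counts are identically zero")
    k_out_guess = k_nucl / plateau_guess

    try:
        if fix_k_nucl:
            popt, _ = curve_fit(lambda t, ko: expected_mt_count(k_nucl, ko, t),
                                times, mean_counts, p0=[k_out_guess])
            kn_hat, ko_hat = k_nucl, float(popt[0])
        else:
            popt, _ = curve_fit(lambda t, kn, ko: expected_mt_count(kn, ko, t),
                                times, mean_counts,
                                p0=[k_nucl, k_out_guess])
            kn_hat, ko_hat = float(popt[0]), float(popt[1])
    except RuntimeError as err:  # pragma: no cover - scipy non-convergence
        raise RuntimeError(f"k_out fit did not converge: {err}") from err
    if ko_hat <= 0 or kn_hat <= 0:
        raise RuntimeError("k_out fit produced non-positive rates")
    resid = mean_counts - expected_mt_count(kn_hat, ko_hat, times)
    rms = float(np.sqrt(np.mean(resid ** 2)) / (kn_hat / ko_hat))
    return KineticFit(k_nucl_hat=kn_hat, k_out_hat=ko_hat, residual=rms,
                      k_nucl_fixed=fix_k_nucl)


def sweet_spot_bounds(sweep: Dict[float, Tuple[float, float]]
                      ) -> Tuple[float, float]:
    """Smallest and largest MT number passing both probability criteria.

    ``sweep`` maps N_MT to ``(P_congression, P_biorientation)``.  A density
    passes when both probabilities exceed 1/2.  Raises ``ValueError`` if no
    density passes or if the passing band is not bracketed by failures on
    both ends.
    """
    ns = sorted(sweep)
    passing = [n for n in ns if sweep[n][0] > 0.5 and sweep[n][1] > 0.5]
    if not passing:
        raise ValueError("no MT density passes both criteria")
    lo, hi = min(passing), max(passing)
    if lo == ns[0] or hi == ns[-1]:
        raise ValueError("passing range not bracketed by failures on both ends")
    return lo, hi


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def summaries_to_frame(summaries: Iterable[RunSummary]):
    """Tidy one-row-per-run table (pandas DataFrame)."""
    import pandas as pd
    rows = []
    for s in summaries:
        rows.append({
            "seed": s.seed, "scenario": s.scenario,
            "congression_time_s": s.congression_time,
            "congressed": s.congressed,
            "biorientation_time_s": s.biorientation_time,
            "bioriented": s.bioriented,
            "congression_deadline_s": s.congression_deadline,
            "biorientation_deadline_s": s.biorientation_deadline,
            "n_steps": s.n_steps,
        })
    return pd.DataFrame(rows)
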