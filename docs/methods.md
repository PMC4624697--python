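# Model and methods

`spindlesim` is an agent-based, three-dimensional stochastic model of
chromosome congression and bi-orientation in a mammalian mitotic cell.  This
note records the model, its assumptions, the numerical choices, and the
places where the design was genuinely open and we had to commit to one
resolution.

## Geometry and agents

The cell cortex is a hard ellipsoid with semi-axes `(a, 0.9a, 0.7a)`,
`a = 15 um`, centred at the origin.  The two spindle poles are fixed at
`(+-a/2, 0, 0)` for the whole run (pole separation dynamics are out of
scope).  At t = 0 — nuclear envelope breakdown — `n_C = 46` chromosomes (10
in the reduced-scale test configurations) are placed i.i.d. uniformly in a
ball of radius `0.65a`; the `wt_interpolar` scenario restricts the start to
the interpolar shell of radius `0.45a`.

A chromosome is a point `r` carrying

* an *arm disk* of radius `r_C = 1.2 um` with normal along the pole–pole
  axis (the cross-section for polar ejection forces; an orientation-free
  spherical cross-section is available via `pef_geometry="sphere"`), and
* a *kinetochore interaction sphere* of radius `r_k = 0.3 um`, split into
  two hemispheres ("left" facing pole 0, "right" facing pole 1), each with
  `N_k = 25` end-on attachment slots.

Microtubules (MTs) are straight rays from a pole with a length, a
growing/shrinking phase, and a birth time.  Tips are clamped to the cortex.

## Microtubule dynamics

Unattached MTs follow dynamic instability with unloaded growth/shrinkage
speeds `v_g = 12`, `v_s = 14 um/min` and switching rates
`p_cat = p_cat0 exp(-F/F_cat)`, `p_res = p_res0 exp(+F/F_res)`, where `F` is
the tension transmitted by an end-on kinetochore coupling (zero otherwise),
`p_cat0 = 0.058 /s`, `p_res0 = 0.045 /s`, `F_cat = 2.4 pN`,
`F_res = 2.3 pN`.  Rates convert to per-step probabilities as
`1 - exp(-rate*dt)`, exact for exponential waiting within a step.

**Cortex contact.**  A growing tip reaching the cortex is clamped and
undergoes an immediate contact-induced catastrophe (the envelope repels
MTs).  Rescue kinetics are otherwise untouched by default
(`boundary_processive=False`): the resulting long MTs (mean ~8-10 um) are
what gives kinetochores at the cell rim enough capture flux and peripheral
chromosomes substantial polar ejection forces.  The price is that
cortex-hitting MTs linger near the envelope through shrink-rescue cycles;
the pathologies this could cause (chromosomes delivered to and pinned at
the boundary) are prevented by the transport rules below, not by shortening
the MTs.  Setting `boundary_processive=True` makes cortex-induced
catastrophes depolymerise without rescue, roughly halving the mean length;
this variant tightens the plate but starves rim kinetochores and is kept as
a configuration option.

**Population modes.**  In fixed-N mode the spindle holds `N_MT` MTs: a MT
shrinking back to the pole is instantly renucleated in a fresh uniform
direction.  Before t = 0 the dynamic population is pre-equilibrated for
`warmup = 300 s` with no chromosome interactions, so lengths and ages are
stationary when the chromosomes are released (the spindle is "already
formed", and the CENP-E age filter has eligible rails at t = 0).  In
nucleation mode the population starts empty, MTs appear from each pole as a
Poisson process of rate `k_nucl` and are removed on collapse; the mean count
follows `N(t) = (k_nucl/k_out) (1 - exp(-k_out t))` with `k_out` the per-MT
collapse rate.

The unloaded mean MT lifetime has the closed form
`T = (v_g + v_s) / (v_s p_cat0 - v_g p_res0)` (bounded regime), verified
against Monte Carlo.  The nucleation-mode scenario sets its catastrophe rate
by inverting this formula at the turnover `k_out = 0.09 /s` typical of
spindle MTs, giving `p_cat0 ~= 0.206 /s` — inside the plausible
0.058–0.58 /s range; at such short mean lengths (~1 um) the cortex is
irrelevant and the closed form is accurate.

Note that the relaxation of the mean count is *not* single-exponential:
lifetimes are a rescue-reinforced mixture, and the measured time to come
within 1% of the plateau is ~7/k_out (~76 s at `k_out = 0.09/s`) rather
than `ln(100)/k_out ~ 51 s`.  At 50 s the mean curve is already within ~4%
of the plateau — visually flat — but the strict 1% criterion lands later.
Similarly, the closed form misfits the early transient by up to ~3% of the
plateau, which is resolvable by ensembles of >~10 runs.

**Interpolar scaffold.**  A fraction `p_sc = 0.1` of MTs is a static
scaffold of interpolar rails: directions are sampled so the ray passes
within `0.45a` of the cell centre and crosses the spindle midplane inside
the cortex; each rail terminates just past the midplane with an antiparallel
overlap drawn from `U(0, 2 * scaffold_overlap)`, `scaffold_overlap =
0.6 um`.  The interdigitating plus ends of the two poles' scaffolds define
the metaphase plate of the model: they are where CENP-E transport delivers
chromosomes and where bi-orientation nucleates.  The overlap zone
(+-1.1 um) is contained in the congression slab (below).

## Motors and attachments

Chromosomes obey the overdamped Euler update `r <- r + F dt / eta` with
`eta = 1e3 pN s/um` and no thermal noise; positions leaving the cortex are
projected radially back to the boundary.  `F` is the sum of:

* **Polar ejection forces** — `F_PEF = 0.5 pN` along the MT direction for
  every MT crossing the arm disk.  PEFs scale linearly with the total MT
  number, which is what closes the congression window from above.
* **Lateral motor transport** — at most one rail per chromosome.  Dynein
  (peripheral chromosomes) pulls `F_DYN = 50 pN` towards the minus end of
  any MT crossing the kinetochore sphere; CENP-E pushes `F_CENPE = 50 pN`
  towards the plus end, but only rides long-lived stable rails — by default
  the interpolar scaffold itself (`cenpe_rails="scaffold"`; the
  `aged_interpolar` option additionally admits dynamic MTs older than
  `tau_MT = 60 s` whose ray passes through the interpolar shell, but with
  full rescue kinetics such aged MTs are mostly cortex-lingerers whose plus
  ends deliver cargo off-plate).  A motor group cannot walk past the end of
  its track: the transport force vanishes when the chromosome's projection
  reaches the rail's plus end (CENP-E holds the kinetochore there for
  end-on conversion) or the pole (dynein).  Rails are dropped when the MT
  collapses or the chromosome leaves the `r_k` proximity of the segment.
* **End-on springs** — zero-rest-length harmonic couplings of stiffness
  `k_k = 100 pN/um` between attached tips and the chromosome centre.

The motor program is deterministic: CENP-E is active initially inside the
`0.45a` shell, dynein outside; dynein chromosomes switch permanently to
CENP-E on arriving within `delta_pole = 5 um` of a pole, the scale of the
pole-proximal (Aurora-A) zone.  The switch radius must exceed the radius at
which the near-pole PEF field stalls dynein — measured at 3.5-4.6 um from
the pole at the default density — or peripheral chromosomes would never
hand over; it must also stay below the stall radius at the highest densities
studied so that PEF overload still blocks the handoff there (the upper edge
of the viable MT-number window).  A CENP-E
knockdown removes the replacement motor, so the switch is disabled and
pole-bound chromosomes stay dynein-held — which is what traps them at the
poles.  End-on attachments form only while CENP-E is active (dynein-coated
kinetochores inhibit them): any free MT tip within `r_k` binds the
hemisphere it touches if a slot is free.

**Stability and error correction.**  Attachments are *stable* only in the
amphitelic configuration — both kinetochores occupied and the union of
attached MTs stemming from both poles; otherwise *unstable*.  Unstable
attachments are slip bonds (`0.1/s * exp(+F/4 pN)`), stable ones catch bonds
(`0.001/s * exp(-F/4 pN)`); each attached MT samples detachment
independently using its chromosome's shared class.  Growth/shrinkage of
stably attached MTs is slowed by `exp(-F/F_g)` / `exp(-F/F_s)`.  A release
from a *stable* attachment is treated as an error-correction event: the
freed tip undergoes a catastrophe and a 5-s re-binding refractory period, so
a mislocated amphitelic lock genuinely dissolves instead of instantly
rebinding the kinetochore it still touches.  Slip-bond releases keep their
fast rebinding equilibrium — that persistent one-sided occupancy is what
lets a passing opposite-pole tip complete a stable pair.  Lateral transport
coexists with unstable end-on attachments (their slip bonds cannot hold
against a 50 pN motor group) and stops only once the chromosome is stably
bi-oriented.

## Observables

* **Congression**: all chromosomes inside the plate slab `|x| <= eps*a`,
  `eps = 0.2` (3 um half-width).  The slab is chosen so that the stably
  bi-oriented plate (half-width ~2-2.6 um, set by the scaffold overlap plus
  local capture sites) robustly reports success while trapped or polar
  chromosomes (>= 3.5 um from the midplane) report failure.  The parameter
  is a configuration knob; every reported bound states its `eps`.
* **Bi-orientation**: all chromosomes simultaneously in the stable class.
* Both are first-passage events with explicit censoring at deadlines
  (defaults 1e3 s for congression, 1e5 s for bi-orientation; reduced-scale
  tests shorten the latter).  Ensemble curves are empirical CDFs with
  censored runs in the denominator; medians are the earliest time the curve
  reaches 1/2 (undefined if the plateau stays below it).
* `fit_kout` least-squares fits the birth–death relaxation to a mean count
  series with `k_nucl` fixed (default) or free; `sweet_spot_bounds` extracts
  the smallest/largest MT number whose congression *and* bi-orientation
  probabilities both exceed 1/2, requiring failures on both flanks.

## Numerics

* `dt = 0.1 s`; a start-up check refuses steps above 20% of the spring
  relaxation time `eta/k_k` (10 s) or with per-step event probabilities
  above 0.5.
* All stochastic events of a step are sampled in parallel against the
  start-of-step state, then applied; MT growth and chromosome motion follow.
* The chromosome–MT interaction geometry (PEF crossings, new-attachment
  searches) is refreshed every `interaction_every = 5` steps (0.5 s) and
  held in between — far below the ~3 s tip transit and ~10 s transport
  timescales; detachments, instability and motion update every step.
* One `SeedSequence` per run spawns independent streams for initial
  placement, nucleation, instability and detachment, so runs are
  bit-reproducible from `(config, seed)` and chromosome-facing randomness is
  insensitive to MT-draw counts.

## Reduced-scale test conditions

The full study conditions (46 chromosomes, up to 3e4 MTs, 1e5 s deadlines)
are too heavy for routine testing; the test suite runs a 10-chromosome cell.
Both the search-and-capture flux onto a kinetochore and the PEFs scale with
the *absolute* MT number, not with MTs per kinetochore, so the reduced cell
keeps the full spindle density `N_MT = 1e4` (the middle of the viable
window); per-kinetochore saturation quantities are unaffected by `n_C`.
A 2000-MT condition sits below the viable window and is used as the
low-density failure point of the MT-number sweep.  Reduced-scale deadlines
are 1e3 s (congression) and 6e3 s (bi-orientation).  Full-scale sweep
configurations matching the published study design are shipped under
`configs/` and are not run in the test suite.

## What the synthetic conditions do and do not show

The generator *is* the model: there is no external data, and tests probe
internal consistency (closed forms vs simulation, invariants, knockdown
phenotypes) rather than agreement with any experimental recording.  Passing
tests show that the implemented rules produce the documented collective
behaviour at the stated scales; they cannot validate the biological
parameter choices themselves.  Known limitations: no chromosome–chromosome
exclusion, no arm elasticity or rotation, no Brownian motion of chromosomes,
no explicit Aurora-B/Kif18A biochemistry beyond the stable/unstable
dichotomy, poles fixed, and no tubulin-pool coupling.  Rim chromosomes (far
from the interpolar scaffold cone) bi-orient slowly at reduced MT numbers
because little capture flux reaches them; this is the model's low-density
failure mode, and it sets the practical duration of wild-type runs.
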