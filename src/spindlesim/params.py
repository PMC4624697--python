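"""Model parameters.

Unit conventions used throughout the package: lengths in micrometres (um),
forces in piconewtons (pN), times in seconds (s).  Velocities are *stored* in
um/min, the unit in which microtubule growth speeds are conventionally
reported, and converted to um/s at the point of use.  The drag coefficient is
stored in pN s/um; 1 kg/s = 1e6 pN s/um.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

#: conversion factor: 1 kg/s expressed in pN s/um
KG_PER_S_TO_PN_S_PER_UM = 1.0e6


@dataclass(frozen=True)
class ParameterSet:
    """All tunable physical and numerical parameters of the simulation.

    Defaults describe a mammalian (human, 46-chromosome) mitotic cell.  The
    population of microtubules is run in exactly one of two modes:

    * **fixed-N mode** (``k_nucl is None``): ``n_mt`` microtubules exist at all
      times; a microtubule that shrinks back to the pole is immediately
      renucleated in a fresh random direction.
    * **nucleation mode** (``k_nucl`` set): the population starts empty, MTs
      nucleate from each pole at rate ``k_nucl`` (per pole) and are removed
      when they shrink back to zero length.
    """

    # --- cell geometry -------------------------------------------------
    a: float = 15.0          #: cortex semi-axis along x (um); b = 0.9a, c = 0.7a
    r_k: float = 0.3         #: kinetochore interaction-sphere radius (um)
    r_c: float = 1.2         #: chromosome arm-disk radius (um)
    n_c: int = 46            #: number of chromosomes

    # --- microtubule dynamic instability (unloaded values) -------------
    v_g: float = 12.0        #: growth velocity (um/min)
    v_s: float = 14.0        #: shrinkage velocity (um/min)
    f_g: float = 6.0         #: growth force sensitivity (pN)
    f_s: float = 4.0         #: shrinkage force sensitivity (pN)
    p_cat0: float = 0.058    #: unloaded catastrophe rate (1/s)
    f_cat: float = 2.4       #: catastrophe force sensitivity (pN)
    p_res0: float = 0.045    #: unloaded rescue rate (1/s)
    f_res: float = 2.3       #: rescue force sensitivity (pN)

    # --- microtubule population ----------------------------------------
    n_mt: int = 10000        #: total MT count in fixed-N mode (both poles)
    k_nucl: Optional[float] = None  #: nucleation rate per pole (1/s); None = fixed-N
    p_sc: float = 0.1        #: fraction of MTs forming the stable interpolar scaffold
    scaffold_overlap: float = 0.6  #: mean antiparallel overlap of scaffold MTs past the midplane (um)
    tau_mt: float = 60.0     #: minimum MT age for CENP-E lateral attachment (s)
    cenpe_rails: str = "scaffold"  #: CENP-E rail eligibility: "scaffold" (stable
                                   #: interpolar rails only) or "aged_interpolar"
                                   #: (also dynamic MTs older than tau_mt whose
                                   #: ray passes the interpolar shell)

    # --- motors and attachments -----------------------------------------
    f_pef: float = 0.5       #: polar ejection force per crossing MT (pN)
    f_cenpe: float = 50.0    #: CENP-E motor-group force, 5 x 10 pN (pN)
    f_dyn: float = 50.0      #: dynein motor-group force, 1.0 x 50 pN (pN)
    n_k: int = 25            #: end-on attachment slots per kinetochore
    k_k: float = 100.0       #: kinetochore-MT spring constant (pN/um)
    p_detach_u0: float = 0.1     #: unloaded detachment rate, unstable attachment (1/s)
    f_detach_u: float = 4.0      #: slip-bond force sensitivity (pN)
    p_detach_s0: float = 0.001   #: unloaded detachment rate, stable attachment (1/s)
    f_detach_s: float = 4.0      #: catch-bond force sensitivity (pN)
    delta_pole: float = 5.0  #: pole-arrival radius triggering dynein->CENP-E switch (um)
    attach_refractory: float = 5.0  #: re-binding dead time after a stochastic detachment (s)

    # --- chromosome mechanics -------------------------------------------
    eta_pn_s_per_um: float = 1.0e3  #: chromosome drag coefficient (pN s/um)

    # --- numerics --------------------------------------------------------
    dt: float = 0.1          #: integration time step (s)
    interaction_every: int = 5  #: steps between interaction-geometry refreshes
                                #: (PEF crossings and new-attachment searches);
                                #: 0.5 s at defaults, well below the ~3 s tip
                                #: transit and ~10 s ride timescales
    warmup: float = 300.0    #: MT-only pre-equilibration before t=0, fixed-N mode (s)
    boundary_processive: bool = True  #: cortex-contact catastrophes depolymerise without rescue
    congression_eps: float = 0.2    #: congression slab half-width as a fraction of a
    pef_geometry: str = "disk"      #: arm cross-section: "disk" (normal x) or "sphere"

    # ------------------------------------------------------------------
    @property
    def v_g_um_s(self) -> float:
        return self.v_g / 60.0

    @property
    def v_s_um_s(self) -> float:
        return self.v_s / 60.0

    @property
    def fixed_n_mode(self) -> bool:
        return self.k_nucl is None

    @property
    def eta_kg_per_s(self) -> float:
        return self.eta_pn_s_per_um / KG_PER_S_TO_PN_S_PER_UM

    def replace(self, **kwargs) -> "ParameterSet":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check physical and numerical sanity; raise ``ValueError`` on failure."""
        positive = [
            "a", "r_k", "r_c", "v_g", "v_s", "f_g", "f_s", "p_cat0", "f_cat",
            "p_res0", "f_res", "k_k", "p_detach_u0",
            "f_detach_u", "p_detach_s0", "f_detach_s", "eta_pn_s_per_um", "dt",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        # motor-group forces may be exactly zero (knockdown scenarios)
        for name in ("f_pef", "f_cenpe", "f_dyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if not 0.0 <= self.p_sc <= 1.0:
            raise ValueError("p_sc must lie in [0, 1]")
        if self.n_c < 0 or self.n_k < 1:
            raise ValueError("n_c must be >= 0 and n_k >= 1")
        if self.k_nucl is not None and self.k_nucl <= 0:
            raise ValueError("k_nucl must be strictly positive in nucleation mode")
        if self.k_nucl is None and self.n_mt < 1:
            raise ValueError("n_mt must be >= 1 in fixed-N mode")
        if self.pef_geometry not in ("disk", "sphere"):
            raise ValueError("pef_geometry must be 'disk' or 'sphere'")
        if self.cenpe_rails not in ("scaffold", "aged_interpolar"):
            raise ValueError("cenpe_rails must be 'scaffold' or 'aged_interpolar'")
        if self.interaction_every < 1:
            raise ValueError("interaction_every must be >= 1")
        if self.interaction_every * self.dt > 1.0:
            raise ValueError("interaction refresh interval must not exceed 1 s")
        self.check_dt_stability()

    def check_dt_stability(self) -> None:
        """Refuse time steps too coarse for the stiffest process.

        The end-on spring relaxes on the scale eta/k_k (10 s at defaults) and
        the per-step probability of the fastest stochastic event must stay
        well below one for the parallel-update scheme to be meaningful.
        """
        if self.dt > 0.2 * self.eta_pn_s_per_um / self.k_k:
            raise ValueError(
                f"dt={self.dt} s exceeds 20% of the spring relaxation time "
                f"eta/k_k={self.eta_pn_s_per_um / self.k_k:.3g} s"
            )
        fastest = max(self.p_cat0, self.p_res0, self.p_detach_u0)
        if fastest * self.dt > 0.5:
            raise ValueError(
                f"dt={self.dt} s gives per-step event rate {fastest * self.dt:.2f}; "
                "reduce dt"
            )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
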