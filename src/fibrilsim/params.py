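"""Model parameters and the default Type III domain stiffness profile.

All mechanical quantities are in pN / nm / s unless a field says otherwise.
The exposure threshold ``eps_t`` is stored in Angstrom because that is the
unit in which thresholds are quoted experimentally (nominal 15 A = 1.5 nm);
``eps_t_nm`` converts it for the force-level code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ConfigError

#: Thermal energy k_B*T at 310 K, pN*nm.
KT = 4.28


@dataclass(frozen=True)
class ModelParams:
    """Every rate and mechanics constant of the assembly model.

    Substrate stiffness and the collective stall force are the two anchors
    of the traction model; the kinetic constants below them are package
    defaults in the motor-clutch literature range, fixed once by the
    calibration procedure in :mod:`fibrilsim.experiments`.
    """

    # Traction / substrate
    k_sub: float = 1000.0      #: substrate stiffness, pN/nm
    f_stall: float = 200.0     #: collective actomyosin stall force, pN
    v_u: float = 120.0         #: unloaded actin retrograde velocity, nm/s

    # Molecular clutch kinetics
    k_on: float = 1.0          #: integrin on-rate per free site, 1/s
    k_off: float = 0.1         #: unloaded integrin off-rate, 1/s
    f_b: float = 2.0           #: Bell characteristic break force, pN
    k_c: float = 5.0           #: clutch spring stiffness, pN/nm

    # Cryptic-site exposure and FN recruitment
    eps_t: float = 15.0        #: exposure threshold, Angstrom
    n_h: float = 4.0           #: Hill coefficient of the exposure hazard
    k_exp: float = 1.0         #: maximal exposure rate, 1/s
    k_fn: float = 0.0017       #: soluble-FN binding rate at an exposed site, 1/s

    # Geometry / elasticity
    l_III: float = 3.2         #: folded Type III domain rest length, nm
    l_I_II: float = 20.0       #: inelastic Type I/II end-connector length, nm
    d_lat: float = 5.0         #: hexagonal cross-section lattice spacing, nm
    L_c: float = 30.0          #: unfolded-domain contour length, nm
    p_wlc: float = 0.4         #: persistence length of the unfolded chain, nm
    kT: float = KT             #: thermal energy, pN*nm

    # Integration
    dt: float = 0.02           #: timestep, s
    duration: float = 900.0    #: simulated assembly time, s
    restretch_duration: float = 600.0  #: simulated re-stretch time, s
    sample_every: float = 1.0  #: trajectory sampling cadence, s
    restretch_sample_every: float = 0.1  #: re-stretch cadence, s (resolves
                                         #: the initial loading slope)

    # Solver
    solver_tol: float = 1e-6   #: max nodal force imbalance, pN
    solver_max_iter: int = 200

    def __post_init__(self) -> None:
        for name in ("k_sub", "f_stall", "v_u", "k_on", "k_off", "f_b", "k_c",
                     "eps_t", "n_h", "k_exp", "l_III", "l_I_II", "d_lat",
                     "L_c", "p_wlc", "kT", "dt", "duration", "sample_every",
                     "restretch_sample_every", "solver_tol"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"parameter {name!r} must be strictly positive")
        if self.k_fn < 0:
            raise ConfigError("parameter 'k_fn' must be non-negative")
        if not self.eps_t_nm < self.L_c - self.l_III:
            raise ConfigError(
                "exposure threshold eps_t must be reachable before the "
                "unfolded contour limit (eps_t/10 < L_c - l_III)")

    @property
    def eps_t_nm(self) -> float:
        """Exposure threshold converted to nm."""
        return self.eps_t / 10.0

    @property
    def max_stretch(self) -> float:
        """Largest admissible domain extension beyond rest, nm."""
        return self.L_c - self.l_III

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown model parameter(s): {sorted(bad)}")
        return cls(**d)


def default_stiffness_values() -> np.ndarray:
    """The shipped 15 resting stiffnesses, pN/nm, indexed by domain 1..15.

    Fifteen values evenly spaced on [0.2, 1.0] with the entry nearest
    0.8 pN/nm replaced by exactly 0.8 and assigned to domain 2 (the one
    per-domain value the model pins down); the remaining values fill
    domains 1, 3..15 in ascending order.  The spectrum is a configuration
    vector -- experiments may replace it wholesale.
    """
    vals = np.linspace(0.2, 1.0, 15)
    j = int(np.argmin(np.abs(vals - 0.8)))
    rest = np.delete(vals, j)
    out = np.empty(15)
    out[1] = 0.8
    out[0] = rest[0]
    out[2:] = rest[1:]
    return out


def validate_stiffness_profile(values: Iterable[float]) -> np.ndarray:
    """Check a 15-entry resting-stiffness vector against the model range."""
    arr = np.asarray(list(values), dtype=float)
    if arr.shape != (15,):
        raise ConfigError("stiffness profile must have exactly 15 entries")
    if np.any(arr < 0.2 - 1e-12) or np.any(arr > 1.0 + 1e-12):
        raise ConfigError("resting stiffnesses must lie in [0.2, 1.0] pN/nm")
    return arr
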