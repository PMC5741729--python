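"""Per-timestep stochastic events: clutch binding/unbinding, cryptic-site
exposure/hiding, and soluble-FN recruitment.

All first-order rates are converted to per-step Bernoulli probabilities
with ``1 - exp(-rate*dt)`` and sampled from one seeded generator in a fixed
order (unbind -> bind -> expose/hide -> FN-bind), so a seed plus a
configuration reproduces the event sequence bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import INTEGRIN_POSITIONS, Fibril
from .mechanics import EquilibriumResult, clutch_off_rate
from .params import ModelParams

INTEGRIN_ON = "INTEGRIN_ON"
INTEGRIN_OFF = "INTEGRIN_OFF"
EXPOSE = "EXPOSE"
HIDE = "HIDE"
FN_BIND = "FN_BIND"


@dataclass
class EventLog:
    """Time-ordered record of every stochastic event in a run."""
    time: list = field(default_factory=list)
    kind: list = field(default_factory=list)
    molecule: list = field(default_factory=list)
    position: list = field(default_factory=list)

    def append(self, t: float, kind: str, molecule: int, position: int) -> None:
        self.time.append(t)
        self.kind.append(kind)
        self.molecule.append(molecule)
        self.position.append(position)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "kind": self.kind,
                             "molecule": self.molecule,
                             "position": self.position})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def records(self):
        return list(zip(self.time, self.kind, self.molecule, self.position))


def rate_to_prob(rate, dt: float):
    """Per-step Bernoulli probability 1 - exp(-rate*dt) of a first-order event."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    return -np.expm1(-rate * dt)


def exposure_hazard(stretch, params: ModelParams):
    """Hill-type cryptic-site exposure rate, 1/s; half-maximal at eps_t."""
    s = np.asarray(stretch, dtype=float)
    if np.any(s < 0):
        raise ValueError("stretch must be >= 0")
    m = params.eps_t_nm
    sn = s**params.n_h
    return params.k_exp * sn / (m**params.n_h + sn)


_WARNED = set()


def _check_dt(params: ModelParams, max_rate: float) -> None:
    if max_rate * params.dt > 0.05 and "dt" not in _WARNED:
        _WARNED.add("dt")
        warnings.warn(
            f"max event rate * dt = {max_rate * params.dt:.3f} > 0.05; "
            "the fixed-step Bernoulli sampling is losing accuracy",
            RuntimeWarning, stacklevel=2)


def step_events(fibril: Fibril, eq: EquilibriumResult, rng: np.random.Generator,
                t: float, params: ModelParams, log: EventLog | None = None,
                recruit: bool = True) -> int:
    """Sample one timestep of stochastic events on a mechanically-solved fibril.

    Order within the step is fixed for determinism: clutch unbinding, then
    clutch binding on perimeter free sites, then cryptic-site exposure (and
    deterministic re-burial below eps_t/2), then soluble-FN recruitment at
    exposed perimeter sites.  Returns the number of molecules added.
    """
    dt = params.dt
    n = fibril.n_nodes
    added = 0

    # 1. clutch unbinding (Bell slip bond at the solved clutch force)
    if eq.clutch_nodes.size:
        rates = clutch_off_rate(eq.clutch_force, params)
        _check_dt(params, float(rates.max()))
        u = rng.random(rates.size)
        off = u < rate_to_prob(rates, dt)
        for j in np.nonzero(off)[0]:
            m, s = int(eq.clutch_mol[j]), int(eq.clutch_site[j])
            fibril.unbind_integrin(m, s)
            if log is not None:
                log.append(t, INTEGRIN_OFF, m, INTEGRIN_POSITIONS[s])

    # 2. clutch binding at free sites of perimeter molecules
    perim = np.fromiter(fibril._perimeter, dtype=np.int64,
                        count=len(fibril._perimeter))
    perim.sort()
    if perim.size:
        free_r, free_s = np.nonzero(~fibril.bond_active[perim])
        if free_r.size:
            p_on = float(rate_to_prob(params.k_on, dt))
            u = rng.random(free_r.size)
            for j in np.nonzero(u < p_on)[0]:
                m, s = int(perim[free_r[j]]), int(free_s[j])
                fibril.bind_integrin(m, s)
                if log is not None:
                    log.append(t, INTEGRIN_ON, m, INTEGRIN_POSITIONS[s])

    # 3. exposure / hiding of cryptic sites (occupied sites are frozen)
    live = fibril.cryptic[:n] & ~fibril.occupied[:n]
    stretch = eq.stretch
    exposed = fibril.exposed[:n]
    hide_mask = live & exposed & (stretch < 0.5 * params.eps_t_nm)
    for i in np.nonzero(hide_mask)[0]:
        fibril.exposed[i] = False
        if log is not None:
            log.append(t, HIDE, int(fibril.node_mol[i]), int(fibril.node_pos[i]))
    cand = np.nonzero(live & ~fibril.exposed[:n])[0]
    if cand.size:
        haz = exposure_hazard(np.maximum(stretch[cand], 0.0), params)
        u = rng.random(cand.size)
        fire = cand[u < rate_to_prob(haz, dt)]
        for i in fire:
            fibril.exposed[i] = True
            if log is not None:
                log.append(t, EXPOSE, int(fibril.node_mol[i]),
                           int(fibril.node_pos[i]))

    # 4. soluble-FN recruitment at exposed, unoccupied perimeter sites
    if recruit and params.k_fn > 0:
        mask = np.zeros(fibril.n_molecules, dtype=bool)
        mask[perim] = True
        cand = np.nonzero(fibril.exposed[:n] & ~fibril.occupied[:n]
                          & fibril.cryptic[:n])[0]
        cand = cand[mask[fibril.node_mol[cand]]]
        if cand.size:
            p_fn = float(rate_to_prob(params.k_fn, dt))
            u = rng.random(cand.size)
            for i in cand[u < p_fn]:
                m = int(fibril.node_mol[i])
                if m not in fibril._perimeter:
                    continue  # surrounded by an attach earlier this step
                fibril.attach_soluble_fn(m, int(fibril.node_pos[i]))
                added += 1
                if log is not None:
                    log.append(t, FN_BIND, m, int(fibril.node_pos[i]))
    return added
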