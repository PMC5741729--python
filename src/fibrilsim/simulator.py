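"""Time-stepping engines: fibril assembly and the relax/re-stretch protocol.

The assembly loop starts from a single substrate-bound dimer and repeats
{advance the actin node kinematically by v_act*dt, relax the spring network
to equilibrium, sample stochastic events}.  The re-stretch protocol takes a
fully assembled fibril, removes every integrin bond (so f_sub = 0 and the
fibril returns to its relaxed length), then re-runs the same loop with FN
recruitment disabled and the bond topology frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Fibril, make_profile
from .errors import SolverError
from .mechanics import actin_velocity, solve_equilibrium
from .params import ModelParams
from .stochastics import EventLog, step_events

_NM_PER_UM = 1000.0


@dataclass
class Trajectory:
    """Sampled time series of one simulation plus the final network state.

    Lengths are reported in micrometres, forces in pN.
    """
    t: np.ndarray            #: sample times, s
    n_fn: np.ndarray         #: molecule count
    L_r: np.ndarray          #: relaxed length, um
    L_s: np.ndarray          #: stretched length, um
    n_integrins: np.ndarray  #: bound clutch count
    f_sub: np.ndarray        #: substrate force, pN
    fibril: Fibril | None = None
    events: EventLog | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dL(self) -> np.ndarray:
        """Fibril stretch L_s - L_r, um."""
        return self.L_s - self.L_r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "n_fn": self.n_fn, "L_r": self.L_r, "L_s": self.L_s,
            "n_integrins": self.n_integrins, "f_sub": self.f_sub,
            "dL": self.dL})

    def save(self, directory, stem: str = "trajectory") -> None:
        """Persist the sampled series (CSV) and network snapshot (JSON)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{stem}.csv", index=False)
        if self.fibril is not None:
            snap = snapshot_dict(self.fibril)
            snap["meta"] = {k: v for k, v in self.meta.items()
                            if isinstance(v, (int, float, str, bool))}
            with open(directory / f"{stem}_network.json", "w") as fh:
                json.dump(snap, fh)
        if self.events is not None:
            self.events.to_csv(directory / f"{stem}_events.csv")


def snapshot_dict(fibril: Fibril) -> dict:
    """JSON-serializable snapshot of molecules, bonds and lattice coords."""
    return {
        "n_molecules": fibril.n_molecules,
        "site_set": sorted(fibril.site_set),
        "profile_k0": [s.k0 for s in fibril.profile],
        "molecules": [
            {"id": m.id, "lattice": list(m.lattice_coord),
             "attachment": (list(m.attachment)
                            if isinstance(m.attachment, tuple)
                            else m.attachment)}
            for m in fibril.molecules],
        "fn_bonds": [[b.parent_id, b.parent_position, b.child_id]
                     for b in fibril.fn_bonds],
    }


def _resolve_hypothesis(hypothesis, params: ModelParams, rng):
    """Accept an experiments.Hypothesis, a site set, or (site_set, profile)."""
    from .experiments import Hypothesis, resolve_profile
    if isinstance(hypothesis, Hypothesis):
        return hypothesis.site_set, resolve_profile(hypothesis, params, rng), \
            hypothesis.scaled_params(params)
    if isinstance(hypothesis, tuple) and len(hypothesis) == 2:
        site_set, profile = hypothesis
        return frozenset(site_set), profile, params
    from .params import default_stiffness_values
    return frozenset(hypothesis), make_profile(default_stiffness_values()), params


def _run_loop(fibril: Fibril, params: ModelParams, rng, duration: float,
              log: EventLog | None, recruit: bool, t0: float = 0.0) -> Trajectory:
    dt = params.dt
    n_steps = int(round(duration / dt))
    sample_stride = max(1, int(round(params.sample_every / dt)))
    n_samples = n_steps // sample_stride + 1
    t = np.empty(n_samples)
    n_fn = np.empty(n_samples, dtype=np.int64)
    L_r = np.empty(n_samples)
    L_s = np.empty(n_samples)
    n_int = np.empty(n_samples, dtype=np.int64)
    f_sub = np.empty(n_samples)

    eq = solve_equilibrium(fibril, fibril.actin_z, params)
    k = 0
    t[k] = t0
    n_fn[k] = fibril.n_molecules
    L_r[k] = fibril.relaxed_tip() / _NM_PER_UM
    L_s[k] = fibril.stretched_tip() / _NM_PER_UM
    n_int[k] = fibril.n_integrins
    f_sub[k] = eq.f_sub
    k += 1

    for step in range(1, n_steps + 1):
        fibril.actin_z += float(actin_velocity(eq.f_sub, params)) * dt
        try:
            eq = solve_equilibrium(fibril, fibril.actin_z, params)
        except SolverError as err:
            err.time = t0 + step * dt
            raise
        step_events(fibril, eq, rng, t0 + step * dt, params,
                    log=log, recruit=recruit)
        if step % sample_stride == 0:
            t[k] = t0 + step * dt
            n_fn[k] = fibril.n_molecules
            L_r[k] = fibril.relaxed_tip() / _NM_PER_UM
            L_s[k] = fibril.stretched_tip() / _NM_PER_UM
            n_int[k] = fibril.n_integrins
            f_sub[k] = eq.f_sub
            k += 1
    return Trajectory(t=t[:k], n_fn=n_fn[:k], L_r=L_r[:k], L_s=L_s[:k],
                      n_integrins=n_int[:k], f_sub=f_sub[:k],
                      fibril=fibril, events=log)


def simulate_assembly(hypothesis, params: ModelParams | None = None,
                      seed: int = 0, log_events: bool = True) -> Trajectory:
    """Assemble one fibril from a single substrate-bound dimer.

    ``hypothesis`` may be an :class:`fibrilsim.experiments.Hypothesis`, a
    bare set of cryptic-site domain indices (default stiffness profile), or
    a ``(site_set, profile)`` pair.  Identical (hypothesis, params, seed)
    always reproduce the identical trajectory.
    """
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    site_set, profile, params = _resolve_hypothesis(hypothesis, params, rng)
    fibril = Fibril(profile, site_set, params)
    log = EventLog() if log_events else None
    traj = _run_loop(fibril, params, rng, params.duration, log, recruit=True)
    traj.meta.update(seed=seed, site_set=sorted(site_set), kind="assembly",
                     duration=params.duration, dt=params.dt)
    return traj


def restretch_protocol(fibril: Fibril, params: ModelParams | None = None,
                       seed: int = 0, duration: float | None = None,
                       log_events: bool = True) -> Trajectory:
    """Relax an assembled fibril and re-stretch it with growth disabled.

    All integrin bonds are removed (f_sub = 0, L_s = L_r), then the
    traction loop runs for ``duration`` (default
    ``params.restretch_duration``) with soluble-FN recruitment off, so the
    molecule count and bond topology stay frozen.  The input fibril is not
    modified.
    """
    params = params or fibril.params
    duration = params.restretch_duration if duration is None else duration
    params = params.with_(sample_every=params.restretch_sample_every)
    rng = np.random.default_rng(seed)
    fib = fibril.copy()
    fib.params = params
    fib.clear_integrins()
    n = fib.n_nodes
    fib.z[:n] = fib.rest_z[:n]
    fib.exposed[:n] = False
    fib.actin_z = fib.stretched_tip()
    log = EventLog() if log_events else None
    traj = _run_loop(fib, params, rng, duration, log, recruit=False)
    traj.meta.update(seed=seed, kind="restretch", duration=duration,
                     dt=params.dt, n_fn=fib.n_molecules)
    return traj


def check_trajectory_invariants(traj: Trajectory, atol: float = 1e-9) -> None:
    """Assert the sampled-frame invariants of any simulation run."""
    assert np.all(np.diff(traj.n_fn) >= 0), "molecule count must not decrease"
    assert np.all(np.diff(traj.L_r) >= -atol), "relaxed length must not decrease"
    assert np.all(traj.dL >= -1e-6), "stretched length must be >= relaxed length"
    assert np.all(traj.f_sub >= -atol), "substrate force must be >= 0"
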