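"""Constitutive laws and the quasi-static force-balance solver.

Three laws drive the model:

* a stretch-dependent Type III domain stiffness that starts at the
  domain-specific resting value ``k0`` and converges to the worm-like-chain
  (WLC) tangent stiffness as the domain unfolds toward its contour length;
* Bell slip-bond kinetics for the integrin clutch off-rate,
  ``k_off* = k_off exp(f/f_b)``;
* a linear force-velocity relation for the collective actomyosin pull,
  ``v = v_u (1 - f_sub/f_stall)`` clamped at stall.

Between stochastic events the network is assumed mechanically relaxed:
:func:`solve_equilibrium` drives the net force on every free node below
tolerance with a damped Newton iteration on the spring tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _solver
from .core import INTEGRIN_POSITIONS, Fibril
from .errors import ContourLimitError, SolverError
from .params import ModelParams

__all__ = [
    "wlc_force", "domain_force", "domain_stiffness", "clutch_off_rate",
    "actin_velocity", "solve_equilibrium", "EquilibriumResult",
]


def _sig_consts(params: ModelParams):
    """(midpoint, width, sigma(0)) of the logistic stiffness blend."""
    m = params.eps_t_nm
    tau = m / 4.0
    sig0 = 1.0 / (1.0 + np.exp(m / tau))
    return m, tau, sig0


def wlc_force(x, params: ModelParams):
    """Worm-like-chain interpolation force at end-to-end extension x (nm)."""
    x = np.asarray(x, dtype=float)
    u = 1.0 - x / params.L_c
    return (params.kT / params.p_wlc) * (0.25 / u**2 - 0.25 + x / params.L_c)


def _blend(stretch, params: ModelParams):
    m, tau, sig0 = _sig_consts(params)
    sig = 1.0 / (1.0 + np.exp(-(np.asarray(stretch, dtype=float) - m) / tau))
    w = (sig - sig0) / (1.0 - sig0)
    dw = sig * (1.0 - sig) / (tau * (1.0 - sig0))
    return w, dw


def _check_stretch(stretch, params: ModelParams):
    s = np.asarray(stretch, dtype=float)
    if np.any(s < 0):
        raise ValueError("domain stretch must be >= 0")
    if np.any(s >= params.max_stretch):
        raise ContourLimitError(
            f"stretch >= contour limit L_c - l_III = {params.max_stretch} nm")
    return s


def domain_force(k0, stretch, params: ModelParams):
    """Tension (pN) of a domain spring at the given stretch (nm).

    Logistic force-level blend between the Hookean resting response k0*s
    and the WLC response of the unfolded chain (shifted to vanish at rest),
    with midpoint at the exposure threshold and width a quarter of it.
    """
    s = _check_stretch(stretch, params)
    w, _ = _blend(s, params)
    fw = wlc_force(s + params.l_III, params) - wlc_force(params.l_III, params)
    return (1.0 - w) * np.asarray(k0, dtype=float) * s + w * fw


def domain_stiffness(k0, stretch, params: ModelParams):
    """Tangent stiffness dF/ds (pN/nm) of a domain spring.

    Exactly k0 at zero stretch; approaches the WLC tangent stiffness (and
    diverges) as stretch nears the contour limit L_c - l_III.
    """
    s = _check_stretch(stretch, params)
    w, dw = _blend(s, params)
    x = s + params.l_III
    u = 1.0 - x / params.L_c
    fw = wlc_force(x, params) - wlc_force(params.l_III, params)
    kw = (params.kT / params.p_wlc) * (0.5 / (params.L_c * u**3)
                                       + 1.0 / params.L_c)
    k0 = np.asarray(k0, dtype=float)
    return (1.0 - w) * k0 + w * kw + dw * (fw - k0 * s)


def clutch_off_rate(f_clutch, params: ModelParams):
    """Bell slip-bond off-rate k_off * exp(f/f_b), 1/s."""
    f = np.asarray(f_clutch, dtype=float)
    if np.any(f < 0):
        raise ValueError("clutch force must be >= 0")
    return params.k_off * np.exp(f / params.f_b)


def actin_velocity(f_sub, params: ModelParams):
    """Load-dependent actin pulling velocity v_u (1 - f/f_stall), >= 0, nm/s."""
    f = np.asarray(f_sub, dtype=float)
    if np.any(f < 0):
        raise ValueError("substrate force must be >= 0")
    return params.v_u * np.maximum(0.0, 1.0 - f / params.f_stall)


@dataclass
class EquilibriumResult:
    """Solved mechanical state of a fibril at one instant."""
    z: np.ndarray             #: node z-positions, nm (view into the fibril)
    stretch: np.ndarray       #: per-node spring extension beyond rest, nm
    tension: np.ndarray       #: per-node spring tension, pN
    f_sub: float              #: substrate force, pN
    clutch_nodes: np.ndarray  #: node index of each bound clutch
    clutch_mol: np.ndarray    #: molecule id of each bound clutch
    clutch_site: np.ndarray   #: site index (0 -> pos 10, 1 -> pos 21)
    clutch_force: np.ndarray  #: per-clutch force, pN
    residual: float           #: max nodal force imbalance, pN
    n_iter: int


_SITE_OFFSETS = np.array([INTEGRIN_POSITIONS[0] - 1, INTEGRIN_POSITIONS[1] - 1],
                         dtype=np.int64)


def _clutch_arrays(fibril: Fibril):
    n_mol = fibril.n_molecules
    mols, sites = np.nonzero(fibril.bond_active[:n_mol])
    starts = np.fromiter((m.node_start for m in fibril.molecules),
                         dtype=np.int64, count=n_mol)
    nodes = starts[mols] + _SITE_OFFSETS[sites]
    offs = fibril.bond_offset[mols, sites].astype(float)
    return mols.astype(np.int64), sites.astype(np.int64), nodes, offs


def solve_equilibrium(fibril: Fibril, actin_z: float | None = None,
                      params: ModelParams | None = None,
                      tol: float | None = None,
                      max_iter: int | None = None) -> EquilibriumResult:
    """Relax the fibril to mechanical equilibrium at the given actin position.

    Boundary conditions: the substrate spring anchors the root at the
    ground, bound clutch springs pull their III_10 nodes toward the actin
    node.  Node positions in the fibril are updated in place (warm-started
    from the previous solve).  Raises :class:`SolverError`, carrying the
    residual, if Newton fails to reach tolerance.
    """
    p = params or fibril.params
    if actin_z is None:
        actin_z = fibril.actin_z
    else:
        fibril.actin_z = float(actin_z)
    if not np.isfinite(actin_z):
        raise ValueError("actin position must be finite")
    tol = p.solver_tol if tol is None else tol
    max_iter = p.solver_max_iter if max_iter is None else max_iter

    n = fibril.n_nodes
    z = fibril.z[:n]
    mols, sites, clutch_nodes, clutch_off = _clutch_arrays(fibril)
    m_sig, tau_sig, sig0 = _sig_consts(p)
    converged, n_iter, residual = _solver.newton_solve(
        z, fibril.node_parent[:n], fibril.spring_k0[:n],
        fibril.spring_rest[:n], fibril.spring_linear[:n],
        clutch_nodes, clutch_off, p.k_c, float(actin_z),
        p.kT / p.p_wlc, p.L_c, p.l_III, m_sig, tau_sig, sig0,
        tol, max_iter)
    if not converged:
        raise SolverError(
            f"equilibrium not converged after {n_iter} iterations "
            f"(residual {residual:.3e} pN)", residual=residual)

    stretch = fibril.stretches()
    tension = np.empty(n)
    tension[0] = p.k_sub * stretch[0]
    lin = fibril.spring_linear[1:n]
    k0s = fibril.spring_k0[1:n]
    s1 = np.clip(stretch[1:], None, _solver._CLAMP_FRAC * p.max_stretch)
    w, _ = _blend(np.maximum(s1, 0.0), p)
    fw = wlc_force(np.maximum(s1, 0.0) + p.l_III, p) - wlc_force(p.l_III, p)
    f_nl = np.where(s1 >= 0,
                    (1.0 - w) * k0s * np.maximum(s1, 0.0) + w * fw,
                    k0s * s1)
    tension[1:] = np.where(lin, k0s * stretch[1:], f_nl)
    ext = np.maximum(0.0, actin_z - z[clutch_nodes] - clutch_off)
    return EquilibriumResult(
        z=z, stretch=stretch, tension=tension,
        f_sub=float(p.k_sub * stretch[0]),
        clutch_nodes=clutch_nodes, clutch_mol=mols, clutch_site=sites,
        clutch_force=p.k_c * ext, residual=float(residual), n_iter=int(n_iter))
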