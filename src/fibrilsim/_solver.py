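"""Numba kernels for the quasi-static spring-tree equilibrium solve.

The network is a rooted tree of one-dimensional springs (nodes ordered so
that every parent index is smaller than its child's), with a linear
substrate spring anchoring node 0 to the ground, tension-only nonlinear
domain springs along the chains, and tension-only linear clutch springs
connecting bound III_10 nodes to the (fixed, per-step) actin position.
Damped Newton with the analytic tangent stiffness; each linear solve is an
O(N) elimination along the tree.
"""

import numpy as np
from numba import njit

#: Fraction of the contour-limit stretch beyond which the force law is
#: linearly extrapolated to keep Newton iterates finite.
_CLAMP_FRAC = 0.97


@njit(cache=True)
def _domain_f_k(s, k0, kT_p, L_c, l_III, m_sig, tau_sig, sig0):
    """Tension and tangent stiffness of one domain spring at stretch s (nm).

    Force-level blend between the Hookean resting regime (slope k0) and the
    worm-like-chain response of the unfolded domain, weighted by a logistic
    in stretch renormalized to vanish exactly at s = 0:

        F(s) = (1 - w) k0 s + w [F_wlc(s + l_III) - F_wlc(l_III)]
        w(s) = (sigma(s) - sigma(0)) / (1 - sigma(0))

    so F'(0) = k0 exactly and F' approaches the WLC tangent as s nears the
    contour limit L_c - l_III.  Compression (s < 0) is linear at k0.
    """
    if s < 0.0:
        return k0 * s, k0
    s_lim = _CLAMP_FRAC * (L_c - l_III)
    if s > s_lim:
        f0, k_lim = _domain_f_k(s_lim, k0, kT_p, L_c, l_III, m_sig, tau_sig, sig0)
        return f0 + k_lim * (s - s_lim), k_lim
    sig = 1.0 / (1.0 + np.exp(-(s - m_sig) / tau_sig))
    w = (sig - sig0) / (1.0 - sig0)
    dw = sig * (1.0 - sig) / (tau_sig * (1.0 - sig0))
    x = s + l_III
    u = 1.0 - x / L_c
    fw = kT_p * (0.25 / (u * u) - 0.25 + x / L_c)
    x0 = l_III
    u0 = 1.0 - x0 / L_c
    fw0 = kT_p * (0.25 / (u0 * u0) - 0.25 + x0 / L_c)
    fw_rel = fw - fw0
    kw = kT_p * (0.5 / (L_c * u * u * u) + 1.0 / L_c)
    f = (1.0 - w) * k0 * s + w * fw_rel
    k = (1.0 - w) * k0 + w * kw + dw * (fw_rel - k0 * s)
    return f, k


@njit(cache=True)
def _residual(z, parent, k0_arr, rest, linear, clutch_nodes, clutch_off,
              k_c, z_act, kT_p, L_c, l_III, m_sig, tau_sig, sig0,
              g, d):
    """Fill net nodal force g and tangent diagonal d; return spring stiffnesses.

    g[i] = -T_i + sum_children T_c + clutch pull on i
    d[i] = k_i + sum_children k_c + clutch stiffness (SPD tree Laplacian diag)
    """
    n = z.shape[0]
    k_edge = np.empty(n)
    for i in range(n):
        g[i] = 0.0
        d[i] = 0.0
    for i in range(n):
        if parent[i] >= 0:
            e = z[i] - z[parent[i]] - rest[i]
        else:
            e = z[i] - rest[i]
        if linear[i]:
            t = k0_arr[i] * e
            k = k0_arr[i]
        else:
            t, k = _domain_f_k(e, k0_arr[i], kT_p, L_c, l_III,
                               m_sig, tau_sig, sig0)
        k_edge[i] = k
        g[i] -= t
        d[i] += k
        if parent[i] >= 0:
            g[parent[i]] += t
            d[parent[i]] += k
    for j in range(clutch_nodes.shape[0]):
        node = clutch_nodes[j]
        ext = z_act - z[node] - clutch_off[j]
        if ext > 0.0:
            g[node] += k_c * ext
            d[node] += k_c
    return k_edge


@njit(cache=True)
def _max_abs(g):
    m = 0.0
    for i in range(g.shape[0]):
        a = abs(g[i])
        if a > m:
            m = a
    return m


@njit(cache=True)
def newton_solve(z, parent, k0_arr, rest, linear, clutch_nodes, clutch_off,
                 k_c, z_act, kT_p, L_c, l_III, m_sig, tau_sig, sig0,
                 tol, max_iter):
    """Damped Newton on nodal z positions; modifies z in place.

    Returns (converged, iterations, final max residual in pN).
    """
    n = z.shape[0]
    g = np.empty(n)
    d = np.empty(n)
    dz = np.empty(n)
    b = np.empty(n)
    dd = np.empty(n)
    z_try = np.empty(n)
    k_edge = _residual(z, parent, k0_arr, rest, linear, clutch_nodes,
                       clutch_off, k_c, z_act, kT_p, L_c, l_III,
                       m_sig, tau_sig, sig0, g, d)
    res = _max_abs(g)
    it = 0
    while res > tol and it < max_iter:
        it += 1
        for i in range(n):
            b[i] = g[i]
            dd[i] = d[i]
        # Eliminate leaves toward the root (parent[i] < i by construction).
        for i in range(n - 1, 0, -1):
            p = parent[i]
            w = k_edge[i] / dd[i]
            dd[p] -= k_edge[i] * w
            b[p] += w * b[i]
        dz[0] = b[0] / dd[0]
        for i in range(1, n):
            dz[i] = (b[i] + k_edge[i] * dz[parent[i]]) / dd[i]
        # Backtracking line search on the residual norm.
        alpha = 1.0
        accepted = False
        for _ in range(40):
            for i in range(n):
                z_try[i] = z[i] + alpha * dz[i]
            k_try = _residual(z_try, parent, k0_arr, rest, linear,
                              clutch_nodes, clutch_off, k_c, z_act, kT_p,
                              L_c, l_III, m_sig, tau_sig, sig0, g, d)
            res_try = _max_abs(g)
            if res_try < res:
                for i in range(n):
                    z[i] = z_try[i]
                k_edge = k_try
                res = res_try
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # Refresh state at current z and stop: no descent direction.
            k_edge = _residual(z, parent, k0_arr, rest, linear, clutch_nodes,
                               clutch_off, k_c, z_act, kT_p, L_c, l_III,
                               m_sig, tau_sig, sig0, g, d)
            res = _max_abs(g)
            break
    return res <= tol, it, res
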