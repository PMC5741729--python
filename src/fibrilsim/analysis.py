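"""Fibril morphometry, population summaries and viscoelastic classification.

Morphometry follows the model's standard measurement set: molecule count,
relaxed length L_r (all springs at rest), stretched length L_s (under
load), bound integrins, cross-section thickness T, substrate force f_sub,
plus the derived extensibility L_s/L_r and aspect ratio L_r/T.  Fluctuating
quantities are averaged over the final ten minutes of assembly.

Re-stretched fibrils fall into two phenotypes: stably stretched fibrils
(SSFs) hold the actomyosin stall force with small fluctuation, while
fluctuating stretched fibrils (FSFs) hover below stall with persistent
bind/unbind noise.  Classification thresholds (window force within 95% of
stall, coefficient of variation below 5%) are package choices exposed as
arguments; the resting stiffness is the initial slope of the force-stretch
curve during re-loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely import MultiPoint, minimum_bounding_radius

from .core import Fibril, axial_to_xy
from .errors import FitError, TopologyError, WindowError
from .params import ModelParams
from .simulator import Trajectory

SSF = "SSF"
FSF = "FSF"


@dataclass
class FibrilSummary:
    """Morphometry of one assembled fibril (final-window averages)."""
    n_fn: int
    L_r: float            #: um
    L_s: float            #: um, mean over the final window
    extensibility: float  #: L_s / L_r
    thickness: float      #: nm
    aspect: float         #: L_r / T (lengths converted to nm)
    n_integrins: float    #: mean over the final window
    f_sub: float          #: pN, mean over the final window
    seed: int | None = None


@dataclass
class RestretchResult:
    """Viscoelastic phenotype of one re-stretched fibril."""
    label: str                  #: SSF or FSF
    resting_stiffness: float    #: pN/um
    window_mean_stretch: float  #: um, final-window mean of dL
    window_mean_force: float    #: pN, final-window mean of f_sub
    n_fn: int | None = None
    seed: int | None = None


def relaxed_length(fibril: Fibril, params: ModelParams | None = None) -> float:
    """Relaxed fibril length, um: every spring at rest, propagated from root.

    Recomputed from the bond topology (not the cached positions) so it can
    serve as an independent check of the incremental bookkeeping.
    """
    p = params or fibril.params
    n = fibril.n_nodes
    parent = fibril.node_parent[:n]
    if n > 1 and np.any(parent[1:] < 0):
        raise TopologyError("fibril network is disconnected")
    z = np.empty(n)
    for i in range(n):
        base = z[parent[i]] if parent[i] >= 0 else 0.0
        z[i] = base + fibril.spring_rest[i]
    return float(z.max() + p.l_I_II) / 1000.0


def stretched_length(fibril: Fibril, params: ModelParams | None = None) -> float:
    """Current stretched fibril length, um."""
    return fibril.stretched_tip() / 1000.0


def thickness(fibril: Fibril, params: ModelParams | None = None) -> float:
    """Fibril thickness, nm: cross-section diameter of the occupied sites.

    Diameter of the smallest circle enclosing the occupied lattice-site
    centers, plus one lattice spacing for the width of a site itself.
    """
    p = params or fibril.params
    pts = [axial_to_xy(c, p.d_lat) for c in fibril.lattice]
    if not pts:
        raise ValueError("fibril has no molecules")
    if len(pts) == 1:
        return p.d_lat
    radius = minimum_bounding_radius(MultiPoint(pts))
    return 2.0 * float(radius) + p.d_lat


def summarize(traj: Trajectory, params: ModelParams | None = None,
              window: float = 600.0) -> FibrilSummary:
    """Morphometry of one assembly run, averaged over the final window (s).

    L_s, f_sub and the integrin count are window means; n_fn and L_r are
    monotone and taken from the final snapshot, as is the thickness.
    """
    p = params or (traj.fibril.params if traj.fibril is not None else ModelParams())
    span = traj.t[-1] - traj.t[0]
    if span < window:
        raise WindowError(f"trajectory spans {span:.0f} s < window {window:.0f} s")
    sel = traj.t >= traj.t[-1] - window
    L_r = float(traj.L_r[-1])
    L_s = float(traj.L_s[sel].mean())
    T = thickness(traj.fibril, p) if traj.fibril is not None else np.nan
    return FibrilSummary(
        n_fn=int(traj.n_fn[-1]), L_r=L_r, L_s=L_s,
        extensibility=L_s / L_r, thickness=T,
        aspect=(L_r * 1000.0) / T,
        n_integrins=float(traj.n_integrins[sel].mean()),
        f_sub=float(traj.f_sub[sel].mean()),
        seed=traj.meta.get("seed"))


def classify_restretch(traj: Trajectory, params: ModelParams | None = None,
                       window: float = 120.0, force_fraction: float = 0.95,
                       cv_max: float = 0.05) -> RestretchResult:
    """Label a re-stretch trajectory as SSF or FSF.

    SSF: the final-window mean substrate force reaches ``force_fraction``
    of the stall force and its coefficient of variation stays below
    ``cv_max``; anything else is an FSF.  Window means of stretch and force
    are reported for both labels.
    """
    p = params or (traj.fibril.params if traj.fibril is not None else ModelParams())
    span = traj.t[-1] - traj.t[0]
    if span < window:
        raise WindowError(f"trajectory spans {span:.0f} s < window {window:.0f} s")
    sel = traj.t >= traj.t[-1] - window
    f = traj.f_sub[sel]
    mean_f = float(f.mean())
    cv = float(f.std() / mean_f) if mean_f > 0 else np.inf
    label = SSF if (mean_f >= force_fraction * p.f_stall and cv < cv_max) else FSF
    return RestretchResult(
        label=label,
        resting_stiffness=resting_stiffness(traj),
        window_mean_stretch=float(traj.dL[sel].mean()),
        window_mean_force=mean_f,
        n_fn=int(traj.n_fn[-1]), seed=traj.meta.get("seed"))


def resting_stiffness(traj: Trajectory, fit_fraction: float = 0.10,
                      plateau_window: float = 120.0) -> float:
    """Initial slope of the force-stretch curve at zero stretch, pN/um.

    Least-squares line through the initial monotone-loading samples whose
    stretch stays below ``fit_fraction`` of the plateau stretch (the mean
    over the trajectory's final ``plateau_window`` seconds).
    """
    dL = traj.dL
    f = traj.f_sub
    sel = traj.t >= traj.t[-1] - plateau_window
    plateau = float(dL[sel].mean())
    if plateau <= 0:
        plateau = float(dL.max())
    cutoff = fit_fraction * plateau
    idx = np.nonzero(dL > cutoff)[0]
    end = idx[0] if idx.size else len(dL)
    if end < 3:
        raise FitError(
            f"only {end} samples with stretch <= {fit_fraction:.0%} of plateau")
    slope, _ = np.polyfit(dL[:end], f[:end], 1)
    return float(slope)


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _slope(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.std(x) == 0:
        return float("nan")
    return float(np.polyfit(x, y, 1)[0])


def _mean_se(values) -> tuple:
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    if v.size == 1:
        return float(v.mean()), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def population_table(summaries) -> pd.DataFrame:
    """Mean +/- standard error of the standard morphometry columns."""
    rows = {}
    for col in ("n_fn", "L_r", "L_s", "extensibility", "aspect"):
        vals = [getattr(s, col) for s in summaries]
        mean, se = _mean_se(vals)
        rows[col] = {"mean": mean, "se": se, "n": len(vals)}
    return pd.DataFrame(rows).T


def population_analysis(summaries, restretch_results=None) -> dict:
    """Population statistics over assembled (and optionally re-stretched) fibrils.

    Returns a dict with a morphometry table, per-label counts/fractions,
    per-label mean +/- SE, and the correlation/slope statistics of the
    viscoelastic analysis.  Degenerate (zero-variance) correlations are
    reported as NaN.
    """
    if len(summaries) < 3:
        raise ValueError("population analysis needs at least 3 fibrils")
    out = {"morphometry": population_table(summaries)}
    if not restretch_results:
        return out
    by_label = {SSF: [r for r in restretch_results if r.label == SSF],
                FSF: [r for r in restretch_results if r.label == FSF]}
    n_tot = len(restretch_results)
    label_rows = {}
    for label, group in by_label.items():
        stiff_mean, stiff_se = _mean_se(r.resting_stiffness for r in group)
        nfn_mean, nfn_se = _mean_se(r.n_fn for r in group)
        label_rows[label] = {
            "count": len(group), "fraction": len(group) / n_tot,
            "n_fn_mean": nfn_mean, "n_fn_se": nfn_se,
            "resting_stiffness_mean": stiff_mean,
            "resting_stiffness_se": stiff_se,
        }
    out["labels"] = pd.DataFrame(label_rows).T
    allr = restretch_results
    fsf, ssf = by_label[FSF], by_label[SSF]
    out["correlations"] = pd.Series({
        "stiffness_vs_nfn": _pearson([r.n_fn for r in allr],
                                     [r.resting_stiffness for r in allr]),
        "fsf_stretch_vs_nfn": _pearson([r.n_fn for r in fsf],
                                       [r.window_mean_stretch for r in fsf]),
        "fsf_force_vs_nfn": _pearson([r.n_fn for r in fsf],
                                     [r.window_mean_force for r in fsf]),
        "ssf_stretch_vs_nfn": _pearson([r.n_fn for r in ssf],
                                       [r.window_mean_stretch for r in ssf]),
        "fsf_force_vs_stretch": _pearson([r.window_mean_stretch for r in fsf],
                                         [r.window_mean_force for r in fsf]),
    })
    out["slopes"] = pd.Series({
        "fsf_force_vs_stretch": _slope([r.window_mean_stretch for r in fsf],
                                       [r.window_mean_force for r in fsf]),
        "ssf_force_vs_stretch": _slope([r.window_mean_stretch for r in ssf],
                                       [r.window_mean_force for r in ssf]),
    })
    return out


def brute_force_enclosing_diameter(points) -> float:
    """O(n^3) smallest-enclosing-circle diameter - oracle for thickness().

    Checks every circle through two (diametral) or three points and returns
    the diameter of the smallest one covering all points.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 1:
        return 0.0
    best = np.inf
    eps = 1e-9

    def covers(c, r):
        return np.all(np.hypot(*(pts - c).T) <= r + eps)

    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2.0
            r = np.hypot(*(pts[i] - pts[j])) / 2.0
            if r < best and covers(c, r):
                best = r
            for k in range(j + 1, n):
                ax, ay = pts[i]
                bx, by = pts[j]
                cx, cy = pts[k]
                dmat = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(dmat) < 1e-12:
                    continue
                ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                      + (cx**2 + cy**2) * (ay - by)) / dmat
                uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                      + (cx**2 + cy**2) * (bx - ax)) / dmat
                c = np.array([ux, uy])
                r = np.hypot(ax - ux, ay - uy)
                if r < best and covers(c, r):
                    best = r
    return 2.0 * best
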