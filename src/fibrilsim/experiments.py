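"""The in-silico experiment matrix: hypothesis catalogue, population
drivers, the (k2^0, eps_t) parameter sweep and the kinetic-constant
calibration procedure.

A :class:`Hypothesis` names a cryptic-binding-site set plus a stiffness
variant: baseline profile, per-simulation scrambled domain order, constant
stiffness at the profile minimum/mean/maximum, and exposure-threshold
scaling.  The shipped catalogue covers every condition of the study design:
fifteen single-site models, the four multi-site models (III_1-3, III_1-9,
III_1-3,11, III_1-15) and the six domain-property variations, each with its
replicate count.  ``scale`` arguments reduce replicate counts for
desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import classify_restretch, population_analysis, summarize
from .core import make_profile
from .errors import CalibrationError, ConfigError
from .params import ModelParams, default_stiffness_values, \
    validate_stiffness_profile
from .simulator import restretch_protocol, simulate_assembly

VARIANTS = ("baseline", "scrambled", "constant_min", "constant_mean",
            "constant_max")


@dataclass(frozen=True)
class Hypothesis:
    """One named experimental condition."""
    name: str
    site_set: frozenset
    stiffness_variant: str = "baseline"
    eps_t_scale: float = 1.0          #: 0.5, 1 or 2 in the catalogue
    n_sims: int = 100
    base_seed: int = 0
    k0_values: tuple = field(default_factory=lambda:
                             tuple(default_stiffness_values()))

    def __post_init__(self):
        if self.stiffness_variant not in VARIANTS:
            raise ConfigError(f"unknown stiffness variant "
                              f"{self.stiffness_variant!r}; one of {VARIANTS}")
        bad = set(self.site_set) - set(range(1, 16))
        if bad:
            raise ConfigError(f"site indices outside 1..15: {sorted(bad)}")
        if self.eps_t_scale <= 0:
            raise ConfigError("eps_t_scale must be positive")
        validate_stiffness_profile(self.k0_values)

    def scaled_params(self, params: ModelParams) -> ModelParams:
        """Apply the hypothesis' exposure-threshold scaling to the params."""
        if self.eps_t_scale == 1.0:
            return params
        return params.with_(eps_t=params.eps_t * self.eps_t_scale)

    def with_(self, **kw) -> "Hypothesis":
        return replace(self, **kw)


def resolve_profile(hyp: Hypothesis, params: ModelParams,
                    rng: np.random.Generator):
    """Build the 15-domain stiffness profile for one simulation.

    The scrambled variant permutes the same 15 values with the
    per-simulation generator, so each replicate gets its own domain order.
    """
    vals = np.asarray(hyp.k0_values, dtype=float)
    if hyp.stiffness_variant == "scrambled":
        vals = rng.permutation(vals)
    elif hyp.stiffness_variant == "constant_min":
        vals = np.full(15, vals.min())
    elif hyp.stiffness_variant == "constant_mean":
        vals = np.full(15, vals.mean())
    elif hyp.stiffness_variant == "constant_max":
        vals = np.full(15, vals.max())
    return make_profile(vals)


def catalogue() -> dict:
    """Every named condition of the study design, keyed by name."""
    cat = {}
    for d in range(1, 16):
        name = f"III_{d}"
        n = 500 if d == 11 else 100
        cat[name] = Hypothesis(name=name, site_set=frozenset({d}), n_sims=n)
    multi = {
        "III_1-3": (frozenset(range(1, 4)), 500),
        "III_1-9": (frozenset(range(1, 10)), 500),
        "III_1-3,11": (frozenset({1, 2, 3, 11}), 500),
        "III_1-15": (frozenset(range(1, 16)), 1000),
    }
    for name, (sites, n) in multi.items():
        cat[name] = Hypothesis(name=name, site_set=sites, n_sims=n)
    all15 = frozenset(range(1, 16))
    cat["scrambled"] = Hypothesis("scrambled", all15, "scrambled", n_sims=1000)
    cat["constant_min"] = Hypothesis("constant_min", all15, "constant_min",
                                     n_sims=500)
    cat["constant_mean"] = Hypothesis("constant_mean", all15, "constant_mean",
                                      n_sims=1000)
    cat["constant_max"] = Hypothesis("constant_max", all15, "constant_max",
                                     n_sims=500)
    cat["eps_t_half"] = Hypothesis("eps_t_half", all15, eps_t_scale=0.5,
                                   n_sims=500)
    cat["eps_t_double"] = Hypothesis("eps_t_double", all15, eps_t_scale=2.0,
                                     n_sims=500)
    return cat


# ---------------------------------------------------------------------------
# Population drivers
# ---------------------------------------------------------------------------

_SUMMARY_COLS = ["seed", "n_fn", "L_r", "L_s", "extensibility", "thickness",
                 "aspect", "n_integrins", "f_sub"]
_RESTRETCH_COLS = ["seed", "n_fn", "label", "resting_stiffness",
                   "window_mean_stretch", "window_mean_force"]


def run_experiment(hypothesis: Hypothesis, params: ModelParams | None = None,
                   out_dir=None, scale: float = 1.0,
                   restretch: bool = False,
                   summary_window: float | None = None) -> dict:
    """Run the replicate population for one hypothesis.

    Seeds are ``base_seed + i`` for i in 0..n-1 (n = round(n_sims*scale)),
    one independent generator per simulation, so any row regenerates
    bit-identically from its seed.  If ``out_dir`` holds a previous
    per-fibril CSV, already-computed seeds are reused (the run is resumable
    by seed index); per-seed failures are recorded and the run continues.
    """
    params = params or ModelParams()
    n = max(1, int(round(hypothesis.n_sims * scale)))
    seeds = [hypothesis.base_seed + i for i in range(n)]
    window = summary_window if summary_window is not None \
        else min(600.0, params.duration / 2.0)

    out_dir = Path(out_dir) if out_dir is not None else None
    done: dict[int, dict] = {}
    done_rs: dict[int, dict] = {}
    if out_dir is not None:
        per_fibril = out_dir / f"{hypothesis.name}_fibrils.csv"
        if per_fibril.exists():
            prev = pd.read_csv(per_fibril)
            done = {int(r["seed"]): dict(r) for _, r in prev.iterrows()}
        rs_path = out_dir / f"{hypothesis.name}_restretch.csv"
        if restretch and rs_path.exists():
            prev = pd.read_csv(rs_path)
            done_rs = {int(r["seed"]): dict(r) for _, r in prev.iterrows()}

    rows, rs_rows, failures = [], [], []
    for seed in seeds:
        if seed in done and (not restretch or seed in done_rs):
            rows.append(done[seed])
            if restretch:
                rs_rows.append(done_rs[seed])
            continue
        try:
            traj = simulate_assembly(hypothesis, params, seed=seed,
                                     log_events=False)
            s = summarize(traj, params, window=window)
            rows.append({c: getattr(s, c) for c in _SUMMARY_COLS})
            if restretch:
                rt = restretch_protocol(traj.fibril, params, seed=seed + 1,
                                        log_events=False)
                r = classify_restretch(rt, params)
                rs_rows.append({c: getattr(r, c) for c in _RESTRETCH_COLS})
        except Exception as err:  # noqa: BLE001 - record and continue
            failures.append({"seed": seed, "error": repr(err)})

    frame = pd.DataFrame(rows, columns=_SUMMARY_COLS)
    result = {"hypothesis": hypothesis, "fibrils": frame,
              "failures": pd.DataFrame(failures)}
    if restretch:
        result["restretch"] = pd.DataFrame(rs_rows, columns=_RESTRETCH_COLS)
    if len(frame) >= 3:
        from .analysis import population_table
        result["population"] = population_table(
            [_row_to_summary(r) for _, r in frame.iterrows()])
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / f"{hypothesis.name}_fibrils.csv", index=False)
        if restretch:
            result["restretch"].to_csv(
                out_dir / f"{hypothesis.name}_restretch.csv", index=False)
        if "population" in result:
            result["population"].to_csv(
                out_dir / f"{hypothesis.name}_population.csv")
        if failures:
            result["failures"].to_csv(
                out_dir / f"{hypothesis.name}_failures.csv", index=False)
        _write_run_log(out_dir, hypothesis, params, seeds)
    return result


def _row_to_summary(row):
    from .analysis import FibrilSummary
    return FibrilSummary(
        n_fn=int(row["n_fn"]), L_r=row["L_r"], L_s=row["L_s"],
        extensibility=row["extensibility"], thickness=row["thickness"],
        aspect=row["aspect"], n_integrins=row["n_integrins"],
        f_sub=row["f_sub"], seed=int(row["seed"]))


def _write_run_log(out_dir: Path, hyp: Hypothesis, params: ModelParams,
                   seeds) -> None:
    import hashlib
    cfg = {"hypothesis": {"name": hyp.name, "site_set": sorted(hyp.site_set),
                          "variant": hyp.stiffness_variant,
                          "eps_t_scale": hyp.eps_t_scale},
           "model": params.to_dict(), "seeds": list(seeds)}
    blob = json.dumps(cfg, sort_keys=True).encode()
    cfg["config_sha256"] = hashlib.sha256(blob).hexdigest()
    with open(out_dir / f"{hyp.name}_runlog.json", "w") as fh:
        json.dump(cfg, fh, indent=1)


def sweep_k2_epst(params: ModelParams | None = None,
                  k2_values=(0.2, 0.4, 0.6, 0.8, 1.0),
                  eps_t_values=(7.5, 15.0, 30.0),
                  n_sims: int = 100, base_seed: int = 0,
                  scale: float = 1.0, out_dir=None) -> pd.DataFrame:
    """Mean morphometry on the (k2^0, eps_t) grid, single III_2 site.

    Each cell replaces domain 2's resting stiffness and the exposure
    threshold, then averages n_fn, L_r and L_s over the replicates.  The
    (0.8 pN/nm, 15 A) cell is the baseline single-III_2 condition.
    """
    params = params or ModelParams()
    base_k0 = default_stiffness_values()
    rows = []
    for k2 in k2_values:
        for eps in eps_t_values:
            k0 = base_k0.copy()
            k0[1] = k2
            hyp = Hypothesis(name=f"III_2_k{k2}_e{eps}",
                             site_set=frozenset({2}),
                             n_sims=n_sims, base_seed=base_seed,
                             k0_values=tuple(k0))
            cell = run_experiment(hyp, params.with_(eps_t=eps), scale=scale)
            f = cell["fibrils"]
            rows.append({"k2_0": k2, "eps_t": eps, "n": len(f),
                         "n_fn_mean": f["n_fn"].mean(),
                         "L_r_mean": f["L_r"].mean(),
                         "L_s_mean": f["L_s"].mean()})
    grid = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        grid.to_csv(out_dir / "sweep_k2_epst.csv", index=False)
    return grid


# ---------------------------------------------------------------------------
# Calibration of the unprinted kinetic constants
# ---------------------------------------------------------------------------

DEFAULT_TARGETS = {
    "allsite_n_fn": (380.0, 450.0),          #: III_1-15 mean molecule count
    "allsite_extensibility": (2.9, 3.6),     #: III_1-15 mean L_s/L_r
    "single_site_n_fn_max": 10.0,            #: III_2 mean molecule count bound
}

#: Free kinetic constants the calibration may move, with log-spaced ranges.
DEFAULT_SEARCH = {
    "k_fn": np.geomspace(5e-4, 5e-2, 7),
    "k_exp": np.geomspace(0.25, 4.0, 3),
}


def evaluate_targets(params: ModelParams, n_seeds: int = 20,
                     base_seed: int = 0) -> dict:
    """Measure the calibration observables at the given parameters."""
    all15 = Hypothesis("III_1-15", frozenset(range(1, 16)), n_sims=n_seeds,
                       base_seed=base_seed)
    single = Hypothesis("III_2", frozenset({2}), n_sims=n_seeds,
                        base_seed=base_seed)
    r_all = run_experiment(all15, params)
    r_one = run_experiment(single, params)
    return {
        "allsite_n_fn": float(r_all["fibrils"]["n_fn"].mean()),
        "allsite_extensibility":
            float(r_all["fibrils"]["extensibility"].mean()),
        "single_site_n_fn": float(r_one["fibrils"]["n_fn"].mean()),
    }


def _meets(scores: dict, targets: dict) -> bool:
    lo, hi = targets["allsite_n_fn"]
    elo, ehi = targets["allsite_extensibility"]
    return (lo <= scores["allsite_n_fn"] <= hi
            and elo <= scores["allsite_extensibility"] <= ehi
            and scores["single_site_n_fn"] < targets["single_site_n_fn_max"])


def calibrate(base_params: ModelParams | None = None,
              search: dict | None = None, targets: dict | None = None,
              n_seeds: int = 20, base_seed: int = 0,
              evaluator=None) -> ModelParams:
    """Grid-search the free kinetic constants until every target is met.

    Walks the (log-spaced) Cartesian grid in a fixed order and returns the
    first :class:`ModelParams` whose 20-seed evaluation lands inside all
    target windows; raises :class:`CalibrationError` (carrying the
    best-scoring point) if none does.  ``evaluator`` may replace
    :func:`evaluate_targets` for testing or cheaper proxies.
    """
    import itertools

    base_params = base_params or ModelParams()
    search = search if search is not None else DEFAULT_SEARCH
    targets = targets if targets is not None else DEFAULT_TARGETS
    evaluator = evaluator or (
        lambda p: evaluate_targets(p, n_seeds=n_seeds, base_seed=base_seed))

    names = list(search)
    best = None
    points = [None]  # the base point first: if it already passes, keep it
    points += list(itertools.product(*(search[k] for k in names)))
    for combo in points:
        if combo is None:
            params = base_params
        else:
            params = base_params.with_(**dict(zip(names, map(float, combo))))
        scores = evaluator(params)
        if _meets(scores, targets):
            return params
        lo, hi = targets["allsite_n_fn"]
        mid = 0.5 * (lo + hi)
        badness = abs(scores["allsite_n_fn"] - mid) / mid \
            + max(0.0, scores["single_site_n_fn"]
                  - targets["single_site_n_fn_max"])
        point = dict(zip(names, map(float, combo))) if combo is not None \
            else {}
        if best is None or badness < best[0]:
            best = (badness, point, scores)
    raise CalibrationError(
        "no parameter set in the searched box met all calibration targets",
        best={"params": best[1], "scores": best[2]} if best else {})


# ---------------------------------------------------------------------------
# Run configuration (YAML/JSON)
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load and validate a run configuration document.

    Sections: ``model`` (ModelParams overrides), ``hypothesis`` (catalogue
    name, or an inline site_set/variant definition) and ``run`` (n_sims,
    base_seed, scale, restretch, out).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
            else json.load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    bad = set(doc) - {"model", "hypothesis", "run"}
    if bad:
        raise ConfigError(f"unknown config section(s): {sorted(bad)}")
    params = ModelParams.from_dict(doc.get("model", {}))
    hyp_doc = doc.get("hypothesis", {})
    if isinstance(hyp_doc, str):
        cat = catalogue()
        if hyp_doc not in cat:
            raise ConfigError(f"unknown catalogue hypothesis {hyp_doc!r}")
        hyp = cat[hyp_doc]
    else:
        allowed = {"name", "site_set", "stiffness_variant", "eps_t_scale",
                   "n_sims", "base_seed", "k0_values"}
        bad = set(hyp_doc) - allowed
        if bad:
            raise ConfigError(f"unknown hypothesis key(s): {sorted(bad)}")
        hyp_doc = dict(hyp_doc)
        hyp_doc["site_set"] = frozenset(hyp_doc.get("site_set", range(1, 16)))
        if "k0_values" in hyp_doc:
            hyp_doc["k0_values"] = tuple(hyp_doc["k0_values"])
        hyp_doc.setdefault("name", "custom")
        hyp = Hypothesis(**hyp_doc)
    run = doc.get("run", {})
    bad = set(run) - {"n_sims", "base_seed", "scale", "restretch", "out"}
    if bad:
        raise ConfigError(f"unknown run key(s): {sorted(bad)}")
    if "n_sims" in run:
        hyp = hyp.with_(n_sims=int(run["n_sims"]))
    if "base_seed" in run:
        hyp = hyp.with_(base_seed=int(run["base_seed"]))
    return {"params": params, "hypothesis": hyp, "run": run}
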