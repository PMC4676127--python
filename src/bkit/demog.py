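"""Two-population demographic models fit to the joint AFS.

The expectation engine is a discrete Wright-Fisher frequency-grid chain,
not a PDE solver and not a coalescent simulator: the density of segregating
sites over derived-allele frequency is propagated by binomial resampling
(drift), deterministic migration and size-change maps, and a constant
influx of new singletons.  Conventions follow the usual diffusion scaling:

* sizes ``nu`` are ratios of the ancestral (reference) diploid size;
* times ``tau`` are in units of 2 N_ref generations;
* migration ``M`` is 2 N_ref m with m the per-lineage per-generation rate;
* ``theta`` = 4 N_ref mu L; every expectation is linear in theta, so fits
  profile it out analytically.

A chain step applies the binomial transition of the grid (drift variance
x(1-x)/G) with probability ``alpha = G dt / nu``, which reproduces the
diffusion drift rate of a population of relative size nu; the singleton
influx per step, theta G dt / 2, then yields the classical equilibrium
spectrum E[eta_i] = nu theta / i.

Four fitted scenarios: IM (split with symmetric migration), BIM (ancestral
bottleneck then split), SBR (split, bottleneck, recovery) and ISB
(ancestral growth, split, independent bottlenecks lasting to the present).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import binom as binom_dist
from scipy.stats import chi2

from bkit.afs import JointAFS, composite_loglik, sample_projection_matrix

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "IM": ("nu1", "nu2", "tau_split", "M"),
    "BIM": ("nu_b", "tau_b", "nu1", "nu2", "tau_split"),
    "SBR": ("tau_split", "nu1_b", "nu2_b", "tau_b", "nu1_r", "nu2_r", "tau_r"),
    "ISB": ("nu_g", "tau_g", "tau_split", "nu1_b", "nu2_b", "tau_b1", "tau_b2"),
}

# parameters optimised as a fraction of tau_split (smooth nesting of the
# epoch-ordering constraints); everything else is optimised in log space
_FRACTION_OF_SPLIT = {
    "ISB": {"tau_b1": "tau_split", "tau_b2": "tau_split"},
}

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu": (1e-3, 50.0),
    "tau": (1e-4, 5.0),
    "M": (0.0, 20.0),
}


def _bounds_for(name: str) -> tuple[float, float]:
    if name.startswith("nu"):
        return DEFAULT_BOUNDS["nu"]
    if name.startswith("tau"):
        return DEFAULT_BOUNDS["tau"]
    return DEFAULT_BOUNDS["M"]


@dataclass
class DemographicModel:
    model_id: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model_id!r}")
        missing = [k for k in MODEL_PARAMS[self.model_id] if k not in self.params]
        if missing:
            raise ValueError(f"missing parameters {missing}")
        for k, v in self.params.items():
            if k.startswith("nu") and v <= 0:
                raise ValueError(f"{k} must be > 0")
            if (k.startswith("tau") or k == "M") and v < 0:
                raise ValueError(f"{k} must be >= 0")
        p = self.params
        if self.model_id == "SBR" and p["tau_b"] + p["tau_r"] > p["tau_split"]:
            raise ValueError("SBR requires tau_b + tau_r <= tau_split")
        if self.model_id == "ISB" and max(p["tau_b1"], p["tau_b2"]) > p["tau_split"]:
            raise ValueError("ISB requires tau_b1, tau_b2 <= tau_split")


@dataclass
class FitResult:
    model_id: str
    params: dict[str, float]
    loglik: float
    n_starts: int
    converged: int
    start_logliks: list[float] = field(default_factory=list)


# --- the Wright-Fisher grid engine -----------------------------------------

class SpectrumEngine:
    """Expected-AFS computations on a frequency grid of size ``grid``."""

    def __init__(self, grid: int = 100):
        if grid < 8:
            raise ValueError("grid too small")
        self.grid = grid
        self.max_migration_chunks = 600
        freqs = np.arange(grid + 1) / grid
        # binomial drift transition: row i -> Binomial(grid, i/grid)
        j = np.arange(grid + 1)
        self._B = binom_dist.pmf(j[None, :], grid, freqs[:, None])
        # mutation-influx profile: solve (I - B^T) eta* = c for eta*_i = 1/i,
        # then keep only the low-count entries (new mutations enter at low
        # frequency; the high-count entries of the exact solution merely
        # compensate the chain's absorption flux and must not be injected).
        # The retained mass sits on counts 1-3 and removes most of the
        # naive inject-at-count-1 low-frequency bias; the stationary
        # spectrum of the actual dynamics is then solved exactly.
        eta_star = np.zeros(grid + 1)
        eta_star[1:grid] = 1.0 / np.arange(1, grid)
        c = eta_star - self._B.T @ eta_star
        c[0] = 0.0
        c[6:] = 0.0
        self._influx = c
        eta0 = np.zeros(grid + 1)
        eta0[1:grid] = np.linalg.solve(
            np.eye(grid - 1) - self._B[1:grid, 1:grid].T, c[1:grid])
        self._eta0 = eta0

    # -- 1D ------------------------------------------------------------

    def equilibrium_1d(self, theta: float = 1.0) -> np.ndarray:
        """Stationary spectrum of the chain (theta/i to within ~1 %)."""
        return theta * self._eta0

    def _epoch_steps(self, nu_min: float, tau: float) -> int:
        # per-step drift-mixture weight alpha = G dt / nu must stay <= 1,
        # and dt <= 1/G keeps the time discretisation fine
        return max(1, int(np.ceil(tau * self.grid / min(nu_min, 1.0))))

    def evolve_1d(self, phi: np.ndarray, nu: float, tau: float,
                  theta: float = 1.0) -> np.ndarray:
        """Advance a 1D spectrum through an epoch of size ``nu``, length ``tau``.

        The epoch map is phi -> A^T phi + f per step; m steps are composed
        by binary doubling, so bottlenecks of any severity cost O(log m).
        """
        if tau <= 0:
            return phi
        G = self.grid
        m = self._epoch_steps(nu, tau)
        dt = tau / m
        alpha = G * dt / nu
        A = (1 - alpha) * np.eye(G + 1) + alpha * self._B
        f = theta * G * dt * self._influx
        At, ft = _power_affine_1d(A, f, m)
        return At.T @ phi + ft

    # -- 2D ------------------------------------------------------------

    def split(self, phi1d: np.ndarray) -> np.ndarray:
        """Both daughter populations inherit the ancestral frequency."""
        G = self.grid
        phi = np.zeros((G + 1, G + 1))
        np.fill_diagonal(phi, phi1d)
        return phi

    def evolve_2d(self, phi: np.ndarray, nu1: float, nu2: float, tau: float,
                  m12: float = 0.0, m21: float = 0.0,
                  theta: float = 1.0) -> np.ndarray:
        """Advance the joint spectrum through a 2D epoch.

        ``m12`` is the scaled rate (2 N_ref m) at which population-1
        lineages are replaced by migrants from population 2, and vice versa
        for ``m21``; migration acts as a deterministic frequency map.
        """
        if tau <= 0:
            return phi
        G = self.grid
        mrate = max(m12, m21)

        def drift_segment(phi: np.ndarray, span: float) -> np.ndarray:
            # map phi -> A1^T phi A2 + C for the whole span, composed by
            # binary doubling: severe bottlenecks cost O(log n_steps)
            n_steps = self._epoch_steps(min(nu1, nu2), span)
            dt = span / n_steps
            a1 = G * dt / nu1
            a2 = G * dt / nu2
            eye = np.eye(G + 1)
            A1 = (1 - a1) * eye + a1 * self._B
            A2 = (1 - a2) * eye + a2 * self._B
            C = np.zeros_like(phi)
            C[:, 0] += theta * G * dt * self._influx
            C[0, :] += theta * G * dt * self._influx
            A1t, A2t, Ct = _power_affine_2d(A1, A2, C, n_steps)
            return A1t.T @ phi @ A2t + Ct

        if mrate == 0:
            return drift_segment(phi, tau)
        # operator splitting: drift in chunks short enough that the
        # deterministic migration shift stays below half a grid cell
        n_chunks = max(1, int(np.ceil(2.0 * tau * mrate * G)))
        if n_chunks > self.max_migration_chunks:
            raise ValueError(
                f"migration epoch needs {n_chunks} chunks "
                f"(> {self.max_migration_chunks}); parameters out of range")
        dt_c = tau / n_chunks
        for _ in range(n_chunks):
            phi = drift_segment(phi, dt_c)
            if m12 > 0:
                phi = _migrate_axis0(phi, m12 * dt_c)
            if m21 > 0:
                phi = _migrate_axis0(phi.T, m21 * dt_c).T
        return phi

    def project(self, phi: np.ndarray, n1: int, n2: int) -> np.ndarray:
        """Binomial sampling of the grid density into an (n1+1)x(n2+1) AFS."""
        P1 = sample_projection_matrix(self.grid, n1)
        P2 = sample_projection_matrix(self.grid, n2)
        M = P1.T @ phi @ P2
        M[0, 0] = 0.0
        M[n1, n2] = 0.0
        return M


def _power_affine_1d(A: np.ndarray, f: np.ndarray, m: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Compose m applications of phi -> A^T phi + f by binary doubling."""
    At = np.eye(A.shape[0])
    ft = np.zeros_like(f)
    P, g = A, f
    while m:
        if m & 1:
            # apply accumulated segment first, then the current power
            ft = P.T @ ft + g
            At = At @ P
        m >>= 1
        if m:
            g = P.T @ g + g
            P = P @ P
    return At, ft


def _power_affine_2d(A1: np.ndarray, A2: np.ndarray, C: np.ndarray, m: int
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compose m applications of phi -> A1^T phi A2 + C by binary doubling."""
    n = A1.shape[0]
    A1t = np.eye(n)
    A2t = np.eye(n)
    Ct = np.zeros_like(C)
    P1, P2, F = A1, A2, C
    while m:
        if m & 1:
            Ct = P1.T @ Ct @ P2 + F
            A1t = A1t @ P1
            A2t = A2t @ P2
        m >>= 1
        if m:
            F = P1.T @ F @ P2 + F
            P1 = P1 @ P1
            P2 = P2 @ P2
    return A1t, A2t, Ct


def _migrate_axis0(phi: np.ndarray, delta: float) -> np.ndarray:
    """Deterministic migration x1' = x1 + delta (x2 - x1), mass-preserving.

    Mass in cell (i, j) moves to the fractional row i + delta (j - i) and is
    split linearly between the two neighbouring rows.
    """
    G = phi.shape[0] - 1
    i = np.arange(G + 1)[:, None].astype(float)
    j = np.arange(G + 1)[None, :].astype(float)
    target = i + delta * (j - i)
    lo = np.floor(target).astype(int)
    frac = target - lo
    hi = np.clip(lo + 1, 0, G)
    lo = np.clip(lo, 0, G)
    out = np.zeros_like(phi)
    cols = np.broadcast_to(np.arange(G + 1)[None, :], phi.shape)
    np.add.at(out, (lo, cols), phi * (1 - frac))
    np.add.at(out, (hi, cols), phi * frac)
    return out


def expected_afs(model: DemographicModel, n1: int, n2: int,
                 grid: int | SpectrumEngine = 100,
                 theta: float = 1.0) -> np.ndarray:
    """Expected joint AFS under a demographic model (corners masked).

    The grid must be comfortably larger than the sample sizes; the
    expectation is linear in ``theta``.
    """
    engine = grid if isinstance(grid, SpectrumEngine) else SpectrumEngine(grid)
    if engine.grid < 4 * max(n1, n2):
        raise ValueError("grid must be at least 4x the larger sample size")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0:
        return np.zeros((n1 + 1, n2 + 1))
    p = model.params
    eta = engine.equilibrium_1d(theta=theta)
    mid = model.model_id
    if mid == "IM":
        phi = engine.split(eta)
        phi = engine.evolve_2d(phi, p["nu1"], p["nu2"], p["tau_split"],
                               m12=p["M"], m21=p["M"], theta=theta)
    elif mid == "BIM":
        eta = engine.evolve_1d(eta, p["nu_b"], p["tau_b"], theta=theta)
        phi = engine.split(eta)
        phi = engine.evolve_2d(phi, p["nu1"], p["nu2"], p["tau_split"],
                               theta=theta)
    elif mid == "SBR":
        phi = engine.split(eta)
        t_anc = p["tau_split"] - p["tau_b"] - p["tau_r"]
        phi = engine.evolve_2d(phi, 1.0, 1.0, t_anc, theta=theta)
        phi = engine.evolve_2d(phi, p["nu1_b"], p["nu2_b"], p["tau_b"],
                               theta=theta)
        phi = engine.evolve_2d(phi, p["nu1_r"], p["nu2_r"], p["tau_r"],
                               theta=theta)
    elif mid == "ISB":
        eta = engine.evolve_1d(eta, p["nu_g"], p["tau_g"], theta=theta)
        phi = engine.split(eta)
        # piecewise epochs: each population drops to its bottleneck size at
        # its own onset time before present
        onsets = sorted({p["tau_b1"], p["tau_b2"]}, reverse=True)
        t_now = p["tau_split"]
        size1, size2 = p["nu_g"], p["nu_g"]
        for onset in onsets + [0.0]:
            span = t_now - onset
            if span > 0:
                phi = engine.evolve_2d(phi, size1, size2, span, theta=theta)
            if onset == p["tau_b1"]:
                size1 = p["nu1_b"]
            if onset == p["tau_b2"]:
                size2 = p["nu2_b"]
            t_now = onset
    else:
        raise ValueError(mid)
    return engine.project(phi, n1, n2)


def isb_init_from_sbr(sbr_params: Mapping[str, float]) -> dict[str, float]:
    """Map a fitted SBR optimum onto the ISB parameter space.

    When SBR's recovery sizes stay near its bottleneck sizes the model is
    close to ISB with bottlenecks of the combined duration; used as an
    informed extra start.
    """
    ts = sbr_params["tau_split"]
    tb = min(0.999 * ts, sbr_params["tau_b"] + sbr_params["tau_r"])
    return {
        "nu_g": 1.0,
        "tau_g": 1e-3,
        "tau_split": ts,
        "nu1_b": sbr_params["nu1_r"],
        "nu2_b": sbr_params["nu2_r"],
        "tau_b1": tb,
        "tau_b2": tb,
    }


def expected_sfs_1d(n: int, grid: int | SpectrumEngine = 200,
                    theta: float = 1.0) -> np.ndarray:
    """Equilibrium single-population sample spectrum (neutral limit)."""
    engine = grid if isinstance(grid, SpectrumEngine) else SpectrumEngine(grid)
    eta = engine.equilibrium_1d(theta=theta)
    P = sample_projection_matrix(engine.grid, n)
    out = P.T @ eta
    out[0] = 0.0
    out[n] = 0.0
    return out


# --- fitting ----------------------------------------------------------------

def _to_internal(model_id: str, params: Mapping[str, float]) -> np.ndarray:
    frac = _FRACTION_OF_SPLIT.get(model_id, {})
    vec = []
    for name in MODEL_PARAMS[model_id]:
        v = params[name]
        if name in frac:
            f = np.clip(v / max(params[frac[name]], 1e-12), 1e-6, 1 - 1e-6)
            vec.append(np.log(f / (1 - f)))
        elif name == "M":
            vec.append(np.log(max(v, 1e-6)))
        else:
            vec.append(np.log(v))
    return np.array(vec)


def _from_internal(model_id: str, vec: np.ndarray) -> dict[str, float]:
    frac = _FRACTION_OF_SPLIT.get(model_id, {})
    names = MODEL_PARAMS[model_id]
    out: dict[str, float] = {}
    for name, v in zip(names, vec):
        if name in frac:
            out[name] = float(1.0 / (1.0 + np.exp(-v)))  # fraction for now
        elif name == "M":
            out[name] = float(np.exp(v))
        else:
            out[name] = float(np.exp(v))
    for name in names:
        if name in frac:
            out[name] = out[name] * out[frac[name]]
    return out


def _random_start(model_id: str, rng: np.random.Generator) -> dict[str, float]:
    params: dict[str, float] = {}
    for name in MODEL_PARAMS[model_id]:
        lo, hi = _bounds_for(name)
        if name == "M":
            params[name] = float(rng.uniform(0.0, 2.0))
        else:
            params[name] = float(np.exp(rng.uniform(np.log(max(lo, 1e-3)),
                                                    np.log(min(hi, 5.0)))))
    frac = _FRACTION_OF_SPLIT.get(model_id, {})
    for name, ref in frac.items():
        params[name] = float(rng.uniform(0.1, 0.9) * params[ref])
    if model_id == "SBR":
        ts = params["tau_split"]
        params["tau_b"] = float(rng.uniform(0.1, 0.45) * ts)
        params["tau_r"] = float(rng.uniform(0.1, 0.45) * ts)
    return params


def _penalised(model_id: str, params: dict[str, float]) -> float:
    """Soft bound penalty added to the negative log likelihood."""
    pen = 0.0
    for name, v in params.items():
        lo, hi = _bounds_for(name)
        if v > hi:
            pen += 1e4 * (np.log(v / hi)) ** 2
        if v < lo and name != "M":
            pen += 1e4 * (np.log(lo / max(v, 1e-300))) ** 2
    return pen


def fit_model(X: JointAFS, model_id: str, starts: int = 5, seed: int = 0,
              grid: int | SpectrumEngine = 100,
              init: Mapping[str, float] | Sequence[Mapping[str, float]] | None = None,
              maxiter: int = 400, polish_factor: int = 4) -> FitResult:
    """Multi-start derivative-free maximisation of the composite likelihood.

    Optimisation runs in log space (epoch-onset times as logit fractions of
    the split time, which keeps the time ordering feasible by construction);
    theta is profiled analytically inside the objective.  ``init`` may give
    one or several informed starting points used before the ``starts``
    random ones; the best coarse optimum is polished with a longer
    Nelder-Mead run (``polish_factor`` times ``maxiter``).  Deterministic
    given ``seed``.
    """
    engine = grid if isinstance(grid, SpectrumEngine) else SpectrumEngine(grid)
    rng = np.random.default_rng(seed)

    def objective(vec: np.ndarray) -> float:
        params = _from_internal(model_id, vec)
        try:
            model = DemographicModel(model_id, params)
            M = expected_afs(model, X.n1, X.n2, grid=engine)
        except (ValueError, FloatingPointError):
            return 1e12
        ll = composite_loglik(X, M, scale_theta=True)
        if not np.isfinite(ll):
            return 1e12
        return -ll + _penalised(model_id, params)

    if init is None:
        inits: list[dict[str, float]] = []
    elif isinstance(init, Mapping):
        inits = [dict(init)]
    else:
        inits = [dict(i) for i in init]
    inits += [_random_start(model_id, rng) for _ in range(starts)]

    best_vec = None
    best_obj = np.inf
    start_lls: list[float] = []
    converged = 0
    errors: list[str] = []
    for s, start in enumerate(inits):
        try:
            vec0 = _to_internal(model_id, start)
            res = optimize.minimize(objective, vec0, method="Nelder-Mead",
                                    options={"maxiter": maxiter,
                                             "xatol": 1e-4, "fatol": 1e-4})
        except Exception as exc:  # pragma: no cover - diagnostics path
            errors.append(f"start {s}: {exc}")
            continue
        start_lls.append(-float(res.fun))
        if res.success:
            converged += 1
        if res.fun < best_obj:
            best_obj = float(res.fun)
            best_vec = res.x
    if best_vec is None:
        raise RuntimeError("all optimisation starts failed: " + "; ".join(errors))
    if polish_factor > 0:
        res = optimize.minimize(objective, best_vec, method="Nelder-Mead",
                                options={"maxiter": polish_factor * maxiter,
                                         "xatol": 1e-5, "fatol": 1e-5})
        if res.fun < best_obj:
            best_obj = float(res.fun)
            best_vec = res.x
    params = _from_internal(model_id, best_vec)
    return FitResult(model_id=model_id, params=params, loglik=-best_obj,
                     n_starts=len(inits), converged=converged,
                     start_logliks=start_lls)


def isb_init_from_bim(bim_params: Mapping[str, float]) -> dict[str, float]:
    """Map a fitted BIM optimum onto the ISB parameter space.

    BIM (ancestral bottleneck of size nu_b for tau_b, then a split into
    nu1, nu2 held to the present) is approximately the ISB corner with the
    growth epoch playing the ancestral-bottleneck role and both
    population bottlenecks starting right at the split.  Useful as an
    informed extra start when fitting ISB.
    """
    return {
        "nu_g": bim_params["nu_b"],
        "tau_g": max(bim_params["tau_b"], 1e-4),
        "tau_split": bim_params["tau_split"],
        "nu1_b": bim_params["nu1"],
        "nu2_b": bim_params["nu2"],
        "tau_b1": 0.999 * bim_params["tau_split"],
        "tau_b2": 0.999 * bim_params["tau_split"],
    }


# --- model comparison -------------------------------------------------------

NESTING: dict[tuple[str, str], int] = {
    # (restricted, full): extra free parameters of the full model
}


def compare_models(fits: Sequence[FitResult],
                   nesting_map: Mapping[tuple[str, str], int] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank fits by log likelihood and run LRTs for declared nested pairs.

    ``nesting_map`` maps (restricted_id, full_id) -> degrees-of-freedom
    difference.  Asking for a pair not declared nested raises.
    """
    ranking = pd.DataFrame(
        [{"model": f.model_id, "loglik": f.loglik,
          "n_params": len(MODEL_PARAMS[f.model_id])} for f in fits]
    ).sort_values("loglik", ascending=False).reset_index(drop=True)
    rows = []
    by_id = {f.model_id: f for f in fits}
    for (restricted, full), df in (nesting_map or {}).items():
        if restricted not in by_id or full not in by_id:
            continue
        if df <= 0:
            raise ValueError(f"pair ({restricted}, {full}) declared with "
                             f"non-positive df; not a valid nesting")
        stat = 2.0 * (by_id[full].loglik - by_id[restricted].loglik)
        rows.append({"restricted": restricted, "full": full, "df": df,
                     "stat": max(stat, 0.0),
                     "p": float(chi2.sf(max(stat, 0.0), df)) if stat != 0 else 1.0})
    lrt = pd.DataFrame(rows, columns=["restricted", "full", "df", "stat", "p"])
    return ranking, lrt


def lrt(full: FitResult, restricted: FitResult, df: int) -> dict:
    """Single log-likelihood-ratio test with chi-square significance."""
    stat = max(0.0, 2.0 * (full.loglik - restricted.loglik))
    return {"stat": stat, "df": df, "p": float(chi2.sf(stat, df)) if stat > 0 else 1.0}


# --- block bootstrap --------------------------------------------------------

def bootstrap_variance(scaffold: np.ndarray, pos: np.ndarray,
                       derived1: np.ndarray, derived2: np.ndarray,
                       n1: int, n2: int, model_id: str,
                       block_bp: int = 1_000_000, B: int = 100, seed: int = 0,
                       grid: int | SpectrumEngine = 100,
                       init: Mapping[str, float] | None = None,
                       starts: int = 1, maxiter: int = 200) -> dict:
    """Block-bootstrap variance of fitted parameters and log likelihood.

    The genome is partitioned into blocks of ``block_bp``; blocks are
    resampled with replacement B times, the AFS rebuilt and the model refit
    (warm-started at ``init`` when given).  Blocks rather than sites are
    resampled to respect linkage.
    """
    from bkit.afs import build_joint_afs

    if B < 1:
        raise ValueError("B must be >= 1")
    scaf = np.asarray(scaffold, dtype=str)
    block_id = np.array([f"{s}:{(p - 1) // block_bp}"
                         for s, p in zip(scaf, np.asarray(pos))])
    blocks = pd.unique(block_id)
    if len(blocks) < 10:
        raise ValueError(f"only {len(blocks)} blocks; need at least 10")
    members = {b: np.flatnonzero(block_id == b) for b in blocks}
    rng = np.random.default_rng(seed)
    engine = grid if isinstance(grid, SpectrumEngine) else SpectrumEngine(grid)
    rows = []
    for rep in range(B):
        chosen = rng.choice(blocks, size=len(blocks), replace=True)
        idx = np.concatenate([members[b] for b in chosen])
        Xb = build_joint_afs(np.asarray(derived1)[idx], np.asarray(derived2)[idx],
                             n1, n2)
        # a fixed fitting seed keeps identical resampled data -> identical
        # refits (and warm-starts stay comparable across replicates)
        fit = fit_model(Xb, model_id, starts=starts, seed=seed,
                        grid=engine, init=init, maxiter=maxiter)
        rows.append({**fit.params, "loglik": fit.loglik})
    reps = pd.DataFrame(rows)
    degenerate = B < 2
    return {
        "replicates": reps,
        "param_variance": (reps.drop(columns="loglik").var(ddof=1).to_dict()
                           if not degenerate else
                           {k: 0.0 for k in reps.columns if k != "loglik"}),
        "loglik_variance": float(reps["loglik"].var(ddof=1)) if not degenerate else 0.0,
        "degenerate": degenerate,
        "B": B,
        "n_blocks": len(blocks),
    }
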