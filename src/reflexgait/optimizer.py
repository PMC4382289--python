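"""Design-vector encoding and CMA-ES optimization of the walking controller.

The design vector stacks the 56 free controller parameters (reflex gains,
thresholds, PD targets and the swing trigger distance d_swing, as enumerated
by the wiring table) with 18 initial conditions (9 coordinates + 9
velocities), 74 entries in total. Optimization uses a (mu/mu_w, lambda)
CMA evolution strategy (rank-one + rank-mu covariance updates, cumulative
step-size adaptation) in bound-normalized coordinates, with candidates
clipped into bounds before evaluation. Rollout evaluations within a
generation are independent and can be distributed over worker processes;
results are re-ordered by candidate index before selection, so parallel and
serial runs select identical parents.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_core import SkeletonModel
from .mtu import MuscleSet
from .objective import ObjectiveWeights, total_objective
from .reflex_control import ControlLayout, ControlParams
from .simulation import Scenario, build_scenario_model, rollout, DT_DEFAULT

log = logging.getLogger(__name__)

N_DESIGN = 74

# Initial-condition bounds (9 q + 9 qdot) and the nominal walking start pose.
# Pose: right leg loading (slightly flexed), left leg mid-swing, trunk with
# a slight forward lean, forward COM velocity near the target speed.
IC_LOWER = np.array([-0.2, 0.90, -0.4, -0.6, 0.0, -0.6, -0.6, 0.0, -0.6,
                     0.3, -0.8, -2.0, -5.0, -5.0, -5.0, -5.0, -5.0, -5.0])
IC_UPPER = np.array([0.2, 1.12, 0.4, 0.9, 1.2, 0.6, 0.9, 1.2, 0.6,
                     2.2, 0.5, 2.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0])
IC_INIT = np.array([0.0, 1.05, -0.1, 0.2, 0.1, -0.05, 0.5, 0.5, 0.0,
                    1.4, -0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])


@dataclass
class DesignVector:
    """Codec between the flat 74-vector and (ControlParams, initial state)."""

    layout: ControlLayout = field(default_factory=ControlLayout.default)

    def __post_init__(self):
        if self.layout.n_free + 18 != N_DESIGN:
            raise ValueError(
                f"wiring table exposes {self.layout.n_free} controller "
                f"parameters; {N_DESIGN - 18} required for the 74-vector")

    @property
    def n(self) -> int:
        return self.layout.n_free + 18

    @property
    def lower(self) -> np.ndarray:
        return np.concatenate([self.layout.lower, IC_LOWER])

    @property
    def upper(self) -> np.ndarray:
        return np.concatenate([self.layout.upper, IC_UPPER])

    @property
    def init(self) -> np.ndarray:
        return np.concatenate([self.layout.init_vector, IC_INIT])

    def decode(self, x: np.ndarray):
        """(ControlParams, 18 initial conditions) from a design vector.

        Out-of-bounds entries are clipped into bounds (the clip count is
        logged at debug level).
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"design vector must have length {self.n}")
        lo, hi = self.lower, self.upper
        clipped = np.clip(x, lo, hi)
        n_clip = int(np.sum(clipped != x))
        if n_clip:
            log.debug("decode: clipped %d entries into bounds", n_clip)
        nc = self.layout.n_free
        return self.layout.decode(clipped[:nc]), clipped[nc:]

    def encode(self, control_params: ControlParams,
               initial_conditions: np.ndarray) -> np.ndarray:
        ic = np.asarray(initial_conditions, dtype=float)
        if ic.shape != (18,):
            raise ValueError("expected 18 initial conditions")
        return np.concatenate([self.layout.encode(control_params), ic])


@dataclass
class OptimizerSettings:
    popsize: int = 16
    sigma0: float = 0.15          # fraction of the normalized bound range
    max_iter: int = 300
    stall_iter: int = 300         # stop after this many non-improving iters
    stall_tol: float = 1e-10
    seed: int = 1
    workers: int = 1
    checkpoint_every: int = 25
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.popsize < 4:
            raise ValueError("popsize must be >= 4")


class RolloutObjective:
    """Picklable design-vector -> R evaluator for one scenario.

    Heavy objects (model arrays, muscle tables) are built lazily per
    process, so the evaluator can be shipped to worker processes cheaply.
    """

    def __init__(self, scenario: Scenario | None = None,
                 weights: ObjectiveWeights | None = None,
                 dt: float = DT_DEFAULT, duration: float | None = None):
        self.scenario = scenario if scenario is not None else Scenario()
        if duration is not None:
            self.scenario = dataclasses.replace(self.scenario,
                                                duration=duration)
        self.weights = (weights if weights is not None
                        else ObjectiveWeights(
                            target_speed=self.scenario.target_speed))
        self.dt = dt
        self._cache = None

    def __getstate__(self):
        d = dict(self.__dict__)
        d["_cache"] = None
        return d

    def _setup(self):
        if self._cache is None:
            model = build_scenario_model(self.scenario)
            model.arrays()
            self._cache = (model, MuscleSet.default(), DesignVector())
        return self._cache

    def evaluate(self, x: np.ndarray) -> dict:
        """Full objective report for one design vector."""
        model, muscles, codec = self._setup()
        cp, ic = codec.decode(x)
        traj = rollout(model, cp, ic, scenario=self.scenario,
                       muscles=muscles, dt=self.dt,
                       fall_height=self.weights.fall_height)
        rep = total_objective(traj, self.weights)
        rep["fell"] = traj.fell
        return rep

    def __call__(self, x: np.ndarray) -> float:
        try:
            return float(self.evaluate(x)["R"])
        except np.linalg.LinAlgError:
            # numerically destroyed rollout: reject the candidate
            return float("inf")


@dataclass
class CMAResult:
    best_x: np.ndarray
    best_f: float
    history: list
    iterations: int
    seed: int


def _eval_population(objective_fn, X, pool):
    if pool is None:
        return [float(objective_fn(x)) for x in X]
    # order-stabilized by construction: map preserves input order
    return [float(v) for v in pool.map(objective_fn, list(X))]


def cma_optimize(objective_fn, x0: np.ndarray,
                 settings: OptimizerSettings | None = None,
                 lower: np.ndarray | None = None,
                 upper: np.ndarray | None = None,
                 pool=None) -> CMAResult:
    """Minimize ``objective_fn`` with a (mu/mu_w, lambda) CMA-ES.

    When ``lower``/``upper`` are given the search runs in bound-normalized
    coordinates and candidates are clipped into bounds before evaluation.
    Deterministic for a fixed seed; non-finite objective values are treated
    as +inf.
    """
    st = settings if settings is not None else OptimizerSettings()
    rng = np.random.default_rng(st.seed)
    x0 = np.asarray(x0, dtype=float)
    n = x0.size

    if lower is not None:
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        span = upper - lower
        span = np.where(span <= 0, 1.0, span)
        to_z = lambda x: (x - lower) / span
        to_x = lambda z: lower + np.clip(z, 0.0, 1.0) * span
    else:
        to_z = lambda x: x
        to_x = lambda z: z

    lam = st.popsize
    mu = lam // 2
    wts = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    wts /= wts.sum()
    mueff = 1.0 / np.sum(wts ** 2)
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    m = to_z(x0).astype(float)
    sigma = st.sigma0
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)
    B = np.eye(n)
    D = np.ones(n)
    eigen_stale = 0

    # seed the best-ever archive with the start point so a good warm start
    # is never lost to an unlucky first generation
    best_x = to_x(m).copy()
    f0 = float(objective_fn(best_x))
    best_f = f0 if np.isfinite(f0) else np.inf
    history = []
    stall = 0

    for it in range(st.max_iter):
        if eigen_stale <= 0:
            C = (C + C.T) / 2
            D2, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(D2, 1e-20))
            eigen_stale = max(1, int(1 / ((c1 + cmu) * n * 10)))
        eigen_stale -= 1

        Z = rng.standard_normal((lam, n))
        Y = Z @ np.diag(D) @ B.T
        Xz = m + sigma * Y
        Xcand = [to_x(z) for z in Xz]
        F = _eval_population(objective_fn, Xcand, pool)
        F = [f if np.isfinite(f) else np.inf for f in F]
        order = np.argsort(F, kind="stable")

        if F[order[0]] < best_f - st.stall_tol:
            stall = 0
        else:
            stall += 1
        if F[order[0]] < best_f:
            best_f = F[order[0]]
            best_x = np.asarray(Xcand[order[0]]).copy()
        history.append({"iter": it, "best": float(F[order[0]]),
                        "mean": float(np.mean([f for f in F
                                               if np.isfinite(f)] or [np.inf])),
                        "best_ever": float(best_f), "sigma": float(sigma)})

        sel = order[:mu]
        y_w = np.sum(wts[:, None] * Y[sel], axis=0)
        m = m + sigma * y_w

        # step-size path (in the isotropic coordinates)
        Cinv_half_y = (Z[sel].T @ wts)      # = B D^-1 B^T y_w / ... by construction
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (B @ Cinv_half_y)
        hsig = (np.linalg.norm(ps)
                / np.sqrt(1 - (1 - cs) ** (2 * (it + 1))) / chi_n
                < 1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        artmp = Y[sel]
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc)
                     + (0 if hsig else 1) * cc * (2 - cc) * C)
             + cmu * (artmp.T * wts) @ artmp)
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, 1e3)

        if st.checkpoint_path and (it + 1) % st.checkpoint_every == 0:
            _write_checkpoint(st.checkpoint_path, best_x, best_f, it, st.seed)
        if stall >= st.stall_iter:
            break

    return CMAResult(best_x=np.asarray(best_x), best_f=float(best_f),
                     history=history, iterations=len(history), seed=st.seed)


def _write_checkpoint(path, best_x, best_f, it, seed):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"best_x": list(map(float, best_x)),
                   "best_f": float(best_f), "iteration": it,
                   "seed": seed}, fh)


@dataclass
class ScenarioSolution:
    scenario: Scenario
    x: np.ndarray
    R: float
    fell: bool
    history: list


def continuation(schedule, base_solution: np.ndarray,
                 settings: OptimizerSettings | None = None,
                 weights: ObjectiveWeights | None = None,
                 dt: float = DT_DEFAULT, pool=None) -> list:
    """Optimize an ordered list of scenarios, warm-starting each from the
    previous solution.

    A scenario whose best solution still falls is flagged; subsequent
    scenarios start from the last non-falling solution.
    """
    st = settings if settings is not None else OptimizerSettings()
    codec = DesignVector()
    results = []
    x_start = np.asarray(base_solution, dtype=float)
    last_good = x_start
    for i, scenario in enumerate(schedule):
        obj = RolloutObjective(scenario, weights=weights, dt=dt)
        sub = dataclasses.replace(st, seed=st.seed + i)
        res = cma_optimize(obj, last_good, sub, lower=codec.lower,
                           upper=codec.upper, pool=pool)
        rep = obj.evaluate(res.best_x)
        sol = ScenarioSolution(scenario=scenario, x=res.best_x, R=res.best_f,
                               fell=bool(rep["fell"]), history=res.history)
        results.append(sol)
        if not sol.fell:
            last_good = res.best_x
        else:
            log.warning("scenario %s: best solution still falls", scenario)
    return results
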