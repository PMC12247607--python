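"""Constrained optimization of tissue conductivities.

The objective is the RMS misfit between simulated and measured
current-induced fields over the masked voxels of all datasets,

    delta_Bz(sigma) = sqrt( (1/N) sum_i ( Bz_sim(sigma, i) - Bz_meas(i) )^2 ),

minimized subject to per-tissue box bounds and the physiological ordering
constraint sigma_WM <= sigma_GM.  Each evaluation runs the full forward
model (finite-volume potential solve + FFT Biot-Savart) for every dataset;
repeated solves are cheap because the CG iteration is warm-started from the
previous potential and evaluations are memoized on the rounded sigma vector.

The ordering constraint is handled by reparameterizing sigma_GM as
sigma_WM plus a non-negative slack, so every iterate of the derivative-free
(Nelder-Mead) search is feasible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .forward import (
    BzField,
    ConductivityVector,
    SolverConfig,
    assign_conductivity,
    bz_from_current_fft,
    current_density,
    solve_potential,
)
from .phantom import ElectrodeMontage, TissueLabelVolume, place_electrodes

__all__ = [
    "Dataset",
    "ObjectiveSpec",
    "OptimizationResult",
    "ForwardEvaluator",
    "delta_bz",
    "optimize_conductivities",
    "joint_objective_stack",
    "make_dataset",
]


@dataclass
class Dataset:
    """One measured B_z volume with its montage and evaluation mask."""

    name: str
    bz_meas: BzField
    mask: np.ndarray
    anode_mask: np.ndarray
    cathode_mask: np.ndarray
    total_current_A: float
    labels: TissueLabelVolume

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError(f"dataset '{self.name}' has an empty mask")


def make_dataset(
    labels: TissueLabelVolume,
    montage: ElectrodeMontage,
    bz_meas: BzField,
    mask: np.ndarray,
    name: str | None = None,
) -> Dataset:
    anode, cathode = place_electrodes(labels, montage)
    return Dataset(
        name=name or montage.name,
        bz_meas=bz_meas,
        mask=mask,
        anode_mask=anode,
        cathode_mask=cathode,
        total_current_A=montage.total_current_A,
        labels=labels,
    )


@dataclass
class ObjectiveSpec:
    """Datasets + constraint configuration for the conductivity fit."""

    datasets: list
    ordering_constraint: bool = True       # sigma_WM <= sigma_GM
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset required")

    @property
    def n_voxels(self) -> int:
        return int(sum(d.mask.sum() for d in self.datasets))


def joint_objective_stack(datasets, **kwargs) -> ObjectiveSpec:
    """Stack several montage datasets of one subject into a joint objective.

    All voxels enter one residual vector with equal weight; each dataset gets
    its own forward solve.  The datasets must share the label volume.
    """
    datasets = list(datasets)
    ref = datasets[0].labels
    for d in datasets[1:]:
        if d.labels.labels.shape != ref.labels.shape or not np.array_equal(
            d.labels.labels, ref.labels
        ):
            raise ValueError("stacked datasets must share the label volume")
    return ObjectiveSpec(datasets=datasets, **kwargs)


@dataclass
class OptimizationResult:
    sigma_opt: ConductivityVector
    delta_initial: float
    delta_final: float
    trace: list                       # [(sigma dict, delta_bz tesla), ...]
    n_forward_solves: int
    converged: bool
    message: str

    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate([v for _, v in self.trace])


class ForwardEvaluator:
    """Memoized forward-model evaluation of delta_Bz with CG warm starts."""

    def __init__(self, spec: ObjectiveSpec):
        self.spec = spec
        self.n_forward_solves = 0
        self._phi_cache: dict = {}       # dataset index -> last potential volume
        self._memo: dict = {}

    @staticmethod
    def _key(cond: ConductivityVector) -> tuple:
        return tuple(
            (t, round(v, 6)) for t, v in sorted(cond.sigma.items())
        )

    def simulated_bz(self, cond: ConductivityVector, i: int) -> np.ndarray:
        ds = self.spec.datasets[i]
        sigma_vol = assign_conductivity(ds.labels, cond)
        phi = solve_potential(
            sigma_vol, ds.labels.grid, ds.anode_mask, ds.cathode_mask,
            ds.total_current_A, self.spec.solver, x0=self._phi_cache.get(i),
        )
        self._phi_cache[i] = phi.phi / phi.scale  # unit-Dirichlet warm start
        self.n_forward_solves += 1
        J = current_density(phi, sigma_vol)
        return bz_from_current_fft(J, self.spec.solver).bz

    def delta_bz(self, cond: ConductivityVector) -> float:
        key = self._key(cond)
        if key in self._memo:
            return self._memo[key]
        ss = 0.0
        n = 0
        for i, ds in enumerate(self.spec.datasets):
            bz = self.simulated_bz(cond, i)
            r = bz[ds.mask] - ds.bz_meas.bz[ds.mask]
            ss += float(np.dot(r, r))
            n += int(ds.mask.sum())
        val = float(np.sqrt(ss / n))
        self._memo[key] = val
        return val


def delta_bz(cond: ConductivityVector, spec: ObjectiveSpec) -> float:
    """One-off RMS misfit (tesla) between simulated and measured B_z."""
    return ForwardEvaluator(spec).delta_bz(cond)


def _pack(cond: ConductivityVector, ordering: bool) -> tuple[np.ndarray, list]:
    """sigma -> optimizer coordinates; GM becomes WM + slack if constrained."""
    free = list(cond.free)
    x = []
    for t in free:
        if ordering and t == "gm":
            x.append(max(cond.sigma["gm"] - cond.sigma["wm"], 0.0))
        else:
            x.append(cond.sigma[t])
    return np.asarray(x), free


def _unpack(
    x: np.ndarray, free: list, template: ConductivityVector, ordering: bool
) -> ConductivityVector:
    sigma = dict(template.sigma)
    for t, v in zip(free, x):
        sigma[t] = float(v)
    if ordering and "gm" in free and "wm" in free:
        lo, hi = template.bounds["gm"]
        sigma["gm"] = float(min(max(sigma["wm"] + x[free.index("gm")], lo), hi))
    return ConductivityVector(sigma=sigma, bounds=template.bounds, fixed=template.fixed)


def optimize_conductivities(
    spec: ObjectiveSpec,
    init: ConductivityVector | None = None,
    max_evaluations: int = 500,
    xatol: float = 1e-4,
) -> OptimizationResult:
    """Bound-constrained derivative-free minimization of delta_Bz.

    Deterministic given the initial point and configuration.  The returned
    sigma is the best evaluated point; the trace holds every (sigma,
    delta_Bz) evaluation in order.
    """
    init = init or ConductivityVector.literature()
    if not init.within_bounds():
        raise ValueError("initial conductivities violate their bounds")
    ordering = spec.ordering_constraint
    x0, free = _pack(init, ordering)
    bounds = []
    for t in free:
        lo, hi = init.bounds[t]
        if ordering and t == "gm":
            bounds.append((0.0, hi - lo))
        else:
            bounds.append((lo, hi))

    evaluator = ForwardEvaluator(spec)
    trace: list = []

    def objective(x: np.ndarray) -> float:
        cond = _unpack(x, free, init, ordering)
        val = evaluator.delta_bz(cond)
        trace.append((dict(cond.sigma), val))
        return val

    delta0 = objective(x0)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={
            "maxfev": max_evaluations,
            "xatol": xatol,
            "fatol": 1e-16,
            "initial_simplex": _initial_simplex(x0, bounds),
        },
    )
    best_idx = int(np.argmin([v for _, v in trace]))
    best_sigma, best_val = trace[best_idx]
    sigma_opt = ConductivityVector(
        sigma=best_sigma, bounds=init.bounds, fixed=init.fixed
    )
    return OptimizationResult(
        sigma_opt=sigma_opt,
        delta_initial=delta0,
        delta_final=best_val,
        trace=trace,
        n_forward_solves=evaluator.n_forward_solves,
        converged=bool(res.success or best_val <= delta0),
        message=str(res.message),
    )


def _initial_simplex(x0: np.ndarray, bounds) -> np.ndarray:
    """Simplex with ~10% of each bound range per vertex, kept inside bounds."""
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for j in range(n):
        lo, hi = bounds[j]
        step = 0.1 * (hi - lo)
        if x0[j] + step <= hi:
            simplex[j + 1, j] += step
        else:
            simplex[j + 1, j] -= step
    return simplex
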