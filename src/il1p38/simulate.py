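"""Numerical integration of a ModelSpec and basal/steady-state location.

The solver is SciPy's LSODA (stiff-capable, variable order): the network
mixes second-scale binding with hour-scale protein turnover.  Tolerances are
part of the contract; defaults are rtol 1e-8, atol 1e-10 nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, InvalidArgumentError, SolverError
from .network import ModelSpec, assemble_odes

__all__ = [
    "SolverSettings",
    "Trajectory",
    "default_grid",
    "integrate",
    "rhs_norm",
    "is_steady",
    "find_basal_state",
]


@dataclass(frozen=True)
class SolverSettings:
    """Integration tolerances and horizon.

    ``stiff`` selects LSODA (automatic stiff/non-stiff switching); setting it
    to False uses an explicit Runge-Kutta method, useful only for tiny test
    systems.
    """

    relative_tolerance: float = 1e-8
    absolute_tolerance: float = 1e-10  # nM
    horizon: float = 2e5  # s
    max_step: float = np.inf  # s
    stiff: bool = True

    def __post_init__(self):
        if not (self.relative_tolerance > 0 and self.absolute_tolerance > 0):
            raise InvalidArgumentError("tolerances must be > 0")
        if not (self.horizon > 0):
            raise InvalidArgumentError("horizon must be > 0")

    @property
    def method(self) -> str:
        return "LSODA" if self.stiff else "RK45"


@dataclass
class Trajectory:
    """Time grid x species concentration matrix from one integration."""

    times: np.ndarray  # (nt,) seconds, strictly increasing, times[0] == 0
    states: np.ndarray  # (nt, ns) nM
    species_order: tuple[str, ...]
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        self.species_order = tuple(self.species_order)

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            j = self.species_order.index(species)
        except ValueError:
            raise InvalidArgumentError(
                f"species {species!r} not in trajectory"
            ) from None
        return self.states[:, j]

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long format: time_s, species, concentration_nM."""
        nt, ns = self.states.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, ns),
                "species": np.tile(np.array(self.species_order), nt),
                "concentration_nM": self.states.ravel(),
            }
        )

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species_order))
        df.insert(0, "time_s", self.times)
        return df


def default_grid(horizon: float, fine_until: float = 600.0,
                 fine_points: int = 601, log_points: int = 300) -> np.ndarray:
    """Output grid: linear over [0, fine_until] to resolve the ~2 min nuclear
    peak, then logarithmically spaced out to ``horizon``."""
    if horizon <= 0:
        raise InvalidArgumentError("horizon must be > 0")
    if horizon <= fine_until:
        return np.linspace(0.0, horizon, fine_points)
    lin = np.linspace(0.0, fine_until, fine_points)
    log = np.geomspace(fine_until, horizon, log_points)[1:]
    return np.concatenate([lin, log])


def integrate(spec: ModelSpec, settings: SolverSettings | None = None,
              output_grid: np.ndarray | None = None) -> Trajectory:
    """Integrate ``spec`` from its initial state over ``output_grid``.

    Deterministic: identical inputs give bitwise-identical output.
    """
    settings = settings or SolverSettings()
    grid = default_grid(settings.horizon) if output_grid is None else np.asarray(
        output_grid, float)
    if grid.ndim != 1 or grid.size < 2:
        raise InvalidArgumentError("output grid needs at least two times")
    if grid[0] != 0.0:
        raise InvalidArgumentError("output grid must start at t = 0")
    if np.any(np.diff(grid) <= 0):
        raise InvalidArgumentError("output grid must be strictly increasing")
    if grid[-1] > settings.horizon * (1 + 1e-12):
        raise InvalidArgumentError("output grid extends beyond the horizon")

    rhs = assemble_odes(spec)
    sol = solve_ivp(
        rhs,
        (0.0, float(grid[-1])),
        spec.initial_state(),
        method=settings.method,
        t_eval=grid,
        rtol=settings.relative_tolerance,
        atol=settings.absolute_tolerance,
        max_step=settings.max_step,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SolverError(f"integration failed at t = {last:g} s: {sol.message}",
                          last_time=last)
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        species_order=spec.species_names,
        solver_meta={
            "method": settings.method,
            "rtol": settings.relative_tolerance,
            "atol": settings.absolute_tolerance,
        },
    )


def rhs_norm(spec: ModelSpec, state: np.ndarray) -> float:
    """Max-norm of d/dt at ``state`` (nM/s)."""
    state = np.asarray(state, float)
    if state.shape != (len(spec.species),):
        raise InvalidArgumentError(
            f"state has shape {state.shape}, expected ({len(spec.species)},)"
        )
    return float(np.max(np.abs(assemble_odes(spec)(0.0, state))))


def is_steady(spec: ModelSpec, state: np.ndarray, tol: float = 1e-8) -> bool:
    """True iff the max-norm of d/dt at ``state`` is <= tol (nM/s)."""
    return rhs_norm(spec, state) <= tol


def _damped_refine(rhs, x, tol, max_iter=400):
    """Damped explicit fixed-point polish x <- x + h f(x) with backtracking.

    Used only to squeeze the last decades out of an already-relaxed state;
    the step size adapts to keep the residual decreasing.
    """
    f = rhs(0.0, x)
    res = float(np.max(np.abs(f)))
    # conservative step from the diagonal of the Jacobian (finite differences)
    eps = 1e-7
    diag = np.zeros_like(x)
    for i in range(x.size):
        dx = eps * max(abs(x[i]), 1.0)
        xp = x.copy()
        xp[i] += dx
        diag[i] = (rhs(0.0, xp)[i] - f[i]) / dx
    scale = float(np.max(np.abs(diag)))
    h = 0.5 / scale if scale > 0 else 1.0
    for _ in range(max_iter):
        if res <= tol:
            break
        xn = np.maximum(x + h * f, 0.0)
        fn = rhs(0.0, xn)
        rn = float(np.max(np.abs(fn)))
        if rn < res:
            x, f, res = xn, fn, rn
            h *= 1.3
        else:
            h *= 0.25
            if h * res < 1e-16:
                break
    return x, res


def find_basal_state(spec: ModelSpec, settings: SolverSettings | None = None,
                     residual_tol: float = 1e-9,
                     max_time: float = 6e6) -> np.ndarray:
    """Relax ``spec`` from its initial state to a stationary point.

    Long-horizon integration in doubling chunks followed by a damped
    fixed-point polish.  Integration (rather than root finding) is used
    deliberately: the TAB1 positive feedback admits a spurious all-zero
    branch that Newton-type root finders can land on.

    Returns a state with max-norm of d/dt below ``residual_tol`` (nM/s), or
    raises :class:`ConvergenceError` carrying the best residual.
    """
    settings = settings or SolverSettings()
    rhs = assemble_odes(spec)
    x = spec.initial_state()
    chunk = settings.horizon
    elapsed = 0.0
    res = float(np.max(np.abs(rhs(0.0, x))))
    while elapsed < max_time and res > residual_tol:
        sol = solve_ivp(rhs, (0.0, chunk), x, method=settings.method,
                        rtol=settings.relative_tolerance,
                        atol=settings.absolute_tolerance)
        if not sol.success:
            raise SolverError(
                f"basal relaxation failed at t = {elapsed + sol.t[-1]:g} s: "
                f"{sol.message}", last_time=elapsed + float(sol.t[-1]))
        x = np.maximum(sol.y[:, -1], 0.0)
        elapsed += chunk
        chunk *= 2.0
        res = float(np.max(np.abs(rhs(0.0, x))))
    if res > residual_tol:
        x, res = _damped_refine(rhs, x, residual_tol)
    else:
        # cheap polish: the integrator leaves residuals near its local error
        x, res = _damped_refine(rhs, x, residual_tol, max_iter=50)
    if res > residual_tol:
        raise ConvergenceError(
            f"basal state not stationary: residual {res:.3e} nM/s after "
            f"{elapsed:g} s of relaxation", residual=res)
    return x
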