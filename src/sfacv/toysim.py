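"""Desk-scale synthetic dynamics for exercising the whole pipeline.

Everything here runs in seconds and uses reduced units (kT = 1); the unit
boundary to kJ/mol sits exactly at the PLUMED I/O and reweighting layers.
Four generators cover the pipeline end to end:

* the canonical two-component SFA test signal whose slowest quadratic
  feature is analytically sin(t);
* a two-state flipping dihedral (symmetric telegraph process with jitter)
  plus fast wrapped noise angles — a cartoon of a rare aromatic side-chain
  flip buried among fast degrees of freedom;
* overdamped Euler-Maruyama Langevin dynamics on small model potentials;
* a toy well-tempered metadynamics integrator whose COLVAR/HILLS output is
  consumed unchanged by the PLUMED parsing and reweighting modules.

Every stochastic operation takes a mandatory seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import DihedralSeries, FeatureSeries
from .plumed_io import ColvarTable, HillsRecord
from .reweight import FESGrid

logger = logging.getLogger(__name__)

#: Default two-state wells (rad): roughly the two rotamer basins of an
#: aromatic chi1 flip.
WELL_A = -np.pi / 3
WELL_B = 2 * np.pi / 3


class ToySimError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model potentials
# ---------------------------------------------------------------------------

@dataclass
class ModelPotential:
    """An analytic potential U(x) in kT units on a bounded domain.

    ``energy`` must be vectorized over a trailing coordinate axis for
    ``dim > 1`` (or over plain arrays for 1-D); ``gradient`` maps a point
    (dim,) to dU/dx (dim,).
    """

    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain: tuple[tuple[float, float], ...]
    label: str = "potential"


def harmonic(k: float = 4.0) -> ModelPotential:
    """1-D harmonic well U = k x^2 / 2 (equilibrium variance 1/k at kT=1)."""
    return ModelPotential(
        dim=1,
        energy=lambda x: 0.5 * k * np.square(np.asarray(x, dtype=float)),
        gradient=lambda x: k * np.asarray(x),
        domain=((-20.0, 20.0),),
        label=f"harmonic(k={k})")


def double_well(barrier: float = 1.0) -> ModelPotential:
    """1-D symmetric double well U = barrier * (x^2 - 1)^2.

    Minima at x = +-1, barrier height ``barrier`` kT at x = 0.
    """
    def u(x):
        x = np.asarray(x, dtype=float)
        return barrier * (x ** 2 - 1.0) ** 2

    def g(x):
        x = np.asarray(x, dtype=float)
        return 4.0 * barrier * x * (x ** 2 - 1.0)

    return ModelPotential(dim=1, energy=u, gradient=g,
                          domain=((-3.0, 3.0),),
                          label=f"double_well(barrier={barrier})")


def separable_2d(p1: ModelPotential, p2: ModelPotential,
                 label: str | None = None) -> ModelPotential:
    """U(x, y) = U1(x) + U2(y) from two 1-D potentials."""
    if p1.dim != 1 or p2.dim != 1:
        raise ToySimError("separable_2d needs two 1-D potentials")

    def u(x):
        x = np.asarray(x, dtype=float)
        return p1.energy(x[..., 0]) + p2.energy(x[..., 1])

    def g(x):
        x = np.asarray(x, dtype=float)
        return np.array([float(p1.gradient(x[:1])[0]),
                         float(p2.gradient(x[1:])[0])])

    return ModelPotential(dim=2, energy=u, gradient=g,
                          domain=(p1.domain[0], p2.domain[0]),
                          label=label or f"{p1.label}+{p2.label}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class ToyRunConfig:
    """Configuration of a toy Langevin / metadynamics run (kT = 1 units).

    The seed is mandatory: there is no implicit randomness anywhere.
    """

    seed: int
    n_steps: int = 100000
    dt: float = 0.01
    friction: float = 1.0
    kt: float = 1.0
    pace: int = 500
    height: float = 0.5
    widths: tuple[float, ...] = (0.3,)
    bias_factor: float = 10.0
    colvar_stride: int = 10
    domain_bound: float = 50.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ToySimError("a seed is mandatory")
        if self.dt <= 0:
            raise ToySimError("step size must be positive")
        if self.bias_factor <= 1:
            raise ToySimError("bias factor must be > 1")


# ---------------------------------------------------------------------------
# synthetic feature signals
# ---------------------------------------------------------------------------

def wiskott_signal(n: int = 5000, dt: float = 0.002 * 2 * np.pi,
                   ) -> FeatureSeries:
    """The canonical two-component SFA test signal.

    x1(t) = sin(t) + cos^2(11 t), x2(t) = cos(11 t) on t = 0, dt, ...
    The driving slow source sin(t) is invisible to any linear readout but
    equals x1 - x2^2 exactly, so quadratic SFA must recover it as the
    slowest feature.
    """
    if n < 100:
        raise ToySimError("need at least 100 frames")
    t = np.arange(n) * dt
    vals = np.column_stack([np.sin(t) + np.cos(11 * t) ** 2,
                            np.cos(11 * t)])
    return FeatureSeries(values=vals, names=["x1", "x2"], dt=dt)


def two_state_dihedral(n: int = 100000, flip_rate: float = 0.005,
                       n_fast: int = 9, seed: int = 7,
                       jitter: float = 0.1, dt: float = 1.0,
                       ) -> DihedralSeries:
    """A rare two-state dihedral flip buried among fast noise angles.

    The slow angle hops between wells near -pi/3 and +2pi/3 as a symmetric
    telegraph process with per-frame flip probability ``flip_rate``, plus
    small Gaussian jitter; the ``n_fast`` extra angles are fast wrapped
    noise.  By construction the flip is the slowest process in the table,
    which is what slow feature analysis must find.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ToySimError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    flips = rng.random(n) < flip_rate
    flips[0] = False
    state = np.cumsum(flips) % 2            # 0 -> well A, 1 -> well B
    slow = np.where(state == 0, WELL_A, WELL_B) + rng.normal(0, jitter, n)
    angles = [slow]
    for _ in range(n_fast):
        angles.append(rng.uniform(-np.pi, np.pi, n))
    vals = np.column_stack(angles)
    # wrap into (-pi, pi]
    vals = np.mod(-vals + np.pi, 2 * np.pi)
    vals = np.pi - vals
    labels = ["chi1_TRP41"] + [f"chi1_FAST{i + 1}" for i in range(n_fast)]
    return DihedralSeries(values=vals, labels=labels, dt=dt)


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

def langevin(potential: ModelPotential, cfg: ToyRunConfig,
             x0: np.ndarray | None = None) -> np.ndarray:
    """Overdamped Euler-Maruyama integration of dx = -grad U dt / g + noise.

    Returns positions of shape (n_steps + 1, dim).  Noise variance is
    2 dt kT / friction per step.  Raises (naming the step) if the walker
    leaves ``cfg.domain_bound``.
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.zeros(potential.dim) if x0 is None else np.array(x0, dtype=float)
    out = np.empty((cfg.n_steps + 1, potential.dim))
    out[0] = x
    amp = np.sqrt(2.0 * cfg.dt * cfg.kt / cfg.friction)
    for step in range(cfg.n_steps):
        force = -potential.gradient(x)
        x = x + force * cfg.dt / cfg.friction + amp * rng.normal(
            size=potential.dim)
        if np.any(np.abs(x) > cfg.domain_bound):
            raise ToySimError(
                f"trajectory diverged at step {step + 1}: x = {x}")
        out[step + 1] = x
    return out


# ---------------------------------------------------------------------------
# toy well-tempered metadynamics
# ---------------------------------------------------------------------------

@dataclass
class CVFunction:
    """A differentiable collective variable s(x) for the toy integrator."""

    name: str
    fn: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray] | None = None
    _eps: float = field(default=1e-5, repr=False)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.grad is not None:
            return np.asarray(self.grad(x), dtype=float)
        g = np.empty_like(x)
        for d in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[d] += self._eps
            xm[d] -= self._eps
            g[d] = (self.fn(xp) - self.fn(xm)) / (2 * self._eps)
        return g


def identity_cv(name: str = "x", dim: int = 0) -> CVFunction:
    """The coordinate itself as CV (gradient is a unit vector)."""
    def grad(x):
        g = np.zeros_like(x)
        g[dim] = 1.0
        return g
    return CVFunction(name=name, fn=lambda x: float(x[dim]), grad=grad)


def wt_metad(potential: ModelPotential, cvs: Sequence[CVFunction],
             cfg: ToyRunConfig, x0: np.ndarray | None = None,
             ) -> tuple[ColvarTable, list[HillsRecord]]:
    """Well-tempered metadynamics on a toy potential (kT = 1 units).

    Gaussians of tempered height h exp(-V(s,t)/((gamma-1) kT)) are deposited
    every ``cfg.pace`` steps; the bias force enters the overdamped Langevin
    update through the CV gradients.  Emits a COLVAR table (time, CVs,
    metad.bias — the instantaneous accumulated bias at each recorded frame)
    and HILLS records storing the ACTUAL deposited heights, exactly the
    dialect the PLUMED parsing and reweighting layers consume.
    """
    ncv = len(cvs)
    if len(cfg.widths) != ncv:
        raise ToySimError(f"{len(cfg.widths)} widths given for {ncv} CVs")
    rng = np.random.default_rng(cfg.seed)
    x = np.zeros(potential.dim) if x0 is None else np.array(x0, dtype=float)
    widths = np.asarray(cfg.widths, dtype=float)
    max_hills = cfg.n_steps // cfg.pace + 1
    h_centers = np.empty((max_hills, ncv))
    h_heights = np.empty(max_hills)
    n_hills = 0
    hills: list[HillsRecord] = []
    rec_t, rec_s, rec_v = [], [], []
    amp = np.sqrt(2.0 * cfg.dt * cfg.kt / cfg.friction)
    gamma = cfg.bias_factor

    def bias_and_dbias(s: np.ndarray) -> tuple[float, np.ndarray]:
        if n_hills == 0:
            return 0.0, np.zeros(ncv)
        diff = (s - h_centers[:n_hills]) / widths
        g = h_heights[:n_hills] * np.exp(-0.5 * np.sum(diff * diff, axis=1))
        V = float(g.sum())
        dV = -(g[:, None] * diff / widths).sum(axis=0)
        return V, dV

    for step in range(cfg.n_steps + 1):
        t = step * cfg.dt
        s = np.array([cv.fn(x) for cv in cvs])
        if step > 0 and step % cfg.pace == 0:
            V_here, _ = bias_and_dbias(s)
            h_dep = cfg.height * np.exp(
                -V_here / ((gamma - 1.0) * cfg.kt))
            h_centers[n_hills] = s
            h_heights[n_hills] = h_dep
            n_hills += 1
            hills.append(HillsRecord(time=t, centers=s.copy(),
                                     widths=widths.copy(), height=h_dep,
                                     bias_factor=gamma))
        if step % cfg.colvar_stride == 0:
            V_now, _ = bias_and_dbias(s)
            rec_t.append(t)
            rec_s.append(s.copy())
            rec_v.append(V_now)
        if step < cfg.n_steps:
            _, dV = bias_and_dbias(s)
            force = -potential.gradient(x)
            for i, cv in enumerate(cvs):
                force = force - dV[i] * cv.gradient(x)
            x = x + force * cfg.dt / cfg.friction + amp * rng.normal(
                size=potential.dim)
            if np.any(np.abs(x) > cfg.domain_bound):
                raise ToySimError(
                    f"trajectory diverged at step {step + 1}: x = {x}")

    df = pd.DataFrame({"time": rec_t})
    svals = np.stack(rec_s)
    for i, cv in enumerate(cvs):
        df[cv.name] = svals[:, i]
    df["metad.bias"] = rec_v
    colvar = ColvarTable(df=df, cv_names=[cv.name for cv in cvs],
                         bias_column="metad.bias")
    return colvar, hills


# ---------------------------------------------------------------------------
# analytic free-energy oracle
# ---------------------------------------------------------------------------

def analytic_fes(potential: ModelPotential, projection: int = 0,
                 bins: int = 100, kt: float = 1.0,
                 quad_points: int = 801) -> FESGrid:
    """Exact (dense-quadrature) free energy along one coordinate.

    F(x) = -kT ln Int exp(-U/kT) over the orthogonal coordinates, evaluated
    at bin centers and min-shifted to zero.  For 1-D potentials this is
    just U - min U.
    """
    lo, hi = potential.domain[projection]
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    if potential.dim == 1:
        # energy is in kT units; scale to the requested kt
        F = kt * np.asarray(potential.energy(centers), dtype=float)
    else:
        others = [d for d in range(potential.dim) if d != projection]
        grids = [np.linspace(*potential.domain[d], quad_points)
                 for d in others]
        mesh = np.meshgrid(centers, *grids, indexing="ij")
        coords = [None] * potential.dim
        coords[projection] = mesh[0]
        for i, d in enumerate(others):
            coords[d] = mesh[1 + i]
        U = potential.energy(np.stack(coords, axis=-1))
        p = np.exp(-U)
        for ax in range(len(others), 0, -1):
            p = np.trapezoid(p, x=grids[ax - 1], axis=ax)
        F = -kt * np.log(p)
    F = F - F.min()
    return FESGrid(edges=[edges], free_energy=F,
                   empty=np.zeros(bins, dtype=bool), kt=kt)
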