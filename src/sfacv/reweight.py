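"""Tiwary-Parrinello reweighting of well-tempered metadynamics.

Well-tempered metadynamics deposits Gaussians of decaying height along the
chosen collective variables; the instantaneous bias V(s, t) distorts the
sampled distribution.  The time-dependent reweighting factor

    c(t) = (1/beta) ln [ sum_s exp(beta*gamma/(gamma-1) V(s,t))
                       / sum_s exp(beta/(gamma-1)   V(s,t)) ]

(evaluated on a CV grid at each deposition) converts the biased trajectory
into unbiased statistics through per-frame weights

    w_t  proportional to  exp(beta (V(s_t, t) - c(t))).

A converging run shows c(t) rising to an asymptotic plateau; the weighted
histogram of any observable then gives its unbiased free-energy surface
F = -kT ln p, min-shifted to zero.

Units: energies in kJ/mol with kT from the molar gas constant at the given
temperature (default 300 K).  Passing ``kt`` directly overrides this, which
the reduced-unit toy engine (kT = 1) uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.constants import R as _GAS_CONSTANT
from scipy.special import logsumexp

from .plumed_io import ColvarTable, HillsRecord, PlumedIOError

logger = logging.getLogger(__name__)

#: Default grid resolution per CV dimension for the c(t) quadrature.
DEFAULT_BINS = 100
#: Grid padding beyond the sampled hill-center range, in max Gaussian widths.
GRID_PAD_WIDTHS = 3.0


def thermal_energy(temperature: float = 300.0,
                   kt: float | None = None) -> float:
    """kT in kJ/mol at ``temperature`` (K), or ``kt`` verbatim if given."""
    if kt is not None:
        return float(kt)
    return _GAS_CONSTANT * temperature / 1000.0


@dataclass
class RctSeries:
    """Time trace of the reweighting factor c(t) at hill-deposition times."""

    times: np.ndarray
    values: np.ndarray   # kJ/mol (or kT units when kt=1)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size == 0 or self.times[0] != 0.0 or self.values[0] != 0.0:
            raise ValueError("c(t) series must start at c(0) = 0")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Stepwise-constant (right-continuous) interpolation: bias only
        changes at depositions."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.values[np.clip(idx, 0, None)]


@dataclass
class FESGrid:
    """Free-energy surface on a binned observable grid.

    ``free_energy`` is NaN where ``empty`` is True; over occupied bins the
    minimum is exactly zero.
    """

    edges: list[np.ndarray]
    free_energy: np.ndarray   # kJ/mol (kT units for kt=1)
    empty: np.ndarray
    kt: float

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def write(self, path: str | Path) -> None:
        """Plain-text grid: bin centers, free energy, empty flag."""
        ndim = len(self.edges)
        with Path(path).open("w") as fh:
            fh.write(f"# sfacv FES, kT = {self.kt!r}\n")
            for d, e in enumerate(self.edges):
                fh.write(f"# edges[{d}]: "
                         + " ".join(format(v, ".9g") for v in e) + "\n")
            cols = [f"center{d}" for d in range(ndim)]
            fh.write("# " + " ".join(cols + ["free_energy", "empty"]) + "\n")
            centers = self.centers
            for idx in np.ndindex(*self.free_energy.shape):
                c = [centers[d][idx[d]] for d in range(ndim)]
                f = self.free_energy[idx]
                fh.write(" ".join(format(v, ".9g") for v in c)
                         + f" {'nan' if self.empty[idx] else format(f, '.9g')}"
                         + f" {int(self.empty[idx])}\n")


# ---------------------------------------------------------------------------
# bias evaluation
# ---------------------------------------------------------------------------

def _hills_arrays(hills: list[HillsRecord]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    times = np.array([h.time for h in hills])
    centers = np.stack([h.centers for h in hills])
    widths = np.stack([h.widths for h in hills])
    heights = np.array([h.height for h in hills])
    return times, centers, widths, heights


def bias_at(hills: list[HillsRecord], point: np.ndarray,
            t: float) -> float:
    """Accumulated bias at CV ``point`` from hills deposited before ``t``."""
    if not hills:
        return 0.0
    point = np.atleast_1d(np.asarray(point, dtype=float))
    if point.size != hills[0].centers.size:
        raise PlumedIOError(
            f"point has {point.size} dims, hills have "
            f"{hills[0].centers.size}")
    times, centers, widths, heights = _hills_arrays(hills)
    active = times < t
    if not np.any(active):
        return 0.0
    d2 = ((point - centers[active]) / widths[active]) ** 2
    return float(np.sum(heights[active] * np.exp(-0.5 * d2.sum(axis=1))))


def _hill_grid(centers: np.ndarray, widths: np.ndarray,
               bins: int) -> list[np.ndarray]:
    """Per-dimension grid covering the hill centers padded by 3 max widths."""
    grids = []
    for d in range(centers.shape[1]):
        pad = GRID_PAD_WIDTHS * widths[:, d].max()
        lo, hi = centers[:, d].min() - pad, centers[:, d].max() + pad
        grids.append(np.linspace(lo, hi, bins))
    return grids


def compute_rct(hills: list[HillsRecord],
                bias_factor: float,
                temperature: float = 300.0,
                kt: float | None = None,
                bins: int = DEFAULT_BINS,
                grid: list[np.ndarray] | None = None) -> RctSeries:
    """Reweighting factor c(t) at every hill-deposition time.

    The accumulated bias V(s, t) is tabulated incrementally on a CV grid
    (default: hill-center range padded by 3 max widths, ``bins`` points per
    dimension) and the two grid sums are evaluated with log-sum-exp.  The
    returned series is prepended with c(0) = 0 (no bias yet).
    """
    if not hills:
        raise PlumedIOError("cannot compute c(t) without hills")
    if bias_factor <= 1:
        raise PlumedIOError("bias factor must be > 1")
    kbt = thermal_energy(temperature, kt)
    beta = 1.0 / kbt
    gamma = bias_factor
    times, centers, widths, heights = _hills_arrays(hills)
    if grid is None:
        grid = _hill_grid(centers, widths, bins)
    mesh = np.meshgrid(*grid, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)  # (G, D)

    V = np.zeros(pts.shape[0])
    out_t = [0.0]
    out_c = [0.0]
    for i in range(len(hills)):
        d2 = ((pts - centers[i]) / widths[i]) ** 2
        V += heights[i] * np.exp(-0.5 * d2.sum(axis=1))
        num = logsumexp(beta * gamma / (gamma - 1.0) * V)
        den = logsumexp(beta / (gamma - 1.0) * V)
        out_t.append(times[i])
        out_c.append(kbt * (num - den))
    return RctSeries(times=np.array(out_t), values=np.array(out_c))


# ---------------------------------------------------------------------------
# frame weights and FES projection
# ---------------------------------------------------------------------------

def frame_weights(colvar: ColvarTable, rct: RctSeries,
                  temperature: float = 300.0,
                  kt: float | None = None) -> np.ndarray:
    """Normalized unbiased weight per frame: w_t ~ exp(beta (V_t - c(t))).

    V_t is the instantaneous bias recorded in the COLVAR bias column; c(t)
    is interpolated stepwise-constant between depositions (frames before
    the first deposition get c = 0).  Weights sum to one.
    """
    kbt = thermal_energy(temperature, kt)
    V = colvar.bias()
    c = rct.at(colvar.times)
    logw = (V - c) / kbt
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def project_fes(observables: np.ndarray, weights: np.ndarray,
                bins: int | tuple[int, ...] = DEFAULT_BINS,
                range_: list[tuple[float, float]] | None = None,
                temperature: float = 300.0,
                kt: float | None = None) -> FESGrid:
    """Weighted free-energy surface F = -kT ln(sum of weights per bin).

    ``observables`` is (T,) for 1-D or (T, 2) for 2-D projections; the
    minimum over occupied bins is shifted to zero and empty bins are
    flagged rather than assigned a number.
    """
    kbt = thermal_energy(temperature, kt)
    obs = np.asarray(observables, dtype=float)
    if obs.ndim == 1:
        obs = obs[:, None]
    if obs.ndim != 2 or obs.shape[1] > 2:
        raise ValueError("only 1-D and 2-D projections are supported")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(obs):
        raise ValueError("observable and weight lengths differ")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    hist, edges = np.histogramdd(obs, bins=bins, range=range_, weights=w)
    empty = hist <= 0.0
    if empty.all():
        raise ValueError("no weight fell inside the requested range")
    F = np.full(hist.shape, np.nan)
    with np.errstate(divide="ignore"):
        F[~empty] = -kbt * np.log(hist[~empty] / total)
    F[~empty] -= F[~empty].min()
    return FESGrid(edges=[np.asarray(e) for e in edges], free_energy=F,
                   empty=empty, kt=kbt)


def reweight_run(colvar: ColvarTable, hills: list[HillsRecord],
                 bias_factor: float,
                 observables: np.ndarray | None = None,
                 bins: int | tuple[int, ...] = DEFAULT_BINS,
                 temperature: float = 300.0,
                 kt: float | None = None,
                 rct_bins: int = DEFAULT_BINS,
                 ) -> tuple[FESGrid, np.ndarray, RctSeries]:
    """Full reweighting chain: c(t) -> frame weights -> projected FES.

    ``observables`` defaults to the COLVAR CV columns themselves.  Returns
    (FESGrid, weights, RctSeries).
    """
    rct = compute_rct(hills, bias_factor, temperature, kt, bins=rct_bins)
    w = frame_weights(colvar, rct, temperature, kt)
    if observables is None:
        observables = colvar.cv_values()
    fes = project_fes(observables, w, bins=bins,
                      temperature=temperature, kt=kt)
    return fes, w, rct
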