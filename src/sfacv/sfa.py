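"""Slow feature analysis (SFA) by whitening plus PCA on finite differences.

Given a J-dimensional input signal C(t), SFA finds output signals
y_k(t) = g_k(c(t)) minimizing the slowness

    Delta(y_k) = <ydot_k^2>      (mean squared one-step difference)

subject to zero mean, unit variance, and mutual decorrelation of the
outputs.  The classical closed-form solution proceeds in four stages:

1. normalize each input column to zero mean and unit (population) variance;
2. optionally expand with all degree-1 and degree-2 monomials
   (quadratic SFA) -- linear SFA skips this;
3. whiten (sphere) the expanded signal, z(t) = S(Z(t) - <Z>), so that
   <z z^T> = I on the retained rank;
4. eigendecompose the second moment of the forward differences
   <zdot zdot^T> w_k = lambda_k w_k and keep the eigenvectors with the
   SMALLEST eigenvalues, ascending.

The slowness of each output then equals its eigenvalue exactly:
Delta(y_k) = lambda_k.  Unlike tICA there is no lag-time parameter anywhere.

All temporal averages use population (1/T) normalization, matching the
<.> notation; finite differences are forward, computed within independent
trajectory segments only, never across a segment boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureSeries

logger = logging.getLogger(__name__)

#: Whitening variance floor: principal components with eigenvalue below
#: this fraction of the largest are discarded (near-null directions explode
#: under D^(-1/2) and contaminate the slowest features).
VARIANCE_FLOOR = 1e-10

#: Relative variance below which an input column counts as degenerate
#: (constant) and is dropped with a warning rather than failing the fit.
DEGENERATE_VARIANCE = 1e-12


class SFAError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SFAModel:
    """A fitted slow-feature transform.

    ``means``/``scales`` normalize the raw inputs; ``sphering`` (K x M) and
    ``expansion_mean`` (M) whiten the (possibly expanded) signal; ``weights``
    (n_components x K) hold the unit-norm slow-feature vectors with
    eigenvalues ascending.
    """

    names: list[str]
    means: np.ndarray
    scales: np.ndarray
    order: int
    expansion_mean: np.ndarray
    sphering: np.ndarray
    weights: np.ndarray
    eigenvalues: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.expansion_mean = np.asarray(self.expansion_mean, dtype=float)
        self.sphering = np.asarray(self.sphering, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.order not in (1, 2):
            raise SFAError("expansion order must be 1 or 2")
        if np.any(np.diff(self.eigenvalues) < 0):
            raise SFAError("eigenvalues must be ascending")
        if np.any(self.eigenvalues < -1e-12):
            raise SFAError("eigenvalues must be non-negative")
        if self.weights.shape[0] > self.rank:
            raise SFAError("more weight vectors than retained rank")

    @property
    def rank(self) -> int:
        return self.sphering.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model as self-describing JSON (bit-stable round trip)."""
        doc = {
            "format": "sfacv-model-v1",
            "names": self.names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "order": self.order,
            "expansion_mean": self.expansion_mean.tolist(),
            "sphering": self.sphering.tolist(),
            "weights": self.weights.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "dropped": self.dropped,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SFAModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "sfacv-model-v1":
            raise SFAError(f"{path}: not an sfacv model file")
        return cls(
            names=doc["names"],
            means=np.array(doc["means"]),
            scales=np.array(doc["scales"]),
            order=doc["order"],
            expansion_mean=np.array(doc["expansion_mean"]),
            sphering=np.array(doc["sphering"]),
            weights=np.array(doc["weights"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            dropped=doc.get("dropped", []),
        )


@dataclass
class SlowFeatureSeries:
    """T x K' table of slow-feature outputs with segments and eigenvalues."""

    values: np.ndarray
    segment_starts: np.ndarray
    eigenvalues: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.segment_starts = np.asarray(self.segment_starts, dtype=np.int64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def normalize(x: FeatureSeries) -> tuple[FeatureSeries, np.ndarray, np.ndarray]:
    """Center and scale each column to mean 0, population variance 1.

    Averages span all frames of all segments.  Columns with (relatively)
    zero variance are dropped with a logged warning; they carry no temporal
    signal and would make the scaling singular.
    """
    mu = x.values.mean(axis=0)
    var = x.values.var(axis=0)  # population (1/T)
    max_var = var.max()
    if max_var <= 0.0:
        raise SFAError("all input columns are constant")
    keep = var > DEGENERATE_VARIANCE * max_var
    if not np.all(keep):
        dropped = [n for n, k in zip(x.names, keep) if not k]
        logger.warning("dropping %d zero-variance column(s): %s",
                       len(dropped), ", ".join(dropped))
    sigma = np.sqrt(var[keep])
    vals = (x.values[:, keep] - mu[keep]) / sigma
    fs = FeatureSeries(values=vals,
                       names=[n for n, k in zip(x.names, keep) if k],
                       segment_starts=x.segment_starts.copy(), dt=x.dt)
    return fs, mu[keep], sigma


def expansion_names(names: list[str], order: int) -> list[str]:
    if order == 1:
        return list(names)
    out = list(names)
    for i, ni in enumerate(names):
        for nj in names[i:]:
            out.append(f"{ni}*{nj}")
    return out


def expand(values: np.ndarray, order: int) -> np.ndarray:
    """Monomial expansion H(c): order 1 is the identity; order 2 appends all
    degree-2 monomials including mixed terms, in the order
    c1..cJ, c1c1, c1c2, .., cJcJ."""
    if order == 1:
        return values
    if order != 2:
        raise SFAError("expansion order must be 1 or 2")
    T, J = values.shape
    cols = [values]
    for i in range(J):
        cols.append(values[:, i:i + 1] * values[:, i:])
    return np.hstack(cols)


def whiten(Z: np.ndarray,
           floor: float = VARIANCE_FLOOR,
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Sphere the expanded signal: z = S (Z - <Z>) with <z z^T> = I.

    S = D^(-1/2) U^T from the eigendecomposition of the covariance of
    (Z - <Z>); principal components with eigenvalue below ``floor`` times
    the largest are discarded (rank truncation).  Returns
    (z, S, <Z>, rank).
    """
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    cov = (Zc.T @ Zc) / Z.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0.0:
        raise SFAError("cannot whiten an all-zero signal")
    keep = evals > floor * evals[-1]
    # descending variance order for a stable, documented component order
    evals, evecs = evals[keep][::-1], evecs[:, keep][:, ::-1]
    S = evecs.T / np.sqrt(evals)[:, None]
    return Zc @ S.T, S, zbar, int(evals.size)


def time_derivative(z: np.ndarray, segment_starts: np.ndarray) -> np.ndarray:
    """Forward differences within each segment; none straddle a boundary.

    Output has T - n_segments rows.
    """
    seg = np.asarray(segment_starts, dtype=np.int64)
    bounds = np.append(seg, z.shape[0])
    if np.any(np.diff(bounds) < 2):
        raise SFAError("every segment needs at least 2 frames")
    dz = np.diff(z, axis=0)
    # forward difference at the last frame of a segment would cross into the
    # next segment; delete those rows
    drop = seg[1:] - 1
    return np.delete(dz, drop, axis=0) if drop.size else dz


def delta_value(y: np.ndarray, segment_starts: np.ndarray) -> float:
    """Slowness Delta(y) = <ydot^2>: mean squared forward difference,
    segment-aware.  Equals the SFA eigenvalue on training output."""
    y = np.asarray(y, dtype=float)
    dy = time_derivative(y.reshape(len(y), -1), segment_starts)
    return float(np.mean(np.sum(dy * dy, axis=1)))


# ---------------------------------------------------------------------------
# fit / transform
# ---------------------------------------------------------------------------

def fit(x: FeatureSeries, order: int = 1, n_components: int = 2) -> SFAModel:
    """Fit SFA: normalize -> expand -> whiten -> finite differences -> PCA.

    Keeps the ``n_components`` eigenvectors of *smallest* eigenvalue of the
    raw second moment of the whitened differences, eigenvalues ascending.
    Each weight vector's sign is fixed so its largest-magnitude pulled-back
    input coefficient is positive (slow features are sign-indeterminate).
    """
    if order not in (1, 2):
        raise SFAError("expansion order must be 1 or 2")
    if n_components < 1:
        raise SFAError("need at least one component")

    normed, mu, sigma = normalize(x)
    Z = expand(normed.values, order)
    z, S, zbar, rank = whiten(Z)
    if n_components > rank:
        raise SFAError(
            f"n_components={n_components} exceeds retained rank {rank}")
    dz = time_derivative(z, normed.segment_starts)
    # raw (uncentered) second moment of the differences
    M = (dz.T @ dz) / dz.shape[0]
    evals, evecs = np.linalg.eigh(M)  # ascending
    order_idx = np.argsort(evals, kind="stable")
    evals, evecs = evals[order_idx], evecs[:, order_idx]
    W = evecs[:, :n_components].T.copy()
    lam = np.clip(evals[:n_components], 0.0, None)

    model = SFAModel(names=normed.names, means=mu, scales=sigma, order=order,
                     expansion_mean=zbar, sphering=S, weights=W,
                     eigenvalues=lam,
                     dropped=[n for n in x.names if n not in normed.names])
    _fix_signs(model)
    return model


def _fix_signs(model: SFAModel) -> None:
    """Flip each w_k so its largest-|pull-back| coefficient is positive."""
    for k in range(model.n_components):
        coeffs = _pullback_row(model, k)
        j = int(np.argmax(np.abs(coeffs)))  # ties -> first index
        if coeffs[j] < 0:
            model.weights[k] = -model.weights[k]


def _pullback_row(model: SFAModel, k: int) -> np.ndarray:
    """Coefficients of component k on the (normalized-then-unscaled) inputs.

    For order 1 the slow feature is exactly affine in the raw inputs:
    y_k = sum_j a_j X_j + b with a_j = (w_k^T S)_j / sigma_j.  For order 2
    the same row gives the coefficients per expanded monomial of the
    normalized signal (no 1/sigma pull-back is possible for products).
    """
    row = model.weights[k] @ model.sphering
    if model.order == 1:
        return row / model.scales
    return row


def pullback_affine(model: SFAModel, k: int) -> tuple[float, np.ndarray]:
    """Express order-1 slow feature k (1-based) as offset + coeffs . X.

    Returns (offset, coefficients aligned with ``model.names``) such that
    evaluating the affine map on raw inputs reproduces ``transform``.
    """
    if model.order != 1:
        raise SFAError("affine pull-back requires an order-1 model")
    if not (1 <= k <= model.n_components):
        raise SFAError(f"component {k} out of range")
    row = model.weights[k - 1] @ model.sphering
    coeffs = row / model.scales
    offset = -float(coeffs @ model.means) - float(row @ model.expansion_mean)
    return offset, coeffs


def rank_weights(model: SFAModel, k: int) -> list[tuple[str, float]]:
    """Feature attribution for component k (1-based).

    Pull-back coefficient per named input feature, sorted by absolute value
    descending (ties broken by original feature index).  For an order-2
    model the attribution is per expanded monomial of the normalized signal.
    """
    if not (1 <= k <= model.n_components):
        raise SFAError(f"component {k} out of range")
    coeffs = _pullback_row(model, k - 1)
    names = expansion_names(model.names, model.order)
    idx = sorted(range(len(coeffs)), key=lambda j: (-abs(coeffs[j]), j))
    return [(names[j], float(coeffs[j])) for j in idx]


def transform(model: SFAModel, x: FeatureSeries) -> SlowFeatureSeries:
    """Apply a fitted model: y_k(t) = w_k . S(H(c(t)) - <Z>).

    Input columns are matched to the model's features by NAME, so column
    order is irrelevant.  On its own training data the output has zero mean,
    unit variance, decorrelated components, and Delta(y_k) = lambda_k.
    """
    pos = {n: j for j, n in enumerate(x.names)}
    missing = [n for n in model.names if n not in pos]
    if missing:
        raise SFAError(f"input lacks model feature(s): {missing}")
    unknown = [n for n in x.names
               if n not in model.names and n not in model.dropped]
    if unknown:
        raise SFAError(f"unknown feature name(s): {unknown}")
    cols = [pos[n] for n in model.names]
    c = (x.values[:, cols] - model.means) / model.scales
    Z = expand(c, model.order)
    y = (Z - model.expansion_mean) @ model.sphering.T @ model.weights.T
    return SlowFeatureSeries(values=y, segment_starts=x.segment_starts.copy(),
                             eigenvalues=model.eigenvalues.copy(), dt=x.dt)
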