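"""Dihedral featurization of MD trajectories.

Turns coordinate trajectories into time-ordered tables of periodic
side-chain/backbone dihedral features (sin/cos expanded), the input signal
consumed by slow feature analysis.  Feature names are carried through the
whole pipeline so that slow-feature weights can be attributed back to
individual torsions.

Conventions
-----------
* Coordinates are stored in nm (GROMACS convention, matching PLUMED).
* Dihedrals follow the IUPAC signed convention: the angle between the two
  plane normals computed with a two-argument arctangent; cis = 0, range
  (-pi, pi].
* Frame indexing is 0-based; times are ``frame_index * dt`` with ``dt`` in ps.
* Independent trajectories concatenated into one table keep explicit segment
  boundaries; downstream finite differences never straddle a boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

ANGLE_KINDS = ("phi", "psi", "chi1", "chi2")

# Heavy-atom quadruples for side-chain torsions.  chi1 is N-CA-CB-<G>,
# chi2 is CA-CB-<G>-<D>, with the conventional heavy-atom choice per
# residue type.  Residues absent from a map do not define that angle.
_CHI1_G = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
}
_CHI2_GD = {
    "ARG": ("CG", "CD"), "GLN": ("CG", "CD"), "GLU": ("CG", "CD"),
    "LYS": ("CG", "CD"), "PRO": ("CG", "CD"),
    "ILE": ("CG1", "CD1"), "LEU": ("CG", "CD1"),
    "PHE": ("CG", "CD1"), "TYR": ("CG", "CD1"), "TRP": ("CG", "CD1"),
    "HIS": ("CG", "ND1"), "ASP": ("CG", "OD1"), "ASN": ("CG", "OD1"),
    "MET": ("CG", "SD"),
}


class FeaturizationError(ValueError):
    """A requested featurization cannot be carried out."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_segments(segment_starts: np.ndarray, n_frames: int,
                    min_len: int = 1) -> np.ndarray:
    seg = np.asarray(segment_starts, dtype=np.int64)
    if seg.ndim != 1 or seg.size == 0 or seg[0] != 0:
        raise ValueError("segment starts must be 1-D and begin with 0")
    if np.any(np.diff(seg) <= 0):
        raise ValueError("segment starts must be strictly increasing")
    if seg[-1] >= n_frames:
        raise ValueError("segment start beyond the last frame")
    bounds = np.append(seg, n_frames)
    if np.any(np.diff(bounds) < min_len):
        raise ValueError(f"every segment needs at least {min_len} frames")
    return seg


@dataclass
class CoordinateTrajectory:
    """Frames of per-atom 3-D positions plus atom metadata.

    ``xyz`` is (T, N, 3) in nm.  ``atom_names``/``residue_names``/
    ``residue_ids`` have length N.  ``dt`` is the frame spacing in ps.
    """

    xyz: np.ndarray
    atom_names: list[str]
    residue_names: list[str]
    residue_ids: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.xyz.shape[1]
        if not (len(self.atom_names) == len(self.residue_names)
                == len(self.residue_ids) == n_atoms):
            raise ValueError("atom metadata length must equal atom count")
        if self.dt <= 0:
            raise ValueError("frame spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]


@dataclass
class DihedralSeries:
    """T x D table of dihedral angles in radians, values in (-pi, pi]."""

    values: np.ndarray
    labels: list[str]
    segment_starts: np.ndarray = field(default_factory=lambda: np.array([0]))
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x angles)")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count must match angle count")
        if np.any(self.values <= -np.pi) or np.any(self.values > np.pi):
            raise ValueError("dihedral values must lie in (-pi, pi]")
        self.segment_starts = _check_segments(
            self.segment_starts, self.values.shape[0])
        if self.dt <= 0:
            raise ValueError("frame spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureSeries:
    """T x J real-valued feature table with named columns and segments."""

    values: np.ndarray
    names: list[str]
    segment_starts: np.ndarray = field(default_factory=lambda: np.array([0]))
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be 2-D with at least one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("name count must match column count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        self.segment_starts = _check_segments(
            self.segment_starts, self.values.shape[0], min_len=2)
        if self.dt <= 0:
            raise ValueError("frame spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# trajectory reading
# ---------------------------------------------------------------------------

def read_trajectory(trajectory_path: str | Path,
                    topology_path: str | Path | None = None,
                    dt: float | None = None) -> CoordinateTrajectory:
    """Load a coordinate trajectory (XTC/DCD/TRR/PDB...) with its topology.

    Coordinates are returned in nm.  ``dt`` overrides the frame spacing in
    ps when the file carries none (single-frame PDBs, some DCDs).
    """
    import mdtraj as md

    trajectory_path = Path(trajectory_path)
    if not trajectory_path.exists():
        raise FileNotFoundError(trajectory_path)
    kwargs = {}
    if topology_path is not None:
        topology_path = Path(topology_path)
        if not topology_path.exists():
            raise FileNotFoundError(topology_path)
        kwargs["top"] = str(topology_path)
    try:
        traj = md.load(str(trajectory_path), **kwargs)
    except (OSError, ValueError, IndexError) as exc:
        raise FeaturizationError(
            f"cannot read trajectory {trajectory_path}: {exc}") from exc

    top = traj.topology
    spacing = dt
    if spacing is None:
        if traj.n_frames > 1 and traj.time is not None:
            diffs = np.diff(traj.time)
            spacing = float(diffs[0]) if np.all(diffs > 0) else 1.0
        else:
            spacing = 1.0
    return CoordinateTrajectory(
        xyz=np.asarray(traj.xyz, dtype=float),
        atom_names=[a.name for a in top.atoms],
        residue_names=[a.residue.name for a in top.atoms],
        residue_ids=np.array([a.residue.resSeq for a in top.atoms]),
        dt=spacing,
    )


# ---------------------------------------------------------------------------
# dihedral geometry
# ---------------------------------------------------------------------------

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> np.ndarray:
    """Signed dihedral of the quadruple (p0, p1, p2, p3), vectorized.

    IUPAC convention via the two plane normals and atan2: cis = 0,
    trans = pi, values in (-pi, pi].  Inputs are (..., 3) arrays.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m = np.cross(b2n, n1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    ang = np.arctan2(y, x)
    # atan2 returns [-pi, pi]; fold the closed lower end onto +pi
    return np.where(ang == -np.pi, np.pi, ang)


def _atom_index(traj: CoordinateTrajectory, resid: int, name: str) -> int:
    hits = [i for i in range(traj.n_atoms)
            if traj.residue_ids[i] == resid and traj.atom_names[i] == name]
    if not hits:
        raise FeaturizationError(
            f"residue {resid} has no atom {name!r}")
    return hits[0]


def _quadruple(traj: CoordinateTrajectory, resid: int,
               kind: str) -> tuple[int, int, int, int]:
    resname = None
    for i in range(traj.n_atoms):
        if traj.residue_ids[i] == resid:
            resname = traj.residue_names[i]
            break
    if resname is None:
        raise FeaturizationError(f"residue id {resid} not in topology")

    if kind == "chi1":
        g = _CHI1_G.get(resname)
        if g is None:
            raise FeaturizationError(
                f"{resname}{resid} does not define chi1")
        names = [(resid, "N"), (resid, "CA"), (resid, "CB"), (resid, g)]
    elif kind == "chi2":
        gd = _CHI2_GD.get(resname)
        if gd is None:
            raise FeaturizationError(
                f"{resname}{resid} does not define chi2")
        names = [(resid, "CA"), (resid, "CB"), (resid, gd[0]), (resid, gd[1])]
    elif kind == "phi":
        names = [(resid - 1, "C"), (resid, "N"), (resid, "CA"), (resid, "C")]
    elif kind == "psi":
        names = [(resid, "N"), (resid, "CA"), (resid, "C"), (resid + 1, "N")]
    else:
        raise FeaturizationError(
            f"unknown angle kind {kind!r}; expected one of {ANGLE_KINDS}")
    return tuple(_atom_index(traj, r, n) for r, n in names)  # type: ignore


def compute_dihedrals(traj: CoordinateTrajectory,
                      selection: Sequence[tuple[int, str]],
                      segment_starts: Sequence[int] | None = None,
                      ) -> DihedralSeries:
    """Compute the selected (residue id, angle kind) dihedrals per frame.

    Every selection entry must be resolvable to its standard atom quadruple;
    a residue lacking the angle (e.g. chi2 of ALA) raises rather than being
    silently skipped.
    """
    if not selection:
        raise FeaturizationError("empty dihedral selection")
    quadruples, labels = [], []
    for resid, kind in selection:
        quadruples.append(_quadruple(traj, resid, kind))
        resname = next(traj.residue_names[i] for i in range(traj.n_atoms)
                       if traj.residue_ids[i] == resid)
        labels.append(f"{kind}_{resname}{resid}")
    idx = np.array(quadruples)  # (D, 4)
    vals = dihedral_angle(traj.xyz[:, idx[:, 0]], traj.xyz[:, idx[:, 1]],
                          traj.xyz[:, idx[:, 2]], traj.xyz[:, idx[:, 3]])
    seg = np.array([0]) if segment_starts is None else np.asarray(segment_starts)
    return DihedralSeries(values=vals, labels=labels,
                          segment_starts=seg, dt=traj.dt)


def torsion_atoms_from_trajectory(
        traj: CoordinateTrajectory,
        selection: Sequence[tuple[int, str]],
) -> dict[str, tuple[int, int, int, int]]:
    """Map torsion labels to 1-based atom serials for PLUMED emission."""
    out = {}
    for resid, kind in selection:
        quad = _quadruple(traj, resid, kind)
        resname = next(traj.residue_names[i] for i in range(traj.n_atoms)
                       if traj.residue_ids[i] == resid)
        out[f"{kind}_{resname}{resid}"] = tuple(i + 1 for i in quad)
    return out


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def sincos_expand(d: DihedralSeries) -> FeatureSeries:
    """Expand each angle into (sin, cos), interleaved per angle.

    The sin/cos map removes the branch cut of the periodic angles; the
    resulting 2D-column table is the standard SFA input for dihedral data.
    """
    T, D = d.values.shape
    vals = np.empty((T, 2 * D))
    names: list[str] = []
    for j, lab in enumerate(d.labels):
        vals[:, 2 * j] = np.sin(d.values[:, j])
        vals[:, 2 * j + 1] = np.cos(d.values[:, j])
        names.extend([f"sin_{lab}", f"cos_{lab}"])
    return FeatureSeries(values=vals, names=names,
                         segment_starts=d.segment_starts.copy(), dt=d.dt)


def concat_segments(series: Sequence[FeatureSeries]) -> FeatureSeries:
    """Stack independent trajectories, recording every original start.

    All inputs must share feature names (same order) and frame spacing.
    """
    if not series:
        raise ValueError("need at least one series")
    first = series[0]
    for s in series[1:]:
        if s.names != first.names:
            raise ValueError("feature names differ between series")
        if s.dt != first.dt:
            raise ValueError("frame spacing differs between series")
    values = np.vstack([s.values for s in series])
    starts: list[int] = []
    offset = 0
    for s in series:
        starts.extend((s.segment_starts + offset).tolist())
        offset += s.n_frames
    return FeatureSeries(values=values, names=list(first.names),
                         segment_starts=np.array(starts), dt=first.dt)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def write_features(fs: FeatureSeries, path: str | Path) -> None:
    """Write a FeatureSeries as self-describing TSV.

    Header comments carry frame spacing and segment starts; the first
    non-comment row is the tab-separated name header, then one row per frame.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frame_spacing_ps: {fs.dt!r}\n")
        fh.write("# segment_starts: "
                 + ",".join(str(i) for i in fs.segment_starts) + "\n")
        fh.write("\t".join(fs.names) + "\n")
        np.savetxt(fh, fs.values, fmt="%.17g", delimiter="\t")


def read_features(path: str | Path) -> FeatureSeries:
    """Read the TSV dialect written by :func:`write_features`."""
    path = Path(path)
    dt, starts, names = 1.0, [0], None
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("# frame_spacing_ps:"):
            dt = float(line.split(":", 1)[1])
        elif line.startswith("# segment_starts:"):
            starts = [int(s) for s in line.split(":", 1)[1].split(",")]
        elif not line.startswith("#"):
            names = line.rstrip("\n").split("\t")
            data_start = i + 1
            break
    if names is None:
        raise ValueError(f"{path}: no header row found")
    values = np.loadtxt(lines[data_start:], delimiter="\t", ndmin=2)
    return FeatureSeries(values=values, names=names,
                         segment_starts=np.array(starts), dt=dt)
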