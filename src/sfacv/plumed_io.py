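"""PLUMED input emission and COLVAR/HILLS parsing.

A fitted order-1 slow-feature model over sin/cos torsion features is
exactly an affine combination of sines and cosines of named torsions, so it
can be exported bit-exactly as PLUMED 2.x actions: one TORSION per unique
torsion, one CUSTOM per collective variable, a METAD action carrying the
well-tempered parameters, and optionally a hand-built funnel restraint
(cone + cylinder wall) for ligand-binding runs.

Dialect: PLUMED 2.x keyword syntax, 1-based atom serials, energies in
kJ/mol, times in ps, angles in rad.  Numeric fields are formatted with 9
significant digits so identical inputs always yield identical bytes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sfa import SFAModel, SlowFeatureSeries, pullback_affine

logger = logging.getLogger(__name__)


class PlumedIOError(ValueError):
    pass


def _fmt(x: float) -> str:
    """Repeatable fixed format, 9 significant digits."""
    return format(float(x), ".9g")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CVSpec:
    """A slow feature flattened to an affine form over sin/cos torsions.

    ``terms`` maps base-feature labels (``sin_<torsion>`` / ``cos_<torsion>``)
    to coefficients; evaluation is ``offset + sum coeff * feature``.
    """

    name: str
    offset: float
    terms: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not any(c != 0.0 for _, c in self.terms):
            raise PlumedIOError(f"CV {self.name!r} has no nonzero coefficient")
        for label, _ in self.terms:
            kind = label.split("_", 1)[0]
            if kind not in ("sin", "cos"):
                raise PlumedIOError(
                    f"CV {self.name!r}: base feature {label!r} is not a "
                    "sin/cos of a torsion")

    @property
    def torsions(self) -> list[str]:
        """Unique torsion labels referenced, in first-appearance order."""
        seen: list[str] = []
        for label, _ in self.terms:
            tor = label.split("_", 1)[1]
            if tor not in seen:
                seen.append(tor)
        return seen

    def evaluate(self, features: dict[str, np.ndarray]) -> np.ndarray:
        """Evaluate the affine form given named base-feature arrays."""
        out = np.full_like(next(iter(features.values())), self.offset,
                           dtype=float)
        for label, coeff in self.terms:
            out = out + coeff * features[label]
        return out


@dataclass
class MetadParams:
    """Well-tempered metadynamics parameters (the published defaults:
    1.50 kJ/mol Gaussians every 500 steps, bias factor 20, 300 K)."""

    height: float = 1.50
    pace: int = 500
    bias_factor: float = 20.0
    widths: tuple[float, ...] = ()
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise PlumedIOError("Gaussian height must be > 0")
        if self.bias_factor <= 1:
            raise PlumedIOError("bias factor must be > 1")
        if self.pace < 1:
            raise PlumedIOError("deposition pace must be >= 1")
        if any(w <= 0 for w in self.widths):
            raise PlumedIOError("Gaussian widths must be > 0")


@dataclass
class FunnelSpec:
    """Funnel restraint: cone of half-angle ``alpha`` up to ``z_cc``, then a
    cylinder of radius ``r_cyl``, enforced by a harmonic upper wall."""

    z_cc: float = 2.0            # nm, cone-to-cylinder switch point
    r_cyl: float = 0.1           # nm, cylinder radius
    alpha: float = 0.5           # rad, cone half-angle
    spring: float = 50000.0      # kJ/mol/nm^2, wall constant
    ligand_atoms: tuple[int, ...] = ()   # 1-based serials, ligand COM
    anchor_atoms: tuple[int, ...] = ()   # 1-based serials, e.g. catalytic dyad

    def __post_init__(self) -> None:
        for val, nm in ((self.z_cc, "z_cc"), (self.r_cyl, "r_cyl"),
                        (self.alpha, "alpha"), (self.spring, "spring")):
            if val <= 0:
                raise PlumedIOError(f"funnel parameter {nm} must be > 0")
        if not self.ligand_atoms or not self.anchor_atoms:
            raise PlumedIOError("funnel needs ligand and anchor atom groups")


@dataclass
class HillsRecord:
    """One deposited Gaussian from a HILLS file."""

    time: float                   # ps
    centers: np.ndarray           # per CV
    widths: np.ndarray            # per CV
    height: float                 # kJ/mol (actual deposited height)
    bias_factor: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if np.any(self.widths <= 0):
            raise PlumedIOError("hill widths must be > 0")
        if self.height < 0:
            raise PlumedIOError("hill height must be >= 0")


@dataclass
class ColvarTable:
    """Parsed COLVAR file: time-sorted CV + bias time series."""

    df: pd.DataFrame
    cv_names: list[str] = field(default_factory=list)
    bias_column: str | None = None

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy()

    def cv_values(self) -> np.ndarray:
        return self.df[self.cv_names].to_numpy()

    def bias(self) -> np.ndarray:
        if self.bias_column is None:
            raise PlumedIOError("COLVAR table has no bias column")
        return self.df[self.bias_column].to_numpy()


# ---------------------------------------------------------------------------
# model -> CV export
# ---------------------------------------------------------------------------

def cv_from_model(model: SFAModel,
                  components: tuple[int, ...] = (1, 2),
                  ) -> list[CVSpec]:
    """Flatten slow features (1-based indices) into explicit affine CVs.

    Requires an order-1 model whose retained features are all sin/cos of
    torsions; the offset folds the input means/scales and expansion mean, so
    evaluating the CVSpec on any frame reproduces ``transform`` exactly.
    """
    if model.order != 1:
        raise PlumedIOError(
            "PLUMED export supports order-1 (linear) models only")
    for n in model.names:
        if n.split("_", 1)[0] not in ("sin", "cos"):
            raise PlumedIOError(
                f"model feature {n!r} is not a sin/cos torsion feature")
    specs = []
    for k in components:
        offset, coeffs = pullback_affine(model, k)
        specs.append(CVSpec(name=f"SF{k}", offset=offset,
                            terms=list(zip(model.names, map(float, coeffs)))))
    return specs


def gaussian_width_heuristic(y: SlowFeatureSeries,
                             n_frames: int = 10000) -> np.ndarray:
    """Per-CV Gaussian width: 1/3 of the standard deviation of each slow
    feature over the first ``n_frames`` frames of the training data."""
    if y.n_frames == 0:
        raise PlumedIOError("empty slow-feature series")
    if y.n_frames < n_frames:
        warnings.warn(
            f"only {y.n_frames} frames available for the width heuristic "
            f"(wanted {n_frames}); using all of them", stacklevel=2)
    window = y.values[:min(n_frames, y.n_frames)]
    return window.std(axis=0) / 3.0


# ---------------------------------------------------------------------------
# PLUMED input emission
# ---------------------------------------------------------------------------

def _torsion_action_label(torsion: str) -> str:
    return f"t_{torsion}"


def _cv_action(cv: CVSpec, torsion_vars: dict[str, str]) -> str:
    """CUSTOM action evaluating the affine sin/cos combination."""
    parts = [_fmt(cv.offset)]
    for label, coeff in cv.terms:
        if coeff == 0.0:
            continue
        kind, torsion = label.split("_", 1)
        parts.append(f"({_fmt(coeff)}*{kind}({torsion_vars[torsion]}))")
    func = "+".join(parts)
    args = ",".join(_torsion_action_label(t) for t in cv.torsions)
    var = ",".join(torsion_vars[t] for t in cv.torsions)
    return (f"{cv.name}: CUSTOM ARG={args} VAR={var} FUNC={func} PERIODIC=NO")


def _funnel_block(funnel: FunnelSpec) -> list[str]:
    lig = ",".join(str(i) for i in funnel.ligand_atoms)
    anc = ",".join(str(i) for i in funnel.anchor_atoms)
    # Hand-built funnel: ligand-COM displacement from the anchor COM is split
    # into an axial component fz (funnel axis taken along the box z axis
    # after orientational fitting) and a radial component frho; the allowed
    # radius R(z) is r_cyl beyond the switch point z_cc and widens as a cone
    # of half-angle alpha below it.  A harmonic upper wall penalizes
    # frho > R(z).
    r_of_z = (f"{_fmt(funnel.r_cyl)}+step({_fmt(funnel.z_cc)}-x)*"
              f"({_fmt(funnel.z_cc)}-x)*tan({_fmt(funnel.alpha)})")
    return [
        "# funnel restraint (cone + cylinder wall)",
        f"lig: COM ATOMS={lig}",
        f"anchor: COM ATOMS={anc}",
        "fdisp: DISTANCE ATOMS=anchor,lig COMPONENTS",
        "fz: COMBINE ARG=fdisp.z PERIODIC=NO",
        "frho: CUSTOM ARG=fdisp.x,fdisp.y VAR=x,y FUNC=sqrt(x*x+y*y) "
        "PERIODIC=NO",
        f"fradius: CUSTOM ARG=fz VAR=x FUNC={r_of_z} PERIODIC=NO",
        "fviol: CUSTOM ARG=frho,fradius VAR=x,y FUNC=step(x-y)*(x-y) "
        "PERIODIC=NO",
        f"funnelwall: UPPER_WALLS ARG=fviol AT=0 KAPPA={_fmt(funnel.spring)}",
    ]


def write_plumed_metad(cvs: list[CVSpec],
                       params: MetadParams,
                       torsion_atoms: dict[str, tuple[int, int, int, int]],
                       funnel: FunnelSpec | None = None,
                       path: str | Path | None = None,
                       colvar_stride: int = 500,
                       hills_file: str = "HILLS",
                       colvar_file: str = "COLVAR") -> str:
    """Emit a complete PLUMED 2.x well-tempered metadynamics input.

    ``torsion_atoms`` maps torsion labels to 1-based atom serial quadruples.
    Output is byte-stable given identical inputs; the text is returned and,
    when ``path`` is given, also written there.
    """
    names = [cv.name for cv in cvs]
    if len(set(names)) != len(names):
        raise PlumedIOError(f"duplicate CV names: {names}")
    if len(params.widths) != len(cvs):
        raise PlumedIOError(
            f"{len(params.widths)} widths given for {len(cvs)} CVs")

    torsions: list[str] = []
    for cv in cvs:
        for t in cv.torsions:
            if t not in torsions:
                torsions.append(t)
    missing = [t for t in torsions if t not in torsion_atoms]
    if missing:
        raise PlumedIOError(f"no atom quadruple for torsion(s): {missing}")

    lines = ["# PLUMED input generated by sfacv",
             "# slow-feature CVs as affine sin/cos torsion combinations"]
    torsion_vars = {t: f"x{i}" for i, t in enumerate(torsions)}
    for t in torsions:
        serials = ",".join(str(i) for i in torsion_atoms[t])
        lines.append(f"{_torsion_action_label(t)}: TORSION ATOMS={serials}")
    for cv in cvs:
        lines.append(_cv_action(cv, torsion_vars))
    if funnel is not None:
        lines.extend(_funnel_block(funnel))
    arg = ",".join(names)
    sigma = ",".join(_fmt(w) for w in params.widths)
    lines.append(
        f"metad: METAD ARG={arg} SIGMA={sigma} HEIGHT={_fmt(params.height)} "
        f"PACE={params.pace} BIASFACTOR={_fmt(params.bias_factor)} "
        f"TEMP={_fmt(params.temperature)} FILE={hills_file}")
    lines.append(
        f"PRINT ARG={arg},metad.bias STRIDE={colvar_stride} "
        f"FILE={colvar_file}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# COLVAR / HILLS parsing and writing
# ---------------------------------------------------------------------------

def _read_fields_header(path: Path) -> tuple[list[str], list[str]]:
    with path.open() as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise PlumedIOError(f"{path}: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    data = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
    return fields, data


def read_hills(path: str | Path, heights: str = "raw") -> list[HillsRecord]:
    """Parse a PLUMED HILLS file into deposition records.

    Columns are bound by header name.  ``heights='raw'`` takes the height
    column as the actual deposited (already tempered) heights — the PLUMED
    convention; ``heights='scaled'`` rescales by (gamma-1)/gamma for
    dialects that store the un-tempered w(t) instead.  Getting this wrong
    silently corrupts every downstream free energy, hence the explicit flag.
    """
    if heights not in ("raw", "scaled"):
        raise PlumedIOError("heights must be 'raw' or 'scaled'")
    path = Path(path)
    fields, data = _read_fields_header(path)
    if not data:
        raise PlumedIOError(f"{path}: no hills in file")
    if "time" not in fields or "height" not in fields:
        raise PlumedIOError(f"{path}: HILLS header lacks time/height")
    cv_names = []
    for f in fields[1:]:
        if f.startswith("sigma_") or f in ("height", "biasf"):
            break
        cv_names.append(f)
    if not cv_names:
        raise PlumedIOError(f"{path}: no CV columns in HILLS header")
    col = {f: i for i, f in enumerate(fields)}
    records = []
    for ln in data:
        parts = ln.split()
        if len(parts) != len(fields):
            raise PlumedIOError(f"{path}: ragged row: {ln.strip()!r}")
        vals = [float(p) for p in parts]
        biasf = vals[col["biasf"]] if "biasf" in col else None
        height = vals[col["height"]]
        if heights == "scaled" and biasf is not None:
            height *= (biasf - 1.0) / biasf
        records.append(HillsRecord(
            time=vals[col["time"]],
            centers=np.array([vals[col[n]] for n in cv_names]),
            widths=np.array([vals[col[f"sigma_{n}"]] for n in cv_names]),
            height=height,
            bias_factor=biasf))
    return records


def write_hills(records: list[HillsRecord], cv_names: list[str],
                path: str | Path) -> None:
    """Write deposition records in the PLUMED HILLS dialect."""
    if not records:
        raise PlumedIOError("no hills to write")
    has_biasf = records[0].bias_factor is not None
    fields = (["time"] + cv_names + [f"sigma_{n}" for n in cv_names]
              + ["height"] + (["biasf"] if has_biasf else []))
    with Path(path).open("w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for r in records:
            row = ([r.time] + list(r.centers) + list(r.widths) + [r.height]
                   + ([r.bias_factor] if has_biasf else []))
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_colvar(path: str | Path) -> ColvarTable:
    """Parse a PLUMED COLVAR file into a time-sorted table.

    Duplicate times from restarts are deduplicated keeping the LAST
    occurrence; a header-only file yields an empty table.
    """
    path = Path(path)
    fields, data = _read_fields_header(path)
    if "time" not in fields:
        raise PlumedIOError(f"{path}: COLVAR header lacks a time column")
    rows = []
    for ln in data:
        parts = ln.split()
        if len(parts) != len(fields):
            raise PlumedIOError(f"{path}: ragged row: {ln.strip()!r}")
        rows.append([float(p) for p in parts])
    df = pd.DataFrame(rows, columns=fields)
    df = df.drop_duplicates(subset="time", keep="last")
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    bias_cols = [f for f in fields if f.endswith(".bias") or f == "bias"]
    cv_names = [f for f in fields
                if f != "time" and f not in bias_cols and "." not in f]
    return ColvarTable(df=df, cv_names=cv_names,
                       bias_column=bias_cols[0] if bias_cols else None)


def write_colvar(df: pd.DataFrame, path: str | Path) -> None:
    """Write a COLVAR-dialect file from a DataFrame with a 'time' column."""
    fields = list(df.columns)
    if "time" not in fields:
        raise PlumedIOError("COLVAR table needs a 'time' column")
    with Path(path).open("w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for row in df.itertuples(index=False):
            fh.write(" ".join(_fmt(v) for v in row) + "\n")
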