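"""Readers and writers for geometries, embedding sites, trajectories and
run configuration.

File conventions: lengths in Å, everything else in atomic units.  All
in-memory objects are in atomic units (bohr, hartree).  Readers reject
malformed input instead of repairing it; writer/reader pairs round-trip
bit-identically on the text they emit.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, nuclear_charge

log = logging.getLogger("diabatmd")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger with one structured line per record."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Geometry


@dataclass
class Geometry:
    """A QM region: element symbols, nuclear charges and positions (bohr)."""

    symbols: list[str]
    charges: np.ndarray  # nuclear charges, e
    coords: np.ndarray  # (n, 3) bohr
    qm_charge: int = 0
    multiplicity_hint: int = 1

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.symbols)
        if self.coords.shape != (n, 3) or self.charges.shape != (n,):
            raise ValueError("symbols, charges and coords lengths disagree")
        if self.multiplicity_hint < 1:
            raise ValueError("multiplicity_hint must be >= 1")
        if n > 1:
            d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)
            if np.min(d[np.triu_indices(n, k=1)]) <= 1e-6:
                raise ValueError("coincident atoms (pair distance <= 1e-6 bohr)")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(list(self.symbols), self.charges.copy(), np.asarray(coords, float),
                        self.qm_charge, self.multiplicity_hint)

    def distance_matrix(self) -> np.ndarray:
        return np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)


def read_xyz(path) -> Geometry:
    """Read a standard XYZ file (Å) into a Geometry (bohr)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: malformed count line (empty file)")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise ValueError(f"{path}: malformed count line {lines[0]!r}") from None
    body = [ln for ln in lines[2 : 2 + count]]
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count or len(atom_lines) < count:
        raise ValueError(f"{path}: count mismatch (declared {count})")
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {ln!r}")
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    charges = np.array([nuclear_charge(s) for s in symbols], dtype=float)
    return Geometry(symbols, charges, np.array(coords) * BOHR_PER_ANGSTROM)


def write_xyz(geometry: Geometry, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n{comment}\n")
        for s, r in zip(geometry.symbols, geometry.coords * ANGSTROM_PER_BOHR):
            fh.write(f"{s} {r[0]:.12f} {r[1]:.12f} {r[2]:.12f}\n")


# ---------------------------------------------------------------------------
# Embedding sites


@dataclass
class EmbeddingSites:
    """AMOEBA-style environment sites: permanent multipoles through
    quadrupoles plus isotropic polarizabilities.

    positions are bohr; charge e; dipole e·bohr; quadrupole (traceless
    Cartesian) e·bohr²; alpha bohr³.  Sites sharing a group_id exclude each
    other from mutual induction.  Frozen sites contribute permanent
    electrostatics but are excluded from the polarization system.
    """

    positions: np.ndarray  # (m, 3)
    charge: np.ndarray  # (m,)
    dipole: np.ndarray  # (m, 3)
    quadrupole: np.ndarray  # (m, 3, 3) symmetric traceless
    alpha: np.ndarray  # (m,)
    polarizable: np.ndarray  # (m,) bool
    frozen: np.ndarray  # (m,) bool
    group_id: np.ndarray  # (m,) int

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        m = self.positions.shape[0]
        self.charge = np.asarray(self.charge, float).reshape(m)
        self.dipole = np.asarray(self.dipole, float).reshape(m, 3)
        self.quadrupole = np.asarray(self.quadrupole, float).reshape(m, 3, 3)
        self.alpha = np.asarray(self.alpha, float).reshape(m)
        self.polarizable = np.asarray(self.polarizable, bool).reshape(m)
        self.frozen = np.asarray(self.frozen, bool).reshape(m)
        self.group_id = np.asarray(self.group_id, int).reshape(m)
        if np.any(self.alpha < 0):
            raise ValueError("negative polarizability")
        if np.any(self.alpha[~self.polarizable] != 0.0):
            raise ValueError("alpha must be 0 on non-polarizable sites")
        for q in self.quadrupole:
            if not np.allclose(q, q.T, atol=1e-10):
                raise ValueError("quadrupole not symmetric")
            if abs(np.trace(q)) > 1e-10:
                raise ValueError("quadrupole not traceless")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls) -> "EmbeddingSites":
        z = np.zeros((0, 3))
        return cls(z, np.zeros(0), z, np.zeros((0, 3, 3)), np.zeros(0),
                   np.zeros(0, bool), np.zeros(0, bool), np.zeros(0, int))


_SITE_COLUMNS = 18  # id x y z q dx dy dz Qxx Qxy Qxz Qyy Qyz Qzz alpha pol frozen group


def read_sites(path) -> EmbeddingSites:
    """Read a columnar site file (positions in Å, multipoles atomic units)."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != _SITE_COLUMNS:
                raise ValueError(f"site line has {len(parts)} fields, expected {_SITE_COLUMNS}: {ln!r}")
            rows.append([float(x) for x in parts])
    if not rows:
        return EmbeddingSites.empty()
    a = np.array(rows)
    pos = a[:, 1:4] * BOHR_PER_ANGSTROM
    q = a[:, 4]
    dip = a[:, 5:8]
    quad = np.zeros((len(rows), 3, 3))
    qxx, qxy, qxz, qyy, qyz, qzz = (a[:, 8], a[:, 9], a[:, 10], a[:, 11], a[:, 12], a[:, 13])
    quad[:, 0, 0], quad[:, 1, 1], quad[:, 2, 2] = qxx, qyy, qzz
    quad[:, 0, 1] = quad[:, 1, 0] = qxy
    quad[:, 0, 2] = quad[:, 2, 0] = qxz
    quad[:, 1, 2] = quad[:, 2, 1] = qyz
    tr = np.trace(quad, axis1=1, axis2=2)
    if np.any(np.abs(tr) >= 1e-8):
        raise ValueError("quadrupole trace beyond tolerance (not traceless)")
    quad -= tr[:, None, None] / 3.0 * np.eye(3)
    alpha = a[:, 14]
    if np.any(alpha < 0):
        raise ValueError("negative polarizability in site file")
    return EmbeddingSites(pos, q, dip, quad, alpha, a[:, 15] != 0, a[:, 16] != 0,
                          a[:, 17].astype(int))


def write_sites(sites: EmbeddingSites, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id x y z q dx dy dz Qxx Qxy Qxz Qyy Qyz Qzz alpha polarizable frozen group\n")
        for i in range(sites.n_sites):
            p = sites.positions[i] * ANGSTROM_PER_BOHR
            d = sites.dipole[i]
            Q = sites.quadrupole[i]
            fields = [f"{i + 1:d}"]
            fields += [f"{v:.12e}" for v in (*p, sites.charge[i], *d,
                                             Q[0, 0], Q[0, 1], Q[0, 2], Q[1, 1], Q[1, 2], Q[2, 2],
                                             sites.alpha[i])]
            fields += [f"{int(sites.polarizable[i])}", f"{int(sites.frozen[i])}",
                       f"{int(sites.group_id[i])}"]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Trajectory frames (extended-XYZ dialect)


@dataclass
class TrajectoryFrame:
    step_index: int
    time: float  # fs
    symbols: list[str]
    coords: np.ndarray  # bohr
    velocities: np.ndarray  # bohr / atomic time unit
    energy_total: float
    energy_qm: float
    energy_fixed_elec: float
    energy_pol: float
    kinetic_energy: float
    dipole_moment: np.ndarray  # (3,) a.u.
    state_label: str = "GS"
    dt: float | None = None  # fs, for the time-consistency invariant

    def validate(self) -> None:
        if self.dt is not None and abs(self.time - self.step_index * self.dt) > 1e-9:
            raise ValueError(
                f"frame time {self.time} != step {self.step_index} x dt {self.dt}")


_FLOAT_FMT = "%.10e"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_traj_frame(frame: TrajectoryFrame, fh) -> None:
    """Append one extended-XYZ record; `fh` is an open text handle or path."""
    frame.validate()
    if isinstance(fh, (str, bytes)) or hasattr(fh, "__fspath__"):
        with open(fh, "a") as handle:
            write_traj_frame(frame, handle)
        return
    n = len(frame.symbols)
    d = frame.dipole_moment
    kv = [
        f"step={frame.step_index}",
        f"time_fs={_fmt(frame.time)}",
        f"E_total={_fmt(frame.energy_total)}",
        f"E_qm={_fmt(frame.energy_qm)}",
        f"E_fixed={_fmt(frame.energy_fixed_elec)}",
        f"E_pol={_fmt(frame.energy_pol)}",
        f"E_kin={_fmt(frame.kinetic_energy)}",
        f"dipole_x={_fmt(d[0])}", f"dipole_y={_fmt(d[1])}", f"dipole_z={_fmt(d[2])}",
        f"state={frame.state_label}",
    ]
    fh.write(f"{n}\n" + " ".join(kv) + "\n")
    ang = frame.coords * ANGSTROM_PER_BOHR
    for s, r, v in zip(frame.symbols, ang, frame.velocities):
        fh.write(f"{s} " + " ".join(_fmt(x) for x in r) + " "
                 + " ".join(_fmt(x) for x in v) + "\n")


def read_traj(path) -> list[TrajectoryFrame]:
    """Read the extended-XYZ trajectory dialect written by write_traj_frame."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        kv = dict(tok.split("=", 1) for tok in lines[i + 1].split())
        symbols, coords, vels = [], [], []
        for ln in lines[i + 2 : i + 2 + n]:
            parts = ln.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
            vels.append([float(x) for x in parts[4:7]])
        frames.append(TrajectoryFrame(
            step_index=int(kv["step"]),
            time=float(kv["time_fs"]),
            symbols=symbols,
            coords=np.array(coords) * BOHR_PER_ANGSTROM,
            velocities=np.array(vels),
            energy_total=float(kv["E_total"]),
            energy_qm=float(kv["E_qm"]),
            energy_fixed_elec=float(kv["E_fixed"]),
            energy_pol=float(kv["E_pol"]),
            kinetic_energy=float(kv["E_kin"]),
            dipole_moment=np.array([float(kv["dipole_x"]), float(kv["dipole_y"]),
                                    float(kv["dipole_z"])]),
            state_label=kv["state"],
        ))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Flat key-value run configuration parsed from TOML."""

    data: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def get(self, dotted_key: str, default=None):
        node = self.data
        for part in dotted_key.split("."):
            if not isinstance(node, dict) or part not in node:
                return default
            node = node[part]
        return node
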