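"""Domain types and file formats shared by every stage of a SuMD run.

Units are the MD conventions used throughout the package: coordinates in
angstroms, time in picoseconds, energies in kcal/mol, masses in amu and
charges in elementary units.  The single mechanical conversion constant
(1 kcal/mol = 418.4 amu A^2/ps^2) lives here and nowhere else.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

# --- physical constants -----------------------------------------------------

#: 1 kcal/mol expressed in amu * A^2 / ps^2
ENERGY_CONVERSION = 418.4
#: Boltzmann constant, kcal / (mol K)
BOLTZMANN_KCAL = 0.0019872041
#: Coulomb constant, kcal * A / (mol e^2)
COULOMB_CONSTANT = 332.0636

ROLE_TARGET = "target"
ROLE_LIGAND = "ligand"


class SumdError(Exception):
    """Base class for package errors."""


class PDBParseError(SumdError):
    pass


class ParameterError(SumdError):
    pass


class ConfigError(SumdError):
    pass


class SelectionError(SumdError):
    pass


class TopologyError(SumdError):
    pass


# --- topology ---------------------------------------------------------------


@dataclass(frozen=True)
class Topology:
    """Per-atom identity, group membership, role and nonbonded parameters.

    Groups are the per-residue unit of the analysis layer (one nucleotide of
    the target, or the whole ligand).  Nonbonded parameters may be absent
    until :func:`load_params` fills them in; operations that need them call
    :meth:`require_parameterized`.
    """

    atom_id: np.ndarray          # (N,) int
    name: np.ndarray             # (N,) str
    group_id: np.ndarray         # (N,) int
    group_name: np.ndarray       # (N,) str
    role: np.ndarray             # (N,) str, 'target' | 'ligand'
    charge: np.ndarray | None = None       # e
    lj_epsilon: np.ndarray | None = None   # kcal/mol
    lj_sigma: np.ndarray | None = None     # A
    mass: np.ndarray | None = None         # amu
    bonds: tuple[tuple[int, int, float, float], ...] = ()
    """Intra-ligand harmonic bonds as (atom index i, atom index j, r0 A, k kcal/mol/A^2)."""

    def __post_init__(self) -> None:
        n = len(self.atom_id)
        if n == 0:
            raise TopologyError("topology has zero atoms")
        if len(np.unique(self.atom_id)) != n:
            raise TopologyError("atom ids are not unique")
        for role in (ROLE_TARGET, ROLE_LIGAND):
            if not np.any(self.role == role):
                raise TopologyError(f"topology has no {role} atoms")
        # a group may not mix roles
        for gid in np.unique(self.group_id):
            roles = np.unique(self.role[self.group_id == gid])
            if len(roles) != 1:
                raise TopologyError(f"group {gid} mixes roles {list(roles)}")
        self._check_params()

    def _check_params(self) -> None:
        if self.lj_sigma is not None and np.any(self.lj_sigma <= 0):
            raise TopologyError("lj_sigma must be > 0")
        if self.lj_epsilon is not None and np.any(self.lj_epsilon < 0):
            raise TopologyError("lj_epsilon must be >= 0")
        if self.mass is not None and np.any(self.mass <= 0):
            raise TopologyError("mass must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    @property
    def target_mask(self) -> np.ndarray:
        return self.role == ROLE_TARGET

    @property
    def ligand_mask(self) -> np.ndarray:
        return self.role == ROLE_LIGAND

    @property
    def target_index(self) -> np.ndarray:
        return np.flatnonzero(self.target_mask)

    @property
    def ligand_index(self) -> np.ndarray:
        return np.flatnonzero(self.ligand_mask)

    @property
    def target_group_ids(self) -> np.ndarray:
        return np.unique(self.group_id[self.target_mask])

    @property
    def parameterized(self) -> bool:
        return all(
            a is not None
            for a in (self.charge, self.lj_epsilon, self.lj_sigma, self.mass)
        )

    def require_parameterized(self) -> None:
        if not self.parameterized:
            raise ParameterError(
                "topology is not parameterized; call load_params first"
            )

    def group_label(self, gid: int) -> str:
        idx = np.flatnonzero(self.group_id == gid)
        if len(idx) == 0:
            raise SelectionError(f"no group with id {gid}")
        return str(self.group_name[idx[0]])

    def with_params(
        self,
        charge: np.ndarray,
        lj_epsilon: np.ndarray,
        lj_sigma: np.ndarray,
        mass: np.ndarray,
    ) -> "Topology":
        return dataclasses.replace(
            self,
            charge=np.asarray(charge, float),
            lj_epsilon=np.asarray(lj_epsilon, float),
            lj_sigma=np.asarray(lj_sigma, float),
            mass=np.asarray(mass, float),
        )


@dataclass
class State:
    """Instantaneous mechanical state plus the RNG stream that produced it.

    ``rng_state`` is the serialized state of a numpy bit generator; carrying
    it in the state makes engine advancement a pure function of
    (state, n_steps, config), which is the reproducibility contract the
    supervision loop and the run manifest rely on.
    """

    positions: np.ndarray   # (N, 3) A
    velocities: np.ndarray  # (N, 3) A/ps
    time: float = 0.0       # ps
    rng_state: dict | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        if self.positions.shape != self.velocities.shape:
            raise SumdError("positions and velocities shapes differ")
        if not np.all(np.isfinite(self.positions)):
            raise SumdError("non-finite coordinates in state")

    def copy(self) -> "State":
        return State(
            self.positions.copy(),
            self.velocities.copy(),
            self.time,
            json.loads(json.dumps(self.rng_state)) if self.rng_state else None,
        )

    def rng(self) -> np.random.Generator:
        """Generator restored from (or initialising) the carried stream."""
        bg = np.random.PCG64()
        if self.rng_state is not None:
            bg.state = self.rng_state
        return np.random.Generator(bg)

    def store_rng(self, rng: np.random.Generator) -> None:
        self.rng_state = rng.bit_generator.state

    @staticmethod
    def seeded(positions, velocities, time, seed) -> "State":
        s = State(np.array(positions, float), np.array(velocities, float), time)
        s.rng_state = np.random.PCG64(seed).state
        return s


@dataclass(frozen=True)
class BindingSiteSpec:
    """Target groups whose (mass-weighted) centroid is the binding-site COM."""

    group_ids: tuple[int, ...]
    mass_weighted: bool = True

    def __post_init__(self) -> None:
        if len(self.group_ids) == 0:
            raise SelectionError("binding site needs at least one group")

    def validate(self, topology: Topology) -> None:
        target_groups = set(int(g) for g in topology.target_group_ids)
        bad = [g for g in self.group_ids if g not in target_groups]
        if bad:
            raise SelectionError(f"site groups {bad} are not target groups")

    def atom_index(self, topology: Topology) -> np.ndarray:
        self.validate(topology)
        return np.flatnonzero(np.isin(topology.group_id, self.group_ids))


# --- configuration ----------------------------------------------------------


@dataclass
class SupervisionConfig:
    """Tabu-like supervision schedule.

    Defaults carry the published protocol numerically: 600 time-unit
    segments, acceptance iff the fitted distance slope is strictly below the
    threshold (0 by default, i.e. "slope is negative"), supervision switched
    off permanently once the ligand--site COM distance samples below 5 A.
    """

    segment_length: float = 600.0
    n_fit_points: int = 20
    slope_threshold: float = 0.0
    switch_off_distance: float = 5.0
    max_segments: int = 500
    max_failed_attempts: int = 30
    relaxation_length: float | None = None  # None -> one segment_length

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ConfigError("segment_length must be > 0")
        if self.n_fit_points < 2:
            raise ConfigError("n_fit_points must be >= 2")
        if self.switch_off_distance <= 0:
            raise ConfigError("switch_off_distance must be > 0")
        if self.max_segments < 1 or self.max_failed_attempts < 1:
            raise ConfigError("segment/attempt budgets must be >= 1")

    @property
    def effective_relaxation_length(self) -> float:
        return (
            self.segment_length
            if self.relaxation_length is None
            else self.relaxation_length
        )


@dataclass
class EngineConfig:
    """Langevin engine knobs: 310 K thermostat with 1/ps friction by default."""

    temperature: float = 310.0
    friction: float = 1.0
    dt: float = 0.05
    restraint_k: float | None = None   # kcal/mol/A^2, None = off
    target_mobility: str = "fixed"     # 'fixed' | 'restrained'
    bond_list: tuple[tuple[int, int, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ConfigError("temperature must be >= 0")
        if self.friction <= 0:
            raise ConfigError("friction must be > 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.target_mobility not in ("fixed", "restrained"):
            raise ConfigError(
                f"target_mobility must be 'fixed' or 'restrained', "
                f"got {self.target_mobility!r}"
            )
        if self.target_mobility == "restrained" and not self.restraint_k:
            raise ConfigError("restrained target requires restraint_k")


@dataclass
class EnergyParams:
    """Screened molecular-mechanics nonbonded parameters.

    The dielectric plus optional Debye screening stand in for solvent and
    the physiological-salt ionic atmosphere; the 9 A cutoff is the plain
    Lennard-Jones truncation distance.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    dielectric: float = 80.0
    debye_length: float | None = 8.0   # A, None = no screening
    nonbonded_cutoff: float = 9.0      # A, may be inf

    def __post_init__(self) -> None:
        if self.dielectric < 1:
            raise ConfigError("dielectric must be >= 1")
        if self.nonbonded_cutoff <= 0:
            raise ConfigError("nonbonded_cutoff must be > 0")
        if self.debye_length is not None and self.debye_length <= 0:
            raise ConfigError("debye_length must be > 0 or None")


@dataclass
class RunConfig:
    """Full run configuration: supervision + engine + energetics + output."""

    supervision: SupervisionConfig = field(default_factory=SupervisionConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    energy: EnergyParams = field(default_factory=EnergyParams)
    frame_interval: float = 20.0   # time units between saved frames
    contact_cutoff: float = 4.0    # A, analysis-layer default
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.contact_cutoff <= 0:
            raise ConfigError("contact_cutoff must be > 0")

    def to_dict(self) -> dict:
        d: dict = {}
        for sub in (self.supervision, self.engine, self.energy):
            for f in dataclasses.fields(sub):
                v = getattr(sub, f.name)
                if isinstance(v, tuple):
                    v = [list(b) for b in v]
                d[f.name] = v
        d["frame_interval"] = self.frame_interval
        d["contact_cutoff"] = self.contact_cutoff
        d["seed"] = self.seed
        return d


_CONFIG_SECTIONS: dict[str, type] = {}
for _cls in (SupervisionConfig, EngineConfig, EnergyParams):
    for _f in dataclasses.fields(_cls):
        _CONFIG_SECTIONS[_f.name] = _cls
_TOP_LEVEL_KEYS = {"frame_interval", "contact_cutoff", "seed"}


def config_from_dict(data: Mapping) -> RunConfig:
    """Build a validated :class:`RunConfig` from a flat key/value mapping."""
    sup_kw: dict = {}
    eng_kw: dict = {}
    ene_kw: dict = {}
    top_kw: dict = {}
    buckets = {SupervisionConfig: sup_kw, EngineConfig: eng_kw, EnergyParams: ene_kw}
    for key, value in data.items():
        if key in _TOP_LEVEL_KEYS:
            top_kw[key] = value
        elif key in _CONFIG_SECTIONS:
            if key == "bond_list" and value is not None:
                value = tuple(
                    (int(i), int(j), float(r0), float(k)) for i, j, r0, k in value
                )
            buckets[_CONFIG_SECTIONS[key]][key] = value
        else:
            raise ConfigError(f"unknown configuration key: {key!r}")
    _check_numeric(data)
    try:
        return RunConfig(
            supervision=SupervisionConfig(**sup_kw),
            engine=EngineConfig(**eng_kw),
            energy=EnergyParams(**ene_kw),
            **top_kw,
        )
    except TypeError as exc:  # wrong value type for a dataclass field
        raise ConfigError(str(exc)) from exc


_NUMERIC_KEYS = {
    "segment_length", "slope_threshold", "switch_off_distance",
    "relaxation_length", "temperature", "friction", "dt", "restraint_k",
    "coulomb_constant", "dielectric", "debye_length", "nonbonded_cutoff",
    "frame_interval", "contact_cutoff",
}
_INT_KEYS = {"n_fit_points", "max_segments", "max_failed_attempts", "seed"}


def _check_numeric(data: Mapping) -> None:
    for key, value in data.items():
        if value is None:
            continue
        if key in _INT_KEYS and not isinstance(value, (int, np.integer)):
            raise ConfigError(f"config key {key!r} must be an integer, got {value!r}")
        if key in _NUMERIC_KEYS and not isinstance(value, (int, float, np.floating)):
            raise ConfigError(f"config key {key!r} must be numeric, got {value!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent keys take the defaults above.

    Unknown keys and mistyped values raise :class:`ConfigError` naming the
    offending key.  Defaulting is idempotent: dumping a loaded config and
    loading it again yields an identical configuration.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# --- run manifest -----------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to replay a run (or campaign) bit-identically."""

    config: dict
    master_seed: int
    replica_seeds: list[int]
    statuses: list[str] = field(default_factory=list)
    segment_stats: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return RunManifest(**data)


# --- PDB I/O ----------------------------------------------------------------

# wwPDB v3.3 fixed columns (0-based, half-open)
_REC = slice(0, 6)
_SERIAL = slice(6, 11)
_NAME = slice(12, 16)
_ALTLOC = 16
_RESNAME = slice(17, 20)
_CHAIN = 21
_RESSEQ = slice(22, 26)
_ICODE = 26
_X = slice(30, 38)
_Y = slice(38, 46)
_Z = slice(46, 54)


def read_pdb(
    path: str | Path,
    role_map: Mapping[str, str] | None = None,
) -> tuple[Topology, list[np.ndarray]]:
    """Read a (possibly multi-MODEL) PDB file.

    Returns an unparameterized topology plus one coordinate set per MODEL
    (a single set if the file has no MODEL records).  Roles come from
    ``role_map`` (chain id -> 'target'/'ligand'); without a map, ATOM
    records are targets and HETATM records ligands.  Group identity is
    (chain, residue number); insertion codes are rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    models: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    in_model = False
    seen_model = False

    names: list[str] = []
    group_keys: list[tuple[str, int]] = []
    resnames: list[str] = []
    roles: list[str] = []
    first_model_done = False

    def parse_atom(line: str, lineno: int):
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(
                f"{path}:{lineno}: ATOM/HETATM record shorter than 54 columns"
            )
        if line[_ICODE].strip():
            raise PDBParseError(
                f"{path}:{lineno}: insertion codes are not supported"
            )
        try:
            x = float(line[_X])
            y = float(line[_Y])
            z = float(line[_Z])
            resseq = int(line[_RESSEQ])
        except ValueError as exc:
            raise PDBParseError(f"{path}:{lineno}: malformed field ({exc})") from exc
        return x, y, z, resseq

    for lineno, line in enumerate(lines, start=1):
        rec = line[_REC].strip() if len(line) >= 6 else line.strip()
        if rec == "MODEL":
            if in_model:
                raise PDBParseError(f"{path}:{lineno}: nested MODEL record")
            in_model = True
            seen_model = True
            current = []
        elif rec == "ENDMDL":
            if not in_model:
                raise PDBParseError(f"{path}:{lineno}: ENDMDL without MODEL")
            in_model = False
            models.append(current)
            first_model_done = True
        elif rec in ("ATOM", "HETATM"):
            x, y, z, resseq = parse_atom(line, lineno)
            current.append((x, y, z))
            if not first_model_done:
                name = line[_NAME].strip()
                chain = line[_CHAIN]
                resname = line[_RESNAME].strip()
                names.append(name)
                group_keys.append((chain, resseq))
                resnames.append(resname)
                if role_map is not None:
                    if chain not in role_map:
                        raise PDBParseError(
                            f"{path}:{lineno}: chain {chain!r} missing from role map"
                        )
                    roles.append(role_map[chain])
                else:
                    roles.append(ROLE_LIGAND if rec == "HETATM" else ROLE_TARGET)

    if not seen_model:
        models.append(current)
    elif in_model:
        raise PDBParseError(f"{path}: unterminated MODEL block")

    if not names:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")

    n = len(names)
    for i, m in enumerate(models):
        if len(m) != n:
            raise PDBParseError(
                f"{path}: MODEL {i + 1} has {len(m)} atoms, expected {n}"
            )

    # sequential group ids in order of first appearance
    gid_of: dict[tuple[str, int], int] = {}
    group_id = np.empty(n, int)
    group_name = np.empty(n, object)
    for i, key in enumerate(group_keys):
        if key not in gid_of:
            gid_of[key] = len(gid_of)
        group_id[i] = gid_of[key]
        group_name[i] = f"{resnames[i]}{key[1]}"

    topo = Topology(
        atom_id=np.arange(1, n + 1),
        name=np.array(names, object),
        group_id=group_id,
        group_name=group_name.astype(str),
        role=np.array(roles, object).astype(str),
    )
    coord_sets = [np.array(m, float) for m in models]
    return topo, coord_sets


def write_pdb(
    path: str | Path,
    topology: Topology,
    coord_sets: Sequence[np.ndarray],
    times: Sequence[float] | None = None,
) -> None:
    """Write coordinate sets as a multi-MODEL PDB (occupancy 1.00, B 0.00)."""
    path = Path(path)
    out: list[str] = []
    chain_of_role = {ROLE_TARGET: "A", ROLE_LIGAND: "B"}
    for m, coords in enumerate(coord_sets, start=1):
        out.append(f"MODEL {m:>8d}")
        if times is not None:
            out.append(f"REMARK   6 TIME {times[m - 1]:.4f}")
        for i in range(topology.n_atoms):
            rec = "ATOM" if topology.role[i] == ROLE_TARGET else "HETATM"
            name = str(topology.name[i])
            # PDB convention: names of <4 chars start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            gname = str(topology.group_name[i])
            resname = "".join(c for c in gname if not c.isdigit())[:3] or "UNK"
            resseq = "".join(c for c in gname if c.isdigit()) or "1"
            x, y, z = coords[i]
            out.append(
                f"{rec:<6s}{int(topology.atom_id[i]) % 100000:>5d} "
                f"{name_field}{'':1s}{resname:>3s} {chain_of_role[str(topology.role[i])]}"
                f"{int(resseq) % 10000:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            )
        out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")


# --- frames table -----------------------------------------------------------


def write_frames_table(
    path: str | Path,
    topology: Topology,
    coord_sets: Sequence[np.ndarray],
    times: Sequence[float],
) -> None:
    """TSV with one row per (frame, atom): frame, time, atom_id, x, y, z."""
    with open(path, "w") as fh:
        fh.write("frame\ttime\tatom_id\tx\ty\tz\n")
        for f, (t, coords) in enumerate(zip(times, coord_sets)):
            for i in range(topology.n_atoms):
                x, y, z = coords[i]
                fh.write(
                    f"{f}\t{t:.6f}\t{int(topology.atom_id[i])}\t"
                    f"{x:.6f}\t{y:.6f}\t{z:.6f}\n"
                )


def read_frames_table(path: str | Path) -> tuple[list[float], list[np.ndarray]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    times: list[float] = []
    coords: list[np.ndarray] = []
    for f, sub in df.groupby("frame", sort=True):
        times.append(float(sub["time"].iloc[0]))
        coords.append(sub[["x", "y", "z"]].to_numpy(float))
    return times, coords


# --- parameter table --------------------------------------------------------


def load_params(topology: Topology, table: str | Path) -> Topology:
    """Assign charge/LJ/mass per atom from a TSV parameter table.

    Rows are keyed by (group_name, atom_name); '*' wildcards either key.
    Match precedence: exact > (group, *) > (*, atom) > (*, *); wildcards
    apply only where no more specific row matches.  Atoms left unmatched
    raise :class:`ParameterError` listing them.
    """
    import pandas as pd

    df = pd.read_csv(table, sep="\t", comment="#")
    required = {"group_name", "atom_name", "charge", "epsilon", "sigma", "mass"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParameterError(
            f"parameter table missing columns: {sorted(missing_cols)}"
        )

    rows: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for _, r in df.iterrows():
        key = (str(r["group_name"]), str(r["atom_name"]))
        rows[key] = (
            float(r["charge"]),
            float(r["epsilon"]),
            float(r["sigma"]),
            float(r["mass"]),
        )

    n = topology.n_atoms
    charge = np.empty(n)
    eps = np.empty(n)
    sig = np.empty(n)
    mass = np.empty(n)
    unmatched: list[tuple[str, str]] = []
    for i in range(n):
        g = str(topology.group_name[i])
        a = str(topology.name[i])
        for key in ((g, a), (g, "*"), ("*", a), ("*", "*")):
            if key in rows:
                charge[i], eps[i], sig[i], mass[i] = rows[key]
                break
        else:
            unmatched.append((g, a))
    if unmatched:
        raise ParameterError(
            "no parameters for atoms: "
            + ", ".join(f"({g}, {a})" for g, a in unmatched[:20])
        )
    return topology.with_params(charge, eps, sig, mass)


def write_params_table(
    path: str | Path,
    rows: Iterable[tuple[str, str, float, float, float, float]],
) -> None:
    with open(path, "w") as fh:
        fh.write("group_name\tatom_name\tcharge\tepsilon\tsigma\tmass\n")
        for g, a, q, e, s, m in rows:
            fh.write(f"{g}\t{a}\t{q:.6f}\t{e:.6f}\t{s:.6f}\t{m:.6f}\n")


# --- small shared geometry helpers ------------------------------------------


def center_of_mass(
    positions: np.ndarray,
    index: np.ndarray,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    if len(index) == 0:
        raise SelectionError("empty selection for center of mass")
    pos = positions[index]
    if masses is None:
        return pos.mean(axis=0)
    w = masses[index]
    return (pos * w[:, None]).sum(axis=0) / w.sum()
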