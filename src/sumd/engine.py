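"""Pluggable dynamics engines.

The supervision loop only requires the :class:`EngineContract`: advance a
state deterministically given its carried RNG stream, resample velocities
from Maxwell-Boltzmann, and report recorded frames.  Two engines satisfy it:

* :class:`LangevinEngine` -- a BAOAB Langevin integrator over the screened
  MM force field (ligand--target nonbonded forces, intra-ligand harmonic
  bonds, optional positional restraints).  Target atoms are immobile by
  default ("fixed") or tethered to their reference coordinates
  ("restrained", 1 kcal/mol/A^2 by default).
* :class:`MockEngine` -- a scripted engine that moves the ligand along a
  prescribed distance schedule; used to exercise the supervision logic in
  isolation.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .core import (
    BOLTZMANN_KCAL,
    ENERGY_CONVERSION,
    EnergyParams,
    EngineConfig,
    SelectionError,
    State,
    SumdError,
    Topology,
    center_of_mass,
)


class IntegrationError(SumdError):
    pass


# --- velocities and temperature --------------------------------------------


def maxwell_sigma(mass: np.ndarray, temperature: float) -> np.ndarray:
    """Per-atom Maxwell-Boltzmann velocity std dev (A/ps) per component."""
    return np.sqrt(BOLTZMANN_KCAL * temperature * ENERGY_CONVERSION / mass)


def resample_velocities(
    state: State,
    topology: Topology,
    temperature: float,
    seed: int | None = None,
    mobile_index: np.ndarray | None = None,
) -> State:
    """Fresh Maxwell-Boltzmann velocities; positions stay bit-identical.

    With ``seed`` given, a fresh stream is started from it; otherwise the
    state's carried stream is consumed (and stored back).  At temperature 0
    all resampled velocities are exactly zero.
    """
    if temperature < 0:
        raise SumdError(f"temperature must be >= 0, got {temperature}")
    topology.require_parameterized()
    new = state.copy()
    if seed is not None:
        rng = np.random.Generator(np.random.PCG64(seed))
    else:
        rng = new.rng()
    if mobile_index is None:
        mobile_index = np.arange(topology.n_atoms)
    if temperature == 0:
        new.velocities[mobile_index] = 0.0
    else:
        sigma = maxwell_sigma(topology.mass[mobile_index], temperature)
        new.velocities[mobile_index] = (
            rng.standard_normal((len(mobile_index), 3)) * sigma[:, None]
        )
    new.store_rng(rng)
    return new


def kinetic_temperature(
    state: State,
    topology: Topology,
    mobile_index: np.ndarray | None = None,
) -> float:
    """Instantaneous kinetic temperature sum(m v^2) / (3 N k_B) in kelvin."""
    topology.require_parameterized()
    if mobile_index is None:
        mobile_index = np.arange(topology.n_atoms)
    if len(mobile_index) == 0:
        raise SelectionError("empty mobile selection for kinetic temperature")
    v2 = (state.velocities[mobile_index] ** 2).sum(axis=1)
    ke_kcal = 0.5 * (topology.mass[mobile_index] * v2).sum() / ENERGY_CONVERSION
    return float(2.0 * ke_kcal / (3.0 * len(mobile_index) * BOLTZMANN_KCAL))


# --- engine contract --------------------------------------------------------


class EngineContract:
    """Minimal capabilities the supervision loop relies on."""

    dt: float

    def advance(
        self, state: State, n_steps: int, record_every: int | None = None
    ) -> tuple[State, list[tuple[float, np.ndarray]]]:
        """Advance ``n_steps``; record (time, positions) every ``record_every``
        steps, always including the final state.  Deterministic given the
        state's carried RNG stream."""
        raise NotImplementedError

    def resample(self, state: State, seed: int | None = None) -> State:
        raise NotImplementedError


# --- force/integrator kernels ----------------------------------------------


@njit(cache=False)
def _forces(
    pos, forces,
    lig_idx, tgt_idx,
    charge, eps, sig,
    kc_over_diel, debye_inv, cutoff2,
    bond_i, bond_j, bond_r0, bond_k,
    restr_idx, restr_ref, restr_k,
):
    """Fill ``forces`` (kcal/mol/A); return (bad_i, bad_j) on overlap else (-1,-1)."""
    forces[:, :] = 0.0
    for a in lig_idx:
        for b in tgt_idx:
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff2:
                continue
            if r2 < 1e-8:
                return a, b
            r = math.sqrt(r2)
            # screened Coulomb: u = A exp(-r/L)/r ; du/dr = -u (1/r + 1/L)
            A = kc_over_diel * charge[a] * charge[b]
            if debye_inv > 0.0:
                u = A * math.exp(-r * debye_inv) / r
                du = -u * (1.0 / r + debye_inv)
            else:
                u = A / r
                du = -u / r
            # LJ with Lorentz-Berthelot combination
            s = 0.5 * (sig[a] + sig[b])
            e = math.sqrt(eps[a] * eps[b])
            sr2 = s * s / r2
            sr6 = sr2 * sr2 * sr2
            du += 4.0 * e * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            f = -du / r
            forces[a, 0] += f * dx
            forces[a, 1] += f * dy
            forces[a, 2] += f * dz
            forces[b, 0] -= f * dx
            forces[b, 1] -= f * dy
            forces[b, 2] -= f * dz
    for n in range(bond_i.shape[0]):
        a = bond_i[n]
        b = bond_j[n]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-8:
            return a, b
        f = -2.0 * bond_k[n] * (r - bond_r0[n]) / r
        forces[a, 0] += f * dx
        forces[a, 1] += f * dy
        forces[a, 2] += f * dz
        forces[b, 0] -= f * dx
        forces[b, 1] -= f * dy
        forces[b, 2] -= f * dz
    if restr_k > 0.0:
        for n in range(restr_idx.shape[0]):
            a = restr_idx[n]
            forces[a, 0] -= 2.0 * restr_k * (pos[a, 0] - restr_ref[n, 0])
            forces[a, 1] -= 2.0 * restr_k * (pos[a, 1] - restr_ref[n, 1])
            forces[a, 2] -= 2.0 * restr_k * (pos[a, 2] - restr_ref[n, 2])
    return -1, -1


@njit(cache=False)
def _baoab_chunk(
    pos, vel, forces,
    mobile_idx, inv_mass_conv,   # ENERGY_CONVERSION / m per mobile atom
    dt, c1, sigma_o,             # O-step decay and per-atom noise scale
    noise,                       # (n_steps, n_mobile, 3)
    lig_idx, tgt_idx, charge, eps, sig,
    kc_over_diel, debye_inv, cutoff2,
    bond_i, bond_j, bond_r0, bond_k,
    restr_idx, restr_ref, restr_k,
):
    """BAOAB steps over mobile atoms; returns (step, bad_i, bad_j) on error."""
    n_steps = noise.shape[0]
    half_dt = 0.5 * dt
    for step in range(n_steps):
        # B: half kick
        for m in range(mobile_idx.shape[0]):
            a = mobile_idx[m]
            acc = inv_mass_conv[m]
            vel[a, 0] += half_dt * forces[a, 0] * acc
            vel[a, 1] += half_dt * forces[a, 1] * acc
            vel[a, 2] += half_dt * forces[a, 2] * acc
        # A: half drift
        for m in range(mobile_idx.shape[0]):
            a = mobile_idx[m]
            pos[a, 0] += half_dt * vel[a, 0]
            pos[a, 1] += half_dt * vel[a, 1]
            pos[a, 2] += half_dt * vel[a, 2]
        # O: exact Ornstein-Uhlenbeck step
        for m in range(mobile_idx.shape[0]):
            a = mobile_idx[m]
            vel[a, 0] = c1 * vel[a, 0] + sigma_o[m] * noise[step, m, 0]
            vel[a, 1] = c1 * vel[a, 1] + sigma_o[m] * noise[step, m, 1]
            vel[a, 2] = c1 * vel[a, 2] + sigma_o[m] * noise[step, m, 2]
        # A: half drift
        for m in range(mobile_idx.shape[0]):
            a = mobile_idx[m]
            pos[a, 0] += half_dt * vel[a, 0]
            pos[a, 1] += half_dt * vel[a, 1]
            pos[a, 2] += half_dt * vel[a, 2]
        # force refresh + B: half kick
        bad_i, bad_j = _forces(
            pos, forces, lig_idx, tgt_idx, charge, eps, sig,
            kc_over_diel, debye_inv, cutoff2,
            bond_i, bond_j, bond_r0, bond_k,
            restr_idx, restr_ref, restr_k,
        )
        if bad_i >= 0:
            return step, bad_i, bad_j
        for m in range(mobile_idx.shape[0]):
            a = mobile_idx[m]
            acc = inv_mass_conv[m]
            vel[a, 0] += half_dt * forces[a, 0] * acc
            vel[a, 1] += half_dt * forces[a, 1] * acc
            vel[a, 2] += half_dt * forces[a, 2] * acc
    return -1, -1, -1


# --- Langevin engine --------------------------------------------------------


class LangevinEngine(EngineContract):
    """Implicit-solvent BAOAB Langevin integrator over the screened MM field.

    Forces are the negative gradient of the ligand--target nonbonded energy
    (matching :mod:`sumd.energetics` exactly, plain truncation at the
    cutoff), intra-ligand harmonic bonds, and, in restrained mode,
    positional restraints tethering target atoms to reference coordinates.
    """

    def __init__(
        self,
        topology: Topology,
        config: EngineConfig | None = None,
        energy_params: EnergyParams | None = None,
        restraint_reference: np.ndarray | None = None,
    ) -> None:
        topology.require_parameterized()
        self.topology = topology
        self.config = config or EngineConfig()
        self.energy_params = energy_params or EnergyParams()
        self.dt = float(self.config.dt)

        if self.config.target_mobility == "fixed":
            self.mobile_index = topology.ligand_index.copy()
        else:
            self.mobile_index = np.arange(topology.n_atoms)
        if not np.all(np.isfinite(topology.mass[self.mobile_index])):
            raise IntegrationError("mobile atoms must have finite mass")

        bonds = self.config.bond_list
        if bonds is None:
            bonds = topology.bonds
        bonds = list(bonds) if bonds else []
        self._bond_i = np.array([b[0] for b in bonds], np.int64)
        self._bond_j = np.array([b[1] for b in bonds], np.int64)
        self._bond_r0 = np.array([b[2] for b in bonds], float)
        self._bond_k = np.array([b[3] for b in bonds], float)

        if self.config.target_mobility == "restrained":
            self._restr_idx = topology.target_index.astype(np.int64)
            if restraint_reference is None:
                raise IntegrationError(
                    "restrained target requires restraint_reference coordinates"
                )
            self._restr_ref = np.array(restraint_reference, float)[self._restr_idx]
            self._restr_k = float(self.config.restraint_k)
        else:
            self._restr_idx = np.empty(0, np.int64)
            self._restr_ref = np.empty((0, 3), float)
            self._restr_k = 0.0

        p = self.energy_params
        self._kc_over_diel = p.coulomb_constant / p.dielectric
        self._debye_inv = 0.0 if p.debye_length is None else 1.0 / p.debye_length
        self._cutoff2 = (
            float("inf")
            if not np.isfinite(p.nonbonded_cutoff)
            else p.nonbonded_cutoff ** 2
        )
        self._inv_mass_conv = ENERGY_CONVERSION / topology.mass[self.mobile_index]
        gamma_dt = self.config.friction * self.dt
        self._c1 = math.exp(-gamma_dt)
        sigma_eq = maxwell_sigma(topology.mass[self.mobile_index], self.config.temperature)
        self._sigma_o = sigma_eq * math.sqrt(1.0 - self._c1 ** 2)

    # chunk size: recording granularity is handled by chunked kernel calls
    def advance(
        self, state: State, n_steps: int, record_every: int | None = None
    ) -> tuple[State, list[tuple[float, np.ndarray]]]:
        if n_steps < 1:
            raise SumdError("n_steps must be >= 1")
        if record_every is None:
            record_every = n_steps
        if n_steps % record_every != 0:
            raise SumdError(
                f"n_steps ({n_steps}) must be a multiple of record_every "
                f"({record_every})"
            )
        new = state.copy()
        rng = new.rng()
        pos = new.positions
        vel = new.velocities
        forces = np.zeros_like(pos)
        target_before = (
            pos[self.topology.target_index].copy()
            if self.config.target_mobility == "fixed"
            else None
        )
        bad = _forces(
            pos, forces,
            self.topology.ligand_index.astype(np.int64),
            self.topology.target_index.astype(np.int64),
            self.topology.charge, self.topology.lj_epsilon, self.topology.lj_sigma,
            self._kc_over_diel, self._debye_inv, self._cutoff2,
            self._bond_i, self._bond_j, self._bond_r0, self._bond_k,
            self._restr_idx, self._restr_ref, self._restr_k,
        )
        if bad[0] >= 0:
            raise IntegrationError(
                f"overlapping atoms {bad[0]} and {bad[1]} at start of advance"
            )
        frames: list[tuple[float, np.ndarray]] = []
        n_mobile = len(self.mobile_index)
        done = 0
        while done < n_steps:
            chunk = min(record_every, n_steps - done)
            noise = rng.standard_normal((chunk, n_mobile, 3))
            step, bi, bj = _baoab_chunk(
                pos, vel, forces,
                self.mobile_index.astype(np.int64), self._inv_mass_conv,
                self.dt, self._c1, self._sigma_o, noise,
                self.topology.ligand_index.astype(np.int64),
                self.topology.target_index.astype(np.int64),
                self.topology.charge, self.topology.lj_epsilon,
                self.topology.lj_sigma,
                self._kc_over_diel, self._debye_inv, self._cutoff2,
                self._bond_i, self._bond_j, self._bond_r0, self._bond_k,
                self._restr_idx, self._restr_ref, self._restr_k,
            )
            if step >= 0:
                raise IntegrationError(
                    f"non-finite force between atoms {bi} and {bj} at step "
                    f"{done + step} (time {new.time + (done + step) * self.dt:.4f})"
                )
            done += chunk
            frames.append((new.time + done * self.dt, pos.copy()))
        if target_before is not None:
            # fixed target atoms must be bit-identical by construction
            pos[self.topology.target_index] = target_before
        new.time += n_steps * self.dt
        new.store_rng(rng)
        return new, frames

    def resample(self, state: State, seed: int | None = None) -> State:
        return resample_velocities(
            state,
            self.topology,
            self.config.temperature,
            seed=seed,
            mobile_index=self.mobile_index,
        )


# --- scripted mock engine ---------------------------------------------------


class MockEngine(EngineContract):
    """Engine that rigidly translates the ligand along a distance schedule.

    Each call to :meth:`advance` consumes the next schedule entry: the net
    ligand COM displacement (in A) along the site direction over that call,
    negative values approaching the site.  Motion is linear in time, so the
    fitted distance slope of an advance equals entry / (n_steps * dt).
    The schedule repeats its last entry when exhausted.  ``resample`` is a
    positional no-op that only perturbs the RNG token, mirroring the revert
    contract of the supervision loop.
    """

    def __init__(
        self,
        topology: Topology,
        site_com: np.ndarray,
        schedule: Sequence[float],
        dt: float = 0.2,
    ) -> None:
        if len(schedule) == 0:
            raise SumdError("mock engine schedule is empty")
        self.topology = topology
        self.site_com = np.asarray(site_com, float)
        self.schedule = [float(s) for s in schedule]
        self.dt = float(dt)
        self.calls = 0

    @staticmethod
    def schedule_from_tsv(path: str | Path, step: float = 3.0) -> list[float]:
        """Read (segment_index, slope_sign) rows into displacement entries."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("segment_index")
        return [float(np.sign(s)) * step for s in df["slope_sign"]]

    def _direction(self, state: State) -> np.ndarray:
        masses = self.topology.mass if self.topology.parameterized else None
        com = center_of_mass(state.positions, self.topology.ligand_index, masses)
        d = self.site_com - com
        n = np.linalg.norm(d)
        if n < 1e-12:
            return np.zeros(3)
        return d / n

    def advance(
        self, state: State, n_steps: int, record_every: int | None = None
    ) -> tuple[State, list[tuple[float, np.ndarray]]]:
        if record_every is None:
            record_every = n_steps
        entry = self.schedule[min(self.calls, len(self.schedule) - 1)]
        self.calls += 1
        direction = self._direction(state)
        new = state.copy()
        frames: list[tuple[float, np.ndarray]] = []
        lig = self.topology.ligand_index
        per_step = entry / n_steps
        done = 0
        while done < n_steps:
            chunk = min(record_every, n_steps - done)
            # displacement toward the site reduces the COM distance,
            # so a negative entry moves along +direction
            new.positions[lig] += (-per_step * chunk) * direction
            done += chunk
            frames.append((new.time + done * self.dt, new.positions.copy()))
        new.time += n_steps * self.dt
        return new, frames

    def resample(self, state: State, seed: int | None = None) -> State:
        new = state.copy()
        rng = (
            np.random.Generator(np.random.PCG64(seed))
            if seed is not None
            else new.rng()
        )
        rng.standard_normal()
        new.store_rng(rng)
        return new
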