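"""Screened molecular-mechanics ligand--target interaction energies.

The per-frame estimator is a pairwise sum of a screened Coulomb term and a
Lennard-Jones term over all (ligand atom, target atom) pairs within the
nonbonded cutoff, decomposed per target group (per nucleotide, in the
nucleic-acid setting).  The dielectric plus optional Debye screening are the
implicit stand-in for solvent and physiological salt; outputs are labelled
"interaction energy (MM, screened)".  Target-internal and ligand-internal
nonbonded terms are never included: the quantity is strictly the
ligand--target interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import EnergyParams, SelectionError, State, SumdError, Topology


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-target-group electrostatic/vdW interaction energies for one frame."""

    group_ids: np.ndarray        # (G,) int, target groups
    group_names: tuple[str, ...]
    electrostatic: np.ndarray    # (G,) kcal/mol
    vdw: np.ndarray              # (G,) kcal/mol

    @property
    def total_electrostatic(self) -> float:
        return float(self.electrostatic.sum())

    @property
    def total_vdw(self) -> float:
        return float(self.vdw.sum())

    @property
    def total(self) -> float:
        return self.total_electrostatic + self.total_vdw

    def per_group_total(self) -> np.ndarray:
        return self.electrostatic + self.vdw


def pair_coulomb(q1: float, q2: float, r: float, params: EnergyParams) -> float:
    """Screened Coulomb energy of a charge pair, truncated at the cutoff.

    k q1 q2 / (eps_r r), multiplied by exp(-r/lambda_D) when Debye
    screening is on; zero beyond the nonbonded cutoff.
    """
    if r <= 0:
        raise SumdError(f"pair distance must be > 0, got {r}")
    if r > params.nonbonded_cutoff:
        return 0.0
    e = params.coulomb_constant * q1 * q2 / (params.dielectric * r)
    if params.debye_length is not None:
        e *= math.exp(-r / params.debye_length)
    return e


def pair_lj(
    eps_i: float,
    eps_j: float,
    sig_i: float,
    sig_j: float,
    r: float,
    params: EnergyParams,
) -> float:
    """Lennard-Jones energy with Lorentz-Berthelot combination, truncated.

    sigma combines arithmetically, epsilon geometrically;
    4 eps [(sigma/r)^12 - (sigma/r)^6], zero beyond the cutoff.
    """
    if r <= 0:
        raise SumdError(f"pair distance must be > 0, got {r}")
    if r > params.nonbonded_cutoff:
        return 0.0
    sigma = 0.5 * (sig_i + sig_j)
    eps = math.sqrt(eps_i * eps_j)
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def interaction_energy(
    state: State | np.ndarray,
    topology: Topology,
    params: EnergyParams | None = None,
) -> EnergyBreakdown:
    """Ligand--target interaction energy of one frame, per target group.

    Each (ligand atom, target atom) pair within the cutoff is attributed to
    the target atom's group; the ligand is treated as one body.  Totals are
    exact sums of the per-group entries.
    """
    if params is None:
        params = EnergyParams()
    topology.require_parameterized()
    pos = state.positions if isinstance(state, State) else np.asarray(state, float)

    lig = topology.ligand_index
    tgt = topology.target_index
    d = pos[lig][:, None, :] - pos[tgt][None, :, :]   # (L, T, 3)
    r = np.sqrt((d * d).sum(axis=2))                  # (L, T)
    if np.any(r <= 0):
        raise SumdError("coincident ligand/target atoms (r = 0)")

    within = r <= params.nonbonded_cutoff

    q = topology.charge
    elec = params.coulomb_constant * np.outer(q[lig], q[tgt]) / (params.dielectric * r)
    if params.debye_length is not None:
        elec = elec * np.exp(-r / params.debye_length)

    sigma = 0.5 * (topology.lj_sigma[lig][:, None] + topology.lj_sigma[tgt][None, :])
    eps = np.sqrt(topology.lj_epsilon[lig][:, None] * topology.lj_epsilon[tgt][None, :])
    sr6 = (sigma / r) ** 6
    vdw = 4.0 * eps * (sr6 * sr6 - sr6)

    elec = np.where(within, elec, 0.0)
    vdw = np.where(within, vdw, 0.0)

    group_ids = topology.target_group_ids
    gid_pos = {int(g): k for k, g in enumerate(group_ids)}
    tgt_slot = np.array([gid_pos[int(g)] for g in topology.group_id[tgt]])

    g_elec = np.zeros(len(group_ids))
    g_vdw = np.zeros(len(group_ids))
    np.add.at(g_elec, tgt_slot, elec.sum(axis=0))
    np.add.at(g_vdw, tgt_slot, vdw.sum(axis=0))

    names = tuple(topology.group_label(int(g)) for g in group_ids)
    return EnergyBreakdown(group_ids, names, g_elec, g_vdw)


def cumulative_energy(series: Sequence[EnergyBreakdown]) -> pd.DataFrame:
    """Frame-by-frame running sums of the per-group interaction energies.

    Returns a tidy frame (frame, group_id, group_name, cum_elec, cum_vdw,
    cum_total); the last frame's values equal the plain sum over the series.
    """
    if len(series) == 0:
        raise SumdError("empty energy series")
    group_ids = series[0].group_ids
    names = series[0].group_names
    elec = np.cumsum([b.electrostatic for b in series], axis=0)
    vdw = np.cumsum([b.vdw for b in series], axis=0)
    records = []
    for f in range(len(series)):
        for k, gid in enumerate(group_ids):
            records.append(
                (f, int(gid), names[k], elec[f, k], vdw[f, k], elec[f, k] + vdw[f, k])
            )
    return pd.DataFrame(
        records,
        columns=["frame", "group_id", "group_name", "cum_elec", "cum_vdw", "cum_total"],
    )


def energy_series(
    frames: Iterable[np.ndarray],
    times: Sequence[float],
    topology: Topology,
    params: EnergyParams | None = None,
) -> pd.DataFrame:
    """Per-frame, per-group energy table with an ALL totals row per frame."""
    records = []
    for f, (t, pos) in enumerate(zip(times, frames)):
        b = interaction_energy(pos, topology, params)
        for k, gid in enumerate(b.group_ids):
            records.append(
                (f, t, str(int(gid)), b.group_names[k],
                 b.electrostatic[k], b.vdw[k], b.electrostatic[k] + b.vdw[k])
            )
        records.append(
            (f, t, "ALL", "ALL", b.total_electrostatic, b.total_vdw, b.total)
        )
    return pd.DataFrame(
        records,
        columns=["frame", "time", "group_id", "group_name", "elec", "vdw", "total"],
    )
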