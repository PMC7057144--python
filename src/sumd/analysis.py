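"""Post-processing of binding trajectories.

The analyses mirror the standard recognition-pathway toolbox: every frame is
rigidly superposed on the target backbone of a reference (Kabsch, proper
rotation), ligand and target RMSD series are measured against the
experimental complex, dynamically contacted target groups are counted within
a 4 A cutoff, and per-frame interaction energies are arranged into a
distance--energy landscape whose x-axis is the ligand--target COM distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BindingSiteSpec,
    SelectionError,
    State,
    SumdError,
    Topology,
    center_of_mass,
)
from .supervision import Trajectory, site_com_distance


class DegeneracyError(SumdError):
    pass


# --- superposition ----------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_index: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    The transform (proper rotation R, det = +1, and translation t) minimises
    the weighted RMSD over the fit selection; it is applied to *all* mobile
    coordinates.  Row-vector convention: x' = (x - com_mobile) R + com_ref.

    Returns (R, t, transformed mobile coordinates) with t such that
    x' = x R + t.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if fit_index is None:
        fit_index = np.arange(len(mobile))
    if len(fit_index) < 3:
        raise DegeneracyError("superposition needs at least 3 fit atoms")
    P = mobile[fit_index]
    Q = reference[fit_index]
    if P.shape != Q.shape:
        raise SumdError("fit selections have different lengths")
    if weights is None:
        w = np.ones(len(fit_index))
    else:
        w = np.asarray(weights, float)[fit_index]
    w = w / w.sum()
    cp = (P * w[:, None]).sum(axis=0)
    cq = (Q * w[:, None]).sum(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    H = P0.T @ (Q0 * w[:, None])
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear/coincident) selections have >1 vanishing
    # singular value relative to the largest
    if S[0] <= 0 or S[1] / S[0] < 1e-10:
        raise DegeneracyError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = cq - cp @ R
    return R, t, mobile @ R + t


def _rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    d2 = ((a - b) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = weights / weights.sum()
    return float(np.sqrt((w * d2).sum()))


# --- RMSD series ------------------------------------------------------------


@dataclass
class RMSDSeries:
    times: np.ndarray
    values: np.ndarray         # (F,) min over reference models
    per_model: np.ndarray      # (F, M)

    @property
    def rmsd_min(self) -> float:
        return float(self.values.min())

    @property
    def rmsd_max(self) -> float:
        return float(self.values.max())

    @property
    def argmin_frame(self) -> int:
        return int(self.values.argmin())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.values)), "time": self.times,
             "rmsd": self.values}
        )


def heavy_atom_index(topology: Topology, index: np.ndarray) -> np.ndarray:
    """Drop hydrogens (atom names starting with H) from a selection."""
    keep = [i for i in index if not str(topology.name[i]).upper().startswith("H")]
    return np.array(keep, int)


def default_fit_index(topology: Topology) -> np.ndarray:
    """Target atoms named P (the nucleic backbone phosphates); all target
    atoms when none are present (bead fixtures)."""
    p = np.flatnonzero(topology.target_mask & (np.char.upper(
        topology.name.astype(str)) == "P"))
    return p if len(p) > 0 else topology.target_index


def _as_models(reference: np.ndarray) -> np.ndarray:
    reference = np.asarray(reference, float)
    return reference[None] if reference.ndim == 2 else reference


def ligand_rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray,
    topology: Topology,
    fit_index: np.ndarray | None = None,
    rmsd_index: np.ndarray | None = None,
    mass_weighted_fit: bool = False,
) -> RMSDSeries:
    """Ligand heavy-atom RMSD vs the reference complex, frame by frame.

    Each frame is first superposed on the target fit selection of the
    reference; the ligand RMSD is then measured without re-fitting.  A
    multi-model reference (an NMR ensemble) yields the per-model series and
    the per-frame minimum.
    """
    models = _as_models(reference)
    if models.shape[1] != topology.n_atoms:
        raise SelectionError(
            f"reference has {models.shape[1]} atoms, topology {topology.n_atoms}"
        )
    if fit_index is None:
        fit_index = default_fit_index(topology)
    if rmsd_index is None:
        rmsd_index = heavy_atom_index(topology, topology.ligand_index)
    if len(rmsd_index) == 0:
        raise SelectionError("empty RMSD selection")
    weights = (
        topology.mass if (mass_weighted_fit and topology.mass is not None) else None
    )
    F, M = trajectory.n_frames, len(models)
    per_model = np.empty((F, M))
    for f, pos in enumerate(trajectory.frames):
        for m, ref in enumerate(models):
            _, _, moved = kabsch_superpose(pos, ref, fit_index, weights)
            per_model[f, m] = _rmsd(moved[rmsd_index], ref[rmsd_index])
    values = per_model.min(axis=1)
    return RMSDSeries(np.asarray(trajectory.times, float), values, per_model)


def target_rmsd_series(
    trajectory: Trajectory,
    topology: Topology,
    reference: np.ndarray | None = None,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> RMSDSeries:
    """Target backbone RMSD with fit and measurement on the same selection.

    The reference defaults to the first trajectory frame.  With
    ``superpose=False`` the raw (unfitted) deviation from the reference is
    reported instead of the post-fit residual.
    """
    if selection is None:
        selection = default_fit_index(topology)
    if reference is None:
        if trajectory.n_frames == 0:
            raise SumdError("empty trajectory")
        reference = trajectory.frames[0]
    models = _as_models(reference)
    F, M = trajectory.n_frames, len(models)
    per_model = np.empty((F, M))
    for f, pos in enumerate(trajectory.frames):
        for m, ref in enumerate(models):
            if superpose:
                _, _, moved = kabsch_superpose(pos, ref, selection)
            else:
                moved = pos
            per_model[f, m] = _rmsd(moved[selection], ref[selection])
    values = per_model.min(axis=1)
    return RMSDSeries(np.asarray(trajectory.times, float), values, per_model)


# --- dynamic contacts -------------------------------------------------------


@dataclass
class ContactFingerprint:
    group_ids: np.ndarray       # (G,) target groups
    group_names: tuple[str, ...]
    counts: np.ndarray          # (F, G) ligand atoms within cutoff of group
    cutoff: float

    @property
    def contacted(self) -> np.ndarray:
        return self.counts > 0

    @property
    def frequency(self) -> np.ndarray:
        """Fraction of frames in which each group is contacted."""
        return self.contacted.mean(axis=0)

    def most_contacted(self) -> list[tuple[int, str, float]]:
        """Groups by descending contact frequency, ties by group id."""
        order = sorted(
            range(len(self.group_ids)),
            key=lambda k: (-self.frequency[k], int(self.group_ids[k])),
        )
        return [
            (int(self.group_ids[k]), self.group_names[k], float(self.frequency[k]))
            for k in order
        ]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for f in range(self.counts.shape[0]):
            for k, gid in enumerate(self.group_ids):
                records.append((f, int(gid), self.group_names[k],
                                int(self.counts[f, k])))
        return pd.DataFrame(records, columns=["frame", "group_id", "group_name",
                                              "count"])


def contact_fingerprint(
    trajectory: Trajectory,
    topology: Topology,
    cutoff: float = 4.0,
) -> ContactFingerprint:
    """Per-frame ligand contacts with each target group.

    A group is contacted in a frame iff any of its atoms lies within
    ``cutoff`` of any ligand atom; the count is the number of ligand atoms
    within the cutoff of the group.
    """
    if cutoff <= 0:
        raise SumdError("contact cutoff must be > 0")
    lig = topology.ligand_index
    tgt = topology.target_index
    group_ids = topology.target_group_ids
    gid_pos = {int(g): k for k, g in enumerate(group_ids)}
    tgt_slot = np.array([gid_pos[int(g)] for g in topology.group_id[tgt]])
    F, G = trajectory.n_frames, len(group_ids)
    counts = np.zeros((F, G), int)
    for f, pos in enumerate(trajectory.frames):
        diff = pos[lig][:, None, :] - pos[tgt][None, :, :]
        r = np.sqrt((diff * diff).sum(axis=2))      # (L, T)
        # min distance of each ligand atom to each group
        for k in range(G):
            rg = r[:, tgt_slot == k]
            counts[f, k] = int((rg.min(axis=1) <= cutoff).sum())
    names = tuple(topology.group_label(int(g)) for g in group_ids)
    return ContactFingerprint(group_ids, names, counts, cutoff)


# --- interaction-energy landscape -------------------------------------------


@dataclass
class LandscapeGrid:
    distance_edges: np.ndarray
    energy_edges: np.ndarray
    counts: np.ndarray          # (Dbins, Ebins) frames per bin
    mean_energy: np.ndarray     # (Dbins, Ebins), NaN in empty bins

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def distance_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                records.append(
                    (self.distance_edges[i], self.distance_edges[i + 1],
                     self.energy_edges[j], self.energy_edges[j + 1],
                     int(self.counts[i, j]), self.mean_energy[i, j])
                )
        return pd.DataFrame(
            records,
            columns=["d_lo", "d_hi", "e_lo", "e_hi", "count", "mean_energy"],
        )


def energy_landscape(
    distances: np.ndarray,
    energies: np.ndarray,
    distance_edges: np.ndarray | int = 24,
    energy_edges: np.ndarray | int = 24,
) -> LandscapeGrid:
    """2-D histogram of frames over (COM distance, interaction energy).

    Per-bin mean energies average the member frames' energies; empty bins
    carry NaN (distinct from a genuine zero mean).  Bin counts always sum
    to the number of frames.
    """
    distances = np.asarray(distances, float)
    energies = np.asarray(energies, float)
    if distances.shape != energies.shape:
        raise SumdError("distance and energy series differ in length")
    for name, arr in (("distance", distances), ("energy", energies)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if len(bad):
            raise SumdError(f"non-finite {name} at frame {bad[0]}")
    if np.isscalar(distance_edges):
        distance_edges = np.linspace(
            distances.min(), distances.max() + 1e-9, int(distance_edges) + 1
        )
    if np.isscalar(energy_edges):
        energy_edges = np.linspace(
            energies.min(), energies.max() + 1e-9, int(energy_edges) + 1
        )
    counts, dx, ex = np.histogram2d(
        distances, energies, bins=[distance_edges, energy_edges]
    )
    esum, _, _ = np.histogram2d(
        distances, energies, bins=[distance_edges, energy_edges], weights=energies
    )
    # histogram2d drops out-of-range points; clip into the outer bins instead
    if counts.sum() != len(distances):
        di = np.clip(np.searchsorted(dx, distances, "right") - 1, 0, len(dx) - 2)
        ei = np.clip(np.searchsorted(ex, energies, "right") - 1, 0, len(ex) - 2)
        counts = np.zeros((len(dx) - 1, len(ex) - 1))
        esum = np.zeros_like(counts)
        np.add.at(counts, (di, ei), 1)
        np.add.at(esum, (di, ei), energies)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, esum / np.maximum(counts, 1), np.nan)
    return LandscapeGrid(np.asarray(dx), np.asarray(ex), counts.astype(int), mean)


# --- convenience series -----------------------------------------------------


def com_distance_series(
    trajectory: Trajectory, topology: Topology, site: BindingSiteSpec
) -> np.ndarray:
    out = np.empty(trajectory.n_frames)
    for f, pos in enumerate(trajectory.frames):
        st = State(pos, np.zeros_like(pos), trajectory.times[f])
        out[f] = site_com_distance(st, topology, site)
    return out


def total_energy_series(trajectory: Trajectory, topology: Topology, params=None):
    from .energetics import interaction_energy

    return np.array(
        [interaction_energy(p, topology, params).total for p in trajectory.frames]
    )


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if width < 1:
        raise SumdError("moving-average width must be >= 1")
    values = np.asarray(values, float)
    out = np.empty_like(values)
    h = width // 2
    for i in range(len(values)):
        lo = max(0, i - h)
        hi = min(len(values), i + h + 1)
        out[i] = values[lo:hi].mean()
    return out
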