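"""The supervised-MD sampling algorithm.

Short unbiased segments are collected while the ligand-COM to binding-site-COM
distance is monitored; the sampled distances of each segment are fitted to a
line, and only segments whose slope is strictly below the threshold (negative,
by default) are kept.  Rejected segments are discarded tabu-style: coordinates
revert bit-identically to the segment start and velocities are redrawn from
Maxwell-Boltzmann.  Once any sampled distance drops below the switch-off
threshold (5 A by default) supervision is disabled permanently and a short
unsupervised relaxation finishes the run.  Campaigns of up to 10 replicas are
ranked and the best one reported.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    BindingSiteSpec,
    RunManifest,
    SelectionError,
    State,
    SumdError,
    SupervisionConfig,
    Topology,
    center_of_mass,
)
from .engine import EngineContract

logger = logging.getLogger("sumd")

ACCEPT = "accept"
REJECT = "reject"
SWITCH_OFF = "switch_off"

STATUS_BOUND = "bound"
STATUS_SEGMENT_BUDGET = "segment_budget_exhausted"
STATUS_ATTEMPT_BUDGET = "attempt_budget_exhausted"


class DegenerateFitError(SumdError):
    pass


# --- reaction coordinate ----------------------------------------------------


def site_com_distance(
    state: State,
    topology: Topology,
    site: BindingSiteSpec,
    ligand_index: np.ndarray | None = None,
) -> float:
    """Distance between the ligand COM and the binding-site COM (A)."""
    if ligand_index is None:
        ligand_index = topology.ligand_index
    if len(ligand_index) == 0:
        raise SelectionError("empty ligand selection")
    site_index = site.atom_index(topology)
    masses = (
        topology.mass
        if (site.mass_weighted and topology.mass is not None)
        else None
    )
    lig_com = center_of_mass(state.positions, ligand_index, masses)
    site_com = center_of_mass(state.positions, site_index, masses)
    return float(np.linalg.norm(lig_com - site_com))


def _com_distance_from_positions(
    positions: np.ndarray,
    topology: Topology,
    site_index: np.ndarray,
    masses: np.ndarray | None,
) -> float:
    lig_com = center_of_mass(positions, topology.ligand_index, masses)
    site_com = center_of_mass(positions, site_index, masses)
    return float(np.linalg.norm(lig_com - site_com))


# --- slope fit and decision -------------------------------------------------


def fit_slope(samples: Sequence[tuple[float, float]]) -> float:
    """Ordinary-least-squares slope of distance vs time (A per time unit)."""
    if len(samples) < 2:
        raise DegenerateFitError("need at least 2 samples for a slope")
    t = np.array([s[0] for s in samples], float)
    d = np.array([s[1] for s in samples], float)
    t_mean = t.mean()
    st2 = ((t - t_mean) ** 2).sum()
    if st2 == 0:
        raise DegenerateFitError("all sample times equal; slope undefined")
    return float(((t - t_mean) * (d - d.mean())).sum() / st2)


@dataclass
class SegmentRecord:
    """One supervision window and the decision taken on it."""

    index: int
    start_time: float
    distance_samples: list[tuple[float, float]]
    slope: float | None
    accepted: bool
    attempt: int
    supervision_active: bool
    decision: str = ""

    @property
    def min_distance(self) -> float:
        return min(d for _, d in self.distance_samples)


def evaluate_segment(record: SegmentRecord, config: SupervisionConfig) -> str:
    """Decide accept / reject / switch_off for a supervised segment.

    Switch-off takes precedence: if any sampled distance dropped below the
    switch-off threshold the segment is retained and supervision ends.
    Otherwise the segment is kept iff its slope is strictly below the
    threshold (a slope exactly at the threshold is rejected).
    """
    if record.min_distance < config.switch_off_distance:
        return SWITCH_OFF
    if record.slope is None:
        raise SumdError("supervised segment has no fitted slope")
    if record.slope < config.slope_threshold:
        return ACCEPT
    return REJECT


# --- trajectory container ---------------------------------------------------


@dataclass
class Trajectory:
    """Accepted frames in time order, with per-frame segment provenance."""

    times: list[float] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)
    segment_index: list[int] = field(default_factory=list)
    status: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        return np.stack(self.frames)

    def append(self, time: float, positions: np.ndarray, segment: int) -> None:
        if self.times and time <= self.times[-1]:
            raise SumdError(
                f"frame times must strictly increase ({time} after {self.times[-1]})"
            )
        self.times.append(float(time))
        self.frames.append(np.array(positions, float))
        self.segment_index.append(int(segment))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for t, f in zip(self.times, self.frames):
            h.update(np.float64(t).tobytes())
            h.update(np.ascontiguousarray(f).tobytes())
        return h.hexdigest()


@dataclass
class SumdResult:
    trajectory: Trajectory
    segments: list[SegmentRecord]
    seed: int
    steps_to_switch_off: int | None   # engine steps until first d < threshold
    total_engine_steps: int
    n_accepted: int
    n_rejected: int

    @property
    def status(self) -> str:
        return self.trajectory.status


def _strides(
    segment_length: float, dt: float, n_fit_points: int, frame_interval: float
) -> tuple[int, int, int, int]:
    """Steps per segment and the sampling/frame/record strides (in steps)."""
    steps = int(round(segment_length / dt))
    if steps < n_fit_points:
        raise SumdError(
            f"segment of {steps} steps cannot carry {n_fit_points} fit points"
        )
    sample_stride = steps // n_fit_points
    steps = sample_stride * n_fit_points   # exact division, endpoint included
    frame_stride = max(1, int(round(frame_interval / dt)))
    record_stride = math.gcd(sample_stride, frame_stride)
    return steps, sample_stride, frame_stride, record_stride


# --- the SuMD loop ----------------------------------------------------------


def run_sumd(
    topology: Topology,
    start_state: State,
    site: BindingSiteSpec,
    config: SupervisionConfig,
    engine: EngineContract,
    frame_interval: float = 20.0,
    seed: int = 0,
) -> SumdResult:
    """Run one supervised binding simulation.

    The loop advances one segment at a time, sampling ``n_fit_points``
    equally spaced distances (endpoint included).  Accepted segments extend
    the trajectory; rejected ones revert coordinates bit-identically to the
    segment start and redraw velocities with a fresh seed.  A sampled
    distance below the switch-off threshold retains the triggering segment,
    disables supervision permanently, and appends an unsupervised
    relaxation phase before the run ends with status "bound".
    """
    site_index = site.atom_index(topology)
    masses = topology.mass if site.mass_weighted else None
    d0 = site_com_distance(start_state, topology, site)
    if d0 <= config.switch_off_distance:
        raise SumdError(
            f"start distance {d0:.2f} A is not above the switch-off "
            f"threshold {config.switch_off_distance} A"
        )

    steps, sample_stride, frame_stride, record_stride = _strides(
        config.segment_length, engine.dt, config.n_fit_points, frame_interval
    )
    seedseq = np.random.SeedSequence(seed)
    resample_seeds = iter(s.generate_state(1)[0] % (2**31) for s in seedseq.spawn(
        config.max_segments * config.max_failed_attempts + config.max_segments + 4
    ))

    state = start_state.copy()
    state.rng_state = np.random.PCG64(next(resample_seeds)).state
    state = engine.resample(state, seed=next(resample_seeds))

    traj = Trajectory()
    traj.append(state.time, state.positions, -1)
    records: list[SegmentRecord] = []

    attempt = 0
    total_steps = 0
    steps_to_switch_off: int | None = None
    n_accepted = 0
    n_rejected = 0
    status = STATUS_SEGMENT_BUDGET

    def segment_frames(new_time0, frames):
        """Split recorded frames into fit samples and trajectory frames."""
        samples = []
        keep = []
        for k, (t, pos) in enumerate(frames, start=1):
            step_no = k * record_stride
            if step_no % sample_stride == 0:
                d = _com_distance_from_positions(pos, topology, site_index, masses)
                samples.append((t, d))
            if step_no % frame_stride == 0:
                keep.append((t, pos))
        return samples, keep

    seg = 0
    while seg < config.max_segments:
        seg_start = state.copy()
        new_state, frames = engine.advance(state, steps, record_stride)
        total_steps += steps
        samples, keep = segment_frames(seg_start.time, frames)
        slope = fit_slope(samples)
        record = SegmentRecord(
            index=seg,
            start_time=seg_start.time,
            distance_samples=samples,
            slope=slope,
            accepted=False,
            attempt=attempt,
            supervision_active=True,
        )
        decision = evaluate_segment(record, config)
        record.decision = decision
        records.append(record)
        logger.info(
            "segment %d attempt %d slope %.5f min_d %.3f -> %s",
            seg, attempt, slope, record.min_distance, decision,
        )

        if decision == REJECT:
            n_rejected += 1
            attempt += 1
            state = engine.resample(seg_start, seed=next(resample_seeds))
            seg += 1
            if attempt >= config.max_failed_attempts:
                status = STATUS_ATTEMPT_BUDGET
                break
            continue

        # accepted (or switch-off): retain the segment's frames
        record.accepted = True
        for t, pos in keep:
            traj.append(t, pos, seg)
        state = new_state
        n_accepted += 1
        attempt = 0
        seg += 1

        if decision == SWITCH_OFF:
            # engine steps until the first sampled sub-threshold distance
            for k, (_, d) in enumerate(samples, start=1):
                if d < config.switch_off_distance:
                    steps_to_switch_off = (
                        total_steps - steps + k * sample_stride
                    )
                    break
            status = STATUS_BOUND
            relax_steps = int(round(config.effective_relaxation_length / engine.dt))
            if relax_steps > 0:
                relax_steps = max(record_stride, (relax_steps // record_stride) * record_stride)
                new_state, frames = engine.advance(state, relax_steps, record_stride)
                total_steps += relax_steps
                _, keep = segment_frames(state.time, frames)
                for t, pos in keep:
                    traj.append(t, pos, seg)
                records.append(
                    SegmentRecord(
                        index=seg,
                        start_time=state.time,
                        distance_samples=[
                            (t, _com_distance_from_positions(
                                pos, topology, site_index, masses))
                            for t, pos in keep
                        ] or [(state.time, record.min_distance)],
                        slope=None,
                        accepted=True,
                        attempt=0,
                        supervision_active=False,
                    )
                )
                state = new_state
            break

    traj.status = status
    return SumdResult(
        trajectory=traj,
        segments=records,
        seed=seed,
        steps_to_switch_off=steps_to_switch_off,
        total_engine_steps=total_steps,
        n_accepted=n_accepted,
        n_rejected=n_rejected,
    )


# --- replica campaigns ------------------------------------------------------


@dataclass
class CampaignSummary:
    results: list[SumdResult]
    replica_seeds: list[int]
    best_index: int | None
    metrics: list[dict]
    manifest: RunManifest

    @property
    def best(self) -> SumdResult | None:
        return None if self.best_index is None else self.results[self.best_index]


def _final_quarter_metrics(
    result: SumdResult,
    topology: Topology,
    site: BindingSiteSpec,
    energy_params=None,
) -> tuple[float, float]:
    """Mean COM distance and mean interaction energy over the last quarter."""
    from .energetics import interaction_energy

    traj = result.trajectory
    n = traj.n_frames
    tail = traj.frames[max(0, n - max(1, n // 4)):]
    site_index = site.atom_index(topology)
    masses = topology.mass if site.mass_weighted else None
    dists = [
        _com_distance_from_positions(p, topology, site_index, masses) for p in tail
    ]
    if energy_params is not None:
        energies = [interaction_energy(p, topology, energy_params).total for p in tail]
        mean_e = float(np.mean(energies))
    else:
        mean_e = 0.0
    return float(np.mean(dists)), mean_e


def run_replicas(
    topology: Topology,
    start_state: State,
    site: BindingSiteSpec,
    config: SupervisionConfig,
    engine: EngineContract,
    n_replicas: int = 10,
    frame_interval: float = 20.0,
    master_seed: int = 0,
    energy_params=None,
    config_snapshot: dict | None = None,
    replica_seeds: Sequence[int] | None = None,
) -> CampaignSummary:
    """Collect up to 10 independent binding replicas and pick the best.

    "Best" = among bound replicas, lowest mean COM distance over the final
    quarter of frames; ties broken by lower mean interaction energy.
    Explicit ``replica_seeds`` (e.g. from a recorded manifest) override the
    seeds derived from ``master_seed``, enabling bit-identical replay.
    """
    if n_replicas < 1:
        raise SumdError("n_replicas must be >= 1")
    if replica_seeds is None:
        ss = np.random.SeedSequence(master_seed)
        replica_seeds = [
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_replicas)
        ]
    else:
        replica_seeds = [int(s) for s in replica_seeds]
        if len(replica_seeds) != n_replicas:
            raise SumdError("replica_seeds length must equal n_replicas")

    manifest = RunManifest(
        config=config_snapshot or {},
        master_seed=int(master_seed),
        replica_seeds=list(replica_seeds),
    )

    results: list[SumdResult] = []
    metrics: list[dict] = []
    for i, s in enumerate(replica_seeds):
        res = run_sumd(
            topology, start_state, site, config, engine,
            frame_interval=frame_interval, seed=s,
        )
        results.append(res)
        mean_d, mean_e = _final_quarter_metrics(res, topology, site, energy_params)
        metrics.append(
            {
                "replica": i,
                "seed": s,
                "status": res.status,
                "mean_final_distance": mean_d,
                "mean_final_energy": mean_e,
                "n_accepted": res.n_accepted,
                "n_rejected": res.n_rejected,
                "engine_steps": res.total_engine_steps,
            }
        )
        manifest.statuses.append(res.status)
        manifest.segment_stats.append(
            {"accepted": res.n_accepted, "rejected": res.n_rejected}
        )

    bound = [
        (m["mean_final_distance"], m["mean_final_energy"], m["replica"])
        for m in metrics
        if m["status"] == STATUS_BOUND
    ]
    best_index = min(bound)[2] if bound else None
    return CampaignSummary(results, list(replica_seeds), best_index, metrics, manifest)
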