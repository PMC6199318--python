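"""Exact stochastic simulation and synthetic single-molecule data.

Generates Gillespie realizations of the metal-ion cycle, renders them into
frame-sampled FRET efficiency traces, extracts pauses (constant-position
stalls), and builds per-condition velocity datasets with quenched disorder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .master_equation import STATE_E, STATE_EM, STATE_EMM, STATE_NAMES, DisorderSpec
from .model_core import MgCondition, ModelSpec, ModelVariant, as_condition

__all__ = [
    "StateTrajectory",
    "FretTrace",
    "PauseRecord",
    "MaxEventsExceededError",
    "transitions_from",
    "simulate_trajectory",
    "trajectory_to_fret",
    "extract_pauses",
    "synth_velocity_dataset",
    "DEFAULT_CONCENTRATION_GRID",
]

#: Default condition grid (mM) for synthetic velocity datasets.
DEFAULT_CONCENTRATION_GRID = (0.03, 0.08, 0.1, 0.2, 0.3, 0.5, 1.0, 3.0, 6.0, 9.0)


class MaxEventsExceededError(RuntimeError):
    """A trajectory exceeded the event safety cap before absorbing."""


@dataclass(frozen=True)
class StateTrajectory:
    """One Gillespie realization of the cycle.

    ``times`` are event times starting at 0; ``states[k]`` and
    ``positions[k]`` hold the chemical state (codes 0/1/2 = E/EM/EMM) and
    cleaved-nucleotide position occupied from ``times[k]`` until the next
    event.  ``terminal`` marks absorption at position ``n_sites``.
    """

    times: np.ndarray
    states: np.ndarray
    positions: np.ndarray
    n_sites: int
    terminal: bool
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=np.int8)
        positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(times) == len(states) == len(positions)):
            raise ValueError("times, states and positions must have equal length")
        if len(times) == 0 or times[0] != 0.0:
            raise ValueError("trajectory must start at time 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("event times must be strictly increasing")
        d = np.diff(positions)
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("positions must be non-decreasing in steps of 1")
        if self.terminal != (positions[-1] == self.n_sites):
            raise ValueError("terminal flag inconsistent with final position")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "positions", positions)

    @property
    def total_time(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class FretTrace:
    """Frame-sampled FRET efficiency trace.

    ``times`` are frame start times on a uniform grid of spacing
    ``frame_dt``; ``fret`` is the frame-averaged efficiency (noise may take
    it outside [0, 1]).  Synthetic traces carry complete provenance metadata
    plus optional per-frame position (frame-averaged) and majority-state
    columns.
    """

    frame_dt: float
    times: np.ndarray
    fret: np.ndarray
    donor: np.ndarray | None = None
    acceptor: np.ndarray | None = None
    positions: np.ndarray | None = None
    states: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fret = np.asarray(self.fret, dtype=float)
        if len(times) < 2:
            raise ValueError("a trace needs at least 2 frames")
        if len(times) != len(fret):
            raise ValueError("times and fret must have equal length")
        dt = np.diff(times)
        if not np.allclose(dt, self.frame_dt, rtol=1e-6, atol=1e-12):
            raise ValueError("frames must be uniformly spaced at frame_dt")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fret", fret)


@dataclass(frozen=True)
class PauseRecord:
    """A maximal constant-position interval longer than the stall threshold."""

    start: float
    duration: float
    position: int
    occupancy: dict

    def __post_init__(self) -> None:
        total = sum(self.occupancy.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"occupancy fractions must sum to 1, got {total!r}")

    @property
    def majority_state(self) -> str:
        return max(self.occupancy, key=self.occupancy.get)


def transitions_from(
    spec: ModelSpec, c: MgCondition | float, state: int, n: int
) -> list[tuple[float, int, int]]:
    """Outgoing transitions ``(rate, new_state, new_position)`` of (state, n).

    This is the same wiring as ``master_equation.build_generator``; a test
    cross-checks the two against each other.
    """
    cond = as_condition(c)
    r = spec.rates
    k_A_on, k_B_on = r.k_A_on(cond), r.k_B_on(cond)
    N = spec.n_sites
    out: list[tuple[float, int, int]] = []
    if spec.variant is ModelVariant.MODEL1:
        if state == STATE_EMM and n < N:
            out.append((r.k_B_off, STATE_EM, n))
        elif state == STATE_EM:
            if n < N:
                out.append((k_B_on, STATE_EMM, n + 1))
            out.append((r.k_A_off, STATE_E, n))
        elif state == STATE_E:
            out.append((k_A_on, STATE_EM, n))
    else:
        if state == STATE_EMM and n < N:
            out.append((r.k_B_off, STATE_E, n + 1))
        elif state == STATE_EM:
            out.append((k_B_on, STATE_EMM, n))
            out.append((r.k_A_off, STATE_E, n))
        elif state == STATE_E:
            out.append((k_A_on, STATE_EM, n))
    return [(rate, s, m) for rate, s, m in out if rate > 0]


def simulate_trajectory(
    spec: ModelSpec,
    c: MgCondition | float,
    seed: int | np.random.Generator | None = None,
    *,
    max_events: int = 10_000_000,
) -> StateTrajectory:
    """Gillespie simulation from EMM(0) until absorption at position N.

    Reproducible given ``seed`` (an int seed or an existing Generator).
    Raises :class:`MaxEventsExceededError` instead of truncating silently.
    """
    cond = as_condition(c)
    if cond.concentration <= 0:
        raise ValueError("simulate_trajectory requires a positive concentration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state, n = STATE_EMM, 0
    t = 0.0
    times = [0.0]
    states = [state]
    positions = [n]
    N = spec.n_sites
    for _ in range(max_events):
        if state == STATE_EMM and n == N:
            break
        moves = transitions_from(spec, cond, state, n)
        total = sum(rate for rate, _, _ in moves)
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        acc = 0.0
        for rate, s, m in moves:
            acc += rate
            if u <= acc:
                state, n = s, m
                break
        times.append(t)
        states.append(state)
        positions.append(n)
    else:
        raise MaxEventsExceededError(
            f"trajectory exceeded {max_events} events before absorbing"
        )
    return StateTrajectory(
        times=np.array(times),
        states=np.array(states, dtype=np.int8),
        positions=np.array(positions),
        n_sites=N,
        terminal=True,
        metadata={
            "variant": spec.variant.value,
            "concentration_mM": cond.concentration,
            "rates": [spec.rates.k_B_off, spec.rates.k_B_b, spec.rates.k_A_off, spec.rates.k_A_b],
        },
    )


def _frame_average_position(traj: StateTrajectory, edges: np.ndarray) -> np.ndarray:
    """Time-average of the position step function over each frame."""
    # Cumulative integral of n(t) at event times; constant extension past the end.
    times = traj.times
    pos = traj.positions.astype(float)
    dt = np.diff(times)
    cum = np.concatenate([[0.0], np.cumsum(pos[:-1] * dt)])

    def integral(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, None)
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 1)
        return cum[idx] + pos[idx] * (t - times[idx])

    return (integral(edges[1:]) - integral(edges[:-1])) / np.diff(edges)


def _frame_majority_state(traj: StateTrajectory, edges: np.ndarray) -> np.ndarray:
    """Time-majority chemical state name within each frame."""
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        occ = _occupancy_in_window(traj, lo, hi)
        out.append(max(occ, key=occ.get))
    return np.array(out)


def _occupancy_in_window(traj: StateTrajectory, lo: float, hi: float) -> dict:
    starts = traj.times
    ends = np.concatenate([traj.times[1:], [max(hi, traj.times[-1])]])
    overlap = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None)
    # Constant extension beyond the recorded span: the initial state holds
    # before t = 0 (pre-reaction lead-in) and the final one after absorption.
    if lo < 0:
        overlap[0] += min(hi, 0.0) - lo
    if hi > ends[-1]:
        overlap[-1] += hi - ends[-1]
    occ = {name: 0.0 for name in STATE_NAMES}
    for code, name in enumerate(STATE_NAMES):
        occ[name] = float(overlap[traj.states == code].sum())
    total = sum(occ.values())
    if total == 0:
        return {name: (1.0 if name == STATE_NAMES[traj.states[-1]] else 0.0) for name in STATE_NAMES}
    return {name: v / total for name, v in occ.items()}


def trajectory_to_fret(
    traj: StateTrajectory,
    frame_dt: float = 0.1,
    e_min: float = 0.26,
    e_max: float = 0.53,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator | None = None,
    *,
    tail: float = 1.0,
    lead: float = 0.5,
    record_states: bool = True,
) -> FretTrace:
    """Render a trajectory into a frame-sampled FRET efficiency trace.

    The per-frame efficiency is the linear map
    ``e_min + (n / N) (e_max - e_min)`` of the *frame-averaged* position
    (translocation events can be fast relative to a frame), plus independent
    Gaussian noise per frame.  The trace opens with ``lead`` seconds of
    pre-reaction plateau at position 0 (the recording starts before the
    reaction does) and extends ``tail`` seconds past absorption at the final
    plateau.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    if e_max <= e_min:
        raise ValueError("e_max must exceed e_min")
    if noise_sd < 0 or lead < 0 or tail < 0:
        raise ValueError("noise_sd, lead and tail must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lead = frame_dt * int(round(lead / frame_dt))
    n_frames = max(2, int(math.ceil((lead + traj.total_time + tail) / frame_dt)))
    edges = np.arange(n_frames + 1) * frame_dt - lead
    nbar = _frame_average_position(traj, edges)
    fret = e_min + (nbar / traj.n_sites) * (e_max - e_min)
    if noise_sd > 0:
        fret = fret + rng.normal(0.0, noise_sd, size=n_frames)
    states = _frame_majority_state(traj, edges) if record_states else None
    return FretTrace(
        frame_dt=frame_dt,
        times=edges[:-1] + lead,  # recording clock: frame 0 starts at t = 0
        fret=fret,
        positions=nbar if record_states else None,
        states=states,
        metadata={
            **traj.metadata,
            "n_sites": traj.n_sites,
            "e_min": e_min,
            "e_max": e_max,
            "noise_sd": noise_sd,
            "lead_s": lead,
            "tail_s": tail,
        },
    )


def extract_pauses(traj: StateTrajectory, min_dwell: float = 2.0) -> list[PauseRecord]:
    """Maximal constant-position intervals longer than ``min_dwell`` seconds.

    Each record carries the time-weighted occupancy fractions of the three
    chemical states within the stall; the terminal (absorbed) segment has no
    defined end and is excluded.
    """
    times = traj.times
    positions = traj.positions
    records: list[PauseRecord] = []
    boundaries = np.nonzero(np.diff(positions) > 0)[0] + 1  # indices where position increments
    seg_start = 0
    for b in boundaries:
        start_t, end_t = times[seg_start], times[b]
        duration = end_t - start_t
        if duration > min_dwell:
            records.append(
                PauseRecord(
                    start=float(start_t),
                    duration=float(duration),
                    position=int(positions[seg_start]),
                    occupancy=_occupancy_in_window(traj, start_t, end_t),
                )
            )
        seg_start = b
    return records


def synth_velocity_dataset(
    spec: ModelSpec,
    concentrations: Sequence[float] | None = None,
    n_traces_per_c: int = 100,
    disorder: DisorderSpec | None = None,
    seed: int | None = None,
):
    """Per-condition velocity dataset from Gillespie runs with disorder.

    For each trace one activation-free-energy offset ``dG ~ Normal(0,
    sigma^2)`` is drawn, all four rates are scaled by ``exp(-dG)``, a
    trajectory is simulated, and the velocity ``n_sites / tau_N`` recorded.
    Returns an :class:`~twometal.inference.VelocityDataset`; per-condition
    mean and SEM are recomputed from the records on demand.
    """
    from .inference import VelocityDataset  # local import to avoid a cycle
    import pandas as pd

    if concentrations is None:
        concentrations = DEFAULT_CONCENTRATION_GRID
    if n_traces_per_c < 1:
        raise ValueError("n_traces_per_c must be >= 1")
    sigma = 0.0 if disorder is None else disorder.sigma
    rng = np.random.default_rng(seed)
    rows = []
    for ci, conc in enumerate(concentrations):
        if conc <= 0:
            raise ValueError("concentrations must be positive")
        for j in range(n_traces_per_c):
            factor = math.exp(-rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            local = spec.with_rates(spec.rates.scaled(factor))
            traj = simulate_trajectory(local, conc, rng)
            rows.append(
                {
                    "mg_mM": float(conc),
                    "velocity_nt_s": spec.n_sites / traj.total_time,
                    "trace_id": f"c{ci}_t{j}",
                }
            )
    return VelocityDataset(records=pd.DataFrame(rows))
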