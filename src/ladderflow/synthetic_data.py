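"""Synthetic RBC-transit simulator producing frame-based detection tables.

The simulator emulates the kind of data that particle tracking of
high-speed video yields for a ladder microchannel: per-frame observations
``(set, frame, time, cell, channel, axial position, normalized lateral
position)``.  It is deliberately reduced physics —

* cells are point particles arriving as a homogeneous Poisson process whose
  rate realises a target parent-channel tube hematocrit,
* the cross-sectional (width-wise) position is a single coordinate in
  ``[0, 1]`` drawn from a symmetric Beta(kappa, kappa) profile; ``kappa = 1``
  is uniform and larger ``kappa`` concentrates cells near the centreline the
  way parachute-shaped RBCs do in narrow channels,
* at each junction a cell follows the separating-streamline rule: it exits
  into the bifurcating channel iff its lateral position lies on the branch
  side of the streamline that divides off the branch's share of the flow,
* cells that continue are remapped by streamline continuity and, between
  junctions, their lateral position relaxes back toward the steady profile
  with probability ``1 - exp(-L_D/lambda)`` (lateral migration with
  characteristic length ``lambda``),
* each cell advects at the local mean velocity of the segment it occupies,
  derived from the Kirchhoff flow solution.

Ground truth (per-cell branch assignment, analytic junction-exit
probabilities) is returned alongside the table for parameter-recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import GeometryError, LadderGeometry
from .network_flow import FlowSolution

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "GroundTruth",
    "DETECTION_COLUMNS",
    "sample_inlet_positions",
    "separating_fraction",
    "relax_positions",
    "junction_exit_probabilities",
    "simulate_transits",
    "set_rng",
    "write_detections",
    "read_detections",
]

#: average volume of a single RBC in um^3, used to convert counts to hematocrit
RBC_VOLUME_UM3 = 94.1

#: column order of every detection table produced or consumed by this package
DETECTION_COLUMNS = ["set", "frame", "time", "cell", "channel", "axial_um", "lateral"]

VelocityProfile = Literal["plug", "parabolic_plate"]


class SimulationError(ValueError):
    """Raised for invalid simulation configurations or mismatched inputs."""


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one synthetic acquisition.

    target_parent_hematocrit
        Tube hematocrit realised in the parent channel (fraction, e.g. 0.10).
    mean_velocity
        Mean flow velocity in the parent channel, m/s.
    frame_rate, frames_per_set, n_sets
        Acquisition protocol: 200 fps, 300 frames (1.5 s) per set, 3
        replicate sets by default.
    profile_concentration
        ``kappa >= 1`` of the Beta(kappa, kappa) lateral profile; 1 = uniform.
    migration_length
        Characteristic axial distance (um) of lateral migration back toward
        the steady profile between junctions; ``inf`` freezes positions.
        Default 200 um, of the order of the branch spacings studied; this is
        a free model parameter, not a measured value.
    velocity_profile
        Velocity profile used for the separating-streamline rule and the
        streamline remapping: ``plug`` (uniform) or ``parabolic_plate``
        (u(x) proportional to x(1-x) across the width).
    rbc_volume
        Single-cell volume in um^3, used to set the arrival rate.
    lead_in_length
        Length (um) of the observed parent-channel stub upstream of the
        first junction; hematocrit of the undisturbed parent flow is
        measured there.
    rng_seed
        Master seed; per-set generators derive from it via :func:`set_rng`.
    """

    target_parent_hematocrit: float
    mean_velocity: float = 1.0
    frame_rate: float = 200.0
    frames_per_set: int = 300
    n_sets: int = 3
    profile_concentration: float = 1.0
    migration_length: float = 200.0
    velocity_profile: VelocityProfile = "plug"
    rbc_volume: float = RBC_VOLUME_UM3
    lead_in_length: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_parent_hematocrit < 1.0:
            raise SimulationError(
                f"hematocrit must be in (0, 1), got {self.target_parent_hematocrit}"
            )
        if self.profile_concentration < 1.0:
            raise SimulationError(
                "profile_concentration (kappa) must be >= 1; kappa < 1 would "
                "concentrate cells at the walls"
            )
        lam = self.migration_length
        if lam is not None and not lam > 0:
            raise SimulationError("migration_length must be > 0 (or inf)")
        for name in ("mean_velocity", "frame_rate", "lead_in_length", "rbc_volume"):
            if not getattr(self, name) > 0:
                raise SimulationError(f"{name} must be > 0")
        for name in ("frames_per_set", "n_sets"):
            if not getattr(self, name) >= 1:
                raise SimulationError(f"{name} must be >= 1")
        if self.velocity_profile not in ("plug", "parabolic_plate"):
            raise SimulationError(f"unknown velocity profile {self.velocity_profile!r}")


@dataclass
class GroundTruth:
    """Simulator-side truth for one set, used by recovery tests.

    ``branch_counts[i]`` counts cells whose entry into branch ``B_{i+1}``
    occurred within the recorded frame window; these are exactly the
    transits a complete detector can observe, so flux counting on the
    detection table reproduces them one for one.
    """

    configured_hematocrit: float
    flow_fractions: np.ndarray
    exit_probabilities: np.ndarray
    n_cells_injected: int
    branch_counts: np.ndarray
    cell_branch: np.ndarray = field(repr=False)
    cell_entry_time: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (per-cell arrays omitted)."""
        return {
            "configured_hematocrit": self.configured_hematocrit,
            "flow_fractions": [float(x) for x in self.flow_fractions],
            "exit_probabilities": [float(x) for x in self.exit_probabilities],
            "n_cells_injected": int(self.n_cells_injected),
            "branch_counts": [int(x) for x in self.branch_counts],
        }


def set_rng(master_seed: int, set_index: int) -> np.random.Generator:
    """Deterministic per-set generator: ``SeedSequence((master_seed, set_index))``."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, set_index)))


# -- lateral-profile primitives -------------------------------------------

def sample_inlet_positions(n: int, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` lateral positions in [0, 1] from Beta(kappa, kappa).

    ``kappa = 1`` is the uniform profile; larger values concentrate mass at
    the channel centre (variance ``1 / (4(2 kappa + 1))``).
    """
    if n < 0:
        raise SimulationError("n must be >= 0")
    if kappa < 1.0:
        raise SimulationError("kappa must be >= 1")
    return rng.beta(kappa, kappa, size=n)


def _flow_cdf(x: np.ndarray | float, profile: VelocityProfile) -> np.ndarray | float:
    """Cumulative volumetric-flow fraction carried between the wall and x."""
    if profile == "plug":
        return x
    x = np.asarray(x, dtype=float)
    return 3.0 * x**2 - 2.0 * x**3


def _flow_cdf_inv(q, profile: VelocityProfile):
    """Inverse of :func:`_flow_cdf`, vectorized (bisection on the monotone CDF)."""
    if profile == "plug":
        return q
    q = np.asarray(q, dtype=float)
    lo = np.zeros_like(q)
    hi = np.ones_like(q)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = _flow_cdf(mid, profile) < q
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def separating_fraction(q: float, velocity_profile: VelocityProfile = "plug") -> float:
    """Lateral coordinate x* of the separating streamline.

    Measured from the branch-side wall: the flow carried over ``[0, x*]``
    equals the branch's flow fraction ``q``.  Plug flow gives ``x* = q``;
    the plane-parabolic profile gives the root of ``3x^2 - 2x^3 = q``.
    """
    if not 0.0 <= q <= 1.0:
        raise SimulationError(f"flow fraction must be in [0, 1], got {q}")
    if velocity_profile == "plug":
        return float(q)
    if q in (0.0, 1.0):
        return float(q)
    return float(optimize.brentq(lambda x: _flow_cdf(x, velocity_profile) - q,
                                 0.0, 1.0, xtol=1e-14))


def relax_positions(
    x: np.ndarray | float,
    distance: float,
    migration_length: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Relax lateral positions toward the steady Beta(kappa, kappa) profile.

    Over an axial distance ``distance`` each position is independently
    redrawn from the steady profile with probability
    ``1 - exp(-distance / migration_length)`` and kept otherwise; this is a
    memoryless surrogate for gradual cross-streamline migration.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    if distance < 0:
        raise SimulationError("distance must be >= 0")
    if not migration_length > 0:
        raise SimulationError("migration_length must be > 0 (or inf)")
    p = -math.expm1(-distance / migration_length) if math.isfinite(migration_length) else 0.0
    if p > 0.0 and x.size:
        redraw = rng.random(x.size) < p
        n_redraw = int(redraw.sum())
        if n_redraw:
            x[redraw] = sample_inlet_positions(n_redraw, kappa, rng)
    return x


# -- shared junction bookkeeping -------------------------------------------

def _junction_fractions(ratios: np.ndarray) -> np.ndarray:
    """Flow fraction q_i = Q_i / (supply flow remaining at junction i)."""
    remaining_before = 1.0 - np.concatenate(([0.0], np.cumsum(ratios)[:-1]))
    q = np.clip(ratios / np.maximum(remaining_before, 1e-300), 0.0, 1.0)
    q[-1] = 1.0  # the supply ends at the last junction: everything exits
    return q


def junction_exit_probabilities(
    geometry: LadderGeometry,
    solution: FlowSolution,
    config: SimulationConfig,
    grid: int = 4096,
) -> np.ndarray:
    """Analytic per-branch transit probabilities for a single cell.

    Propagates the lateral-position distribution through the junction rules
    (separating streamline, streamline remapping, migration relaxation) by
    deterministic quadrature on a grid, giving the exact marginal
    probability that a cell exits through each branch.  In the null limit
    (kappa = 1, migration off, plug profile) this reduces to the fractional
    flow ratios.
    """
    ratios = np.asarray(solution.fractional_ratios, dtype=float)
    if ratios.size != geometry.n_branches:
        raise SimulationError("flow solution does not match geometry")
    kappa = config.profile_concentration
    profile = config.velocity_profile
    lam = config.migration_length
    p_relax = (-math.expm1(-geometry.branch_spacing / lam)
               if math.isfinite(lam) else 0.0)

    xg = np.linspace(0.0, 1.0, grid + 1)
    cdf_beta = stats.beta.cdf(xg, kappa, kappa)
    cdf = cdf_beta.copy()          # conditional CDF of survivors
    survival = 1.0
    q = _junction_fractions(ratios)
    probs = np.empty(ratios.size)
    for i in range(ratios.size):
        if i == ratios.size - 1:
            probs[i] = survival
            break
        xs = separating_fraction(q[i], profile)
        c_star = float(np.interp(xs, xg, cdf))
        probs[i] = survival * c_star
        stay = max(1.0 - c_star, 1e-300)
        # streamline remap: survivor at x maps to y with F(x) = q + (1-q) F(y)
        x_of_y = _flow_cdf_inv(q[i] + (1.0 - q[i]) * _flow_cdf(xg, profile), profile)
        cdf = (np.interp(x_of_y, xg, cdf) - c_star) / stay
        cdf = np.clip(cdf, 0.0, 1.0)
        cdf[0], cdf[-1] = 0.0, 1.0
        if p_relax > 0.0:
            cdf = (1.0 - p_relax) * cdf + p_relax * cdf_beta
        survival *= 1.0 - c_star
    return probs


# -- the simulator ----------------------------------------------------------

def _ranges(counts: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(c)`` for each c in counts, without a Python loop."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    return np.arange(total, dtype=np.int64) - np.repeat(ends - counts, counts)


def _branch_entry_lateral(x: np.ndarray, xs: float, profile: VelocityProfile) -> np.ndarray:
    """Map a parent lateral position below the separating streamline into the branch."""
    if xs <= 0.0:
        return np.zeros_like(x)
    return np.asarray(_flow_cdf_inv(_flow_cdf(x, profile) / _flow_cdf(xs, profile),
                                    profile), dtype=float)


def _remap_survivors(x: np.ndarray, xs: float, profile: VelocityProfile) -> np.ndarray:
    """Streamline-continuity remap of positions above the separating streamline."""
    q = _flow_cdf(xs, profile)
    return np.asarray(_flow_cdf_inv((_flow_cdf(x, profile) - q) / (1.0 - q), profile),
                      dtype=float)


def simulate_transits(
    geometry: LadderGeometry,
    solution: FlowSolution,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    set_id: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one acquisition set and return (detection table, ground truth).

    Cells enter the observed lead-in as a Poisson process with rate
    ``H_P * A_P * v / V_RBC``; each advects at the local mean velocity of
    the segment it occupies and follows the separating-streamline rule at
    each junction.  Snapshots are recorded at the frame times.  A transit
    through a bifurcating channel faster than one frame interval is
    recorded once, at the first frame time after branch entry, with the
    axial position clamped to the branch outlet (axial == L_B); region-of-
    interest counting uses half-open axial intervals, so such outlet rows
    never inflate occupancy statistics while keeping flux counting exact.

    Axial positions are channel-local: parent positions are measured from
    the start of the lead-in (junction ``i`` sits at
    ``lead_in_length + (i-1) L_D``), branch positions from the branch
    entrance.
    """
    ratios = np.asarray(solution.fractional_ratios, dtype=float)
    n_b = geometry.n_branches
    if ratios.size != n_b:
        raise SimulationError(
            f"flow solution has {ratios.size} branches, geometry has {n_b}"
        )
    rng = rng if rng is not None else set_rng(config.rng_seed, set_id)

    v = config.mean_velocity * 1e6                     # um/s in the parent inlet
    fps = config.frame_rate
    n_frames = config.frames_per_set
    t_last = (n_frames - 1) / fps
    kappa = config.profile_concentration
    profile = config.velocity_profile
    lam = config.migration_length
    ld = geometry.branch_spacing
    lb = geometry.branch_length
    lead = config.lead_in_length

    q = _junction_fractions(ratios)
    remaining_after = np.clip(1.0 - np.cumsum(ratios), 0.0, None)
    v_segment = v * remaining_after[:-1]               # parent segment i (after junction i)
    v_branch = v * ratios * (geometry.parent_area / geometry.branch_area)
    junction_axial = lead + ld * np.arange(n_b)

    # worst-case residence from inlet to a branch outlet, for warm-up margins
    tau_max = lead / v + float(np.sum(ld / v_segment)) + float(np.max(lb / v_branch))

    rate = (config.target_parent_hematocrit * geometry.parent_area * v
            / config.rbc_volume)                       # cells / s
    t0, t1 = -tau_max, t_last
    n_cells = int(rng.poisson(rate * (t1 - t0)))
    arrivals = np.sort(rng.uniform(t0, t1, size=n_cells))
    x0 = sample_inlet_positions(n_cells, kappa, rng)

    # --- propagate cells through the junctions (vectorized over cells) ---
    idx = np.arange(n_cells)
    x = x0.copy()
    t = arrivals + lead / v                            # time at junction 1
    cell_branch = np.full(n_cells, -1, dtype=np.int64)
    entry_time = np.full(n_cells, np.nan)
    branch_lateral = np.full(n_cells, np.nan)
    # per parent-segment records: (cell index, entry time, lateral)
    seg_records: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    for i in range(n_b):
        if idx.size == 0:
            break
        if i == n_b - 1:
            exit_mask = np.ones(idx.size, dtype=bool)
            xs = 1.0
        else:
            xs = separating_fraction(q[i], profile)
            exit_mask = x < xs
        out = idx[exit_mask]
        cell_branch[out] = i
        entry_time[out] = t[exit_mask]
        branch_lateral[out] = _branch_entry_lateral(x[exit_mask], xs, profile)
        keep = ~exit_mask
        idx, x, t = idx[keep], x[keep], t[keep]
        if i < n_b - 1 and idx.size:
            x = _remap_survivors(x, xs, profile)
            x = relax_positions(x, ld, lam, kappa, rng)
            seg_records.append((idx.copy(), t.copy(), x.copy()))
            t = t + ld / v_segment[i]

    # --- frame-snapshot rows ---
    frames_list, cells_list, chan_list, axial_list, lat_list = [], [], [], [], []

    def _interval_rows(cell_idx, t_enter, speed, axial0, lateral, channel, length):
        """Frames with t_enter <= t_k < t_enter + length/speed, clipped to the set."""
        t_exit = t_enter + length / speed
        k0 = np.ceil(t_enter * fps - 1e-12).astype(np.int64)
        k1 = np.ceil(t_exit * fps - 1e-12).astype(np.int64) - 1
        k0c = np.maximum(k0, 0)
        k1c = np.minimum(k1, n_frames - 1)
        counts = np.maximum(k1c - k0c + 1, 0)
        if counts.sum() == 0:
            return counts
        rows_cell = np.repeat(cell_idx, counts)
        rows_k = np.repeat(k0c, counts) + _ranges(counts)
        rows_t_enter = np.repeat(t_enter, counts)
        frames_list.append(rows_k)
        cells_list.append(rows_cell)
        chan_list.append(np.full(rows_k.size, channel, dtype=object))
        axial_list.append(axial0 + (rows_k / fps - rows_t_enter) * speed)
        lat_list.append(np.repeat(lateral, counts))
        return counts

    # lead-in (full parent velocity, axial origin 0)
    _interval_rows(np.arange(n_cells), arrivals, v, 0.0, x0, "P", lead)
    # inter-junction parent segments
    for i, (cells_i, t_i, x_i) in enumerate(seg_records):
        _interval_rows(cells_i, t_i, v_segment[i], junction_axial[i], x_i, "P", ld)
    # branches: interior frames plus outlet-clamped row for sub-frame transits
    for i in range(n_b):
        in_window = (cell_branch == i) & (entry_time >= 0.0) & (entry_time <= t_last)
        cells_i = np.flatnonzero(in_window)
        if cells_i.size == 0:
            continue
        te = entry_time[cells_i]
        counts = _interval_rows(cells_i, te, v_branch[i], 0.0,
                                branch_lateral[cells_i], f"B{i + 1}", lb)
        missed = counts == 0
        if np.any(missed):
            k_pause = np.ceil(te[missed] * fps - 1e-12).astype(np.int64)
            frames_list.append(k_pause)
            cells_list.append(cells_i[missed])
            chan_list.append(np.full(int(missed.sum()), f"B{i + 1}", dtype=object))
            axial_list.append(np.full(int(missed.sum()), float(lb)))
            lat_list.append(branch_lateral[cells_i][missed])

    frames = np.concatenate(frames_list) if frames_list else np.empty(0, np.int64)
    table = pd.DataFrame({
        "set": np.full(frames.size, set_id, dtype=np.int64),
        "frame": frames,
        "time": frames / fps,
        "cell": np.concatenate(cells_list) if cells_list else np.empty(0, np.int64),
        "channel": np.concatenate(chan_list) if chan_list else np.empty(0, object),
        "axial_um": np.concatenate(axial_list) if axial_list else np.empty(0),
        "lateral": np.concatenate(lat_list) if lat_list else np.empty(0),
    })
    table.sort_values(["frame", "cell"], inplace=True, kind="stable", ignore_index=True)

    observable = (entry_time >= 0.0) & (entry_time <= t_last)
    branch_counts = np.bincount(cell_branch[observable], minlength=n_b)
    truth = GroundTruth(
        configured_hematocrit=config.target_parent_hematocrit,
        flow_fractions=ratios.copy(),
        exit_probabilities=junction_exit_probabilities(geometry, solution, config),
        n_cells_injected=n_cells,
        branch_counts=branch_counts,
        cell_branch=cell_branch,
        cell_entry_time=entry_time,
    )
    return table, truth


# -- delimited-text IO ------------------------------------------------------

def write_detections(table: pd.DataFrame, path) -> None:
    """Write a detection table as CSV with the documented fixed header."""
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise SimulationError(f"detection table missing columns {missing}")
    table.loc[:, DETECTION_COLUMNS].to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    """Read a detection table written by :func:`write_detections`."""
    table = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise SimulationError(f"{path}: missing columns {missing}")
    return table.astype({"set": np.int64, "frame": np.int64, "cell": np.int64})
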