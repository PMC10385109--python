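"""Estimators for RBC partitioning from frame-based detection tables.

Quantities measured by the original experiments and recomputed here from a
detection table:

* tube hematocrit ``H = N_bar * V_RBC / V_ROI`` — the frame-averaged count
  of cells inside a region of interest (ROI), converted to a volume
  fraction with the single-cell volume;
* fractional RBC flux ``F_i / F_P`` — the share of branch-transiting cells
  that passed through bifurcating channel ``B_i``;
* cross-sectional distributions — histograms of the width-normalized
  lateral position in a thin axial slab;
* replicate aggregation — mean and sample SD over acquisition sets.

Tube hematocrit is an occupancy (volume-fraction) quantity; under non-plug
velocity profiles it differs from the flux-weighted discharge hematocrit,
so the two must not be conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryError, LadderGeometry
from .synthetic_data import RBC_VOLUME_UM3

__all__ = [
    "EstimationError",
    "RegionOfInterest",
    "HematocritEstimate",
    "FluxEstimate",
    "CrossSectionProfile",
    "ReplicateSummary",
    "default_roi",
    "tube_hematocrit",
    "fractional_rbc_flux",
    "cross_section_profile",
    "aggregate_replicates",
]


class EstimationError(ValueError):
    """Raised for undefined estimates (empty ROI volume, zero flux, ...)."""


@dataclass(frozen=True)
class RegionOfInterest:
    """Axial slab of one channel used for occupancy counting.

    The axial interval is half-open ``[axial_start, axial_stop)`` in the
    channel-local coordinate (um); width and height are the full channel
    cross-section (um).
    """

    channel: str
    axial_start: float
    axial_stop: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not self.axial_stop > self.axial_start:
            raise EstimationError("ROI axial interval must have positive length")
        if not (self.width > 0 and self.height > 0):
            raise EstimationError("ROI cross-section must be positive")

    @property
    def volume(self) -> float:
        """ROI volume in um^3."""
        return (self.axial_stop - self.axial_start) * self.width * self.height


def default_roi(geometry: LadderGeometry, channel: str,
                axial_span: float = 100.0) -> RegionOfInterest:
    """Packaged default ROI: full cross-section, axial span up to 100 um.

    For the parent channel the ROI sits on the observed lead-in upstream of
    the first junction; for a bifurcating channel it starts at the branch
    entrance and is clipped to the branch length, which keeps the
    branch-outlet boundary (axial == L_B) outside the half-open interval.
    """
    if channel == "P":
        return RegionOfInterest("P", 0.0, axial_span,
                                geometry.parent_width, geometry.height)
    if channel.startswith("B"):
        try:
            i = int(channel[1:])
        except ValueError:
            raise GeometryError(f"unknown channel {channel!r}") from None
        if not 1 <= i <= geometry.n_branches:
            raise GeometryError(f"channel {channel!r} outside B1..B{geometry.n_branches}")
        stop = min(axial_span, geometry.branch_length)
        return RegionOfInterest(channel, 0.0, stop,
                                geometry.branch_width, geometry.height)
    raise GeometryError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class HematocritEstimate:
    """Tube hematocrit of one channel; ``per_set`` holds replicate values."""

    channel: str
    hematocrit: float
    per_set: np.ndarray
    sd: float
    n_frames: int
    normalized: float | None = None


@dataclass(frozen=True)
class FluxEstimate:
    """Per-branch transit counts and fractional RBC flux."""

    branches: tuple[str, ...]
    counts: np.ndarray            # pooled over sets, per branch
    total: int                    # F_P
    fractions: np.ndarray         # F_i / F_P, pooled
    per_set_fractions: np.ndarray  # shape (n_sets, n_branches)
    sd: np.ndarray                # SD of per-set fractions


@dataclass(frozen=True)
class CrossSectionProfile:
    """Histogram of normalized lateral positions in a thin axial slab."""

    label: str
    bin_edges: np.ndarray
    counts: np.ndarray
    frequencies: np.ndarray


@dataclass(frozen=True)
class ReplicateSummary:
    mean: np.ndarray | float
    sd: np.ndarray | float
    n: int


def _frames_per_set(detections: pd.DataFrame, n_frames: int | None) -> int:
    if n_frames is not None:
        if n_frames < 1:
            raise EstimationError("n_frames must be >= 1")
        return int(n_frames)
    if detections.empty:
        raise EstimationError("cannot infer the frame range from an empty table")
    return int(detections["frame"].max()) + 1


def tube_hematocrit(
    detections: pd.DataFrame,
    roi: RegionOfInterest,
    v_rbc: float = RBC_VOLUME_UM3,
    n_frames: int | None = None,
) -> HematocritEstimate:
    """Tube hematocrit of the ROI channel, ``H = N_bar * V_RBC / V_ROI``.

    Counts, per frame, the cells whose axial position lies in the half-open
    ROI interval, averaging over all ``n_frames`` frames of every set
    (frames with no detection count as zero).  ``n_frames`` is inferred
    from the table's largest frame index when not given; pass it explicitly
    when trailing frames may be empty.
    """
    if roi.volume <= 0:
        raise EstimationError("ROI volume must be positive")
    nf = _frames_per_set(detections, n_frames)
    sets = sorted(detections["set"].unique())
    if not sets:
        raise EstimationError("detection table has no sets")
    in_roi = detections[
        (detections["channel"] == roi.channel)
        & (detections["axial_um"] >= roi.axial_start)
        & (detections["axial_um"] < roi.axial_stop)
    ]
    per_set = []
    for s in sets:
        counts = in_roi.loc[in_roi["set"] == s, "frame"].value_counts()
        per_set.append(counts.reindex(range(nf), fill_value=0).mean())
    per_set = np.asarray(per_set, dtype=float) * v_rbc / roi.volume
    sd = float(np.std(per_set, ddof=1)) if len(per_set) > 1 else float("nan")
    return HematocritEstimate(
        channel=roi.channel,
        hematocrit=float(per_set.mean()),
        per_set=per_set,
        sd=sd,
        n_frames=nf * len(sets),
    )


def normalized_hematocrit(estimate: HematocritEstimate,
                          parent: HematocritEstimate) -> HematocritEstimate:
    """Return a copy of ``estimate`` with ``normalized = H_i / H_P`` filled in."""
    if not parent.hematocrit > 0:
        raise EstimationError("parent hematocrit is zero; normalization undefined")
    from dataclasses import replace
    return replace(estimate, normalized=estimate.hematocrit / parent.hematocrit)


def fractional_rbc_flux(
    detections: pd.DataFrame,
    window: tuple[float, float] | None = None,
    n_branches: int | None = None,
) -> FluxEstimate:
    """Fractional RBC flux ``F_i / F_P`` from branch-entry transitions.

    ``F_i`` counts distinct cells whose recorded channel first becomes
    ``B_i`` within the time window (default: the full recording).  A cell
    observed in a branch over many frames counts once; cells still inside a
    branch at the window end are counted through their entry.
    """
    branch_rows = detections[detections["channel"].str.startswith("B")]
    if n_branches is None:
        if branch_rows.empty:
            raise EstimationError("no branch detections; flux undefined")
        n_branches = max(int(c[1:]) for c in branch_rows["channel"].unique())
    labels = tuple(f"B{i}" for i in range(1, n_branches + 1))

    # first entry time of each (set, cell) into each branch
    entries = (branch_rows.groupby(["set", "cell", "channel"], sort=False)["time"]
               .min().reset_index())
    if window is not None:
        t0, t1 = window
        if not t1 > t0:
            raise EstimationError("window must have positive duration")
        entries = entries[(entries["time"] >= t0) & (entries["time"] <= t1)]

    sets = sorted(detections["set"].unique())
    per_set_counts = np.zeros((len(sets), n_branches), dtype=np.int64)
    for k, s in enumerate(sets):
        sub = entries[entries["set"] == s]
        for j, lab in enumerate(labels):
            per_set_counts[k, j] = int((sub["channel"] == lab).sum())
    counts = per_set_counts.sum(axis=0)
    total = int(counts.sum())
    if total == 0:
        raise EstimationError("no branch transits in the window; F_P = 0")
    per_set_totals = per_set_counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_set_fractions = np.where(per_set_totals > 0,
                                     per_set_counts / per_set_totals, np.nan)
    sd = (np.nanstd(per_set_fractions, axis=0, ddof=1)
          if len(sets) > 1 else np.full(n_branches, np.nan))
    return FluxEstimate(
        branches=labels,
        counts=counts,
        total=total,
        fractions=counts / total,
        per_set_fractions=per_set_fractions,
        sd=sd,
    )


def cross_section_profile(
    detections: pd.DataFrame,
    channel: str,
    axial: float,
    tolerance: float,
    n_bins: int = 10,
    label: str | None = None,
) -> CrossSectionProfile:
    """Histogram of lateral positions within ``axial +- tolerance`` of a slab.

    Bins are ``n_bins`` equal-width half-open intervals ``[a, b)`` on
    [0, 1], the final bin closed.  An empty slab yields all-zero counts.
    """
    if n_bins < 2:
        raise EstimationError("n_bins must be >= 2")
    if tolerance <= 0:
        raise EstimationError("tolerance must be > 0")
    sub = detections[
        (detections["channel"] == channel)
        & ((detections["axial_um"] - axial).abs() <= tolerance)
    ]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(sub["lateral"].to_numpy(), bins=edges)
    total = counts.sum()
    freqs = counts / total if total > 0 else np.zeros(n_bins)
    return CrossSectionProfile(
        label=label or f"{channel}@{axial:g}um",
        bin_edges=edges,
        counts=counts,
        frequencies=freqs,
    )


def aggregate_replicates(per_set_estimates: Sequence) -> ReplicateSummary:
    """Mean and sample SD (``n - 1`` denominator) across replicate sets.

    Accepts a sequence of scalars or of equal-length vectors (one entry per
    set).  With a single set the SD is undefined and returned as NaN.
    """
    if len(per_set_estimates) == 0:
        raise EstimationError("no replicate estimates to aggregate")
    arr = np.asarray(per_set_estimates, dtype=float)
    mean = arr.mean(axis=0)
    if arr.shape[0] > 1:
        sd = arr.std(axis=0, ddof=1)
    else:
        sd = np.full_like(mean, np.nan) if np.ndim(mean) else float("nan")
    squeeze = lambda v: float(v) if np.ndim(v) == 0 else v
    return ReplicateSummary(mean=squeeze(mean), sd=squeeze(sd), n=arr.shape[0])
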