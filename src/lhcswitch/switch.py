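"""Ensemble correlation machinery for the conformational switch.

Each independent simulation is reduced to mean structural and energetic
deltas against the crystal reference, the per-simulation deltas form an
ensemble of (Δstructure, ΔE) points with the crystal at the origin, and
a Pearson correlation with a least-squares trend line is fitted across
the ensemble.  A separate within-trajectory scan tests whether two
time series are synchronized frame by frame — reported per trajectory,
never pooled, since pooling manufactures correlation out of
between-simulation offsets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .structure import TimeSeries

__all__ = [
    "SwitchPoint",
    "EnsembleCorrelation",
    "SynchronizationResult",
    "series_mean",
    "delta_vs_crystal",
    "ensemble_pearson",
    "synchronization_scan",
    "build_report",
    "load_switch_points_csv",
]


@dataclass(frozen=True)
class SwitchPoint:
    """One simulation's (Δstructure, Δcoupling) point.

    ``delta_x`` is the structural delta (Å for a distance, degrees for a
    tilt angle) and ``delta_e`` the coupling delta in cm⁻¹, both taken
    against the crystal value so that the crystal itself sits at (0, 0).
    """

    sim_id: str
    delta_x: float
    delta_e: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_x) and np.isfinite(self.delta_e)):
            raise ValueError("switch-point deltas must be finite")


@dataclass(frozen=True)
class EnsembleCorrelation:
    """Pearson r and trend line over an ensemble of switch points."""

    r: float
    slope: float
    intercept: float
    n_points: int
    include_crystal_origin: bool

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r out of [-1, 1]")
        if self.n_points < 3:
            raise ValueError("a reported correlation needs >= 3 points")


@dataclass(frozen=True)
class SynchronizationResult:
    """Within-trajectory paired scatter and its Pearson r."""

    r: float
    n_frames: int
    x: np.ndarray
    y: np.ndarray


def series_mean(ts: TimeSeries, discard_fraction: float = 0.0) -> float:
    """Mean of a series after discarding the leading equilibration part.

    ``discard_fraction`` ∈ [0, 1) drops the first fraction of frames
    (floor semantics: ``discard = floor(f · n)``).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise AnalysisError("discard_fraction must be in [0, 1)")
    n = len(ts)
    start = int(discard_fraction * n)
    if start >= n:
        raise AnalysisError("series empty after discard")
    return float(np.mean(ts.values[start:]))


def delta_vs_crystal(sim_mean: float, crystal_value: float,
                     convention: str = "signed") -> float:
    """Delta of a simulation mean against the crystal reference.

    ``signed``: sim − crystal.  ``magnitude_decrease``: |crystal| − |sim|
    (positive when the simulation weakens the quantity, matching
    "decrease" phrasings regardless of the sign of the coupling).
    """
    if convention == "signed":
        return float(sim_mean - crystal_value)
    if convention == "magnitude_decrease":
        return float(abs(crystal_value) - abs(sim_mean))
    raise AnalysisError(f"unknown delta convention {convention!r}")


def ensemble_pearson(points: list[SwitchPoint],
                     include_crystal_origin: bool = True) -> EnsembleCorrelation:
    """Pearson r and least-squares line over the switch-point ensemble.

    The crystal contributes the exact (0, 0) point when
    ``include_crystal_origin`` is set (the default).  Duplicate points
    are legitimate and enter the fit with their multiplicity.
    """
    xs = [p.delta_x for p in points]
    ys = [p.delta_e for p in points]
    if include_crystal_origin:
        xs.append(0.0)
        ys.append(0.0)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(x) < 3:
        raise AnalysisError("need >= 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance in one coordinate: r undefined")
    fit = stats.linregress(x, y)
    return EnsembleCorrelation(
        r=float(fit.rvalue), slope=float(fit.slope),
        intercept=float(fit.intercept), n_points=len(x),
        include_crystal_origin=include_crystal_origin,
    )


def synchronization_scan(ts_x: TimeSeries, ts_y: TimeSeries) -> SynchronizationResult:
    """Frame-paired correlation of two time series from one trajectory."""
    if len(ts_x) != len(ts_y):
        raise AnalysisError(
            f"series lengths differ ({len(ts_x)} vs {len(ts_y)})"
        )
    if len(ts_x) < 3:
        raise AnalysisError("need >= 3 frames")
    if np.ptp(ts_x.values) == 0 or np.ptp(ts_y.values) == 0:
        raise AnalysisError("constant series: r undefined")
    r, _ = stats.pearsonr(ts_x.values, ts_y.values)
    return SynchronizationResult(
        r=float(r), n_frames=len(ts_x),
        x=ts_x.values.copy(), y=ts_y.values.copy(),
    )


def load_switch_points_csv(path: str | Path) -> list[SwitchPoint]:
    """Read an ensemble from CSV with columns sim_id, delta_x, delta_e.

    External point tables (e.g. published per-simulation deltas) are
    consumed through this path rather than re-derived.
    """
    df = pd.read_csv(path)
    required = {"sim_id", "delta_x", "delta_e"}
    missing = required - set(df.columns)
    if missing:
        raise AnalysisError(f"{path}: missing columns {sorted(missing)}")
    return [
        SwitchPoint(sim_id=str(row.sim_id), delta_x=float(row.delta_x),
                    delta_e=float(row.delta_e))
        for row in df.itertuples(index=False)
    ]


def build_report(config: dict, results: dict) -> str:
    """Assemble a deterministic machine-readable analysis report.

    ``results`` maps section name → payload (dataclasses, arrays and
    TimeSeries are serialized).  Identical inputs give byte-identical
    JSON.
    """
    if not results:
        raise AnalysisError("no analysis results to report")

    def _convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, TimeSeries):
            return {"times_ns": obj.times.tolist(), "values": obj.values.tolist(),
                    "label": obj.label}
        if isinstance(obj, (SwitchPoint, EnsembleCorrelation)):
            return asdict(obj)
        if isinstance(obj, SynchronizationResult):
            return {"r": obj.r, "n_frames": obj.n_frames,
                    "x": obj.x.tolist(), "y": obj.y.tolist()}
        if isinstance(obj, dict):
            return {str(k): _convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_convert(v) for v in obj]
        return obj

    from . import __version__

    payload = {
        "software": {"name": "lhcswitch", "version": __version__},
        "config": _convert(config),
        "results": _convert(results),
    }
    return json.dumps(payload, sort_keys=True, indent=2)
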