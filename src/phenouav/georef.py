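"""Georeferencing accuracy accounting against surveyed ground targets.

Horizontal accuracy: per-axis deltas (measured − surveyed) on independent
checkpoints, summarized as mean, SD and RMSE.  Vertical accuracy: linear
regression of target heights read off the crop surface model on their
surveyed heights.  Acceptance follows the ground-sampling-distance (GSD)
multiples customary in UAV photogrammetry: SD within 1–2 x GSD
horizontally and 2–3 x GSD vertically.

SD uses the population convention (divide by n) so the identity
``RMSE^2 = mean^2 + SD^2`` holds exactly; the sample convention is
available via ``ddof=1``.  All computation is in projected meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import ElevationGrid, sample_target_height
from .trial import GroundTarget

__all__ = [
    "AxisSummary",
    "GeorefReport",
    "horizontal_deltas",
    "vertical_accuracy",
    "check_accuracy_criteria",
]


class ValidationError(ValueError):
    pass


@dataclass
class AxisSummary:
    deltas: np.ndarray
    mean: float
    sd: float
    rmse: float


def _summarize(deltas: np.ndarray, ddof: int = 0) -> AxisSummary:
    d = np.asarray(deltas, dtype=float)
    return AxisSummary(
        deltas=d,
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=ddof)) if d.size > ddof else float("nan"),
        rmse=float(np.sqrt(np.mean(d**2))),
    )


@dataclass
class GeorefReport:
    n_targets: int = 0
    x: AxisSummary | None = None
    y: AxisSummary | None = None
    z: AxisSummary | None = None
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    rmse_z: float = float("nan")  # residual RMSE of the vertical regression
    gsd_m: float = float("nan")
    flags: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"n_targets": self.n_targets, "gsd_m": self.gsd_m, "flags": dict(self.flags)}
        for name in ("x", "y", "z"):
            ax = getattr(self, name)
            if ax is not None:
                out[name] = {"mean": ax.mean, "sd": ax.sd, "rmse": ax.rmse}
        for name in ("slope", "intercept", "r_squared", "rmse_z"):
            out[name] = getattr(self, name)
        return out


def horizontal_deltas(
    targets: list[GroundTarget], role: str = "checkpoint", ddof: int = 0
) -> GeorefReport:
    """Per-axis XY error statistics on targets of the given role.

    Deltas are measured − surveyed; checkpoints are the honest choice since
    they never entered the bundle adjustment.
    """
    sel = [
        t
        for t in targets
        if t.role == role and np.isfinite(t.measured_x) and np.isfinite(t.measured_y)
    ]
    if not sel:
        raise ValidationError(f"no targets with role {role!r} carrying measured XY")
    dx = np.array([t.measured_x - t.surveyed_x for t in sel])
    dy = np.array([t.measured_y - t.surveyed_y for t in sel])
    return GeorefReport(n_targets=len(sel), x=_summarize(dx, ddof), y=_summarize(dy, ddof))


def vertical_accuracy(
    targets: list[GroundTarget],
    csm: ElevationGrid | None = None,
    ddof: int = 0,
) -> GeorefReport:
    """Regress CSM-derived target heights on surveyed heights.

    If a CSM is passed, measured heights are (re)sampled from it at each
    target's footprint; otherwise the targets' ``measured_z`` is used.
    Convention (documented, the field reports it both ways): measured is the
    response, surveyed the regressor.  Requires >= 3 targets spanning a
    positive height range.
    """
    sel = []
    for t in targets:
        mz = t.measured_z
        if csm is not None:
            samp = sample_target_height(csm, t.surveyed_x, t.surveyed_y, footprint_m=t.side_m * 0.6)
            mz = samp.height_m
        if np.isfinite(mz) and np.isfinite(t.surveyed_z):
            sel.append((t.surveyed_z, mz))
    if len(sel) < 3:
        raise ValidationError("need >= 3 targets with surveyed and measured heights")
    surveyed = np.array([s for s, _ in sel])
    measured = np.array([m for _, m in sel])
    if np.ptp(surveyed) <= 0:
        raise ValidationError("surveyed heights span zero range; R^2 undefined")
    fit = stats.linregress(surveyed, measured)
    resid = measured - (fit.intercept + fit.slope * surveyed)
    dz = measured - surveyed
    return GeorefReport(
        n_targets=len(sel),
        z=_summarize(dz, ddof),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse_z=float(np.sqrt(np.mean(resid**2))),
    )


def check_accuracy_criteria(report: GeorefReport, gsd_m: float) -> dict[str, bool]:
    """GSD-multiple acceptance: SD <= 2xGSD per horizontal axis, <= 3xGSD
    vertically; the stricter 1x/2x thresholds are reported alongside."""
    if gsd_m <= 0:
        raise ValueError("gsd_m must be > 0")
    flags: dict[str, bool] = {}
    if report.x is not None and report.y is not None:
        flags["horizontal_pass"] = report.x.sd <= 2 * gsd_m and report.y.sd <= 2 * gsd_m
        flags["horizontal_strict"] = report.x.sd <= gsd_m and report.y.sd <= gsd_m
    if report.z is not None:
        flags["vertical_pass"] = report.z.sd <= 3 * gsd_m
        flags["vertical_strict"] = report.z.sd <= 2 * gsd_m
    report.gsd_m = gsd_m
    report.flags.update(flags)
    return flags
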