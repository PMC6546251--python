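"""Machine-checkable postulates on subcellular-process dynamics.

The model's steady states are accepted only if, at every trajectory
checkpoint, the observed dynamics match a set of postulated constraints:

* ~10% of anterograde vesicles in the neurite-shaft cytoplasm are
  microtubule-bound and moving (the rest are the membrane reservoir),
* ~10% of anterograde vesicles in the growth-cone cytoplasm fuse with the
  growth-cone membrane per minute,
* ~90% of retrograde vesicles in shaft and cell body are moving,
* the cycling-membrane rate (retrograde fusion with the TGN) is
  0.5 um^2/min,
* the growth-cone plasma membrane stays at 50 um^2,
* dynamic microtubules fill 20 um of the growing neurite,
* the shaft elongates at the specified velocity.

The moving-fraction postulates are evaluated on the dominant carrier
classes (coat-B anterograde, coat-A retrograde); the small missorted
streams are reported separately by the trajectory schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import TrajectoryRecord


def endocytosis_rate_bounds(
    gc_pm_area: float = 50.0, t_fast_min: float = 30.0, t_slow_min: float = 60.0
) -> tuple[float, float]:
    """(lower, upper) endocytosis rate, um^2/min, from complete
    growth-cone membrane internalisation within 30-60 min."""
    return gc_pm_area / t_slow_min, gc_pm_area / t_fast_min


@dataclass(frozen=True)
class PostulateSet:
    antero_moving_fraction_nsc: float = 0.10
    antero_moving_fraction_gcc: float = 0.10
    retro_moving_fraction: float = 0.90
    cycling_rate: float = 0.5  # um^2/min
    gc_pm_area: float = 50.0  # um^2
    dynamic_span: float = 20.0  # um
    rel_tol: float = 0.05
    #: optional per-postulate tolerance overrides, name -> relative tol
    tolerances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or any(t <= 0 for t in self.tolerances.values()):
            raise SchemaError("tolerances must be > 0")
        for name in (
            "antero_moving_fraction_nsc",
            "antero_moving_fraction_gcc",
            "retro_moving_fraction",
        ):
            if not (0 < getattr(self, name) < 1):
                raise SchemaError(f"{name} must lie in (0, 1)")

    def tol(self, name: str) -> float:
        return self.tolerances.get(name, self.rel_tol)


@dataclass
class ConstraintReport:
    """Per-checkpoint, per-postulate comparison plus the overall verdict."""

    table: pd.DataFrame  # checkpoint x postulate long form
    summary: pd.DataFrame  # mean/std/max deviation per postulate
    overall_pass: bool

    def failed(self) -> pd.DataFrame:
        return self.table[~self.table["passed"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        verdict = "PASS" if self.overall_pass else "FAIL"
        return f"ConstraintReport [{verdict}]\n{self.summary.to_string()}"


_REQUIRED_COLUMNS = (
    "time_min",
    "shaft_length_um",
    "antero_moving_frac_nsc",
    "gcc_fusing_frac",
    "retro_moving_frac_nsc",
    "retro_fusion_area_tgn",
    "area_gc_pm",
    "dynamic_span_um",
)


def check_constraints(
    trajectory: TrajectoryRecord,
    postulates: PostulateSet,
    target_velocity: float,
) -> ConstraintReport:
    """Validate a trajectory against the postulates at every checkpoint.

    The outgrowth velocity is measured as the least-squares slope of shaft
    length over the trailing checkpoint window (robust at steady state);
    all other postulates are instantaneous observables.  Relative
    deviations are taken against max(|target|, 1) so a zero-velocity
    target remains checkable.
    """
    frame = trajectory.frame
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trajectory missing required columns: {missing}")
    if len(frame) < 2:
        raise SchemaError("trajectory needs at least 2 checkpoints")

    t = frame["time_min"].to_numpy()
    shaft = frame["shaft_length_um"].to_numpy()
    rows = []
    for k in range(1, len(frame)):
        # trailing-window slope, um/h
        sl = np.polyfit(t[: k + 1], shaft[: k + 1], 1)[0] * 60.0
        obs = {
            "velocity_um_per_h": sl,
            "antero_moving_fraction_nsc": frame["antero_moving_frac_nsc"].iloc[k],
            "antero_moving_fraction_gcc": frame["gcc_fusing_frac"].iloc[k],
            "retro_moving_fraction": frame["retro_moving_frac_nsc"].iloc[k],
            "cycling_rate": frame["retro_fusion_area_tgn"].iloc[k],
            "gc_pm_area": frame["area_gc_pm"].iloc[k],
            "dynamic_span": frame["dynamic_span_um"].iloc[k],
        }
        targets = {
            "velocity_um_per_h": target_velocity,
            "antero_moving_fraction_nsc": postulates.antero_moving_fraction_nsc,
            "antero_moving_fraction_gcc": postulates.antero_moving_fraction_gcc,
            "retro_moving_fraction": postulates.retro_moving_fraction,
            "cycling_rate": postulates.cycling_rate,
            "gc_pm_area": postulates.gc_pm_area,
            "dynamic_span": postulates.dynamic_span,
        }
        for name, value in obs.items():
            target = targets[name]
            dev = abs(value - target) / max(abs(target), 1.0)
            tol = postulates.tol(name)
            rows.append(
                {
                    "time_min": t[k],
                    "postulate": name,
                    "observed": float(value),
                    "target": float(target),
                    "rel_deviation": float(dev),
                    "tolerance": tol,
                    "passed": bool(dev <= tol),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("postulate", sort=False)
        .agg(
            mean_observed=("observed", "mean"),
            std_observed=("observed", "std"),
            target=("target", "first"),
            max_rel_deviation=("rel_deviation", "max"),
            all_passed=("passed", "all"),
        )
        .reset_index()
    )
    return ConstraintReport(
        table=table, summary=summary, overall_pass=bool(table["passed"].all())
    )
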