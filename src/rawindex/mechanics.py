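"""Ex vivo tensile-curve analysis: ultimate tensile strength and energy loss.

Uniaxial failure curves give the ultimate tensile strength (UTS), the stress
at the first discontinuity or at the global maximum of the stress-strain
curve. Biaxial loading/unloading loops give the hysteresis energy loss, the
percentage of the area under the loading curve not returned on unloading —
a measure of tissue viscoelasticity. Aneurysm wall with UTS below 0.3 MPa is
classified as mechanically weak, a threshold drawn from testing of ruptured
aneurysm tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: UTS below this (MPa) marks low regional strength.
UTS_THRESHOLD_MPA = 0.3


@dataclass
class StressStrainCurve:
    """Loading (and optional unloading) branch of one tensile test.

    ``abscissa`` may be engineering strain (dimensionless) or stretch
    ``lambda = 1 + strain``; all analyses here are invariant to that choice.
    Stress is in MPa (first Piola-Kirchhoff for biaxial tests).
    """

    abscissa: np.ndarray
    stress: np.ndarray
    unloading_abscissa: np.ndarray | None = None
    unloading_stress: np.ndarray | None = None
    direction: str = "circumferential"
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.abscissa.shape != self.stress.shape:
            raise ValueError("abscissa and stress lengths differ")
        if not np.all(np.isfinite(self.stress)):
            raise ValueError("non-finite stress values")
        if self.unloading_abscissa is not None:
            self.unloading_abscissa = np.asarray(self.unloading_abscissa, dtype=float)
            self.unloading_stress = np.asarray(self.unloading_stress, dtype=float)

    @property
    def has_unloading(self) -> bool:
        return self.unloading_abscissa is not None

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"abscissa": self.abscissa, "stress_MPa": self.stress,
                              "branch": "loading"})]
        if self.has_unloading:
            rows.append(pd.DataFrame({"abscissa": self.unloading_abscissa,
                                      "stress_MPa": self.unloading_stress,
                                      "branch": "unloading"}))
        df = pd.concat(rows, ignore_index=True)
        df["direction"] = self.direction
        df["sample_id"] = self.sample_id
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sample_id: str | None = None) -> "StressStrainCurve":
        df = pd.read_csv(path)
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        if df.empty:
            raise ValueError(f"no samples found in {path}")
        load = df[df["branch"] == "loading"]
        unload = df[df["branch"] == "unloading"]
        return cls(
            load["abscissa"].to_numpy(), load["stress_MPa"].to_numpy(),
            unload["abscissa"].to_numpy() if len(unload) else None,
            unload["stress_MPa"].to_numpy() if len(unload) else None,
            direction=str(df["direction"].iloc[0]) if "direction" in df else "circumferential",
            sample_id=str(df["sample_id"].iloc[0]) if "sample_id" in df else "",
        )


@dataclass
class CurveAnalysis:
    """Results of analysing one tensile curve."""

    uts: float
    failure_index: int
    energy_loss: float | None = None  # percent; None without an unloading branch
    low_strength: bool = False
    sample_id: str = ""
    direction: str = ""


def uts(curve: StressStrainCurve, drop_fraction: float = 0.02) -> CurveAnalysis:
    """Ultimate tensile strength: stress at the first discontinuity, or at
    the global maximum of the loading branch.

    A discontinuity is a relative drop of at least ``drop_fraction`` below
    the running maximum; the failure sample is then the running-maximum
    sample preceding that drop.  Without a discontinuity the failure sample
    is the global maximum.  The default 2% drop tolerance absorbs load-cell
    jitter without masking real tears.
    """
    s = curve.stress
    if len(s) < 3:
        raise ValueError("curve too short (need >= 3 loading samples)")
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    run_max = np.maximum.accumulate(s)
    drops = np.nonzero(s < (1.0 - drop_fraction) * run_max)[0]
    if len(drops):
        i = int(np.argmax(s[: drops[0]]))
    else:
        i = int(np.argmax(s))
    value = float(s[i])
    return CurveAnalysis(uts=value, failure_index=i,
                         low_strength=value < UTS_THRESHOLD_MPA,
                         sample_id=curve.sample_id, direction=curve.direction)


def energy_loss(loading_abscissa: np.ndarray, loading_stress: np.ndarray,
                unloading_abscissa: np.ndarray, unloading_stress: np.ndarray,
                tol: float = 1e-9) -> float:
    """Hysteresis energy loss in percent.

    ``100 * (A_loading - A_unloading) / A_loading`` with areas by the
    trapezoidal rule over the common abscissa interval of the two branches
    (each branch sorted by abscissa first).  Invariant to expressing the
    abscissa as strain or stretch.
    """
    lx, ly = _sorted_branch(loading_abscissa, loading_stress)
    ux, uy = _sorted_branch(unloading_abscissa, unloading_stress)
    lo, hi = max(lx[0], ux[0]), min(lx[-1], ux[-1])
    if hi <= lo:
        raise ValueError("loading and unloading branches share no abscissa interval")
    a_load = _area(lx, ly, lo, hi)
    a_unload = _area(ux, uy, lo, hi)
    if a_load <= 0:
        raise ValueError("zero area under the loading curve")
    loss = 100.0 * (a_load - a_unload) / a_load
    if loss < -100.0 * tol / a_load or loss > 100.0 * (1 + tol / a_load):
        warnings.warn("unloading branch exceeds loading beyond tolerance; "
                      "energy loss clipped to [0, 100]%", stacklevel=2)
    return float(np.clip(loss, 0.0, 100.0))


def strength_class(uts_mpa: float, threshold: float = UTS_THRESHOLD_MPA) -> str:
    """'low' regional strength iff UTS < threshold (strict)."""
    if uts_mpa < 0:
        raise ValueError("UTS must be non-negative")
    return "low" if uts_mpa < threshold else "high"


def analyze_curve(curve: StressStrainCurve, drop_fraction: float = 0.02,
                  uts_threshold: float = UTS_THRESHOLD_MPA) -> CurveAnalysis:
    """Full analysis of one curve: UTS (+ strength class) and, if an
    unloading branch is present, hysteresis energy loss."""
    res = uts(curve, drop_fraction)
    res.low_strength = res.uts < uts_threshold
    if curve.has_unloading:
        # hysteresis is evaluated on the pre-failure (monotone) loading part
        stop = res.failure_index + 1
        res.energy_loss = energy_loss(curve.abscissa[:stop], curve.stress[:stop],
                                      curve.unloading_abscissa, curve.unloading_stress)
    return res


def _sorted_branch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("branch needs >= 2 (abscissa, stress) samples")
    order = np.argsort(x, kind="stable")
    return x[order], y[order]


def _area(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of the branch restricted to [lo, hi]."""
    grid = np.unique(np.concatenate([[lo, hi], x[(x > lo) & (x < hi)]]))
    return float(np.trapezoid(np.interp(grid, x, y), grid))
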