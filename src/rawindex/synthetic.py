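"""Synthetic abdominal-aortic-aneurysm inputs with analytic ground truth.

Patient inputs for the RAW pipeline — segmented lumen / outer-wall surfaces,
tracked wall motion over the cardiac cycle, and wall-shear-stress fields —
come from gated CT plus CFD and cannot be shipped. This module builds
AAA-like stand-ins on which every downstream stage has an exact oracle:

* fusiform wall and lumen as structured tubes (rings x circumferential
  nodes) with identical connectivity, separated by a prescribed thrombus
  gap ``g(z, theta)``;
* wall motion as per-ring affine radial scaling ``r -> lambda(t) r``, so the
  per-face maximum principal Green-Lagrange strain is exactly
  ``(lambda_max^2 - 1) / 2``;
* WSS magnitude proportional to ``(r_neck / r_local)^3`` — the cubic
  radius dependence of Poiseuille wall shear at fixed flow — reproducing
  the low shear observed in the dilated sac;
* tensile curves with an exponential loading law, a planted failure point
  and a planted hysteresis-area fraction.

Everything is a pure, seeded function of its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .mesh import SurfaceMesh
from .mechanics import StressStrainCurve

#: cardiac cycle length used for synthetic phase times (s)
CYCLE_S = 1.0


def default_ilt_profile(neck_radius: float, max_radius: float, length: float,
                        peak_mm: float = 8.0, eccentricity: float = 0.5) -> Callable:
    """Thrombus gap concentrated in the sac, biased toward the anterior
    (-y) wall: ``peak * sin^2(pi z / L) * (1 + ecc*sin(theta)) / (1+ecc)``.

    The 8 mm default peak, averaged over the patched surface, lands near
    the 4-5 mm regional means typical of resected AAAs.
    """

    def profile(z: np.ndarray, theta: np.ndarray) -> np.ndarray:
        axial = np.sin(np.pi * np.clip(z, 0, length) / length) ** 2
        circ = (1.0 + eccentricity * np.sin(-theta)) / (1.0 + eccentricity)
        return peak_mm * axial * circ

    return profile


@dataclass
class SyntheticAAAConfig:
    """Geometry, motion and hemodynamic parameters of a synthetic AAA.

    Defaults emulate the imaged cohort: a ~22 mm infrarenal neck dilating
    to a ~54 mm maximum diameter over an 11 cm segment, radial pulsation
    sized for a peak principal strain of ~0.03, and neck shear of ~1.5 Pa
    decaying into the sac.
    """

    neck_radius: float = 11.0       # mm
    max_radius: float = 27.0        # mm
    length: float = 110.0           # mm
    n_axial_rings: int = 49
    n_circ: int = 48
    ilt_profile: Callable | None = None   # (z_mm, theta_rad) -> gap mm
    pulsatility: float = 0.0296     # peak radial stretch - 1
    n_phases: int = 20
    wss_peak: float = 1.5           # Pa, at the neck
    node_jitter_sd: float = 0.0     # mm, optional geometric noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neck_radius <= 0 or self.max_radius < self.neck_radius:
            raise ValueError("need max_radius >= neck_radius > 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_circ < 3:
            raise ValueError("n_circ must be >= 3")
        if self.n_axial_rings < 2:
            raise ValueError("n_axial_rings must be >= 2")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.pulsatility < 0:
            raise ValueError("pulsatility must be >= 0")
        if self.ilt_profile is None:
            self.ilt_profile = default_ilt_profile(
                self.neck_radius, self.max_radius, self.length)


@dataclass
class SyntheticAAA:
    """A generated AAA with the ground-truth fields its construction implies."""

    outer_wall: SurfaceMesh
    lumen: SurfaceMesh
    phase_positions: np.ndarray      # (n_phases, n_nodes, 3) mm
    phase_times: np.ndarray          # (n_phases,) s
    wss_series: np.ndarray           # (n_phases, n_faces, 3) Pa
    truth_ilt: np.ndarray            # per outer-wall node, mm
    truth_max_principal_strain: np.ndarray  # per face, dimensionless
    truth_patch_quadrant: np.ndarray        # per face, {LA, LP, RA, RP}
    config: SyntheticAAAConfig = field(repr=False, default=None)


def _tube_faces(n_rings: int, n_circ: int) -> np.ndarray:
    """Consistent quad-split triangulation of a structured tube."""
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.asarray(faces, dtype=np.int64)


def wall_radius(cfg: SyntheticAAAConfig, z: np.ndarray) -> np.ndarray:
    """Fusiform outer-wall radius profile: neck -> sac -> neck."""
    return cfg.neck_radius + (cfg.max_radius - cfg.neck_radius) * np.sin(
        np.pi * np.asarray(z) / cfg.length) ** 2


def make_aaa(cfg: SyntheticAAAConfig) -> SyntheticAAA:
    """Generate the wall/lumen pair, phase motion, WSS series and truths."""
    rng = np.random.default_rng(cfg.seed)
    z = np.linspace(0.0, cfg.length, cfg.n_axial_rings)
    theta = np.linspace(0.0, 2 * np.pi, cfg.n_circ, endpoint=False)
    Z, TH = np.meshgrid(z, theta, indexing="ij")
    z_flat, th_flat = Z.ravel(), TH.ravel()

    r_wall = wall_radius(cfg, z_flat)
    gap = np.asarray(cfg.ilt_profile(z_flat, th_flat), dtype=float)
    if np.any(gap < 0):
        raise ValueError("ilt_profile must be non-negative everywhere")
    r_lumen = r_wall - gap
    if np.any(r_lumen <= 0.05 * cfg.neck_radius):
        raise ValueError("ilt_profile too thick: lumen collapses")

    def _points(r: np.ndarray) -> np.ndarray:
        return np.column_stack([r * np.cos(th_flat), r * np.sin(th_flat), z_flat])

    wall_pts = _points(r_wall)
    lumen_pts = _points(r_lumen)
    if cfg.node_jitter_sd > 0:
        wall_pts = wall_pts + rng.normal(0, cfg.node_jitter_sd, wall_pts.shape)
        lumen_pts = lumen_pts + rng.normal(0, cfg.node_jitter_sd, lumen_pts.shape)

    faces = _tube_faces(cfg.n_axial_rings, cfg.n_circ)
    wall = SurfaceMesh(wall_pts, faces)
    lumen = SurfaceMesh(lumen_pts, faces.copy())

    # raised-cosine systolic waveform; s(0) = 0 so phase 0 is the reference
    phase_times = np.arange(cfg.n_phases) * CYCLE_S / cfg.n_phases
    s = 0.5 * (1.0 - np.cos(2 * np.pi * phase_times / CYCLE_S))
    lam = 1.0 + cfg.pulsatility * s
    phase_positions = np.empty((cfg.n_phases, len(wall_pts), 3))
    for k, lk in enumerate(lam):
        phase_positions[k] = np.column_stack(
            [lk * wall_pts[:, 0], lk * wall_pts[:, 1], wall_pts[:, 2]])

    # radial scaling moves in-surface chords by at most (and circumferential
    # chords by exactly) lambda, so the peak principal stretch is lambda_max
    lam_max = float(lam.max())
    truth_strain = np.full(len(faces), 0.5 * (lam_max**2 - 1.0))

    centroids = wall.face_centroids()
    r_local = np.hypot(centroids[:, 0], centroids[:, 1])
    mag = cfg.wss_peak * (cfg.neck_radius / r_local) ** 3
    waveform = 0.25 + 0.75 * s  # diastolic floor keeps shear nonzero
    wss_series = np.zeros((cfg.n_phases, len(faces), 3))
    wss_series[:, :, 2] = waveform[:, None] * mag[None, :]

    # quadrant truth from construction angles (left = +x, anterior = -y)
    side = np.where(centroids[:, 0] >= 0, "L", "R")
    ap = np.where(centroids[:, 1] <= 0, "A", "P")
    quadrant = np.char.add(side, ap)

    wall.node_data["truth_ilt"] = gap
    wall.face_data["truth_max_principal_strain"] = truth_strain
    return SyntheticAAA(wall, lumen, phase_positions, phase_times, wss_series,
                        gap, truth_strain, quadrant, cfg)


# ---------------------------------------------------------------------------
# tensile curves


@dataclass
class SyntheticCurveConfig:
    """Exponential-law tensile curve with planted failure and hysteresis.

    Loading follows ``sigma = a (exp(b eps) - 1)``, the usual convex
    stiffening of collagenous tissue, up to the planted ``failure_stress``.
    ``failure_mode='peak'`` rounds off after the maximum; ``'discontinuity'``
    plants a sharp partial tear (relative drop ``discontinuity_drop``)
    followed by renewed stiffening, so first-tear detection is exercised
    against a later, higher global maximum.
    """

    a: float = 0.05                 # MPa
    b: float = 4.0                  # dimensionless
    failure_stress: float = 0.7     # MPa (cohort mean UTS ~0.71)
    failure_mode: str = "peak"      # 'peak' | 'discontinuity'
    hysteresis_fraction: float = 0.34  # cohort mean energy loss ~34%
    discontinuity_drop: float = 0.10
    noise_sd: float = 0.0           # MPa
    n_samples: int = 200
    direction: str = "circumferential"
    sample_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.failure_stress <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("a, b and failure_stress must be positive")
        if not 0 <= self.hysteresis_fraction < 1:
            raise ValueError("hysteresis_fraction must be in [0, 1)")
        if self.failure_mode not in ("peak", "discontinuity"):
            raise ValueError(f"unknown failure_mode {self.failure_mode!r}")
        if not 0 < self.discontinuity_drop < 1:
            raise ValueError("discontinuity_drop must be in (0, 1)")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")


def make_curve(cfg: SyntheticCurveConfig) -> StressStrainCurve:
    """Generate one loading/unloading curve pair with known UTS and
    hysteresis-area fraction (exact on the emitted samples at zero noise)."""
    rng = np.random.default_rng(cfg.seed)
    eps_f = np.log1p(cfg.failure_stress / cfg.a) / cfg.b
    eps = np.linspace(0.0, eps_f, cfg.n_samples)
    sigma = cfg.a * np.expm1(cfg.b * eps)
    sigma[-1] = cfg.failure_stress  # exact by construction

    if cfg.failure_mode == "discontinuity":
        # tear: drop, then re-stiffen past the old maximum
        n_tail = cfg.n_samples // 4
        eps_tail = eps_f + np.linspace(eps_f / cfg.n_samples, 0.5 * eps_f, n_tail)
        drop_to = (1.0 - cfg.discontinuity_drop) * cfg.failure_stress
        sigma_tail = drop_to + (1.3 * cfg.failure_stress - drop_to) * np.linspace(
            0.0, 1.0, n_tail)
        eps_all = np.concatenate([eps, eps_tail])
        sigma_all = np.concatenate([sigma, sigma_tail])
    else:
        # rounded post-peak tail dropping well below the peak
        n_tail = cfg.n_samples // 8
        eps_tail = eps_f + np.linspace(eps_f / cfg.n_samples, 0.2 * eps_f, n_tail)
        sigma_tail = cfg.failure_stress * (1.0 - 0.3 * np.linspace(
            1.0 / n_tail, 1.0, n_tail))
        eps_all = np.concatenate([eps, eps_tail])
        sigma_all = np.concatenate([sigma, sigma_tail])

    un_eps, un_sigma = _unloading_branch(eps, sigma, cfg.hysteresis_fraction)

    if cfg.noise_sd > 0:
        sigma_all = sigma_all + rng.normal(0, cfg.noise_sd, sigma_all.shape)
        un_sigma = un_sigma + rng.normal(0, cfg.noise_sd, un_sigma.shape)

    return StressStrainCurve(eps_all, sigma_all, un_eps, un_sigma,
                             direction=cfg.direction, sample_id=cfg.sample_id,
                             meta={"config": cfg})


def _unloading_branch(eps: np.ndarray, sigma: np.ndarray,
                      h: float) -> tuple[np.ndarray, np.ndarray]:
    """Power-law unloading through the loop tips whose trapezoidal area is
    exactly ``(1 - h)`` times the loading area on the same grid."""
    if h == 0.0:
        return eps[::-1].copy(), sigma[::-1].copy()
    a_load = float(np.trapezoid(sigma, eps))
    target = (1.0 - h) * a_load
    tip_s, tip_e = sigma[-1], eps[-1]

    def area(p: float) -> float:
        return float(np.trapezoid(tip_s * (eps / tip_e) ** p, eps))

    # area(p) decreases monotonically from tip_s*tip_e (p->0) to 0 (p->inf)
    p = brentq(lambda p: area(p) - target, 1e-9, 500.0, xtol=1e-14)
    return eps[::-1].copy(), (tip_s * (eps / tip_e) ** p)[::-1]


# ---------------------------------------------------------------------------
# cohorts with planted regional weakness


def make_cohort(n_patients: int = 9, seed: int = 0,
                uts_scale: float = 0.45, uts_noise_sd: float = 0.18,
                run_pipeline_fn=None) -> "pd.DataFrame":
    """Synthetic resected cohort: per-patch descriptors plus a planted
    ex vivo tensile strength that is genuinely lower in weak regions.

    Each patient gets its own anatomy (sac size, thrombus load, pulsation,
    neck shear drawn around the cohort defaults) and is run through the
    full descriptor pipeline. Every patch is then assigned a planted UTS:
    a log-normal strength whose median decays with the patch's normalised
    weakness (thick ILT, low TAWSS, high strain), so mechanically weak
    tissue co-locates with the hemodynamic/kinematic risk pattern but with
    realistic overlap between groups. The UTS is delivered as a full
    tensile curve and read back through the curve analyser.

    Returns one row per (patient, patch) with descriptors, RAW (combined
    patient + population categories), planted and recovered UTS, and the
    low/high strength class at 0.3 MPa.
    """
    import pandas as pd

    from .mechanics import analyze_curve, strength_class
    from .pipeline import PipelineConfig, run_pipeline
    from .raw import score_patch_table

    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        cfg = SyntheticAAAConfig(
            max_radius=float(rng.uniform(20.0, 32.0)),
            pulsatility=float(rng.uniform(0.015, 0.045)),
            wss_peak=float(rng.uniform(1.0, 2.0)),
            ilt_profile=default_ilt_profile(
                11.0, 27.0, 110.0,
                peak_mm=float(rng.uniform(4.0, 10.0)),
                eccentricity=float(rng.uniform(0.2, 0.7))),
            seed=int(rng.integers(2**31 - 1)),
        )
        aaa = make_aaa(cfg)
        run = run_pipeline_fn or run_pipeline
        res = run(PipelineConfig(synthetic=True, seed=cfg.seed, output_dir=""),
                  aaa=aaa)
        t = res.patch_table[["patch", "area_mm2", "ilt_mm", "strain",
                             "tawss_pa"]].copy()
        t.insert(0, "patient", p + 1)
        rows.append(t)
    table = pd.concat(rows, ignore_index=True)

    # normalised weakness: thick ILT, high strain, low shear
    z = table[["ilt_mm", "strain", "tawss_pa"]].apply(
        lambda c: (c - c.mean()) / c.std(ddof=0))
    weakness = (z["ilt_mm"] + z["strain"] - z["tawss_pa"]).to_numpy() / 3.0

    planted = uts_scale * np.exp(-0.8 * weakness
                                 + rng.normal(0.0, uts_noise_sd, len(table)))
    measured = np.empty(len(table))
    for i, s in enumerate(planted):
        curve = make_curve(SyntheticCurveConfig(
            failure_stress=float(s), hysteresis_fraction=0.34,
            sample_id=f"p{table['patient'][i]}-{table['patch'][i]}",
            seed=int(rng.integers(2**31 - 1))))
        measured[i] = analyze_curve(curve).uts
    table["uts_planted_mpa"] = planted
    table["uts_mpa"] = measured
    table["strength_class"] = [strength_class(u) for u in measured]
    return score_patch_table(table, patient_column="patient")
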