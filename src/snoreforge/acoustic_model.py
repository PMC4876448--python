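"""Lumped-element acoustic model of the upper airway.

The airway is a single collapsible-tube segment represented by its
electrical equivalent: pressure plays the role of voltage and volume flow
the role of current.  A series branch carries the viscous resistance of the
airflow (R_a) and the inertance of the moving air column (L_a); a shunt
branch carries the compressibility of the enclosed air (C_a), a thermal-loss
conductance (G_a), and a yielding-wall branch (R_w–L_w–C_w in series)
representing the damping, mass and stiffness of the tissue layer between
the lumen and the neck surface.

The transfer function from the vibratory source pressure to the pressure at
the shunt (the neck-surface microphone) is the voltage divider

    H(f) = Z_sh / (Z_a + Z_sh),   Z_a = R_a + j*w*L_a,
    Z_sh = 1 / (j*w*C_a + G_a + 1/Z_w),  Z_w = R_w + j*w*L_w + 1/(j*w*C_w).

In the lossless rigid-wall limit the first resonance is the quarter-wave-
like lumped value f1 = 1/(2*pi*sqrt(L_a*C_a)) = c/(2*pi*l), which depends
on airway length only — area and wall thickness drop out.

Element formulas (per tube of length l, area A, perimeter S = 2*pi*T_r,
wall thickness h):

    L_a = rho*l/A                 air-column mass
    C_a = A*l/(rho*c^2)           air compressibility
    R_a = 8*mu*l/(pi*T_r^4)       Poiseuille viscous loss
          [+ (S*l/A^2)*sqrt(w*rho*mu/2) boundary-layer term, optional]
    G_a = thermal_coeff*S*l*sqrt(w)   heat-conduction loss at the wall
    R_w = b_wall/(S*l);  L_w = rho_wall*h_eff/(S*l);  C_w = S*l/k_wall

where h_eff = (N_r^2 - T_r^2)/(2*T_r) is the equivalent thickness of the
full tissue annulus between lumen and neck surface referred to the lumen
wall (the annulus cross-section divided by the lumen circumference), so the
wall inertance accounts for all of the tissue mass that the vibrating lumen
wall must accelerate.  With this mass loading the wall branch perturbs the
first resonance by under ~1 % at cohort-mean anatomy, consistent with the
observed independence of the modeled resonance from area and thickness.

"Gain" of the model is 20*log10|H| at the subject's source pitch; "modeled
intensity" adds a Bernoulli source-scaling term -20*e*log10(A/A_ref)
(default exponent e = 2, i.e. source pressure ~ dynamic pressure ~ 1/A^2 at
fixed flow), so narrowing raises the modeled intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .anatomy import AirwayGeometry, SubjectAnatomy, derive_geometry

__all__ = [
    "PhysicalConstants",
    "ModelConfig",
    "AcousticElements",
    "TransferFunction",
    "ModelPrediction",
    "compute_elements",
    "transfer_function",
    "predict_subject",
    "sweep_length",
    "sweep_narrowing",
    "LOSSLESS",
]

#: cohort-mean anatomy used as the default operating point (cm / cm² / Hz)
MEAN_NC_CM = 41.8
MEAN_UA_XSA_CM2 = 2.6
MEAN_UA_LENGTH_CM = 9.1
MEAN_PITCH_HZ = 102.1


@dataclass(frozen=True)
class PhysicalConstants:
    """Air and tissue properties (humid air at body temperature).

    ``thermal_coeff`` lumps (gamma-1)/(rho*c^2) * sqrt(lambda/(2*c_p*rho))
    for humid body-temperature air into one coefficient so that
    G_a = thermal_coeff * S*l * sqrt(omega).
    ``b_wall``/``k_wall`` are per-unit-area tissue damping and stiffness in
    the range reported for yielding vocal-tract walls.
    """

    rho_air: float = 1.14  # kg/m^3
    c_sound: float = 354.0  # m/s
    mu_air: float = 1.86e-5  # Pa*s
    gamma: float = 1.4
    thermal_coeff: float = 8.9e-9  # m^3 * s^-0.5 / (Pa * s * m^2)
    rho_wall: float = 1000.0  # kg/m^3
    b_wall: float = 1600.0  # N*s/m^3
    k_wall: float = 3.0e5  # N/m^3

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Topology and numerical switches for the circuit model."""

    include_wall: bool = True
    include_thermal: bool = True
    include_viscous: bool = True
    boundary_layer: bool = False  # add sqrt(w)-dependent term to R_a
    source_exponent: float = 2.0  # Bernoulli exponent e in the source scaling
    f_lo_hz: float = 100.0  # resonance search band
    f_hi_hz: float = 4000.0
    grid_step_hz: float = 1.0
    refine_tol_hz: float = 0.01
    area_ref_cm2: float = MEAN_UA_XSA_CM2  # reference area of the source scaling
    default_pitch_hz: float = MEAN_PITCH_HZ


#: rigid-wall, zero-loss variant used by closed-form oracles
LOSSLESS = ModelConfig(
    include_wall=False, include_thermal=False, include_viscous=False
)


@dataclass(frozen=True)
class AcousticElements:
    """The seven circuit values at one frequency (SI acoustic units)."""

    R_a: float  # Pa*s/m^3
    L_a: float  # Pa*s^2/m^3
    C_a: float  # m^3/Pa
    G_a: float  # m^3/(Pa*s)
    R_w: float
    L_w: float
    C_w: float


@dataclass
class TransferFunction:
    """Complex response on a frequency grid plus the located first peak."""

    freqs: np.ndarray
    H: np.ndarray
    f1_hz: float

    def gain_db(self, f: float | np.ndarray) -> float | np.ndarray:
        """20*log10|H| interpolated onto ``f``."""
        mag = np.interp(f, self.freqs, np.abs(self.H))
        return 20.0 * np.log10(mag)


@dataclass(frozen=True)
class ModelPrediction:
    subject_id: str
    f1_hz: float
    gain_db_at_pitch: float
    intensity_db: float


def _annulus_thickness(geom: AirwayGeometry) -> float:
    """Equivalent wall thickness carrying the full tissue-annulus mass.

    (N_r^2 - T_r^2)/(2*T_r): the annulus cross-section divided by the lumen
    circumference, so rho_wall * h_eff is the tissue mass per unit lumen
    surface.  Strictly increasing in wall thickness h at fixed T_r.
    """
    t_r, n_r = geom.tube_radius_m, geom.neck_radius_m
    return (n_r * n_r - t_r * t_r) / (2.0 * t_r)


def compute_elements(
    geom: AirwayGeometry,
    f: float,
    constants: PhysicalConstants = PhysicalConstants(),
    config: ModelConfig = ModelConfig(),
) -> AcousticElements:
    """Evaluate the seven lumped elements for one geometry at frequency f."""
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    w = 2.0 * math.pi * f
    l, A = geom.length_m, geom.area_m2
    S, t_r, h = geom.circumference_m, geom.tube_radius_m, geom.wall_thickness_m
    c = constants.c_sound
    rho = constants.rho_air

    L_a = rho * l / A
    C_a = A * l / (rho * c * c)
    R_a = 0.0
    if config.include_viscous:
        R_a = 8.0 * constants.mu_air * l / (math.pi * t_r**4)
        if config.boundary_layer:
            R_a += (S * l / A**2) * math.sqrt(w * rho * constants.mu_air / 2.0)
    G_a = 0.0
    if config.include_thermal:
        G_a = constants.thermal_coeff * S * l * math.sqrt(w)
    R_w = constants.b_wall / (S * l)
    L_w = constants.rho_wall * _annulus_thickness(geom) / (S * l)
    C_w = S * l / constants.k_wall
    return AcousticElements(R_a=R_a, L_a=L_a, C_a=C_a, G_a=G_a, R_w=R_w, L_w=L_w, C_w=C_w)


def _response(
    geom: AirwayGeometry,
    f: np.ndarray,
    constants: PhysicalConstants,
    config: ModelConfig,
) -> np.ndarray:
    """Vectorized H(f); H(0) := 1 (open shunt at DC)."""
    f = np.asarray(f, dtype=float)
    w = 2.0 * math.pi * f
    l, A = geom.length_m, geom.area_m2
    S, t_r, h = geom.circumference_m, geom.tube_radius_m, geom.wall_thickness_m
    rho, c = constants.rho_air, constants.c_sound

    L_a = rho * l / A
    C_a = A * l / (rho * c * c)
    with np.errstate(divide="ignore", invalid="ignore"):
        R_a = np.zeros_like(f)
        if config.include_viscous:
            R_a = R_a + 8.0 * constants.mu_air * l / (math.pi * t_r**4)
            if config.boundary_layer:
                R_a = R_a + (S * l / A**2) * np.sqrt(w * rho * constants.mu_air / 2.0)
        Z_a = R_a + 1j * w * L_a
        Y_sh = 1j * w * C_a
        if config.include_thermal:
            Y_sh = Y_sh + constants.thermal_coeff * S * l * np.sqrt(w)
        if config.include_wall:
            R_w = constants.b_wall / (S * l)
            L_w = constants.rho_wall * _annulus_thickness(geom) / (S * l)
            C_w = S * l / constants.k_wall
            Z_w = R_w + 1j * w * L_w + 1.0 / (1j * w * C_w)
            Y_sh = Y_sh + 1.0 / Z_w
        # H = Z_sh/(Z_a+Z_sh) written divider-free as 1/(1 + Z_a*Y_sh)
        H = 1.0 / (1.0 + Z_a * Y_sh)
    H = np.where(f == 0.0, 1.0 + 0.0j, H)
    return H


def _golden_max(fun, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximization on [lo, hi]; ties resolve toward lo."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > tol:
        if fc >= fd:  # keep the lower-frequency bracket on ties
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def transfer_function(
    geom: AirwayGeometry,
    constants: PhysicalConstants = PhysicalConstants(),
    f_grid: np.ndarray | None = None,
    config: ModelConfig = ModelConfig(),
) -> TransferFunction:
    """Evaluate H on a grid and locate the first magnitude peak (f1).

    The peak is found by argmax of |H| on the grid restricted to the search
    band [f_lo_hz, f_hi_hz] (first index wins on exact ties), then refined
    by golden-section search in the bracketing interval to ``refine_tol_hz``.
    """
    if f_grid is None:
        f_grid = np.arange(
            config.f_lo_hz, config.f_hi_hz + config.grid_step_hz, config.grid_step_hz
        )
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(np.diff(f_grid) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    H = _response(geom, f_grid, constants, config)

    band = (f_grid >= config.f_lo_hz) & (f_grid <= config.f_hi_hz)
    if not band.any():
        band = np.ones_like(f_grid, dtype=bool)
    idx_band = np.flatnonzero(band)
    mag = np.abs(H[idx_band])
    k = idx_band[int(np.argmax(mag))]
    lo = f_grid[max(k - 1, 0)]
    hi = f_grid[min(k + 1, f_grid.size - 1)]
    if hi > lo:
        f1 = _golden_max(
            lambda x: float(np.abs(_response(geom, np.array([x]), constants, config))[0]),
            lo,
            hi,
            config.refine_tol_hz,
        )
    else:
        f1 = float(f_grid[k])
    return TransferFunction(freqs=f_grid, H=H, f1_hz=f1)


def _source_scaling_db(area_m2: float, config: ModelConfig) -> float:
    """Bernoulli source level change relative to the reference area (dB)."""
    a_ref = config.area_ref_cm2 * 1e-4
    return -20.0 * config.source_exponent * math.log10(area_m2 / a_ref)


def predict_subject(
    subject: SubjectAnatomy,
    constants: PhysicalConstants = PhysicalConstants(),
    config: ModelConfig = ModelConfig(),
    use_after_sleep: bool = False,
) -> ModelPrediction:
    """Model one subject: resonance, gain at pitch, and modeled intensity."""
    geom = derive_geometry(subject, use_after_sleep=use_after_sleep)
    tf = transfer_function(geom, constants, config=config)
    pitch = subject.pitch_hz if subject.pitch_hz is not None else config.default_pitch_hz
    gain = float(
        20.0 * np.log10(np.abs(_response(geom, np.array([pitch]), constants, config))[0])
    )
    intensity = gain + _source_scaling_db(geom.area_m2, config)
    return ModelPrediction(
        subject_id=subject.subject_id,
        f1_hz=tf.f1_hz,
        gain_db_at_pitch=gain,
        intensity_db=intensity,
    )


def sweep_length(
    l_lo_cm: float = 7.0,
    l_hi_cm: float = 12.5,
    n_points: int = 12,
    nc_cm: float = MEAN_NC_CM,
    ua_xsa_cm2: float = MEAN_UA_XSA_CM2,
    constants: PhysicalConstants = PhysicalConstants(),
    config: ModelConfig = ModelConfig(),
):
    """Sweep airway length at fixed area/neck and track the modeled F1.

    Returns ``(table, r, p)`` where the table has columns
    ``ua_length_cm`` and ``f1_hz`` and ``r`` is the Pearson correlation
    between length and F1.
    """
    import pandas as pd

    if n_points < 2 or not (l_hi_cm > l_lo_cm > 0):
        raise ValueError("need n_points >= 2 and a non-degenerate length range")
    lengths = np.linspace(l_lo_cm, l_hi_cm, n_points)
    f1s = []
    for l_cm in lengths:
        subj = SubjectAnatomy("sweep", nc=nc_cm, ua_xsa=ua_xsa_cm2, ua_length=float(l_cm))
        geom = derive_geometry(subj)
        f1s.append(transfer_function(geom, constants, config=config).f1_hz)
    f1s = np.asarray(f1s)
    r, p = stats.pearsonr(lengths, f1s)
    table = pd.DataFrame({"ua_length_cm": lengths, "f1_hz": f1s})
    return table, float(r), float(p)


def sweep_narrowing(
    baseline: SubjectAnatomy | None = None,
    narrowing_pct: np.ndarray | list[float] | None = None,
    constants: PhysicalConstants = PhysicalConstants(),
    config: ModelConfig = ModelConfig(),
):
    """Sweep percentage change in UA-XSA at fixed NC; track modeled intensity.

    ``narrowing_pct`` holds percentage area changes (negative = narrowing).
    NC stays fixed so the wall thickness h = N_r − T_r grows as the lumen
    shrinks, as in the paired before/after-sleep comparison this mirrors.
    Returns ``(table, r, p)`` with columns ``pct_delta_area``/``intensity_db``.
    """
    import pandas as pd

    if baseline is None:
        baseline = SubjectAnatomy(
            "mean",
            nc=MEAN_NC_CM,
            ua_xsa=MEAN_UA_XSA_CM2,
            ua_length=MEAN_UA_LENGTH_CM,
            pitch_hz=MEAN_PITCH_HZ,
        )
    if narrowing_pct is None:
        narrowing_pct = np.arange(0.0, -31.0, -5.0)
    narrowing_pct = np.asarray(narrowing_pct, dtype=float)
    if np.any(narrowing_pct <= -100.0) or np.any(narrowing_pct >= 100.0):
        raise ValueError("area changes must lie in (-100, 100) percent")

    # intensity relative to the baseline subject's own area
    cfg = replace(config, area_ref_cm2=baseline.ua_xsa)
    rows = []
    for pct in narrowing_pct:
        subj = SubjectAnatomy(
            baseline.subject_id,
            nc=baseline.nc,
            ua_xsa=baseline.ua_xsa * (1.0 + pct / 100.0),
            ua_length=baseline.ua_length,
            pitch_hz=baseline.pitch_hz,
        )
        pred = predict_subject(subj, constants, cfg)
        rows.append((float(pct), pred.intensity_db))
    table = pd.DataFrame(rows, columns=["pct_delta_area", "intensity_db"])
    if len(table) >= 3:
        r, p = stats.pearsonr(table["pct_delta_area"], table["intensity_db"])
    elif len(table) == 2:
        r, p = (-1.0 if table["intensity_db"].iloc[1] > table["intensity_db"].iloc[0]
                else 1.0), float("nan")
    else:
        r, p = float("nan"), float("nan")
    return table, float(r), float(p)
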