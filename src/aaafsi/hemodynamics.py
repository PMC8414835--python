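"""Reduced-order pulsatile hemodynamics for the AAA pipeline.

Covers the cuff-to-aortic blood-pressure conversion, Carreau shear-thinning
blood rheology, a generic triphasic abdominal-aortic inlet waveform, the
3-element Windkessel outlet (characteristic impedance Z, peripheral
resistance R, compliance C) with an added upstream compliance C_A
representing volume storage of the distensible aneurysm, patient-specific
tuning of R and C against the target aortic pressures, and Poiseuille-based
wall-shear-stress recovery.

Clinical units at the API (mmHg, mL/s, L/min, mm); SI in the circuit solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy.integrate import solve_ivp, trapezoid

MMHG_TO_PA = 133.322
ML_S_TO_M3_S = 1e-6
BLOOD_DENSITY = 1040.0  # kg/m^3

__all__ = [
    "BloodPressure",
    "CarreauParams",
    "InletWaveform",
    "WindkesselModel",
    "HemoSolution",
    "convert_brachial_to_aa",
    "mean_arterial_pressure",
    "carreau_viscosity",
    "characteristic_impedance",
    "initial_windkessel",
    "estimate_aaa_compliance",
    "generic_inlet_waveform",
    "inlet_centerline_velocity",
    "simulate_0d_circuit",
    "tune_windkessel",
    "poiseuille_wss",
]


class TuningError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory or []


# --------------------------------------------------------------------------- #
# blood pressure
# --------------------------------------------------------------------------- #

#: brachial-cuff-to-abdominal-aortic conversion factors (cuff overestimates
#: diastolic by 12% and underestimates systolic by 5% in AAA patients)
DIASTOLIC_FACTOR = 0.88
SYSTOLIC_FACTOR = 1.05


@dataclass(frozen=True)
class BloodPressure:
    """Brachial cuff pressures and the derived abdominal-aortic (AA) pair."""

    brachial_dia: float
    brachial_sys: float
    aa_dia: float
    aa_sys: float

    def __post_init__(self):
        if not (self.brachial_sys > self.brachial_dia and self.aa_sys > self.aa_dia):
            raise ValueError("systolic pressure must exceed diastolic pressure")


def convert_brachial_to_aa(
    brachial_dia: float,
    brachial_sys: float,
    dia_factor: float = DIASTOLIC_FACTOR,
    sys_factor: float = SYSTOLIC_FACTOR,
) -> BloodPressure:
    """Convert a brachial cuff pair (mmHg) to abdominal-aortic pressures."""
    if not (brachial_sys > brachial_dia > 0):
        raise ValueError("require systolic > diastolic > 0")
    return BloodPressure(
        brachial_dia=float(brachial_dia),
        brachial_sys=float(brachial_sys),
        aa_dia=dia_factor * brachial_dia,
        aa_sys=sys_factor * brachial_sys,
    )


def mean_arterial_pressure(dia: float, sys: float) -> float:
    """MAP = (2/3) diastolic + (1/3) systolic (mmHg)."""
    if sys < dia:
        raise ValueError("systolic below diastolic")
    return (2.0 * dia + sys) / 3.0


# --------------------------------------------------------------------------- #
# rheology
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CarreauParams:
    """Carreau blood parameters: eta(g) = eta_inf + (eta0 - eta_inf)
    (1 + (lam g)^2)^((n-1)/2)."""

    eta0: float = 0.056  # Pa s, zero-shear viscosity
    eta_inf: float = 0.00345  # Pa s, infinite-shear viscosity
    lam: float = 3.313  # s, time constant
    n: float = 0.3568  # power index

    def __post_init__(self):
        if not (self.eta0 > self.eta_inf > 0 and self.lam > 0 and 0 < self.n < 1):
            raise ValueError("non-physical Carreau parameters")


def carreau_viscosity(shear_rate, params: CarreauParams | None = None):
    """Shear-thinning viscosity (Pa s); strictly decreasing in shear rate."""
    p = params or CarreauParams()
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    eta = p.eta_inf + (p.eta0 - p.eta_inf) * (1.0 + (p.lam * g) ** 2) ** ((p.n - 1.0) / 2.0)
    return eta if eta.shape else float(eta)


# --------------------------------------------------------------------------- #
# inlet waveform
# --------------------------------------------------------------------------- #


@dataclass
class WaveformShape:
    """Template of the triphasic infrarenal flow shape (fractions of the
    period): a systolic peak, an early-diastolic reverse-flow dip and a low
    forward diastolic baseline."""

    peak_time: float = 0.18
    peak_width: float = 0.12
    reverse_time: float = 0.47
    reverse_width: float = 0.10
    reverse_amplitude: float = 0.25  # relative to the systolic peak
    baseline: float = 0.12
    n_harmonics: int = 24


@dataclass
class InletWaveform:
    """Periodic inlet flow built from a truncated Fourier series.

    The Fourier representation makes the waveform exactly periodic and its
    analytic time average exactly ``mean_flow`` (the zeroth coefficient),
    independent of sampling.
    """

    period: float  # s
    mean_flow: float  # L/min
    shape: WaveformShape = field(default_factory=WaveformShape)
    _coeffs: np.ndarray = field(default=None, repr=False)  # complex, k = 0..K

    def __post_init__(self):
        if self._coeffs is None:
            self._coeffs = _template_coefficients(self.shape, self.mean_flow)

    def __call__(self, t) -> np.ndarray:
        """Flow in mL/s at time(s) t (s)."""
        t = np.asarray(t, dtype=float)
        u = np.atleast_1d(t) / self.period
        k = np.arange(1, len(self._coeffs))
        q = np.real(
            self._coeffs[0]
            + 2.0 * np.sum(self._coeffs[1:, None] * np.exp(2j * np.pi * k[:, None] * u[None, :]), axis=0)
        )
        return float(q[0]) if t.shape == () else q

    def samples(self, n: int = 1000) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.period, n)
        return t, self(t)

    def time_average(self, n: int = 1000) -> float:
        """Trapezoidal time average over one period, in L/min."""
        t, q = self.samples(n)
        return trapezoid(q, t) / self.period * 60.0 / 1000.0


def _template_coefficients(shape: WaveformShape, mean_flow_l_min: float) -> np.ndarray:
    """Fourier coefficients of the Gaussian-bump template, rescaled so the
    zeroth coefficient equals the requested mean flow (mL/s)."""
    n_dense = 2048
    u = np.arange(n_dense) / n_dense
    s = (
        np.exp(-(((u - shape.peak_time) / shape.peak_width) ** 2))
        - shape.reverse_amplitude * np.exp(-(((u - shape.reverse_time) / shape.reverse_width) ** 2))
        + shape.baseline
    )
    c = np.fft.rfft(s) / n_dense
    c = c[: shape.n_harmonics + 1]
    mean_target = mean_flow_l_min * 1000.0 / 60.0  # mL/s
    c *= mean_target / np.real(c[0])
    return c


def generic_inlet_waveform(
    heart_rate: float = 75.0,
    mean_flow: float = 0.96,
    shape: WaveformShape | None = None,
) -> InletWaveform:
    """Generic triphasic abdominal-aortic inlet waveform.

    ``heart_rate`` in beats/min (75 -> period 0.8 s), ``mean_flow`` in L/min
    (default 0.96); the time average equals ``mean_flow`` analytically.
    """
    if mean_flow <= 0 or heart_rate <= 0:
        raise ValueError("heart rate and mean flow must be positive")
    return InletWaveform(
        period=60.0 / heart_rate, mean_flow=float(mean_flow), shape=shape or WaveformShape()
    )


def inlet_centerline_velocity(q: float, a_in: float) -> float:
    """Poiseuille centreline velocity v_max = 2 q / (pi a^2).

    ``q`` in mL/s (mm^3/ms equivalently treated consistently), ``a_in`` in mm;
    returns mm/s (q converted to mm^3/s).
    """
    if a_in <= 0:
        raise ValueError("inlet radius must be positive")
    return 2.0 * (q * 1000.0) / (np.pi * a_in**2)


# --------------------------------------------------------------------------- #
# Windkessel
# --------------------------------------------------------------------------- #


@dataclass
class WindkesselModel:
    """3-element Windkessel with an added upstream AAA compliance C_A.

    SI units: Z, R in Pa s/m^3; C, C_A in m^3/Pa.  The inflow enters the AAA
    node, where C_A stores volume to ground, then passes Z in series to the
    R parallel C termination.
    """

    Z: float
    R: float
    C: float
    C_A: float = 0.0
    tau: float = 0.6  # s, RC time used at initialization
    rho: float = BLOOD_DENSITY

    def __post_init__(self):
        if not (self.Z > 0 and self.R > 0 and self.C > 0):
            raise ValueError("Z, R and C must be positive")
        if self.C_A < 0:
            raise ValueError("C_A must be non-negative")

    @property
    def total_resistance(self) -> float:
        return self.Z + self.R


def characteristic_impedance(
    rho: float, h: float, E: float, nu: float, a: float
) -> float:
    """Z = sqrt(rho h E / (2 pi^2 (1 - nu^2) a^5)) for minimal outlet
    reflections; SI inputs (kg/m^3, m, Pa, -, m) give Pa s/m^3."""
    if min(rho, h, E, a) <= 0 or not nu < 1.0:
        raise ValueError("all arguments must be positive with nu < 1")
    return float(np.sqrt(rho * h * E / (2.0 * np.pi**2 * (1.0 - nu**2) * a**5)))


def initial_windkessel(
    p_mean: float, q_mean: float, Z: float, tau: float = 0.6, C_A: float = 0.0
) -> WindkesselModel:
    """First Windkessel estimate: R = p_mean/q_mean - Z and C = tau/R.

    ``p_mean`` in mmHg, ``q_mean`` in mL/s, ``Z`` in Pa s/m^3.
    """
    R_T = (p_mean * MMHG_TO_PA) / (q_mean * ML_S_TO_M3_S)
    R = R_T - Z
    if R <= 0:
        raise ValueError(
            f"characteristic impedance ({Z:.3g}) exceeds total resistance ({R_T:.3g})"
        )
    return WindkesselModel(Z=Z, R=R, C=tau / R, C_A=C_A, tau=tau)


def estimate_aaa_compliance(
    V_dia: float, V_sys: float, P_dia: float, P_sys: float
) -> float:
    """AAA compliance C_A = (V_sys - V_dia)/(P_sys - P_dia).

    Volumes in mm^3 and pressures in mmHg give mm^3/mmHg; negative values are
    returned but flagged as non-physical.
    """
    if P_sys <= P_dia:
        raise ValueError("systolic pressure must exceed diastolic")
    c = (V_sys - V_dia) / (P_sys - P_dia)
    if c < 0:
        warnings.warn("negative AAA compliance (systolic volume below diastolic)", stacklevel=2)
    return float(c)


def compliance_si(c_mm3_per_mmhg: float) -> float:
    """mm^3/mmHg -> m^3/Pa."""
    return c_mm3_per_mmhg * 1e-9 / MMHG_TO_PA


def cylinder_compliance(d_max: float, length: float, G: float, h: float = 2.0) -> float:
    """Linearized volume compliance of a thin-walled incompressible cylinder.

    dV/dP = 2 pi r^3 L / (3 G h) from the Laplace hoop stress and the
    incompressible plane-strain modulus 3G.  ``d_max`` and ``h`` in mm,
    ``length`` in mm, ``G`` in MPa; returns mm^3/mmHg.
    """
    r = d_max / 2.0 * 1e-3
    c_si = 2.0 * np.pi * r**3 * (length * 1e-3) / (3.0 * G * 1e6 * h * 1e-3)
    return c_si * MMHG_TO_PA * 1e9


def fusiform_compliance(
    d_max: float, length: float, G: float, h: float = 2.0, neck_diameter: float = 20.0
) -> float:
    """Closed-form AAA compliance for a fusiform dilation profile (mm^3/mmHg).

    Integrates the local cylinder compliance 2 pi r(s)^3 / (3 G h) along the
    sac, with the radius following a Gaussian bump from ``neck_diameter`` up
    to ``d_max`` over ``length`` (mm).  The stand-in for the volumetric
    estimate when only the patient-table summary (no wall mesh) is available,
    e.g. for batch Windkessel tuning.
    """
    s = np.linspace(0.0, length, 200)
    r = (neck_diameter + (d_max - neck_diameter) * np.exp(-(((s - length / 2) / (length / 4.5)) ** 2))) / 2e3
    c_si = trapezoid(2.0 * np.pi * r**3 / (3.0 * G * 1e6 * h * 1e-3), s * 1e-3)
    return c_si * MMHG_TO_PA * 1e9


# --------------------------------------------------------------------------- #
# lumped circuit
# --------------------------------------------------------------------------- #


def simulate_0d_circuit(
    waveform: InletWaveform,
    wk: WindkesselModel,
    n_cycles: int = 10,
    n_per_cycle: int = 400,
    periodicity_tol: float = 0.1,
    require_periodic: bool = True,
):
    """Integrate the lumped circuit and return the periodic last cycle.

    Returns ``(t, p_aaa)`` with t (s) spanning one period and the AAA-node
    pressure in mmHg.  Raises if the cycle-to-cycle maximum pressure change
    still exceeds ``periodicity_tol`` mmHg after ``n_cycles``.
    """
    T = waveform.period
    q_in = lambda t: waveform(t) * ML_S_TO_M3_S  # m^3/s
    q_mean = waveform.mean_flow * 1000.0 / 60.0 * ML_S_TO_M3_S

    # start from the steady state of the mean inflow so the transient decays
    # within a few RC times
    if wk.C_A > 0:
        def rhs(t, y):
            p1, pc = y
            q_out = (p1 - pc) / wk.Z
            return [(q_in(t) - q_out) / wk.C_A, (q_out - pc / wk.R) / wk.C]
        y0 = [wk.total_resistance * q_mean, wk.R * q_mean]
    else:
        def rhs(t, y):
            (pc,) = y
            return [(q_in(t) - pc / wk.R) / wk.C]
        y0 = [wk.R * q_mean]

    t_eval = np.linspace(0.0, n_cycles * T, n_cycles * n_per_cycle + 1)
    sol = solve_ivp(
        rhs, (0.0, n_cycles * T), y0, t_eval=t_eval, method="LSODA",
        rtol=1e-7, atol=1e-9, max_step=T / 50,
    )
    if not sol.success:
        raise RuntimeError(f"circuit integration failed: {sol.message}")

    if wk.C_A > 0:
        p_aaa = sol.y[0]
    else:
        p_aaa = sol.y[0] + wk.Z * q_in(sol.t)
    p_aaa = p_aaa / MMHG_TO_PA

    last = p_aaa[-n_per_cycle - 1 :]
    prev = p_aaa[-2 * n_per_cycle - 1 : -n_per_cycle]
    dmax = float(np.max(np.abs(last - prev)))
    if require_periodic and dmax > periodicity_tol:
        raise RuntimeError(
            f"circuit not periodic after {n_cycles} cycles (max cycle-to-cycle "
            f"pressure change {dmax:.3f} mmHg)"
        )
    t_last = t_eval[-n_per_cycle - 1 :] - t_eval[-n_per_cycle - 1]
    return t_last, last


def aaa_node_impedance(wk: WindkesselModel, omega) -> np.ndarray:
    """Complex input impedance of the C_A + (Z - R||C) circuit at the AAA node."""
    omega = np.asarray(omega, dtype=float)
    z_term = wk.Z + wk.R / (1.0 + 1j * omega * wk.R * wk.C)
    return 1.0 / (1j * omega * wk.C_A + 1.0 / z_term)


def periodic_pressure(
    waveform: InletWaveform, wk: WindkesselModel, n_samples: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """Exact periodic AAA-node pressure of the linear circuit (mmHg).

    The inlet waveform is a finite Fourier series, so the periodic steady
    state follows directly from the node impedance at each harmonic; no
    transient integration is involved.
    """
    T = waveform.period
    k = np.arange(len(waveform._coeffs))
    omega = 2.0 * np.pi * k / T
    q_c = waveform._coeffs * ML_S_TO_M3_S  # m^3/s
    p_c = aaa_node_impedance(wk, omega) * q_c
    t = np.linspace(0.0, T, n_samples + 1)
    phase = np.exp(2j * np.pi * np.outer(k, t / T))
    p = np.real(p_c[0] + 2.0 * np.sum(p_c[1:, None] * phase[1:], axis=0))
    return t, p / MMHG_TO_PA


def tune_windkessel(
    waveform: InletWaveform,
    targets: BloodPressure,
    C_A: float = 0.0,
    init: WindkesselModel | None = None,
    tol_mmhg: float = 0.5,
    max_iter: int = 100,
    n_cycles: int = 12,
) -> tuple[WindkesselModel, list[dict]]:
    """Fixed-point tuning of R and C against the AA diastolic/systolic targets.

    Per iteration the total resistance is scaled by the ratio of target to
    simulated mean pressure and the compliance by the ratio of simulated to
    target pulse pressure; converged when both simulated extremes are within
    ``tol_mmhg`` of the targets.  Returns the tuned model and an iteration log.
    """
    wk = init
    if wk is None:
        q_mean = waveform.mean_flow * 1000.0 / 60.0
        p_mean = mean_arterial_pressure(targets.aa_dia, targets.aa_sys)
        z_default = 6.0e7  # Pa s/m^3, typical infrarenal characteristic impedance
        wk = initial_windkessel(p_mean, q_mean, z_default, C_A=C_A)
    else:
        wk = replace(init, C_A=C_A)

    log: list[dict] = []
    for it in range(max_iter):
        _, p = periodic_pressure(waveform, wk)
        dia, sys = float(p.min()), float(p.max())
        log.append({"iter": it, "R": wk.R, "C": wk.C, "dia": dia, "sys": sys})
        if abs(dia - targets.aa_dia) <= tol_mmhg and abs(sys - targets.aa_sys) <= tol_mmhg:
            return wk, log
        mean_t = mean_arterial_pressure(targets.aa_dia, targets.aa_sys)
        pulse_t = targets.aa_sys - targets.aa_dia
        mean_s = mean_arterial_pressure(dia, sys)
        pulse_s = max(sys - dia, 1e-6)
        R_T = wk.total_resistance * (mean_t / mean_s)
        R_new = R_T - wk.Z
        if R_new <= 0:
            raise TuningError("tuned peripheral resistance became non-positive", log)
        C_new = wk.C * (pulse_s / pulse_t)
        wk = replace(wk, R=R_new, C=C_new)
    raise TuningError(
        f"Windkessel tuning did not converge in {max_iter} iterations", log
    )


# --------------------------------------------------------------------------- #
# wall shear stress
# --------------------------------------------------------------------------- #


def poiseuille_wss(q, a, params: CarreauParams | None = None):
    """Signed Poiseuille wall shear stress (Pa) at flow q (mL/s), radius a (mm).

    Wall shear rate 4 q / (pi a^3) evaluated with the Carreau viscosity at its
    own magnitude; the sign follows the flow direction.  A reduced-order
    recovery: no secondary-flow or Womersley correction.
    """
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("radius must be positive")
    gw = 4.0 * (q * 1e-6) / (np.pi * (a * 1e-3) ** 3)  # 1/s
    tau = carreau_viscosity(np.abs(gw), params) * np.abs(gw) * np.sign(gw)
    return tau if tau.shape else float(tau)


@dataclass
class HemoSolution:
    """Pressure/flow/WSS time series on the axial lumen discretization."""

    time: np.ndarray  # (nt,) s
    pressure: np.ndarray  # (nt, nz) mmHg
    flow: np.ndarray  # (nt, nz) mL/s
    wss: np.ndarray  # (nt, nz) Pa
    radii: np.ndarray  # (nt, nz) mm
    stations: np.ndarray  # (nz,) mm arc length

    def mass_balance_error(self) -> float:
        """Max |inflow - outflow - dV/dt| over the cycle, relative to the
        cycle-mean inflow."""
        dt = np.diff(self.time)
        a = np.pi * (self.radii * 1e-3) ** 2  # m^2
        dz = np.diff(self.stations) * 1e-3
        vol = np.sum(0.5 * (a[:, 1:] + a[:, :-1]) * dz, axis=1)  # m^3
        dvdt = np.diff(vol) / dt
        qin = self.flow[1:, 0] * 1e-6
        qout = self.flow[1:, -1] * 1e-6
        resid = qin - qout - dvdt
        qbar = np.mean(np.abs(self.flow[:, 0] * 1e-6))
        return float(np.max(np.abs(resid)) / qbar)
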