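"""Wall-mechanics and hemodynamics metrics for the PSE vs no-PSE comparison.

Time-averaged wall shear stress (TAWSS) and oscillatory shear index (OSI)
per wall point, pressure scaling to the measured systolic blood pressure,
per-node spatial differences between the two study arms, percentile
summaries (99th displacement/stress/OSI, 1st TAWSS), corrected displacement
(systolic relative to diastolic instead of measured geometry), and Wilcoxon
signed-rank statistics for paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import product
import json
import math

import numpy as np
from scipy.integrate import trapezoid
from scipy import stats as sps

__all__ = [
    "WssSeries",
    "MetricReport",
    "tawss",
    "osi",
    "scale_to_measured_sbp",
    "spatial_difference",
    "percentile_extreme",
    "corrected_displacement",
    "wilcoxon_signed_rank",
    "compare_arms",
]


@dataclass
class WssSeries:
    """Signed WSS samples over one cycle: shape (nt, n_points), uniform grid."""

    values: np.ndarray
    period: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 16:
            raise ValueError("need at least 16 samples per cycle")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.linspace(0.0, self.period, self.values.shape[0])


def tawss(series: WssSeries) -> np.ndarray:
    """Time-averaged |WSS| (Pa) per point, trapezoidal rule over one cycle."""
    return trapezoid(np.abs(series.values), series.time, axis=0) / series.period


def osi(series: WssSeries):
    """Oscillatory shear index 0.5 (1 - |int WSS| / int |WSS|) in [0, 0.5].

    0 for unidirectional WSS, 0.5 for oscillating WSS with zero mean.
    Degenerate all-zero signals yield NaN (undefined) rather than a number.
    """
    num = np.abs(trapezoid(series.values, series.time, axis=0))
    den = trapezoid(np.abs(series.values), series.time, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 0.5 * (1.0 - num / den)
    out = np.where(den > 0, out, np.nan)
    return out if out.shape != (1,) else float(out[0])


def scale_to_measured_sbp(value, sbp_aa: float, sbp_fsi: float):
    """Scale a quantity by the measured-to-simulated systolic pressure ratio."""
    if sbp_fsi <= 0:
        raise ValueError("simulated systolic pressure must be positive")
    return np.asarray(value) * (sbp_aa / sbp_fsi) if np.ndim(value) else value * sbp_aa / sbp_fsi


def spatial_difference(field_nopse: np.ndarray, field_pse: np.ndarray):
    """Per-node spatial difference (%) and its mean absolute summary.

    delta_s = (phi_noPSE - phi_PSE) / mean(phi_PSE) * 100 per node;
    the summary is mean(|delta_s|).  Fields must share the mesh.
    """
    a = np.asarray(field_nopse, dtype=float)
    b = np.asarray(field_pse, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fields must be defined on identical node sets")
    mu = b.mean()
    if mu == 0:
        raise ZeroDivisionError("PSE field has zero mean; spatial difference undefined")
    delta = (a - b) / mu * 100.0
    return delta, float(np.mean(np.abs(delta)))


def percentile_extreme(field: np.ndarray, which: str) -> float:
    """p99 or p1 of a field with linear order-statistic interpolation."""
    f = np.asarray(field, dtype=float)
    if f.size == 0:
        raise ValueError("empty field")
    if which == "p99":
        q = 99.0
    elif which == "p1":
        q = 1.0
    else:
        raise ValueError("which must be 'p99' or 'p1'")
    return float(np.percentile(f, q, method="linear"))


def corrected_displacement(systolic: np.ndarray, diastolic: np.ndarray) -> np.ndarray:
    """Per-node |u_sys - u_dia| (mm): systolic motion relative to diastole."""
    s = np.asarray(systolic, dtype=float)
    d = np.asarray(diastolic, dtype=float)
    if s.shape != d.shape:
        raise ValueError("displacement fields must share the mesh")
    return np.linalg.norm(s - d, axis=-1)


def wilcoxon_signed_rank(a, b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Exact null distribution for small tie-free samples, normal approximation
    with tie/zero handling otherwise; zero differences are discarded
    (Wilcoxon's rule).  All-zero differences are degenerate and reported as
    not applicable instead of a p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if not np.any(d):
        return {"statistic": math.nan, "p": math.nan, "applicable": False,
                "significant": False}
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "applicable": True,
        "significant": bool(res.pvalue < 0.05),
    }


def wilcoxon_enumerated(a, b) -> dict:
    """Brute-force exact Wilcoxon two-sided p by enumerating all sign vectors.

    Independent oracle for small n (exponential cost); tie-free data only.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0 or n > 16:
        raise ValueError("oracle supports 1..16 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_obs = min(w_pos, n * (n + 1) / 2 - w_pos)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, n * (n + 1) / 2 - w) <= w_obs:
            count += 1
    return {"statistic": float(w_obs), "p": count / 2**n}


# --------------------------------------------------------------------------- #
# arm comparison
# --------------------------------------------------------------------------- #


@dataclass
class MetricReport:
    """Summary metrics of both FSI arms and their differences.

    Percentiles are taken over the native AAA region only (the straight
    elongations are excluded); displacement percentiles over nodes, stress
    percentiles over quadrature points, TAWSS/OSI over axial stations.
    Spatial differences follow the scaled fields; percentages are relative.
    """

    pse: dict
    nopse: dict
    differences: dict
    tests: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, **kwargs)


def node_native_mask(mesh, native_mask: np.ndarray) -> np.ndarray:
    """Per-node mask of the native AAA region on the wall lattice.

    Lattice node id = (sheet * n_rings + ring) * m + circ, so the axial ring
    of any node is (id // m) mod n_rings.
    """
    ids = np.arange(mesh.nodes.shape[0])
    ring = (ids // mesh.nodes_per_ring) % mesh.n_rings
    return native_mask[ring]


def element_native_mask(mesh, native_mask: np.ndarray) -> np.ndarray:
    """Per-element mask: an element is native if its centre node's ring is."""
    centre = mesh.hex_elements[:, 13]  # local (1,1,1)
    ring = (centre // mesh.nodes_per_ring) % mesh.n_rings
    return native_mask[ring]


def _arm_metrics(result, sbp_aa: float) -> dict:
    from .wall_fem import von_mises  # local import to avoid cycles

    mesh = result.mesh
    station_mask = result.native_mask
    nmask = node_native_mask(mesh, station_mask)
    emask = element_native_mask(mesh, station_mask)
    sbp_fsi = result.simulated_dia_sys[1]

    disp = np.linalg.norm(result.systolic_state.displacement, axis=1)[nmask]
    corr = corrected_displacement(
        result.systolic_state.displacement, result.diastolic_state.displacement
    )[nmask]
    vm = von_mises(result.systolic_state.cauchy_stress)[emask].ravel()

    series = WssSeries(result.wss[:, station_mask], float(result.time[-1] - result.time[0]))
    ta = tawss(series)
    os_ = np.atleast_1d(osi(series))

    scale = sbp_aa / sbp_fsi
    return {
        "sbp_fsi": float(sbp_fsi),
        "dbp_fsi": float(result.simulated_dia_sys[0]),
        "p99_displacement": percentile_extreme(disp, "p99") * scale,
        "p99_corrected_displacement": percentile_extreme(corr, "p99") * scale,
        "p99_von_mises_kpa": percentile_extreme(vm, "p99") * scale,
        "p1_tawss": percentile_extreme(ta * scale, "p1"),
        "p99_osi": percentile_extreme(os_, "p99"),
        "_fields": {
            "displacement": disp * scale,
            "stress": vm * scale,
            "tawss": ta * scale,
            "osi": os_,
        },
    }


def arm_metrics(result, sbp_aa: float) -> dict:
    """Percentile metrics of one FSI arm (fields scaled to the measured SBP)."""
    m = _arm_metrics(result, sbp_aa)
    m.pop("_fields")
    return m


def compare_arms(result_pse, result_nopse, sbp_aa: float) -> MetricReport:
    """Build the full PSE vs no-PSE metric report (fields scaled per arm)."""
    m_pse = _arm_metrics(result_pse, sbp_aa)
    m_nopse = _arm_metrics(result_nopse, sbp_aa)

    diffs = {}
    tests = {}
    for key in ("displacement", "stress", "tawss", "osi"):
        f_pse = m_pse["_fields"][key]
        f_nopse = m_nopse["_fields"][key]
        delta, summary = spatial_difference(f_nopse, f_pse)
        diffs[f"{key}_mean_abs_spatial_pct"] = summary
        diffs[f"{key}_mean_spatial_pct"] = float(delta.mean())
        sub = slice(None) if len(f_pse) <= 200 else slice(0, None, len(f_pse) // 200)
        tests[key] = wilcoxon_signed_rank(f_nopse[sub], f_pse[sub])

    for key, sign in (
        ("p99_displacement", 1),
        ("p99_corrected_displacement", 1),
        ("p99_von_mises_kpa", 1),
        ("p1_tawss", 1),
        ("p99_osi", 1),
    ):
        diffs[f"{key}_pct_change"] = (
            (m_nopse[key] - m_pse[key]) / m_pse[key] * 100.0 if m_pse[key] else math.nan
        )

    for m in (m_pse, m_nopse):
        m.pop("_fields")
    return MetricReport(pse=m_pse, nopse=m_nopse, differences=diffs, tests=tests)
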