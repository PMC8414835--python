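"""End-to-end pipeline: segmentation fixture -> meshes -> pre-stress ->
Windkessel tuning -> FSI arms -> metric report.

One :class:`RunConfig` fully determines a run (clinical units, explicit
seed); :func:`build_context` performs every stage up to and including the
Windkessel tuning, :func:`run_arm` executes one FSI arm, and
:func:`compare_arms_pipeline` produces the PSE vs no-PSE metric report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import geometry as geo
from . import hemodynamics as hemo
from . import metrics as met
from . import wall_fem as wall
from .fsi_coupling import CouplingConfig, FsiResult, run_fsi

__all__ = ["RunConfig", "PipelineContext", "build_context", "run_arm", "compare_arms_pipeline"]


@dataclass
class RunConfig:
    """Full configuration of one synthetic-patient FSI study."""

    schema_version: int = 1
    seed: int = 1
    # geometry
    max_diameter: float = 47.0  # mm
    neck_diameter: float = 22.0  # mm
    sac_length: float = 75.0  # mm
    asymmetry: float = 0.40
    centerline_bow: float = 15.0  # mm
    n_contours: int = 40
    noise_sd: float = 0.15  # mm
    target_edge: float = 7.0  # mm (desk-scale coarse default)
    wall_thickness: float = 2.0  # mm
    wall_layers: int = 2
    # material: group modulus by default; explicit G (MPa) overrides
    shear_modulus: float | None = None
    # pressures & flow
    brachial_dia: float = 81.0  # mmHg (cohort average)
    brachial_sys: float = 135.0  # mmHg
    heart_rate: float = 75.0  # bpm
    mean_flow: float = 0.96  # L/min
    # coupling
    dt: float = 0.004  # s
    n_cycles: int = 3
    coupling_tol: float = 1e-5
    omega: float = 0.5
    scheme: str = "iqn-ils"
    bim_increments: int = 20

    def __post_init__(self):
        for name in ("max_diameter", "neck_diameter", "sac_length", "target_edge",
                     "wall_thickness", "brachial_dia", "brachial_sys", "heart_rate",
                     "mean_flow", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in outputs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def coupling(self, prestress: bool) -> CouplingConfig:
        return CouplingConfig(
            dt=self.dt,
            n_cycles=self.n_cycles,
            tol=self.coupling_tol,
            omega=self.omega,
            prestress=prestress,
            scheme=self.scheme,
        )


@dataclass
class PipelineContext:
    """Everything shared between the two FSI arms of one study."""

    config: RunConfig
    stack: geo.ContourStack
    surface: geo.LumenSurfaceMesh
    mesh: geo.WallMesh
    group: str
    d_max: float
    material: wall.Material
    bp: hemo.BloodPressure
    waveform: hemo.InletWaveform
    prestate: wall.WallState
    fem: wall.WallFem = field(repr=False, default=None)
    windkessel: dict = field(default_factory=dict)  # per arm
    compliance: dict = field(default_factory=dict)  # per arm, mm^3/mmHg


def build_context(cfg: RunConfig) -> PipelineContext:
    """Geometry, meshes, material, pre-stress, per-arm C_A and tuned Windkessel."""
    profile = geo.AaaProfile(
        max_diameter=cfg.max_diameter,
        neck_diameter=cfg.neck_diameter,
        sac_length=cfg.sac_length,
        asymmetry=cfg.asymmetry,
        centerline_bow=cfg.centerline_bow,
        n_contours=cfg.n_contours,
        noise_sd=cfg.noise_sd,
    )
    stack = geo.generate_synthetic_aaa(profile, seed=cfg.seed)
    info = geo.max_diameter_and_group(stack)
    elongated = geo.elongate_contours(stack)
    surface = geo.build_lumen_surface(elongated, target_edge=cfg.target_edge)
    mesh = geo.extrude_wall_mesh(surface, thickness=cfg.wall_thickness, layers=cfg.wall_layers)

    if cfg.shear_modulus is not None:
        material = wall.Material(G=cfg.shear_modulus)
    else:
        material = wall.assign_shear_modulus(info["group"])

    bp = hemo.convert_brachial_to_aa(cfg.brachial_dia, cfg.brachial_sys)
    waveform = hemo.generic_inlet_waveform(cfg.heart_rate, cfg.mean_flow)

    fem = wall.WallFem(mesh, material)
    prestate = wall.bim_prestress(mesh, material, bp.aa_dia, i_max=cfg.bim_increments, fem=fem)

    ctx = PipelineContext(
        config=cfg, stack=stack, surface=surface, mesh=mesh, group=info["group"],
        d_max=info["d_max"], material=material, bp=bp, waveform=waveform,
        prestate=prestate, fem=fem,
    )
    for arm in ("pse", "nopse"):
        ca = _arm_compliance(ctx, arm)
        wk, _ = hemo.tune_windkessel(waveform, bp, C_A=hemo.compliance_si(ca))
        ctx.compliance[arm] = ca
        ctx.windkessel[arm] = wk
    return ctx


def _arm_compliance(ctx: PipelineContext, arm: str) -> float:
    """C_A from the diastolic/systolic enclosed volumes of the arm's protocol."""
    bp, mesh, surface = ctx.bp, ctx.mesh, ctx.surface
    lum = mesh.node_sets["luminal"]
    if arm == "pse":
        v_dia = geo.enclosed_lumen_volume(surface)
        st_sys = wall.solve_static_inflation(
            mesh, ctx.material, bp.aa_sys, initial=ctx.prestate, fem=ctx.fem
        )
        v_sys = geo.enclosed_lumen_volume(
            surface.with_nodes(mesh.nodes[lum] + st_sys.displacement[lum])
        )
    else:
        st_dia = wall.solve_static_inflation(mesh, ctx.material, bp.aa_dia, fem=ctx.fem)
        st_sys = wall.solve_static_inflation(
            mesh, ctx.material, bp.aa_sys, initial=st_dia, fem=ctx.fem
        )
        v_dia = geo.enclosed_lumen_volume(
            surface.with_nodes(mesh.nodes[lum] + st_dia.displacement[lum])
        )
        v_sys = geo.enclosed_lumen_volume(
            surface.with_nodes(mesh.nodes[lum] + st_sys.displacement[lum])
        )
    return hemo.estimate_aaa_compliance(v_dia, v_sys, bp.aa_dia, bp.aa_sys)


def run_arm(ctx: PipelineContext, arm: str) -> FsiResult:
    """Execute one FSI arm ('pse' or 'nopse') of the study."""
    if arm not in ("pse", "nopse"):
        raise ValueError("arm must be 'pse' or 'nopse'")
    prestress = arm == "pse"
    return run_fsi(
        ctx.mesh,
        ctx.material,
        ctx.waveform,
        ctx.windkessel[arm],
        ctx.bp.aa_dia,
        ctx.config.coupling(prestress),
        prestate=ctx.prestate if prestress else None,
        fem=ctx.fem,
    )


def compare_arms_pipeline(cfg: RunConfig):
    """Run both arms and build the metric report.

    Returns (report, context, result_pse, result_nopse).
    """
    ctx = build_context(cfg)
    res_pse = run_arm(ctx, "pse")
    res_nopse = run_arm(ctx, "nopse")
    report = met.compare_arms(res_pse, res_nopse, ctx.bp.aa_sys)
    return report, ctx, res_pse, res_nopse
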