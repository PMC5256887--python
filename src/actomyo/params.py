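"""Parameter registry and computational domain.

Internal unit system: lengths in nm, forces in pN, time in s, energies in
pN*nm.  Thermal energy at 300 K is kBT = 4.114 pN*nm.

The reference geometry is a thin 4 x 8 x 0.5 um slab, periodic along y only;
the x and z boundaries repel segments harmonically.  The reference bending
stiffness of actin is derived from the filament persistence length
(Lp = 9 um) via kappa_b = Lp * kBT / r0 for a discrete chain of 140-nm
segments.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

KBT_300K = 4.114          # pN nm
AVOGADRO = 6.02214076e23  # 1/mol
NM3_TO_LITER = 1e-24

#: persistence length of F-actin encoded by the reference bending stiffness (nm)
ACTIN_PERSISTENCE_LENGTH = 9000.0

ACTIN_SEGMENT_LENGTH = 140.0  # nm
KB_ACTIN_REF = ACTIN_PERSISTENCE_LENGTH * KBT_300K / ACTIN_SEGMENT_LENGTH


@dataclasses.dataclass
class Domain:
    """Rectangular simulation box, periodic along y, repulsive walls in x and z."""

    size_x: float = 4000.0
    size_y: float = 8000.0
    size_z: float = 500.0
    periodic_y: bool = True

    def __post_init__(self) -> None:
        if min(self.size_x, self.size_y, self.size_z) <= 0:
            raise ValueError("domain sizes must be positive")

    @property
    def size(self) -> np.ndarray:
        return np.array([self.size_x, self.size_y, self.size_z])

    @property
    def volume_nm3(self) -> float:
        return self.size_x * self.size_y * self.size_z

    @property
    def volume_liters(self) -> float:
        return self.volume_nm3 * NM3_TO_LITER

    def wrap_y(self, points: np.ndarray) -> np.ndarray:
        """Map y coordinates into [0, size_y)."""
        out = np.array(points, dtype=float, copy=True)
        if self.periodic_y:
            out[..., 1] %= self.size_y
        return out


@dataclasses.dataclass
class ParameterSet:
    """All model parameters (nm, pN, s).

    Stiffness naming: ``ks_*`` extensional (pN/nm), ``kb_*`` bending
    (pN nm/rad^2).  Motor spring indices follow the element layout: the
    backbone segments share one extensional stiffness, each arm has a
    transverse spring (rest length 13.5 nm, backbone endpoint to binding
    point) and a longitudinal spring (rest length 0) that penalizes the
    component of the arm vector along the actin axis.
    """

    # composition
    ca_uM: float = 40.0           # actin concentration
    r_motor: float = 0.08         # motor molecules per actin monomer
    r_acp: float = 0.02           # cross-linker molecules per actin monomer

    # extensional stiffnesses (pN/nm)
    ks_actin: float = 1.0
    ks_acp: float = 0.25
    ks_motor_backbone: float = 1.0
    ks_motor_trans: float = 0.25
    ks_motor_long: float = 0.25
    kr_repulsion: float = 1.63
    k_wall: float = 1.0

    # bending stiffnesses (pN nm / rad^2)
    kb_actin: float = KB_ACTIN_REF
    kb_acp: float = 26.4
    kb_motor: float = 2.0 * KB_ACTIN_REF

    # equilibrium lengths (nm) and angles (rad)
    r0_actin: float = ACTIN_SEGMENT_LENGTH
    r0_acp: float = 23.5
    r0_motor_backbone: float = 42.0
    r0_motor_trans: float = 13.5
    r0_motor_long: float = 0.0
    theta0_actin: float = 0.0
    theta0_acp: float = 0.0
    theta0_motor: float = 0.0

    # hydrodynamic diameters for the cylinder drag formula (nm)
    rc_actin: float = 7.0
    rc_acp: float = 10.0
    rc_motor: float = 10.0

    viscosity: float = 5.0e-7     # pN s / nm^2 (0.5 Pa s, effective medium)
    kBT: float = KBT_300K
    dt: float = 1.5e-5            # s

    # cross-linker (ACP) kinetics
    k_ub0_acp: float = 0.115      # 1/s, zero-force unbinding rate
    lambda_acp: float = 0.104     # nm, force sensitivity of the slip bond
    k_bind_acp: float = 30.0      # 1/s per candidate pair within capture range
    capture_acp: float = 33.5     # nm, hinge-to-site capture distance

    # motor kinetics
    k_bind_motor_per_head: float = 40.0   # 1/s per head
    n_heads: int = 8
    n_arms: int = 8
    f_stall: float = 5.7          # pN
    v_unloaded: float = 140.0     # nm/s
    step_size: float = 7.0        # nm per mechanochemical step
    k_ub0_motor: float = 0.049    # 1/s at zero load
    lambda_motor: float = 1.0     # nm, catch-bond sensitivity (resisting load)
    f_release_assist: float = 4.0 # pN, assisting load beyond which the arm lets go
    capture_motor: float = 23.5   # nm, backbone-endpoint-to-site capture distance

    # actin architecture and turnover
    site_spacing: float = 7.0     # nm between binding sites
    monomers_per_segment: int = 52
    k_turnover: float = 0.0       # 1/s, polymerization = reference depoly rate
    xi_depoly: float = 0.0        # depolymerization inhibition factor in [0, 1]
    target_filament_length: float = 1560.0  # nm, setpoint of nucleation control

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = [
            self.ks_actin, self.ks_acp, self.ks_motor_backbone,
            self.ks_motor_trans, self.ks_motor_long, self.kr_repulsion,
            self.k_wall, self.kb_actin, self.kb_acp, self.kb_motor,
            self.k_ub0_acp, self.lambda_acp, self.k_bind_acp,
            self.k_bind_motor_per_head, self.k_ub0_motor, self.k_turnover,
            self.ca_uM, self.r_motor, self.r_acp,
        ]
        if any(v < 0 for v in nonneg):
            raise ValueError("stiffnesses, rates and densities must be >= 0")
        if not (0.0 <= self.xi_depoly <= 1.0):
            raise ValueError("xi_depoly must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        positive = [
            self.r0_actin, self.r0_acp, self.r0_motor_backbone,
            self.r0_motor_trans, self.rc_actin, self.viscosity, self.kBT,
            self.site_spacing, self.step_size,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("equilibrium lengths and physical scales must be > 0")
        if self.r0_motor_long != 0.0:
            raise ValueError("longitudinal motor spring has zero rest length")

    # ---- derived quantities -------------------------------------------------

    @property
    def sites_per_segment(self) -> int:
        return int(round(self.r0_actin / self.site_spacing))

    @property
    def k_walk0(self) -> float:
        """Unloaded stepping rate (1/s): v0 / step size."""
        return self.v_unloaded / self.step_size

    @property
    def k_bind_motor(self) -> float:
        """Binding rate of one motor arm (1/s): 40 * N_h."""
        return self.k_bind_motor_per_head * self.n_heads

    @property
    def molecules_per_ensemble(self) -> int:
        """Two-headed myosin molecules represented by one ensemble."""
        return self.n_arms * self.n_heads // 2

    @property
    def segments_per_filament_target(self) -> int:
        return max(1, int(round(self.target_filament_length / self.r0_actin)))

    def monomer_budget(self, domain: Domain) -> int:
        """Total actin monomers implied by C_A and the domain volume."""
        return int(round(self.ca_uM * 1e-6 * AVOGADRO * domain.volume_liters))

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def drag_coefficient(r0: float, rc: float, mu: float) -> float:
    """Approximate drag of a cylindrical segment (length r0, diameter rc).

    zeta = 3 pi mu rc (3 + 2 r0/rc) / 5; reduces to the Stokes sphere
    3 pi mu rc at r0 = rc.
    """
    if r0 <= 0 or rc <= 0 or mu <= 0:
        raise ValueError("drag_coefficient requires positive arguments")
    return 3.0 * math.pi * mu * rc * (3.0 + 2.0 * r0 / rc) / 5.0


def zeta_actin(p: ParameterSet) -> float:
    return drag_coefficient(p.r0_actin, p.rc_actin, p.viscosity)


def zeta_acp(p: ParameterSet) -> float:
    # the hinge point carries the whole two-armed cross-linker
    return drag_coefficient(2.0 * p.r0_acp, p.rc_acp, p.viscosity)


def zeta_motor(p: ParameterSet) -> float:
    return drag_coefficient(p.r0_motor_backbone, p.rc_motor, p.viscosity)
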