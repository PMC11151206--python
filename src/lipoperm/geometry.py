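"""Liposome population geometry and cuvette mixing protocol.

The dye-release assay measures efflux from a suspension of roughly
log-normally sized unilamellar vesicles.  Everything the kinetic and
partitioning equations need — membrane volume ``V_lip``, encapsulated
aqueous volume ``V_in``, external volume ``V_out`` and total permeation
area ``A`` — follows from three ingredients: the vesicle size
distribution, the bilayer thickness, and how much lipid was pipetted
into the cuvette.

Size-distribution summaries follow aerosol/colloid convention: the
volume-weighted mean diameter ``d_v`` is the fourth-over-third moment of
the number distribution and the Sauter (surface-area mean) diameter
``d_32`` is the third-over-second moment.  For a log-normal number
distribution with median ``m`` and geometric standard deviation ``g``
these have the closed forms ``m·exp(3.5·ln²g)`` and ``m·exp(2.5·ln²g)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GeometryError",
    "LiposomePopulation",
    "MixingProtocol",
    "AssayGeometry",
    "volume_mean_diameter",
    "sauter_diameter",
    "assay_geometry",
]

#: bilayer thickness of the DPPC:DPPG:cholesterol membrane, nm
DEFAULT_MEMBRANE_THICKNESS_NM = 4.059

# unit conversions
_NM3_TO_UL = 1e-18  # 1 nm^3 = 1e-21 cm^3 = 1e-18 uL
_NM2_TO_CM2 = 1e-14
_UL_TO_CM3 = 1e-3


class GeometryError(ValueError):
    """Raised for physically impossible liposome geometry."""


@dataclass(frozen=True)
class LiposomePopulation:
    """Log-normal vesicle population plus membrane and lipid loading.

    Parameters
    ----------
    size_median : float
        Median vesicle diameter of the number distribution, nm.
    size_gsd : float
        Geometric standard deviation; 1.0 means monodisperse.
    d_mem : float
        Bilayer thickness, nm.
    lipid_conc_stock : float
        Lipid concentration of the purified stock, mg/mL.
    lipid_density : float
        Density of the lipid phase, g/mL.  Phospholipid bilayers are
        order-unity; 1.0 g/mL is the standard working value.
    """

    size_median: float = 200.0
    size_gsd: float = 1.0
    d_mem: float = DEFAULT_MEMBRANE_THICKNESS_NM
    lipid_conc_stock: float = 3.5
    lipid_density: float = 1.0

    def __post_init__(self) -> None:
        if not (self.d_mem > 0):
            raise GeometryError(f"membrane thickness must be positive, got {self.d_mem}")
        if not (self.size_median > 2 * self.d_mem):
            raise GeometryError(
                f"median diameter {self.size_median} nm must exceed twice the "
                f"membrane thickness ({2 * self.d_mem} nm)"
            )
        if not (self.size_gsd >= 1.0):
            raise GeometryError(f"geometric SD must be >= 1, got {self.size_gsd}")
        if self.lipid_conc_stock < 0:
            raise GeometryError("stock lipid concentration must be non-negative")
        if not (self.lipid_density > 0):
            raise GeometryError("lipid density must be positive")


@dataclass(frozen=True)
class MixingProtocol:
    """Volumes dispensed into the measuring cuvette, in μL.

    The default reproduces the assay protocol: 60 μL of purified
    liposome stock mixed with 1140 μL of PBS, with 5 μL of diluted
    Triton added at the end of the run.
    """

    V_stock: float = 60.0
    V_buffer: float = 1140.0
    V_triton: float = 5.0
    include_triton_volume: bool = False  # Triton volume is negligible by default

    def __post_init__(self) -> None:
        if min(self.V_stock, self.V_buffer, self.V_triton) < 0:
            raise ValueError("protocol volumes must be non-negative")
        if self.V_stock + self.V_buffer <= 0:
            raise ValueError("total dispensed volume must be positive")

    @property
    def V_total(self) -> float:
        """Total liquid volume relevant for concentrations, μL."""
        v = self.V_stock + self.V_buffer
        if self.include_triton_volume:
            v += self.V_triton
        return v


@dataclass(frozen=True)
class AssayGeometry:
    """Derived volumes and permeation area for one cuvette.

    All volumes in μL, area in cm², diameters in nm.  ``V_aq`` is the
    total aqueous volume ``V_in + V_out``; the closure
    ``V_aq + V_lip == V_total`` holds to rounding.
    """

    V_lip: float
    V_in: float
    V_out: float
    A: float
    d_v: float
    d_Sauter: float
    n_vesicles: float = field(default=0.0)

    @property
    def V_aq(self) -> float:
        return self.V_in + self.V_out

    def __post_init__(self) -> None:
        if self.V_lip > 0 and not (self.A > 0):
            raise GeometryError("permeation area must be positive when lipid is present")
        if self.d_Sauter > self.d_v * (1 + 1e-12):
            raise GeometryError("Sauter diameter cannot exceed the volume mean diameter")


def _lognormal_moment_ratio(pop: LiposomePopulation, p: int, q: int) -> float:
    """E[d^p]/E[d^q] for the log-normal number distribution.

    E[d^n] = median^n · exp(n²·ln²(gsd)/2), so the ratio is
    median^(p−q) · exp((p²−q²)·ln²(gsd)/2).
    """
    s2 = math.log(pop.size_gsd) ** 2
    return pop.size_median ** (p - q) * math.exp(0.5 * (p * p - q * q) * s2)


def volume_mean_diameter(pop: LiposomePopulation) -> float:
    """Volume-weighted mean diameter d_v = Σn d⁴ / Σn d³, in nm."""
    return _lognormal_moment_ratio(pop, 4, 3)


def sauter_diameter(pop: LiposomePopulation) -> float:
    """Surface-area mean (Sauter) diameter d_32 = Σn d³ / Σn d², in nm."""
    return _lognormal_moment_ratio(pop, 3, 2)


def assay_geometry(pop: LiposomePopulation, protocol: MixingProtocol) -> AssayGeometry:
    """Compute cuvette volumes and permeation area.

    The lipid mass pipetted in is ``lipid_conc_stock · V_stock``; dividing
    by the lipid density gives the total membrane volume ``V_lip``.  The
    vesicle count follows from the per-vesicle shell volume
    ``(π/6)[d_v³ − (d_v − 2 d_mem)³]`` evaluated at the volume-mean
    diameter, and from the count the encapsulated volume and total area.

    Raises
    ------
    GeometryError
        If the inner diameter ``d_v − 2·d_mem`` is not positive.
    """
    d_v = volume_mean_diameter(pop)
    d_s = sauter_diameter(pop)
    d_in = d_v - 2.0 * pop.d_mem
    if d_in <= 0:
        raise GeometryError(
            f"volume mean diameter {d_v:.3g} nm does not exceed twice the "
            f"membrane thickness {pop.d_mem} nm"
        )

    lipid_mass_mg = pop.lipid_conc_stock * protocol.V_stock * 1e-3  # mg/mL · μL · 1e-3
    V_lip = lipid_mass_mg / pop.lipid_density  # mg / (mg/μL) = μL

    if V_lip == 0.0:
        return AssayGeometry(
            V_lip=0.0,
            V_in=0.0,
            V_out=protocol.V_total,
            A=0.0,
            d_v=d_v,
            d_Sauter=d_s,
            n_vesicles=0.0,
        )

    shell_per_vesicle = math.pi / 6.0 * (d_v**3 - d_in**3) * _NM3_TO_UL
    count = V_lip / shell_per_vesicle
    V_in = count * math.pi / 6.0 * d_in**3 * _NM3_TO_UL
    A = count * math.pi * d_s**2 * _NM2_TO_CM2
    V_out = protocol.V_total - V_lip - V_in
    if V_out <= 0:
        raise GeometryError("lipid and encapsulated volume exceed the dispensed volume")
    return AssayGeometry(
        V_lip=V_lip, V_in=V_in, V_out=V_out, A=A, d_v=d_v, d_Sauter=d_s, n_vesicles=count
    )
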