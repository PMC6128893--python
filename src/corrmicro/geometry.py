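"""Divergent-beam holographic geometry and its parallel-beam reduction.

A point source (waveguide exit) at distance ``z1`` upstream of the sample
and a detector at ``z2`` downstream produce a cone-beam in-line hologram.
By the Fresnel scaling theorem this is equivalent to a parallel-beam
hologram recorded at the effective distance ``z_eff = z1*z2/(z1+z2)`` and
sampled at the demagnified pixel ``p_eff = p/M`` with geometric
magnification ``M = (z1+z2)/z1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# hc in keV*nm (CODATA): lambda[nm] = HC_KEV_NM / E[keV]
HC_KEV_NM = 1.239842


def wavelength_nm(photon_energy_kev: float) -> float:
    """Photon wavelength in nm from energy in keV."""
    if photon_energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_NM / photon_energy_kev


@dataclass(frozen=True)
class OpticalGeometry:
    """Cone-beam geometry with derived parallel-beam equivalents.

    Parameters
    ----------
    photon_energy : float
        Photon energy in keV.
    z1 : float
        Focus-to-sample distance in mm.
    z2 : float
        Sample-to-detector distance in mm.
    pixel_size : float
        Physical detector pixel size in um.

    Derived attributes (set in ``__post_init__``): ``wavelength`` (nm),
    ``magnification``, ``pixel_size_eff`` (nm), ``z_eff`` (mm).
    """

    photon_energy: float = 13.8
    z1: float = 10.0
    z2: float = 5000.0
    pixel_size: float = 6.5

    wavelength: float = field(init=False)
    magnification: float = field(init=False)
    pixel_size_eff: float = field(init=False)
    z_eff: float = field(init=False)

    def __post_init__(self) -> None:
        if self.z1 <= 0:
            raise ValueError("z1 must be positive")
        if self.z2 < 0:
            raise ValueError("z2 must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        lam = wavelength_nm(self.photon_energy)
        m = (self.z1 + self.z2) / self.z1
        object.__setattr__(self, "wavelength", lam)
        object.__setattr__(self, "magnification", m)
        # pixel_size is um, effective pixel reported in nm
        object.__setattr__(self, "pixel_size_eff", self.pixel_size * 1e3 / m)
        object.__setattr__(self, "z_eff", self.z1 * self.z2 / (self.z1 + self.z2))

    def to_dict(self) -> dict:
        return {
            "photon_energy_kev": self.photon_energy,
            "z1_mm": self.z1,
            "z2_mm": self.z2,
            "pixel_size_um": self.pixel_size,
            "wavelength_nm": self.wavelength,
            "magnification": self.magnification,
            "pixel_size_eff_nm": self.pixel_size_eff,
            "z_eff_mm": self.z_eff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalGeometry":
        return cls(
            photon_energy=d["photon_energy_kev"],
            z1=d["z1_mm"],
            z2=d["z2_mm"],
            pixel_size=d["pixel_size_um"],
        )


def effective_geometry(
    z1: float, z2: float, pixel_size: float = 6.5, photon_energy: float = 13.8
) -> OpticalGeometry:
    """Build an :class:`OpticalGeometry` from cone-beam distances.

    ``z1``, ``z2`` in mm, ``pixel_size`` in um, ``photon_energy`` in keV.
    """
    return OpticalGeometry(
        photon_energy=photon_energy, z1=z1, z2=z2, pixel_size=pixel_size
    )
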