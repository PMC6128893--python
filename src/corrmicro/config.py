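"""Run configuration: every pipeline parameter in one serializable object.

Instrument defaults follow the experiment the package emulates: 13.8 keV
photons, 6.5 um holography detector pixels ~5 m behind the sample, a
300 x 300 nm^2 (FWHM) focus with ~1.1e11 ph/s flux, 1 um scan steps and
a dark-field threshold of 7.5e5 ph/s.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PhantomConfig:
    n_filaments: int = 30
    orientation_spread: float = 15.0
    label_fraction: float = 0.7
    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 40.0  # nm
    main_axis: float = 30.0  # deg
    filament_width: tuple[float, float] = (100.0, 400.0)
    filament_amp: float = 0.5
    envelope_amp: float = 0.15
    nucleus_scale: float = 1.0
    nucleus_texture_amp: float = 0.25
    nucleus_texture_nm: float = 150.0
    phase_scale: float = 0.4


@dataclass
class GeometryConfig:
    photon_energy: float = 13.8  # keV
    z1: float = 125.0  # mm; sets p_eff ~ 158 nm, alias-safe at 512^2
    z2: float = 5000.0  # mm
    pixel_size: float = 6.5  # um


@dataclass
class FluorescenceConfig:
    wavelength_fl: float = 651.0  # nm, dye emission peak
    na: float = 0.95
    sted_gain: float = 3.0  # confocal FWHM / STED FWHM
    photon_budget: float = 200.0  # mean counts at brightest pixel


@dataclass
class HolographyConfig:
    photon_budget: float = 5000.0  # photons/pixel empty beam
    offset_px: tuple[int, int] = (6, -9)  # stage offset between modalities
    alpha_low: float = 1e-3
    alpha_high: float = 1e-1
    zero_border: int = 16  # px border used to fix the CTF phase offset
    support_smoothing_fwhm: float = 6.0
    support_threshold: float = 0.1
    support_dilation: int = 4
    beta: float = 0.7  # relaxed for Poisson-noisy holograms
    n_iter: int = 500


@dataclass
class ScanConfig:
    shape: tuple[int, int] = (16, 16)
    step_um: float = 1.0
    origin_um: tuple[float, float] = (2.74, 2.74)
    fwhm_y: float = 300.0  # nm
    fwhm_z: float = 300.0
    flux: float = 1.1e11  # ph/s
    exposure: float = 0.05  # s
    det_size: int = 128
    beamstop_radius: float = 20.0
    gap_width: int = 17
    background_rate: float = 10.0  # counts/pixel/s


@dataclass
class SaxsAnalysisConfig:
    darkfield_threshold: float = 7.5e5  # ph/s
    q_range: tuple[float, float] = (0.0, 0.8)  # nm^-1
    n_radial_bins: int = 64


@dataclass
class PsdConfig:
    window: str | None = "hann"
    signal_range: tuple[float, float] = (0.004, 0.018)  # nm^-1
    noise_range: tuple[float, float] = (0.05, 0.078)


@dataclass
class TracerConfig:
    smoothing: float = 1.5
    n_orientations: int = 18
    line_length: float = 15.0
    threshold: float = 0.975
    min_segment: int = 8


@dataclass
class RegistrationConfig:
    upsampling: int = 100


@dataclass
class RunConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fluorescence: FluorescenceConfig = field(default_factory=FluorescenceConfig)
    holography: HolographyConfig = field(default_factory=HolographyConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    saxs: SaxsAnalysisConfig = field(default_factory=SaxsAnalysisConfig)
    psd: PsdConfig = field(default_factory=PsdConfig)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {"seed": d.get("seed", 0)}
        for name, sub_cls in [
            ("phantom", PhantomConfig),
            ("geometry", GeometryConfig),
            ("fluorescence", FluorescenceConfig),
            ("holography", HolographyConfig),
            ("scan", ScanConfig),
            ("saxs", SaxsAnalysisConfig),
            ("psd", PsdConfig),
            ("tracer", TracerConfig),
            ("registration", RegistrationConfig),
        ]:
            sub = dict(d.get(name, {}))
            for f in dataclasses.fields(sub_cls):
                if f.name in sub and isinstance(sub[f.name], list):
                    sub[f.name] = tuple(sub[f.name])
            kwargs[name] = sub_cls(**sub)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance."""
        payload = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(x) for x in obj]
    if isinstance(obj, list):
        return [_listify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj
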