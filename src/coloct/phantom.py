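"""Synthetic helical-scan OCT phantom of a layered cylindrical colon wall.

The generator emulates the statistical structure the downstream analysis
assumes, with full ground truth:

* a four-layer wall (colonic mucosa, muscularis mucosa, submucosa,
  muscularis propria, lumen → serosa), each layer decaying with depth
  according to the Beer–Lambert law ``I = I0 · exp(−2·μA·z)`` where μA is
  the summed scattering + absorption coefficient and the factor 2 accounts
  for the round trip of the probe beam;
* a transparent protective sheath rendered as two thin bright rings;
* fully developed speckle as unit-mean multiplicative exponential noise;
* sheath-detachment gaps — angular spans where the tissue loses contact
  with the sheath and the wall surface is pushed radially outward;
* per-frame motion jitter (radial and angular) and a smooth surface
  waviness;
* an angular "crypt" reflectivity modulation of the mucosa, so en-face
  slices show a texture with known ground truth;
* a colitis effect applied to challenged mice: wall thickening and a drop
  in attenuation at the inflammation peak, recovery afterwards.

All interfaces are quantized to integer depth samples so that ground-truth
masks, boundaries and thicknesses are exactly consistent with the rendered
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import ScanGeometry
from .reconstruction import OCTVolume

__all__ = [
    "LayerSpec",
    "SheathSpec",
    "DetachmentSpec",
    "MotionJitterSpec",
    "CryptModulationSpec",
    "PhantomSpec",
    "ColitisEffect",
    "StudyDesign",
    "GroundTruth",
    "StudyRecord",
    "PhantomError",
    "default_phantom_geometry",
    "murine_colon_layers",
    "sheath_band_samples",
    "default_segmentation_params",
    "simulate_ascan",
    "simulate_volume",
    "simulate_study",
]

LAYER_NAMES = (
    "colonic_mucosa",
    "muscularis_mucosa",
    "submucosa",
    "muscularis_propria",
)

#: Extra reflectivity factor applied to the single sample at each layer's
#: top interface (specular spike on top of the diffuse backscatter level).
INTERFACE_SPIKE_GAIN = 2.0

#: Radial margin (µm) between depth sample 0 and the sheath inner wall.
PROBE_MARGIN_UM = 50.0


class PhantomError(ValueError):
    """Raised for inconsistent phantom specifications."""


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: thickness, attenuation μA = μs + μa, reflectivity."""

    name: str
    thickness_um: float
    attenuation_mm: float
    surface_reflectivity: float

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise PhantomError(f"layer {self.name}: thickness must be > 0")
        if self.attenuation_mm < 0 or self.surface_reflectivity < 0:
            raise PhantomError(f"layer {self.name}: attenuation and reflectivity must be >= 0")


@dataclass(frozen=True)
class SheathSpec:
    inner_radius_mm: float = 0.20
    outer_radius_mm: float = 0.25
    reflectivity: float = 2.0


@dataclass(frozen=True)
class DetachmentSpec:
    """Angular spans where the wall detaches from the sheath."""

    n_gaps: int = 1
    angular_width_deg: float = 25.0
    max_radial_offset_um: float = 150.0


@dataclass(frozen=True)
class MotionJitterSpec:
    """Per-frame rigid displacement scales (SD of zero-mean draws)."""

    radial_sd_um: float = 10.0
    angular_sd_deg: float = 0.5


@dataclass(frozen=True)
class CryptModulationSpec:
    """Sinusoidal angular modulation of mucosal reflectivity."""

    amplitude: float = 0.3
    angular_period_deg: float = 12.0


def murine_colon_layers() -> tuple[LayerSpec, ...]:
    """Baseline layer stack (lumen → serosa), literature-plausible murine values."""
    return (
        LayerSpec("colonic_mucosa", 200.0, 3.0, 1.0),
        LayerSpec("muscularis_mucosa", 30.0, 1.0, 0.8),
        LayerSpec("submucosa", 50.0, 2.0, 0.9),
        LayerSpec("muscularis_propria", 100.0, 1.5, 0.7),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic colon phantom.

    ``biological_cv`` is the coefficient of variation of the per-mouse,
    per-imaging-day multiplicative factors applied to layer thicknesses and
    attenuations in :func:`simulate_study`; it models between-animal and
    between-session biological variability.
    """

    layers: tuple[LayerSpec, ...] = field(default_factory=murine_colon_layers)
    lumen_radius_mm: float = 0.25
    sheath: SheathSpec = field(default_factory=SheathSpec)
    speckle_model: str = "exponential"  # "exponential" or "none"
    noise_floor: float = 1e-3
    detachment: DetachmentSpec = field(default_factory=DetachmentSpec)
    motion_jitter: MotionJitterSpec = field(default_factory=MotionJitterSpec)
    crypt_modulation: CryptModulationSpec = field(default_factory=CryptModulationSpec)
    surface_waviness_um: float = 15.0
    biological_cv: float = 0.05
    seed: int = 1234

    def __post_init__(self) -> None:
        if not self.layers:
            raise PhantomError("at least one layer required")
        if not (self.sheath.inner_radius_mm < self.sheath.outer_radius_mm <= self.lumen_radius_mm):
            raise PhantomError(
                "radii must satisfy sheath_inner < sheath_outer <= lumen_radius"
            )
        if self.speckle_model not in ("exponential", "none"):
            raise PhantomError(f"unknown speckle model {self.speckle_model!r}")
        if self.noise_floor < 0:
            raise PhantomError("noise_floor must be >= 0")


@dataclass(frozen=True)
class ColitisEffect:
    """Phenomenological colitis effect for the challenged group.

    ``day_schedule`` maps study day → (thickness multiplier, attenuation
    multiplier).  Day 0 is the pre-induction baseline and must map to
    (1, 1).  The defaults place the inflammation peak at day 9 (wall
    thickened ×1.5, attenuation reduced ×0.7) with full recovery by day 24.
    """

    day_schedule: dict = field(
        default_factory=lambda: {0: (1.0, 1.0), 9: (1.5, 0.7), 24: (1.0, 1.0)}
    )

    def __post_init__(self) -> None:
        for day, (tm, am) in self.day_schedule.items():
            if tm <= 0 or am <= 0:
                raise PhantomError(f"day {day}: multipliers must be > 0")
        if 0 in self.day_schedule and self.day_schedule[0] != (1.0, 1.0):
            raise PhantomError("day 0 multipliers must be (1, 1)")

    def multipliers(self, day: int) -> tuple[float, float]:
        return self.day_schedule.get(day, (1.0, 1.0))

    @classmethod
    def null(cls) -> "ColitisEffect":
        """No-effect schedule (all multipliers 1) for calibration studies."""
        return cls(day_schedule={0: (1.0, 1.0), 9: (1.0, 1.0), 24: (1.0, 1.0)})


@dataclass(frozen=True)
class StudyDesign:
    """Longitudinal two-group design: mice imaged repeatedly over days."""

    groups: tuple[str, ...] = ("unchallenged", "challenged")
    days: tuple[int, ...] = (0, 9, 24)
    n_per_group: int = 3
    n_locations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise PhantomError("need at least one mouse per group")
        if 0 not in self.days:
            raise PhantomError("days must include the baseline day 0")


@dataclass
class GroundTruth:
    """Exact per-voxel truth for one simulated volume.

    Boundaries are integer depth-sample indices per (B-scan, A-line);
    ``layer_boundaries[..., k]`` is the top interface of layer ``k`` and the
    last entry is the wall bottom.  ``layer_offsets`` gives the interface
    rows relative to the wall top (constant over the volume), which is the
    layer geometry in flattened coordinates.
    """

    top_boundary: np.ndarray  # (nb, na) int
    bottom_boundary: np.ndarray  # (nb, na) int
    layer_boundaries: np.ndarray  # (nb, na, n_layers + 1) int
    layer_offsets: np.ndarray  # (n_layers + 1,) int, relative to top
    true_thickness_um: np.ndarray  # (nb, na) float
    true_attenuation_mm: dict  # layer name -> μA (mm⁻¹)
    crypt_pattern: np.ndarray  # (na,) nominal angular modulation pattern

    @property
    def wall_mask(self) -> np.ndarray:
        """Binary volume, 1 exactly on [top, bottom) per A-line."""
        nb, na = self.top_boundary.shape
        nd = int(self.bottom_boundary.max()) + 1
        d = np.arange(nd)
        return (
            (d >= self.top_boundary[..., None]) & (d < self.bottom_boundary[..., None])
        ).astype(np.uint8)

    def wall_mask_for(self, n_depth_samples: int) -> np.ndarray:
        d = np.arange(n_depth_samples)
        return (
            (d >= self.top_boundary[..., None]) & (d < self.bottom_boundary[..., None])
        ).astype(np.uint8)


@dataclass
class StudyRecord:
    mouse_id: str
    group: str
    day: int
    volume: OCTVolume | None
    truth: GroundTruth


def default_phantom_geometry(
    n_bscans: int = 40,
    a_lines_per_bscan: int = 360,
    n_depth_samples: int = 256,
    pullback_length: float = 12.0,
) -> ScanGeometry:
    """A scaled-down scan geometry sized for the default phantom.

    Rates and pullback match the instrument (2400 rpm, 0.1 mm/s); the pixel
    counts are reduced so simulated studies stay light.
    """
    return ScanGeometry(
        a_line_rate=100_000.0,
        rotation_speed=2400.0,
        pullback_speed=0.1,
        pullback_length=pullback_length,
        a_lines_per_bscan=a_lines_per_bscan,
        n_bscans=n_bscans,
        axial_pixel_pitch=5.0,
        n_depth_samples=n_depth_samples,
        sheath_outer_radius=0.25,
        refractive_index=1.38,
    )


# ---------------------------------------------------------------------------
# rendering helpers


def _samples_per_um(geom: ScanGeometry) -> float:
    """Depth samples per physical µm of tissue."""
    return geom.refractive_index / geom.axial_pixel_pitch


def _radius_to_sample(radius_mm: float, spec: PhantomSpec, geom: ScanGeometry) -> float:
    """Depth-sample index of a radius; sample 0 sits PROBE_MARGIN_UM inside
    the sheath inner wall.  Placement uses the in-air pitch (the sheath gap
    is air/saline, not tissue)."""
    r0_mm = spec.sheath.inner_radius_mm - PROBE_MARGIN_UM / 1000.0
    return (radius_mm - r0_mm) * 1000.0 / geom.axial_pixel_pitch


def _layer_cum_samples(
    layers: Sequence[LayerSpec], geom: ScanGeometry
) -> np.ndarray:
    """Cumulative interface offsets in integer depth samples, top-relative."""
    t_um = np.array([l.thickness_um for l in layers])
    cum = np.concatenate([[0.0], np.cumsum(t_um)]) * _samples_per_um(geom)
    return np.round(cum).astype(int)


def _render_profiles(
    interfaces: np.ndarray,
    attns: np.ndarray,
    refls: np.ndarray,
    geom: ScanGeometry,
    mucosa_gain: np.ndarray | float = 1.0,
    spike_gain: float = INTERFACE_SPIKE_GAIN,
) -> np.ndarray:
    """Noiseless Beer–Lambert profiles for a stack of A-lines.

    ``interfaces``: (..., n_layers+1) integer sample indices; returns
    intensity array of shape (..., n_depth_samples).  Within layer k the
    profile is ``refl_k · T_k · exp(−2 μ_k (z − z_k))`` with T_k the
    two-way transmission through all layers above.
    """
    nd = geom.n_depth_samples
    d = np.arange(nd)
    pitch_mm = geom.axial_pixel_pitch / geom.refractive_index / 1000.0
    lead = interfaces.shape[:-1]
    n_layers = interfaces.shape[-1] - 1
    signal = np.zeros(lead + (nd,))
    T = np.ones(lead)
    for k in range(n_layers):
        bk = interfaces[..., k]
        bk1 = interfaces[..., k + 1]
        gain = mucosa_gain if k == 0 else 1.0
        amp = refls[k] * T * gain
        inlayer = (d >= bk[..., None]) & (d < bk1[..., None])
        decay = np.exp(-2.0 * attns[k] * (d - bk[..., None]) * pitch_mm)
        signal += np.where(inlayer, amp[..., None] * decay, 0.0)
        # specular spike at the layer's top interface
        spike_idx = np.clip(bk, 0, nd - 1)
        np.put_along_axis(
            signal,
            spike_idx[..., None],
            np.take_along_axis(signal, spike_idx[..., None], axis=-1)
            + (spike_gain - 1.0) * amp[..., None],
            axis=-1,
        )
        T = T * np.exp(-2.0 * attns[k] * (bk1 - bk) * pitch_mm)
    return signal


def sheath_band_samples(
    spec: PhantomSpec, geom: ScanGeometry, margin_px: int = 3
) -> tuple[int, int]:
    """Half-open depth-row interval occupied by the sheath rings + margin."""
    s_in = int(round(_radius_to_sample(spec.sheath.inner_radius_mm, spec, geom)))
    s_out = int(round(_radius_to_sample(spec.sheath.outer_radius_mm, spec, geom)))
    return (s_in - margin_px, s_out + 2 + margin_px)  # rings are 2 samples thick


def default_segmentation_params(spec: PhantomSpec, geom: ScanGeometry, **overrides):
    """Segmentation parameters wired to this phantom's sheath placement."""
    from .segmentation import SegmentationParams

    margin = overrides.pop("sheath_margin_px", 3)
    s_out = int(round(_radius_to_sample(spec.sheath.outer_radius_mm, spec, geom)))
    return SegmentationParams(
        sheath_margin_px=margin,
        sheath_band_px=sheath_band_samples(spec, geom, margin),
        contact_row=s_out,
        **overrides,
    )


def simulate_ascan(
    boundaries: Sequence[int],
    layer_attns: Sequence[float],
    geom: ScanGeometry,
    rng: np.random.Generator | None = None,
    reflectivities: Sequence[float] | None = None,
    noise_floor: float = 0.0,
    spike_gain: float = 1.0,
) -> np.ndarray:
    """Simulate a single A-scan intensity profile.

    ``boundaries`` are the sorted interface depth indices (wall top, each
    internal interface, wall bottom); ``layer_attns`` the μA of each layer in
    mm⁻¹.  With ``rng=None`` the noiseless mean profile is returned;
    otherwise unit-mean exponential speckle multiplies (signal + floor).
    """
    boundaries = np.asarray(boundaries, dtype=int)
    attns = np.asarray(layer_attns, dtype=float)
    if boundaries.ndim != 1 or len(boundaries) != len(attns) + 1:
        raise PhantomError("need n_layers + 1 sorted boundaries")
    if np.any(np.diff(boundaries) <= 0):
        raise PhantomError("boundaries must be strictly increasing")
    if np.any(attns < 0):
        raise PhantomError("attenuations must be >= 0")
    if reflectivities is None:
        refls = np.ones(len(attns))
    else:
        refls = np.asarray(reflectivities, dtype=float)
    profile = _render_profiles(boundaries, attns, refls, geom, spike_gain=spike_gain)
    if rng is not None:
        profile = profile * rng.standard_exponential(profile.shape)
    return profile + noise_floor


def _angular_profiles(
    spec: PhantomSpec, geom: ScanGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-(frame, A-line) top-boundary offset (samples), per-A-line crypt
    gain, and the nominal crypt pattern."""
    nb, na = geom.n_bscans, geom.a_lines_per_bscan
    theta = 2.0 * np.pi * np.arange(na) / na  # nominal angle per A-line
    spu = _samples_per_um(geom)

    # per-frame rigid motion jitter
    dr = rng.normal(0.0, spec.motion_jitter.radial_sd_um, size=nb)
    dtheta = np.deg2rad(rng.normal(0.0, spec.motion_jitter.angular_sd_deg, size=nb))
    ang = theta[None, :] + dtheta[:, None]  # (nb, na) effective angle

    # smooth surface waviness: 2 cycles per revolution, slowly drifting phase
    phase = np.linspace(0.0, np.pi / 2.0, nb)
    offset_um = spec.surface_waviness_um * np.sin(2.0 * ang + phase[:, None])
    offset_um = offset_um + dr[:, None]

    # detachment gaps: raised-cosine outward push over random angular spans
    det = spec.detachment
    if det.n_gaps > 0 and det.max_radial_offset_um > 0:
        half = np.deg2rad(det.angular_width_deg) / 2.0
        centers = rng.uniform(0.0, 2.0 * np.pi, size=det.n_gaps)
        for c in centers:
            delta = np.angle(np.exp(1j * (ang - c)))  # wrapped difference
            bump = np.where(
                np.abs(delta) < half,
                0.5 * (1.0 + np.cos(np.pi * delta / half)),
                0.0,
            )
            offset_um = offset_um + det.max_radial_offset_um * bump

    crypt = spec.crypt_modulation
    n_cycles = max(1, round(360.0 / crypt.angular_period_deg))
    pattern = np.sin(n_cycles * theta)
    gain = 1.0 + crypt.amplitude * np.sin(n_cycles * ang)
    return offset_um * spu, gain, pattern


def _realize(
    spec: PhantomSpec,
    geom: ScanGeometry,
    rng: np.random.Generator,
    thickness_multiplier: float = 1.0,
    attenuation_multiplier: float = 1.0,
    render: bool = True,
) -> tuple[OCTVolume | None, GroundTruth]:
    layers = [
        replace(l, thickness_um=l.thickness_um * thickness_multiplier,
                attenuation_mm=l.attenuation_mm * attenuation_multiplier)
        for l in spec.layers
    ]
    nb, na, nd = geom.n_bscans, geom.a_lines_per_bscan, geom.n_depth_samples

    top_offset, mucosa_gain, pattern = _angular_profiles(spec, geom, rng)
    top0 = _radius_to_sample(spec.lumen_radius_mm, spec, geom)
    top = np.round(top0 + top_offset).astype(int)
    # tissue cannot sit inside the sheath: clamp to the sheath outer surface
    s_out = int(round(_radius_to_sample(spec.sheath.outer_radius_mm, spec, geom)))
    top = np.maximum(top, s_out)
    if np.any(top < 0):
        raise PhantomError("wall top boundary above depth sample 0")
    cum = _layer_cum_samples(layers, geom)  # (n_layers + 1,)
    interfaces = top[..., None] + cum[None, None, :]
    if interfaces.max() >= nd:
        raise PhantomError(
            f"colon wall extends beyond the depth range: deepest interface at "
            f"sample {int(interfaces.max())}, but n_depth_samples = {nd}; "
            f"increase n_depth_samples or shrink the phantom"
        )

    attns = np.array([l.attenuation_mm for l in layers])
    refls = np.array([l.surface_reflectivity for l in layers])
    truth = GroundTruth(
        top_boundary=interfaces[..., 0].copy(),
        bottom_boundary=interfaces[..., -1].copy(),
        layer_boundaries=interfaces,
        layer_offsets=cum.copy(),
        true_thickness_um=(interfaces[..., -1] - interfaces[..., 0])
        / _samples_per_um(geom)
        * np.ones((nb, na)),
        true_attenuation_mm={l.name: l.attenuation_mm for l in layers},
        crypt_pattern=pattern,
    )
    if not render:
        return None, truth

    signal = _render_profiles(interfaces, attns, refls, geom, mucosa_gain=mucosa_gain)
    # sheath: two thin bright rings at the inner and outer wall
    for r_mm in (spec.sheath.inner_radius_mm, spec.sheath.outer_radius_mm):
        s = int(round(_radius_to_sample(r_mm, spec, geom)))
        for ds in (0, 1):
            if 0 <= s + ds < nd:
                signal[:, :, s + ds] += spec.sheath.reflectivity
    if spec.speckle_model == "exponential":
        signal = signal * rng.standard_exponential(signal.shape)
    signal = signal + spec.noise_floor
    vol = OCTVolume(data=signal, geom=geom, scale="linear")
    return vol, truth


def simulate_volume(
    spec: PhantomSpec,
    geom: ScanGeometry | None = None,
    rng: np.random.Generator | None = None,
    render: bool = True,
) -> tuple[OCTVolume | None, GroundTruth]:
    """Render one helical-scan volume of the phantom with its ground truth.

    A fixed ``spec.seed`` makes the output bit-reproducible; pass an
    explicit ``rng`` to override the stream (used by :func:`simulate_study`
    to split streams per mouse and day).
    """
    if geom is None:
        geom = default_phantom_geometry()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return _realize(spec, geom, rng, render=render)


def simulate_study(
    design: StudyDesign,
    spec: PhantomSpec | None = None,
    effect: ColitisEffect | None = None,
    geom: ScanGeometry | None = None,
    render: bool = True,
) -> list[StudyRecord]:
    """Simulate a longitudinal two-group colitis study.

    Challenged mice get the effect multipliers of each day's schedule;
    unchallenged mice always use baseline.  On top of the schedule, every
    mouse-day draws independent biological variation factors for thickness
    and attenuation (normal, CV = ``spec.biological_cv``), modelling
    between-animal and between-session variability.  Random streams are
    split per (group, mouse, day) with ``numpy`` spawn keys, so adding a
    mouse or day never perturbs existing draws.

    With ``render=False`` only ground truth is generated (volumes are
    ``None``) — sufficient for study-level statistical simulations where
    voxel data is not needed.
    """
    if spec is None:
        spec = PhantomSpec()
    if effect is None:
        effect = ColitisEffect()
    if geom is None:
        geom = default_phantom_geometry()
    records: list[StudyRecord] = []
    for gi, group in enumerate(design.groups):
        for mi in range(design.n_per_group):
            mouse_id = f"{group[:4]}{mi + 1}"
            for day in design.days:
                ss = np.random.SeedSequence(
                    entropy=design.seed, spawn_key=(gi, mi, int(day))
                )
                rng = np.random.default_rng(ss)
                tm, am = effect.multipliers(day) if group == "challenged" else (1.0, 1.0)
                cv = spec.biological_cv
                bio_t = max(0.1, 1.0 + cv * rng.standard_normal())
                bio_a = max(0.1, 1.0 + cv * rng.standard_normal())
                vol, truth = _realize(
                    spec,
                    geom,
                    rng,
                    thickness_multiplier=tm * bio_t,
                    attenuation_multiplier=am * bio_a,
                    render=render,
                )
                records.append(StudyRecord(mouse_id, group, day, vol, truth))
    return records
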