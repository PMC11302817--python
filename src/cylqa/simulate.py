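"""Synthetic paired dose-map generation on a cylindrical diode array.

Produces pairs of "calculated" (planning-system channel, carrying exactly one
injected delivery error) and "measured" (error-free channel with multiplicative
detector noise) dose maps on the unwrapped surface of a cylindrical diode
array.  The forward dose model is deliberately simple — divergent rectangular
apertures with Gaussian penumbra, exponential attenuation along the chord
through the phantom, and an inverse-square factor — but it is a smooth
function of the gantry, collimator and couch angles, so the four error classes
leave distinct, physically plausible signatures on the maps.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Sequence

import numpy as np
from scipy.special import erf

TWO_PI = 2.0 * math.pi

__all__ = [
    "ErrorClass",
    "Technique",
    "DetectorGeometry",
    "BeamConfig",
    "ErrorSpec",
    "DetectorMap",
    "PlanSample",
    "SimConfig",
    "render_plan",
    "measure",
    "generate_dataset",
]


class ErrorClass(enum.IntEnum):
    """The five delivery-error classes."""

    NORMAL = 0
    GANTRY = 1
    COLLIMATOR = 2
    COUCH = 3
    DOSE = 4


class Technique(str, enum.Enum):
    IMRT = "IMRT"
    VMAT = "VMAT"


@dataclasses.dataclass(frozen=True)
class DetectorGeometry:
    """Cylindrical diode array unwrapped to an ``n_axial x n_circ`` grid.

    Row 0 is the most superior ring; column ``j`` sits at azimuth
    ``2*pi*j / n_circ`` with azimuth 0 at the top of the cylinder (under the
    beam when the gantry is at 0 degrees).
    """

    n_axial: int = 21
    n_circ: int = 66
    radius: float = 104.0
    axial_pitch: float = 10.0

    def __post_init__(self) -> None:
        if self.n_axial < 2:
            raise ValueError(f"n_axial must be >= 2, got {self.n_axial}")
        if self.n_circ < 4:
            raise ValueError(f"n_circ must be >= 4, got {self.n_circ}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.axial_pitch <= 0:
            raise ValueError(f"axial_pitch must be > 0, got {self.axial_pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_axial, self.n_circ)

    @property
    def n_diodes(self) -> int:
        return self.n_axial * self.n_circ

    @property
    def circumference(self) -> float:
        return TWO_PI * self.radius

    @property
    def circ_pitch(self) -> float:
        """Arc length between adjacent columns (mm)."""
        return self.circumference / self.n_circ

    def azimuths(self) -> np.ndarray:
        return TWO_PI * np.arange(self.n_circ) / self.n_circ

    def axial_positions(self) -> np.ndarray:
        """Axial coordinate of each row (mm), row 0 most superior."""
        half = 0.5 * (self.n_axial - 1)
        return (half - np.arange(self.n_axial)) * self.axial_pitch

    def positions(self) -> np.ndarray:
        """(n_diodes, 3) diode coordinates, row-major.

        Room frame: x lateral, y along the cylinder axis (superior positive),
        z vertical up.  All diodes lie exactly on the cylinder surface.
        """
        phi = self.azimuths()
        y = self.axial_positions()
        x = self.radius * np.sin(phi)
        z = self.radius * np.cos(phi)
        pts = np.empty((self.n_axial, self.n_circ, 3))
        pts[..., 0] = x[None, :]
        pts[..., 1] = y[:, None]
        pts[..., 2] = z[None, :]
        return pts.reshape(-1, 3)


Aperture = tuple[float, float, float, float]  # (cu, cv, half_u, half_v) mm at isocenter


@dataclasses.dataclass(frozen=True)
class BeamConfig:
    """One static field or one full arc.

    ``apertures`` are rectangular openings in beam coordinates at the
    isocenter plane: (u-center, v-center, u-half-width, v-half-width), mm.
    """

    gantry_deg: float
    collimator_deg: float = 0.0
    mu_weight: float = 1.0
    apertures: tuple[Aperture, ...] = ((0.0, 0.0, 50.0, 50.0),)
    is_arc: bool = False
    arc_span_deg: float = 0.0
    n_control_points: int = 0

    def __post_init__(self) -> None:
        if self.mu_weight <= 0:
            raise ValueError(f"mu_weight must be > 0, got {self.mu_weight}")
        if not self.apertures:
            raise ValueError("apertures must be non-empty")
        for ap in self.apertures:
            if ap[2] <= 0 or ap[3] <= 0:
                raise ValueError(f"apertures: degenerate half-widths in {ap}")
        if self.is_arc and self.n_control_points < 8:
            raise ValueError(
                f"n_control_points must be >= 8 for arcs, got {self.n_control_points}"
            )


@dataclasses.dataclass(frozen=True)
class ErrorSpec:
    """A single injected delivery error (or none)."""

    error_class: ErrorClass
    magnitude: float = 0.0  # degrees for rotational classes, fraction for dose
    sign: int = 1

    def __post_init__(self) -> None:
        if self.error_class == ErrorClass.NORMAL and self.magnitude != 0.0:
            raise ValueError("error_class=NORMAL requires magnitude 0")
        if self.error_class != ErrorClass.NORMAL and self.magnitude <= 0:
            raise ValueError(f"magnitude must be > 0 for {self.error_class.name}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")

    @classmethod
    def normal(cls) -> "ErrorSpec":
        return cls(ErrorClass.NORMAL, 0.0, 1)

    @classmethod
    def make(cls, error_class: ErrorClass, sign: int = 1,
             magnitude: float | None = None) -> "ErrorSpec":
        if error_class == ErrorClass.NORMAL:
            return cls.normal()
        if magnitude is None:
            magnitude = 0.02 if error_class == ErrorClass.DOSE else 1.0
        return cls(error_class, magnitude, sign)

    @property
    def signed_magnitude(self) -> float:
        return self.sign * self.magnitude


@dataclasses.dataclass(frozen=True)
class DetectorMap:
    """Dose values on the unwrapped cylinder surface."""

    values: np.ndarray
    geometry: DetectorGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {v.shape} does not match geometry {self.geometry.shape}"
            )
        if np.any(v < 0):
            raise ValueError("values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def max(self) -> float:
        return float(self.values.max())


@dataclasses.dataclass(frozen=True)
class PlanSample:
    """One paired calculated/measured instance with its error label."""

    calculated: DetectorMap
    measured: DetectorMap
    label: ErrorSpec
    technique: Technique
    plan_id: str

    def __post_init__(self) -> None:
        if self.calculated.geometry != self.measured.geometry:
            raise ValueError("calculated and measured maps must share one geometry")
        if (self.technique == Technique.VMAT
                and self.label.error_class == ErrorClass.GANTRY):
            raise ValueError("VMAT samples cannot carry a gantry error")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Knobs for the random plan generator."""

    n_per_class: int = 60
    attenuation: float = 0.005       # 1/mm through the phantom
    noise_sigma: float = 0.005       # multiplicative, fraction of each value
    seed: int = 0
    imrt_fraction: float = 0.66
    n_beams: tuple[int, int] = (5, 9)
    n_apertures: tuple[int, int] = (2, 4)
    aperture_half_width: tuple[float, float] = (8.0, 30.0)
    aperture_center: tuple[float, float] = (-40.0, 40.0)
    penumbra_sigma: float = 1.5      # mm at isocenter
    sad: float = 1000.0
    arc_control_points: int = 36
    gantry_magnitude: float = 1.0    # degrees
    collimator_magnitude: float = 1.0
    couch_magnitude: float = 1.0
    dose_magnitude: float = 0.02     # fraction
    geometry: DetectorGeometry = DetectorGeometry()

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _control_points(beam: BeamConfig) -> list[tuple[float, float, float]]:
    """Expand a beam to (gantry, collimator, mu) control points."""
    if not beam.is_arc:
        return [(beam.gantry_deg, beam.collimator_deg, beam.mu_weight)]
    n = beam.n_control_points
    step = beam.arc_span_deg / n
    return [
        (beam.gantry_deg + (k + 0.5) * step, beam.collimator_deg, beam.mu_weight / n)
        for k in range(n)
    ]


def _aperture_transmission(u: np.ndarray, v: np.ndarray,
                           apertures: Sequence[Aperture], sigma: float) -> np.ndarray:
    t = np.zeros_like(u)
    s = math.sqrt(2.0) * sigma
    for cu, cv, hu, hv in apertures:
        tu = 0.5 * (erf((u - (cu - hu)) / s) - erf((u - (cu + hu)) / s))
        tv = 0.5 * (erf((v - (cv - hv)) / s) - erf((v - (cv + hv)) / s))
        t += tu * tv
    return np.clip(t, 0.0, 1.0)


def _chord_depth(source: np.ndarray, diodes: np.ndarray, radius: float) -> np.ndarray:
    """Path length (mm) inside the cylinder from the entry point to each diode.

    The cylinder is x^2 + z^2 = radius^2 about the y axis; diodes on the near
    (entry) side get depth ~0, diodes on the far side the full chord.
    """
    d = diodes - source[None, :]
    length = np.linalg.norm(d, axis=1)
    dirs = d / length[:, None]
    a = dirs[:, 0] ** 2 + dirs[:, 2] ** 2
    b = 2.0 * (source[0] * dirs[:, 0] + source[2] * dirs[:, 2])
    c = source[0] ** 2 + source[2] ** 2 - radius ** 2
    disc = b * b - 4.0 * a * c
    depth = np.zeros_like(length)
    ok = (disc > 0) & (a > 1e-12)
    t_entry = np.zeros_like(length)
    t_entry[ok] = (-b[ok] - np.sqrt(disc[ok])) / (2.0 * a[ok])
    depth[ok] = np.clip(length[ok] - t_entry[ok], 0.0, None)
    return depth


def render_plan(beams: Sequence[BeamConfig], geometry: DetectorGeometry,
                error: ErrorSpec, *, attenuation: float = 0.005,
                penumbra_sigma: float = 1.5, sad: float = 1000.0) -> DetectorMap:
    """Render the detector dose map for a plan with one injected error.

    The error transform is applied before rendering: a gantry error offsets
    every gantry angle, a collimator error every collimator angle, a couch
    error rotates the diode array about the vertical axis through isocenter
    (implemented as the inverse rotation of every beam), and a dose error
    scales every monitor-unit weight.
    """
    if not beams:
        raise ValueError("beams must be non-empty")
    if not isinstance(error, ErrorSpec):
        raise TypeError("error must be an ErrorSpec")

    d_gantry = d_coll = couch_angle = 0.0
    mu_scale = 1.0
    if error.error_class == ErrorClass.GANTRY:
        d_gantry = error.signed_magnitude
    elif error.error_class == ErrorClass.COLLIMATOR:
        d_coll = error.signed_magnitude
    elif error.error_class == ErrorClass.COUCH:
        couch_angle = error.signed_magnitude
    elif error.error_class == ErrorClass.DOSE:
        mu_scale = 1.0 + error.signed_magnitude

    # Rotating the phantom (diodes) by +a about the vertical axis is the
    # same as rotating every beam by -a with the phantom fixed.
    rz = _rotation_z(-couch_angle)
    diodes = geometry.positions()
    dose = np.zeros(geometry.n_diodes)

    for beam in beams:
        for gantry, coll, mu in _control_points(beam):
            g = math.radians(gantry + d_gantry)
            source = np.array([sad * math.sin(g), 0.0, sad * math.cos(g)])
            # transverse beam axes before collimator rotation
            e1 = np.array([math.cos(g), 0.0, -math.sin(g)])
            e2 = np.array([0.0, 1.0, 0.0])
            psi = math.radians(coll + d_coll)
            u_axis = math.cos(psi) * e1 + math.sin(psi) * e2
            v_axis = -math.sin(psi) * e1 + math.cos(psi) * e2
            source = rz @ source
            u_axis = rz @ u_axis
            v_axis = rz @ v_axis
            axis = -source / sad  # unit vector source -> isocenter

            d = diodes - source[None, :]
            w = d @ axis
            scale = sad / w
            u = (d @ u_axis) * scale
            v = (d @ v_axis) * scale
            trans = _aperture_transmission(u, v, beam.apertures, penumbra_sigma)
            depth = _chord_depth(source, diodes, geometry.radius)
            dose += (mu * mu_scale) * trans * np.exp(-attenuation * depth) * scale ** 2

    return DetectorMap(dose.reshape(geometry.shape), geometry)


def measure(true_map: DetectorMap, noise_sigma: float, seed: int) -> DetectorMap:
    """Apply multiplicative detector noise: each value times Normal(1, sigma)."""
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    if noise_sigma == 0:
        return DetectorMap(true_map.values.copy(), true_map.geometry)
    rng = np.random.default_rng(seed)
    noisy = true_map.values * rng.normal(1.0, noise_sigma, true_map.values.shape)
    return DetectorMap(np.clip(noisy, 0.0, None), true_map.geometry)


def _random_beams(rng: np.random.Generator, technique: Technique,
                  config: SimConfig) -> list[BeamConfig]:
    def random_apertures() -> tuple[Aperture, ...]:
        na = int(rng.integers(config.n_apertures[0], config.n_apertures[1] + 1))
        aps = []
        for _ in range(na):
            cu = rng.uniform(*config.aperture_center)
            cv = rng.uniform(*config.aperture_center)
            hu = rng.uniform(*config.aperture_half_width)
            hv = rng.uniform(*config.aperture_half_width)
            aps.append((float(cu), float(cv), float(hu), float(hv)))
        return tuple(aps)

    if technique == Technique.VMAT:
        return [BeamConfig(
            gantry_deg=float(rng.uniform(0.0, 360.0)),
            collimator_deg=float(rng.uniform(0.0, 360.0)),
            mu_weight=float(rng.uniform(0.7, 1.3)),
            apertures=random_apertures(),
            is_arc=True,
            arc_span_deg=360.0,
            n_control_points=config.arc_control_points,
        )]
    nb = int(rng.integers(config.n_beams[0], config.n_beams[1] + 1))
    base = 360.0 * np.arange(nb) / nb
    jitter = rng.uniform(0.0, 360.0 / nb, nb)
    beams = []
    for k in range(nb):
        beams.append(BeamConfig(
            gantry_deg=float((base[k] + jitter[k]) % 360.0),
            collimator_deg=float(rng.uniform(0.0, 360.0)),
            mu_weight=float(rng.uniform(0.7, 1.3)),
            apertures=random_apertures(),
        ))
    return beams


def _class_magnitude(config: SimConfig, cls: ErrorClass) -> float:
    return {
        ErrorClass.GANTRY: config.gantry_magnitude,
        ErrorClass.COLLIMATOR: config.collimator_magnitude,
        ErrorClass.COUCH: config.couch_magnitude,
        ErrorClass.DOSE: config.dose_magnitude,
    }[cls]


def generate_dataset(config: SimConfig) -> list[PlanSample]:
    """Generate a balanced 5-class dataset of paired calculated/measured maps.

    Gantry-error samples are drawn only from static-field plans; signs within
    each error class alternate so both polarities appear in equal number.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    render_kw = dict(attenuation=config.attenuation,
                     penumbra_sigma=config.penumbra_sigma, sad=config.sad)
    samples: list[PlanSample] = []
    for cls in ErrorClass:
        for i in range(config.n_per_class):
            if cls == ErrorClass.GANTRY:
                technique = Technique.IMRT
            else:
                technique = (Technique.IMRT if rng.random() < config.imrt_fraction
                             else Technique.VMAT)
            beams = _random_beams(rng, technique, config)
            sign = 1 if i % 2 == 0 else -1
            if cls == ErrorClass.NORMAL:
                error = ErrorSpec.normal()
            else:
                error = ErrorSpec(cls, _class_magnitude(config, cls), sign)
            calculated = render_plan(beams, geom, error, **render_kw)
            true_measured = render_plan(beams, geom, ErrorSpec.normal(), **render_kw)
            noise_seed = int(rng.integers(0, 2 ** 31))
            measured = measure(true_measured, config.noise_sigma, noise_seed)
            samples.append(PlanSample(
                calculated=calculated, measured=measured, label=error,
                technique=technique, plan_id=f"P{len(samples):04d}",
            ))
    order = rng.permutation(len(samples))
    return [samples[k] for k in order]
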