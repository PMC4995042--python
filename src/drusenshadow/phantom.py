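"""Digital macular phantom: layered retina, drusen, and a choriocapillaris flow layer.

The phantom is the ground truth that the rest of the pipeline images.  It is a
3 x 3 mm lateral field (macular OCTA field of view) with a depth axis ``z`` in
micrometres increasing away from the instrument (z = 0 at the top of a B-scan,
the zero-delay position of the vitreoretinal protocol).  Anatomy, from top to
bottom: vitreous, neurosensory retina, the RPE band, druse material (between
the elevated RPE and Bruch's membrane inside druse footprints), a thin
choriocapillaris (CC) flow layer immediately below Bruch's membrane, and
choroid underneath.

Drusen are dome-shaped deposits sitting on Bruch's membrane that lift the RPE;
only drusen with lateral diameter >= 165 um are considered large enough for
analysis.  A lateral flow map assigns an erythrocyte speed to the CC layer;
regions of exactly zero speed are true flow voids, the ground truth against
which "false-positive flow impairment" is defined.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import IntEnum
import numpy as np

__all__ = [
    "TissueLabel",
    "OpticalProperties",
    "Druse",
    "FlowMap",
    "EyePhantom",
    "DEFAULT_OPTICS",
    "DEFAULT_CONFIG",
    "ELIGIBLE_DIAMETER_UM",
    "make_phantom",
    "tissue_at",
    "eligible_drusen",
    "druse_roi",
]

#: Minimum lateral diameter (um) for a druse to enter the analysis.
ELIGIBLE_DIAMETER_UM = 165.0


class TissueLabel(IntEnum):
    VITREOUS = 0
    RETINA = 1
    RPE = 2
    DRUSE = 3
    CHORIOCAPILLARIS = 4
    CHOROID = 5


@dataclass(frozen=True)
class OpticalProperties:
    """Backscatter and attenuation of one tissue class at both device wavelengths.

    ``reflectivity`` is a dimensionless backscatter amplitude coefficient;
    ``attenuation_840`` / ``attenuation_1050`` are attenuation coefficients in
    1/mm at the two centre wavelengths.  For the strongly pigmented tissues
    (RPE, druse) the 840-nm coefficient must not be smaller than the 1050-nm
    one: the longer wavelength penetrates the RPE better.
    """

    tissue_label: TissueLabel
    reflectivity: float
    attenuation_840: float
    attenuation_1050: float

    def __post_init__(self) -> None:
        for name in ("reflectivity", "attenuation_840", "attenuation_1050"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.tissue_label in (TissueLabel.RPE, TissueLabel.DRUSE):
            if self.attenuation_840 < self.attenuation_1050:
                raise ValueError(
                    f"{self.tissue_label.name}: attenuation at 840 nm "
                    f"({self.attenuation_840}) must be >= attenuation at 1050 nm "
                    f"({self.attenuation_1050})"
                )

    def attenuation(self, wavelength_nm: float) -> float:
        """Attenuation coefficient (1/mm) for the closer of the two wavelengths."""
        if abs(wavelength_nm - 840.0) <= abs(wavelength_nm - 1050.0):
            return self.attenuation_840
        return self.attenuation_1050


def _default_optics() -> dict[TissueLabel, OpticalProperties]:
    # reflectivity / mu_840 / mu_1050 (1/mm); ordering encodes that 840 nm is
    # attenuated more strongly by RPE and druse material than 1050 nm.
    table = [
        (TissueLabel.VITREOUS, 0.0, 0.0, 0.0),
        (TissueLabel.RETINA, 0.2, 1.0, 0.8),
        (TissueLabel.RPE, 1.0, 8.0, 3.0),
        (TissueLabel.DRUSE, 0.4, 4.0, 1.5),
        (TissueLabel.CHORIOCAPILLARIS, 0.6, 2.0, 1.5),
        (TissueLabel.CHOROID, 0.5, 2.0, 1.5),
    ]
    return {
        lab: OpticalProperties(lab, r, a840, a1050) for lab, r, a840, a1050 in table
    }


DEFAULT_OPTICS = _default_optics()


@dataclass(frozen=True)
class Druse:
    """A dome-shaped deposit between the RPE and Bruch's membrane.

    The default profile is a paraboloid dome
    ``h(r) = height * max(0, 1 - (2 r / diameter)**2)``; a Gaussian profile
    (same apex height, footprint taken at the 2-sigma radius) is available.
    """

    center_xy: tuple[float, float]  # mm, field coordinates
    diameter: float  # um, lateral extent
    height: float  # um, apical RPE elevation above its resting position
    profile: str = "parabolic"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"druse diameter must be > 0, got {self.diameter}")
        if self.height <= 0:
            raise ValueError(f"druse height must be > 0, got {self.height}")
        if self.profile not in ("parabolic", "gaussian"):
            raise ValueError(f"unknown druse profile {self.profile!r}")

    @property
    def radius_um(self) -> float:
        return self.diameter / 2.0

    @property
    def analysis_eligible(self) -> bool:
        return self.diameter >= ELIGIBLE_DIAMETER_UM

    def elevation(self, r_um: np.ndarray | float) -> np.ndarray | float:
        """Dome height (um) at lateral distance ``r_um`` from the centre."""
        r = np.asarray(r_um, dtype=float)
        if self.profile == "parabolic":
            h = self.height * np.maximum(0.0, 1.0 - (2.0 * r / self.diameter) ** 2)
        else:  # gaussian, truncated at the footprint edge
            sigma = self.diameter / 4.0
            h = np.where(
                r <= self.radius_um,
                self.height * np.exp(-0.5 * (r / sigma) ** 2),
                0.0,
            )
        return h if np.ndim(r_um) else float(h)


@dataclass
class FlowMap:
    """Lateral field of CC erythrocyte speed (mm/s) with explicit true voids."""

    flow_speed: np.ndarray  # (ny, nx), mm/s, >= 0
    void_regions: list[tuple[float, float, float]] = field(default_factory=list)
    # each void: (center_x_mm, center_y_mm, radius_um)

    def __post_init__(self) -> None:
        if np.any(self.flow_speed < 0) or not np.all(np.isfinite(self.flow_speed)):
            raise ValueError("flow speeds must be finite and >= 0")


@dataclass
class EyePhantom:
    """Ground-truth anatomy and optics for one simulated macula."""

    field_size: tuple[float, float]  # mm x mm
    grid: tuple[int, int, int]  # (ny, nx, nz)
    axial_pitch_um: float
    ilm_depth: np.ndarray  # (ny, nx), um
    rpe_depth: np.ndarray  # (ny, nx), um — top of the RPE band
    bm_depth: np.ndarray  # (ny, nx), um — Bruch's membrane (flat by default)
    rpe_thickness_um: float
    cc_thickness_um: float
    drusen: list[Druse]
    flow: FlowMap
    optics: dict[TissueLabel, OpticalProperties]
    config: dict = field(default_factory=dict)
    seed: int | None = None

    # ---- lateral geometry helpers -------------------------------------
    @property
    def ny(self) -> int:
        return self.grid[0]

    @property
    def nx(self) -> int:
        return self.grid[1]

    @property
    def nz(self) -> int:
        return self.grid[2]

    @property
    def pitch_x_mm(self) -> float:
        return self.field_size[0] / self.nx

    @property
    def pitch_y_mm(self) -> float:
        return self.field_size[1] / self.ny

    def lateral_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates ``(x, y)`` as broadcastable (ny, nx) arrays."""
        x = (np.arange(self.nx) + 0.5) * self.pitch_x_mm
        y = (np.arange(self.ny) + 0.5) * self.pitch_y_mm
        return np.meshgrid(x, y)

    def z_centers_um(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.axial_pitch_um

    def depth_um(self) -> float:
        return self.nz * self.axial_pitch_um

    # ---- surfaces ------------------------------------------------------
    def druse_elevation_map(self) -> np.ndarray:
        """RPE elevation above its resting depth (um), max over overlapping drusen."""
        elev = np.zeros((self.ny, self.nx))
        if not self.drusen:
            return elev
        x, y = self.lateral_coords_mm()
        for d in self.drusen:
            r_um = 1000.0 * np.hypot(x - d.center_xy[0], y - d.center_xy[1])
            elev = np.maximum(elev, d.elevation(r_um))
        return elev

    def boundaries(self) -> dict[str, np.ndarray]:
        """Depth (um) of each tissue interface per lateral pixel."""
        return {
            "ilm": self.ilm_depth,
            "rpe_top": self.rpe_depth,
            "rpe_bottom": self.rpe_depth + self.rpe_thickness_um,
            "bm": self.bm_depth,
            "cc_bottom": self.bm_depth + self.cc_thickness_um,
        }

    def label_volume(self) -> np.ndarray:
        """(ny, nx, nz) uint8 volume of :class:`TissueLabel` at voxel centres."""
        z = self.z_centers_um()[None, None, :]
        b = self.boundaries()
        labels = np.full((self.ny, self.nx, self.nz), TissueLabel.CHOROID, dtype=np.uint8)
        labels[z[..., :] < b["cc_bottom"][..., None]] = TissueLabel.CHORIOCAPILLARIS
        labels[z < b["bm"][..., None]] = TissueLabel.DRUSE
        labels[z < b["rpe_bottom"][..., None]] = TissueLabel.RPE
        labels[z < b["rpe_top"][..., None]] = TissueLabel.RETINA
        labels[z < b["ilm"][..., None]] = TissueLabel.VITREOUS
        return labels

    def cc_mask(self) -> np.ndarray:
        """(ny, nx, nz) boolean mask of the CC layer (BM to BM + cc_thickness)."""
        z = self.z_centers_um()[None, None, :]
        return (z >= self.bm_depth[..., None]) & (
            z < (self.bm_depth + self.cc_thickness_um)[..., None]
        )

    def validate(self) -> None:
        if np.any(self.ilm_depth >= self.rpe_depth):
            raise ValueError("ILM must lie above the RPE everywhere")
        if np.any(self.rpe_depth + self.rpe_thickness_um > self.bm_depth + 1e-9):
            raise ValueError("RPE band must lie above (or on) Bruch's membrane")
        if np.any(self.bm_depth + self.cc_thickness_um > self.depth_um()):
            raise ValueError("CC layer extends below the imaged depth range")


# ----------------------------------------------------------------------
# configuration & construction
# ----------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "field_mm": [3.0, 3.0],
    # desk-scale grid (ny, nx, nz); full device grids come from the preset
    "grid": [192, 192, 320],
    "axial_pitch_um": 3.0,
    "layers": {
        "ilm_um": 150.0,
        "bm_um": 460.0,
        "rpe_thickness_um": 30.0,
        "cc_thickness_um": 60.0,
    },
    # macular cohort of large soft drusen; heights ~0.45 * diameter
    "drusen": [
        {"center_mm": [0.8, 0.8], "diameter_um": 200.0, "height_um": 90.0},
        {"center_mm": [2.1, 0.9], "diameter_um": 300.0, "height_um": 135.0},
        {"center_mm": [0.9, 2.1], "diameter_um": 400.0, "height_um": 180.0},
        {"center_mm": [2.1, 2.2], "diameter_um": 500.0, "height_um": 225.0},
    ],
    "flow": {"scenario": "uniform", "speed_mm_s": 3.0},
    "optics": {},  # per-tissue overrides {label_name: {reflectivity: .., ...}}
    "attenuation_scale": 1.0,
}


def _build_optics(overrides: dict, attenuation_scale: float) -> dict[TissueLabel, OpticalProperties]:
    table = {}
    for label, props in DEFAULT_OPTICS.items():
        o = overrides.get(label.name.lower(), {})
        table[label] = OpticalProperties(
            label,
            float(o.get("reflectivity", props.reflectivity)),
            float(o.get("attenuation_840", props.attenuation_840)) * attenuation_scale,
            float(o.get("attenuation_1050", props.attenuation_1050)) * attenuation_scale,
        )
    return table


def _build_flow(cfg: dict, phantom_drusen: list[Druse], field_mm, grid, rng) -> FlowMap:
    ny, nx = grid[0], grid[1]
    scenario = cfg.get("scenario", "uniform")
    speed = float(cfg.get("speed_mm_s", 3.0))
    if speed < 0:
        raise ValueError("flow speed must be >= 0")
    flow = np.full((ny, nx), speed)
    voids: list[tuple[float, float, float]] = []
    if scenario == "uniform":
        pass
    elif scenario == "voids_under_drusen":
        which = cfg.get("void_druse_indices")
        idx = range(len(phantom_drusen)) if which is None else which
        frac = float(cfg.get("void_radius_fraction", 0.8))
        for i in idx:
            d = phantom_drusen[i]
            voids.append((d.center_xy[0], d.center_xy[1], frac * d.radius_um))
    elif scenario == "voids_elsewhere":
        for v in cfg.get("voids", []):
            voids.append((float(v["center_mm"][0]), float(v["center_mm"][1]), float(v["radius_um"])))
    else:
        raise ValueError(f"unknown flow scenario {scenario!r}")
    if voids:
        x = (np.arange(nx) + 0.5) * (field_mm[0] / nx)
        y = (np.arange(ny) + 0.5) * (field_mm[1] / ny)
        xx, yy = np.meshgrid(x, y)
        for cx, cy, r_um in voids:
            flow[1000.0 * np.hypot(xx - cx, yy - cy) <= r_um] = 0.0
    return FlowMap(flow_speed=flow, void_regions=voids)


def make_phantom(config: dict | None = None, seed: int = 0) -> EyePhantom:
    """Build an :class:`EyePhantom` from a configuration mapping.

    Deterministic for a fixed ``(config, seed)``.  The seed only matters when
    the configuration requests randomised druse placement
    (``drusen: {"random": {...}}``).
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = copy.deepcopy(v)

    field_mm = tuple(float(v) for v in cfg["field_mm"])
    grid = tuple(int(v) for v in cfg["grid"])
    pitch = float(cfg["axial_pitch_um"])
    if min(field_mm) <= 0 or min(grid) <= 0 or pitch <= 0:
        raise ValueError("field size, grid and axial pitch must be positive")
    layers = cfg["layers"]
    ilm = float(layers["ilm_um"])
    bm = float(layers["bm_um"])
    rpe_th = float(layers["rpe_thickness_um"])
    cc_th = float(layers["cc_thickness_um"])
    if not (0 < ilm < bm) or rpe_th <= 0 or cc_th <= 0:
        raise ValueError("layer depths must satisfy 0 < ILM < BM with positive thicknesses")

    rng = np.random.default_rng(seed)
    drusen = _parse_drusen(cfg["drusen"], field_mm, rng)

    for d in drusen:
        for c, half in zip(d.center_xy, field_mm):
            if c - d.radius_um / 1000.0 < 0 or c + d.radius_um / 1000.0 > half:
                raise ValueError(
                    f"druse at {d.center_xy} mm (diameter {d.diameter} um) "
                    "leaves the field"
                )
        if d.height + rpe_th > bm - ilm:
            raise ValueError("druse too tall: RPE would be lifted above the ILM")

    ny, nx, nz = grid
    ilm_depth = np.full((ny, nx), ilm)
    bm_depth = np.full((ny, nx), bm)

    phantom = EyePhantom(
        field_size=field_mm,
        grid=grid,
        axial_pitch_um=pitch,
        ilm_depth=ilm_depth,
        rpe_depth=np.full((ny, nx), bm - rpe_th),
        bm_depth=bm_depth,
        rpe_thickness_um=rpe_th,
        cc_thickness_um=cc_th,
        drusen=drusen,
        flow=FlowMap(flow_speed=np.zeros((ny, nx))),
        optics=_build_optics(cfg.get("optics") or {}, float(cfg.get("attenuation_scale", 1.0))),
        config=cfg,
        seed=seed,
    )
    # RPE top = BM - band thickness - druse elevation
    phantom.rpe_depth = bm_depth - rpe_th - phantom.druse_elevation_map()
    phantom.flow = _build_flow(cfg.get("flow") or {}, drusen, field_mm, grid, rng)
    phantom.validate()
    return phantom


def _parse_drusen(spec, field_mm, rng) -> list[Druse]:
    if isinstance(spec, dict) and "random" in spec:
        r = spec["random"]
        n = int(r.get("n", 4))
        dlo, dhi = r.get("diameter_range_um", [180.0, 500.0])
        aspect = float(r.get("height_over_diameter", 0.45))
        margin = 1.05
        drusen = []
        for _ in range(n):
            diam = float(rng.uniform(dlo, dhi))
            rad_mm = margin * diam / 2000.0
            cx = float(rng.uniform(rad_mm, field_mm[0] - rad_mm))
            cy = float(rng.uniform(rad_mm, field_mm[1] - rad_mm))
            drusen.append(Druse((cx, cy), diam, aspect * diam))
        return drusen
    return [
        Druse(
            center_xy=tuple(float(v) for v in d["center_mm"]),
            diameter=float(d["diameter_um"]),
            height=float(d["height_um"]),
            profile=d.get("profile", "parabolic"),
        )
        for d in spec
    ]


# ----------------------------------------------------------------------
# queries
# ----------------------------------------------------------------------

def tissue_at(phantom: EyePhantom, x: float, y: float, z: float) -> TissueLabel:
    """Tissue label at field position ``(x, y)`` mm and depth ``z`` um."""
    if not (0 <= x <= phantom.field_size[0] and 0 <= y <= phantom.field_size[1]):
        raise ValueError(f"({x}, {y}) mm is outside the {phantom.field_size} mm field")
    if z < 0:
        raise ValueError("depth z must be >= 0")
    ix = min(int(x / phantom.pitch_x_mm), phantom.nx - 1)
    iy = min(int(y / phantom.pitch_y_mm), phantom.ny - 1)
    b = phantom.boundaries()
    if z < b["ilm"][iy, ix]:
        return TissueLabel.VITREOUS
    if z < b["rpe_top"][iy, ix]:
        return TissueLabel.RETINA
    if z < b["rpe_bottom"][iy, ix]:
        return TissueLabel.RPE
    if z < b["bm"][iy, ix]:
        return TissueLabel.DRUSE
    if z < b["cc_bottom"][iy, ix]:
        return TissueLabel.CHORIOCAPILLARIS
    return TissueLabel.CHOROID


def eligible_drusen(phantom: EyePhantom) -> list[Druse]:
    """Drusen large enough for analysis (diameter >= 165 um), order preserved."""
    return [d for d in phantom.drusen if d.analysis_eligible]


def druse_roi(
    phantom: EyePhantom,
    druse: Druse,
    grid: tuple[int, int] | None = None,
) -> np.ndarray:
    """Boolean lateral mask of pixels whose centres lie in the druse footprint disc."""
    if druse not in phantom.drusen:
        raise ValueError("druse does not belong to this phantom")
    if grid is None:
        grid = (phantom.ny, phantom.nx)
    ny, nx = grid
    if ny <= 0 or nx <= 0:
        raise ValueError("grid must have at least one pixel in each direction")
    x = (np.arange(nx) + 0.5) * (phantom.field_size[0] / nx)
    y = (np.arange(ny) + 0.5) * (phantom.field_size[1] / ny)
    xx, yy = np.meshgrid(x, y)
    r_um = 1000.0 * np.hypot(xx - druse.center_xy[0], yy - druse.center_xy[1])
    return r_um <= druse.radius_um
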