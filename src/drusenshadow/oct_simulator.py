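"""Repeated-B-scan OCT amplitude simulation for two OCTA device presets.

Two acquisition presets are modelled after the devices compared in the study
conditions:

* ``SD840`` — a spectral-domain instrument at ~840 nm, 70 kHz A-scan rate,
  2 repeated B-scans per location on a 304 x 304 grid, ~5 ms interscan time,
  ~5 um axial resolution.  Spectrometer detection makes it subject to
  sensitivity roll-off with depth under the vitreoretinal protocol.
* ``SS1050`` — a swept-source prototype at ~1050 nm, 400 kHz, 5 repeats on a
  500 x 500 grid, ~1.5 ms interscan time, ~8.5 um axial resolution, with
  negligible roll-off.

The forward model composes, per voxel,

    mean amplitude = reflectivity(tissue) * attenuation_factor * sensitivity(z)

with round-trip Beer-Lambert attenuation ``exp(-2 * integral of mu dz)`` using
the per-tissue coefficient at the preset wavelength, and a Gaussian-in-depth
sensitivity profile normalised to 1 at the zero-delay (z = 0) falling to 1/2
at the 6-dB roll-off depth.  Fully developed speckle is modelled as the
modulus of a circular complex Gaussian field; erythrocyte flow decorrelates
the speckle between repeats with pairwise complex correlation
``rho = exp(-(v * dt / L_c)**2)``, and detection noise is a circular complex
Gaussian of scale ``sigma_n`` added independently to every repeat (so a
signal-free voxel has Rayleigh-distributed amplitude of scale ``sigma_n``).

Volumes are simulated on the phantom's desk-scale grid by default; the full
device grids are available via ``use_device_grid``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .phantom import EyePhantom, TissueLabel

__all__ = [
    "DevicePreset",
    "OCTVolume",
    "SD840",
    "SS1050",
    "PRESETS",
    "DECORRELATION_LENGTH_UM",
    "sensitivity",
    "attenuation_factor",
    "flow_correlation",
    "mean_amplitude_volume",
    "simulate_volume",
    "estimate_pair_correlation",
]

#: Speckle decorrelation length constant L_c (um): lateral displacement of
#: scatterers that fully randomises the speckle phasor.
DECORRELATION_LENGTH_UM = 10.0

#: Amplitude-noise scale sigma_n shared by both presets (see methods note).
DEFAULT_NOISE_FLOOR = 0.03

#: Mean of |CN(0, 1)| — normalisation so that E[amplitude] equals the model mean.
_RAYLEIGH_MEAN_UNIT = float(np.sqrt(np.pi) / 2.0)


@dataclass(frozen=True)
class DevicePreset:
    """Acquisition physics and geometry of one OCTA device."""

    name: str
    center_wavelength_nm: float
    ascan_rate_hz: float
    repeats: int  # R, repeated B-scans per location
    n_locations: int  # B-scan positions (slow axis)
    n_ascans: int  # A-scans per B-scan (fast axis)
    interscan_time_ms: float  # dt between repeats at one location
    axial_resolution_um: float
    rolloff_6db_depth_um: float  # depth where sensitivity amplitude = 1/2; inf allowed
    noise_floor: float = DEFAULT_NOISE_FLOOR

    def __post_init__(self) -> None:
        if self.repeats < 2:
            raise ValueError("OCTA requires at least 2 repeated B-scans")
        if self.noise_floor < 0:
            raise ValueError("noise floor must be >= 0")
        if self.rolloff_6db_depth_um <= 0:
            raise ValueError("roll-off depth must be positive (inf for none)")

    def replace(self, **kwargs) -> "DevicePreset":
        return dataclasses.replace(self, **kwargs)


SD840 = DevicePreset(
    name="SD840",
    center_wavelength_nm=840.0,
    ascan_rate_hz=70_000.0,
    repeats=2,
    n_locations=304,
    n_ascans=304,
    interscan_time_ms=5.0,
    axial_resolution_um=5.0,
    rolloff_6db_depth_um=600.0,
)

SS1050 = DevicePreset(
    name="SS1050",
    center_wavelength_nm=1050.0,
    ascan_rate_hz=400_000.0,
    repeats=5,
    n_locations=500,
    n_ascans=500,
    interscan_time_ms=1.5,
    axial_resolution_um=8.5,
    rolloff_6db_depth_um=np.inf,
)

PRESETS = {"SD840": SD840, "SS1050": SS1050}


@dataclass
class OCTVolume:
    """Repeated-B-scan amplitude data on a (R, ny, nx, nz) grid."""

    amplitudes: np.ndarray  # float32, (R, ny, nx, nz), >= 0
    preset: DevicePreset
    axial_pitch_um: float
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplitudes.ndim != 4:
            raise ValueError("amplitudes must be (repeats, ny, nx, nz)")
        if self.amplitudes.shape[0] < 2:
            raise ValueError("OCTA requires at least 2 repeats")
        if not np.all(np.isfinite(self.amplitudes)) or np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be finite and >= 0")

    @property
    def repeats(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.amplitudes.shape[1:]

    def mean_amplitude(self) -> np.ndarray:
        """Per-voxel mean over repeats — the OCT signal used for thresholding."""
        return self.amplitudes.mean(axis=0)


# ----------------------------------------------------------------------
# physics factors
# ----------------------------------------------------------------------

def sensitivity(preset: DevicePreset, z_um: np.ndarray | float) -> np.ndarray | float:
    """Depth-dependent sensitivity in (0, 1]; 1 at the zero-delay (z = 0).

    Gaussian roll-off ``exp(-ln 2 * (z / z_6dB)**2)``, so the amplitude
    sensitivity is exactly 1/2 at the 6-dB depth; identically 1 when the
    preset has no roll-off (``z_6dB = inf``).
    """
    z = np.asarray(z_um, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be >= 0")
    if np.isinf(preset.rolloff_6db_depth_um):
        out = np.ones_like(z)
    else:
        out = np.exp(-np.log(2.0) * (z / preset.rolloff_6db_depth_um) ** 2)
    return out if np.ndim(z_um) else float(out)


def _mu_for(phantom: EyePhantom, preset: DevicePreset) -> dict[TissueLabel, float]:
    return {
        lab: props.attenuation(preset.center_wavelength_nm)
        for lab, props in phantom.optics.items()
    }


def _path_attenuation_map(phantom: EyePhantom, preset: DevicePreset) -> np.ndarray:
    """(ny, nx, nz) round-trip Beer-Lambert factor at voxel centres (analytic).

    Each A-scan path is decomposed into the layer segments above depth z; the
    attenuation integral is exact for the piecewise-constant tissue model.
    """
    mu = _mu_for(phantom, preset)
    b = phantom.boundaries()
    # segment boundaries top->bottom, each (ny, nx)
    tops = [
        np.zeros_like(b["ilm"]), b["ilm"], b["rpe_top"], b["rpe_bottom"], b["bm"],
        b["cc_bottom"],
    ]
    bottoms = [
        b["ilm"], b["rpe_top"], b["rpe_bottom"], b["bm"], b["cc_bottom"],
        np.full_like(b["ilm"], phantom.depth_um()),
    ]
    labels = [
        TissueLabel.VITREOUS, TissueLabel.RETINA, TissueLabel.RPE,
        TissueLabel.DRUSE, TissueLabel.CHORIOCAPILLARIS, TissueLabel.CHOROID,
    ]
    z = phantom.z_centers_um()[None, None, :]
    integral = np.zeros((phantom.ny, phantom.nx, phantom.nz))
    for top, bottom, lab in zip(tops, bottoms, labels):
        m = mu[lab]
        if m == 0.0:
            continue
        # path length (mm) through this segment above depth z
        length_um = np.clip(z - top[..., None], 0.0, (bottom - top)[..., None])
        integral += m * (length_um / 1000.0)
    return np.exp(-2.0 * integral)


def attenuation_factor(
    phantom: EyePhantom,
    preset: DevicePreset,
    x_mm: float,
    y_mm: float,
    z_um: float,
) -> float:
    """Round-trip Beer-Lambert factor exp(-2 * integral_0^z mu ds) at one point."""
    if not (0 <= x_mm <= phantom.field_size[0] and 0 <= y_mm <= phantom.field_size[1]):
        raise ValueError("point outside the lateral field")
    if not (0 <= z_um <= phantom.depth_um()):
        raise ValueError("depth outside the volume")
    mu = _mu_for(phantom, preset)
    ix = min(int(x_mm / phantom.pitch_x_mm), phantom.nx - 1)
    iy = min(int(y_mm / phantom.pitch_y_mm), phantom.ny - 1)
    b = phantom.boundaries()
    edges = [
        (0.0, b["ilm"][iy, ix], TissueLabel.VITREOUS),
        (b["ilm"][iy, ix], b["rpe_top"][iy, ix], TissueLabel.RETINA),
        (b["rpe_top"][iy, ix], b["rpe_bottom"][iy, ix], TissueLabel.RPE),
        (b["rpe_bottom"][iy, ix], b["bm"][iy, ix], TissueLabel.DRUSE),
        (b["bm"][iy, ix], b["cc_bottom"][iy, ix], TissueLabel.CHORIOCAPILLARIS),
        (b["cc_bottom"][iy, ix], phantom.depth_um(), TissueLabel.CHOROID),
    ]
    integral = 0.0
    for top, bottom, lab in edges:
        length_um = min(max(z_um - top, 0.0), bottom - top)
        integral += mu[lab] * length_um / 1000.0
    return float(np.exp(-2.0 * integral))


def flow_correlation(
    speed_mm_s: np.ndarray | float,
    preset: DevicePreset,
    decorrelation_length_um: float = DECORRELATION_LENGTH_UM,
) -> np.ndarray | float:
    """Pairwise speckle correlation between consecutive repeats.

    ``rho = exp(-(v * dt / L_c)**2)``: static tissue gives rho = 1 (identical
    speckle), fast flow fully randomises the phasor between repeats.
    """
    v = np.asarray(speed_mm_s, dtype=float)
    displacement_um = v * preset.interscan_time_ms  # mm/s * ms = um
    rho = np.exp(-((displacement_um / decorrelation_length_um) ** 2))
    return rho if np.ndim(speed_mm_s) else float(rho)


def mean_amplitude_volume(phantom: EyePhantom, preset: DevicePreset) -> np.ndarray:
    """(ny, nx, nz) noise- and speckle-free mean amplitude."""
    labels = phantom.label_volume()
    refl = np.zeros(len(TissueLabel))
    for lab, props in phantom.optics.items():
        refl[int(lab)] = props.reflectivity
    amp = refl[labels]
    amp *= _path_attenuation_map(phantom, preset)
    amp *= sensitivity(preset, phantom.z_centers_um())[None, None, :]
    return amp


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------

def simulate_volume(
    phantom: EyePhantom,
    preset: DevicePreset,
    seed: int = 0,
    noise_on: bool = True,
    speckle_on: bool = True,
    decorrelation_length_um: float = DECORRELATION_LENGTH_UM,
    use_device_grid: bool = False,
) -> OCTVolume:
    """Simulate the repeated-B-scan amplitude volume for one device preset.

    Repeats share a speckle realisation that is progressively renewed where
    there is flow: the complex field of repeat ``n + 1`` is
    ``rho * g_n + sqrt(1 - rho**2) * w`` with ``w`` a fresh circular Gaussian
    innovation, which gives consecutive repeats complex correlation ``rho``.
    With speckle and noise off, all repeats are identical (static tissue
    produces no angiography signal).  Deterministic per (inputs, seed).
    """
    if preset.repeats < 2:
        raise ValueError("OCTA requires at least 2 repeats")
    if use_device_grid:
        cfg = dict(phantom.config)
        cfg["grid"] = [preset.n_locations, preset.n_ascans, phantom.nz]
        from .phantom import make_phantom  # resample geometry on the device grid

        phantom = make_phantom(cfg, seed=phantom.seed or 0)

    mean_amp = mean_amplitude_volume(phantom, preset)
    if not np.all(np.isfinite(mean_amp)):
        raise ValueError("non-finite optics produced non-finite amplitudes")
    R = preset.repeats
    ny, nx, nz = mean_amp.shape
    rng = np.random.default_rng(seed)

    # per-voxel repeat-to-repeat correlation: flow only inside the CC layer
    rho = np.ones((ny, nx, nz), dtype=np.float32)
    cc = phantom.cc_mask()
    rho_lat = flow_correlation(
        phantom.flow.flow_speed, preset, decorrelation_length_um
    ).astype(np.float32)
    rho[cc] = np.broadcast_to(rho_lat[..., None], (ny, nx, nz))[cc]

    amplitudes = np.empty((R, ny, nx, nz), dtype=np.float32)
    if speckle_on:
        scale = (mean_amp / _RAYLEIGH_MEAN_UNIT).astype(np.float32)
        g = _complex_unit_field(rng, (ny, nx, nz))
        mix = np.sqrt(1.0 - rho.astype(np.float64) ** 2).astype(np.float32)
        for n in range(R):
            if n > 0:
                g = rho * g + mix * _complex_unit_field(rng, (ny, nx, nz))
            field = scale * g
            if noise_on and preset.noise_floor > 0:
                field = field + _complex_noise(rng, (ny, nx, nz), preset.noise_floor)
            amplitudes[n] = np.abs(field)
    else:
        base = mean_amp.astype(np.complex64)
        for n in range(R):
            field = base
            if noise_on and preset.noise_floor > 0:
                field = field + _complex_noise(rng, (ny, nx, nz), preset.noise_floor)
            amplitudes[n] = np.abs(field)

    return OCTVolume(
        amplitudes=amplitudes,
        preset=preset,
        axial_pitch_um=phantom.axial_pitch_um,
        provenance={
            "seed": int(seed),
            "phantom_seed": phantom.seed,
            "noise_on": bool(noise_on),
            "speckle_on": bool(speckle_on),
            "decorrelation_length_um": float(decorrelation_length_um),
            "grid": [ny, nx, nz],
        },
    )


def _complex_unit_field(rng, shape) -> np.ndarray:
    """Circular complex Gaussian with E[|g|^2] = 1 (components var 1/2)."""
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    return (re + 1j * im).astype(np.complex64) * np.float32(np.sqrt(0.5))


def _complex_noise(rng, shape, sigma: float) -> np.ndarray:
    """Additive detection noise; its amplitude alone is Rayleigh(sigma)."""
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    return (re + 1j * im).astype(np.complex64) * np.float32(sigma)


def estimate_pair_correlation(
    volume: OCTVolume, mask: np.ndarray | None = None
) -> float:
    """Estimate the constructed complex pair correlation |rho| from amplitudes.

    For jointly circular Gaussian speckle the intensity correlation between
    repeats equals |rho|^2, so sqrt of the empirical intensity correlation is
    an estimator of the complex correlation magnitude that was mixed in.
    Averaged over consecutive repeat pairs.
    """
    a = volume.amplitudes
    if mask is None:
        mask = np.ones(a.shape[1:], dtype=bool)
    vals = []
    for n in range(volume.repeats - 1):
        i1 = a[n][mask].astype(np.float64) ** 2
        i2 = a[n + 1][mask].astype(np.float64) ** 2
        c = np.corrcoef(i1, i2)[0, 1]
        vals.append(np.sqrt(max(c, 0.0)))
    return float(np.mean(vals))
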