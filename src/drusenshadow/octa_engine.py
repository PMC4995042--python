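"""Decorrelation angiography and OCT-signal-based thresholding.

The angiography statistic is an unsplit, intensity-based pairwise
decorrelation over consecutive repeated B-scans,

    D = 1 - (1 / (R - 1)) * sum_n  A_n A_{n+1} / ((A_n^2 + A_{n+1}^2) / 2),

bounded in [0, 1] by the AM-GM inequality.  Identical repeats give D = 0 (no
flow); erythrocyte motion between repeats drives D toward 1.  A pair with
both amplitudes exactly zero contributes decorrelation 0 — an empty signal
must not fabricate flow.

Because low-OCT-signal voxels are noise-dominated and would otherwise show
spuriously high decorrelation, the angiogram is masked on the OCT signal: the
noise mean and standard deviation are estimated from a signal-free region
(vitreous by default) of the mean-over-repeats amplitude, the threshold is
set 2 standard deviations above the noise mean, and every voxel whose OCT
signal falls below the threshold has its decorrelation set to zero.  This is
exactly the step that makes shadowed voxels with true flow indistinguishable
from voxels without flow.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .oct_simulator import OCTVolume
from .phantom import EyePhantom, TissueLabel

__all__ = [
    "NoiseStats",
    "OCTAVolume",
    "decorrelate",
    "estimate_noise",
    "apply_threshold",
    "default_noise_region",
    "run_angiography",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseStats:
    """Noise statistics of the OCT signal and the derived masking threshold."""

    mean: float
    sd: float
    threshold: float  # always mean + 2 * sd
    region: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        expected = self.mean + 2.0 * self.sd
        if not np.isclose(self.threshold, expected, rtol=0, atol=1e-12 * max(1.0, abs(expected))):
            raise ValueError("threshold must equal mean + 2 * sd")

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float, region: str = "") -> "NoiseStats":
        return cls(mean=float(mean), sd=float(sd), threshold=float(mean + 2.0 * sd), region=region)


@dataclass
class OCTAVolume:
    """Thresholded decorrelation volume with its OCT signal and mask."""

    decorrelation: np.ndarray  # (ny, nx, nz) in [0, 1]; 0 wherever masked
    mask_below_threshold: np.ndarray  # bool, True where OCT signal < threshold
    noise: NoiseStats
    mean_oct: np.ndarray  # per-voxel mean amplitude over repeats
    preset_name: str = ""
    axial_pitch_um: float = float("nan")
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.decorrelation
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("decorrelation must lie in [0, 1]")
        if np.any(d[self.mask_below_threshold] != 0):
            raise ValueError("masked voxels must have decorrelation 0")


def decorrelate(volume: OCTVolume) -> np.ndarray:
    """Raw decorrelation field over consecutive repeat pairs (no thresholding)."""
    a = volume.amplitudes
    if a.shape[0] < 2:
        raise ValueError("decorrelation requires at least 2 repeats")
    if np.any(a < 0):
        raise ValueError("amplitudes must be non-negative")
    acc = np.zeros(a.shape[1:], dtype=np.float64)
    for n in range(a.shape[0] - 1):
        a1 = a[n].astype(np.float64)
        a2 = a[n + 1].astype(np.float64)
        num = a1 * a2
        den = 0.5 * (a1 * a1 + a2 * a2)
        # 0/0 pair (both amplitudes zero): define the pair as fully correlated
        ratio = np.divide(num, den, out=np.ones_like(num), where=den > 0)
        acc += 1.0 - ratio
    d = acc / (a.shape[0] - 1)
    return np.clip(d, 0.0, 1.0)


def estimate_noise(volume: OCTVolume, noise_region: np.ndarray) -> NoiseStats:
    """Sample mean/SD of the mean-over-repeats amplitude inside ``noise_region``."""
    region = np.asarray(noise_region, dtype=bool)
    if region.shape != volume.shape:
        raise ValueError("noise region shape must match the volume grid")
    if not region.any():
        raise ValueError("noise region is empty")
    vals = volume.mean_amplitude()[region].astype(np.float64)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return NoiseStats.from_mean_sd(mean, sd, region=f"{int(region.sum())} voxels")


def apply_threshold(
    decorrelation: np.ndarray,
    mean_oct: np.ndarray,
    noise: NoiseStats,
    **volume_meta,
) -> OCTAVolume:
    """Zero the angiogram wherever the OCT signal is below the threshold.

    The comparison is strict: a voxel whose OCT signal equals the threshold
    exactly is retained.  Idempotent.
    """
    d = np.asarray(decorrelation)
    m = np.asarray(mean_oct)
    if d.shape != m.shape:
        raise ValueError(f"shape mismatch: decorrelation {d.shape} vs OCT {m.shape}")
    mask = m < noise.threshold
    out = np.where(mask, d.dtype.type(0), d)
    return OCTAVolume(
        decorrelation=out,
        mask_below_threshold=mask,
        noise=noise,
        mean_oct=m,
        **volume_meta,
    )


def default_noise_region(phantom: EyePhantom, erosion_px: int = 2) -> np.ndarray:
    """Vitreous voxels (above the ILM), eroded to stay clear of the interface."""
    region = phantom.label_volume() == TissueLabel.VITREOUS
    if erosion_px > 0:
        region = ndimage.binary_erosion(region, iterations=erosion_px)
    if not region.any():
        raise ValueError("vitreous noise region is empty after erosion")
    return region


def run_angiography(
    volume: OCTVolume,
    noise_region: np.ndarray,
    tissue_region: np.ndarray | None = None,
) -> OCTAVolume:
    """decorrelate -> estimate_noise -> apply_threshold, with provenance.

    ``tissue_region`` (ground-truth non-vitreous mask) is only used to warn
    when the declared noise region overlaps tissue.
    """
    if tissue_region is not None and np.any(noise_region & tissue_region):
        log.warning("noise region overlaps tissue: threshold will be biased high")
    d = decorrelate(volume)
    noise = estimate_noise(volume, noise_region)
    return apply_threshold(
        d,
        volume.mean_amplitude(),
        noise,
        preset_name=volume.preset.name,
        axial_pitch_um=volume.axial_pitch_um,
        provenance=dict(volume.provenance),
    )
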