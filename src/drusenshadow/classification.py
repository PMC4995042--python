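"""Per-druse grading, cohort aggregation, and interreader agreement.

The grading follows the clinical reading workflow.  For each druse and
device, an automatic "reader" judges whether the en face OCTA CC slab shows
low signal under the druse; where it does, the en face OCT CC slab is
consulted to split the loss into:

* **ambiguous** — low OCTA signal co-located with low OCT signal: the dark
  angiogram may reflect absent flow, thresholding of an attenuated OCT
  signal, or both;
* **unambiguous** — low OCTA signal with preserved OCT signal: interpretable
  as a true flow alteration.

**False-positive flow impairment** on one device is ambiguous loss on that
device with *no* OCTA signal loss on the other device — a
shadowing/thresholding artifact rather than choriocapillaris pathology.

The human judgment of "an area of low signal" is automated with two explicit
parameters: a slab pixel is *low* when its value falls below ``k`` times the
median of the background (all slab pixels outside every druse footprint,
eroded), and an ROI is flagged when at least a fraction ``f`` of its pixels
are low.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .slab_projection import EnFacePair

__all__ = [
    "ReaderParams",
    "DruseAssessment",
    "DruseGrade",
    "CohortSummary",
    "DEFAULT_READER",
    "assess_roi",
    "classify_druse",
    "aggregate",
    "agreement",
    "grade_cohort",
    "round_pct",
    "load_reference_cohort",
    "grades_from_assessments",
]

DEVICES = ("SD840", "SS1050")


@dataclass(frozen=True)
class ReaderParams:
    """Explicit parameters of the automatic low-signal reader."""

    low_pixel_factor: float = 0.6  # k: pixel is low if value < k * background median
    low_area_fraction: float = 0.35  # f: ROI is low if >= f of its pixels are low
    background_erosion_px: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.low_pixel_factor < 1):
            raise ValueError("low_pixel_factor k must be in (0, 1)")
        if not (0 < self.low_area_fraction <= 1):
            raise ValueError("low_area_fraction f must be in (0, 1]")


DEFAULT_READER = ReaderParams()


@dataclass(frozen=True)
class DruseAssessment:
    """One device's reading of one druse: low OCTA, and (if so) low OCT."""

    device: str
    low_octa: bool
    low_oct: bool  # only interpreted when low_octa is True

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}")


@dataclass(frozen=True)
class DruseGrade:
    """Joint two-device classification of one druse."""

    sd_loss: bool
    sd_class: str  # none | ambiguous | unambiguous
    ss_loss: bool
    ss_class: str
    sd_false_positive: bool
    ss_false_positive: bool

    def __post_init__(self) -> None:
        for cls, loss in ((self.sd_class, self.sd_loss), (self.ss_class, self.ss_loss)):
            if cls not in ("none", "ambiguous", "unambiguous"):
                raise ValueError(f"unknown class {cls!r}")
            if (cls == "none") != (not loss):
                raise ValueError("class 'none' must coincide with no loss")
        if self.sd_false_positive and not (self.sd_class == "ambiguous" and not self.ss_loss):
            raise ValueError("SD false positive requires SD-ambiguous and no SS loss")
        if self.ss_false_positive and not (self.ss_class == "ambiguous" and not self.sd_loss):
            raise ValueError("SS false positive requires SS-ambiguous and no SD loss")


@dataclass(frozen=True)
class DeviceTally:
    n_loss: int
    pct_loss: float | None
    n_ambiguous: int
    pct_ambiguous: float | None  # of losses
    n_unambiguous: int
    pct_unambiguous: float | None  # of losses
    n_false_positive: int
    pct_false_positive: float | None  # of losses


@dataclass(frozen=True)
class CohortSummary:
    n_drusen: int
    sd: DeviceTally
    ss: DeviceTally


def round_pct(count: int, denom: int) -> float | None:
    """Percentage rounded half-up to 1 decimal; None when the denominator is 0."""
    if denom == 0:
        return None
    pct = Decimal(100 * int(count)) / Decimal(int(denom))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ----------------------------------------------------------------------
# reading en face slabs
# ----------------------------------------------------------------------

def _default_background(roi_union: np.ndarray, erosion_px: int) -> np.ndarray:
    bg = ~np.asarray(roi_union, dtype=bool)
    if erosion_px > 0:
        bg = ndimage.binary_erosion(bg, iterations=erosion_px)
    return bg


def _is_low(slab: np.ndarray, roi: np.ndarray, background: np.ndarray, reader: ReaderParams) -> bool:
    ref = float(np.median(slab[background]))
    low = slab[roi] < reader.low_pixel_factor * ref
    return bool(low.mean() >= reader.low_area_fraction)


def assess_roi(
    pair: EnFacePair,
    roi: np.ndarray,
    reader: ReaderParams = DEFAULT_READER,
    background: np.ndarray | None = None,
) -> DruseAssessment:
    """Automatic reading of one druse footprint on one device's slab pair.

    ``background`` is the reference region; by default the complement of the
    ROI eroded by ``background_erosion_px`` pixels (cohort-level calls pass
    the complement of *all* ROIs instead).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    if background is None:
        background = _default_background(roi, reader.background_erosion_px)
    background = np.asarray(background, dtype=bool)
    if not background.any():
        raise ValueError("background region is empty")
    low_octa = _is_low(pair.octa_slab, roi, background, reader)
    low_oct = _is_low(pair.oct_slab, roi, background, reader)
    return DruseAssessment(device=pair.device, low_octa=low_octa, low_oct=low_oct)


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

def _device_class(a: DruseAssessment) -> str:
    if not a.low_octa:
        return "none"
    return "ambiguous" if a.low_oct else "unambiguous"


def classify_druse(sd: DruseAssessment, ss: DruseAssessment) -> DruseGrade:
    """Joint grade from the two single-device assessments."""
    if sd.device != "SD840" or ss.device != "SS1050":
        raise ValueError(f"device mismatch: got ({sd.device}, {ss.device})")
    sd_class = _device_class(sd)
    ss_class = _device_class(ss)
    return DruseGrade(
        sd_loss=sd.low_octa,
        sd_class=sd_class,
        ss_loss=ss.low_octa,
        ss_class=ss_class,
        sd_false_positive=(sd_class == "ambiguous") and not ss.low_octa,
        ss_false_positive=(ss_class == "ambiguous") and not sd.low_octa,
    )


def _tally(grades: Sequence[DruseGrade], device: str) -> DeviceTally:
    if device == "SD840":
        losses = [g for g in grades if g.sd_loss]
        classes = [g.sd_class for g in losses]
        n_fp = sum(g.sd_false_positive for g in grades)
    else:
        losses = [g for g in grades if g.ss_loss]
        classes = [g.ss_class for g in losses]
        n_fp = sum(g.ss_false_positive for g in grades)
    n_loss = len(losses)
    n_amb = classes.count("ambiguous")
    n_unamb = classes.count("unambiguous")
    n = len(grades)
    return DeviceTally(
        n_loss=n_loss,
        pct_loss=round_pct(n_loss, n),
        n_ambiguous=n_amb,
        pct_ambiguous=round_pct(n_amb, n_loss),
        n_unambiguous=n_unamb,
        pct_unambiguous=round_pct(n_unamb, n_loss),
        n_false_positive=n_fp,
        pct_false_positive=round_pct(n_fp, n_loss),
    )


def aggregate(grades: Sequence[DruseGrade]) -> CohortSummary:
    """Study-level tallies; percentage denominators follow the reading protocol
    (losses out of all drusen; classes and false positives out of losses)."""
    return CohortSummary(
        n_drusen=len(grades),
        sd=_tally(grades, "SD840"),
        ss=_tally(grades, "SS1050"),
    )


# ----------------------------------------------------------------------
# interreader agreement
# ----------------------------------------------------------------------

def agreement(grades_a: Sequence, grades_b: Sequence) -> tuple[float, float]:
    """Percent agreement and Cohen's kappa between two readers' label lists.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with chance agreement ``p_e`` from the
    product of the two readers' marginal label frequencies.  Perfect observed
    agreement gives kappa = 1 regardless of the marginals (including the
    degenerate single-label case where ``1 - p_e = 0``).
    """
    if len(grades_a) != len(grades_b):
        raise ValueError("label lists must have equal length")
    n = len(grades_a)
    if n == 0:
        raise ValueError("label lists must be non-empty")
    matches = sum(a == b for a, b in zip(grades_a, grades_b))
    p_o = matches / n
    pct = 100.0 * p_o
    ca, cb = Counter(grades_a), Counter(grades_b)
    labels = set(ca) | set(cb)
    p_e = sum((ca[l] / n) * (cb[l] / n) for l in labels)
    if p_o == 1.0:
        return pct, 1.0
    kappa = (p_o - p_e) / (1.0 - p_e)
    return pct, float(kappa)


# ----------------------------------------------------------------------
# cohort pipeline and the reconstructed 23-druse reference cohort
# ----------------------------------------------------------------------

def grade_cohort(
    pairs_by_device: dict[str, EnFacePair],
    rois: Sequence[np.ndarray],
    reader: ReaderParams = DEFAULT_READER,
) -> tuple[list[DruseGrade], CohortSummary]:
    """Assess every druse ROI on both devices, classify, and aggregate."""
    for dev in DEVICES:
        if dev not in pairs_by_device:
            raise ValueError(f"missing en face pair for device {dev}")
    grades = []
    for dev in DEVICES:
        shape = pairs_by_device[dev].octa_slab.shape
        union = np.zeros(shape, dtype=bool)
        for roi in rois:
            if roi.shape != shape:
                raise ValueError("ROI grid does not match the slab grid")
            union |= roi
        pairs_by_device[dev].provenance.setdefault("n_rois", len(rois))
    backgrounds = {
        dev: _default_background(
            np.any([_as_bool(r) for r in rois], axis=0) if rois else
            np.zeros(pairs_by_device[dev].octa_slab.shape, bool),
            reader.background_erosion_px,
        )
        for dev in DEVICES
    }
    for roi in rois:
        sd = assess_roi(pairs_by_device["SD840"], roi, reader, backgrounds["SD840"])
        ss = assess_roi(pairs_by_device["SS1050"], roi, reader, backgrounds["SS1050"])
        grades.append(classify_druse(sd, ss))
    return grades, aggregate(grades)


def _as_bool(a) -> np.ndarray:
    return np.asarray(a, dtype=bool)


def grades_to_frame(grades: Sequence[DruseGrade]) -> pd.DataFrame:
    """Long-format per-druse table (one row per druse and device)."""
    rows = []
    for i, g in enumerate(grades, start=1):
        rows.append(
            dict(druse_id=i, device="SD840", loss=g.sd_loss, cls=g.sd_class,
                 false_positive=g.sd_false_positive)
        )
        rows.append(
            dict(druse_id=i, device="SS1050", loss=g.ss_loss, cls=g.ss_class,
                 false_positive=g.ss_false_positive)
        )
    return pd.DataFrame(rows)


def summary_to_frame(summary: CohortSummary) -> pd.DataFrame:
    rows = []
    for dev, t in (("SD840", summary.sd), ("SS1050", summary.ss)):
        rows.append(
            dict(
                device=dev,
                n_drusen=summary.n_drusen,
                n_loss=t.n_loss,
                pct_loss=t.pct_loss,
                n_ambiguous=t.n_ambiguous,
                pct_ambiguous=t.pct_ambiguous,
                n_unambiguous=t.n_unambiguous,
                pct_unambiguous=t.pct_unambiguous,
                n_false_positive=t.n_false_positive,
                pct_false_positive=t.pct_false_positive,
            )
        )
    return pd.DataFrame(rows)


def load_reference_cohort() -> pd.DataFrame:
    """The synthetic 23-druse grading table shipped with the package.

    A per-druse assignment consistent with the published study-level tallies
    (the study reports only the tallies, so one consistent per-druse table is
    fixed here; it is synthetic, not patient data).
    """
    with resources.files("drusenshadow.data").joinpath(
        "cohort23_synthetic.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    for col in ("sd_low_octa", "sd_low_oct", "ss_low_octa", "ss_low_oct"):
        df[col] = df[col].astype(bool)
    return df


def grades_from_assessments(df: pd.DataFrame) -> list[DruseGrade]:
    """Classify every row of a per-druse assessment table."""
    grades = []
    for _, row in df.iterrows():
        sd = DruseAssessment("SD840", bool(row["sd_low_octa"]), bool(row["sd_low_oct"]))
        ss = DruseAssessment("SS1050", bool(row["ss_low_octa"]), bool(row["ss_low_oct"]))
        grades.append(classify_druse(sd, ss))
    return grades
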