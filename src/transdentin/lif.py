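"""Micro laser-induced fluorescence (u-LIF) intensity-to-concentration workflow.

The measurement chain mirrors the laboratory procedure for tracking a
fluorescent dye (Rhodamine B) in a glass capillary: acquire a burst of
frames, average them into a mean image, calibrate fluorescence intensity
against a short series of standards of known concentration (0.05, 0.025 and
0.00 mg/L by convention, the zero standard fixing the background), and map
measured intensities back to concentrations over a physical region of
interest (ROI, 300x580 um by default).

At the low dye concentrations used, the intensity response is linear in
concentration (the quantum yield decreases only weakly with concentration),
so the calibration is a straight line; recovered values above the highest
calibrated standard are flagged rather than trusted.

Because no instrument is attached, the module also contains the synthetic
stack generator used throughout the tests: a linear intensity model plus
additive Gaussian sensor noise, with an axial concentration profile
broadcast across the transverse direction (diffusion in the capillary is
one-dimensional, so concentration is constant across the diameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityStack",
    "CalibrationCurve",
    "RegionOfInterest",
    "ConcentrationMeasurement",
    "mean_frame",
    "fit_calibration",
    "to_concentration",
    "synthesize_stack",
    "write_stack",
    "read_stack",
]


@dataclass(frozen=True)
class IntensityStack:
    """A burst of fluorescence frames.

    ``frames`` has shape (n_frames, height, width); intensities are in
    arbitrary units, finite and non-negative.  ``pixel_pitch`` is in
    micrometres per pixel.
    """

    frames: np.ndarray
    pixel_pitch: float = 10.0  # um / pixel
    frame_rate: float = 5.0  # Hz

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, H, W) array with >= 1 frame")
        if not np.all(np.isfinite(frames)) or np.any(frames < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangle in physical units (um).

    ``x`` runs along the capillary axis (image columns), ``y`` across it
    (rows).  Conversion to pixels floors to the fully enclosed rectangle.
    """

    x0: float = 0.0
    y0: float = 0.0
    width: float = 300.0
    height: float = 580.0

    def to_slices(self, pixel_pitch: float, shape: tuple) -> tuple:
        rows = slice(
            int(math.ceil(self.y0 / pixel_pitch)),
            int(math.floor((self.y0 + self.height) / pixel_pitch)),
        )
        cols = slice(
            int(math.ceil(self.x0 / pixel_pitch)),
            int(math.floor((self.x0 + self.width) / pixel_pitch)),
        )
        rows = slice(max(rows.start, 0), min(rows.stop, shape[0]))
        cols = slice(max(cols.start, 0), min(cols.stop, shape[1]))
        if rows.stop <= rows.start or cols.stop <= cols.start:
            raise ValueError("ROI does not enclose any whole pixel of the image")
        return rows, cols


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-concentration map ``I = slope*C + intercept``."""

    slope: float  # a.u. per (mg/L)
    intercept: float  # a.u., background at zero concentration
    residual: float  # RMS intensity residual of the fit
    concentrations: tuple = field(default_factory=tuple)  # standards, mg/L
    intensities: tuple = field(default_factory=tuple)  # ROI means, a.u.

    @property
    def max_calibrated(self) -> float:
        return max(self.concentrations) if self.concentrations else math.inf

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "residual": self.residual,
            "concentrations_mg_per_l": list(self.concentrations),
            "intensities_au": list(self.intensities),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            residual=d["residual"],
            concentrations=tuple(d.get("concentrations_mg_per_l", ())),
            intensities=tuple(d.get("intensities_au", ())),
        )


@dataclass(frozen=True)
class ConcentrationMeasurement:
    roi_mean: float  # mg/L
    concentration_map: np.ndarray  # mg/L, full mean-frame extent
    out_of_range: bool  # any ROI value above the highest calibrated standard


def mean_frame(stack: IntensityStack) -> np.ndarray:
    """Pixelwise mean over the burst (noise drops as 1/sqrt(n_frames))."""
    return stack.frames.mean(axis=0)


def _roi_mean(stack: IntensityStack, roi: RegionOfInterest) -> float:
    rows, cols = roi.to_slices(stack.pixel_pitch, stack.shape)
    return float(mean_frame(stack)[rows, cols].mean())


def fit_calibration(standards, roi: RegionOfInterest = RegionOfInterest()) -> CalibrationCurve:
    """Fit the calibration line through (concentration, ROI mean intensity).

    *standards* is an iterable of ``(concentration mg/L, IntensityStack)``
    pairs; at least two distinct concentrations are required.  The zero
    standard, when present, pins the background intercept.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    concentrations = np.array([c for c, _ in standards], dtype=float)
    if np.unique(concentrations).size < 2:
        raise ValueError("calibration standards must have distinct concentrations")
    intensities = np.array([_roi_mean(stack, roi) for _, stack in standards])
    slope, intercept = np.polyfit(concentrations, intensities, 1)
    fitted = slope * concentrations + intercept
    residual = float(np.sqrt(np.mean((fitted - intensities) ** 2)))
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        residual=residual,
        concentrations=tuple(concentrations.tolist()),
        intensities=tuple(intensities.tolist()),
    )


def to_concentration(
    stack: IntensityStack,
    curve: CalibrationCurve,
    roi: RegionOfInterest = RegionOfInterest(),
) -> ConcentrationMeasurement:
    """Invert the calibration on the stack's mean frame.

    ``C = (I - intercept)/slope`` clipped at zero; the ROI mean is the
    headline value.  Values above the highest calibrated standard set the
    ``out_of_range`` flag (the linear model is unverified there).
    """
    if curve.slope <= 0:
        raise ValueError(f"invalid calibration curve: slope {curve.slope} <= 0")
    image = mean_frame(stack)
    concentration_map = np.maximum((image - curve.intercept) / curve.slope, 0.0)
    rows, cols = roi.to_slices(stack.pixel_pitch, stack.shape)
    patch = concentration_map[rows, cols]
    return ConcentrationMeasurement(
        roi_mean=float(patch.mean()),
        concentration_map=concentration_map,
        out_of_range=bool(np.any(patch > curve.max_calibrated * (1 + 1e-9))),
    )


def synthesize_stack(
    concentration,
    slope: float,
    intercept: float,
    n_frames: int = 20,
    noise_sigma: float = 0.0,
    seed=None,
    shape: tuple = (58, 30),
    pixel_pitch: float = 10.0,
    frame_rate: float = 5.0,
) -> IntensityStack:
    """Generate a synthetic burst with the linear sensor model.

    *concentration* (mg/L) is a scalar for a homogeneous field or a 1-D axial
    profile of length ``shape[1]`` broadcast down the image columns (the
    transverse direction carries no concentration variation).  Noise is
    additive Gaussian per pixel per frame with standard deviation
    ``noise_sigma`` in intensity units; generation is deterministic for a
    fixed seed.  Intensities are floored at zero, as a sensor's output is.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    concentration = np.asarray(concentration, dtype=float)
    if concentration.ndim == 0:
        base = np.full(shape, float(concentration))
    elif concentration.ndim == 1:
        if concentration.size != shape[1]:
            raise ValueError(
                f"axial profile length {concentration.size} != image width {shape[1]}"
            )
        base = np.broadcast_to(concentration, shape).copy()
    else:
        raise ValueError("concentration must be scalar or a 1-D axial profile")
    clean = slope * base + intercept
    rng = np.random.default_rng(seed)
    frames = clean[None, :, :] + rng.normal(0.0, noise_sigma, (n_frames, *shape)) if (
        noise_sigma > 0
    ) else np.repeat(clean[None, :, :], n_frames, axis=0)
    frames = np.maximum(frames, 0.0)
    return IntensityStack(frames=frames, pixel_pitch=pixel_pitch, frame_rate=frame_rate)


def run_synthetic_profile_experiment(
    truth_concentrations,
    slope: float = 1000.0,
    intercept: float = 5.0,
    standards: tuple = (0.05, 0.025, 0.0),
    n_frames: int = 20,
    noise_fraction: float = 0.02,
    seed: int = 0,
    roi: RegionOfInterest = RegionOfInterest(),
    shape: tuple = (58, 30),
):
    """Full synthetic measurement campaign for a known axial profile.

    Emulates the laboratory layout: one burst per axial location (the
    microscope is translated between bursts, so each location yields its own
    stack with the locally uniform concentration), a calibration series at
    the standard concentrations, and ROI-mean recovery of every location.
    ``noise_fraction`` sets the additive noise sigma as a fraction of the
    intensity dynamic range spanned by the standards.

    Returns ``(recovered, curve)``: the recovered concentrations (mg/L, one
    per location) and the fitted :class:`CalibrationCurve`.
    """
    truth = np.asarray(truth_concentrations, dtype=float)
    noise_sigma = noise_fraction * slope * (max(standards) - min(standards))
    rng = np.random.default_rng(seed)

    def burst(concentration):
        return synthesize_stack(
            concentration,
            slope,
            intercept,
            n_frames=n_frames,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31)),
            shape=shape,
        )

    curve = fit_calibration([(c, burst(c)) for c in standards], roi)
    recovered = np.array(
        [to_concentration(burst(c), curve, roi).roi_mean for c in truth]
    )
    return recovered, curve


def write_stack(path, stack: IntensityStack) -> None:
    """Write the burst as a multi-page 32-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, stack.frames.astype(np.float32))


def read_stack(path, pixel_pitch: float = 10.0, frame_rate: float = 5.0) -> IntensityStack:
    import tifffile

    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    return IntensityStack(frames=frames, pixel_pitch=pixel_pitch, frame_rate=frame_rate)
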