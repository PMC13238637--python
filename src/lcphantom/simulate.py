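"""Synthetic fluoroscopic frame generation and uncompressed DICOM I/O.

The signal chain is deliberately minimal: the spectrum-weighted transmission
through the local material path length sets the expected detected quanta per
pixel, quantum noise is Poisson, detector blur is a single Gaussian PSF, the
readout applies an affine gain/offset plus Gaussian electronic noise, and the
result is clipped and quantized to the detector bit depth.  Automatic
exposure control, scatter, grids and vendor denoising are not modelled; their
aggregate effect is folded into the gain/noise knobs.  Holes render brighter
than the background (pixel value tracks detected quanta), so the CNR of a
hole is positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from scipy import ndimage

from .geometry import PhantomModel, ThicknessMap, rasterize
from .materials import Material
from .spectrum import BeamQuality, generate_spectrum

__all__ = [
    "DetectorModel",
    "AcquisitionConfig",
    "SyntheticFrame",
    "DEFAULT_KERMA_RATES",
    "expected_quanta_map",
    "simulate_frame",
    "write_dicom",
    "read_dicom",
]

#: Air kerma rates (uGy/min) measured at the phantom entrance for Q1-Q3.
DEFAULT_KERMA_RATES = {"Q1": 73.0, "Q2": 78.0, "Q3": 66.0}

#: Detected quanta per uGy per pixel; calibrated so that the default Q1
#: acquisition (73 uGy/min, 1 s) yields a background CNR of about 1 at the
#: 1.0-mm hole of the central LC module.  A free calibration knob, not a
#: physical claim.
DEFAULT_QUANTA_PER_KERMA_PIXEL = 95.0


@dataclass(frozen=True)
class DetectorModel:
    """Abstracted image-intensifier/flat-panel chain."""

    pixel_pitch: float = 0.25        # mm
    gain: float = 8.0                # pixel-value units per detected quantum
    offset: float = 50.0             # pixel-value units
    blur_sigma: float = 0.3          # mm, Gaussian PSF proxy
    electronic_noise_sd: float = 2.0  # pixel-value units
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.blur_sigma < 0 or self.electronic_noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.bit_depth not in (12, 16):
            raise ValueError("bit_depth must be 12 or 16")


@dataclass(frozen=True)
class AcquisitionConfig:
    """One exposure: beam, dose rate, integration time and seeding."""

    beam: BeamQuality
    air_kerma_rate: float            # uGy/min at the phantom surface
    exposure_time: float = 1.0       # s
    quanta_per_kerma_pixel: float = DEFAULT_QUANTA_PER_KERMA_PIXEL
    seed: int = 0
    quantum_noise: bool = True

    def __post_init__(self) -> None:
        if self.air_kerma_rate <= 0 or self.exposure_time <= 0:
            raise ValueError("air_kerma_rate and exposure_time must be positive")

    @property
    def open_beam_quanta(self) -> float:
        """Expected detected quanta in a zero-thickness pixel."""
        return (
            self.air_kerma_rate / 60.0 * self.exposure_time * self.quanta_per_kerma_pixel
        )


@dataclass(frozen=True)
class SyntheticFrame:
    """A simulated fluoroscopic frame plus acquisition metadata."""

    pixels: np.ndarray = field(repr=False)
    pixel_pitch: float
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Plate-frame (x, y) coordinates (mm) of pixel centres."""
        rows, cols = self.pixels.shape
        half_x, half_y = cols * self.pixel_pitch / 2, rows * self.pixel_pitch / 2
        x = (np.arange(cols) + 0.5) * self.pixel_pitch - half_x
        y = half_y - (np.arange(rows) + 0.5) * self.pixel_pitch
        return x, y


def _transmission_lut(material: Material, beam: BeamQuality, thicknesses_mm: np.ndarray):
    """Spectrum-weighted transmission for each unique path length."""
    s = generate_spectrum(beam)
    mu = material.linear_attenuation(s.grid.centers)  # 1/cm
    total = np.sum(s.fluence)
    t_cm = thicknesses_mm[:, np.newaxis] / 10.0
    return np.sum(s.fluence[np.newaxis, :] * np.exp(-mu[np.newaxis, :] * t_cm), axis=1) / total


def expected_quanta_map(
    tmap: ThicknessMap, beam: BeamQuality, acq: AcquisitionConfig, material: Material
) -> np.ndarray:
    """Per-pixel mean detected quanta through the thickness map."""
    uniq, inverse = np.unique(tmap.grid, return_inverse=True)
    trans = _transmission_lut(material, beam, uniq)
    return acq.open_beam_quanta * trans[inverse].reshape(tmap.grid.shape)


def simulate_frame(
    phantom: PhantomModel,
    det: DetectorModel,
    acq: AcquisitionConfig,
    image_size: int | None = None,
) -> SyntheticFrame:
    """Simulate one frame of a phantom; bit-identical for a fixed seed."""
    if image_size is None:
        image_size = max(512, int(np.ceil(phantom.outer_diameter / det.pixel_pitch)) + 32)
    tmap = rasterize(phantom, det.pixel_pitch, image_size)
    q = expected_quanta_map(tmap, acq.beam, acq, phantom.material)

    rng = np.random.default_rng(acq.seed)
    img = rng.poisson(q).astype(float) if acq.quantum_noise else q.copy()
    if det.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=det.blur_sigma / det.pixel_pitch)
    img = det.gain * img + det.offset
    if det.electronic_noise_sd > 0:
        img = img + rng.normal(0.0, det.electronic_noise_sd, img.shape)

    vmax = 2**det.bit_depth - 1
    saturated = np.sum(img[tmap.fov_mask] > vmax)
    if saturated > 0.01 * tmap.fov_mask.sum():
        warnings.warn(
            f"{saturated} in-field pixels ({100 * saturated / tmap.fov_mask.sum():.1f}%) "
            f"saturate the {det.bit_depth}-bit range",
            RuntimeWarning,
            stacklevel=2,
        )
    pixels = np.clip(np.rint(img), 0, vmax).astype(np.uint16)
    meta = {
        "phantom": phantom.name,
        "beam": acq.beam.name,
        "kvp": acq.beam.kvp,
        "seed": acq.seed,
        "air_kerma_rate_uGy_min": acq.air_kerma_rate,
        "exposure_time_s": acq.exposure_time,
        "quanta_per_kerma_pixel": acq.quanta_per_kerma_pixel,
        "bit_depth": det.bit_depth,
    }
    return SyntheticFrame(pixels=pixels, pixel_pitch=det.pixel_pitch, metadata=meta)


def write_dicom(frame: SyntheticFrame, path) -> None:
    """Write a frame as uncompressed explicit-little-endian grayscale DICOM."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    # UID derived from the frame metadata: reruns are bit-identical
    meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[json.dumps(frame.metadata, sort_keys=True)]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RF"
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = frame.metadata.get("phantom", "phantom")
    ds.Rows, ds.Columns = frame.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = int(frame.metadata.get("bit_depth", 16))
    ds.HighBit = ds.BitsStored - 1
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [frame.pixel_pitch, frame.pixel_pitch]
    if "kvp" in frame.metadata:
        ds.KVP = str(frame.metadata["kvp"])
    ds.ImageComments = json.dumps(frame.metadata)
    ds.PixelData = np.ascontiguousarray(frame.pixels, dtype=np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dicom(path) -> SyntheticFrame:
    """Read a frame written by :func:`write_dicom` (or any compatible file)."""
    ds = pydicom.dcmread(path)
    if ds.file_meta.TransferSyntaxUID.is_compressed:
        raise ValueError("compressed DICOM transfer syntaxes are not supported")
    if ds.SamplesPerPixel != 1 or not str(ds.PhotometricInterpretation).startswith(
        "MONOCHROME"
    ):
        raise ValueError("only grayscale (MONOCHROME) frames are supported")
    try:
        metadata = json.loads(getattr(ds, "ImageComments", "") or "{}")
    except json.JSONDecodeError:
        metadata = {}
    metadata.setdefault("bit_depth", int(ds.BitsStored))
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    return SyntheticFrame(
        pixels=ds.pixel_array.copy(),
        pixel_pitch=float(spacing[0]),
        metadata=metadata,
    )
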