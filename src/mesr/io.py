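"""Reading and writing of images, sinograms and phantom parameter tables.

Float images travel as NPZ; 8-bit/16-bit image files (PNG/TIFF) go through
imageio with an affine intensity mapping recorded nowhere — image files are a
display/interchange format here, NPZ is the lossless one.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .phantoms import EllipseSpec, to_display_range
from .tomography import RingAcquisition, Sinogram

__all__ = [
    "read_image",
    "write_image",
    "save_sinogram",
    "load_sinogram",
    "save_ring_acquisition",
    "load_ring_acquisition",
    "write_ellipse_table",
    "read_ellipse_table",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as float64 (NPZ key ``image``, else imageio)."""
    path = Path(path)
    if path.suffix == ".npz":
        return np.asarray(np.load(path)["image"], dtype=float)
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an image: NPZ losslessly, PNG/TIFF as 16-bit display-mapped."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.suffix == ".npz":
        np.savez_compressed(path, image=image)
        return
    scaled = to_display_range(image) / 255.0 * 65535.0
    iio.imwrite(path, np.round(scaled).astype(np.uint16))


def save_sinogram(path: str | Path, sino: Sinogram) -> None:
    np.savez_compressed(
        path,
        values=sino.values,
        angles_deg=sino.angles_deg,
        radial_offsets=sino.radial_offsets,
    )


def load_sinogram(path: str | Path) -> Sinogram:
    z = np.load(path)
    return Sinogram(z["values"], z["angles_deg"], z["radial_offsets"])


def save_sinogram_csv(path: str | Path, sino: Sinogram) -> None:
    """CSV export: first column the angle (deg), remaining columns g(theta, r)
    at the radial offsets given in the header row."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["angle_deg"] + [f"{r:.6g}" for r in sino.radial_offsets])
        for th, row in zip(sino.angles_deg, sino.values):
            w.writerow([f"{th:.6g}"] + [repr(v) for v in row])


def save_ring_acquisition(path: str | Path, acq: RingAcquisition) -> None:
    np.savez_compressed(path, amplitudes=acq.amplitudes, ring_radius=acq.ring_radius)


def load_ring_acquisition(path: str | Path) -> RingAcquisition:
    z = np.load(path)
    return RingAcquisition(z["amplitudes"], ring_radius=float(z["ring_radius"]))


_TABLE_HEADER = ["N0", "x0", "y0", "a", "b", "phi", "rho"]


def write_ellipse_table(path: str | Path, specs: list[EllipseSpec]) -> None:
    """CSV export of an ellipse phantom parameter table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TABLE_HEADER)
        for i, s in enumerate(specs, start=1):
            w.writerow([i, s.x0, s.y0, s.a, s.b, s.phi_deg, s.rho])


def read_ellipse_table(path: str | Path) -> list[EllipseSpec]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        EllipseSpec(
            float(r["x0"]), float(r["y0"]), float(r["a"]),
            float(r["b"]), float(r["phi"]), float(r["rho"]),
        )
        for r in rows
    ]
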