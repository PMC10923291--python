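"""Dispersion-index analysis of 16-bit fluorescence images.

Settled condensate droplets show up as bright regions on a dim background,
inflating the variance-to-mean ratio of pixel intensities.  The dispersion
index DI = sigma^2 / mu (population variance over mean of all pixels) is
~1 for a homogeneous Poisson-limited image and >> 1 once droplets appear;
fitted against total protein concentration with the shared logistic
machinery it yields the experimental saturation concentration phi_exp.

Images enter as 16-bit grayscale TIFFs plus a manifest CSV
(path, concentration_uM, z_um, replicate); only surface planes (lowest
z per stack) are analyzed.  No background subtraction or saturation
masking is applied; a warning is emitted when more than 0.1% of pixels
sit at the 16-bit ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .saturation import SaturationModel, SaturationResults

N_IMAGES_PER_POINT = 15  # replicate images per concentration point

SATURATION_CEILING = 65535
SATURATION_WARN_FRACTION = 1e-3


@dataclass
class ImageRecord:
    """One acquired (or synthesized) 16-bit grayscale image with its
    grouping metadata."""

    pixels: np.ndarray
    concentration_uM: float
    z_um: float = 0.0
    replicate: int = 0
    channel: str = "fluorescence"
    path: str | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise ValueError("empty image")
        if px.min() < 0 or px.max() > SATURATION_CEILING:
            raise ValueError("pixel values outside the 16-bit range [0, 65535]")
        self.pixels = px


@dataclass(frozen=True)
class DIMeasurement:
    """Pixel-intensity mean, population variance, and their ratio."""

    mean: float
    variance: float

    @property
    def di(self) -> float:
        return self.variance / self.mean


def dispersion_index(image) -> DIMeasurement:
    """Dispersion index sigma^2/mu over all pixels of a 16-bit image.

    Population variance (divide by the pixel count).  A constant image has
    DI = 0; an all-zero image has no defined DI and raises.
    """
    px = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    if px.size == 0:
        raise ValueError("empty image")
    data = px.astype(np.float64)
    mu = float(data.mean())
    if mu == 0:
        raise ValueError("all-zero image: dispersion index undefined (mean = 0)")
    sat = float((px == SATURATION_CEILING).mean())
    if sat > SATURATION_WARN_FRACTION:
        warnings.warn(
            f"{sat:.2%} of pixels are intensity-saturated at {SATURATION_CEILING}"
        )
    return DIMeasurement(mean=mu, variance=float(data.var()))


@dataclass
class DISeries:
    """Per-concentration dispersion-index measurements."""

    data: dict[float, list[DIMeasurement]] = field(default_factory=dict)

    def concentrations(self) -> list[float]:
        return sorted(self.data)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"concentration_uM": c, "replicate": i, "mean": m.mean,
             "variance": m.variance, "DI": m.di}
            for c in self.concentrations()
            for i, m in enumerate(self.data[c])
        ]
        return pd.DataFrame(rows)

    def to_mapping(self) -> dict[float, list[float]]:
        return {c: [m.di for m in vals] for c, vals in self.data.items()}


def build_di_series(records, strict: bool = False,
                    n_expected: int = N_IMAGES_PER_POINT) -> DISeries:
    """Group fluorescence images by concentration and compute DI on the
    surface plane of each stack.

    The surface plane is the lowest z tag within each (concentration,
    replicate) stack — settled droplets live at z ~ 0 — so off-surface
    planes are discarded.  A concentration with a replicate count other
    than ``n_expected`` warns (raises in strict mode).
    """
    surface: dict[tuple[float, int], ImageRecord] = {}
    for rec in records:
        if rec.channel != "fluorescence":
            continue
        key = (float(rec.concentration_uM), int(rec.replicate))
        if key not in surface or rec.z_um < surface[key].z_um:
            surface[key] = rec
    series = DISeries()
    for (c, _rep), rec in sorted(surface.items()):
        series.data.setdefault(c, []).append(dispersion_index(rec))
    for c, vals in series.data.items():
        if len(vals) != n_expected:
            msg = (f"concentration {c} uM has {len(vals)} surface images "
                   f"(expected {n_expected})")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
    return series


def estimate_phi_exp(series: DISeries, B: int = 5000, seed=None,
                     per_point_n: int | None = None) -> SaturationResults:
    """Saturation concentration phi_exp (uM) from a DI series.

    Fits the logistic to all per-image DI values and bootstraps phi over
    per-concentration resamples.  A flat or right-censored series returns
    ``success=False`` with the reason (e.g. not fittable up to the maximum
    measured concentration).
    """
    model = SaturationModel.from_series(series.to_mapping(), value_kind="DI")
    res = model.fit()
    if res.success and B:
        res.bootstrap(B=B, per_point_n=per_point_n, seed=seed)
    return res


def read_manifest(manifest_csv, root=None) -> list[ImageRecord]:
    """Load images listed in a manifest CSV with columns
    (path, concentration_uM, z_um, replicate)."""
    import tifffile

    manifest_csv = Path(manifest_csv)
    root = Path(root) if root is not None else manifest_csv.parent
    df = pd.read_csv(manifest_csv)
    records = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = root / p
        px = tifffile.imread(p)
        records.append(
            ImageRecord(
                pixels=px,
                concentration_uM=float(row["concentration_uM"]),
                z_um=float(row.get("z_um", 0.0)),
                replicate=int(row.get("replicate", 0)),
                path=str(p),
            )
        )
    return records
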