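"""Synthetic abdominal-CT phantom: body, spine, two kidneys, optional cysts.

Slices are drawn in Hounsfield units on a uniform pixel grid. Geometry
follows radiological display: the patient's anatomical left appears on the
image right, so the kidney at columns greater than the spine column carries
side label 1 (anatomical left) and the image-left kidney carries label 2
(anatomical right). Ground-truth masks and ellipsoid volumes are known
analytically, which makes the phantom usable as an oracle for the
segmentation metrics and for kidney volumetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "PhantomSample", "generate_slice", "generate_series"]

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic slice generator.

    All lengths are in millimetres. ``kidney_semiaxes_mm`` are the (a, b, c)
    semi-axes of each kidney ellipsoid: a across columns, b across rows and
    c along the slice axis.
    """

    image_size: int = 256
    pixel_spacing_mm: float = 0.625
    slice_thickness_mm: float = 1.0
    inter_slice_mm: float = 1.0
    body_hu: float = 40.0
    spine_hu: float = 700.0
    kidney_hu: float = 30.0
    cyst_hu: float = 10.0
    noise_sd_hu: float = 0.0
    n_cysts_per_kidney: int = 0
    kidney_semiaxes_mm: tuple[float, float, float] = (20.0, 15.0, 30.0)
    kidney_offset_frac: float = 0.28
    jitter_px: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        for name in ("pixel_spacing_mm", "slice_thickness_mm", "inter_slice_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(s <= 0 for s in self.kidney_semiaxes_mm):
            raise ValueError("kidney semi-axes must be strictly positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if self.n_cysts_per_kidney < 0:
            raise ValueError("n_cysts_per_kidney must be non-negative")
        hus = {self.body_hu, self.spine_hu, self.kidney_hu, self.cyst_hu, AIR_HU}
        if len(hus) != 5:
            raise ValueError("body/spine/kidney/cyst/air HU values must be distinct")
        self._check_geometry()

    @classmethod
    def scaled(cls, image_size: int, reference_size: int = 256,
               reference_spacing_mm: float = 0.625, **overrides) -> "PhantomSpec":
        """Spec with the acquisition field of view (160 mm at the reference
        512->256 resampled grid) preserved at a different grid size, so the
        same anatomy fits coarse test images."""
        spacing = reference_spacing_mm * reference_size / image_size
        return cls(image_size=image_size, pixel_spacing_mm=spacing, **overrides)

    # -- geometry ------------------------------------------------------
    @property
    def center(self) -> tuple[float, float]:
        """(row, col) of the grid centre, symmetric under horizontal flip."""
        c = (self.image_size - 1) / 2.0
        return c, c

    @property
    def spine_column(self) -> int:
        return self.image_size // 2

    @property
    def body_semiaxes_px(self) -> tuple[float, float]:
        return 0.35 * self.image_size, 0.45 * self.image_size  # (row, col)

    @property
    def spine_semiaxes_px(self) -> tuple[float, float]:
        return 0.055 * self.image_size, 0.045 * self.image_size

    @property
    def kidney_semiaxes_px(self) -> tuple[float, float]:
        a, b, _ = self.kidney_semiaxes_mm
        return b / self.pixel_spacing_mm, a / self.pixel_spacing_mm  # (row, col)

    def kidney_centers_px(self) -> list[tuple[float, float]]:
        """Centres [(row, col) image-right/anatomical-left, image-left]."""
        crow, ccol = self.center
        off = self.kidney_offset_frac * self.image_size
        return [(crow, ccol + off), (crow, ccol - off)]

    def _check_geometry(self):
        kr, kc = self.kidney_semiaxes_px
        br, bc = self.body_semiaxes_px
        sr, sc = self.spine_semiaxes_px
        crow, ccol = self.center
        margin = self.jitter_px + 1.0
        for row, col in self.kidney_centers_px():
            # kidney inside body ellipse (conservative bounding-box check)
            if (abs(row - crow) + kr + margin > br
                    or abs(col - ccol) + kc + margin > bc):
                raise ValueError("kidney ellipse does not fit inside the body")
            # kidney clear of the spine
            if abs(col - ccol) - kc - margin < sc:
                raise ValueError("kidney ellipse overlaps the spine")


@dataclass
class PhantomSample:
    """One synthetic slice: HU image, binary kidney mask and side labels."""

    image: np.ndarray
    mask: np.ndarray
    side_labels: np.ndarray
    spine_column: int
    z_position_mm: float = 0.0

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.array_equal(self.mask, self.side_labels > 0):
            raise ValueError("mask must equal (side_labels > 0)")


def _ellipse_mask(size: int, center: tuple[float, float],
                  semiaxes: tuple[float, float]) -> np.ndarray:
    rows, cols = np.ogrid[:size, :size]
    r0, c0 = center
    ar, ac = semiaxes
    return ((rows - r0) / ar) ** 2 + ((cols - c0) / ac) ** 2 <= 1.0


def _place_cysts(rng: np.random.Generator, n: int, center, semiaxes,
                 size: int) -> np.ndarray:
    """Disks of radius ~ 0.2*min(semiaxes), centres drawn inside the kidney
    scaled so the full disk stays inside the ellipse."""
    out = np.zeros((size, size), dtype=bool)
    ar, ac = semiaxes
    radius = 0.2 * min(ar, ac)
    shrink = 1.0 - radius / min(ar, ac) - 0.05
    for _ in range(n):
        while True:
            u = rng.uniform(-1, 1, size=2)
            if u @ u <= 1.0:
                break
        cr = center[0] + u[0] * ar * shrink
        cc = center[1] + u[1] * ac * shrink
        out |= _ellipse_mask(size, (cr, cc), (radius, radius))
    return out


def _render(spec: PhantomSpec, rng: np.random.Generator,
            kidney_semiaxes_px: tuple[float, float] | None,
            z_position_mm: float = 0.0) -> PhantomSample:
    size = spec.image_size
    image = np.full((size, size), AIR_HU)
    image[_ellipse_mask(size, spec.center, spec.body_semiaxes_px)] = spec.body_hu

    side_labels = np.zeros((size, size), dtype=np.uint8)
    centers = spec.kidney_centers_px()
    if spec.jitter_px > 0:
        jit = rng.uniform(-spec.jitter_px, spec.jitter_px, size=(2, 2))
        centers = [(r + j[0], c + j[1]) for (r, c), j in zip(centers, jit)]
    else:
        rng.uniform(size=(2, 2))  # keep the stream aligned across settings
    if kidney_semiaxes_px is not None:
        for label, center in zip((1, 2), centers):
            kmask = _ellipse_mask(size, center, kidney_semiaxes_px)
            image[kmask] = spec.kidney_hu
            side_labels[kmask] = label
            if spec.n_cysts_per_kidney:
                cysts = _place_cysts(rng, spec.n_cysts_per_kidney, center,
                                     kidney_semiaxes_px, size) & kmask
                image[cysts] = spec.cyst_hu

    image[_ellipse_mask(size, spec.center, spec.spine_semiaxes_px)] = spec.spine_hu

    if spec.noise_sd_hu > 0:
        image = image + rng.normal(0.0, spec.noise_sd_hu, size=image.shape)

    return PhantomSample(image=image, mask=side_labels > 0,
                         side_labels=side_labels,
                         spine_column=spec.spine_column,
                         z_position_mm=z_position_mm)


def generate_slice(spec: PhantomSpec,
                   rng: np.random.Generator | int | None = None) -> PhantomSample:
    """Generate one 2-D phantom slice through the kidney equators.

    Deterministic given the spec seed (or an explicit generator). Cysts are
    low-attenuation disks fully inside the kidneys and are *included* in the
    binary kidney mask.
    """
    rng = _as_rng(rng, spec.seed)
    return _render(spec, rng, spec.kidney_semiaxes_px)


def generate_series(spec: PhantomSpec, n_slices: int,
                    rng: np.random.Generator | int | None = None
                    ) -> list[PhantomSample]:
    """Generate parallel slices through two 3-D kidney ellipsoids.

    Slices are spaced ``inter_slice_mm`` apart, centred on the kidney
    equator (z = 0). The per-slice kidney cross-section at height z has
    in-plane semi-axes scaled by sqrt(1 - (z/c)^2); outside |z| < c the
    slice has an empty mask. Each sample's ``z_position_mm`` is recorded.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = _as_rng(rng, spec.seed)
    a, b, c = spec.kidney_semiaxes_mm
    z0 = -(n_slices - 1) / 2.0 * spec.inter_slice_mm
    samples = []
    for i in range(n_slices):
        z = z0 + i * spec.inter_slice_mm
        if abs(z) < c:
            s = np.sqrt(1.0 - (z / c) ** 2)
            semiaxes_px = (s * b / spec.pixel_spacing_mm,
                           s * a / spec.pixel_spacing_mm)
        else:
            semiaxes_px = None
        samples.append(_render(spec, rng, semiaxes_px, z_position_mm=z))
    return samples


def analytic_kidney_volume_mm3(spec: PhantomSpec) -> float:
    """Closed-form volume of ONE kidney ellipsoid, 4/3*pi*a*b*c."""
    a, b, c = spec.kidney_semiaxes_mm
    return 4.0 / 3.0 * np.pi * a * b * c


def _as_rng(rng, seed: int) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(seed)
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng
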