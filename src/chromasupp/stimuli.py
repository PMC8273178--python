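"""Stimulus generation and photometric measurement for both experiments.

All stimuli are rasterised as physical images: a luminance plane in cd/m^2
plus CIE 1931 (x, y) chromaticity planes, with display geometry metadata.

Imaging experiment: ten Munsell patches (3.0 deg, 15 arcmin black fringe)
on a 12.4 deg ring over an achromatic ellipse texture (600 ellipses,
3.3 x 1.8 deg, eight luminance levels), with a scrambled counterpart made
by permuting pixel locations.  A control variant puts the patches on a
uniformly black background.

Psychophysics: a vertical achromatic grating (0.67 c/deg) under a
decremental exponential contrast envelope (1/e at 3.75 deg) with the same
patch ring overlaid, plus a square-texture mask.

Rendering is a pure function of (spec, seed): identical inputs give
bit-identical images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .munsell import (
    D65_WHITE,
    MunsellChip,
    chip_set,
    parse_chroma_condition,
    white_luminance_for_value5,
)

__all__ = [
    "DisplayGeometry",
    "PatchPatternSpec",
    "TextureSpec",
    "GratingSpec",
    "StimulusImage",
    "FMRI_DISPLAY",
    "PSYCHO_DISPLAY",
    "render_patch_pattern",
    "render_texture",
    "render_grating",
    "scramble",
    "measure_michelson",
    "save_stimulus",
    "load_stimulus",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Screen geometry: viewing distance, angular size, pixel resolution."""

    viewing_distance_cm: float
    screen_deg: tuple  # (width, height) in degrees of visual angle
    resolution: tuple  # (width, height) in pixels

    def __post_init__(self):
        if self.viewing_distance_cm <= 0 or min(self.screen_deg) <= 0 \
                or min(self.resolution) <= 0:
            raise ValueError("display geometry fields must be strictly positive")

    @property
    def px_per_deg(self) -> tuple:
        return (self.resolution[0] / self.screen_deg[0],
                self.resolution[1] / self.screen_deg[1])

    def pixel_grid_deg(self) -> tuple:
        """Pixel-center coordinates in degrees, origin at screen center.

        Returns (X, Y) arrays of shape (height, width); x grows rightward,
        y upward.  The linear small-angle degree<->pixel map is invertible.
        """
        w, h = self.resolution
        ppx, ppy = self.px_per_deg
        x = (np.arange(w) + 0.5 - w / 2) / ppx
        y = (h / 2 - (np.arange(h) + 0.5)) / ppy
        return np.meshgrid(x, y)


#: Projector geometry of the imaging experiment.
FMRI_DISPLAY = DisplayGeometry(69.0, (31.5, 25.2), (1280, 1024))
#: CRT geometry of the psychophysical experiment (vertical resolution chosen
#: to give square pixels at the stated angular size).
PSYCHO_DISPLAY = DisplayGeometry(54.4, (31.5, 23.6), (1280, 959))

#: Luminance of the uniformly black control background (cd/m^2).
BLACK_LEVEL = 0.05

#: Default eight-level ellipse-texture luminances: equally spaced over the
#: printed range (endpoints included).
ELLIPSE_LEVELS = tuple(np.linspace(0.23, 30.24, 8))
#: Eight-level square-mask luminances of the psychophysical experiment.
MASK_LEVELS = tuple(np.linspace(0.32, 30.37, 8))


@dataclass(frozen=True)
class PatchPatternSpec:
    """Ring of ten Munsell patches over a textured or black background."""

    n_patches: int = 10
    circle_diameter_deg: float = 12.4
    patch_diameter_deg: float = 3.0
    fringe_width_arcmin: float = 15.0
    rotation_jitter_deg: tuple = (-12.0, 0.0, 12.0)
    chroma_condition: str = "/0"
    background: str = "texture"  # "texture" | "black"
    value5_luminance: float = 16.0
    fixation_size_deg: float = 0.3  # white central fixation rectangle
    fixation_luminance: float = 30.24

    def __post_init__(self):
        parse_chroma_condition(self.chroma_condition)
        if self.background not in ("texture", "black"):
            raise ValueError(f"background must be 'texture' or 'black', "
                             f"got {self.background!r}")


@dataclass(frozen=True)
class TextureSpec:
    """Achromatic texture: random ellipses (background) or square tiling (mask)."""

    element_shape: str = "ellipse"  # "ellipse" | "square"
    element_size_deg: tuple = (3.3, 1.8)
    n_elements: int = 600
    luminance_levels: tuple = ELLIPSE_LEVELS

    def __post_init__(self):
        if self.element_shape not in ("ellipse", "square"):
            raise ValueError(f"unknown element shape {self.element_shape!r}")
        if len(self.luminance_levels) != 8:
            raise ValueError(
                f"texture requires exactly 8 luminance levels, "
                f"got {len(self.luminance_levels)}"
            )

    @classmethod
    def fmri_background(cls) -> "TextureSpec":
        return cls()

    @classmethod
    def psycho_mask(cls) -> "TextureSpec":
        return cls(element_shape="square", element_size_deg=(1.5, 1.5),
                   n_elements=0, luminance_levels=MASK_LEVELS)


@dataclass(frozen=True)
class GratingSpec:
    """Enveloped vertical grating with an optional patch-ring overlay."""

    spatial_frequency_cpd: float = 0.67
    envelope_decay_deg: float = 3.75   # radius of 1/e contrast decline
    mean_luminance: float = 19.8
    max_michelson_contrast: float = 0.50
    overlay: "PatchPatternSpec | None" = field(
        default_factory=lambda: PatchPatternSpec(
            background="black", value5_luminance=19.8)
    )

    def __post_init__(self):
        if not 0.0 <= self.max_michelson_contrast < 1.0:
            raise ValueError("contrast must lie in [0, 1)")


@dataclass
class StimulusImage:
    """Rasterised stimulus: luminance + chromaticity planes + provenance."""

    luminance: np.ndarray        # cd/m^2, shape (H, W)
    chroma_x: np.ndarray
    chroma_y: np.ndarray
    geometry: DisplayGeometry
    provenance: dict
    masks: dict = field(default_factory=dict)  # named boolean regions

    def __post_init__(self):
        if np.any(self.luminance < 0):
            raise ValueError("luminances must be non-negative")


def _spec_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _blank(geometry: DisplayGeometry, luminance: float = 0.0) -> StimulusImage:
    w, h = geometry.resolution
    return StimulusImage(
        luminance=np.full((h, w), luminance, float),
        chroma_x=np.full((h, w), D65_WHITE[0]),
        chroma_y=np.full((h, w), D65_WHITE[1]),
        geometry=geometry,
        provenance={},
    )


def render_texture(
    spec: TextureSpec,
    seed: int,
    geometry: DisplayGeometry = FMRI_DISPLAY,
    region: "np.ndarray | None" = None,
) -> StimulusImage:
    """Render an achromatic texture; every textured pixel takes one of the
    eight luminance levels.

    Ellipse mode scatters `n_elements` randomly oriented/positioned
    ellipses; uncovered pixels (the 600 stated ellipses leave a few
    percent of the screen bare) are filled per pixel with random level
    draws so the eight-level invariant holds everywhere.  Square mode
    tiles the region with axis-aligned squares.  `region` restricts the
    texture to a boolean mask (outside it the image is black).
    """
    rng = np.random.default_rng(seed)
    img = _blank(geometry)
    X, Y = geometry.pixel_grid_deg()
    levels = np.asarray(spec.luminance_levels, float)
    h, w = img.luminance.shape

    if spec.element_shape == "square":
        sx, sy = spec.element_size_deg
        col = np.floor((X + geometry.screen_deg[0] / 2) / sx).astype(int)
        row = np.floor((geometry.screen_deg[1] / 2 - Y) / sy).astype(int)
        ncols = int(np.ceil(geometry.screen_deg[0] / sx))
        tile_levels = rng.integers(0, 8, size=(row.max() + 1, ncols))
        img.luminance = levels[tile_levels[row, col]]
    else:
        a, b = spec.element_size_deg[0] / 2, spec.element_size_deg[1] / 2
        # base fill: per-pixel level draws under the scattered ellipses
        img.luminance = levels[rng.integers(0, 8, size=(h, w))]
        half_w, half_h = geometry.screen_deg[0] / 2, geometry.screen_deg[1] / 2
        cx = rng.uniform(-half_w, half_w, spec.n_elements)
        cy = rng.uniform(-half_h, half_h, spec.n_elements)
        theta = rng.uniform(0, np.pi, spec.n_elements)
        lev = rng.integers(0, 8, spec.n_elements)
        ppx, ppy = geometry.px_per_deg
        for i in range(spec.n_elements):
            # bounding box in pixels around the ellipse
            r = max(a, b)
            c0 = max(int((cx[i] - r + half_w) * ppx) - 1, 0)
            c1 = min(int((cx[i] + r + half_w) * ppx) + 2, w)
            r0 = max(int((half_h - (cy[i] + r)) * ppy) - 1, 0)
            r1 = min(int((half_h - (cy[i] - r)) * ppy) + 2, h)
            if c0 >= c1 or r0 >= r1:
                continue
            xs = X[r0:r1, c0:c1] - cx[i]
            ys = Y[r0:r1, c0:c1] - cy[i]
            ct, st = np.cos(theta[i]), np.sin(theta[i])
            u = xs * ct + ys * st
            v = -xs * st + ys * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            patch = img.luminance[r0:r1, c0:c1]
            patch[inside] = levels[lev[i]]

    if region is not None:
        img.luminance = np.where(region, img.luminance, 0.0)
    img.provenance = {"kind": "texture", "spec": _spec_dict(spec), "seed": int(seed)}
    return img


def _patch_ring(spec: PatchPatternSpec, geometry: DisplayGeometry, rng):
    """Patch centers (deg) after whole-ring jitter, plus the hue permutation."""
    jitter = float(rng.choice(np.asarray(spec.rotation_jitter_deg, float)))
    perm = rng.permutation(spec.n_patches)
    radius = spec.circle_diameter_deg / 2
    outer = spec.patch_diameter_deg / 2 + spec.fringe_width_arcmin / 60.0
    if radius + outer > min(geometry.screen_deg) / 2:
        raise ValueError("patch ring exceeds the screen bounds")
    # patch 0 at 12 o'clock before jitter; equal 36 deg polar steps
    angles = 90.0 - 360.0 * np.arange(spec.n_patches) / spec.n_patches + jitter
    cx = radius * np.cos(np.deg2rad(angles))
    cy = radius * np.sin(np.deg2rad(angles))
    return cx, cy, jitter, perm


def _draw_patches(img: StimulusImage, spec: PatchPatternSpec, cx, cy, perm,
                  chips: "list[MunsellChip]") -> np.ndarray:
    """Stamp the fringed patches onto the image; returns the patch-area mask."""
    X, Y = img.geometry.pixel_grid_deg()
    r_patch = spec.patch_diameter_deg / 2
    r_outer = r_patch + spec.fringe_width_arcmin / 60.0
    area = np.zeros(img.luminance.shape, bool)
    for k in range(spec.n_patches):
        chip = chips[perm[k]]
        d2 = (X - cx[k]) ** 2 + (Y - cy[k]) ** 2
        disk = d2 <= r_patch**2
        ring = (d2 > r_patch**2) & (d2 <= r_outer**2)
        img.luminance[ring] = 0.0
        img.luminance[disk] = chip.luminance
        img.chroma_x[disk] = chip.chromaticity[0]
        img.chroma_y[disk] = chip.chromaticity[1]
        img.chroma_x[ring] = D65_WHITE[0]
        img.chroma_y[ring] = D65_WHITE[1]
        area |= disk | ring
    return area


def _fixation_mask(spec_size: float, geometry: DisplayGeometry) -> np.ndarray:
    X, Y = geometry.pixel_grid_deg()
    half = spec_size / 2
    return (np.abs(X) <= half) & (np.abs(Y) <= half)


def render_patch_pattern(
    spec: PatchPatternSpec,
    seed: int,
    geometry: DisplayGeometry = FMRI_DISPLAY,
) -> StimulusImage:
    """Render one patch-pattern stimulus.

    The ring jitter (one of -12/0/+12 deg, applied to the whole ring) and
    the hue arrangement are drawn once per seed, matching the per-block
    randomisation of the experiment; both are recorded in provenance.
    """
    rng = np.random.default_rng(seed)
    if spec.background == "texture":
        img = render_texture(TextureSpec.fmri_background(),
                             seed=int(rng.integers(2**31)), geometry=geometry)
    else:
        img = _blank(geometry, BLACK_LEVEL)
    cx, cy, jitter, perm = _patch_ring(spec, geometry, rng)
    chips = chip_set(spec.chroma_condition,
                     white_luminance_for_value5(spec.value5_luminance))
    area = _draw_patches(img, spec, cx, cy, perm, chips)

    fix = _fixation_mask(spec.fixation_size_deg, geometry)
    img.luminance[fix] = spec.fixation_luminance
    img.chroma_x[fix] = D65_WHITE[0]
    img.chroma_y[fix] = D65_WHITE[1]

    img.masks = {"patches": area, "fixation": fix}
    img.provenance = {
        "kind": "patch_pattern",
        "spec": _spec_dict(spec),
        "seed": int(seed),
        "ring_jitter_deg": jitter,
        "hue_permutation": perm.tolist(),
        "patch_centers_deg": np.column_stack([cx, cy]).tolist(),
    }
    return img


def scramble(
    image: StimulusImage,
    seed: int,
    mode: str = "full",
    protect_fixation: bool = True,
) -> StimulusImage:
    """Scrambled counterpart: a permutation of pixel locations.

    ``full`` permutes every pixel on the screen (optionally sparing the
    fixation rectangle), preserving the pixel-value multiset exactly.
    ``patches_only`` permutes only pixels at the patch locations and keeps
    the remainder uniformly black, as in the control experiment.
    """
    if mode not in ("full", "patches_only"):
        raise ValueError(f"unknown scramble mode {mode!r}")
    rng = np.random.default_rng(seed)
    h, w = image.luminance.shape
    fix = image.masks.get("fixation")
    if fix is None:
        fix = np.zeros((h, w), bool)

    if mode == "full":
        movable = ~fix if protect_fixation else np.ones((h, w), bool)
        out = StimulusImage(
            luminance=image.luminance.copy(),
            chroma_x=image.chroma_x.copy(),
            chroma_y=image.chroma_y.copy(),
            geometry=image.geometry,
            provenance={},
            masks={k: v.copy() for k, v in image.masks.items()},
        )
    else:
        patches = image.masks.get("patches")
        if patches is None:
            raise ValueError("patches_only scrambling needs a patch-pattern input")
        movable = patches & (~fix if protect_fixation else True)
        out = _blank(image.geometry, BLACK_LEVEL)
        out.masks = {k: v.copy() for k, v in image.masks.items()}
        if protect_fixation:
            out.luminance[fix] = image.luminance[fix]
            out.chroma_x[fix] = image.chroma_x[fix]
            out.chroma_y[fix] = image.chroma_y[fix]

    idx = np.flatnonzero(movable.ravel())
    perm = rng.permutation(idx.size)
    for plane_name in ("luminance", "chroma_x", "chroma_y"):
        src = getattr(image, plane_name).ravel()[idx]
        dst = getattr(out, plane_name).ravel().copy()
        dst[idx] = src[perm]
        setattr(out, plane_name, dst.reshape(h, w))
    out.provenance = {
        "kind": "scramble",
        "mode": mode,
        "protect_fixation": bool(protect_fixation),
        "seed": int(seed),
        "source": image.provenance,
    }
    return out


def _grating_amplitude(C: float, f: float, decay: float) -> float:
    """Modulation amplitude giving a rendered spatial-max Michelson of C.

    With the center fixed at a trough (envelope 1), the global luminance
    maximum sits at the first carrier peak, where the radial envelope has
    already declined to e1 = exp(-1/(2 f decay)).  Solving
    (A e1 + A) / (2 + A e1 - A) = C gives the calibrated amplitude, which
    fixes the *measured* spatially-maximum Michelson contrast at C, as the
    stimulus was specified.
    """
    if C == 0:
        return 0.0
    e1 = np.exp(-1.0 / (2.0 * f * decay))
    return 2.0 * C / (1.0 + e1 + C * (1.0 - e1))


def render_grating(
    spec: GratingSpec,
    seed: int = 0,
    geometry: DisplayGeometry = PSYCHO_DISPLAY,
) -> StimulusImage:
    """Render the enveloped grating with the patch-ring overlay.

    L(x, y) = L_mean [1 + A exp(-r/decay) cos(2 pi f x + pi)] with a
    vertical carrier and phase fixed so the screen center is a luminance
    trough (negative contrast at the center).  A is calibrated so that the
    spatially-maximum Michelson contrast of the rendered grating equals
    ``max_michelson_contrast``.  The seed drives only the overlay's hue
    arrangement and ring jitter.
    """
    img = _blank(geometry, spec.mean_luminance)
    X, Y = geometry.pixel_grid_deg()
    A = _grating_amplitude(spec.max_michelson_contrast,
                           spec.spatial_frequency_cpd, spec.envelope_decay_deg)
    r = np.hypot(X, Y)
    carrier = np.cos(2 * np.pi * spec.spatial_frequency_cpd * X + np.pi)
    img.luminance = spec.mean_luminance * (
        1.0 + A * np.exp(-r / spec.envelope_decay_deg) * carrier
    )
    grating_mask = np.ones(img.luminance.shape, bool)

    overlay_info = None
    if spec.overlay is not None:
        rng = np.random.default_rng(seed)
        cx, cy, jitter, perm = _patch_ring(spec.overlay, geometry, rng)
        chips = chip_set(spec.overlay.chroma_condition,
                         white_luminance_for_value5(spec.overlay.value5_luminance))
        area = _draw_patches(img, spec.overlay, cx, cy, perm, chips)
        grating_mask &= ~area
        img.masks["patches"] = area
        overlay_info = {
            "chroma_condition": spec.overlay.chroma_condition,
            "ring_jitter_deg": jitter,
            "hue_permutation": perm.tolist(),
        }

    img.masks["grating"] = grating_mask
    img.provenance = {
        "kind": "grating",
        "spec": {
            "spatial_frequency_cpd": spec.spatial_frequency_cpd,
            "envelope_decay_deg": spec.envelope_decay_deg,
            "mean_luminance": spec.mean_luminance,
            "max_michelson_contrast": spec.max_michelson_contrast,
        },
        "amplitude": A,
        "overlay": overlay_info,
        "seed": int(seed),
    }
    return img


def measure_michelson(image: StimulusImage, region: "np.ndarray | str | None" = None) -> float:
    """Michelson contrast (Lmax - Lmin)/(Lmax + Lmin) over a region.

    `region` is a boolean mask, the name of a stored mask (e.g.
    ``"grating"``), or None for the whole image.
    """
    if isinstance(region, str):
        region = image.masks[region]
    lum = image.luminance if region is None else image.luminance[region]
    if lum.size == 0:
        raise ValueError("empty region")
    lmax, lmin = float(lum.max()), float(lum.min())
    if lmax + lmin == 0:
        raise ValueError("contrast undefined over an all-zero region")
    return (lmax - lmin) / (lmax + lmin)


def save_stimulus(image: StimulusImage, path_stem) -> list:
    """Write a stimulus as 16-bit PNGs plus a JSON sidecar.

    ``<stem>.png`` holds the scaled luminance plane, ``<stem>.chroma.png``
    a palette index into the sidecar's chromaticity list; the sidecar
    carries the palette, scale, spec and seed.  Returns the written paths.
    """
    from PIL import Image

    path_stem = str(path_stem)
    lum = image.luminance
    scale = 65535.0 / max(float(lum.max()), 1e-9)
    lum16 = np.round(lum * scale).astype(np.uint16)

    pairs = np.stack([image.chroma_x.ravel(), image.chroma_y.ravel()], 1)
    palette, inverse = np.unique(pairs, axis=0, return_inverse=True)
    if palette.shape[0] > 65535:
        raise ValueError("chromaticity palette too large for 16-bit index")
    idx16 = inverse.astype(np.uint16).reshape(lum.shape)

    paths = [path_stem + ".png", path_stem + ".chroma.png", path_stem + ".json"]
    Image.fromarray(lum16).save(paths[0])
    Image.fromarray(idx16).save(paths[1])
    sidecar = {
        "luminance_scale": scale,
        "chromaticity_palette": palette.tolist(),
        "geometry": _spec_dict(image.geometry),
        "provenance": image.provenance,
    }
    with open(paths[2], "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return paths


def load_stimulus(path_stem) -> StimulusImage:
    """Reload a stimulus written by :func:`save_stimulus`.

    Luminance is quantised to the 16-bit grid of the PNG; chromaticity is
    exact via the palette.
    """
    from PIL import Image

    path_stem = str(path_stem)
    with open(path_stem + ".json") as fh:
        sidecar = json.load(fh)
    lum16 = np.asarray(Image.open(path_stem + ".png"), np.uint16)
    idx16 = np.asarray(Image.open(path_stem + ".chroma.png"), np.uint16)
    palette = np.asarray(sidecar["chromaticity_palette"], float)
    geom = sidecar["geometry"]
    return StimulusImage(
        luminance=lum16.astype(float) / sidecar["luminance_scale"],
        chroma_x=palette[idx16, 0],
        chroma_y=palette[idx16, 1],
        geometry=DisplayGeometry(geom["viewing_distance_cm"],
                                 tuple(geom["screen_deg"]),
                                 tuple(geom["resolution"])),
        provenance=sidecar["provenance"],
    )
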