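"""Colour-space plumbing and protanope (red-green dichromat) vision simulation.

The search space throughout the package is the 24-bit sRGB cube: every
target colour is an 8-bit ``(r, g, b)`` triplet.  A simulated protanope
sees a projection of that cube onto a two-dimensional surface; the
projection follows the Viénot, Brettel & Mollon construction: linearise
the sRGB channels, transform to an LMS-like cone space, replace the
missing long-wavelength signal by the plane spanned by white and blue
(which both survive the projection unchanged), transform back and
re-quantise to 8 bits.

Reference implementations of this construction differ in their
transfer function and rounding conventions, and the projected gamut's
unique-colour count is highly sensitive to both; here they are
explicit configuration, and the gamut enumeration records the
achieved count together with the convention that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "ColourTriplet",
    "LinearColour",
    "Gamut",
    "AchromaticColourError",
    "srgb_to_linear",
    "linear_to_srgb",
    "simulate_protanope",
    "simulate_protanope_image",
    "protan_map",
    "enumerate_trichromat_gamut",
    "enumerate_dichromat_gamut",
    "hue_angle",
    "hue_angles",
    "codes_to_rgb",
    "rgb_to_codes",
]

N_TRICHROMAT = 256 ** 3

# Viénot/Brettel/Mollon RGB->LMS matrix and the protanope replacement of
# the L row (L' = 2.02344 M - 2.52581 S); white and the blue primary are
# fixed points of the projection.
_RGB_TO_LMS = np.array(
    [
        [17.8824, 43.5161, 4.11935],
        [3.45565, 27.1554, 3.86714],
        [0.0299566, 0.184309, 1.46709],
    ]
)
_PROTAN_LMS = np.array(
    [
        [0.0, 2.02344, -2.52581],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
    ]
)
# Composite linear-RGB -> linear-RGB projection (exact inverse, float64).
_PROTAN_RGB = np.linalg.solve(_RGB_TO_LMS, _PROTAN_LMS @ _RGB_TO_LMS)

# Affine gamma pre-step from the Viénot et al. reference implementation.
_VIENOT_SCALE = 0.992052
_VIENOT_OFFSET = 0.003974

DEFAULT_TRANSFER = "gamma22"
DEFAULT_ROUNDING = "half-away"


class AchromaticColourError(ValueError):
    """Hue is undefined for colours on the achromatic (r=g=b) axis."""


class ColourTriplet(NamedTuple):
    """8-bit sRGB colour; hashable and ordered so gamuts deduplicate."""

    r: int
    g: int
    b: int

    def validate(self) -> "ColourTriplet":
        for v in self:
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 255):
                raise ValueError(f"channel out of 8-bit range: {self}")
        return self


class LinearColour(NamedTuple):
    """Linear-light intensities, each in [0, 1]."""

    r: float
    g: float
    b: float


def _decode_lut(transfer: str) -> np.ndarray:
    """256-entry LUT: 8-bit code -> linear intensity."""
    x = np.arange(256) / 255.0
    if transfer == "gamma22":
        return x ** 2.2
    if transfer == "vienot":
        return (_VIENOT_SCALE * x + _VIENOT_OFFSET) ** 2.2
    if transfer == "srgb":
        return np.where(x <= 0.04045, x / 12.92, ((x + 0.055) / 1.055) ** 2.4)
    raise ValueError(f"unknown transfer function: {transfer!r}")


def _encode(lin: np.ndarray, transfer: str) -> np.ndarray:
    """Linear intensity in [0, 1] -> continuous 0-255 code value."""
    lin = np.maximum(lin, 0.0)
    if transfer in ("gamma22", "vienot"):
        # the vienot convention applies its affine step on decode only,
        # matching the reference implementation's forward-only usage
        v = lin ** (1.0 / 2.2)
    elif transfer == "srgb":
        v = np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)
    else:
        raise ValueError(f"unknown transfer function: {transfer!r}")
    return v * 255.0


def _quantise(v: np.ndarray, rounding: str) -> np.ndarray:
    if rounding == "half-away":
        q = np.floor(v + 0.5)
    elif rounding == "half-even":
        q = np.rint(v)
    else:
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    return np.clip(q, 0, 255)


def srgb_to_linear(c: ColourTriplet, transfer: str = DEFAULT_TRANSFER) -> LinearColour:
    """Decode an 8-bit sRGB triplet to linear light.

    Monotone per channel; 0 maps to 0 and 255 to 1 for the pure-gamma
    and piecewise-sRGB transfers.
    """
    c = ColourTriplet(*c).validate()
    lut = _decode_lut(transfer)
    return LinearColour(*(float(lut[v]) for v in c))


def linear_to_srgb(
    c: LinearColour,
    transfer: str = DEFAULT_TRANSFER,
    rounding: str = DEFAULT_ROUNDING,
) -> ColourTriplet:
    """Encode linear light back to an 8-bit triplet (clamped)."""
    arr = np.clip(np.asarray(c, dtype=float), 0.0, 1.0)
    q = _quantise(_encode(arr, transfer), rounding).astype(int)
    return ColourTriplet(*(int(v) for v in q))


def protan_map(
    rgb: np.ndarray,
    transfer: str = DEFAULT_TRANSFER,
    rounding: str = DEFAULT_ROUNDING,
) -> np.ndarray:
    """Vectorised protanope simulation on an ``(..., 3)`` uint8 array."""
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing dimension of 3 (RGB)")
    lut = _decode_lut(transfer)
    lin = lut[rgb]
    out = np.clip(lin @ _PROTAN_RGB.T, 0.0, 1.0)
    return _quantise(_encode(out, transfer), rounding).astype(np.uint8)


def simulate_protanope(
    c: ColourTriplet,
    transfer: str = DEFAULT_TRANSFER,
    rounding: str = DEFAULT_ROUNDING,
) -> ColourTriplet:
    """Project a single colour onto the protanope confusion surface.

    Achromatic inputs are returned unchanged (the construction keeps
    the white-black axis fixed).
    """
    c = ColourTriplet(*c).validate()
    out = protan_map(np.asarray(c, dtype=np.uint8), transfer, rounding)
    return ColourTriplet(*(int(v) for v in out))


def simulate_protanope_image(
    img: np.ndarray,
    transfer: str = DEFAULT_TRANSFER,
    rounding: str = DEFAULT_ROUNDING,
) -> np.ndarray:
    """Pixelwise protanope simulation of an ``(H, W, 3)`` uint8 raster."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return protan_map(img, transfer, rounding)


def rgb_to_codes(rgb: np.ndarray) -> np.ndarray:
    """Pack ``(..., 3)`` uint8 triplets into 24-bit integer codes."""
    rgb = np.asarray(rgb, dtype=np.uint32)
    return (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]


def codes_to_rgb(codes: np.ndarray) -> np.ndarray:
    """Unpack 24-bit codes into ``(..., 3)`` uint8 triplets."""
    codes = np.asarray(codes, dtype=np.uint32)
    return np.stack(
        [(codes >> 16) & 255, (codes >> 8) & 255, codes & 255], axis=-1
    ).astype(np.uint8)


@dataclass(frozen=True)
class Gamut:
    """A deduplicated set of 8-bit colours, stored as sorted 24-bit codes."""

    codes: np.ndarray
    label: str  # "trichromat" | "dichromat"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.uint32)
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, colour) -> bool:
        code = rgb_to_codes(np.asarray(tuple(colour), dtype=np.uint8))
        idx = np.searchsorted(self.codes, code)
        return bool(idx < self.codes.size and self.codes[idx] == code)

    @property
    def rgb(self) -> np.ndarray:
        """Members as an ``(n, 3)`` uint8 array."""
        return codes_to_rgb(self.codes)

    def members(self) -> Iterator[ColourTriplet]:
        for row in self.rgb:
            yield ColourTriplet(int(row[0]), int(row[1]), int(row[2]))


def enumerate_trichromat_gamut() -> Gamut:
    """The full 24-bit RGB cube: 16,777,216 colours."""
    return Gamut(
        codes=np.arange(N_TRICHROMAT, dtype=np.uint32),
        label="trichromat",
        metadata={"count": N_TRICHROMAT},
    )


def enumerate_dichromat_gamut(
    transfer: str = DEFAULT_TRANSFER,
    rounding: str = DEFAULT_ROUNDING,
) -> Gamut:
    """Unique 8-bit colours reachable by protanope projection of the cube.

    Enumerates the image of all 2^24 triplets under ``simulate_protanope``
    (vectorised, exploiting linearity of the projection so the full cube
    never has to be materialised at once).  The achieved unique count and
    the transfer/rounding convention used are recorded in the metadata:
    the count is a sensitive joint fingerprint of those conventions.
    """
    lut = _decode_lut(transfer)
    A = _PROTAN_RGB
    # per output channel, precompute the (g, b) contribution plane
    planes = [np.add.outer(A[k, 1] * lut, A[k, 2] * lut) for k in range(3)]
    per_r: list[np.ndarray] = []
    for r in range(256):
        outs = []
        for k in range(3):
            lin = np.clip(A[k, 0] * lut[r] + planes[k], 0.0, 1.0)
            outs.append(_quantise(_encode(lin, transfer), rounding).astype(np.uint32))
        code = (outs[0] << 16) | (outs[1] << 8) | outs[2]
        per_r.append(np.unique(code))
    codes = np.unique(np.concatenate(per_r))
    return Gamut(
        codes=codes,
        label="dichromat",
        metadata={
            "count": int(codes.size),
            "transfer": transfer,
            "rounding": rounding,
        },
    )


def hue_angle(c: ColourTriplet) -> float:
    """Standard hue angle in degrees: red 0, yellow 60, green 120, cyan 180,
    blue 240, magenta 300.

    Raises :class:`AchromaticColourError` for r=g=b, where hue is undefined.
    """
    c = ColourTriplet(*c).validate()
    if c.r == c.g == c.b:
        raise AchromaticColourError(f"hue undefined for achromatic colour {c}")
    return float(hue_angles(np.asarray(c, dtype=np.uint8)[None, :])[0])


def hue_angles(rgb: np.ndarray) -> np.ndarray:
    """Vectorised hue angle for ``(n, 3)`` uint8 colours; NaN where achromatic."""
    arr = np.asarray(rgb, dtype=float)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    delta = mx - mn
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(
            mx == r,
            (g - b) / delta % 6.0,
            np.where(mx == g, (b - r) / delta + 2.0, (r - g) / delta + 4.0),
        )
    h = h * 60.0
    h = np.where(delta == 0, np.nan, h)
    return h % 360.0
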