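"""Three-layer search stimuli: background, shaded sphere target, occluders.

A stimulus is built the way the visual-search task frames it: a natural
background, a uniformly coloured sphere embedded at a permissible
position, and a foreground layer whose pixels are re-painted over the
sphere so that a controlled fraction of it is hidden.  Field photographs
are replaced by a procedural generator — multi-octave value noise mapped
through an environment palette — so the whole pipeline runs without any
external imagery; real background photographs and occlusion masks can be
supplied instead wherever a :class:`StimulusScene` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .colour import ColourTriplet

__all__ = [
    "StimulusScene",
    "SphereSprite",
    "ComposedStimulus",
    "PlacementError",
    "PlacementInfeasibleError",
    "EnvironmentConfig",
    "DEFAULT_ENVIRONMENTS",
    "generate_background",
    "shade_sphere",
    "compose",
    "sample_placement",
    "disc_mask",
]

SPHERE_DIAMETER = 128  # pixels, the experiment's target size
DEFAULT_CANVAS = (1920, 1080)  # (width, height) of the presented stimulus


class PlacementError(ValueError):
    """Sphere centre outside the permissible-position mask."""


class PlacementInfeasibleError(RuntimeError):
    """No permissible centre achieved the requested occlusion range."""


@dataclass(frozen=True)
class EnvironmentConfig:
    """Palette and occluder statistics for one procedural environment.

    ``palette`` is an ordered list of 8-bit colours; the background noise
    field indexes into it by linear interpolation.  ``occluder_cover``
    is the mean fraction of pixels belonging to the foreground layer
    (branches, grasses); the thresholded noise field varies around it
    spatially, which is what makes a range of occlusion fractions
    reachable by rejection sampling.
    """

    name: str
    palette: tuple[tuple[int, int, int], ...]
    occluder_cover: float = 0.375
    background_octaves: int = 4
    occluder_octaves: int = 5
    base_cell: int = 64  # coarsest noise cell size in pixels


DEFAULT_ENVIRONMENTS: dict[str, EnvironmentConfig] = {
    "forest": EnvironmentConfig(
        name="forest",
        palette=(
            (26, 36, 14),
            (52, 62, 24),
            (70, 80, 40),
            (96, 84, 46),
            (58, 92, 38),
            (120, 104, 62),
        ),
    ),
    "desert": EnvironmentConfig(
        name="desert",
        palette=(
            (132, 108, 80),
            (150, 125, 95),
            (172, 146, 112),
            (200, 175, 140),
            (214, 192, 158),
        ),
    ),
}


@dataclass(frozen=True)
class StimulusScene:
    """Background raster plus occluder and permissible-position masks."""

    background: np.ndarray  # (H, W, 3) uint8
    occluder_mask: np.ndarray  # (H, W) bool, True where foreground pixels exist
    permissible_mask: np.ndarray  # (H, W) bool, True where a centre may go
    environment: str
    sphere_diameter: int = SPHERE_DIAMETER
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, w = self.background.shape[:2]
        if self.occluder_mask.shape != (h, w) or self.permissible_mask.shape != (h, w):
            raise ValueError("scene rasters must share dimensions")


@dataclass(frozen=True)
class SphereSprite:
    """Shaded sphere target of a single base colour.

    ``alpha`` is the opaque disc support; ``shading`` the multiplicative
    factor in (0, 1] applied to the base colour inside it.
    """

    colour: ColourTriplet
    diameter: int
    alpha: np.ndarray  # (d, d) bool
    shading: np.ndarray  # (d, d) float, in (0, 1] where alpha

    @property
    def rgba(self) -> np.ndarray:
        """(d, d, 4) uint8 raster with transparency outside the disc."""
        d = self.diameter
        out = np.zeros((d, d, 4), dtype=np.uint8)
        base = np.asarray(self.colour, dtype=float)
        shaded = np.floor(self.shading[..., None] * base + 0.5).astype(np.uint8)
        out[..., :3] = np.where(self.alpha[..., None], shaded, 0)
        out[..., 3] = np.where(self.alpha, 255, 0)
        return out


@dataclass(frozen=True)
class ComposedStimulus:
    image: np.ndarray  # (H, W, 3) uint8
    sphere_centre: tuple[int, int]  # (x, y), 0-based, x rightward y downward
    occlusion_fraction: float
    side: str  # "left" | "right" of the image midline


def _value_noise(
    shape: tuple[int, int], rng: np.random.Generator, octaves: int, base_cell: int
) -> np.ndarray:
    """Multi-octave bilinear value noise in [0, 1], deterministic in rng."""
    h, w = shape
    total = np.zeros((h, w))
    amp_sum = 0.0
    for o in range(octaves):
        cell = max(2, base_cell >> o)
        amp = 0.5 ** o
        gh, gw = h // cell + 2, w // cell + 2
        grid = rng.random((gh, gw))
        ys = np.arange(h) / cell
        xs = np.arange(w) / cell
        y0 = ys.astype(int)
        x0 = xs.astype(int)
        fy = (ys - y0)[:, None]
        fx = (xs - x0)[None, :]
        # smoothstep easing avoids grid-aligned creases
        fy = fy * fy * (3 - 2 * fy)
        fx = fx * fx * (3 - 2 * fx)
        g00 = grid[np.ix_(y0, x0)]
        g01 = grid[np.ix_(y0, x0 + 1)]
        g10 = grid[np.ix_(y0 + 1, x0)]
        g11 = grid[np.ix_(y0 + 1, x0 + 1)]
        layer = (
            g00 * (1 - fy) * (1 - fx)
            + g01 * (1 - fy) * fx
            + g10 * fy * (1 - fx)
            + g11 * fy * fx
        )
        total += amp * layer
        amp_sum += amp
    return total / amp_sum


def _inside_frame_mask(shape: tuple[int, int], diameter: int) -> np.ndarray:
    """Centres for which the full disc lies inside the frame."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    lo = (diameter - 1) // 2  # pixels left/above the centre pixel
    hi = diameter // 2  # pixels right/below the centre pixel
    if h - 1 - hi >= lo and w - 1 - hi >= lo:
        mask[lo : h - hi, lo : w - hi] = True
    return mask


def generate_background(
    environment: str,
    seed: int,
    size: tuple[int, int] = DEFAULT_CANVAS,
    environments: dict[str, EnvironmentConfig] | None = None,
    sphere_diameter: int = SPHERE_DIAMETER,
) -> StimulusScene:
    """Procedural background + occluder layer for one environment.

    Deterministic given ``(environment, seed, size)``.  The background is
    value noise mapped through the environment palette; the occluder mask
    is an independent noise field thresholded at the configured mean
    cover, so local cover varies smoothly across the image.
    """
    envs = DEFAULT_ENVIRONMENTS if environments is None else environments
    if environment not in envs:
        raise ValueError(
            f"unknown environment {environment!r}; configured: {sorted(envs)}"
        )
    cfg = envs[environment]
    w, h = size
    env_tag = int.from_bytes(environment.encode()[:4].ljust(4, b"\0"), "big")
    rng = np.random.default_rng(np.random.SeedSequence([seed, env_tag]))

    field_bg = _value_noise((h, w), rng, cfg.background_octaves, cfg.base_cell)
    palette = np.asarray(cfg.palette, dtype=float)
    if len(palette) == 1:
        background = np.broadcast_to(
            palette[0].astype(np.uint8), (h, w, 3)
        ).copy()
    else:
        pos = field_bg * (len(palette) - 1)
        i0 = np.clip(pos.astype(int), 0, len(palette) - 2)
        frac = (pos - i0)[..., None]
        background = np.floor(
            palette[i0] * (1 - frac) + palette[i0 + 1] * frac + 0.5
        ).astype(np.uint8)

    field_occ = _value_noise((h, w), rng, cfg.occluder_octaves, cfg.base_cell)
    thresh = np.quantile(field_occ, 1.0 - cfg.occluder_cover)
    occluder = field_occ > thresh

    permissible = _inside_frame_mask((h, w), sphere_diameter)
    return StimulusScene(
        background=background,
        occluder_mask=occluder,
        permissible_mask=permissible,
        environment=environment,
        sphere_diameter=sphere_diameter,
        metadata={"seed": seed, "occluder_cover": cfg.occluder_cover},
    )


def disc_mask(diameter: int) -> np.ndarray:
    """Boolean disc of the given diameter whose widest row spans exactly
    ``diameter`` pixels."""
    c = (diameter - 1) / 2.0
    r = diameter / 2.0
    yy, xx = np.mgrid[0:diameter, 0:diameter]
    return (xx - c) ** 2 + (yy - c) ** 2 <= r * r


# light direction for sphere shading: from upper-left, slightly towards
# the viewer; y is downward so "up" is negative y
_LIGHT = np.array([-0.45, -0.45, 0.771])
_LIGHT = _LIGHT / np.linalg.norm(_LIGHT)
_AMBIENT = 0.2


def shade_sphere(colour: ColourTriplet, diameter: int = SPHERE_DIAMETER) -> SphereSprite:
    """Lambertian-shaded sphere sprite of one base colour.

    A single distant light from the upper left; the shading factor is
    ``max(ambient, n·L)`` of the implied sphere normal, so it equals 1.0
    exactly at the highlight point and never reaches 0.
    """
    if diameter < 3:
        raise ValueError("sphere diameter must be at least 3 px")
    colour = ColourTriplet(*colour).validate()
    c = (diameter - 1) / 2.0
    r = diameter / 2.0
    yy, xx = np.mgrid[0:diameter, 0:diameter]
    dx = (xx - c) / r
    dy = (yy - c) / r
    rho2 = dx * dx + dy * dy
    alpha = (xx - c) ** 2 + (yy - c) ** 2 <= r * r
    nz = np.sqrt(np.clip(1.0 - rho2, 0.0, 1.0))
    lambert = dx * _LIGHT[0] + dy * _LIGHT[1] + nz * _LIGHT[2]
    shading = np.clip(lambert, _AMBIENT, 1.0)
    shading = np.where(alpha, shading, 0.0)
    return SphereSprite(colour=colour, diameter=diameter, alpha=alpha, shading=shading)


def _disc_footprint(
    scene: StimulusScene, diameter: int, centre: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Slices into the scene plus the disc mask aligned to them."""
    cx, cy = centre
    off = (diameter - 1) // 2
    x0 = cx - off
    y0 = cy - off
    return slice(y0, y0 + diameter), slice(x0, x0 + diameter), disc_mask(diameter)


def occlusion_fraction_at(
    scene: StimulusScene, centre: tuple[int, int], diameter: int | None = None
) -> float:
    """Fraction of the sphere's disc pixels covered by the occluder layer."""
    d = scene.sphere_diameter if diameter is None else diameter
    ys, xs, disc = _disc_footprint(scene, d, centre)
    covered = scene.occluder_mask[ys, xs] & disc
    return float(covered.sum() / disc.sum())


def compose(
    scene: StimulusScene, sprite: SphereSprite, centre: tuple[int, int]
) -> ComposedStimulus:
    """Superimpose the sphere at ``centre``, then re-paint occluder pixels.

    ``centre`` is an ``(x, y)`` pixel position and must be permissible.
    The occlusion fraction is computed exactly from the masks.
    """
    cx, cy = centre
    if not scene.permissible_mask[cy, cx]:
        raise PlacementError(f"centre {centre} outside the permissible mask")
    ys, xs, disc = _disc_footprint(scene, sprite.diameter, centre)
    image = scene.background.copy()
    region = image[ys, xs]
    base = np.asarray(sprite.colour, dtype=float)
    shaded = np.floor(sprite.shading[..., None] * base + 0.5).astype(np.uint8)
    occ_here = scene.occluder_mask[ys, xs]
    paint = sprite.alpha & ~occ_here  # occluders stay on top of the sphere
    region[paint] = shaded[paint]
    image[ys, xs] = region
    frac = float((sprite.alpha & occ_here).sum() / sprite.alpha.sum())
    w = scene.background.shape[1]
    side = "left" if cx < w / 2 else "right"
    return ComposedStimulus(
        image=image, sphere_centre=(cx, cy), occlusion_fraction=frac, side=side
    )


def sample_placement(
    scene: StimulusScene,
    occlusion_range: tuple[float, float] = (0.25, 0.50),
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> tuple[tuple[int, int], float]:
    """Rejection-sample a permissible centre whose occlusion fraction falls
    in ``occlusion_range``.

    Returns ``(centre, realised_fraction)``.  Raises
    :class:`PlacementInfeasibleError` when ``max_tries`` uniform draws from
    the permissible mask all fail, which signals a degenerate scene for the
    requested range.
    """
    lo, hi = occlusion_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("occlusion_range must be within [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ys_all, xs_all = np.nonzero(scene.permissible_mask)
    if ys_all.size == 0:
        raise PlacementInfeasibleError("scene has no permissible positions")
    for _ in range(max_tries):
        i = int(rng.integers(ys_all.size))
        centre = (int(xs_all[i]), int(ys_all[i]))
        frac = occlusion_fraction_at(scene, centre)
        if lo <= frac <= hi:
            return centre, frac
    raise PlacementInfeasibleError(
        f"no placement with occlusion in [{lo}, {hi}] after {max_tries} tries"
    )
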