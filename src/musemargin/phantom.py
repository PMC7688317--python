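"""Synthetic MUSE-like phantom: scenes, tiles and exact ground truth.

Deep-UV surface-excitation images of PI/EY-stained breast tissue have a
characteristic phenotype: propidium-iodide-stained nuclei are bright in the
red channel, eosin-Y-stained cytoplasm and connective tissue are green,
adipocytes appear as dark rounded vacuoles with sparse nuclei at their rims,
and invasive carcinoma shows dense, enlarged, irregular nuclei.  The phantom
renders that phenotype onto a labelled region layout, records the exact
per-pixel nuclear mask and tissue label map, and can then cut the scene into
overlapping stage tiles with multiplicative vignetting and additive sensor
noise — giving the whole downstream pipeline ground-truthed inputs.

Nuclei are placed by a hard-core point process (dart throwing with a minimum
centre separation of 0.8x the sum of the two radii), which keeps the
ground-truth nuclear area fraction well defined and the segmentation
testable.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from scipy.ndimage import binary_erosion, gaussian_filter

from .stitch import Tile

__all__ = [
    "TISSUE_CLASSES",
    "INVASIVE_CLASSES",
    "LABEL_CODES",
    "Region",
    "IntensityModel",
    "PhantomSpec",
    "PhantomTruth",
    "ShadingField",
    "make_shading_field",
    "identity_shading",
    "generate_scene",
    "render_tiles",
    "vertical_strip_layout",
    "write_phantom",
]

TISSUE_CLASSES = ("adipose", "stroma", "lobule_duct", "IDC", "ILC")
INVASIVE_CLASSES = ("IDC", "ILC")

#: Integer codes used in label maps; 0 is reserved for unlabeled background.
LABEL_CODES = {name: i + 1 for i, name in enumerate(TISSUE_CLASSES)}

# Nuclear number densities (nuclei per mm^2 of tissue).  Chosen so that
# density x mean nuclear area reproduces realistic patch-level nuclear area
# fractions: ~0.03 for adipose-rich, ~0.07 for fibrous/glandular stroma and
# ~0.20-0.23 for invasive carcinoma.
DEFAULT_DENSITY_PER_MM2 = {
    "adipose": 350.0,
    "stroma": 900.0,
    "lobule_duct": 1400.0,
    "IDC": 1700.0,
    "ILC": 2000.0,
}

# Nuclear radius (mean, spread) in micrometres; carcinoma nuclei enlarged.
DEFAULT_RADIUS_UM = {
    "adipose": (5.0, 0.8),
    "stroma": (5.0, 0.8),
    "lobule_duct": (5.0, 0.8),
    "IDC": (6.0, 1.0),
    "ILC": (6.0, 1.0),
}

#: Default pixel pitch such that a 250 um scoring window is exactly 198 px.
DEFAULT_PIXEL_PITCH_UM = 1.2626


@dataclass
class Region:
    """One labelled tissue region, given as a polygon or a boolean mask."""

    tissue_class: str
    polygon: np.ndarray | None = None  # (N, 2) array of (x, y) vertices, px
    mask: np.ndarray | None = None

    def rasterize(self, height: int, width: int) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (height, width):
                raise ValueError("region mask shape does not match scene")
            return m
        if self.polygon is None:
            raise ValueError("region needs a polygon or a mask")
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise ValueError("polygon must be an (N, 2) array of (x, y)")
        if (
            poly[:, 0].min() < 0
            or poly[:, 1].min() < 0
            or poly[:, 0].max() > width
            or poly[:, 1].max() > height
        ):
            raise ValueError("region polygon extends outside image bounds")
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(height, width))
        m = np.zeros((height, width), dtype=bool)
        m[rr, cc] = True
        return m


@dataclass
class IntensityModel:
    """Mean RGB emission (0..1) per scene component.

    The study's stains have no published quantitative emission statistics,
    so these are free parameters; the defaults put nuclei in roughly the
    top 1-5% of red-channel intensities, the regime the downstream
    70%-of-the-top-1% threshold rule presumes.
    """

    background: tuple[float, float, float] = (0.010, 0.012, 0.020)
    nucleus: tuple[float, float, float] = (0.88, 0.40, 0.08)
    cytoplasm: dict = field(
        default_factory=lambda: {
            "adipose": (0.050, 0.180, 0.030),
            "stroma": (0.100, 0.420, 0.050),
            "lobule_duct": (0.130, 0.400, 0.050),
            "IDC": (0.160, 0.350, 0.060),
            "ILC": (0.170, 0.340, 0.060),
        }
    )
    vacuole: tuple[float, float, float] = (0.020, 0.080, 0.020)
    #: std of the smooth multiplicative texture modulating the scene
    texture_sigma: float = 0.012


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scene."""

    width_px: int
    height_px: int
    regions: list[Region]
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    nuclei_density_per_mm2: dict = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_PER_MM2)
    )
    nucleus_radius_um: dict = field(default_factory=lambda: dict(DEFAULT_RADIUS_UM))
    intensity: IntensityModel = field(default_factory=IntensityModel)
    #: adipocyte vacuoles per mm^2 of adipose region and their radius range
    vacuole_density_per_mm2: float = 180.0
    vacuole_radius_um: tuple[float, float] = (18.0, 35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        for cls, d in self.nuclei_density_per_mm2.items():
            if d < 0:
                raise ValueError(f"negative nuclear density for {cls!r}")
        for cls, (mu, sd) in self.nucleus_radius_um.items():
            if mu <= 0 or sd < 0:
                raise ValueError(f"invalid nuclear radius for {cls!r}")
        for reg in self.regions:
            if reg.tissue_class not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue class {reg.tissue_class!r}")
        dens = self.nuclei_density_per_mm2
        present = {r.tissue_class for r in self.regions}
        for tumor in present & set(INVASIVE_CLASSES):
            for normal in present & {"stroma", "adipose"}:
                if dens.get(tumor, 0.0) <= dens.get(normal, 0.0):
                    raise ValueError(
                        f"{tumor} nuclear density must exceed {normal} density: "
                        "the N/C contrast the analysis assumes must exist"
                    )

    @property
    def um_per_px(self) -> float:
        return self.pixel_pitch_um

    @property
    def mm2_per_px(self) -> float:
        return (self.pixel_pitch_um / 1000.0) ** 2


@dataclass
class PhantomTruth:
    """Exact ground truth for one generated scene."""

    label_map: np.ndarray  # uint8, codes per LABEL_CODES, 0 = unlabeled
    nuclear_mask: np.ndarray  # bool
    nuclear_fraction_per_region: list[dict]
    tile_manifest: list[dict] = field(default_factory=list)
    label_codes: dict = field(default_factory=lambda: dict(LABEL_CODES))


@dataclass
class ShadingField:
    """Smooth strictly-positive multiplicative gain image with mean 1."""

    gain: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=np.float64)
        if g.min() <= 0:
            raise ValueError("shading gain must be strictly positive")
        if abs(g.mean() - 1.0) > 1e-6:
            raise ValueError("shading gain must have spatial mean 1")
        self.gain = g


def make_shading_field(
    shape: tuple[int, int], vignette_strength: float
) -> ShadingField:
    """Radially symmetric vignette, normalised to spatial mean 1.

    The unnormalised profile is ``1 - s * (r / r_max)^2`` where ``r`` is the
    distance from the image centre and ``r_max`` the centre-to-corner
    distance, so the centre/corner gain ratio is ``1 / (1 - s)`` regardless
    of normalisation.
    """
    if not 0.0 <= vignette_strength < 1.0:
        raise ValueError("vignette strength must lie in [0, 1)")
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    r2max = cy**2 + cx**2
    profile = 1.0 - vignette_strength * (r2 / r2max if r2max > 0 else 0.0)
    return ShadingField(gain=profile / profile.mean())


def identity_shading(shape: tuple[int, int]) -> ShadingField:
    return ShadingField(gain=np.ones(shape))


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _hard_core_positions(
    eligible: np.ndarray,
    n_target: int,
    radii_px: np.ndarray,
    rng: np.random.Generator,
    max_attempts_factor: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement with minimum separation 0.8 * (r_i + r_j).

    Returns accepted (y, x) centres and the radii actually used.  Falls
    short of ``n_target`` only when the region saturates within the attempt
    budget.
    """
    ys, xs = np.nonzero(eligible)
    if len(ys) == 0 or n_target == 0:
        return np.empty((0, 2)), np.empty(0)
    cell = max(2.0 * 0.8 * (radii_px.max() if len(radii_px) else 1.0), 1.0)
    buckets: dict[tuple[int, int], list[int]] = {}
    acc_c: list[tuple[float, float]] = []
    acc_r: list[float] = []
    attempts = 0
    budget = max_attempts_factor * n_target
    while len(acc_c) < n_target and attempts < budget:
        attempts += 1
        k = int(rng.integers(0, len(ys)))
        cy = ys[k] + rng.uniform(-0.5, 0.5)
        cx = xs[k] + rng.uniform(-0.5, 0.5)
        r = radii_px[len(acc_c) % len(radii_px)]
        bx, by = int(cx // cell), int(cy // cell)
        ok = True
        for nb in (
            (by + dy, bx + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        ):
            for idx in buckets.get(nb, ()):
                oy, ox = acc_c[idx]
                min_d = 0.8 * (r + acc_r[idx])
                if (cy - oy) ** 2 + (cx - ox) ** 2 < min_d * min_d:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault((by, bx), []).append(len(acc_c))
            acc_c.append((cy, cx))
            acc_r.append(r)
    return np.asarray(acc_c).reshape(-1, 2), np.asarray(acc_r)


def generate_scene(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render the phantom scene and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Returns an 8-bit RGB image of
    shape ``(height_px, width_px, 3)`` and the :class:`PhantomTruth` whose
    nuclear mask is exactly the set of rendered nucleus pixels.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    im = spec.intensity

    label_map = np.zeros((h, w), dtype=np.uint8)
    scene = np.empty((h, w, 3), dtype=np.float64)
    scene[:] = im.background
    nuclear_mask = np.zeros((h, w), dtype=bool)
    nuclei_per_region: list[int] = []

    region_masks: list[np.ndarray] = []
    coverage = np.zeros((h, w), dtype=np.uint8)
    for reg in spec.regions:
        m = reg.rasterize(h, w)
        coverage += m.astype(np.uint8)
        region_masks.append(m)
    if coverage.max() > 1:
        raise ValueError(
            "region layout has overlapping, contradictory tissue labels"
        )

    px = spec.pixel_pitch_um

    # cytoplasm / vacuoles first, nuclei on top
    vacuole_interior = np.zeros((h, w), dtype=bool)
    for reg, m in zip(spec.regions, region_masks):
        label_map[m] = LABEL_CODES[reg.tissue_class]
        scene[m] = im.cytoplasm[reg.tissue_class]
        if reg.tissue_class == "adipose":
            area_mm2 = m.sum() * spec.mm2_per_px
            n_vac = rng.poisson(spec.vacuole_density_per_mm2 * area_mm2)
            ys, xs = np.nonzero(m)
            for _ in range(int(n_vac)):
                k = int(rng.integers(0, len(ys)))
                r_um = rng.uniform(*spec.vacuole_radius_um)
                rr, cc = draw_disk(
                    (ys[k], xs[k]), r_um / px, shape=(h, w)
                )
                keep = m[rr, cc]
                scene[rr[keep], cc[keep]] = im.vacuole
                vacuole_interior[rr[keep], cc[keep]] = True

    # nuclei: hard-core placement per region; inside adipose regions nuclei
    # avoid vacuole interiors (minus a thin rim), so they sit at rims/septa
    for reg, m in zip(spec.regions, region_masks):
        dens = spec.nuclei_density_per_mm2.get(reg.tissue_class, 0.0)
        if dens <= 0:
            nuclei_per_region.append(0)
            continue
        mu_um, sd_um = spec.nucleus_radius_um[reg.tissue_class]
        area_mm2 = m.sum() * spec.mm2_per_px
        n_target = int(rng.poisson(dens * area_mm2))
        eligible = m
        if reg.tissue_class == "adipose" and vacuole_interior.any():
            rim_px = max(int(round(2.0 * mu_um / px)), 1)
            core = binary_erosion(
                vacuole_interior, iterations=rim_px, border_value=0
            )
            eligible = m & ~core
        radii_um = np.clip(
            rng.normal(mu_um, sd_um, size=max(n_target, 1)),
            0.4 * mu_um,
            2.0 * mu_um,
        )
        centres, radii = _hard_core_positions(
            eligible, n_target, radii_um / px, rng
        )
        nuclei_per_region.append(len(centres))
        for (cy, cx), r in zip(centres, radii):
            q = rng.uniform(0.7, 1.0)  # axis ratio, area-preserving
            theta = rng.uniform(0.0, np.pi)
            rr, cc = draw_ellipse(
                cy, cx, r / np.sqrt(q), r * np.sqrt(q),
                shape=(h, w), rotation=theta,
            )
            scene[rr, cc] = im.nucleus
            nuclear_mask[rr, cc] = True

    # smooth multiplicative texture so tissue is not perfectly flat
    if im.texture_sigma > 0:
        t = gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
        std = t.std()
        if std > 0:
            t *= im.texture_sigma / std
        scene *= (1.0 + t)[:, :, None]

    scene_u8 = np.clip(np.rint(scene * 255.0), 0, 255).astype(np.uint8)

    fractions = []
    for k, (reg, m) in enumerate(zip(spec.regions, region_masks)):
        n_pix = int(m.sum())
        n_nuc = int((nuclear_mask & m).sum())
        fractions.append(
            {
                "tissue_class": reg.tissue_class,
                "region_px": n_pix,
                "nuclear_px": n_nuc,
                "nuclear_fraction": (n_nuc / n_pix) if n_pix else 0.0,
                "n_nuclei": nuclei_per_region[k],
            }
        )
    truth = PhantomTruth(
        label_map=label_map,
        nuclear_mask=nuclear_mask,
        nuclear_fraction_per_region=fractions,
    )
    return scene_u8, truth


def vertical_strip_layout(
    width_px: int, height_px: int, classes: list[str]
) -> list[Region]:
    """Equal-width vertical strips, one per tissue class, left to right."""
    n = len(classes)
    edges = np.linspace(0, width_px, n + 1).round().astype(int)
    regions = []
    for i, cls in enumerate(classes):
        m = np.zeros((height_px, width_px), dtype=bool)
        m[:, edges[i] : edges[i + 1]] = True
        regions.append(Region(tissue_class=cls, mask=m))
    return regions


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


def render_tiles(
    scene: np.ndarray,
    tile_w_px: int,
    tile_h_px: int,
    overlap_x_um: float = 750.0,
    overlap_y_um: float = 600.0,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    shading: ShadingField | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[Tile], list[dict]]:
    """Cut the scene into a grid of overlapping stage tiles.

    Adjacent tiles share the stated overlap (rounded to whole pixels at the
    given pitch).  Each tile is the scene crop multiplied by the shading
    gain, plus additive Gaussian noise of standard deviation ``noise_sigma``
    (on the 0..1 scale), clipped and re-quantised.  The manifest records
    grid indices and true offsets; with identity shading and zero noise each
    tile equals its crop exactly.
    """
    h, w = scene.shape[0], scene.shape[1]
    if tile_w_px > w or tile_h_px > h:
        raise ValueError("tile dimensions must not exceed the scene")
    ox = int(round(overlap_x_um / pixel_pitch_um))
    oy = int(round(overlap_y_um / pixel_pitch_um))
    if ox >= tile_w_px or oy >= tile_h_px:
        raise ValueError("overlap must be smaller than the tile size")
    step_x = tile_w_px - ox
    step_y = tile_h_px - oy
    xs = list(range(0, w - tile_w_px + 1, step_x))
    ys = list(range(0, h - tile_h_px + 1, step_y))

    if shading is not None and shading.gain.shape != (tile_h_px, tile_w_px):
        raise ValueError("shading field shape must match the tile size")
    rng = np.random.default_rng(seed)
    gain = shading.gain if shading is not None else None

    tiles: list[Tile] = []
    manifest: list[dict] = []
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            crop = scene[y0 : y0 + tile_h_px, x0 : x0 + tile_w_px].astype(
                np.float64
            ) / 255.0
            if gain is not None:
                crop = crop * gain[:, :, None]
            if noise_sigma > 0:
                crop = crop + rng.normal(
                    0.0, noise_sigma, size=crop.shape
                )
            img = np.clip(np.rint(crop * 255.0), 0, 255).astype(np.uint8)
            tiles.append(
                Tile(
                    image=img,
                    grid_row=j,
                    grid_col=i,
                    nominal_offset_px=(float(x0), float(y0)),
                )
            )
            manifest.append(
                {
                    "grid_row": j,
                    "grid_col": i,
                    "x0_px": x0,
                    "y0_px": y0,
                    "tile_w_px": tile_w_px,
                    "tile_h_px": tile_h_px,
                }
            )
    return tiles, manifest


def write_phantom(
    outdir: str | Path,
    scene: np.ndarray,
    truth: PhantomTruth,
    tiles: list[Tile],
    manifest: list[dict],
    pixel_pitch_um: float,
    seed: int,
) -> None:
    """Persist tiles (TIFF), truth rasters (PNG) and JSON manifests."""
    import imageio.v3 as iio
    import tifffile

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tiles").mkdir(exist_ok=True)
    for t in tiles:
        tifffile.imwrite(
            out / "tiles" / f"tile_r{t.grid_row}_c{t.grid_col}.tif", t.image
        )
    tifffile.imwrite(out / "scene.tif", scene)
    iio.imwrite(
        out / "truth_nuclear_mask.png",
        (truth.nuclear_mask.astype(np.uint8) * 255),
    )
    iio.imwrite(out / "truth_label_map.png", truth.label_map)
    meta = {
        "pixel_pitch_um": pixel_pitch_um,
        "seed": seed,
        "label_codes": truth.label_codes,
        "tiles": manifest,
        "nuclear_fraction_per_region": truth.nuclear_fraction_per_region,
    }
    (out / "manifest.json").write_text(json.dumps(meta, indent=2))
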