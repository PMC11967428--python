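"""Synthetic multichannel fluorescence fields with exact ground truth.

Two kinds of field are emulated:

* **FFPE-like tumor fields** — a contiguous tumor region delineated by an
  epithelial-marker channel, densely packed nuclei (tumor inside the region,
  stromal outside), and a punctate trogocytic-marker channel in which every
  tumor cell carries a *planted* marker-coverage fraction, constructed as an
  exact pixel-count subset of its territory.
* **Co-culture fields** — a monolayer of large tumor cells, a fraction of
  which contain marker-coated hollow spheres (trogosomes) of known diameter
  planted beside the nucleus.

Nuisances are independently switchable so each robustness property isolates
one effect: scaled-Poisson shot noise, additive Gaussian read noise, a linear
shading ramp, and a per-cell lognormal autofluorescence plateau that stands
in for residual tissue background (and is all a secondary-antibody-only
control field contains).  The point-spread function is a Gaussian of
σ = 0.4 px, the diffraction-limited width of high-NA 60× imaging at
0.2–0.25 µm/px sampling; the trogocytic channel of FFPE fields is rendered
without PSF so planted coverage stays an exact pixel-count ratio.

Territories in the ground truth are computed with the pipeline's own
region-seeded Voronoi operator on the ground-truth nucleus disks, so the
geometry the generator plants is the geometry the pipeline measures.
Everything is drawn from one seeded generator: identical params + seed give
bit-identical fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import GenerationError, ValidationError
from .image_io import MultiChannelImage
from .segmentation import NucleiLabels, canonical_relabel
from .tumor_map import TumorMask, select_tumor_nuclei, voronoi_territories

__all__ = [
    "SyntheticParams",
    "SyntheticGroundTruth",
    "generate_ffpe_field",
    "generate_control_field",
    "generate_coculture_field",
    "generate_coculture_timecourse",
    "default_timecourse_params",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for one synthetic field.

    Defaults describe an FFPE tumor field: a 128×128 µm field of view at
    0.2 µm/px with 100 tumor cells inside a wobbly-disk tumor region and 20
    stromal cells outside, nuclei of radius 2.5 ± 0.3 µm packed at ≥ 6 µm
    spacing.  40% of tumor cells express the trogocytic marker with coverage
    ~ U(0.3, 0.95); the rest carry none.  Use :meth:`coculture` for the
    co-culture monolayer geometry.
    """

    shape: tuple[int, int] = (640, 640)
    pixel_size_um: float = 0.2
    n_tumor_cells: int = 100
    n_stromal_cells: int = 20
    nucleus_radius_um: float = 2.5
    nucleus_radius_sd_um: float = 0.3
    min_spacing_um: float = 6.0
    whole_field_tumor: bool = False
    tumor_region_radius_frac: float = 0.42
    tumor_region_wobble: float = 0.12
    # channel amplitudes (arbitrary normalized units)
    nuclei_amplitude: float = 0.9
    tumor_amplitude: float = 0.75
    marker_amplitude: float = 0.8
    # planted marker coverage
    expressing_fraction: float = 0.4
    expressing_coverage_range: tuple[float, float] = (0.3, 0.95)
    background_coverage_range: tuple[float, float] = (0.0, 0.0)
    coverage_values: tuple[float, ...] | None = None
    # planted trogosomes (co-culture)
    trog_fraction_large: float = 0.0
    trog_large_diameter_range: tuple[float, float] = (5.5, 9.0)
    trog_small_fraction: float = 0.3
    trog_small_diameter_range: tuple[float, float] = (1.8, 4.5)
    trog_diameters_um: tuple[float, ...] | None = None
    trog_ring_amplitude: float = 0.9
    trog_hollow_fraction: float = 0.3
    trog_ring_inner_fraction: float = 0.7
    # nuisance models
    psf_sigma_px: float = 0.4
    autofluorescence: bool = True
    af_base: float = 0.01
    af_median: float = 0.02
    af_sigma_log: float = 0.35
    photon_scale: float = 300.0
    read_noise_sd: float = 0.01
    shading_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.n_tumor_cells < 0 or self.n_stromal_cells < 0:
            raise ValidationError("cell counts must be >= 0")
        if self.nucleus_radius_um <= 0 or self.min_spacing_um <= 0:
            raise ValidationError("nucleus radius and spacing must be > 0")
        for lo, hi in (
            self.expressing_coverage_range,
            self.background_coverage_range,
        ):
            if not (0 <= lo <= hi <= 1):
                raise ValidationError("coverage ranges must satisfy 0 <= lo <= hi <= 1")
        if not (0 <= self.expressing_fraction <= 1):
            raise ValidationError("expressing_fraction must be in [0, 1]")
        if not (0 <= self.trog_fraction_large <= 1):
            raise ValidationError("trog_fraction_large must be in [0, 1]")
        if self.coverage_values is not None and len(self.coverage_values) != self.n_tumor_cells:
            raise ValidationError("coverage_values must list one value per tumor cell")

    @classmethod
    def coculture(cls, **overrides) -> "SyntheticParams":
        """Co-culture monolayer preset: large, well-spaced cultured cells.

        240×240 µm at 0.25 µm/px, 100 cells with 4 µm nuclei at ≥ 22 µm
        spacing, no tumor-region boundary (the monolayer fills the dish), no
        punctate coverage — the marker channel holds only planted trogosome
        rings plus background.
        """
        base = dict(
            shape=(960, 960),
            pixel_size_um=0.25,
            n_tumor_cells=100,
            n_stromal_cells=0,
            nucleus_radius_um=4.0,
            nucleus_radius_sd_um=0.4,
            min_spacing_um=20.0,
            whole_field_tumor=True,
            expressing_fraction=0.0,
            background_coverage_range=(0.0, 0.0),
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **kwargs) -> "SyntheticParams":
        return dataclasses.replace(self, **kwargs)

    def noiseless(self) -> "SyntheticParams":
        """Copy with every nuisance model switched off (pure planted signal)."""
        return self.replace(
            photon_scale=0.0,
            read_noise_sd=0.0,
            shading_amplitude=0.0,
            autofluorescence=False,
        )


@dataclass
class SyntheticGroundTruth:
    """Exact per-nucleus / per-cell / per-trogosome truth for one field."""

    params: SyntheticParams
    nuclei_labels: np.ndarray  # all nuclei (tumor + stromal), canonical ids
    is_tumor: np.ndarray  # per nucleus id (1..n) in label order
    nucleus_centroids: np.ndarray  # (n, 2) row, col
    nucleus_radii_px: np.ndarray
    tumor_mask: np.ndarray
    territories: np.ndarray  # tumor-cell territories, ids 1..n_tumor
    planted_coverage: np.ndarray  # per territory id
    achieved_coverage: np.ndarray  # nearest pixel-count realizable fraction
    expresses: np.ndarray  # per territory id
    af_amplitudes: np.ndarray  # per territory id (0 when autofluorescence off)
    trogosomes: list = field(default_factory=list)  # dicts: owner, center, diameter_um, hollow
    planted_pct_large: float | None = None

    @property
    def n_cells(self) -> int:
        return int(self.territories.max())


# ----------------------------------------------------------------------------
# geometry helpers


def _tumor_region(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.shape
    if params.whole_field_tumor:
        return np.ones((h, w), dtype=bool)
    yy, xx = np.indices((h, w))
    cy, cx = (h - 1) / 2, (w - 1) / 2
    rho = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    base_r = params.tumor_region_radius_frac * min(h, w)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    wob = params.tumor_region_wobble
    r_theta = base_r * (1 + wob * np.sin(3 * theta + phi1) + 0.6 * wob * np.sin(5 * theta + phi2))
    return rho <= r_theta


def _poisson_disk(
    allowed: np.ndarray,
    n: int,
    min_dist_px: float,
    rng: np.random.Generator,
    taken: np.ndarray | None = None,
    max_tries_per_point: int = 2000,
) -> np.ndarray:
    """Dart-throwing Poisson-disk sampling of n centers inside a mask."""
    coords = np.argwhere(allowed)
    if len(coords) == 0 and n > 0:
        raise GenerationError("no room to place cells; reduce counts or spacing")
    accepted: list[np.ndarray] = [] if taken is None else [c for c in taken]
    placed = []
    d2_min = min_dist_px**2
    for _ in range(n):
        for _try in range(max_tries_per_point):
            cand = coords[rng.integers(len(coords))]
            if accepted:
                arr = np.asarray(accepted, dtype=np.float64)
                if ((arr - cand) ** 2).sum(axis=1).min() < d2_min:
                    continue
            accepted.append(cand.astype(np.float64))
            placed.append(cand)
            break
        else:
            raise GenerationError(
                f"could not place {n} cells at {min_dist_px:.1f} px spacing; "
                "use fewer cells or a larger field"
            )
    return np.asarray(placed, dtype=np.float64).reshape(-1, 2)


def _jittered_grid(
    shape: tuple[int, int],
    n: int,
    min_dist_px: float,
    margin_px: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jittered square-grid placement for confluent monolayers.

    The grid step is the largest that still yields n sites; jitter is capped
    so neighbors stay ``min_dist_px`` apart.  Deterministic per rng state.
    """
    h, w = shape
    usable_h, usable_w = h - 2 * margin_px, w - 2 * margin_px
    per_side = int(np.ceil(np.sqrt(n)))
    step = min(usable_h, usable_w) / per_side
    if step < min_dist_px:
        raise GenerationError(
            f"cannot fit {n} cells at {min_dist_px:.0f} px spacing; "
            "use fewer cells or a larger field"
        )
    jitter = (step - min_dist_px) / 2
    gy = margin_px + step / 2 + step * np.arange(int(np.floor(usable_h / step + 1e-9)))
    gx = margin_px + step / 2 + step * np.arange(int(np.floor(usable_w / step + 1e-9)))
    centers = np.array([(y, x) for y in gy for x in gx])
    centers = centers + rng.uniform(-jitter, jitter, size=centers.shape)
    pick = rng.permutation(len(centers))[:n]
    return centers[np.sort(pick)]


def _render_disks(
    shape: tuple[int, int], centers: np.ndarray, radii_px: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Disk label raster in canonical order, plus the permutation applied.

    Returns ``(labels, perm)`` where ``perm[c - 1]`` is the input index of
    the disk that received canonical label ``c`` (labels are ordered by each
    disk's first raster pixel, which need not follow center order when radii
    differ).
    """
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.indices(shape)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii_px), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        labels[d2 <= r**2] = i
    canon = canonical_relabel(labels)
    n = len(centers)
    perm = np.zeros(n, dtype=np.int64)
    flat_raw, flat_canon = labels.ravel(), canon.ravel()
    _, first = np.unique(flat_raw, return_index=True)
    for idx in first:
        raw = flat_raw[idx]
        if raw:
            perm[flat_canon[idx] - 1] = raw - 1
    return canon, perm


def _apply_noise(
    channel: np.ndarray, params: SyntheticParams, rng: np.random.Generator
) -> np.ndarray:
    out = channel.astype(np.float64)
    if params.shading_amplitude > 0:
        h, w = out.shape
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.indices((h, w))
        ramp = (xx / max(w - 1, 1)) * np.cos(theta) + (yy / max(h - 1, 1)) * np.sin(theta)
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
        out = out + params.shading_amplitude * ramp
    if params.photon_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * params.photon_scale) / params.photon_scale
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _blur(channel: np.ndarray, sigma_px: float) -> np.ndarray:
    return ndi.gaussian_filter(channel, sigma_px) if sigma_px > 0 else channel


# ----------------------------------------------------------------------------
# field generators


def _layout(params: SyntheticParams, rng: np.random.Generator):
    """Place nuclei, build label rasters, the tumor mask and territories."""
    px = params.pixel_size_um
    region = _tumor_region(params, rng)
    margin_px = int(np.ceil((params.nucleus_radius_um + 3 * params.nucleus_radius_sd_um) / px)) + 2
    spacing_px = params.min_spacing_um / px

    if params.whole_field_tumor:
        tumor_centers = _jittered_grid(
            params.shape, params.n_tumor_cells, spacing_px, margin_px, rng
        )
    else:
        inner = ndi.binary_erosion(region, iterations=margin_px) if margin_px else region
        tumor_centers = _poisson_disk(inner, params.n_tumor_cells, spacing_px, rng)

    if params.n_stromal_cells:
        outer = ~ndi.binary_dilation(region, iterations=margin_px)
        outer[:margin_px] = outer[-margin_px:] = False
        outer[:, :margin_px] = outer[:, -margin_px:] = False
        stromal_centers = _poisson_disk(
            outer, params.n_stromal_cells, spacing_px, rng, taken=tumor_centers
        )
    else:
        stromal_centers = np.zeros((0, 2))

    centers = np.vstack([tumor_centers, stromal_centers])
    n = len(centers)
    # radii clipped to ±3 sd (physiological range) and to half the spacing so
    # neighboring disks never merge
    max_r_px = spacing_px / 2 - 1
    r_lo = max(params.nucleus_radius_um - 3 * params.nucleus_radius_sd_um, 0.1) / px
    r_hi = (params.nucleus_radius_um + 3 * params.nucleus_radius_sd_um) / px
    radii_px = np.clip(
        rng.normal(params.nucleus_radius_um, params.nucleus_radius_sd_um, size=n) / px,
        max(2.0, r_lo),
        max(2.0, min(r_hi, max_r_px)),
    )
    is_tumor_in = np.concatenate(
        [np.ones(len(tumor_centers), bool), np.zeros(len(stromal_centers), bool)]
    )

    nuclei_labels, perm = _render_disks(params.shape, centers, radii_px)
    # align per-nucleus arrays with canonical label ids
    centers, radii_px, is_tumor_in = centers[perm], radii_px[perm], is_tumor_in[perm]
    gt_nuclei = NucleiLabels(nuclei_labels)
    tumor_nuclei = select_tumor_nuclei(gt_nuclei, TumorMask(region, 0.0), 0.5)
    if tumor_nuclei.count != params.n_tumor_cells:
        raise GenerationError(
            "planted tumor nuclei are not cleanly inside the tumor region; "
            "reduce counts or spacing"
        )
    cellmap = voronoi_territories(tumor_nuclei, TumorMask(region, 0.0), px)
    return region, centers, radii_px, is_tumor_in, nuclei_labels, tumor_nuclei, cellmap


def _draw_coverages(params: SyntheticParams, rng: np.random.Generator):
    n = params.n_tumor_cells
    if params.coverage_values is not None:
        planted = np.asarray(params.coverage_values, dtype=np.float64)
        expresses = planted > 0
        return planted, expresses
    expresses = rng.random(n) < params.expressing_fraction
    lo_e, hi_e = params.expressing_coverage_range
    lo_b, hi_b = params.background_coverage_range
    planted = np.where(
        expresses,
        rng.uniform(lo_e, hi_e, size=n),
        rng.uniform(lo_b, hi_b, size=n),
    )
    return planted, expresses


def _base_channels(params, rng, centers, radii_px, is_tumor, region):
    """Nuclei and tumor-marker channels (pre-noise)."""
    h, w = params.shape
    nuclei_ch = np.zeros((h, w))
    yy, xx = np.indices((h, w))
    for (cy, cx), r in zip(centers, radii_px):
        sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        nuclei_ch[sel] = params.nuclei_amplitude
    nuclei_ch = _blur(nuclei_ch, params.psf_sigma_px)
    if params.whole_field_tumor:
        # cytoplasm glow falling off from each nucleus; the mask itself is
        # taken as the whole frame via a fixed zero threshold downstream
        d_bg = ndi.distance_transform_edt(~(_render_disks(params.shape, centers, radii_px)[0] > 0))
        sigma = 8.0 / params.pixel_size_um
        tumor_ch = params.tumor_amplitude * np.exp(-(d_bg**2) / (2 * sigma**2))
    else:
        tumor_ch = np.where(region, params.tumor_amplitude, 0.0)
    return nuclei_ch, tumor_ch


def _af_field(params, rng, cellmap):
    """Per-cell lognormal autofluorescence plateau plus a base level."""
    n = cellmap.count
    if not params.autofluorescence:
        return np.zeros(params.shape), np.zeros(n)
    amps = rng.lognormal(np.log(params.af_median), params.af_sigma_log, size=n)
    af = np.full(params.shape, params.af_base, dtype=np.float64)
    if n:
        lut = np.concatenate([[0.0], amps])
        af = af + lut[cellmap.territories]
    return af, amps


def generate_ffpe_field(params: SyntheticParams) -> tuple[MultiChannelImage, SyntheticGroundTruth]:
    """FFPE-like tumor field with planted per-cell marker coverage.

    The trogocytic channel is an exact random pixel subset of each territory
    at the planted coverage fraction (``round(c · N) / N`` recorded as the
    achieved fraction), rendered without PSF so the pre-noise coverage is an
    exact pixel-count ratio.
    """
    rng = np.random.default_rng(params.seed)
    region, centers, radii_px, is_tumor, nuclei_labels, tumor_nuclei, cellmap = _layout(params, rng)
    planted, expresses = _draw_coverages(params, rng)

    marker = np.zeros(params.shape)
    achieved = np.zeros(cellmap.count)
    flat_terr = cellmap.territories.ravel()
    for k in range(1, cellmap.count + 1):
        pix = np.flatnonzero(flat_terr == k)
        n_pos = int(round(planted[k - 1] * len(pix)))
        if n_pos:
            chosen = rng.choice(pix, size=n_pos, replace=False)
            marker.ravel()[chosen] = params.marker_amplitude
        achieved[k - 1] = n_pos / len(pix)

    af, amps = _af_field(params, rng, cellmap)
    marker = marker + af

    nuclei_ch, tumor_ch = _base_channels(params, rng, centers, radii_px, is_tumor, region)
    channels = np.stack(
        [
            _apply_noise(nuclei_ch, params, rng),
            _apply_noise(tumor_ch, params, rng),
            _apply_noise(marker, params, rng),
        ]
    ).astype(np.float32)

    image = MultiChannelImage(
        pixels=channels,
        channel_roles={"nuclei": 0, "tumor_marker": 1, "trogo_marker": 2},
        pixel_size_um=params.pixel_size_um,
        source_id=f"synthetic-ffpe-{params.seed}",
    )
    truth = SyntheticGroundTruth(
        params=params,
        nuclei_labels=nuclei_labels,
        is_tumor=is_tumor,
        nucleus_centroids=centers,
        nucleus_radii_px=radii_px,
        tumor_mask=region,
        territories=cellmap.territories,
        planted_coverage=planted,
        achieved_coverage=achieved,
        expresses=expresses,
        af_amplitudes=amps,
    )
    return image, truth


def generate_control_field(params: SyntheticParams) -> tuple[MultiChannelImage, SyntheticGroundTruth]:
    """Secondary-antibody-only control: marker channel is background only."""
    zero = params.replace(
        coverage_values=tuple([0.0] * params.n_tumor_cells),
        expressing_fraction=0.0,
    )
    image, truth = generate_ffpe_field(zero)
    image = MultiChannelImage(
        pixels=image.pixels,
        channel_roles=dict(image.channel_roles),
        pixel_size_um=image.pixel_size_um,
        source_id=f"synthetic-control-{params.seed}",
    )
    return image, truth


def _place_trogosome(
    territory_mask: np.ndarray,
    nucleus_center: np.ndarray,
    nucleus_radius_px: float,
    radius_px: float,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """A center whose ring fits in the territory, centroid outside the nucleus."""
    r_int = int(np.ceil(radius_px)) + 2
    allowed = ndi.binary_erosion(territory_mask, iterations=r_int)
    if not allowed.any():
        return None
    yy, xx = np.indices(territory_mask.shape)
    far_enough = (yy - nucleus_center[0]) ** 2 + (xx - nucleus_center[1]) ** 2 > (
        nucleus_radius_px + 2
    ) ** 2
    allowed &= far_enough
    coords = np.argwhere(allowed)
    if len(coords) == 0:
        return None
    return tuple(coords[rng.integers(len(coords))])


def generate_coculture_field(params: SyntheticParams) -> tuple[MultiChannelImage, SyntheticGroundTruth]:
    """Co-culture monolayer with planted hollow trogosome rings.

    Exactly ``round(trog_fraction_large · n)`` cells receive one trogosome
    drawn from the large-diameter range; a further ``trog_small_fraction`` of
    the remaining cells receive a small one.  ``trog_diameters_um`` instead
    plants one trogosome of each listed diameter in cells 1, 2, ….  Rings
    are annuli of outer radius d/2 (inner 70%) at full amplitude with the
    interior filled at ``trog_hollow_fraction`` of ring intensity; a planted
    ring always fits inside its territory with its center off the nucleus.
    """
    rng = np.random.default_rng(params.seed)
    region, centers, radii_px, is_tumor, nuclei_labels, tumor_nuclei, cellmap = _layout(params, rng)
    px = params.pixel_size_um
    n = cellmap.count

    assignments: list[tuple[int, float]] = []  # (owner id, diameter um)
    if params.trog_diameters_um is not None:
        if len(params.trog_diameters_um) > n:
            raise GenerationError("more planted diameters than cells")
        assignments = [(k + 1, float(d)) for k, d in enumerate(params.trog_diameters_um)]
        n_large_cells = sum(d > 5.0 for _, d in assignments)
    else:
        ids = rng.permutation(n) + 1
        n_large = int(round(params.trog_fraction_large * n))
        lo, hi = params.trog_large_diameter_range
        for k in ids[:n_large]:
            assignments.append((int(k), float(rng.uniform(lo, hi))))
        rest = ids[n_large:]
        n_small = int(round(params.trog_small_fraction * len(rest)))
        lo_s, hi_s = params.trog_small_diameter_range
        for k in rest[:n_small]:
            assignments.append((int(k), float(rng.uniform(lo_s, hi_s))))
        n_large_cells = n_large

    # territory id k corresponds to the k-th tumor nucleus in raster order
    t_centers, t_radii = centers[is_tumor], radii_px[is_tumor]
    marker = np.zeros(params.shape)
    yy, xx = np.indices(params.shape)
    trogosomes = []
    for owner, d_um in sorted(assignments):
        radius_px = d_um / 2 / px
        terr_mask = cellmap.territories == owner
        center = _place_trogosome(
            terr_mask, t_centers[owner - 1], t_radii[owner - 1], radius_px, rng
        )
        if center is None:
            raise GenerationError(
                f"cell {owner}: no room for a {d_um:.1f} µm trogosome; "
                "increase spacing or shrink diameters"
            )
        rho2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
        # annulus at least 2 px thick so rasterization leaves it watertight
        inner_r = min(params.trog_ring_inner_fraction * radius_px, radius_px - 2.0)
        inside = rho2 <= radius_px**2
        ring = inside & (rho2 > inner_r**2)
        marker[inside] = np.maximum(
            marker[inside], params.trog_hollow_fraction * params.trog_ring_amplitude
        )
        marker[ring] = params.trog_ring_amplitude
        trogosomes.append(
            {
                "owner": owner,
                "center": (int(center[0]), int(center[1])),
                "diameter_um": d_um,
                "hollow_fraction": params.trog_hollow_fraction,
            }
        )
    marker = _blur(marker, params.psf_sigma_px)

    af, amps = _af_field(params, rng, cellmap)
    marker = marker + af

    nuclei_ch, tumor_ch = _base_channels(params, rng, centers, radii_px, is_tumor, region)
    channels = np.stack(
        [
            _apply_noise(nuclei_ch, params, rng),
            _apply_noise(tumor_ch, params, rng),
            _apply_noise(marker, params, rng),
        ]
    ).astype(np.float32)

    image = MultiChannelImage(
        pixels=channels,
        channel_roles={"nuclei": 0, "tumor_marker": 1, "trogo_marker": 2},
        pixel_size_um=px,
        source_id=f"synthetic-coculture-{params.seed}",
    )
    truth = SyntheticGroundTruth(
        params=params,
        nuclei_labels=nuclei_labels,
        is_tumor=is_tumor,
        nucleus_centroids=centers,
        nucleus_radii_px=radii_px,
        tumor_mask=region,
        territories=cellmap.territories,
        planted_coverage=np.zeros(n),
        achieved_coverage=np.zeros(n),
        expresses=np.zeros(n, dtype=bool),
        af_amplitudes=amps,
        trogosomes=trogosomes,
        planted_pct_large=100.0 * n_large_cells / n if n else None,
    )
    return image, truth


def generate_coculture_timecourse(
    params_per_timepoint: Sequence[SyntheticParams],
) -> list[tuple[MultiChannelImage, SyntheticGroundTruth]]:
    """One co-culture field per timepoint."""
    if len(params_per_timepoint) < 1:
        raise ValidationError("need at least one timepoint")
    return [generate_coculture_field(p) for p in params_per_timepoint]


def default_timecourse_params(seed: int = 0, **overrides) -> list[SyntheticParams]:
    """The 4 h / 8 h / 16 h co-culture design.

    Planted fractions of cells bearing a large (> 5 µm) trogosome rise with
    co-culture duration — 10%, 35% and 62% — mirroring progressive trogosome
    accumulation and growth over a timecourse.
    """
    fracs = (0.10, 0.35, 0.62)
    return [
        SyntheticParams.coculture(
            trog_fraction_large=f, seed=seed + i, **overrides
        )
        for i, f in enumerate(fracs)
    ]
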