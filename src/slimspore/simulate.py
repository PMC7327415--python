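"""Ground-truthed synthetic Slimfield data.

The generator emulates the imaging physics of a two-channel millisecond
single-molecule fluorescence microscope pointed at rod-shaped *B. subtilis*
cells:

* the cell membrane is a hollow cylinder capped with hemispherical shells
  at either end, with 1-pixel-thick walls, stained in the FM4-64 channel;
* sporulation produces a stage-specific spore feature -- a cell-width disk
  septum (stage II_i), released SpoIIE modelled as a hemispherical shell
  capped by a disk (stage II_ii), a hemispherical-shell septum during
  engulfment (stage II_iii) and a spherical shell after engulfment
  (stage III).  The SpoIIE feature appears in the mYPet channel and the
  corresponding membrane structure in the FM channel (identical except in
  stage II_ii, where the membrane septum is still flat); stage I has no
  feature.  Septal/engulfment membrane carries twice the stain density of
  the lateral wall, reflecting its double leaflet;
* every emitter contributes a 2D Gaussian point spread function
  (FWHM ~250 nm); emitters outside the ~350 nm depth of field are rendered
  wider (linearly in defocus) with their photon count conserved;
* optional Poisson shot noise plus a constant camera background and
  Gaussian read noise.

Photobleaching stacks, Brownian diffusing-foci movies and FRAP recovery
curves are generated with the same conventions so that every downstream
estimator can be validated against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

STAGES = ("I", "II_i", "II_ii", "II_iii", "III")

# ---------------------------------------------------------------------------
# domain types


@dataclass
class CellGeometry:
    """Rod-shaped cell plus stage-specific spore feature, all lengths in nm
    unless suffixed otherwise.

    ``length_um`` is the cylindrical body only; the hemispherical caps add
    one cell radius at each end.  ``feature_params`` carries the
    stage-specific dimensions (septum offset from the pole-side cap base,
    released-shell radius, engulfment-dome radius, spore-shell radius).
    """

    length_um: float = 2.4
    width_um: float = 0.9
    pixel_size_nm: float = 80.0
    wall_thickness_px: float = 1.0
    stage: str = "I"
    feature_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("cell dimensions and pixel size must be positive")
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        defaults = {
            # septum plane, measured from the pole-side cap base into the body
            "septum_offset_nm": 300.0,
            # released-SpoIIE shell (stage II_ii)
            "release_radius_nm": 280.0,
            # engulfment dome (stage II_iii); the engulfing membrane hugs
            # the cell wall, so its radius is close to the inner cell radius
            "dome_radius_nm": 420.0,
            # engulfed spore shell (stage III)
            "spore_radius_nm": 330.0,
        }
        defaults.update(self.feature_params)
        self.feature_params = defaults

    @property
    def radius_nm(self) -> float:
        return self.width_um * 1e3 / 2.0

    @property
    def length_nm(self) -> float:
        return self.length_um * 1e3

    @property
    def wall_nm(self) -> float:
        return self.wall_thickness_px * self.pixel_size_nm


@dataclass
class EmitterModel:
    """Point-sampled fluorophore density on the declared surfaces.

    ``positions_nm`` is (n, 3): x along the cell axis (0 at the pole-distal
    cap base), y across the cell, z along the optical axis (0 at the cell
    mid-plane).  ``brightness`` is expected photons per emitter per frame.
    """

    positions_nm: np.ndarray
    brightness: np.ndarray
    channel: str = "mYPet"
    geometry: CellGeometry | None = None

    @property
    def n(self) -> int:
        return len(self.positions_nm)

    @property
    def total_brightness(self) -> float:
        return float(np.sum(self.brightness))


@dataclass
class NoiseModel:
    """Camera noise: constant background offset, Poisson shot noise and
    optional Gaussian read noise.  The presets are stand-ins for camera
    calibrations at two severities."""

    background_offset: float = 0.0
    poisson: bool = False
    gaussian_read_sigma: float = 0.0
    preset: str = "none"

    def __post_init__(self) -> None:
        if self.background_offset < 0 or self.gaussian_read_sigma < 0:
            raise ValueError("noise parameters must be nonnegative")

    @classmethod
    def from_preset(cls, name: str) -> "NoiseModel":
        presets = {
            "none": cls(0.0, False, 0.0, "none"),
            "average": cls(20.0, True, 2.0, "average"),
            "extreme": cls(80.0, True, 10.0, "extreme"),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(f"unknown noise preset {name!r}") from None


@dataclass
class ImageStack:
    """Time-ordered photon-count frames with calibration metadata."""

    frames: np.ndarray                  # (T, H, W), photons
    frame_interval_ms: float = 5.0
    pixel_size_nm: float = 80.0
    channel: str = "mYPet"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (T, H, W) with T >= 1")
        if self.frame_interval_ms <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("calibration fields must be positive")
        if np.any(self.frames < 0):
            raise ValueError("photon counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ms


@dataclass
class GroundTruth:
    """Sidecar truth for a synthetic dataset (whatever the generator knows)."""

    stage: str | None = None
    positions_nm: np.ndarray | None = None      # per-focus true positions
    stoichiometries: np.ndarray | None = None
    D_um2_s: float | None = None
    sigma_loc_nm: float | None = None
    t_b_ms: float | None = None
    t_r_s: float | None = None
    I_single: float | None = None
    n_molecules: int | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# surface samplers (uniform by area, seeded)


def _sample_cylinder(rng, n, radius, x0, x1):
    x = rng.uniform(x0, x1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([x, radius * np.cos(phi), radius * np.sin(phi)])


def _sample_sphere_band(rng, n, radius, center, cos_lo=-1.0, cos_hi=1.0,
                        axis_sign=1.0):
    """Uniform points on the spherical zone with axial direction cosine in
    [cos_lo, cos_hi]; the zone axis is +x scaled by ``axis_sign``."""
    c = rng.uniform(cos_lo, cos_hi, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(np.clip(1 - c ** 2, 0, None))
    pts = np.column_stack([
        axis_sign * radius * c,
        radius * s * np.cos(phi),
        radius * s * np.sin(phi),
    ])
    return pts + np.asarray(center)


def _sample_disk(rng, n, radius, x, r_min=0.0):
    r = np.sqrt(rng.uniform(r_min ** 2, radius ** 2, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([np.full(n, float(x)),
                            r * np.cos(phi), r * np.sin(phi)])


def _cell_surfaces(geom: CellGeometry):
    """(sampler, area_um2) pairs for the plain membrane."""
    r, L = geom.radius_nm, geom.length_nm
    cyl_area = 2 * np.pi * r * L * 1e-6
    cap_area = 2 * np.pi * r ** 2 * 1e-6
    return [
        (lambda rng, n: _sample_cylinder(rng, n, r, 0.0, L), cyl_area),
        (lambda rng, n: _sample_sphere_band(rng, n, r, (0.0, 0, 0), 0, 1, -1.0),
         cap_area),
        (lambda rng, n: _sample_sphere_band(rng, n, r, (L, 0, 0), 0, 1, 1.0),
         cap_area),
    ]


def _feature_surfaces(geom: CellGeometry, channel: str = "mYPet"):
    """(sampler, area_um2) pairs for the stage-specific spore feature.

    The feature sits at the pole-side (x = L) end of the cell.  Stage I has
    no feature.  The FM4-64 channel reports membrane topology, so during
    stage II_ii it shows the (still flat) asymmetric septum while the mYPet
    channel shows the released SpoIIE envelope; in every other stage the
    SpoIIE feature coincides with the septal/engulfment membrane and the
    same geometry is rendered in both channels.
    """
    p = geom.feature_params
    r, L = geom.radius_nm, geom.length_nm
    xs = L - p["septum_offset_nm"]           # septum plane
    if geom.stage == "I":
        return []
    if geom.stage == "II_i" or (geom.stage == "II_ii" and channel == "FM"):
        # flat cell-width disk septum
        area = np.pi * r ** 2 * 1e-6
        return [(lambda rng, n: _sample_disk(rng, n, r, xs), area)]
    if geom.stage == "II_ii":
        # released SpoIIE coats the forespore envelope: polar hemispherical
        # shell closed by the septal disk, joined by the short cylindrical
        # flank of the forespore membrane
        rf = p["release_radius_nm"]
        flank = rf
        hemi = 2 * np.pi * rf ** 2 * 1e-6
        disk = np.pi * rf ** 2 * 1e-6
        side = 2 * np.pi * rf * flank * 1e-6
        return [
            (lambda rng, n: _sample_sphere_band(
                rng, n, rf, (xs + flank, 0, 0), 0, 1, 1.0), hemi),
            (lambda rng, n: _sample_cylinder(rng, n, rf, xs, xs + flank), side),
            (lambda rng, n: _sample_disk(rng, n, rf, xs), disk),
        ]
    if geom.stage == "II_iii":
        # engulfment: hemispherical-shell septum, apex toward the mother cell
        rd = p["dome_radius_nm"]
        hemi = 2 * np.pi * rd ** 2 * 1e-6
        return [
            (lambda rng, n: _sample_sphere_band(rng, n, rd, (xs, 0, 0), 0, 1, -1.0),
             hemi),
        ]
    if geom.stage == "III":
        # engulfed forespore: full spherical shell near the pole
        rs = p["spore_radius_nm"]
        xc = L + geom.radius_nm - rs - 1.5 * geom.wall_nm
        area = 4 * np.pi * rs ** 2 * 1e-6
        return [
            (lambda rng, n: _sample_sphere_band(rng, n, rs, (xc, 0, 0), -1, 1, 1.0),
             area),
        ]
    raise ValueError(f"unknown stage {geom.stage!r}")


def build_cell_model(
    geometry: CellGeometry,
    seed: int,
    channel: str = "mYPet",
    surface_density_um2: float = 4000.0,
    brightness: float = 100.0,
    septum_density_factor: float = 2.0,
) -> EmitterModel:
    """Sample fluorophore positions on the membrane/feature surfaces.

    The FM4-64 channel carries the whole membrane (cylinder + two
    hemispherical caps) plus the stage feature at ``septum_density_factor``
    times the lateral-wall density (septal/engulfment membrane is a double
    leaflet).  The mYPet channel carries the feature only; a stage-I mYPet
    model is therefore empty.  Emitters are jittered radially by half the
    wall thickness.  Placement is uniform by surface area and seeded.
    """
    if channel not in ("mYPet", "FM"):
        raise ValueError(f"unknown channel {channel!r}")
    rng = np.random.default_rng(seed)
    surfaces: list[tuple] = []
    if channel == "FM":
        surfaces += [(s, a, 1.0) for s, a in _cell_surfaces(geometry)]
        surfaces += [(s, a, septum_density_factor)
                     for s, a in _feature_surfaces(geometry, channel)]
    else:
        surfaces += [(s, a, 1.0) for s, a in _feature_surfaces(geometry, channel)]

    chunks = []
    for sampler, area, factor in surfaces:
        n = int(round(surface_density_um2 * area * factor))
        if n == 0:
            continue
        pts = sampler(rng, n)
        # 1-px wall: radial jitter about the surface, isotropic stand-in
        pts = pts + rng.uniform(-geometry.wall_nm / 2, geometry.wall_nm / 2,
                                pts.shape)
        chunks.append(pts)
    if chunks:
        positions = np.vstack(chunks)
    else:
        positions = np.empty((0, 3))
    return EmitterModel(
        positions_nm=positions,
        brightness=np.full(len(positions), float(brightness)),
        channel=channel,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# rendering


def _defocus_sigma_px(z_nm, psf_fwhm_nm, focal_plane_nm, depth_of_field_nm,
                      pixel_size_nm, defocus_slope=1.0):
    """PSF width per emitter: nominal inside the depth of field, growing
    linearly with defocus beyond it (photons conserved by renormalization)."""
    sigma0 = psf_fwhm_nm / 2.355 / pixel_size_nm
    dz = np.abs(np.asarray(z_nm, dtype=float) - focal_plane_nm)
    excess = np.clip(dz - depth_of_field_nm / 2.0, 0.0, None)
    return sigma0 * (1.0 + defocus_slope * excess / (depth_of_field_nm / 2.0))


def render_spots(
    shape: tuple[int, int],
    x_px: np.ndarray,
    y_px: np.ndarray,
    sigma_px: np.ndarray,
    brightness: np.ndarray,
) -> np.ndarray:
    """Accumulate sub-pixel 2D Gaussians of per-spot width onto a frame.

    Each spot deposits exactly ``brightness`` photons on an infinite grid
    (the kernel is normalized by its discrete sum over a +-4 sigma window),
    so summed frame intensity conserves total emitter brightness for spots
    away from the edge.
    """
    h, w = shape
    out = np.zeros((h, w))
    x_px = np.atleast_1d(np.asarray(x_px, dtype=float))
    y_px = np.atleast_1d(np.asarray(y_px, dtype=float))
    sigma_px = np.broadcast_to(np.atleast_1d(np.asarray(sigma_px, float)),
                               x_px.shape)
    brightness = np.broadcast_to(np.atleast_1d(np.asarray(brightness, float)),
                                 x_px.shape)
    if x_px.size == 0:
        return out
    # group by window radius so widely defocused emitters don't force a
    # huge window on everything
    radius = np.maximum(np.ceil(4.0 * sigma_px).astype(int), 2)
    out_pad = None
    rmax = int(radius.max())
    hp, wp = h + 2 * rmax, w + 2 * rmax
    out_pad = np.zeros(hp * wp)
    for r in np.unique(radius):
        sel = radius == r
        cx = x_px[sel] + rmax
        cy = y_px[sel] + rmax
        s = sigma_px[sel]
        b = brightness[sel]
        ix = np.round(cx).astype(int)
        iy = np.round(cy).astype(int)
        offs = np.arange(-r, r + 1)
        gx = np.exp(-0.5 * ((ix[:, None] + offs[None, :] - cx[:, None])
                            / s[:, None]) ** 2)
        gy = np.exp(-0.5 * ((iy[:, None] + offs[None, :] - cy[:, None])
                            / s[:, None]) ** 2)
        gx /= gx.sum(axis=1, keepdims=True)
        gy /= gy.sum(axis=1, keepdims=True)
        wgt = b[:, None, None] * gy[:, :, None] * gx[:, None, :]
        rows = iy[:, None] + offs[None, :]
        cols = ix[:, None] + offs[None, :]
        flat = (rows[:, :, None] * wp + cols[:, None, :]).ravel()
        out_pad += np.bincount(flat, weights=wgt.ravel(), minlength=hp * wp)
    out_pad = out_pad.reshape(hp, wp)
    return out_pad[rmax:rmax + h, rmax:rmax + w]


def apply_noise(expected: np.ndarray, noise: NoiseModel | None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Poisson-draw each pixel about expectation + background; clip at 0."""
    if noise is None or (not noise.poisson and noise.background_offset == 0
                         and noise.gaussian_read_sigma == 0):
        return expected.copy()
    if rng is None:
        rng = np.random.default_rng()
    img = expected + noise.background_offset
    if noise.poisson:
        img = rng.poisson(img).astype(float)
    if noise.gaussian_read_sigma > 0:
        img = img + rng.normal(0, noise.gaussian_read_sigma, img.shape)
    return np.clip(img, 0, None)


def frame_shape_for(geometry: CellGeometry, margin_px: int = 10) -> tuple[int, int]:
    px = geometry.pixel_size_nm
    w = int(np.ceil((geometry.length_nm + 2 * geometry.radius_nm) / px)) + 2 * margin_px
    h = int(np.ceil(2 * geometry.radius_nm / px)) + 2 * margin_px
    return h, w


def render_frame(
    model: EmitterModel,
    psf_fwhm_nm: float = 250.0,
    focal_plane_nm: float = 0.0,
    depth_of_field_nm: float = 350.0,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    shape: tuple[int, int] | None = None,
    margin_px: int = 10,
    defocus_slope: float = 1.0,
) -> np.ndarray:
    """Render one expected-photon frame of an emitter model (plus noise).

    The cell axis runs along image columns; the frame origin places the
    pole-distal cap base at column ``margin_px`` and the cell axis at the
    middle row.  With ``noise=None`` the output is the exact expected-photon
    image.
    """
    if psf_fwhm_nm <= 0:
        raise ValueError("psf_fwhm_nm must be positive")
    geom = model.geometry
    if shape is None:
        if geom is None:
            raise ValueError("shape required for models without geometry")
        shape = frame_shape_for(geom, margin_px)
    h, w = shape
    px = geom.pixel_size_nm if geom is not None else 80.0
    if model.n == 0:
        expected = np.zeros(shape)
    else:
        pos = model.positions_nm
        x0 = -(geom.radius_nm if geom is not None else 0.0) - margin_px * px
        x_px = (pos[:, 0] - x0) / px - 0.5
        y_px = pos[:, 1] / px + h / 2.0 - 0.5
        sig = _defocus_sigma_px(pos[:, 2], psf_fwhm_nm, focal_plane_nm,
                                depth_of_field_nm, px, defocus_slope)
        expected = render_spots(shape, x_px, y_px, sig, model.brightness)
    rng = np.random.default_rng(seed)
    return apply_noise(expected, noise, rng)


def simulate_stage_image(
    geometry: CellGeometry,
    seed: int,
    noise: NoiseModel | None = None,
    n_average_frames: int = 5,
    psf_fwhm_nm: float = 250.0,
    depth_of_field_nm: float = 350.0,
    surface_density_um2: float = 4000.0,
    brightness: float = 100.0,
) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Render a two-channel stack for one stage-labelled cell.

    Returns {"mYPet": stack, "FM": stack} of ``n_average_frames`` frames
    (identical expectations, independently noised) plus ground truth.
    """
    stacks = {}
    rng = np.random.default_rng(seed)
    for channel in ("mYPet", "FM"):
        model = build_cell_model(geometry, seed=int(rng.integers(2 ** 31)),
                                 channel=channel,
                                 surface_density_um2=surface_density_um2,
                                 brightness=brightness)
        expected = render_frame(model, psf_fwhm_nm=psf_fwhm_nm,
                                depth_of_field_nm=depth_of_field_nm,
                                noise=None)
        frames = np.stack([
            apply_noise(expected, noise,
                        np.random.default_rng(int(rng.integers(2 ** 31))))
            for _ in range(n_average_frames)
        ])
        stacks[channel] = ImageStack(frames, pixel_size_nm=geometry.pixel_size_nm,
                                     channel=channel)
    truth = GroundTruth(stage=geometry.stage,
                        extras={"geometry": geometry})
    return stacks, truth


# ---------------------------------------------------------------------------
# photobleaching stacks


def simulate_bleach_stack(
    foci_spec: Sequence[tuple[tuple[float, float], int]],
    t_b_ms: float = 100.0,
    I_single: float = 100.0,
    n_frames: int = 60,
    frame_interval_ms: float = 5.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (48, 48),
    psf_fwhm_nm: float = 250.0,
    pixel_size_nm: float = 80.0,
) -> tuple[ImageStack, GroundTruth]:
    """Step-wise photobleaching movie of static foci.

    ``foci_spec`` is a list of ((x_px, y_px), stoichiometry).  Each molecule
    photobleaches independently with exponential lifetime ``t_b_ms``; a
    focus' brightness is its surviving-molecule count times ``I_single``, so
    noise-free traces drop in steps of ~``I_single`` and the ensemble mean
    decays as exp(-t / t_b).
    """
    if t_b_ms <= 0:
        raise ValueError("t_b_ms must be positive")
    positions = []
    stoichs = []
    for (x, y), s in foci_spec:
        if s < 1:
            raise ValueError("stoichiometries must be >= 1")
        positions.append((float(x), float(y)))
        stoichs.append(int(s))
    rng = np.random.default_rng(seed)
    sigma_px = psf_fwhm_nm / 2.355 / pixel_size_nm
    times = np.arange(n_frames) * frame_interval_ms
    # per-molecule exponential bleach times
    lifetimes = [rng.exponential(t_b_ms, s) for s in stoichs]
    surviving = np.array([
        [int(np.sum(lt > t)) for t in times] for lt in lifetimes
    ])  # (n_foci, n_frames)
    frames = np.empty((n_frames,) + shape)
    xs = np.array([p[0] for p in positions])
    ys = np.array([p[1] for p in positions])
    for i in range(n_frames):
        b = surviving[:, i] * I_single
        frames[i] = apply_noise(
            render_spots(shape, xs, ys, np.full(len(xs), sigma_px), b),
            noise, np.random.default_rng(int(rng.integers(2 ** 31))))
    stack = ImageStack(frames, frame_interval_ms=frame_interval_ms,
                       pixel_size_nm=pixel_size_nm, channel="mYPet")
    truth = GroundTruth(
        positions_nm=np.column_stack([xs, ys]) * pixel_size_nm,
        stoichiometries=np.array(stoichs),
        t_b_ms=t_b_ms, I_single=I_single,
        extras={"surviving": surviving, "times_ms": times},
    )
    return stack, truth


def bleach_traces(stack: ImageStack, truth: GroundTruth,
                  radius_px: float = 5.0) -> list[np.ndarray]:
    """Noise-free-style intensity traces read from a bleach stack by direct
    circular-aperture sums at the true positions (generator-side helper; the
    analysis path uses :mod:`slimspore.tracking`)."""
    h, w = stack.frames.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    traces = []
    for pos in truth.positions_nm / stack.pixel_size_nm:
        mask = (xx - pos[0]) ** 2 + (yy - pos[1]) ** 2 <= radius_px ** 2
        traces.append(stack.frames[:, mask].sum(axis=1))
    return traces


# ---------------------------------------------------------------------------
# diffusing foci


def simulate_diffusing_foci(
    D_um2_s: float,
    n_tracks: int,
    n_frames: int,
    frame_interval_ms: float = 5.0,
    sigma_loc_nm: float = 40.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], GroundTruth]:
    """2D Brownian trajectories with Gaussian localization error.

    Returns a list of (n_frames, 2) arrays of *observed* positions in nm
    (true Brownian path, step variance 2 D dt per axis, plus independent
    N(0, sigma_loc) on every coordinate) and the ground truth with the true
    paths in ``extras['true_positions']``.
    """
    if D_um2_s < 0 or sigma_loc_nm < 0:
        raise ValueError("D and localization error must be nonnegative")
    rng = np.random.default_rng(seed)
    dt_s = frame_interval_ms * 1e-3
    step_sd_nm = np.sqrt(2.0 * D_um2_s * dt_s) * 1e3   # per axis
    observed, true_paths = [], []
    for _ in range(n_tracks):
        steps = rng.normal(0.0, step_sd_nm, (n_frames - 1, 2))
        path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        obs = path + rng.normal(0.0, sigma_loc_nm, path.shape)
        true_paths.append(path)
        observed.append(obs)
    truth = GroundTruth(D_um2_s=D_um2_s, sigma_loc_nm=sigma_loc_nm,
                        extras={"true_positions": true_paths,
                                "frame_interval_ms": frame_interval_ms})
    return observed, truth


# ---------------------------------------------------------------------------
# FRAP


def simulate_frap(
    t_r_s: float,
    f_bleach: float,
    f_plateau: float,
    times_s: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Exponential fluorescence recovery
    f(t) = f_plateau - (f_plateau - f_bleach) exp(-t / t_r), plus optional
    Gaussian noise.  Times are seconds after the bleach."""
    if t_r_s <= 0:
        raise ValueError("t_r_s must be positive")
    if not (0 <= f_bleach <= f_plateau <= 1):
        raise ValueError("require 0 <= f_bleach <= f_plateau <= 1")
    t = np.asarray(times_s, dtype=float)
    f = f_plateau - (f_plateau - f_bleach) * np.exp(-t / t_r_s)
    if noise_sigma > 0:
        f = f + np.random.default_rng(seed).normal(0, noise_sigma, f.shape)
    return f


# ---------------------------------------------------------------------------
# dataset writer


def write_synthetic_dataset(
    out_dir: str | Path,
    stage: str,
    n_cells: int,
    noise: str = "none",
    seed: int = 0,
    length_range_um: tuple[float, float] = (2.0, 3.0),
    **render_kwargs,
) -> list[dict]:
    """Simulate ``n_cells`` stage-labelled cells, write one multi-page TIFF
    per channel per cell plus a JSON ground-truth sidecar; returns the
    manifest."""
    from slimspore.io import save_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    noise_model = NoiseModel.from_preset(noise)
    manifest = []
    for i in range(n_cells):
        geom = CellGeometry(
            length_um=float(rng.uniform(*length_range_um)), stage=stage)
        stacks, truth = simulate_stage_image(
            geom, seed=int(rng.integers(2 ** 31)), noise=noise_model,
            **render_kwargs)
        rec = {"cell_id": f"{stage}_{i:04d}", "stage": stage,
               "length_um": geom.length_um, "width_um": geom.width_um}
        for channel, stack in stacks.items():
            fname = out / f"{rec['cell_id']}_{channel}.tif"
            save_stack(stack, fname)
            rec[f"{channel}_file"] = fname.name
        manifest.append(rec)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
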