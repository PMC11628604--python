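"""Synthetic fluorescence-microscopy benchmark generator.

Produces calibrated multi-channel fields of view (amyloid-plaque stain,
microglia stain, astrocyte reporter), single-channel TIRF-style spot frames,
and per-mouse cohort tables, all with exact ground truth. The generator is
the benchmark for the downstream quantification stages: plaques are rendered
with a tunable bright-core / speckled-halo structure (a monotone knob for
texture-based compactness), microglia as blurred somata with random-walk
branch processes whose density near plaque edges scales with plaque load,
and dose–response tables follow a linear APOE -> guanidine-soluble Abeta42
model with group-specific slopes.

Every draw goes through `numpy.random.default_rng`, so identical
(config, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import ConfigurationError, child_seed

# Field-of-view extents of the 40x / 20x objectives (um) and the default
# sampling used for rendered frames.
FOV_40X_UM = 438.88
FOV_20X_UM = 880.42
DEFAULT_PIXEL_SIZE_UM = 0.43

# Plaque-association rule: centroid inside the plaque mask or within this
# distance of its edge.
ASSOCIATION_RADIUS_UM = 5.0

# Rendered intensity levels (arbitrary fluorescence units, pre-noise).
# The plaque channel is bright so that shot noise stays small relative to
# the core/halo contrast: the homogeneous core then occupies few gray levels
# after per-plaque quantization while the speckled halo (per-pixel uniform
# intensities) spreads over many, which is what makes ASM a monotone
# compactness readout.
_BACKGROUND = 8.0
_PLAQUE_CORE = 3200.0
_HALO_LO = 400.0
_HALO_HI = 2800.0
_SOMA_LEVEL = 150.0
_BRANCH_LEVEL = 110.0

# Microglial depletion by CSF1R inhibition, as the surviving fraction of the
# baseline population per genotype group (83% / 77% / 87% reductions).
PLX_SURVIVING_FRACTION = {"APOE2": 0.17, "APOE3": 0.23, "APOE4": 0.13}
# Shift in mean guanidine-soluble Abeta42 under depletion, per group
# (treatment contrasts of the confounder-adjusted regressions).
PLX_ABETA_SHIFT = {"APOE2": -148.2, "APOE3": -28.53, "APOE4": -357.1}


@dataclass
class FieldOfView:
    """A calibrated multi-channel 2D image.

    channels: float array (C, H, W); channel_roles maps a role name
    ("plaque", "microglia", "reporter", or "spots") to a channel index.
    """

    channels: np.ndarray
    channel_roles: dict
    pixel_size_um: float
    fov_size_um: float

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.channels.ndim != 3:
            raise ConfigurationError("channels must be a (C, H, W) array")
        n = self.channels.shape[1]
        if self.channels.shape[1] != self.channels.shape[2]:
            raise ConfigurationError("frames are square")
        if abs(n * self.pixel_size_um - self.fov_size_um) > self.pixel_size_um:
            raise ConfigurationError(
                "pixel_size_um * pixel count must equal fov_size_um within one pixel"
            )

    def channel(self, role: str) -> np.ndarray:
        return self.channels[self.channel_roles[role]]

    @property
    def n_pixels(self) -> int:
        return self.channels.shape[1]


@dataclass
class GroundTruth:
    """Instance-level truth for one field of view.

    plaques / microglia are per-instance tables; the label images map every
    labelled pixel to exactly one instance (1-based ids matching the table).
    """

    plaque_labels: np.ndarray | None = None
    plaques: pd.DataFrame | None = None
    microglia_labels: np.ndarray | None = None
    microglia: pd.DataFrame | None = None
    spot_positions: np.ndarray | None = None  # (K, 2) as (x, y) pixel coords

    @property
    def n_plaques(self) -> int:
        return 0 if self.plaques is None else len(self.plaques)

    @property
    def n_microglia(self) -> int:
        return 0 if self.microglia is None else len(self.microglia)

    @property
    def n_spots(self) -> int:
        return 0 if self.spot_positions is None else len(self.spot_positions)


@dataclass
class GroupSpec:
    """Generative parameters of one experimental group.

    plaque_density is the Poisson mean of plaques per FOV; diameters are
    log-normal (median um, sigma of log); core_fraction is Beta(a, b) or a
    fixed float in [0, 1]; APOE levels are log-normal in arbitrary ELISA
    units with Abeta42 = intercept + slope * APOE + N(0, noise_sd);
    pa_recruitment_coeff adds plaque-associated microglia per unit plaque
    area fraction; spot_rate is the Poisson mean of soluble-aggregate spots
    per TIRF frame.
    """

    name: str
    plaque_density: float = 0.0
    plaque_diameter_dist: tuple = (20.0, 0.35)
    core_fraction_dist: object = (4.0, 4.0)
    apoe_level_dist: tuple = (2000.0, 0.4)
    abeta_slope: float = 0.0
    abeta_intercept: float = 100.0
    abeta_noise_sd: float = 80.0
    microglia_base_density: float = 60.0
    pa_recruitment_coeff: float = 900.0
    spot_rate: float = 50.0
    treatment: str = "control"

    def __post_init__(self):
        for attr in ("plaque_density", "microglia_base_density",
                     "pa_recruitment_coeff", "spot_rate"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{attr} must be >= 0")
        if isinstance(self.core_fraction_dist, (int, float)):
            if not 0.0 <= float(self.core_fraction_dist) <= 1.0:
                raise ConfigurationError("fixed core_fraction must be in [0, 1]")

    def sample_core_fraction(self, rng: np.random.Generator) -> float:
        if isinstance(self.core_fraction_dist, (int, float)):
            return float(self.core_fraction_dist)
        a, b = self.core_fraction_dist
        return float(rng.beta(a, b))

    def expected_abeta(self) -> float:
        med, sig = self.apoe_level_dist
        mean_apoe = 0.0 if med <= 0 else med * np.exp(sig**2 / 2.0)
        return self.abeta_intercept + self.abeta_slope * mean_apoe


def default_groups() -> list[GroupSpec]:
    """The four-group study design: APOE-null plus three isoform groups.

    Slopes of the Abeta42 dose–response are the isoform-specific values
    (APOE4 0.23, APOE2 0.11, APOE3 0.005); the knockout forms no fibrillar
    plaques but carries the highest soluble-aggregate load.
    """
    return [
        GroupSpec("APOEKO", plaque_density=0.0, apoe_level_dist=(0.0, 0.0),
                  abeta_slope=0.0, abeta_intercept=30.0, abeta_noise_sd=15.0,
                  spot_rate=140.0),
        GroupSpec("APOE2", plaque_density=12.0, abeta_slope=0.11,
                  abeta_noise_sd=105.0, spot_rate=80.0),
        GroupSpec("APOE3", plaque_density=6.0, abeta_slope=0.005,
                  abeta_noise_sd=100.0, spot_rate=45.0),
        GroupSpec("APOE4", plaque_density=25.0, abeta_slope=0.23,
                  abeta_noise_sd=150.0, spot_rate=40.0),
    ]


def plx_treated(spec: GroupSpec) -> GroupSpec:
    """CSF1R-inhibitor (PLX3397) counterpart of a group.

    Microglial densities are multiplied by the group's surviving fraction
    and the Abeta42 intercept shifted by the depletion contrast.
    """
    f = PLX_SURVIVING_FRACTION.get(spec.name, 0.2)
    return replace(
        spec,
        treatment="PLX3397",
        microglia_base_density=spec.microglia_base_density * f,
        pa_recruitment_coeff=spec.pa_recruitment_coeff * f,
        abeta_intercept=spec.abeta_intercept + PLX_ABETA_SHIFT.get(spec.name, 0.0),
    )


@dataclass
class CohortConfig:
    groups: list
    mice_per_group: int = 8
    fovs_per_mouse: int = 3       # mean of 3 fields of view per mouse
    rng_seed: int = 0
    simpull_replicates: int = 3   # technical replicates per mouse
    simpull_fovs_per_replicate: int = 9

    def __post_init__(self):
        if self.mice_per_group < 1:
            raise ConfigurationError("mice_per_group must be >= 1")
        if self.fovs_per_mouse < 1:
            raise ConfigurationError("fovs_per_mouse must be >= 1")


@dataclass
class CohortTable:
    """Tables emitted by the cohort generator.

    mice: one row per mouse (group, treatment, apoe_level, abeta42 plus
    per-FOV aggregates averaged over that mouse's FOVs); fovs: one row per
    FOV with ground-truth counts; spots: one row per TIRF frame.
    """

    mice: pd.DataFrame
    fovs: pd.DataFrame
    spots: pd.DataFrame


# ---------------------------------------------------------------------------
# geometry sampling (shared by the rendered and table-only paths)
# ---------------------------------------------------------------------------

@dataclass
class _FovGeometry:
    # plaques: columns cx_um, cy_um, radius_um, core_fraction
    plaques: pd.DataFrame
    # cells: columns x_um, y_um, soma_radius_um, recruited, plaque_associated
    cells: pd.DataFrame
    area_fraction: float


def _sample_fov_geometry(spec: GroupSpec, rng: np.random.Generator,
                         fov_size_um: float,
                         plaque_density: float | None = None) -> _FovGeometry:
    dens = spec.plaque_density if plaque_density is None else plaque_density
    n_plq = int(rng.poisson(dens))
    med, sig = spec.plaque_diameter_dist

    cx, cy, radii, cores = [], [], [], []
    for _ in range(n_plq):
        d = med * float(np.exp(sig * rng.standard_normal()))
        r = max(d / 2.0, 1.0)
        cf = spec.sample_core_fraction(rng)
        placed = False
        for _attempt in range(200):
            x = float(rng.uniform(r + 1.0, fov_size_um - r - 1.0))
            y = float(rng.uniform(r + 1.0, fov_size_um - r - 1.0))
            if all(np.hypot(x - px, y - py) >= r + pr + 2.0
                   for px, py, pr in zip(cx, cy, radii)):
                placed = True
                break
        if not placed:
            # dense field: accept the last candidate, overlaps allowed
            pass
        cx.append(x)
        cy.append(y)
        radii.append(r)
        cores.append(cf)
    plaques = pd.DataFrame({"cx_um": cx, "cy_um": cy, "radius_um": radii,
                            "core_fraction": cores})
    area_fraction = float(np.pi * np.sum(np.square(radii)) / fov_size_um**2)

    # Homogeneous background pool; cells landing within the association
    # radius of a plaque are plaque-associated, which makes the residual
    # non-associated count decline with plaque load.
    n_base = int(rng.poisson(spec.microglia_base_density))
    bx = rng.uniform(5.0, fov_size_um - 5.0, size=n_base)
    by = rng.uniform(5.0, fov_size_um - 5.0, size=n_base)
    # Recruitment: extra plaque-associated cells in the peri-plaque ring.
    n_rec = int(rng.poisson(spec.pa_recruitment_coeff * area_fraction))
    rx, ry = [], []
    if n_rec > 0 and n_plq > 0:
        weights = np.square(radii) / np.sum(np.square(radii))
        which = rng.choice(n_plq, size=n_rec, p=weights)
        ang = rng.uniform(0.0, 2 * np.pi, size=n_rec)
        rad = np.array(radii)[which] + rng.uniform(-2.0, 4.0, size=n_rec)
        rx = np.clip(np.array(cx)[which] + rad * np.cos(ang), 5.0, fov_size_um - 5.0)
        ry = np.clip(np.array(cy)[which] + rad * np.sin(ang), 5.0, fov_size_um - 5.0)
    x_all = np.concatenate([bx, np.asarray(rx, float)])
    y_all = np.concatenate([by, np.asarray(ry, float)])
    recruited = np.concatenate([np.zeros(n_base, bool), np.ones(len(np.asarray(rx, float)), bool)])

    if n_plq > 0 and len(x_all) > 0:
        dx = x_all[:, None] - np.asarray(cx)[None, :]
        dy = y_all[:, None] - np.asarray(cy)[None, :]
        edge = np.hypot(dx, dy) - np.asarray(radii)[None, :]
        pa = edge.min(axis=1) <= ASSOCIATION_RADIUS_UM
    else:
        pa = np.zeros(len(x_all), bool)

    soma_r = np.clip(rng.normal(3.5, 0.4, size=len(x_all)), 2.5, 5.0)
    cells = pd.DataFrame({"x_um": x_all, "y_um": y_all,
                          "soma_radius_um": soma_r,
                          "recruited": recruited,
                          "plaque_associated": pa})
    return _FovGeometry(plaques=plaques, cells=cells, area_fraction=area_fraction)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _disk_grids(n_px: int, cx: float, cy: float, r: float):
    """Bounding-box slice and distance grid for a disk (pixel coords)."""
    lo_y = max(int(np.floor(cy - r)) - 1, 0)
    hi_y = min(int(np.ceil(cy + r)) + 2, n_px)
    lo_x = max(int(np.floor(cx - r)) - 1, 0)
    hi_x = min(int(np.ceil(cx + r)) + 2, n_px)
    yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
    d = np.hypot(yy - cy, xx - cx)
    return (slice(lo_y, hi_y), slice(lo_x, hi_x)), d


def _render_plaque_channel(geom: _FovGeometry, rng, n_px, pixel_size_um):
    img = np.full((n_px, n_px), _BACKGROUND)
    labels = np.zeros((n_px, n_px), np.int32)
    for i, row in enumerate(geom.plaques.itertuples(), start=1):
        r_px = row.radius_um / pixel_size_um
        cx_px = row.cx_um / pixel_size_um
        cy_px = row.cy_um / pixel_size_um
        sl, d = _disk_grids(n_px, cx_px, cy_px, r_px)
        inside = d <= r_px
        core = d <= row.core_fraction * r_px
        halo = inside & ~core
        speckle = rng.uniform(_HALO_LO, _HALO_HI, size=d.shape)
        patch = img[sl]
        patch[core] = np.maximum(patch[core], _PLAQUE_CORE)
        patch[halo] = np.maximum(patch[halo], speckle[halo])
        lab = labels[sl]
        lab[inside & (lab == 0)] = i
    return img, labels


def _walk_branch(rng, y0, x0, target_len_px, n_px):
    """Persistent 8-neighbour random walk; returns pixels and length in px."""
    ang = float(rng.uniform(0, 2 * np.pi))
    y, x = float(y0), float(x0)
    pix = []
    length = 0.0
    while length < target_len_px:
        ang += float(rng.normal(0.0, 0.25))
        dy = int(np.round(np.sin(ang)))
        dx = int(np.round(np.cos(ang)))
        if dy == 0 and dx == 0:
            dx = 1
        y += dy
        x += dx
        if not (0 <= y < n_px and 0 <= x < n_px):
            break
        step = float(np.hypot(dy, dx))
        length += step
        pix.append((int(y), int(x)))
    return pix, length


def _render_microglia_channel(geom: _FovGeometry, rng, n_px, pixel_size_um):
    img = np.full((n_px, n_px), _BACKGROUND)
    labels = np.zeros((n_px, n_px), np.int32)
    # pixels contested by overlapping cells belong to the nearer soma centre
    owner_dist = np.full((n_px, n_px), np.inf)
    proc_len_um = np.zeros(len(geom.cells))
    for i, row in enumerate(geom.cells.itertuples(), start=1):
        cx_px = row.x_um / pixel_size_um
        cy_px = row.y_um / pixel_size_um
        r_px = row.soma_radius_um / pixel_size_um
        n_branches = int(rng.integers(3, 7))
        total = 0.0
        for _b in range(n_branches):
            target_um = float(rng.uniform(8.0, 25.0))
            ang0 = float(rng.uniform(0, 2 * np.pi))
            y0 = cy_px + r_px * np.sin(ang0)
            x0 = cx_px + r_px * np.cos(ang0)
            pix, length_px = _walk_branch(rng, y0, x0, target_um / pixel_size_um, n_px)
            total += length_px * pixel_size_um
            for (py, px_) in pix:
                img[py, px_] = max(img[py, px_], _BRANCH_LEVEL)
                d = float(np.hypot(py - cy_px, px_ - cx_px))
                if d < owner_dist[py, px_]:
                    owner_dist[py, px_] = d
                    labels[py, px_] = i
        sl, d = _disk_grids(n_px, cx_px, cy_px, r_px)
        inside = d <= r_px
        patch = img[sl]
        patch[inside] = np.maximum(patch[inside], _SOMA_LEVEL)
        lab = labels[sl]
        od = owner_dist[sl]
        closer = inside & (d < od)
        lab[closer] = i
        od[closer] = d[closer]
        proc_len_um[i - 1] = total
    img = ndi.gaussian_filter(img, 1.0)
    return img, labels, proc_len_um


def _render_reporter_channel(rng, n_px):
    img = np.zeros((n_px, n_px))
    n_blobs = int(rng.integers(4, 9))
    for _ in range(n_blobs):
        y, x = rng.uniform(0, n_px, size=2)
        img[int(y) % n_px, int(x) % n_px] += float(rng.uniform(2e4, 6e4))
    img = ndi.gaussian_filter(img, n_px / 16.0) + _BACKGROUND
    return img


def _add_noise(img, rng, read_noise_sd=2.0):
    """Poisson shot noise plus additive Gaussian read noise."""
    out = rng.poisson(np.clip(img, 0, None)).astype(float)
    out += rng.normal(0.0, read_noise_sd, size=img.shape)
    return out


def generate_fov(spec: GroupSpec, seed: int, *,
                 pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                 fov_size_um: float = FOV_40X_UM,
                 plaque_density: float | None = None,
                 read_noise_sd: float = 2.0,
                 shot_noise: bool = True) -> tuple[FieldOfView, GroundTruth]:
    """Render one multi-channel field of view with ground truth."""
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be > 0")
    rng = np.random.default_rng(seed)
    n_px = int(round(fov_size_um / pixel_size_um))
    geom = _sample_fov_geometry(spec, rng, fov_size_um, plaque_density)

    plq_img, plq_labels = _render_plaque_channel(geom, rng, n_px, pixel_size_um)
    mic_img, mic_labels, proc_len = _render_microglia_channel(
        geom, rng, n_px, pixel_size_um)
    rep_img = _render_reporter_channel(rng, n_px)

    chans = []
    for im in (plq_img, mic_img, rep_img):
        if shot_noise:
            chans.append(_add_noise(im, rng, read_noise_sd))
        else:
            chans.append(im + rng.normal(0.0, read_noise_sd, size=im.shape))

    fov = FieldOfView(channels=np.stack(chans),
                      channel_roles={"plaque": 0, "microglia": 1, "reporter": 2},
                      pixel_size_um=pixel_size_um,
                      fov_size_um=n_px * pixel_size_um)
    plaques = geom.plaques.copy()
    plaques.insert(0, "plaque_id", np.arange(1, len(plaques) + 1))
    microglia = geom.cells.copy()
    microglia.insert(0, "cell_id", np.arange(1, len(microglia) + 1))
    microglia["process_length_um"] = proc_len
    gt = GroundTruth(plaque_labels=plq_labels, plaques=plaques,
                     microglia_labels=mic_labels, microglia=microglia)
    return fov, gt


def generate_simpull_fov(spec: GroupSpec, seed: int, *,
                         frame_px: int = 256,
                         pixel_size_um: float = 0.16,
                         spot_sigma_px: float = 1.5,
                         snr: float = 10.0,
                         background: float = 50.0,
                         read_noise_sd: float = 2.0,
                         spot_rate: float | None = None
                         ) -> tuple[FieldOfView, GroundTruth]:
    """One TIRF-style frame of diffraction-limited spots over noisy background.

    SNR is the peak spot amplitude over the background noise SD
    (sqrt(background shot variance + read variance)).
    """
    if spec.spot_rate < 0:
        raise ConfigurationError("spot_rate must be >= 0")
    rng = np.random.default_rng(seed)
    rate = spec.spot_rate if spot_rate is None else spot_rate
    k = int(rng.poisson(rate))
    margin = 4.0 * spot_sigma_px
    if k > 0:
        xs = rng.uniform(margin, frame_px - margin, size=k)
        ys = rng.uniform(margin, frame_px - margin, size=k)
        pos = np.column_stack([xs, ys])
    else:
        pos = np.zeros((0, 2))

    noise_sd = float(np.sqrt(background + read_noise_sd**2))
    amp = snr * noise_sd
    img = np.full((frame_px, frame_px), background)
    half = int(np.ceil(4 * spot_sigma_px))
    for x, y in pos:
        lo_y, hi_y = max(int(y) - half, 0), min(int(y) + half + 1, frame_px)
        lo_x, hi_x = max(int(x) - half, 0), min(int(x) + half + 1, frame_px)
        yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        img[lo_y:hi_y, lo_x:hi_x] += amp * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * spot_sigma_px**2))
    img = _add_noise(img, rng, read_noise_sd)

    fov = FieldOfView(channels=img[None, :, :], channel_roles={"spots": 0},
                      pixel_size_um=pixel_size_um,
                      fov_size_um=frame_px * pixel_size_um)
    return fov, GroundTruth(spot_positions=pos)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _mouse_id(spec: GroupSpec, j: int) -> str:
    tag = spec.name if spec.treatment == "control" else f"{spec.name}+{spec.treatment}"
    return f"{tag}-m{j:02d}"


def generate_cohort(config: CohortConfig, *,
                    render_images: bool = False,
                    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                    fov_size_um: float = FOV_40X_UM
                    ) -> tuple[list, CohortTable]:
    """Generate a cohort: per-mouse dose–response values plus per-FOV truth.

    Per mouse, APOE level is drawn from the group's log-normal, Abeta42 from
    the linear dose–response, and that mouse's plaque density is scaled by
    its Abeta42 relative to the group expectation, coupling plaque load to
    amyloid burden. Geometry and rendering use separate child RNG streams,
    so the emitted tables are identical whether or not images are rendered.
    """
    seed = config.rng_seed
    fovs_out = []
    mouse_rows, fov_rows, spot_rows = [], [], []
    for gi, spec in enumerate(config.groups):
        for j in range(config.mice_per_group):
            mid = _mouse_id(spec, j)
            m_rng = np.random.default_rng(child_seed(seed, f"mouse/{gi}/{j}"))
            med, sig = spec.apoe_level_dist
            apoe = 0.0 if med <= 0 else float(med * np.exp(sig * m_rng.standard_normal()))
            abeta = float(spec.abeta_intercept + spec.abeta_slope * apoe
                          + m_rng.normal(0.0, spec.abeta_noise_sd))
            expected = spec.expected_abeta()
            if spec.plaque_density > 0 and expected > 0:
                dens = spec.plaque_density * max(abeta, 0.0) / expected
            else:
                dens = spec.plaque_density
            mouse_rows.append(dict(mouse_id=mid, group=spec.name,
                                   treatment=spec.treatment,
                                   apoe_level=apoe, abeta42=abeta,
                                   plaque_density=dens))
            for k in range(config.fovs_per_mouse):
                g_rng = np.random.default_rng(child_seed(seed, f"geom/{mid}/{k}"))
                geom = _sample_fov_geometry(spec, g_rng, fov_size_um, dens)
                n_pa = int(geom.cells["plaque_associated"].sum())
                fov_rows.append(dict(
                    mouse_id=mid, group=spec.name, treatment=spec.treatment,
                    fov=k, n_plaques=len(geom.plaques),
                    plaque_area_fraction=geom.area_fraction,
                    n_microglia=len(geom.cells), n_pa=n_pa,
                    n_nonpa=len(geom.cells) - n_pa))
                if render_images:
                    r_seed = child_seed(seed, f"render/{mid}/{k}")
                    fov, gt = _render_geometry(
                        spec, geom, r_seed, pixel_size_um, fov_size_um)
                    fovs_out.append((fov, gt))
            for r in range(config.simpull_replicates):
                s_rng = np.random.default_rng(child_seed(seed, f"spots/{mid}/{r}"))
                counts = s_rng.poisson(spec.spot_rate,
                                       size=config.simpull_fovs_per_replicate)
                for f, c in enumerate(counts):
                    spot_rows.append(dict(mouse_id=mid, group=spec.name,
                                          treatment=spec.treatment,
                                          replicate=r, frame=f, n_spots=int(c)))

    mice = pd.DataFrame(mouse_rows)
    fovs = pd.DataFrame(fov_rows)
    spots = pd.DataFrame(spot_rows)
    agg = (fovs.groupby("mouse_id")
               [["n_plaques", "plaque_area_fraction", "n_microglia", "n_pa", "n_nonpa"]]
               .mean().add_prefix("mean_"))
    mice = mice.merge(agg, on="mouse_id", how="left")
    return fovs_out, CohortTable(mice=mice, fovs=fovs, spots=spots)


def _render_geometry(spec, geom, seed, pixel_size_um, fov_size_um):
    """Render a pre-sampled FOV geometry (used by the cohort path)."""
    rng = np.random.default_rng(seed)
    n_px = int(round(fov_size_um / pixel_size_um))
    plq_img, plq_labels = _render_plaque_channel(geom, rng, n_px, pixel_size_um)
    mic_img, mic_labels, proc_len = _render_microglia_channel(
        geom, rng, n_px, pixel_size_um)
    rep_img = _render_reporter_channel(rng, n_px)
    chans = [_add_noise(im, rng) for im in (plq_img, mic_img, rep_img)]
    fov = FieldOfView(channels=np.stack(chans),
                      channel_roles={"plaque": 0, "microglia": 1, "reporter": 2},
                      pixel_size_um=pixel_size_um,
                      fov_size_um=n_px * pixel_size_um)
    plaques = geom.plaques.copy()
    plaques.insert(0, "plaque_id", np.arange(1, len(plaques) + 1))
    microglia = geom.cells.copy()
    microglia.insert(0, "cell_id", np.arange(1, len(microglia) + 1))
    microglia["process_length_um"] = proc_len
    return fov, GroundTruth(plaque_labels=plq_labels, plaques=plaques,
                            microglia_labels=mic_labels, microglia=microglia)


def simulate_cohort_table(config: CohortConfig) -> CohortTable:
    """Table-level cohort draw (no pixel rendering); identical tables to
    `generate_cohort(..., render_images=True)` under the same config."""
    return generate_cohort(config, render_images=False)[1]
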