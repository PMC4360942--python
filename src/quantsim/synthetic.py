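"""Ground-truth simulator for calibration and SIM inputs, plus the
Monte-Carlo ensemble oracle used to validate the predicted noise maps.

Forward model
-------------
Expected per-phase signal at pixel (row, col):

    lambda_i = F * (1 + m * cos(2*pi*col/T + phi + (i-1)*2*pi/3)) + B

with F the in-focus photon density, B the unmodulated (out-of-focus)
background, m the modulation contrast, T the grid period in pixels and phi
the grid phase. The camera maps photons to grey levels as

    DN = round(clip(g * Poisson(lambda) + Normal(0, sigma_read) + offset,
                    0, 2^bits - 1))

Background is injected directly as the unmodulated B term rather than via
PSF convolution of a 3-D object: the per-pixel reconstruction algorithms
only distinguish modulated from unmodulated light, so this is the minimal
faithful model.

All randomness flows from one master seed through ``numpy.random.
SeedSequence`` spawning, so every output is bit-reproducible and per-frame
streams are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .calibration import FlatFieldSeries, IlluminationLevel
from .errors import LayoutError
from .reconstruction import CalibrationProfile, process_triplet
from .sim_model import DEFAULT_PHASE_ORDER, PHASE_STEP, split_concatenated


@dataclass(frozen=True)
class CameraModel:
    """Linear camera: gain (DN/photon), dark offset, Gaussian read noise."""

    gain_dn_per_photon: float = 2.0
    offset_dn: float = 100.0
    read_noise_sigma_dn: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.gain_dn_per_photon > 0:
            raise ValueError(f"gain must be positive, got {self.gain_dn_per_photon}")
        if self.read_noise_sigma_dn < 0:
            raise ValueError("read noise sigma cannot be negative")
        if not 8 <= int(self.bit_depth) <= 16:
            raise ValueError(f"bit_depth must be in [8, 16], got {self.bit_depth}")

    @property
    def full_scale(self) -> int:
        return 2 ** int(self.bit_depth) - 1

    def expose(
        self, expected_photons: NDArray[np.float64], rng: np.random.Generator
    ) -> NDArray[np.float64]:
        """One noisy exposure of an expected-photon image, in DN."""
        photons = rng.poisson(expected_photons).astype(np.float64)
        dn = self.gain_dn_per_photon * photons + self.offset_dn
        if self.read_noise_sigma_dn > 0:
            dn = dn + rng.normal(0.0, self.read_noise_sigma_dn, size=dn.shape)
        return np.clip(np.rint(dn), 0, self.full_scale)

    def expose_noiseless(self, expected_photons: NDArray[np.float64]) -> NDArray[np.float64]:
        """Deterministic exposure: no Poisson/read noise, no rounding/clipping."""
        return self.gain_dn_per_photon * np.asarray(expected_photons, float) + self.offset_dn


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth for one depth layer of a SIM acquisition.

    ``in_focus_photons`` (F) and ``background_photons`` (B) are expected
    photons per frame; scalars broadcast to ``shape``.
    """

    in_focus_photons: NDArray[np.float64]
    background_photons: NDArray[np.float64]
    modulation_contrast: float = 0.5
    grid_period_px: float = 8.0
    grid_phase_rad: float = 0.0
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.in_focus_photons, dtype=np.float64)
        b = np.asarray(self.background_photons, dtype=np.float64)
        shape = self.shape
        if shape is None:
            shape = f.shape if f.ndim == 2 else b.shape if b.ndim == 2 else None
        if shape is None or len(shape) != 2:
            raise LayoutError(
                "scene shape is undetermined: pass 2-D F/B images or an "
                "explicit shape for scalar photon densities"
            )
        f = np.broadcast_to(f, shape).astype(np.float64)
        b = np.broadcast_to(b, shape).astype(np.float64)
        if (f < 0).any() or (b < 0).any():
            raise ValueError("photon densities must be non-negative everywhere")
        if not 0.0 < self.modulation_contrast <= 1.0:
            raise ValueError(
                f"modulation contrast must lie in (0, 1], got {self.modulation_contrast}"
            )
        if not self.grid_period_px > 0:
            raise ValueError("grid period must be positive")
        object.__setattr__(self, "in_focus_photons", f)
        object.__setattr__(self, "background_photons", b)
        object.__setattr__(self, "shape", tuple(shape))

    def expected_phases(self) -> tuple[NDArray[np.float64], ...]:
        """Expected photons per pixel for each of the three grid phases."""
        rows, cols = self.shape
        x = np.arange(cols, dtype=np.float64)[None, :]
        carrier = 2.0 * np.pi * x / self.grid_period_px + self.grid_phase_rad
        out = []
        for i in range(3):
            mod = 1.0 + self.modulation_contrast * np.cos(carrier + i * PHASE_STEP)
            out.append(self.in_focus_photons * mod + self.background_photons)
        return tuple(np.broadcast_to(p, self.shape).astype(np.float64) for p in out)


def uniform_scene(
    shape: tuple[int, int],
    in_focus: float,
    background: float = 0.0,
    *,
    modulation_contrast: float = 0.5,
    grid_period_px: float = 8.0,
    grid_phase_rad: float = 0.0,
) -> SyntheticScene:
    """Spatially flat scene — the workhorse for moment checks."""
    return SyntheticScene(
        in_focus_photons=np.full(shape, float(in_focus)),
        background_photons=np.full(shape, float(background)),
        modulation_contrast=modulation_contrast,
        grid_period_px=grid_period_px,
        grid_phase_rad=grid_phase_rad,
    )


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def render_triplet(
    scene: SyntheticScene,
    camera: CameraModel,
    *,
    seed: int = 0,
    noiseless: bool = False,
    order: tuple[int, int, int] = DEFAULT_PHASE_ORDER,
) -> NDArray[np.float64]:
    """Render one concatenated 3M x N DN image of the scene.

    The three phase exposures use independent random streams spawned from
    ``seed``. With ``noiseless`` the expected DN are returned without
    Poisson/Gaussian noise or quantization. A saturation warning is issued
    (not raised) if the expected DN exceed full scale anywhere.
    """
    lambdas = scene.expected_phases()
    expected_peak_dn = camera.expose_noiseless(max(float(l.max()) for l in lambdas))
    if expected_peak_dn > camera.full_scale:
        warnings.warn(
            f"expected signal reaches {expected_peak_dn:.0f} DN, above the "
            f"camera full scale of {camera.full_scale}; highlights will clip",
            stacklevel=2,
        )
    if sorted(order) != [0, 1, 2]:
        raise ValueError(f"phase order must permute (0, 1, 2), got {order}")
    if noiseless:
        frames = [camera.expose_noiseless(l) for l in lambdas]
    else:
        rngs = _spawn_rngs(seed, 3)
        frames = [camera.expose(l, rng) for l, rng in zip(lambdas, rngs)]
    return np.concatenate([frames[phase_idx] for phase_idx in order], axis=0)


def default_photon_levels(
    camera: CameraModel,
    n_levels: int = 8,
    *,
    top_fraction: float = 0.8,
    decades: float = 2.2,
) -> list[float]:
    """Standard photon-transfer illumination ladder for a camera.

    A dark level followed by a geometric ramp ending at ``top_fraction`` of
    full scale. Geometric spacing concentrates levels at low intensity,
    where the read-noise intercept is constrained, while still reaching
    near saturation as the acquisition protocol requires.
    """
    if n_levels < 6:
        raise ValueError(
            f"{n_levels} levels requested; the protocol requires more than five"
        )
    top = top_fraction * (camera.full_scale - camera.offset_dn) / camera.gain_dn_per_photon
    ramp = top * 10.0 ** np.linspace(-decades, 0.0, n_levels - 1)
    return [0.0] + [float(v) for v in ramp]


def render_flatfield_series(
    camera: CameraModel,
    photon_levels: list[float] | None = None,
    *,
    frame_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    bit_depth: int | None = None,
) -> FlatFieldSeries:
    """Simulate the photon-transfer protocol: two frames per level.

    ``photon_levels`` are expected photons per pixel, ordered from the
    mandatory zero-illumination dark level upward; more than five levels
    are required, matching the acquisition protocol. Defaults to
    :func:`default_photon_levels` for the camera.
    """
    if photon_levels is None:
        photon_levels = default_photon_levels(camera)
    levels = [float(v) for v in photon_levels]
    if len(levels) < 6:
        raise LayoutError(
            f"{len(levels)} illumination levels given; the protocol requires "
            "more than five steps"
        )
    if levels[0] != 0.0:
        raise LayoutError(
            f"the first level must be the dark (0 photon) pair, got {levels[0]}"
        )
    rngs = _spawn_rngs(seed, 2 * len(levels))
    out = []
    for k, n_photons in enumerate(levels):
        lam = np.full(frame_shape, n_photons)
        frame_a = camera.expose(lam, rngs[2 * k])
        frame_b = camera.expose(lam, rngs[2 * k + 1])
        out.append(IlluminationLevel(frame_a, frame_b, nominal_order=k))
    return FlatFieldSeries(
        levels=tuple(out),
        bit_depth=bit_depth if bit_depth is not None else camera.bit_depth,
        integration_time_tag="synthetic",
    )


def render_bead_field(
    n_beads: int,
    peak_photons: float,
    *,
    bead_sigma_px: float = 1.2,
    shape: tuple[int, int] = (256, 256),
    modulation_contrast: float = 0.6,
    grid_period_px: float = 8.0,
    grid_phase_rad: float = 0.0,
    background_photons: float = 0.0,
    camera: CameraModel | None = None,
    seed: int = 0,
    noiseless: bool = False,
) -> NDArray[np.float64]:
    """Simulate a thin fluorescent-bead slide as a concatenated DN triplet.

    Beads are Gaussian spots of peak ``peak_photons`` at uniformly random
    positions; background defaults to zero, matching the thin-sample
    assumption (beads smaller than the sectioning thickness) under which
    the sectioned/wide-field ratio equals the modulation contrast.
    """
    if camera is None:
        camera = CameraModel()
    pos_rng, render_seed = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.Generator(np.random.PCG64(pos_rng))
    rows, cols = shape
    f = np.zeros(shape, dtype=np.float64)
    if n_beads > 0:
        ys = rng.uniform(0, rows, size=n_beads)
        xs = rng.uniform(0, cols, size=n_beads)
        yy = np.arange(rows, dtype=np.float64)[:, None]
        xx = np.arange(cols, dtype=np.float64)[None, :]
        for y0, x0 in zip(ys, xs):
            f += peak_photons * np.exp(
                -((yy - y0) ** 2 + (xx - x0) ** 2) / (2.0 * bead_sigma_px**2)
            )
    scene = SyntheticScene(
        in_focus_photons=f,
        background_photons=np.full(shape, float(background_photons)),
        modulation_contrast=modulation_contrast,
        grid_period_px=grid_period_px,
        grid_phase_rad=grid_phase_rad,
    )
    return render_triplet(
        scene, camera, seed=render_seed.generate_state(1)[0] % (2**31), noiseless=noiseless
    )


def render_stack(
    scenes: list[SyntheticScene],
    camera: CameraModel,
    *,
    seed: int = 0,
    noiseless: bool = False,
) -> list[NDArray[np.float64]]:
    """Render one concatenated triplet per depth, independently seeded."""
    if not scenes:
        raise LayoutError("stack is empty: at least one scene is required")
    shape = scenes[0].shape
    for k, scene in enumerate(scenes):
        if scene.shape != shape:
            raise LayoutError(
                f"scene {k} has shape {scene.shape}, expected {shape}"
            )
    page_seeds = [s.generate_state(1)[0] % (2**31)
                  for s in np.random.SeedSequence(seed).spawn(len(scenes))]
    return [
        render_triplet(scene, camera, seed=ps, noiseless=noiseless)
        for scene, ps in zip(scenes, page_seeds)
    ]


@dataclass(frozen=True)
class EnsembleStats:
    """Pixel-wise ensemble mean and standard deviation of the four outputs."""

    mean: dict[str, NDArray[np.float64]]
    std: dict[str, NDArray[np.float64]]
    n_reps: int


def monte_carlo_oracle(
    scene: SyntheticScene,
    camera: CameraModel,
    calib: CalibrationProfile,
    *,
    n_reps: int = 1000,
    seed: int = 0,
) -> EnsembleStats:
    """Empirical reference for the noise maps.

    Renders ``n_reps`` independent triplets of the same scene, reconstructs
    each, and returns the per-pixel ensemble mean and standard deviation of
    all four output images. The ensemble standard deviation of the photon
    images is the ground truth the predicted noise maps are judged
    against.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100 for stable statistics, got {n_reps}")
    rep_seeds = [s.generate_state(1)[0] % (2**31)
                 for s in np.random.SeedSequence(seed).spawn(n_reps)]
    names = ("widefield", "sectioned", "widefield_noise", "sectioned_noise")
    acc = {n: np.zeros(scene.shape) for n in names}
    acc_sq = {n: np.zeros(scene.shape) for n in names}
    baseline: dict[str, NDArray[np.float64]] = {}
    for rs in rep_seeds:
        concat = render_triplet(scene, camera, seed=rs)
        result = process_triplet(split_concatenated(concat), calib)
        for n, img in result.images().items():
            # accumulate relative to the first replicate to avoid
            # catastrophic cancellation in the variance
            if n not in baseline:
                baseline[n] = img.copy()
            delta = img - baseline[n]
            acc[n] += delta
            acc_sq[n] += delta * delta
    mean_delta = {n: acc[n] / n_reps for n in names}
    mean = {n: baseline[n] + mean_delta[n] for n in names}
    std = {
        n: np.sqrt(np.maximum(acc_sq[n] / n_reps - mean_delta[n] ** 2, 0.0)
                   * n_reps / (n_reps - 1))
        for n in names
    }
    return EnsembleStats(mean=mean, std=std, n_reps=n_reps)
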