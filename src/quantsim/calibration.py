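"""Camera-gain and modulation-contrast calibration.

Two bench experiments feed the quantitative pipeline:

1. *Photon transfer* — pairs of uniformly illuminated frames at more than
   five illumination levels from dark to near saturation. For a linear
   shot-noise-limited camera, variance(DN) = g * mean(DN above dark) +
   read-noise variance, so an ordinary least-squares line through the
   mean-variance points yields the gain g (DN/photon) and the read noise.
   Differencing the two frames of each pair cancels fixed-pattern structure
   before the variance is estimated.

2. *Modulation contrast* — a raw SIM triplet of a thin fluorescent-bead
   layer. With negligible out-of-focus light the demodulated amplitude over
   the wide-field image equals the illumination modulation contrast m at
   every lit pixel; the median of that ratio over the brightest pixels is
   the calibrated m, one scalar per objective/grid combination.

The classic shot-noise photon counter N = (mean/sigma)^2 is provided as a
cross-check on uniform fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence
import warnings

import numpy as np
from numpy.typing import NDArray
from scipy import stats

from .errors import (
    CalibrationError,
    EmptySelectionError,
    InsufficientLevelsError,
    LayoutError,
)
from .sim_model import PhaseTriplet, sectioned_raw, widefield_raw

MIN_LEVELS = 6  # the protocol requires more than five illumination steps
DEFAULT_SATURATION_CUT = 0.9
DEFAULT_SELECTION_PERCENTILE = 95.0


@dataclass(frozen=True)
class IlluminationLevel:
    """One illumination step: two frames captured at identical settings."""

    frame_a: NDArray[np.float64]
    frame_b: NDArray[np.float64]
    nominal_order: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.frame_a, dtype=np.float64)
        b = np.asarray(self.frame_b, dtype=np.float64)
        if a.shape != b.shape:
            raise LayoutError(
                f"paired frames must share dimensions, got {a.shape} vs {b.shape}"
            )
        object.__setattr__(self, "frame_a", a)
        object.__setattr__(self, "frame_b", b)


@dataclass(frozen=True)
class FlatFieldSeries:
    """Ordered flat-field levels for photon-transfer calibration.

    The first level must be the dark (zero-illumination) pair; it anchors
    the camera offset. More than five levels are required.
    """

    levels: tuple[IlluminationLevel, ...]
    bit_depth: int = 16
    integration_time_tag: str = ""

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        if len(levels) < MIN_LEVELS:
            raise InsufficientLevelsError(
                f"flat-field series has {len(levels)} levels; the calibration "
                f"protocol requires more than five illumination steps"
            )
        object.__setattr__(self, "levels", levels)
        if not 8 <= int(self.bit_depth) <= 16:
            raise ValueError(f"bit_depth must be in [8, 16], got {self.bit_depth}")

    @property
    def full_scale(self) -> int:
        return 2 ** int(self.bit_depth) - 1

    @property
    def dark_level_dn(self) -> float:
        """Camera offset: mean of the zero-illumination pair."""
        dark = self.levels[0]
        return float((dark.frame_a.mean() + dark.frame_b.mean()) / 2.0)


@dataclass(frozen=True)
class GainFit:
    """Photon-transfer fit result.

    gain_dn_per_photon is the slope of the variance-mean line; the
    intercept is the read-noise variance in DN^2 (clamped at zero if the
    fit extrapolates below it); offset_dn is the dark level.
    """

    gain_dn_per_photon: float
    offset_dn: float
    read_noise_var_dn2: float
    fit_points: tuple[tuple[float, float], ...] = ()
    levels_used: int = 0
    levels_excluded: int = 0

    def __post_init__(self) -> None:
        if not self.gain_dn_per_photon > 0:
            raise CalibrationError(
                f"camera gain must be positive, got {self.gain_dn_per_photon}"
            )
        if self.read_noise_var_dn2 < 0:
            raise CalibrationError(
                f"read-noise variance cannot be negative, got {self.read_noise_var_dn2}"
            )

    @property
    def read_noise_sigma_photons(self) -> float:
        """Read noise expressed as a photon-equivalent standard deviation."""
        return float(np.sqrt(self.read_noise_var_dn2) / self.gain_dn_per_photon)


@dataclass(frozen=True)
class ContrastFit:
    """Illumination modulation contrast estimate for one objective/grid."""

    modulation_contrast: float
    pixels_used: int = 0
    selection_threshold: float = float("nan")
    ratio_median: float = float("nan")
    ratio_iqr: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.modulation_contrast <= 1.0:
            raise CalibrationError(
                "modulation contrast must lie in (0, 1], got "
                f"{self.modulation_contrast}"
            )


def mean_variance_points(series: FlatFieldSeries) -> list[tuple[float, float]]:
    """Per-level (mean_dn, variance_dn2) points for the photon-transfer fit.

    mean: spatial mean of (frame_a + frame_b)/2 minus the dark level.
    variance: spatial variance of (frame_a - frame_b), halved — the pair
    difference doubles the temporal variance while cancelling any static
    per-pixel offset/response pattern common to both frames.
    """
    offset = series.dark_level_dn
    points: list[tuple[float, float]] = []
    for level in series.levels:
        mean_dn = float(((level.frame_a + level.frame_b) / 2.0).mean()) - offset
        var_dn2 = float(np.var(level.frame_a - level.frame_b)) / 2.0
        points.append((mean_dn, var_dn2))
    return points


def _variance_weighted_line(
    means: NDArray[np.float64], variances: NDArray[np.float64]
) -> tuple[float, float]:
    """Variance-weighted straight-line fit of variance against mean.

    The sampling error of a spatial variance estimate scales with the
    variance itself (sd ~ v * sqrt(2/n)), so least squares is iteratively
    reweighted by 1/fitted_variance^2, starting from an unweighted fit.
    Without the weighting the bright levels — whose variance estimates are
    absolutely the noisiest — drown out the dark levels that carry
    essentially all the information about the read-noise intercept.
    Data already on an exact line are reproduced exactly.
    """
    res = stats.linregress(means, variances)
    slope, intercept = float(res.slope), float(res.intercept)
    floor = 1e-6 * max(1.0, float(np.max(np.abs(variances))))
    for _ in range(2):
        predicted = np.maximum(slope * means + intercept, floor)
        weights = 1.0 / predicted**2
        design = np.column_stack([np.ones_like(means), means])
        wdesign = design * weights[:, None]
        coeffs = np.linalg.solve(design.T @ wdesign, wdesign.T @ variances)
        intercept, slope = float(coeffs[0]), float(coeffs[1])
    return slope, intercept


def fit_gain(
    points: Sequence[tuple[float, float]],
    *,
    saturation_cut: float = DEFAULT_SATURATION_CUT,
    bit_depth: int = 16,
    offset_dn: float = 0.0,
) -> GainFit:
    """Photon-transfer fit: variance = g * mean + read-noise variance.

    Points whose raw mean (offset re-added) exceeds ``saturation_cut`` of
    full scale are excluded before fitting; clipping near saturation bends
    the variance-mean line downward and would bias the slope.

    Raises
    ------
    InsufficientLevelsError
        Fewer than six points supplied, or fewer than five usable after
        saturation exclusion.
    CalibrationError
        Non-positive fitted slope.
    """
    pts = [(float(m), float(v)) for m, v in points]
    if len(pts) < MIN_LEVELS:
        raise InsufficientLevelsError(
            f"{len(pts)} mean-variance points supplied; the calibration "
            f"protocol requires more than five illumination steps"
        )
    full_scale = 2 ** int(bit_depth) - 1
    limit = saturation_cut * full_scale
    usable = [(m, v) for m, v in pts if m + offset_dn <= limit]
    n_excluded = len(pts) - len(usable)
    if len(usable) < MIN_LEVELS - 1:
        raise InsufficientLevelsError(
            f"only {len(usable)} usable points remain after excluding "
            f"{n_excluded} near-saturation levels (mean above "
            f"{saturation_cut:.0%} of full scale); at least {MIN_LEVELS - 1} are needed"
        )
    means = np.array([m for m, _ in usable])
    variances = np.array([v for _, v in usable])
    gain, intercept = _variance_weighted_line(means, variances)
    if gain <= 0:
        raise CalibrationError(
            f"photon-transfer fit produced non-positive gain ({gain:.4g} "
            "DN/photon); check illumination ordering and saturation"
        )
    if intercept < 0:
        warnings.warn(
            f"fitted read-noise variance is negative ({intercept:.4g} DN^2); "
            "clamping to 0",
            stacklevel=2,
        )
        intercept = 0.0
    return GainFit(
        gain_dn_per_photon=gain,
        offset_dn=float(offset_dn),
        read_noise_var_dn2=intercept,
        fit_points=tuple(usable),
        levels_used=len(usable),
        levels_excluded=n_excluded,
    )


def calibrate_gain(
    series: FlatFieldSeries,
    *,
    saturation_cut: float = DEFAULT_SATURATION_CUT,
) -> GainFit:
    """Full photon-transfer calibration from a flat-field series."""
    return fit_gain(
        mean_variance_points(series),
        saturation_cut=saturation_cut,
        bit_depth=series.bit_depth,
        offset_dn=series.dark_level_dn,
    )


def photon_count_uniform(mean_dn_offset_subtracted: float, sigma_dn: float) -> float:
    """Shot-noise photon count of a uniform field: N = (mean/sigma)^2.

    Valid for a shot-noise-limited linear detector: mean = g N and
    variance = g^2 N, so the ratio is gain-independent.

    Raises
    ------
    CalibrationError
        If sigma_dn is not positive (a noiseless field has no defined
        shot-noise photon count).
    """
    if not sigma_dn > 0:
        raise CalibrationError(
            f"photon counting requires a positive noise level, got sigma={sigma_dn}"
        )
    return float((mean_dn_offset_subtracted / sigma_dn) ** 2)


SelectionRule = Callable[[NDArray[np.float64]], NDArray[np.bool_]]


def percentile_selection(percentile: float = DEFAULT_SELECTION_PERCENTILE) -> SelectionRule:
    """Select pixels whose wide-field intensity exceeds the given percentile."""

    def rule(widefield: NDArray[np.float64]) -> NDArray[np.bool_]:
        threshold = np.percentile(widefield, percentile)
        return (widefield >= threshold) & (widefield > 0)

    rule.percentile = percentile  # type: ignore[attr-defined]
    return rule


def estimate_modulation_contrast(
    bead_triplet: PhaseTriplet,
    gain: GainFit,
    selection: SelectionRule | None = None,
) -> ContrastFit:
    """Estimate modulation contrast m from a raw bead-field triplet (DN).

    Offset-subtracts the three phases, demodulates, and takes the median of
    sectioned/wide-field over the selected bright pixels. For a thin bead
    layer (beads smaller than the sectioning thickness, no out-of-focus
    light) this ratio equals m exactly under the demodulation convention;
    uniform background biases it downward, which is why the protocol calls
    for a thin sample.
    """
    if selection is None:
        selection = percentile_selection()
    sub = PhaseTriplet(
        bead_triplet.i1 - gain.offset_dn,
        bead_triplet.i2 - gain.offset_dn,
        bead_triplet.i3 - gain.offset_dn,
        pixel_unit=bead_triplet.pixel_unit,
    )
    w = widefield_raw(sub)
    s = sectioned_raw(sub)
    mask = selection(w)
    # significance floor: a percentile rule always finds "brightest" pixels,
    # even in a dark field where they are pure read noise
    mask &= w > 10.0 * gain.read_noise_sigma_photons
    n_selected = int(mask.sum())
    if n_selected == 0:
        raise EmptySelectionError(
            "no pixels passed the bead-selection rule; the bead field may be "
            "dark or the layout order wrong"
        )
    ratios = s[mask] / w[mask]
    median = float(np.median(ratios))
    q75, q25 = np.percentile(ratios, [75.0, 25.0])
    if not 0.0 < median <= 1.0:
        raise CalibrationError(
            f"median sectioned/wide-field ratio is {median:.4g}, outside (0, 1]; "
            "this suggests a defocused grid or a wrong concatenation layout"
        )
    threshold = float(getattr(selection, "percentile", float("nan")))
    return ContrastFit(
        modulation_contrast=median,
        pixels_used=n_selected,
        selection_threshold=threshold,
        ratio_median=median,
        ratio_iqr=float(q75 - q25),
    )
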