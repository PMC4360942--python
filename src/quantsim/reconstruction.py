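"""Calibrated reconstruction: photon-unit images and per-pixel noise maps.

Given the camera gain g (DN/photon), dark offset, read-noise variance and
illumination modulation contrast m, a raw phase triplet is converted into
four M x N images per depth: wide-field photons, sectioned photons, and the
predicted standard deviation (noise map) of each, all in photon units.

Photon estimates
----------------
Each phase is converted to photons as (DN - offset)/g. The wide-field image
is the three-phase mean; the sectioned image is the demodulated amplitude
divided by m, since only the fraction m of the in-focus signal is
modulated. With per-phase model I_i = F (1 + m cos(phi_i)) + B the
wide-field estimate is F + B and the sectioned estimate is F, removing the
out-of-focus background B in expectation.

Shot-noise bias correction
--------------------------
The square-law demodulation is nonlinear, so noise does not average out of
it: the sum of pairwise squared differences D acquires an additive
expectation 2*(v1+v2+v3) from the per-phase variances v_i, inflating the
demodulated amplitude, while the square root's concavity deflates it at low
modulation signal-to-noise. The default sectioned estimator therefore works
at the power level: P = (2/9) D - (4/9) (v1+v2+v3) is an unbiased estimate
of the squared modulation amplitude, and the amplitude is recovered with a
second-order Taylor correction for the square root. On noiseless input the
correction subtracts variance that is not there, so an uncorrected path
(``bias_corrected=False``) reproduces the plain demodulation exactly.

Noise maps
----------
Per-phase variance is shot noise (Poisson: variance = photon count,
plug-in-estimated from the observed counts) plus read noise expressed in
photons. The wide-field map follows exactly from the variance of a mean of
three frames. The sectioned map propagates the per-phase variances through
the square-law demodulation to first order (delta method) and divides by m;
background photons cancel from the sectioned *signal* but their shot noise
does not, and the division by m < 1 amplifies the result — the noise maps
quantify both effects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .calibration import ContrastFit, GainFit
from .errors import CalibrationError, LayoutError
from .sim_model import (
    SECTIONING_PREFACTOR,
    DEFAULT_PHASE_ORDER,
    PhaseTriplet,
    PixelUnit,
    pairwise_sq_diff_sum,
    split_concatenated,
    widefield_raw,
)

#: Sum of squared demodulation derivatives averaged over the grid phase;
#: used where the local modulation is numerically zero and the exact
#: derivative is singular.
_PHASE_AVERAGED_DERIV_SQ = 2.0 / 3.0


@dataclass(frozen=True)
class CalibrationProfile:
    """Everything needed to turn raw DN triplets into photon images."""

    gain: GainFit
    contrast: ContrastFit
    created_with: Mapping[str, str] = field(default_factory=dict)

    @property
    def digest(self) -> str:
        """Stable hash of the numeric calibration values.

        Changes whenever any calibration number changes, so output
        manifests can be traced to the exact calibration used.
        """
        payload = json.dumps(
            {
                "gain_dn_per_photon": self.gain.gain_dn_per_photon,
                "offset_dn": self.gain.offset_dn,
                "read_noise_var_dn2": self.gain.read_noise_var_dn2,
                "modulation_contrast": self.contrast.modulation_contrast,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class QuantResult:
    """Four photon-unit images for one depth layer."""

    widefield_photons: NDArray[np.float64]
    sectioned_photons: NDArray[np.float64]
    widefield_noise: NDArray[np.float64]
    sectioned_noise: NDArray[np.float64]
    depth_index: int = 0
    depth_um: float | None = None

    def __post_init__(self) -> None:
        shape = self.widefield_photons.shape
        for name in ("sectioned_photons", "widefield_noise", "sectioned_noise"):
            if getattr(self, name).shape != shape:
                raise LayoutError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if self.depth_index < 0:
            raise ValueError(f"depth_index must be >= 0, got {self.depth_index}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.widefield_photons.shape  # type: ignore[return-value]

    def images(self) -> dict[str, NDArray[np.float64]]:
        return {
            "widefield": self.widefield_photons,
            "sectioned": self.sectioned_photons,
            "widefield_noise": self.widefield_noise,
            "sectioned_noise": self.sectioned_noise,
        }


def to_photons(image_dn: ArrayLike, gain: GainFit) -> NDArray[np.float64]:
    """Convert grey levels to photons: (DN - offset)/g.

    Values below the dark level map to negative photons and are retained:
    clamping before averaging would bias dim-pixel estimates upward.
    """
    arr = np.asarray(image_dn, dtype=np.float64)
    return (arr - gain.offset_dn) / gain.gain_dn_per_photon


def triplet_to_photons(t: PhaseTriplet, gain: GainFit) -> PhaseTriplet:
    """Convert each phase of a DN triplet to photon units."""
    return PhaseTriplet(
        to_photons(t.i1, gain),
        to_photons(t.i2, gain),
        to_photons(t.i3, gain),
        pixel_unit=PixelUnit.PHOTONS,
    )


def _per_phase_variances(
    t_photons: PhaseTriplet, gain: GainFit
) -> tuple[NDArray[np.float64], ...]:
    # Plug-in shot variance = observed photon count (clamped at 0 where
    # noise dips below dark) plus photon-equivalent read-noise variance.
    read_var = gain.read_noise_var_dn2 / gain.gain_dn_per_photon**2
    return tuple(np.maximum(p, 0.0) + read_var for p in t_photons.phases())


def noise_widefield(t_photons: PhaseTriplet, gain: GainFit) -> NDArray[np.float64]:
    """Predicted sigma of the wide-field image, in photons.

    Variance of the three-frame mean: (sum of per-frame variances)/9, each
    frame contributing its shot variance plus read-noise variance.
    """
    v1, v2, v3 = _per_phase_variances(t_photons, gain)
    return np.sqrt((v1 + v2 + v3) / 9.0)


def _modulation_power_stats(
    t_photons: PhaseTriplet, gain: GainFit
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Plain modulation power P = (2/9) D, its propagated variance, and the
    mean per-phase variance.

    P equals the squared modulation amplitude (sectioned_raw squared) and
    Var(P) = (16/81) * sum_i (2 I_i - I_j - I_k)^2 v_i by first-order
    propagation of the per-phase variances v_i.
    """
    i1, i2, i3 = t_photons.phases()
    v1, v2, v3 = _per_phase_variances(t_photons, gain)
    power = SECTIONING_PREFACTOR**2 * pairwise_sq_diff_sum(t_photons)
    g1 = 2.0 * i1 - i2 - i3
    g2 = 2.0 * i2 - i1 - i3
    g3 = 2.0 * i3 - i1 - i2
    var_power = (16.0 / 81.0) * (g1 * g1 * v1 + g2 * g2 * v2 + g3 * g3 * v3)
    mean_var = (v1 + v2 + v3) / 3.0
    return power, var_power, mean_var


def sectioned_amplitude(
    t_photons: PhaseTriplet, gain: GainFit, *, bias_corrected: bool = True
) -> NDArray[np.float64]:
    """Modulated (in-focus) amplitude estimate, in photons, before the 1/m scaling.

    With ``bias_corrected`` (default) the squared amplitude is first
    debiased — noise inflates the plain power by (4/9)(v1+v2+v3) in
    expectation — and the square root's concavity bias is removed to second
    order. Without it this is exactly ``sectioned_raw``.
    """
    power, var_power, mean_var = _modulation_power_stats(t_photons, gain)
    if not bias_corrected:
        return np.sqrt(power)
    debiased = power - 2.0 * _PHASE_AVERAGED_DERIV_SQ * mean_var
    sigma_power = np.sqrt(var_power)
    amp = np.sqrt(np.maximum(debiased, 0.0))
    # second-order sqrt correction, with the denominator floored at the
    # power noise scale so low-signal pixels stay finite
    denom = np.maximum(debiased, sigma_power)
    with np.errstate(divide="ignore", invalid="ignore"):
        correction = np.where(
            var_power > 0.0, var_power / (8.0 * denom**1.5), 0.0
        )
    return amp + correction


def noise_sectioned(
    t_photons: PhaseTriplet, m: float, gain: GainFit, *, bias_corrected: bool = True
) -> NDArray[np.float64]:
    """Predicted sigma of the sectioned image, in photons.

    First-order propagation through the square-law demodulation: with the
    modulation power P (squared amplitude) and its propagated variance
    Var(P), sigma(I_s) = sqrt(Var(P)) / (2 * amplitude), equivalent to the
    delta-method form sum_i (dI_s/dI_i)^2 v_i with dI_s/dI_i =
    (sqrt(2)/3)(2 I_i - I_j - I_k)/sqrt(D); the map is sqrt(Var)/m.

    The amplitude in the denominator is the same estimate the sectioned
    image reports, floored at the power-noise quarter-power scale so
    low-modulation pixels stay finite. Where the modulation power is
    numerically zero the phase-averaged closed form Var(I_s) = (2/3) *
    (mean photon count + read variance in photons) is substituted — the
    delta-method limit for a locally unmodulated pixel.
    """
    if not 0.0 < m <= 1.0:
        raise CalibrationError(f"modulation contrast must lie in (0, 1], got {m}")
    power, var_power, mean_var = _modulation_power_stats(t_photons, gain)
    amp = sectioned_amplitude(t_photons, gain, bias_corrected=bias_corrected)
    degenerate = (power <= 1e-12 * np.maximum(mean_var, 1.0)) | (var_power <= 0.0)
    floor = var_power**0.25
    denom = np.maximum(amp, floor)
    denom = np.where(degenerate, 1.0, denom)
    var_s = np.where(
        degenerate,
        _PHASE_AVERAGED_DERIV_SQ * mean_var,
        var_power / (4.0 * denom**2),
    )
    return np.sqrt(var_s) / m


def process_triplet(t: PhaseTriplet, calib: CalibrationProfile, *,
                    depth_index: int = 0, depth_um: float | None = None,
                    bias_corrected: bool = True) -> QuantResult:
    """Reconstruct one depth layer from a raw DN triplet.

    Returns the four photon-unit images. Intermediate negative photon
    values are retained for unbiasedness; the final sectioned image is
    clamped at zero (non-negative by construction, but the clamp guards the
    unit contract). ``bias_corrected=False`` reproduces the plain
    sectioned_raw / m estimate, exact on noiseless input.
    """
    m = calib.contrast.modulation_contrast
    tp = triplet_to_photons(t, calib.gain)
    widefield = widefield_raw(tp)
    amp = sectioned_amplitude(tp, calib.gain, bias_corrected=bias_corrected)
    sectioned = np.maximum(amp / m, 0.0)
    return QuantResult(
        widefield_photons=widefield,
        sectioned_photons=sectioned,
        widefield_noise=noise_widefield(tp, calib.gain),
        sectioned_noise=noise_sectioned(
            tp, m, calib.gain, bias_corrected=bias_corrected
        ),
        depth_index=depth_index,
        depth_um=depth_um,
    )


def process_stack(
    stack: Sequence[ArrayLike],
    calib: CalibrationProfile,
    *,
    z_step_um: float | None = None,
    order: tuple[int, int, int] = DEFAULT_PHASE_ORDER,
) -> list[QuantResult]:
    """Process an ordered stack of concatenated 3M x N images, one per depth.

    Depths are reconstructed independently; page order is depth order.
    """
    pages = [np.asarray(p, dtype=np.float64) for p in stack]
    if not pages:
        raise LayoutError("stack is empty: at least one depth page is required")
    shape = pages[0].shape
    for k, page in enumerate(pages):
        if page.shape != shape:
            raise LayoutError(
                f"stack page {k} has shape {page.shape}, expected {shape}"
            )
    results = []
    for k, page in enumerate(pages):
        t = split_concatenated(page, order=order)
        depth_um = k * z_step_um if z_step_um is not None else None
        results.append(process_triplet(t, calib, depth_index=k, depth_um=depth_um))
    return results


def photon_noise_histograms(
    result: QuantResult, bin_width: float
) -> dict[str, tuple[NDArray[np.float64], NDArray[np.int64]]]:
    """Histogram each of the four images over a common photon range.

    Returns, per image name, (bin_edges, counts); counts sum to M*N. The
    signal pair (wide-field/sectioned) shares one binning and the noise
    pair another, so the distributions are directly comparable — the
    sectioned image shows more low-photon ("dark") pixels than the
    wide-field image because the background is removed, and its noise
    histogram sits higher because demodulation amplifies shot noise.
    """
    if not bin_width > 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    images = result.images()
    out: dict[str, tuple[NDArray[np.float64], NDArray[np.int64]]] = {}
    for group in (("widefield", "sectioned"), ("widefield_noise", "sectioned_noise")):
        lo = min(float(images[name].min()) for name in group)
        hi = max(float(images[name].max()) for name in group)
        lo = min(lo, 0.0)
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width + 1e-9)))
        edges = lo + bin_width * np.arange(n_bins + 1)
        # make the top edge inclusive of the maximum
        if edges[-1] <= hi:
            edges = np.append(edges, edges[-1] + bin_width)
        for name in group:
            counts, _ = np.histogram(images[name], bins=edges)
            out[name] = (edges, counts.astype(np.int64))
    return out
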