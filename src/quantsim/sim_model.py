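"""Phase-triplet data model and square-law demodulation.

Optical-sectioning SIM acquires three images of the same field with a
sinusoidal illumination grid shifted by 0, 2pi/3 and 4pi/3. Only in-focus
light carries the grid modulation, so the per-pixel modulation amplitude is
the in-focus signal and the phase average is the equivalent uniform-
illumination (wide-field) image. This module holds the pure mathematics of
that demodulation, independent of camera units and calibration.

The sectioned image uses the standard three-phase square-law form

    I_s = (sqrt(2)/3) * sqrt[(I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2]

whose prefactor is chosen so that a pure sinusoid of amplitude B
demodulates to exactly B; downstream photon estimates are invariant to this
convention as long as modulation-contrast calibration uses the same form.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import LayoutError

PHASE_STEP = 2.0 * math.pi / 3.0
#: Prefactor of the square-law demodulation; sqrt(2)/3 makes a sinusoid of
#: amplitude B demodulate to exactly B.
SECTIONING_PREFACTOR = math.sqrt(2.0) / 3.0

DEFAULT_PHASE_ORDER = (0, 1, 2)


class PixelUnit(str, enum.Enum):
    """Unit carried by a triplet's pixel values."""

    DN = "DN"
    PHOTONS = "photons"


@dataclass(frozen=True)
class PhaseTriplet:
    """Three co-registered M x N images at illumination phases 0, 2pi/3, 4pi/3.

    Parameters
    ----------
    i1, i2, i3
        The three phase images. Converted to float64 on construction;
        integer DN are only preserved at I/O boundaries.
    pixel_unit
        Whether pixel values are raw camera grey levels (DN) or photons.
    """

    i1: NDArray[np.float64]
    i2: NDArray[np.float64]
    i3: NDArray[np.float64]
    pixel_unit: PixelUnit = PixelUnit.DN
    phase_step: float = field(default=PHASE_STEP)

    def __post_init__(self) -> None:
        for name in ("i1", "i2", "i3"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
                raise LayoutError(
                    f"phase image {name} must be a 2-D matrix with at least "
                    f"one row and column, got shape {arr.shape}"
                )
            object.__setattr__(self, name, arr)
        if self.i1.shape != self.i2.shape or self.i1.shape != self.i3.shape:
            raise LayoutError(
                "phase images must share dimensions, got "
                f"{self.i1.shape}, {self.i2.shape}, {self.i3.shape}"
            )
        if not math.isclose(self.phase_step, PHASE_STEP, rel_tol=1e-12):
            raise ValueError(
                f"only the 2*pi/3 phase step is supported, got {self.phase_step}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.i1.shape  # type: ignore[return-value]

    def phases(self) -> tuple[NDArray[np.float64], ...]:
        return (self.i1, self.i2, self.i3)

    def concatenate(self, order: tuple[int, int, int] = DEFAULT_PHASE_ORDER) -> NDArray[np.float64]:
        """Re-concatenate the triplet row-wise into a 3M x N array.

        Inverse of :func:`split_concatenated` for the same ``order``: the
        block occupying the k-th row third is the phase ``order[k]``.
        """
        blocks = [None, None, None]
        imgs = self.phases()
        for block_idx, phase_idx in enumerate(_validate_order(order)):
            blocks[block_idx] = imgs[phase_idx]
        return np.concatenate(blocks, axis=0)


@dataclass(frozen=True)
class DemodResult:
    """Demodulated pair: optically sectioned and wide-field images."""

    sectioned: NDArray[np.float64]
    widefield: NDArray[np.float64]

    def __post_init__(self) -> None:
        if self.sectioned.shape != self.widefield.shape:
            raise LayoutError("sectioned and widefield images must share dimensions")


def _validate_order(order: tuple[int, int, int]) -> tuple[int, int, int]:
    order = tuple(int(k) for k in order)  # type: ignore[assignment]
    if sorted(order) != [0, 1, 2]:
        raise ValueError(
            f"phase order must be a permutation of (0, 1, 2), got {order}"
        )
    return order


def split_concatenated(
    stacked: ArrayLike,
    order: tuple[int, int, int] = DEFAULT_PHASE_ORDER,
    pixel_unit: PixelUnit = PixelUnit.DN,
) -> PhaseTriplet:
    """Split a row-wise concatenated 3M x N image into a phase triplet.

    The acquisition convention concatenates the three phase images into one
    3M x N array. ``order[k]`` names which phase (0-based) the k-th row
    third holds; the default is phases 1, 2, 3 from top to bottom.

    Raises
    ------
    LayoutError
        If the row count is not divisible by three.
    """
    arr = np.asarray(stacked, dtype=np.float64)
    if arr.ndim != 2:
        raise LayoutError(f"expected a 2-D concatenated image, got shape {arr.shape}")
    rows, cols = arr.shape
    if rows % 3 != 0 or rows == 0:
        raise LayoutError(
            f"concatenated image must have a row count divisible by 3; "
            f"got {rows} rows x {cols} columns"
        )
    m = rows // 3
    blocks = [arr[k * m : (k + 1) * m, :] for k in range(3)]
    phases: list[NDArray[np.float64] | None] = [None, None, None]
    for block_idx, phase_idx in enumerate(_validate_order(order)):
        phases[phase_idx] = blocks[block_idx]
    return PhaseTriplet(phases[0], phases[1], phases[2], pixel_unit=pixel_unit)


def pairwise_sq_diff_sum(t: PhaseTriplet) -> NDArray[np.float64]:
    """Per-pixel sum of pairwise squared phase differences.

    For a sinusoid of amplitude B this equals (9/2) B^2 regardless of the
    grid phase. Shared by the demodulation and its noise propagation.
    """
    d12 = t.i1 - t.i2
    d13 = t.i1 - t.i3
    d23 = t.i2 - t.i3
    return d12 * d12 + d13 * d13 + d23 * d23


def sectioned_raw(t: PhaseTriplet) -> NDArray[np.float64]:
    """Square-law demodulated amplitude, in the triplet's own unit.

    Non-negative by construction, invariant under any permutation of the
    three phases and under a common additive offset, and returns exactly B
    for a sinusoidal triplet of amplitude B.
    """
    return SECTIONING_PREFACTOR * np.sqrt(pairwise_sq_diff_sum(t))


def widefield_raw(t: PhaseTriplet) -> NDArray[np.float64]:
    """Wide-field image: arithmetic mean of the three phases.

    For three phases 2pi/3 apart the modulated term sums to zero, so the
    mean equals the uniform-illumination equivalent of a single exposure.
    """
    return (t.i1 + t.i2 + t.i3) / 3.0


def demodulate(t: PhaseTriplet) -> DemodResult:
    """Convenience wrapper returning both demodulated images."""
    return DemodResult(sectioned=sectioned_raw(t), widefield=widefield_raw(t))
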