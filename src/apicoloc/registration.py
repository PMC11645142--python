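"""4i preprocessing: projection, cross-cycle alignment, illumination correction.

The chain mirrors standard multi-cycle immunofluorescence preprocessing:
maximum-intensity projection of each z-stack, estimation of the integer
translation between cycles from the nuclear (DAPI) channel by zero-normalized
cross-correlation (NCC), propagation of each cycle's offset to its other
channels, cropping of all cycles to the common overlap rectangle, and
flat-field illumination correction by division with a smooth multiplicative
surface.

Registration is integer-pixel only: intensities are never resampled, which
keeps downstream pixelwise correlation statistics exact.  The NCC argmax is
taken over the exhaustive +/- ``max_shift_px`` window; the implementation
accelerates the candidate sums with FFT correlation and integral images but
reproduces the exhaustive search exactly, including the tie-break (smallest
``|dy| + |dx|``, then lexicographic ``(dy, dx)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .images import (
    DAPI,
    ApicolocError,
    ChannelImage,
    CycleStack,
    InconsistentStackError,
    logger,
    translate,
)

__all__ = [
    "ShiftSet",
    "max_project",
    "project_stack",
    "estimate_shift_ncc",
    "align_and_crop",
    "estimate_illumination",
    "flatfield_correct",
]

DEFAULT_MAX_SHIFT_PX = 32


@dataclass
class ShiftSet:
    """Per-cycle integer offsets relative to cycle 1, with the crop window.

    ``shifts[k]`` is the ``(dy, dx)`` by which cycle ``k+1`` appears translated
    relative to cycle 1 (cycle 1 is ``(0, 0)``); ``correlations[k]`` the NCC at
    that offset.  ``crop`` is the common overlap rectangle in cycle-1
    coordinates as ``(y0, y1, x0, x1)`` (half-open).
    """

    shifts: list[tuple[int, int]]
    correlations: list[float]
    crop: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if tuple(self.shifts[0]) != (0, 0):
            raise ApicolocError("cycle 1 offset must be (0, 0)")
        y0, y1, x0, x1 = self.crop
        if y1 <= y0 or x1 <= x0:
            raise ApicolocError("overlap rectangle is empty")


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def max_project(zstack: list[ChannelImage] | ChannelImage) -> ChannelImage:
    """Maximum-intensity projection: per-pixel maximum over z-planes.

    Metadata of the first plane is preserved.  A single plane (or a bare
    ChannelImage) is returned as an identical copy, making the operation
    idempotent.
    """
    if isinstance(zstack, ChannelImage):
        zstack = [zstack]
    if len(zstack) == 0:
        raise InconsistentStackError("empty z-stack")
    shapes = {im.shape for im in zstack}
    if len(shapes) > 1:
        raise InconsistentStackError(f"z-planes disagree in shape: {shapes}")
    out = zstack[0].pixels.copy()
    for im in zstack[1:]:
        np.maximum(out, im.pixels, out=out)
    return zstack[0].with_pixels(out)


def project_stack(stack: CycleStack) -> CycleStack:
    """Project every z-stack of a raw acquisition into 2-D cycle images."""
    if not stack.zstacks:
        return stack
    cycles: list[list[ChannelImage]] = []
    for c in range(1, len(stack.cycles) + 1):
        row = list(stack.cycles[c - 1])
        for (cyc, ch), planes in stack.zstacks.items():
            if cyc == c:
                row.append(max_project(planes))
        cycles.append(row)
    return CycleStack(cycles=cycles)


# ---------------------------------------------------------------------------
# Shift estimation (zero-normalized cross-correlation)
# ---------------------------------------------------------------------------

def _rect_sums(cum: np.ndarray, y0: int, y1: int, x0: int, x1: int) -> float:
    """Sum over the half-open rectangle [y0:y1, x0:x1] from a padded cumsum."""
    return cum[y1, x1] - cum[y0, x1] - cum[y1, x0] + cum[y0, x0]


def estimate_shift_ncc(reference: ChannelImage, moving: ChannelImage,
                       max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
                       ) -> tuple[tuple[int, int], float]:
    """Estimate the integer offset of ``moving`` relative to ``reference``.

    Returns ``((dy, dx), ncc)`` where ``moving`` best matches ``reference``
    translated by ``(dy, dx)``; the score is the zero-normalized
    cross-correlation over the geometric overlap of the two frames at that
    offset.  The argmax is taken over the exhaustive window
    ``|dy|, |dx| <= max_shift_px``; exact ties are broken by smallest
    ``|dy| + |dx|``, then lexicographically by ``(dy, dx)``.

    Raises on shape mismatch, an over-large window, or when every candidate
    offset has zero variance in the overlap (unalignable pair).
    """
    ref, mov = reference.pixels, moving.pixels
    if ref.shape != mov.shape:
        raise InconsistentStackError("reference and moving images differ in shape")
    h, w = ref.shape
    if max_shift_px >= min(h, w) / 2:
        raise ApicolocError("max_shift_px must be below half the smallest dimension")

    # Cross term sum(ref[y, x] * mov[y + dy, x + dx]) for all (dy, dx) at once:
    # full cross-correlation via FFT convolution with the flipped reference.
    xcorr = signal.fftconvolve(mov, ref[::-1, ::-1], mode="full")
    # xcorr index (h - 1 + dy, w - 1 + dx) == sum over overlap at offset (dy, dx)

    cum_r = np.zeros((h + 1, w + 1))
    cum_r[1:, 1:] = ref.cumsum(0).cumsum(1)
    cum_r2 = np.zeros((h + 1, w + 1))
    cum_r2[1:, 1:] = (ref**2).cumsum(0).cumsum(1)
    cum_m = np.zeros((h + 1, w + 1))
    cum_m[1:, 1:] = mov.cumsum(0).cumsum(1)
    cum_m2 = np.zeros((h + 1, w + 1))
    cum_m2[1:, 1:] = (mov**2).cumsum(0).cumsum(1)

    best: tuple[float, int, int, int] | None = None  # (-ncc, |dy|+|dx|, dy, dx)
    best_ncc = None
    for dy in range(-max_shift_px, max_shift_px + 1):
        ry0, ry1 = max(0, -dy), min(h, h - dy)  # ref rows in overlap
        for dx in range(-max_shift_px, max_shift_px + 1):
            rx0, rx1 = max(0, -dx), min(w, w - dx)
            n = (ry1 - ry0) * (rx1 - rx0)
            if n < 2:
                continue
            s_r = _rect_sums(cum_r, ry0, ry1, rx0, rx1)
            s_r2 = _rect_sums(cum_r2, ry0, ry1, rx0, rx1)
            s_m = _rect_sums(cum_m, ry0 + dy, ry1 + dy, rx0 + dx, rx1 + dx)
            s_m2 = _rect_sums(cum_m2, ry0 + dy, ry1 + dy, rx0 + dx, rx1 + dx)
            s_rm = xcorr[h - 1 + dy, w - 1 + dx]
            var_r = s_r2 - s_r**2 / n
            var_m = s_m2 - s_m**2 / n
            if var_r <= 1e-9 * max(s_r2, 1.0) or var_m <= 1e-9 * max(s_m2, 1.0):
                continue
            ncc = (s_rm - s_r * s_m / n) / np.sqrt(var_r * var_m)
            key = (-round(ncc, 12), abs(dy) + abs(dx), dy, dx)
            if best is None or key < best:
                best = key
                best_ncc = float(ncc)
    if best is None:
        raise ApicolocError("unalignable pair: zero variance at every candidate offset")
    return (best[2], best[3]), best_ncc


def estimate_shift_ncc_bruteforce(reference: ChannelImage, moving: ChannelImage,
                                  max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
                                  ) -> tuple[tuple[int, int], float]:
    """Direct per-offset NCC (no FFT/integral-image acceleration).

    Reference implementation of the exhaustive-window contract; quadratic and
    slow, kept for verification of :func:`estimate_shift_ncc`.
    """
    ref, mov = reference.pixels, moving.pixels
    if ref.shape != mov.shape:
        raise InconsistentStackError("reference and moving images differ in shape")
    h, w = ref.shape
    best = None
    for dy in range(-max_shift_px, max_shift_px + 1):
        for dx in range(-max_shift_px, max_shift_px + 1):
            ry0, ry1 = max(0, -dy), min(h, h - dy)
            rx0, rx1 = max(0, -dx), min(w, w - dx)
            if ry1 - ry0 < 1 or rx1 - rx0 < 1:
                continue
            a = ref[ry0:ry1, rx0:rx1].ravel()
            bb = mov[ry0 + dy : ry1 + dy, rx0 + dx : rx1 + dx].ravel()
            if a.size < 2 or a.std() == 0 or bb.std() == 0:
                continue
            ncc = float(np.corrcoef(a, bb)[0, 1])
            key = (-round(ncc, 12), abs(dy) + abs(dx), dy, dx)
            if best is None or key < best:
                best = key
    if best is None:
        raise ApicolocError("unalignable pair: zero variance at every candidate offset")
    return (best[2], best[3]), -best[0]


# ---------------------------------------------------------------------------
# Alignment and cropping
# ---------------------------------------------------------------------------

def overlap_rectangle(shape: tuple[int, int],
                      shifts: list[tuple[int, int]]) -> tuple[int, int, int, int]:
    """Common rectangle, in cycle-1 coordinates, seen by every shifted cycle.

    A cycle translated by ``(dy, dx)`` covers reference rows
    ``[max(0, dy), h + min(0, dy))`` after being shifted back into the
    reference frame; the crop is the intersection over cycles.
    """
    h, w = shape
    y0 = max(max(0, dy) for dy, _ in shifts)
    y1 = min(h + min(0, dy) for dy, _ in shifts)
    x0 = max(max(0, dx) for _, dx in shifts)
    x1 = min(w + min(0, dx) for _, dx in shifts)
    if y1 <= y0 or x1 <= x0:
        raise ApicolocError("empty overlap rectangle: excessive inter-cycle drift")
    return (y0, y1, x0, x1)


def align_and_crop(stack: CycleStack, max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
                   ) -> tuple[CycleStack, ShiftSet]:
    """Register every cycle to cycle 1 on DAPI and crop to the common area.

    Each cycle's offset is estimated from its nuclear channel against cycle 1;
    the same offset is then applied to all of that cycle's channels (undoing
    the stage shift), and every image is cropped to the maximal rectangle
    observed in all shifted cycles.
    """
    stack = project_stack(stack)
    ref = stack.get(1, DAPI)
    shifts: list[tuple[int, int]] = [(0, 0)]
    corrs: list[float] = [1.0]
    for c in range(2, stack.n_cycles + 1):
        (dy, dx), ncc = estimate_shift_ncc(ref, stack.get(c, DAPI), max_shift_px)
        shifts.append((dy, dx))
        corrs.append(ncc)
    crop = overlap_rectangle(stack.shape, shifts)
    y0, y1, x0, x1 = crop

    cycles: list[list[ChannelImage]] = []
    for c, row in enumerate(stack.cycles, start=1):
        dy, dx = shifts[c - 1]
        out_row = []
        for im in row:
            aligned = translate(im.pixels, -dy, -dx) if (dy, dx) != (0, 0) else im.pixels
            out_row.append(im.with_pixels(aligned[y0:y1, x0:x1]))
        cycles.append(out_row)
    logger.info("aligned %d cycles; shifts=%s; crop=%s", stack.n_cycles, shifts, crop)
    return CycleStack(cycles=cycles), ShiftSet(shifts=shifts, correlations=corrs, crop=crop)


# ---------------------------------------------------------------------------
# Flat-field illumination correction
# ---------------------------------------------------------------------------

def estimate_illumination(images: list[ChannelImage],
                          smooth_frac: float = 0.10) -> np.ndarray:
    """Estimate a smooth multiplicative illumination surface.

    The per-pixel median across the input images is smoothed with a heavy
    Gaussian (sigma = ``smooth_frac`` of the image width) and normalized to
    mean 1.  With a single image the surface is that image smoothed and
    normalized.
    """
    if len(images) == 0:
        raise ApicolocError("need at least one image")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise InconsistentStackError("illumination inputs disagree in shape")
    med = np.median(np.stack([im.pixels for im in images]), axis=0)
    sigma = smooth_frac * med.shape[1]
    # odd-reflection padding preserves linear intensity ramps under the heavy
    # blur, so vignetting-like gradients are estimated correctly at borders
    pad = int(np.ceil(3 * sigma))
    pad_y, pad_x = min(pad, med.shape[0] - 1), min(pad, med.shape[1] - 1)
    padded = np.pad(med, ((pad_y, pad_y), (pad_x, pad_x)),
                    mode="reflect", reflect_type="odd")
    smoothed = ndimage.gaussian_filter(padded, sigma, mode="nearest")
    surface = smoothed[pad_y : pad_y + med.shape[0], pad_x : pad_x + med.shape[1]]
    mean = surface.mean()
    if mean <= 0:
        raise ApicolocError("cannot normalize an all-zero illumination surface")
    return surface / mean


def flatfield_correct(image: ChannelImage, surface: np.ndarray) -> ChannelImage:
    """Divide an image by the illumination surface (pixelwise)."""
    if image.shape != surface.shape:
        raise InconsistentStackError("image and surface differ in shape")
    if surface.min() <= 0:
        raise ApicolocError("illumination surface must be strictly positive")
    return image.with_pixels(image.pixels / surface)
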