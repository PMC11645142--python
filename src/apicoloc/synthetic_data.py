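"""Synthetic microscopy image generation with full ground truth.

Two families of fixtures are produced:

* **Tissue sections** (:func:`generate_tissue`) emulating kidney-cortex
  cryosections: ring-shaped tubule cross-sections with a MUC1-like apical
  membrane band, a UMOD-like cargo channel split between the apical band and
  the intracellular annulus at a known fraction, an LTL-like lectin channel
  carrying a periodic cortex texture, and a DAPI channel (diffuse tissue
  signal plus nuclei).

* **4i cycle stacks** (:func:`generate_4i_stack`) emulating multi-cycle
  iterative-immunofluorescence acquisitions of adherent cells: a fixed scene
  of cells (nucleus, ER, named subcellular compartments, a cargo marker whose
  mask is split across compartments at known fractions, and optional marker
  pairs with a tunable pixelwise correlation), re-imaged over several cycles
  with known integer stage shifts and fresh noise.

Every generator records the ground-truth masks and drawn parameters in a
:class:`GroundTruth` object so each downstream stage can be validated without
any external data.  Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .images import (
    DAPI,
    ChannelImage,
    CycleStack,
    InfeasibleSpecError,
    translate,
)

__all__ = [
    "TissueSpec",
    "FourISpec",
    "GroundTruth",
    "generate_tissue",
    "generate_4i_stack",
    "generate_bimodal_field",
    "write_ground_truth",
]


# ---------------------------------------------------------------------------
# Specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class TissueSpec:
    """Parameters of one synthetic kidney-section field.

    Intensities are arbitrary fluorescence units; distances in micrometres.
    ``apical_fraction`` is the fraction of each positive tubule's cargo
    budget placed in the apical band (the rest goes to the intracellular
    annulus); ``umod_positive_fraction`` is the fraction of tubules that
    express cargo at all.
    """

    seed: int
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    n_tubules: int = 18
    tubule_outer_radius_um: float = 14.0
    lumen_radius_um: float = 6.0
    apical_band_um: float = 3.0
    apical_fraction: float = 0.7
    umod_positive_fraction: float = 1.0
    background_level: float = 20.0
    signal_level: float = 2000.0
    noise_sd: float = 10.0
    psf_sigma_um: float = 0.5
    cortex_texture_period_um: float = 8.0
    include_papilla: bool = False

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise InfeasibleSpecError("pixel_size_um must be positive")
        if not 0.0 <= self.apical_fraction <= 1.0:
            raise InfeasibleSpecError("apical_fraction must lie in [0, 1]")
        if not 0.0 <= self.umod_positive_fraction <= 1.0:
            raise InfeasibleSpecError("umod_positive_fraction must lie in [0, 1]")
        if self.lumen_radius_um + self.apical_band_um >= self.tubule_outer_radius_um:
            raise InfeasibleSpecError(
                "lumen + apical band must fit inside the tubule outer radius")
        if min(self.background_level, self.signal_level, self.noise_sd,
               self.psf_sigma_um) < 0:
            raise InfeasibleSpecError("levels, noise and PSF sigma must be >= 0")
        if self.cortex_texture_period_um <= 0:
            raise InfeasibleSpecError("cortex_texture_period_um must be positive")
        if self.n_tubules < 1:
            raise InfeasibleSpecError("need at least one tubule")


@dataclass
class FourISpec:
    """Parameters of one synthetic 4i acquisition (one field of one well).

    ``channel_plan[k]`` lists the marker names imaged in cycle ``k+1``; the
    nuclear channel is added to every cycle automatically if missing.
    ``target_correlations`` maps marker pairs to the pixelwise Pearson
    correlation their within-cell textures should realize.
    ``compartment_fractions`` gives the ground-truth split of the cargo
    marker's mask across named compartments (summing to at most 1; any
    remainder is placed in unassigned cytoplasm).
    """

    seed: int
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.2
    n_cycles: int = 3
    n_cells: int = 40
    cycle_shifts_px: list[tuple[int, int]] | None = None
    channel_plan: list[list[str]] | None = None
    target_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    compartment_fractions: dict[str, float] = field(default_factory=dict)
    cargo_channel: str = "UMOD"
    er_channel: str = "CANX"
    cell_radius_um: float = 4.0
    nucleus_radius_um: float = 2.0
    cargo_density: float = 0.25
    background_level: float = 20.0
    signal_level: float = 1000.0
    noise_sd: float = 10.0
    n_z: int = 1
    max_shift_px: int = 32

    def __post_init__(self) -> None:
        if self.cycle_shifts_px is None:
            self.cycle_shifts_px = [(0, 0)] * self.n_cycles
        if self.channel_plan is None:
            plan: list[list[str]] = [[DAPI, self.cargo_channel], [DAPI, self.er_channel]]
            comp = [DAPI] + sorted(self.compartment_fractions)
            while len(plan) < self.n_cycles:
                plan.append(list(comp))
            self.channel_plan = plan[: self.n_cycles]

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise InfeasibleSpecError("pixel_size_um must be positive")
        if self.n_cycles < 1:
            raise InfeasibleSpecError("need at least one cycle")
        if len(self.cycle_shifts_px) != self.n_cycles:
            raise InfeasibleSpecError("one shift per cycle is required")
        if tuple(self.cycle_shifts_px[0]) != (0, 0):
            raise InfeasibleSpecError("cycle 1 must have shift (0, 0)")
        for dy, dx in self.cycle_shifts_px:
            if max(abs(dy), abs(dx)) > self.max_shift_px:
                raise InfeasibleSpecError(
                    f"shift ({dy}, {dx}) exceeds declared maximum {self.max_shift_px}")
        for rho in self.target_correlations.values():
            if not -1.0 <= rho <= 1.0:
                raise InfeasibleSpecError("target correlations must lie in [-1, 1]")
        fsum = sum(self.compartment_fractions.values())
        if fsum > 1.0 + 1e-12 or any(f < 0 for f in self.compartment_fractions.values()):
            raise InfeasibleSpecError("compartment fractions must be >= 0 and sum to <= 1")
        if not 0 < self.cargo_density <= 1:
            raise InfeasibleSpecError("cargo_density must lie in (0, 1]")
        if self.n_z < 1:
            raise InfeasibleSpecError("n_z must be >= 1")
        corr_names = {m for pair in self.target_correlations for m in pair}
        special = set(self.compartment_fractions) | {DAPI, self.cargo_channel, self.er_channel}
        if corr_names & special:
            raise InfeasibleSpecError(
                "correlated-texture markers must not double as nuclear/ER/cargo/"
                f"compartment channels: {sorted(corr_names & special)}")


@dataclass
class GroundTruth:
    """Everything a test needs about a generated field.

    ``masks`` holds boolean masks per object class, ``labels`` integer label
    maps, ``params`` the numeric parameters actually drawn (per-tubule
    positivity and apical fraction, per-cycle shifts, realized per-pair
    correlations, ...).  Masks are geometrically consistent with the rendered
    images *before* blur and noise.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Shared geometry helpers
# ---------------------------------------------------------------------------

def _grid_jitter_centers(rng: np.random.Generator, region_ok, pitch: float,
                         jitter: float, shape: tuple[int, int], n: int,
                         what: str) -> np.ndarray:
    """Place ``n`` centers at least ``pitch - 2*jitter`` apart inside a region.

    Centers sit on a square grid of the given pitch with uniform jitter, which
    guarantees the minimum spacing by construction; a random subset of the
    admissible slots is returned.  Raises :class:`InfeasibleSpecError` when the
    region admits fewer than ``n`` slots (bounded placement failure).
    """
    h, w = shape
    ys = np.arange(pitch / 2, h, pitch)
    xs = np.arange(pitch / 2, w, pitch)
    cand = []
    for y in ys:
        for x in xs:
            cy = y + rng.uniform(-jitter, jitter)
            cx = x + rng.uniform(-jitter, jitter)
            if region_ok(cy, cx):
                cand.append((cy, cx))
    if len(cand) < n:
        raise InfeasibleSpecError(
            f"cannot place {n} non-overlapping {what} (only {len(cand)} slots fit)")
    idx = rng.choice(len(cand), size=n, replace=False)
    return np.asarray([cand[i] for i in sorted(idx)])


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _radius_sq(shape: tuple[int, int], cy: float, cx: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2


# ---------------------------------------------------------------------------
# Tissue sections
# ---------------------------------------------------------------------------

def generate_tissue(spec: TissueSpec) -> tuple[dict[str, ChannelImage], GroundTruth]:
    """Render one synthetic kidney-section field.

    Returns the channel set ``{DAPI, UMOD, MUC1, LTL}`` and the ground truth.
    Per positive tubule, the cargo budget is ``signal_level x (apical band
    pixel count)``: a fraction ``apical_fraction`` of it is spread uniformly
    over the apical band and the remainder uniformly over the intracellular
    annulus, so total rendered cargo intensity is conserved across the split.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_size_px)
    px = spec.pixel_size_um
    b, s = spec.background_level, spec.signal_level
    outer = spec.tubule_outer_radius_um / px
    lumen_r = spec.lumen_radius_um / px
    apical_r = (spec.lumen_radius_um + spec.apical_band_um) / px

    # Tissue: one large disk; cortex: tissue minus the (optional) papilla.
    tis_cy, tis_cx = shape[0] / 2, shape[1] / 2
    tis_r = 0.46 * min(shape)
    tissue = _disk_mask(shape, tis_cy, tis_cx, tis_r)
    papilla = np.zeros(shape, dtype=bool)
    if spec.include_papilla:
        pap_r = 0.12 * tis_r
        papilla = _disk_mask(shape, tis_cy + 0.55 * tis_r, tis_cx, pap_r) & tissue
    cortex = tissue & ~papilla

    # Tubule centers: jittered grid keeps centers >= 2.6 * outer radius apart,
    # wide enough that 8 um expansions of neighboring apical bands stay
    # disconnected for the default geometry (satisfies the >= 2 * outer bound).
    pitch = 2.7 * outer
    jitter = 0.1 * outer / 2
    margin = outer + 2 * jitter + 2
    pap_dist = ndimage.distance_transform_edt(~papilla) if papilla.any() else None
    def _in_cortex(cy, cx):
        if (cy - tis_cy) ** 2 + (cx - tis_cx) ** 2 > (tis_r - margin) ** 2:
            return False
        return pap_dist is None or pap_dist[int(round(cy)), int(round(cx))] > margin
    centers = _grid_jitter_centers(rng, _in_cortex, pitch, jitter, shape,
                                   spec.n_tubules, "tubules")

    tubule_labels = np.zeros(shape, dtype=np.int32)
    lumen = np.zeros(shape, dtype=bool)
    apical = np.zeros(shape, dtype=bool)
    intracellular = np.zeros(shape, dtype=bool)
    for i, (cy, cx) in enumerate(centers, start=1):
        r2 = _radius_sq(shape, cy, cx)
        disk = r2 <= outer**2
        tubule_labels[disk] = i
        lumen |= r2 < lumen_r**2
        apical |= (r2 >= lumen_r**2) & (r2 < apical_r**2)
        intracellular |= (r2 >= apical_r**2) & disk
    tubule = tubule_labels > 0

    n_pos = int(round(spec.umod_positive_fraction * spec.n_tubules))
    pos_ids = np.zeros(spec.n_tubules, dtype=bool)
    pos_ids[rng.choice(spec.n_tubules, size=n_pos, replace=False)] = True

    # --- channels (noise-free) ---
    diffuse = 0.15 * s  # MUC1 in cellular tissue, above lumen/background
    muc1 = np.full(shape, b)
    muc1[tissue & ~lumen] += diffuse
    muc1[apical] = b + s
    muc1[papilla] = b + 2.0 * s

    umod = np.full(shape, b)
    for i in range(1, spec.n_tubules + 1):
        if not pos_ids[i - 1]:
            continue
        t_apical = apical & (tubule_labels == i)
        t_intra = intracellular & (tubule_labels == i)
        n_a, n_i = int(t_apical.sum()), int(t_intra.sum())
        budget = s * n_a
        if n_a:
            umod[t_apical] += spec.apical_fraction * budget / n_a
        if n_i:
            umod[t_intra] += (1.0 - spec.apical_fraction) * budget / n_i

    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float64)
    period_px = spec.cortex_texture_period_um / px
    tex = 0.5 + 0.5 * np.sin(2 * np.pi * yy / period_px) * np.sin(2 * np.pi * xx / period_px)
    ltl = np.full(shape, b)
    ltl[cortex] += s * tex[cortex]
    ltl[papilla] += 0.25 * s

    # Nuclei: small disks scattered in tissue outside lumens and apical bands.
    nuc_r = 2.5 / px
    nuc_pitch, nuc_jitter = 5.0 * nuc_r, 1.0 * nuc_r
    def _nucleus_ok(cy, cx):
        iy, ix = int(round(cy)), int(round(cx))
        return tissue[iy, ix] and not lumen[iy, ix] and not apical[iy, ix]
    n_nuclei_max = max(1, int(tissue.sum() / (nuc_pitch**2 * 1.6)))
    try:
        nuc_centers = _grid_jitter_centers(rng, _nucleus_ok, nuc_pitch, nuc_jitter,
                                           shape, n_nuclei_max, "nuclei")
    except InfeasibleSpecError:  # tiny frames: take whatever fits
        nuc_centers = _grid_jitter_centers(rng, _nucleus_ok, nuc_pitch, nuc_jitter,
                                           shape, 1, "nuclei")
    nuclei_labels = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx) in enumerate(nuc_centers, start=1):
        nuclei_labels[_disk_mask(shape, cy, cx, nuc_r)] = i
    dapi = np.full(shape, b)
    dapi[tissue] += 0.25 * s
    dapi[nuclei_labels > 0] = b + s

    channels = {}
    for name, img in [(DAPI, dapi), ("UMOD", umod), ("MUC1", muc1), ("LTL", ltl)]:
        out = img
        if spec.psf_sigma_um > 0:
            out = ndimage.gaussian_filter(out, spec.psf_sigma_um / px)
        if spec.noise_sd > 0:
            out = out + rng.normal(0.0, spec.noise_sd, shape)
        channels[name] = ChannelImage(np.maximum(out, 0.0), channel=name,
                                      pixel_size_um=px)

    gt = GroundTruth(
        masks={
            "tissue": tissue, "cortex": cortex, "papilla": papilla,
            "tubule": tubule, "lumen": lumen, "apical": apical,
            "intracellular": intracellular,
        },
        labels={"tubules": tubule_labels, "nuclei": nuclei_labels},
        params={
            "apical_fraction": [spec.apical_fraction] * spec.n_tubules,
            "umod_positive": pos_ids.tolist(),
            "tubule_centers_px": centers.tolist(),
            "background_level": b,
            "signal_level": s,
        },
    )
    return channels, gt


# ---------------------------------------------------------------------------
# 4i cycle stacks
# ---------------------------------------------------------------------------

def _correlated_latents(rng: np.random.Generator, markers: list[str],
                        correlations: dict[tuple[str, str], float],
                        n: int) -> dict[str, np.ndarray]:
    """Draw standard-normal textures with the requested pairwise correlations.

    Builds the full correlation matrix and factors it (Cholesky, with an
    eigenvalue fallback); an indefinite matrix means the request is not
    realizable.  For a single pair this reduces to the classic mixing
    construction ``B = rho * A + sqrt(1 - rho^2) * W``.
    """
    k = len(markers)
    corr = np.eye(k)
    idx = {m: i for i, m in enumerate(markers)}
    for (a, bb), rho in correlations.items():
        corr[idx[a], idx[bb]] = corr[idx[bb], idx[a]] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        if w.min() < -1e-10:
            raise InfeasibleSpecError(
                "requested correlation matrix is not realizable") from None
        chol = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    z = rng.standard_normal((k, n))
    mixed = chol @ z
    return {m: mixed[idx[m]] for m in markers}


def generate_4i_stack(spec: FourISpec) -> tuple[CycleStack, GroundTruth]:
    """Render one synthetic 4i acquisition.

    A single cell scene is built once; each cycle re-images it translated by
    that cycle's integer stage shift (border filled with the background level)
    with fresh additive Gaussian noise, emulating imperfect stage
    repositioning between staining cycles.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_size_px)
    px = spec.pixel_size_um
    b, s = spec.background_level, spec.signal_level
    cell_r = spec.cell_radius_um / px
    nuc_r = spec.nucleus_radius_um / px

    pitch = 2.2 * cell_r
    jitter = 0.05 * cell_r
    margin = cell_r + jitter + spec.max_shift_px + 1
    def _in_frame(cy, cx):
        return (margin <= cy <= shape[0] - margin) and (margin <= cx <= shape[1] - margin)
    centers = _grid_jitter_centers(rng, _in_frame, pitch, jitter, shape,
                                   spec.n_cells, "cells")

    cells = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        cells[_disk_mask(shape, cy, cx, cell_r)] = i
        nuclei[_disk_mask(shape, cy, cx, nuc_r)] = i
    cell_mask = cells > 0
    cyto_mask = cell_mask & (nuclei == 0)

    # Compartments: per cell, contiguous angular sectors of the cytoplasm with
    # area shares matching the cargo fractions (plus an unassigned remainder).
    comp_names = sorted(spec.compartment_fractions)
    comp_masks = {c: np.zeros(shape, dtype=bool) for c in comp_names}
    fr = np.asarray([spec.compartment_fractions[c] for c in comp_names])
    # sector shares: compartments get their fraction of the circle, scaled so
    # small fractions still have room for their cargo quota (min share 2x).
    shares = np.minimum(np.maximum(fr * 1.5, 0.05), 0.9 / max(len(fr), 1)) if len(fr) else fr
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float64)
    cargo_mask = np.zeros(shape, dtype=bool)
    for i, (cy, cx) in enumerate(centers, start=1):
        this_cyto = cyto_mask & (cells == i)
        theta = (np.arctan2(yy - cy, xx - cx) + np.pi) / (2 * np.pi)  # in [0, 1)
        lo = 0.0
        for c, share in zip(comp_names, shares):
            comp_masks[c] |= this_cyto & (theta >= lo) & (theta < lo + share)
            lo += share
        # cargo: sample pixels per compartment at the ground-truth fractions
        n_cargo = max(1, int(round(spec.cargo_density * this_cyto.sum())))
        unassigned = this_cyto.copy()
        taken = 0
        for c, f in zip(comp_names, fr):
            pool = np.flatnonzero(comp_masks[c] & this_cyto)
            quota = int(round(f * n_cargo))
            if quota > pool.size:
                raise InfeasibleSpecError(
                    f"compartment {c!r} too small for its cargo fraction")
            pick = rng.choice(pool, size=quota, replace=False)
            cargo_mask.flat[pick] = True
            unassigned.flat[pool] = False
            taken += quota
        pool = np.flatnonzero(unassigned)
        rest = min(max(n_cargo - taken, 0), pool.size)
        if rest:
            pick = rng.choice(pool, size=rest, replace=False)
            cargo_mask.flat[pick] = True

    # Correlated marker textures (within cells), standardized latents.
    corr_markers = sorted({m for pair in spec.target_correlations for m in pair})
    n_in_cells = int(cell_mask.sum())
    latents = _correlated_latents(rng, corr_markers, spec.target_correlations,
                                  n_in_cells)
    realized: dict[str, float] = {}
    marker_fields: dict[str, np.ndarray] = {}
    for m in corr_markers:
        f2d = np.full(shape, b)
        f2d[cell_mask] = 0.5 * s + 0.1 * s * latents[m]
        marker_fields[m] = np.maximum(f2d, 0.0)
    for (a, bb), _rho in spec.target_correlations.items():
        va, vb = latents[a], latents[bb]
        denom = va.std() * vb.std()
        realized[f"{a}|{bb}"] = float(((va - va.mean()) * (vb - vb.mean())).mean() / denom)

    def _render(channel: str) -> np.ndarray:
        if channel == DAPI:
            img = np.full(shape, b)
            img[nuclei > 0] = b + s
        elif channel == spec.er_channel:
            img = np.full(shape, b)
            img[cell_mask] = b + 0.4 * s
            img[cyto_mask] = b + 0.7 * s
        elif channel == spec.cargo_channel:
            img = np.full(shape, b)
            img[cargo_mask] = b + s
        elif channel in comp_masks:
            img = np.full(shape, b)
            img[comp_masks[channel]] = b + s
        elif channel in marker_fields:
            img = marker_fields[channel]
        else:
            img = np.full(shape, b)
            img[cell_mask] = b + 0.5 * s
        return img

    # z weights: symmetric profile peaking at 1 so max over z == the scene.
    if spec.n_z > 1:
        zc = (spec.n_z - 1) / 2
        zw = np.cos((np.arange(spec.n_z) - zc) / (zc + 1) * np.pi / 2) ** 2
        zw = 0.3 + 0.7 * zw / zw.max()
        zw[int(round(zc))] = 1.0
    else:
        zw = np.ones(1)

    cycles: list[list[ChannelImage]] = []
    zstacks: dict[tuple[int, str], list[ChannelImage]] = {}
    for c, (dy, dx) in enumerate(spec.cycle_shifts_px, start=1):
        plan = list(spec.channel_plan[c - 1])
        if DAPI not in plan:
            plan.insert(0, DAPI)
        row: list[ChannelImage] = []
        for ch in plan:
            scene = translate(_render(ch), dy, dx, fill=b)
            if spec.n_z == 1:
                out = scene if spec.noise_sd == 0 else np.maximum(
                    scene + rng.normal(0.0, spec.noise_sd, shape), 0.0)
                row.append(ChannelImage(out, channel=ch, cycle=c, pixel_size_um=px))
            else:
                planes = []
                for w in zw:
                    pl = scene * w
                    if spec.noise_sd > 0:
                        pl = np.maximum(pl + rng.normal(0.0, spec.noise_sd, shape), 0.0)
                    planes.append(ChannelImage(pl, channel=ch, cycle=c, pixel_size_um=px))
                zstacks[(c, ch)] = planes
        cycles.append(row)

    stack = CycleStack(cycles=cycles, zstacks=zstacks) if spec.n_z == 1 else \
        CycleStack.__new__(CycleStack)
    if spec.n_z > 1:  # bypass the 2-D validation; projection rebuilds cycles
        stack.cycles = [[] for _ in range(spec.n_cycles)]
        stack.zstacks = zstacks

    gt = GroundTruth(
        masks={"cargo": cargo_mask,
               **{f"compartment_{c}": m for c, m in comp_masks.items()}},
        labels={"cells": cells, "nuclei": nuclei},
        params={
            "cycle_shifts_px": [tuple(sh) for sh in spec.cycle_shifts_px],
            "realized_correlations": realized,
            "compartment_fractions": dict(spec.compartment_fractions),
            "n_cells": spec.n_cells,
            "background_level": b,
            "signal_level": s,
        },
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Bimodal threshold fixtures
# ---------------------------------------------------------------------------

def generate_bimodal_field(mu0: float, mu1: float, sd: float, mix: float,
                           size: tuple[int, int], seed: int) -> ChannelImage:
    """Two-component Gaussian-mixture intensity field for threshold tests.

    Each pixel is drawn from ``N(mu0, sd)`` with probability ``mix`` and from
    ``N(mu1, sd)`` otherwise, rounded to integers and clipped to the 8-bit
    dynamic range [0, 255].
    """
    if sd <= 0:
        raise InfeasibleSpecError("sd must be positive")
    if not 0 < mix < 1:
        raise InfeasibleSpecError("mix must lie in (0, 1)")
    if mu0 > mu1:
        raise InfeasibleSpecError("mu0 must not exceed mu1")
    rng = np.random.default_rng(seed)
    low = rng.random(size) < mix
    vals = np.where(low, rng.normal(mu0, sd, size), rng.normal(mu1, sd, size))
    vals = np.clip(np.round(vals), 0, 255)
    return ChannelImage(vals, channel="bimodal")


# ---------------------------------------------------------------------------
# Ground-truth sidecar
# ---------------------------------------------------------------------------

def write_ground_truth(path, gt: GroundTruth) -> None:
    """Write a ground-truth sidecar: a .npz of masks/labels + a JSON of params."""
    path = Path(path)
    arrays = {f"mask_{k}": v for k, v in gt.masks.items()}
    arrays.update({f"labels_{k}": v for k, v in gt.labels.items()})
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(gt.params, fh, indent=2, default=str)
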