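"""Ground-truthed synthetic intravital movies and benchmark fixtures.

The generator emulates the image features that make intravital nuclear
segmentation hard: dense fields of elliptical nuclei, heterogeneous per-cell
brightness, uneven background, shot/read noise, thresholding speckle, and
small frame-to-frame drift — together with a drug channel whose kinetics
follow a vessel bolus (single-exponential decay) feeding first-order cellular
uptake.  Every generated scene carries its exact ground truth (per-cell
masks, centers, true concentration curves, the vessel curve), so the whole
analysis pipeline can be validated quantitatively without any external data.

All randomness flows from the single ``seed`` in :class:`SceneSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigError, GenerationError
from .image_io import ChannelStack, _shift_frame
from .pk import CalibrationCurve, one_compartment_concentration
from .segmentation import disk_element

__all__ = [
    "Kinetics",
    "SceneSpec",
    "GroundTruth",
    "generate_movie",
    "generate_metric_fixtures",
    "two_blob_fixture",
]

NUCLEAR_CHANNEL = "nuclear"
DRUG_CHANNEL = "drug"


@dataclass
class Kinetics:
    """One-compartment bolus/uptake parameters (rates in 1/s, peak in µM)."""

    vessel_peak_uM: float = 6.0
    k_decay: float = 4e-4
    k_in: float = 5e-4
    k_out: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("vessel_peak_uM", "k_decay", "k_in", "k_out"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SceneSpec:
    """Full description of a synthetic two-channel scene.

    Geometry: ``n_cells`` elliptical nuclei of radius in ``radius_range``
    (px) and brightness in ``brightness_range``, placed without overlap
    unless ``overlap_allowed``; a vessel occupies a vertical strip at the
    left edge.  Noise: additive Gaussian ``noise_sigma`` plus
    ``speckle_count`` bright single-pixel artifacts per nuclear frame.
    Motion: cumulative global drift of ``drift_px_per_frame``.  Kinetics and
    the fluorescence calibration line tie the drug channel to true
    concentrations.  ``k_in_cv`` is the lognormal coefficient of variation of
    per-cell uptake (cell-to-cell pharmacokinetic heterogeneity);
    ``cytosol_conc_ratio`` the cytosolic-to-nuclear concentration ratio
    rendered in a perinuclear ring.
    """

    n_cells: int = 50
    field_size: int = 256
    radius_range: tuple[float, float] = (4.0, 7.0)
    brightness_range: tuple[float, float] = (0.3, 1.0)
    overlap_allowed: bool = False
    speckle_count: int = 0
    noise_sigma: float = 0.01
    drift_px_per_frame: float = 0.0
    n_frames: int = 1
    frame_interval_s: float = 75.0
    kinetics: Kinetics = field(default_factory=Kinetics)
    # slope sized so the brightest plausible cell (~25 µM) stays inside the
    # [0, 1] fluorescence range; negative intercept <=> a detector dark level
    # of 0.05 fluorescence units at zero concentration, so background noise
    # is not clipped at 0
    calibration_slope: float = 30.0  # µM per fluorescence unit
    calibration_intercept: float = -1.5
    k_in_cv: float = 0.5
    cytosol_conc_ratio: float = 0.02
    cytosol_ring_px: int = 5
    vessel_width_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.brightness_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("brightness_range must lie in (0, 1]")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ConfigError("invalid radius_range")
        if self.n_cells < 0 or self.n_frames < 1 or self.field_size < 16:
            raise ConfigError("invalid scene dimensions")
        if self.noise_sigma < 0 or self.speckle_count < 0:
            raise ConfigError("noise parameters must be >= 0")

    def calibration(self) -> CalibrationCurve:
        return CalibrationCurve(
            slope=self.calibration_slope,
            intercept=self.calibration_intercept,
            r_squared=1.0,
            valid_range=(0.0, 1.0),
        )


@dataclass
class GroundTruth:
    """Exact truth of a generated scene.

    cells : per-cell static properties — id, frame-0 center (row, col),
        semi-axes (a, b), orientation theta, brightness, effective k_in.
    centers : (n_frames, n_cells, 2) drifted centers per frame.
    conc_uM : (n_frames, n_cells) true nuclear concentrations.
    masks / label_maps : per-frame true nuclear masks and cell-id maps.
    vessel_roi : (row_start, row_stop, col_start, col_stop).
    vessel_uM : (n_frames,) true vessel concentration.
    offsets : applied (drow, dcol) drift per frame.
    """

    cells: list[dict]
    centers: np.ndarray
    conc_uM: np.ndarray
    masks: np.ndarray
    label_maps: np.ndarray
    vessel_roi: tuple[int, int, int, int]
    vessel_uM: np.ndarray
    offsets: list[tuple[int, int]]
    spec: SceneSpec


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> list[dict]:
    """Rejection-sample non-overlapping ellipse parameters."""
    margin = spec.radius_range[1] + 3
    col_min = spec.vessel_width_px + spec.radius_range[1] + 4
    cells: list[dict] = []
    attempts = 0
    max_attempts = 4000 * max(spec.n_cells, 1)
    while len(cells) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {spec.n_cells} non-overlapping cells in a "
                f"{spec.field_size}px field after {max_attempts} attempts"
            )
        r = rng.uniform(*spec.radius_range)
        row = rng.uniform(margin, spec.field_size - margin)
        col = rng.uniform(col_min, spec.field_size - margin)
        if not spec.overlap_allowed:
            ok = all(
                np.hypot(row - c["row"], col - c["col"]) > r + c["a"] + 2 for c in cells
            )
            if not ok:
                continue
        cells.append(
            {
                "id": len(cells) + 1,
                "row": row,
                "col": col,
                "a": r,
                "b": r * rng.uniform(0.7, 1.0),
                "theta": rng.uniform(0, np.pi),
                "brightness": rng.uniform(*spec.brightness_range),
            }
        )
    return cells


def _render_cells(cells: list[dict], shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Render nuclei (max-composited, 1-px soft edge) and the true label map."""
    img = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)
    for c in cells:
        rmax = int(np.ceil(max(c["a"], c["b"]))) + 2
        r0 = max(int(c["row"]) - rmax, 0)
        r1 = min(int(c["row"]) + rmax + 1, shape[0])
        c0 = max(int(c["col"]) - rmax, 0)
        c1 = min(int(c["col"]) + rmax + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dr, dc = rr - c["row"], cc - c["col"]
        ct, st = np.cos(c["theta"]), np.sin(c["theta"])
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        e = np.sqrt((u / c["a"]) ** 2 + (v / c["b"]) ** 2)
        # soft edge ~1 px wide across the ellipse boundary
        soft = np.clip((1.0 - e) * min(c["a"], c["b"]) + 0.5, 0.0, 1.0)
        patch = c["brightness"] * soft
        img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], patch)
        inside = e <= 1.0
        labels[r0:r1, c0:c1][inside] = c["id"]
    return img, labels


def generate_movie(spec: SceneSpec) -> tuple[ChannelStack, GroundTruth]:
    """Generate a two-channel movie (or Z-stack) with full ground truth.

    The nuclear channel composites per-cell soft-edged ellipses, speckles and
    Gaussian noise; the drug channel renders the vessel strip at
    ``C_v(t) = peak * exp(-k_decay t)`` and each nucleus at its closed-form
    one-compartment concentration, mapped to fluorescence by inverting the
    calibration line.  The same cumulative integer drift is applied to both
    channels, with zero fill at exposed edges.  Bit-identical for equal specs.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.field_size, spec.field_size)
    cells = _place_cells(spec, rng)
    kin = spec.kinetics
    cal = spec.calibration()

    if spec.k_in_cv > 0 and cells:
        sigma = np.sqrt(np.log1p(spec.k_in_cv**2))
        mult = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=len(cells))
    else:
        mult = np.ones(len(cells))
    for c, m in zip(cells, mult):
        c["k_in"] = kin.k_in * float(m)

    times = np.arange(spec.n_frames) * spec.frame_interval_s
    vessel_uM = kin.vessel_peak_uM * np.exp(-kin.k_decay * times)
    conc = np.zeros((spec.n_frames, len(cells)))
    for j, c in enumerate(cells):
        conc[:, j] = one_compartment_concentration(
            times, kin.vessel_peak_uM, kin.k_decay, c["k_in"], kin.k_out
        )

    base_nuc, base_labels = _render_cells(cells, shape)
    nuc_mask = base_labels > 0
    ring = (
        ndi.binary_dilation(nuc_mask, structure=disk_element(spec.cytosol_ring_px))
        & ~nuc_mask
    )
    vessel_roi = (0, spec.field_size, 0, spec.vessel_width_px)

    drift = spec.drift_px_per_frame
    offsets = [
        (int(round(drift * t)), int(round(drift * t))) for t in range(spec.n_frames)
    ]

    nuclear = np.zeros((spec.n_frames,) + shape)
    drug = np.zeros((spec.n_frames,) + shape)
    masks = np.zeros((spec.n_frames,) + shape, dtype=bool)
    label_maps = np.zeros((spec.n_frames,) + shape, dtype=int)
    centers = np.zeros((spec.n_frames, len(cells), 2))
    base_centers = np.array([[c["row"], c["col"]] for c in cells]).reshape(-1, 2)

    for t in range(spec.n_frames):
        nuc = base_nuc
        # drug fluorescence: nuclei at C_i(t), perinuclear ring at a fixed
        # fraction of it, vessel strip at C_v(t)
        conc_map = np.zeros(shape)
        if cells:
            conc_map = np.concatenate([[0.0], conc[t]])[base_labels]
            # perinuclear ring carries a fixed fraction of its nucleus' conc
            ring_src = np.concatenate([[0.0], conc[t] * spec.cytosol_conc_ratio])[
                _nearest_label(base_labels, ring)
            ]
            conc_map = conc_map + np.where(ring, ring_src, 0.0)
        conc_map[
            vessel_roi[0] : vessel_roi[1], vessel_roi[2] : vessel_roi[3]
        ] = vessel_uM[t]
        dr_frame = cal.inverse(conc_map)
        dr, dc = offsets[t]
        labels_t = base_labels
        if (dr, dc) != (0, 0):
            nuc = _shift_frame(nuc, dr, dc)
            dr_frame = _shift_frame(dr_frame, dr, dc)
            labels_t = _shift_frame(base_labels, dr, dc)
        nuc = nuc.copy()
        if spec.speckle_count:
            sr = rng.integers(0, shape[0], spec.speckle_count)
            sc = rng.integers(0, shape[1], spec.speckle_count)
            nuc[sr, sc] = rng.uniform(0.7, 1.0, spec.speckle_count)
        if spec.noise_sigma:
            nuc = nuc + rng.normal(0, spec.noise_sigma, shape)
            dr_frame = dr_frame + rng.normal(0, spec.noise_sigma, shape)
        nuclear[t] = np.clip(nuc, 0, 1)
        drug[t] = np.clip(dr_frame, 0, 1)
        masks[t] = labels_t > 0
        label_maps[t] = labels_t
        centers[t] = base_centers + np.array([dr, dc])

    stack = ChannelStack(
        channels={NUCLEAR_CHANNEL: nuclear, DRUG_CHANNEL: drug},
        axis_kind="time",
        frame_interval_s=spec.frame_interval_s,
        pixel_size_um=1.0,
        bit_depth_source=16,
    )
    truth = GroundTruth(
        cells=cells,
        centers=centers,
        conc_uM=conc,
        masks=masks,
        label_maps=label_maps,
        vessel_roi=vessel_roi,
        vessel_uM=vessel_uM,
        offsets=offsets,
        spec=spec,
    )
    return stack, truth


def _nearest_label(labels: np.ndarray, where: np.ndarray) -> np.ndarray:
    """Propagate each background pixel's nearest nonzero label (EDT-based)."""
    if not labels.any():
        return labels
    _, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    out = labels.copy()
    out[where] = labels[ir[where], ic[where]]
    return out


def _spec_for_fixture(kind: str, seed: int) -> SceneSpec:
    if kind == "multibright":
        return SceneSpec(
            n_cells=12, field_size=128, radius_range=(5.0, 8.0),
            brightness_range=(0.22, 0.95), noise_sigma=0.005, seed=seed,
        )
    if kind == "dense":
        return SceneSpec(
            n_cells=56, field_size=160, radius_range=(4.0, 6.0),
            brightness_range=(0.75, 0.85), noise_sigma=0.005, seed=seed,
        )
    if kind == "dense_multibright":
        return SceneSpec(
            n_cells=56, field_size=160, radius_range=(4.0, 6.0),
            brightness_range=(0.25, 0.95), noise_sigma=0.005, seed=seed,
        )
    if kind == "highmag":
        return SceneSpec(
            n_cells=4, field_size=160, radius_range=(14.0, 18.0),
            brightness_range=(0.6, 0.8), noise_sigma=0.005, seed=seed,
        )
    raise ConfigError(f"unknown fixture kind {kind!r}")


def generate_metric_fixtures(kind: str, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One frame of a named imaging-complication class plus its exact mask.

    Kinds mirror the canonical hard cases of intravital nuclear imaging:
    ``multibright`` (per-cell brightness spanning at least a 3x ratio),
    ``dense`` (>= 50 nuclei, >= 30 % of them within 2 px of a neighbour),
    ``dense_multibright`` (both at once) and ``highmag`` (few large nuclei
    with intracellular texture).  The returned mask — the union of the
    generated nucleus supports — stands in for a reviewer's manual
    reference.
    """
    spec = _spec_for_fixture(kind, seed)
    rng = np.random.default_rng(spec.seed)
    shape = (spec.field_size, spec.field_size)
    if kind in ("multibright", "dense_multibright"):
        cells = _place_cells(spec, rng)
        lo, hi = spec.brightness_range
        for i, c in enumerate(cells):  # guarantee the >= 3x brightness span
            c["brightness"] = lo if i % 2 == 0 else rng.uniform(max(hi - 0.2, lo), hi)
    elif kind == "dense":
        cells = _paired_placement(spec, rng)
    else:
        cells = _place_cells(spec, rng)
    img, labels = _render_cells(cells, shape)
    if kind == "highmag":
        # intracellular detail: smooth multiplicative texture inside nuclei
        texture = ndi.gaussian_filter(rng.normal(0, 1, shape), 3)
        texture = 1.0 + 0.25 * texture / max(np.abs(texture).max(), 1e-9)
        img = np.where(labels > 0, img * texture, img)
    img = np.clip(img + rng.normal(0, spec.noise_sigma, shape), 0, 1)
    return img, labels > 0


def _paired_placement(spec: SceneSpec, rng: np.random.Generator) -> list[dict]:
    """Dense placement where >= 30 % of cells sit within 2 px of a neighbour."""
    cells = _place_cells(spec, rng)
    # convert ~40 % of cells into tight pairs by adding a close companion
    n_pairs = max(1, int(0.2 * len(cells)))
    paired = cells[: len(cells) - n_pairs]
    for i, c in enumerate(cells[len(cells) - n_pairs :]):
        host = paired[i % len(paired)]
        r = rng.uniform(*spec.radius_range)
        angle = rng.uniform(0, 2 * np.pi)
        dist = host["a"] + r + rng.uniform(0.5, 2.0)
        paired.append(
            {
                "id": 0,
                "row": float(np.clip(host["row"] + dist * np.sin(angle), 8, spec.field_size - 8)),
                "col": float(np.clip(host["col"] + dist * np.cos(angle), spec.vessel_width_px + 8, spec.field_size - 8)),
                "a": r,
                "b": r * rng.uniform(0.8, 1.0),
                "theta": rng.uniform(0, np.pi),
                "brightness": rng.uniform(*spec.brightness_range),
            }
        )
    for i, c in enumerate(paired):
        c["id"] = i + 1
    return paired


def two_blob_fixture(
    dim_level: float = 0.3,
    bright_level: float = 0.9,
    field_size: int = 96,
    blob_radius: float = 9.0,
    ramp_max: float = 0.25,
    noise_sigma: float = 0.005,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The canonical multiple-brightness test scene.

    A bright and a dim circular blob on a left-to-right background ramp
    (0 -> ``ramp_max``): an image with multiple brightness levels on uneven
    background, where a single global threshold cannot capture both blobs.
    Returns ``(frame, dim_mask, bright_mask)``.
    """
    rng = np.random.default_rng(seed)
    shape = (field_size, field_size)
    ramp = np.tile(np.linspace(0, ramp_max, field_size), (field_size, 1))
    rr, cc = np.mgrid[0:field_size, 0:field_size]

    def blob(crow, ccol):
        d = np.hypot(rr - crow, cc - ccol)
        soft = np.clip(blob_radius - d + 0.5, 0, 1)
        return soft, d <= blob_radius

    jitter = rng.uniform(-4, 4, size=4)
    dim_soft, dim_mask = blob(field_size * 0.3 + jitter[0], field_size * 0.26 + jitter[1])
    bright_soft, bright_mask = blob(field_size * 0.68 + jitter[2], field_size * 0.72 + jitter[3])
    frame = np.maximum.reduce(
        [ramp, dim_level * dim_soft, bright_level * bright_soft]
    )
    frame = np.clip(frame + rng.normal(0, noise_sigma, shape), 0, 1)
    return frame, dim_mask, bright_mask
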