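"""Fluorescence-to-concentration conversion and per-cell drug analytics.

A dilution series of the fluorophore-labeled drug imaged under the
acquisition settings gives a calibration line mapping mean fluorescence to
concentration (µM).  Applied to the drug channel inside segmented nuclear
borders, it yields per-cell intracellular drug concentrations over time,
from which the analytics of a single-cell pharmacokinetics assay follow:
mean ± sd nuclear concentration per frame, the concentration inside a vessel
ROI, the fraction of cells below a therapeutic threshold (1.5 µM by
default), and the nuclear vs. cytosolic partitioning of the drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import CalibrationError, ConfigError, StructuralError
from .segmentation import LabeledRegions, disk_element

__all__ = [
    "CalibrationCurve",
    "ConcentrationSeries",
    "fit_calibration",
    "fluorescence_to_concentration",
    "cell_concentrations",
    "vessel_curve",
    "subtherapeutic_fraction",
    "nuclear_fraction",
    "one_compartment_concentration",
    "fit_uptake_kinetics",
]

THERAPEUTIC_THRESHOLD_UM = 1.5  # default therapeutic cutoff, µM


@dataclass
class CalibrationCurve:
    """Linear map from fluorescence (normalized units) to concentration (µM).

    ``concentration = slope * fluorescence + intercept``.  ``valid_range``
    spans the fluorescence values observed in the dilution series;
    conversions outside it are extrapolations and are flagged as such.
    """

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope}")
        if not self.valid_range[0] < self.valid_range[1]:
            raise CalibrationError("valid_range min must be < max")

    def convert(self, fluor) -> np.ndarray:
        return self.slope * np.asarray(fluor, dtype=float) + self.intercept

    def inverse(self, conc) -> np.ndarray:
        """Concentration back to fluorescence (used by the simulator)."""
        return (np.asarray(conc, dtype=float) - self.intercept) / self.slope


def fit_calibration(dilution_table) -> CalibrationCurve:
    """Ordinary least-squares calibration line from a dilution series.

    ``dilution_table`` is an iterable of ``(concentration_uM, mean_fluorescence)``
    pairs (or a DataFrame with those two columns, in that order).  At least 3
    points and 2 distinct concentrations are required.
    """
    table = np.asarray(pd.DataFrame(dilution_table).iloc[:, :2], dtype=float)
    if table.shape[0] < 3:
        raise CalibrationError(f"need >= 3 dilution points, got {table.shape[0]}")
    conc, fluor = table[:, 0], table[:, 1]
    if np.unique(conc).size < 2:
        raise CalibrationError("need >= 2 distinct concentrations")
    if np.ptp(fluor) == 0:
        raise CalibrationError("dilution fluorescence has zero variance")
    fit = linregress(fluor, conc)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        valid_range=(float(fluor.min()), float(fluor.max())),
    )


def fluorescence_to_concentration(curve: CalibrationCurve, fluor: float) -> tuple[float, bool]:
    """Convert one fluorescence value; returns ``(concentration_uM, extrapolated)``.

    Values outside the calibrated fluorescence range are still converted but
    flagged as extrapolated.
    """
    lo, hi = curve.valid_range
    extrapolated = not (lo <= fluor <= hi)
    return float(curve.convert(fluor)), extrapolated


@dataclass
class ConcentrationSeries:
    """Per-frame and per-cell drug concentrations of one movie.

    frames : DataFrame(time_s, n_cells, mean_uM, sd_uM[, vessel_uM]) — the
        per-frame mean and population standard deviation over cells; NaN
        marks frames with no cells (undefined).
    cells : long DataFrame(frame, time_s, cell_id, conc_uM).
    """

    frames: pd.DataFrame
    cells: pd.DataFrame

    def cell_curve(self, frame: int, cell_id: int) -> float:
        sel = self.cells[(self.cells["frame"] == frame) & (self.cells["cell_id"] == cell_id)]
        if sel.empty:
            raise StructuralError(f"no cell {cell_id} in frame {frame}")
        return float(sel["conc_uM"].iloc[0])


def cell_concentrations(
    regions_per_frame: list[LabeledRegions],
    drug_frames: np.ndarray,
    curve: CalibrationCurve,
    frame_interval_s: float = 75.0,
    background: float = 0.0,
) -> ConcentrationSeries:
    """Per-cell nuclear drug concentration in every frame.

    Each cell's concentration is the calibration-converted mean of the drug
    channel over the cell's member pixels (the area enclosed by its border).
    ``background`` is an optional constant fluorescence background subtracted
    before conversion (default 0).  A frame with no cells is recorded with an
    empty cell list and NaN summary statistics.
    """
    drug_frames = np.asarray(drug_frames, dtype=float)
    if len(regions_per_frame) != drug_frames.shape[0]:
        raise StructuralError(
            f"{len(regions_per_frame)} labelings vs {drug_frames.shape[0]} drug frames"
        )
    frame_rows, cell_rows = [], []
    for i, labeled in enumerate(regions_per_frame):
        t = i * frame_interval_s
        concs = []
        if labeled.n_regions:
            ids = np.array([r.id for r in labeled.regions])
            means = ndi.mean(drug_frames[i], labeled.label_map, ids)
            concs = curve.convert(np.asarray(means) - background)
            for r, c in zip(labeled.regions, concs):
                cell_rows.append(
                    {"frame": i, "time_s": t, "cell_id": r.id, "conc_uM": float(c)}
                )
        concs = np.asarray(concs, dtype=float)
        frame_rows.append(
            {
                "frame": i,
                "time_s": t,
                "n_cells": int(concs.size),
                "mean_uM": float(concs.mean()) if concs.size else math.nan,
                "sd_uM": float(concs.std()) if concs.size else math.nan,
            }
        )
    return ConcentrationSeries(
        frames=pd.DataFrame(frame_rows),
        cells=pd.DataFrame(cell_rows, columns=["frame", "time_s", "cell_id", "conc_uM"]),
    )


def vessel_curve(
    drug_frames: np.ndarray,
    roi: tuple[int, int, int, int],
    curve: CalibrationCurve,
    frame_interval_s: float = 75.0,
) -> pd.DataFrame:
    """Mean converted concentration inside a rectangular vessel ROI per frame.

    ``roi`` is ``(row_start, row_stop, col_start, col_stop)`` in slice
    semantics (stop exclusive).
    """
    drug_frames = np.asarray(drug_frames, dtype=float)
    r0, r1, c0, c1 = roi
    h, w = drug_frames.shape[1:]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise StructuralError(f"ROI {roi} outside frame bounds {(h, w)}")
    means = drug_frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return pd.DataFrame(
        {
            "frame": np.arange(drug_frames.shape[0]),
            "time_s": np.arange(drug_frames.shape[0]) * frame_interval_s,
            "vessel_uM": curve.convert(means),
        }
    )


def subtherapeutic_fraction(concentrations, threshold_uM: float = THERAPEUTIC_THRESHOLD_UM) -> float:
    """Fraction of cells strictly below the therapeutic concentration."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        return math.nan
    return float(np.count_nonzero(conc < threshold_uM) / conc.size)


def nuclear_fraction(
    nuclei: LabeledRegions,
    drug_frame: np.ndarray,
    ring_radius: int = 5,
    background: float = 0.0,
) -> float:
    """Share of cellular drug signal residing in the nuclear compartment.

    The cytosol is approximated by a ring: the dilation of the nuclear mask
    by a disk of ``ring_radius`` minus the nuclei themselves.  Returns
    ``sum(drug over nuclei) / sum(drug over nuclei + ring)``, or NaN when the
    combined signal is zero (undefined).  ``background`` is a constant
    fluorescence offset (detector dark level) subtracted before summing so
    the ratio reflects drug signal, not sensor baseline.
    """
    if ring_radius < 1:
        raise ConfigError("ring_radius must be >= 1")
    if not nuclei.n_regions:
        raise StructuralError("no nuclei to evaluate")
    drug_frame = np.clip(np.asarray(drug_frame, dtype=float) - background, 0.0, None)
    nuc = nuclei.label_map > 0
    if nuc.shape != drug_frame.shape:
        raise StructuralError("nuclei and drug frame shapes differ")
    dilated = ndi.binary_dilation(nuc, structure=disk_element(ring_radius))
    ring = dilated & ~nuc
    total = float(drug_frame[nuc].sum() + drug_frame[ring].sum())
    if total == 0:
        return math.nan
    return float(drug_frame[nuc].sum() / total)


def one_compartment_concentration(
    t, vessel_peak_uM: float, k_decay: float, k_in: float, k_out: float
) -> np.ndarray:
    """Closed-form intracellular concentration under a one-compartment model.

    The vessel bolus decays as ``C_v(t) = peak * exp(-k_decay t)`` and the
    cell takes up drug by first-order exchange, ``dC/dt = k_in C_v - k_out C``
    with ``C(0) = 0``.  All rate constants in 1/s, time in s, output in µM.
    """
    t = np.asarray(t, dtype=float)
    a = vessel_peak_uM * k_in
    if math.isclose(k_out, k_decay, rel_tol=1e-12, abs_tol=1e-15):
        return a * t * np.exp(-k_decay * t)
    return a * (np.exp(-k_decay * t) - np.exp(-k_out * t)) / (k_out - k_decay)


def fit_uptake_kinetics(
    times_s,
    mean_conc_uM,
    vessel_peak_uM: float,
    k_decay: float,
    initial: tuple[float, float] = (1e-3, 1e-3),
) -> dict[str, float]:
    """Least-squares refit of the uptake constants from a measured mean curve.

    With the vessel input (peak and decay rate) known, ``k_in`` and ``k_out``
    are recovered by nonlinear least squares against
    :func:`one_compartment_concentration`.
    """
    times_s = np.asarray(times_s, dtype=float)
    mean_conc_uM = np.asarray(mean_conc_uM, dtype=float)
    ok = np.isfinite(mean_conc_uM)
    if ok.sum() < 3:
        raise StructuralError("need >= 3 finite points to fit kinetics")

    def model(t, k_in, k_out):
        return one_compartment_concentration(t, vessel_peak_uM, k_decay, k_in, k_out)

    popt, _ = curve_fit(
        model,
        times_s[ok],
        mean_conc_uM[ok],
        p0=initial,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    return {"k_in": float(popt[0]), "k_out": float(popt[1])}
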