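"""Fluorometric exoenzyme activities from MUF-substrate plate assays.

Plate-reader time series of 4-methylumbelliferone (MUF) fluorescence are
converted to substrate-cleavage rates in four steps: fit a linear standard
curve over known MUF concentrations, invert fluorescence to concentration,
take the OLS slope of concentration against time (per hour), and convert the
in-assay rate to moles per hour, optionally normalised to 16S rRNA gene
copies and expressed in attomol (1 amol = 1e-18 mol) per hour per copy.

Default assay geometry: 50 uL sample + 50 uL substrate + 100 uL buffer =
200 uL total assay volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError

__all__ = [
    "MUF_STANDARDS_UM",
    "DEFAULT_ASSAY_VOLUME_L",
    "FluorescenceSeries",
    "StandardCurve",
    "ActivityResult",
    "fit_standard_curve",
    "fluorescence_to_concentration",
    "activity_rate",
    "normalize_activity",
    "measure_activity",
    "activity_ratio_profile",
    "read_plate_csv",
]

#: Standard-curve MUF concentrations (uM) used by the assay protocol.
MUF_STANDARDS_UM = (0.0, 0.5, 1.0, 1.5, 2.0, 3.5, 7.5)

#: 50 uL sample + 50 uL substrate + 100 uL buffer.
DEFAULT_ASSAY_VOLUME_L = 200e-6


@dataclass
class FluorescenceSeries:
    """One well's fluorescence time series.

    ``times_min`` are minutes from assay start (strictly increasing);
    fluorescence is in arbitrary plate-reader units.
    """

    times_min: np.ndarray
    fluorescence: np.ndarray
    well: str = ""
    substrate: str | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times_min.shape != self.fluorescence.shape or self.times_min.ndim != 1:
            raise ValidationError("times and fluorescence must be equal-length 1-D arrays")
        if len(self.times_min) and np.any(np.diff(self.times_min) <= 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class StandardCurve:
    """Linear MUF standard curve: fluorescence = slope * conc + intercept."""

    concentrations_um: tuple[float, ...]
    fluorescence: tuple[float, ...]
    slope: float  # AU per uM
    intercept: float  # AU
    r_squared: float


@dataclass(frozen=True)
class ActivityResult:
    """Enzyme activity with its unit chain.

    rate_um_per_h (in-assay) -> rate_mol_per_h (x 1e-6 x assay volume in L)
    -> per_copy_amol_per_h (/ gene copies, x 1e18).
    """

    rate_um_per_h: float
    rate_mol_per_h: float
    assay_volume_l: float
    gene_copies: float | None = None
    per_copy_amol_per_h: float | None = None
    substrate: str | None = None
    well: str = ""


def fit_standard_curve(
    concentrations_um: Sequence[float], fluorescence: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares standard curve over known MUF concentrations.

    Requires at least three distinct concentrations and a strictly positive
    fitted slope (fluorescence must increase with MUF).
    """
    conc = np.asarray(concentrations_um, dtype=float)
    fluo = np.asarray(fluorescence, dtype=float)
    if conc.shape != fluo.shape or conc.ndim != 1:
        raise ValidationError("concentration and fluorescence lists must match")
    if len(np.unique(conc)) < 3:
        raise ValidationError(
            "standard curve needs at least 3 distinct concentrations"
        )
    fit = stats.linregress(conc, fluo)
    if not np.isfinite(fit.slope) or fit.slope <= 0:
        raise ValidationError(
            f"standard curve slope {fit.slope} is not positive; the curve "
            "cannot be inverted"
        )
    return StandardCurve(
        concentrations_um=tuple(conc),
        fluorescence=tuple(fluo),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def fluorescence_to_concentration(
    series: FluorescenceSeries,
    curve: StandardCurve,
    blank: FluorescenceSeries | None = None,
) -> np.ndarray:
    """Back-calculate MUF concentrations (uM) from fluorescence.

    conc = (fluorescence - intercept) / slope, per time point. An optional
    substrate-free blank series (same time base) is subtracted point-wise
    first. Slightly negative values near zero are retained, not clipped, so
    zero-activity series stay unbiased.
    """
    if curve.slope <= 0:
        raise ValidationError("cannot invert a standard curve with slope <= 0")
    fluo = series.fluorescence
    if blank is not None:
        if len(blank) != len(series) or not np.allclose(blank.times_min, series.times_min):
            raise ValidationError("blank series must share the sample's time base")
        fluo = fluo - blank.fluorescence
    return (fluo - curve.intercept) / curve.slope


def activity_rate(
    times_min: Sequence[float],
    conc_um: Sequence[float],
    window: tuple[float, float] | None = None,
    max_slope_window_min: float | None = None,
) -> float:
    """MUF release rate in uM per hour: OLS slope of concentration vs time.

    ``window`` restricts the fit to times in [t0, t1] minutes (default: full
    series). ``max_slope_window_min`` instead slides a window of the given
    width along the series and returns the steepest slope — useful when
    substrate depletion bends the late part of the curve.
    """
    t = np.asarray(times_min, dtype=float)
    c = np.asarray(conc_um, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValidationError("times and concentrations must be equal-length 1-D arrays")
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, c = t[keep], c[keep]
    if len(t) < 3:
        raise ValidationError("rate fitting needs at least 3 points in the window")

    def slope_per_hour(tt: np.ndarray, cc: np.ndarray) -> float:
        return float(stats.linregress(tt / 60.0, cc).slope)

    if max_slope_window_min is None:
        return slope_per_hour(t, c)
    best = -np.inf
    for i in range(len(t)):
        keep = (t >= t[i]) & (t <= t[i] + max_slope_window_min)
        if keep.sum() < 3:
            continue
        best = max(best, slope_per_hour(t[keep], c[keep]))
    if not np.isfinite(best):
        raise ValidationError(
            f"no window of {max_slope_window_min} min holds 3 points"
        )
    return best


def normalize_activity(
    rate_um_per_h: float, assay_volume_l: float, gene_copies: float
) -> float:
    """Per-gene-copy activity in amol/h/copy.

    uM/h x volume(L) = umol/h -> x1e-6 mol/h; divided by copies and expressed
    in attomol (x1e18). Example: 1 nmol/h over 1e9 copies = 1 amol/h/copy.
    """
    if assay_volume_l <= 0:
        raise ValidationError("assay volume must be positive")
    if gene_copies <= 0:
        raise ValidationError(
            "gene_copies must be positive; per-copy normalisation needs the "
            "qPCR-derived 16S copy number of the assayed material"
        )
    mol_per_h = rate_um_per_h * 1e-6 * assay_volume_l
    return mol_per_h / gene_copies * 1e18


def measure_activity(
    series: FluorescenceSeries,
    curve: StandardCurve,
    assay_volume_l: float = DEFAULT_ASSAY_VOLUME_L,
    gene_copies: float | None = None,
    blank: FluorescenceSeries | None = None,
    window: tuple[float, float] | None = None,
    max_slope_window_min: float | None = None,
) -> ActivityResult:
    """Full chain: fluorescence series -> (per-copy) enzyme activity."""
    conc = fluorescence_to_concentration(series, curve, blank=blank)
    rate = activity_rate(
        series.times_min, conc, window=window, max_slope_window_min=max_slope_window_min
    )
    mol_per_h = rate * 1e-6 * assay_volume_l
    per_copy = (
        normalize_activity(rate, assay_volume_l, gene_copies)
        if gene_copies is not None
        else None
    )
    return ActivityResult(
        rate_um_per_h=rate,
        rate_mol_per_h=mol_per_h,
        assay_volume_l=assay_volume_l,
        gene_copies=gene_copies,
        per_copy_amol_per_h=per_copy,
        substrate=series.substrate,
        well=series.well,
    )


def activity_ratio_profile(activities: Mapping[str, float]) -> pd.Series:
    """Substrate activity profile normalised to its maximum.

    The ratio pattern between substrates (e.g. alpha-glucoside :
    beta-cellobioside : beta-xyloside) is the comparison device for asking
    whether two communities deploy the same enzymatic repertoire; it is
    invariant to the per-copy normalisation factor.
    """
    s = pd.Series(dict(activities), dtype=float)
    if s.empty:
        raise ValidationError("no activities given")
    top = s.max()
    if top <= 0:
        raise ValidationError("all activities are non-positive; no ratio profile")
    return s / top


def read_plate_csv(path: str | Path) -> dict[str, FluorescenceSeries]:
    """Read a long-format plate-reader export.

    Expected columns: ``well``, ``minute``, ``fluorescence``, and optionally
    ``substrate``. Returns one series per well, sorted by time.
    """
    df = pd.read_csv(path)
    required = {"well", "minute", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"plate CSV {path} is missing columns {sorted(missing)}")
    out: dict[str, FluorescenceSeries] = {}
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("minute")
        substrate = None
        if "substrate" in sub.columns and sub["substrate"].notna().any():
            substrate = str(sub["substrate"].dropna().iloc[0])
        out[str(well)] = FluorescenceSeries(
            times_min=sub["minute"].to_numpy(dtype=float),
            fluorescence=sub["fluorescence"].to_numpy(dtype=float),
            well=str(well),
            substrate=substrate,
        )
    return out
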