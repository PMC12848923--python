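"""Core stable-isotope arithmetic for water samples.

Hydrogen and oxygen isotope abundances of water are expressed in δ notation:
the per-mil deviation of a sample's heavy/light isotope ratio (D/H or
¹⁸O/¹⁶O) from the VSMOW standard,

    δ = (R_sample / R_standard − 1) × 1000   [‰].

This module provides δ arithmetic (:func:`delta_from_ratio`,
:func:`d_excess`), ordinary-least-squares fitting of a local meteoric water
line (LMWL, δD regressed on δ¹⁸O for precipitation samples,
:func:`fit_meteoric_line`), and per-soil-layer source summaries
(:func:`summarize_sources`) that feed the Bayesian mixing model.

Sample tables are plain :class:`pandas.DataFrame` objects with the column
schema in :data:`SAMPLE_COLUMNS`; depth intervals are half-open
``[top, bottom)`` in centimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, MissingSourceError

__all__ = [
    "SAMPLE_COLUMNS",
    "DELTA_ENVELOPE",
    "SOIL_INTERVALS_CM",
    "SOURCE_INTERVALS_CM",
    "DEFAULT_DEPTH_GROUPS",
    "MeteoricLineFit",
    "SourceSummary",
    "layer_label",
    "delta_from_ratio",
    "d_excess",
    "fit_meteoric_line",
    "summarize_sources",
    "read_samples",
    "write_samples",
]

#: Column schema shared by every sample table in the package.
SAMPLE_COLUMNS = [
    "site_id",
    "sample_type",  # precipitation | soil | xylem
    "depth_top_cm",
    "depth_bottom_cm",
    "group",
    "species",
    "replicate",
    "d2H_permil",
    "d18O_permil",
    "date",
]

#: Sanity envelope for any δ value handled by the package (‰ VSMOW).
DELTA_ENVELOPE = (-200.0, 50.0)

#: The nine sampled soil depth intervals (cm, top inclusive, bottom exclusive).
SOIL_INTERVALS_CM: list[tuple[float, float]] = [
    (0, 5), (5, 10), (10, 20), (20, 40), (40, 60),
    (60, 80), (80, 100), (100, 120), (120, 150),
]

#: Default mixing-source scheme: the eight shallowest intervals. The deepest
#: (120-150 cm) interval is sampled but excluded as a source by default.
SOURCE_INTERVALS_CM: list[tuple[float, float]] = SOIL_INTERVALS_CM[:8]


def layer_label(top: float, bottom: float) -> str:
    """Canonical label for a depth interval, e.g. ``"40-60 cm"``."""
    fmt = lambda v: f"{v:g}"
    return f"{fmt(top)}-{fmt(bottom)} cm"


#: Default aggregation of the eight source layers into ecological depth
#: groups: shallow (herb root zone), intermediate (semi-shrub), deep (shrub),
#: plus the 100-120 cm remainder reported separately.
DEFAULT_DEPTH_GROUPS: dict[str, str] = {
    layer_label(0, 5): "0-20 cm",
    layer_label(5, 10): "0-20 cm",
    layer_label(10, 20): "0-20 cm",
    layer_label(20, 40): "20-40 cm",
    layer_label(40, 60): "40-100 cm",
    layer_label(60, 80): "40-100 cm",
    layer_label(80, 100): "40-100 cm",
    layer_label(100, 120): "100-120 cm",
}


@dataclass(frozen=True)
class MeteoricLineFit:
    """OLS fit of δD on δ¹⁸O for precipitation samples.

    Attributes
    ----------
    slope, intercept
        Regression coefficients (‰/‰ and ‰). A slope below the global
        meteoric water line's 8 together with an elevated intercept is the
        classic signature of sub-cloud evaporation and moisture recycling.
    r_squared
        Coefficient of determination; equals the squared Pearson
        correlation of the two isotope vectors.
    n
        Number of samples used.
    residual_sd
        Standard deviation of the fit residuals (‰, n−2 denominator).
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float

    def predict(self, d18o: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(d18o) + self.intercept


@dataclass(frozen=True)
class SourceSummary:
    """Per-soil-layer isotope summary used as a mixing-model source."""

    label: str
    top_cm: float
    bottom_cm: float
    mean_d2H: float
    sd_d2H: float
    mean_d18O: float
    sd_d18O: float
    n: int
    single_replicate: bool = False  # SD reported as 0; data-quality flag


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """δ value (‰) of an isotope abundance ratio against a standard.

    Raises
    ------
    DegenerateInputError
        If ``r_standard`` is not strictly positive or ``r_sample`` negative.
    """
    if r_standard <= 0:
        raise DegenerateInputError(f"standard ratio must be > 0, got {r_standard}")
    if r_sample < 0:
        raise DegenerateInputError(f"sample ratio must be >= 0, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if r_standard <= 0:
        raise DegenerateInputError(f"standard ratio must be > 0, got {r_standard}")
    return r_standard * (1.0 + delta / 1000.0)


def d_excess(d2h: float | np.ndarray, d18o: float | np.ndarray) -> float | np.ndarray:
    """Deuterium excess d = δD − 8·δ¹⁸O (‰).

    Points on the global meteoric water line (δD = 8·δ¹⁸O + 10) have
    d-excess exactly 10 ‰; evaporated waters fall below.
    """
    if isinstance(d2h, np.ndarray) or isinstance(d18o, np.ndarray):
        return np.asarray(d2h) - 8.0 * np.asarray(d18o)
    return d2h - 8.0 * d18o


def _isotope_vectors(samples) -> tuple[np.ndarray, np.ndarray]:
    """Extract (δ¹⁸O, δD) vectors from a DataFrame or a pair-sequence."""
    if isinstance(samples, pd.DataFrame):
        return (
            samples["d18O_permil"].to_numpy(dtype=float),
            samples["d2H_permil"].to_numpy(dtype=float),
        )
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DegenerateInputError(
            "expected a sample DataFrame or an (n, 2) array of (d18O, d2H) pairs"
        )
    return arr[:, 0], arr[:, 1]


def fit_meteoric_line(samples) -> MeteoricLineFit:
    """Fit the local meteoric water line by OLS of δD on δ¹⁸O.

    Parameters
    ----------
    samples
        Precipitation samples: a DataFrame with ``d18O_permil`` /
        ``d2H_permil`` columns, or an ``(n, 2)`` array of (δ¹⁸O, δD) pairs.

    Raises
    ------
    DegenerateInputError
        Fewer than 3 samples, or zero δ¹⁸O variance.
    """
    x, y = _isotope_vectors(samples)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 precipitation samples, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero d18O variance: meteoric line undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(res.ssr / (n - 2))) if n > 2 else 0.0
    return MeteoricLineFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n=n,
        residual_sd=resid_sd,
    )


def summarize_sources(
    soil_samples: pd.DataFrame,
    scheme: Sequence[tuple[float, float]] = SOURCE_INTERVALS_CM,
) -> list[SourceSummary]:
    """Per-layer mean/SD/n of δ²H and δ¹⁸O over a layer scheme.

    A sample belongs to the layer whose half-open interval ``[top, bottom)``
    contains its depth midpoint. SDs use the n−1 denominator; single-
    replicate layers get SD 0 with a warning and a ``single_replicate``
    flag rather than an error (the mixing model applies an SD floor).

    Raises
    ------
    MissingSourceError
        If a layer of the scheme has no samples, naming the layer.
    """
    soil = soil_samples[soil_samples["sample_type"] == "soil"]
    mid = (
        soil["depth_top_cm"].to_numpy(dtype=float)
        + soil["depth_bottom_cm"].to_numpy(dtype=float)
    ) / 2.0
    out: list[SourceSummary] = []
    for top, bottom in scheme:
        sel = soil[(mid >= top) & (mid < bottom)]
        label = layer_label(top, bottom)
        if sel.empty:
            raise MissingSourceError(f"no soil samples for layer {label}")
        n = len(sel)
        single = n == 1
        if single:
            warnings.warn(
                f"layer {label} has a single replicate; SD reported as 0",
                stacklevel=2,
            )
        out.append(
            SourceSummary(
                label=label,
                top_cm=top,
                bottom_cm=bottom,
                mean_d2H=float(sel["d2H_permil"].mean()),
                sd_d2H=0.0 if single else float(sel["d2H_permil"].std(ddof=1)),
                mean_d18O=float(sel["d18O_permil"].mean()),
                sd_d18O=0.0 if single else float(sel["d18O_permil"].std(ddof=1)),
                n=n,
                single_replicate=single,
            )
        )
    return out


def read_samples(path) -> pd.DataFrame:
    """Read a sample CSV in the package schema."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise DegenerateInputError(f"sample CSV {path} missing columns {missing}")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SAMPLE_COLUMNS)
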