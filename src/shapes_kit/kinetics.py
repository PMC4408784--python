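"""Reagent-hydrolysis kinetics.

Isatoic-anhydride SHAPE reagents hydrolyse in aqueous buffer to fluorescent
2-amino-benzoates, so the reagent pool's decay can be followed as a rising
fluorescence f(x) = y0 + a * (1 - exp(-b * x)) with offset y0, amplitude a
and decay constant b (per minute). The half-life of the reagent pool,
which decays as exp(-b * t), is ln(2) / b.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, FitError


@dataclass
class KineticsFit:
    y0: float  # fluorescence offset, arbitrary units
    a: float  # amplitude, same units
    b: float  # decay constant, 1/min
    half_life: float | None  # ln(2)/b in minutes; None when flagged
    residual_sse: float
    flagged: bool = False
    message: str = ""


def _model(x: np.ndarray, y0: float, a: float, b: float) -> np.ndarray:
    return y0 + a * (1.0 - np.exp(-b * x))


def half_life(b: float) -> float:
    """Half-life ln(2)/b (minutes) of a pool decaying as exp(-b t)."""
    if b <= 0:
        raise DataError(f"half-life undefined for decay constant b={b}")
    return float(np.log(2.0) / b)


def fit_exponential_rise(times: np.ndarray, fluorescence: np.ndarray) -> KineticsFit:
    """Nonlinear least-squares fit of the three-parameter rise-to-maximum model.

    Initialization from the data: y0 <- first value, a <- observed range,
    b <- 1/time span. A fit with b <= 0, a non-identifiable amplitude or a
    singular covariance is returned flagged rather than raised; failure to
    converge raises FitError with the optimizer message.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise DataError("times and fluorescence must be 1-D and the same length")
    if len(x) < 4:
        raise DataError(f"need at least 4 time points, got {len(x)}")
    if (np.diff(x) <= 0).any():
        raise DataError("times must be strictly increasing")

    span = x[-1] - x[0]
    scale = np.ptp(y)
    p0 = (float(y[0]), float(scale) if scale > 0 else 1.0, 1.0 / span)
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # a singular covariance is reported through the flagged field
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(
                _model, x, y, p0=p0, xtol=1e-10, ftol=1e-10, gtol=1e-10, maxfev=20000
            )
    except RuntimeError as exc:
        raise FitError(f"exponential-rise fit did not converge: {exc}") from exc
    y0, a, b = map(float, popt)
    sse = float(np.sum((y - _model(x, *popt)) ** 2))

    flagged = False
    message = ""
    denom = scale if scale > 0 else 1.0
    if not np.all(np.isfinite(pcov)):
        flagged, message = True, "singular covariance (parameters not identifiable)"
    elif b <= 0:
        flagged, message = True, f"non-positive decay constant b={b:.4g}"
    elif abs(a) <= 1e-9 * denom:
        flagged, message = True, "zero amplitude (decay constant not identifiable)"
    return KineticsFit(
        y0=y0,
        a=a,
        b=b,
        half_life=None if flagged else half_life(b),
        residual_sse=sse,
        flagged=flagged,
        message=message,
    )


def read_kinetics_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """CSV with columns time_min, fluorescence (header optional)."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if "time_min" in cols:
        t = df[df.columns[cols.index("time_min")]].to_numpy(float)
        f = df[df.columns[cols.index("fluorescence")]].to_numpy(float)
    else:  # headerless: first two columns
        df = pd.read_csv(path, header=None, comment="#")
        t = df.iloc[:, 0].to_numpy(float)
        f = df.iloc[:, 1].to_numpy(float)
    return t, f


def write_fit_json(path, fit: KineticsFit) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(fit), fh, indent=2)
        fh.write("\n")
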