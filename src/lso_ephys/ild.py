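"""ILD tuning curves and sigmoid characterization.

An ILD function is the mean firing rate in a fixed response window (onset
[0, 10) ms or sustained [10, 25) ms re stimulus onset) as a function of the
interaural level difference (contra SPL - ipsi SPL; the ipsilateral level is
held fixed while the contralateral level varies).  In the LSO's IE geometry
rate falls as the ILD grows toward contra-louder, so the fit is a decreasing
four-parameter logistic

    rate(ild) = floor + (ceiling - floor) / (1 + exp((ild - midpoint)/width))

whose midpoint and 20-80% slope span summarize where on the ILD axis the
cell operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

from .core_io import Sweep, ToneStimulus, ValidationError
from .spike_stats import extract_trains, window_rate

__all__ = ["ILDCurve", "SigmoidFit", "WINDOWS", "build_ild_curve", "fit_ild_sigmoid"]

WINDOWS: Dict[str, Tuple[float, float]] = {
    "onset": (0.0, 10.0),
    "sustained": (10.0, 25.0),
}


@dataclass
class SigmoidFit:
    """Fitted decreasing logistic ILD function."""

    floor: float  # spikes/s
    ceiling: float  # spikes/s
    midpoint: Optional[float]  # dB ILD
    width: Optional[float]  # dB
    range_20_80: Optional[Tuple[float, float]]  # dB
    converged: bool
    rmse: float  # spikes/s

    @property
    def slope_at_midpoint(self) -> Optional[float]:
        """Spikes/s per dB at the midpoint (negative: rate falls with ILD)."""
        if self.width is None:
            return None
        return -(self.ceiling - self.floor) / (4.0 * self.width)


@dataclass
class ILDCurve:
    """Spike rate vs ILD for one response window."""

    ild: np.ndarray  # dB, strictly increasing
    rate: np.ndarray  # spikes/s
    window: Tuple[float, float]  # ms
    window_name: str = ""
    n_reps: int = 0
    fit: Optional[SigmoidFit] = None

    @property
    def normalized_rate(self) -> np.ndarray:
        m = self.rate.max()
        return self.rate / m if m > 0 else np.zeros_like(self.rate)


def _resolve_window(window: Union[str, Tuple[float, float]]) -> Tuple[str, Tuple[float, float]]:
    if isinstance(window, str):
        if window not in WINDOWS:
            raise ValidationError(f"unknown window {window!r}")
        return window, WINDOWS[window]
    return "", (float(window[0]), float(window[1]))


def build_ild_curve(
    protocols: Union[Mapping[str, Sequence[Sweep]], Sequence[Sequence[Sweep]]],
    window: Union[str, Tuple[float, float]] = "onset",
    **detect_kwargs,
) -> ILDCurve:
    """Windowed rate per ILD condition from binaural sweep sets.

    Each element of ``protocols`` is one condition (all repetitions of one
    contralateral level).  The ipsilateral level must be fixed across the
    set; ILD = contra - ipsi.
    """
    if isinstance(protocols, Mapping):
        condition_sets = list(protocols.values())
    else:
        condition_sets = list(protocols)
    if len(condition_sets) < 3:
        raise ValidationError("need at least 3 ILD conditions")
    name, win = _resolve_window(window)
    ilds: List[float] = []
    rates: List[float] = []
    ipsi_levels = set()
    n_reps = 0
    for sweeps in condition_sets:
        stim = sweeps[0].stimulus
        if not isinstance(stim, ToneStimulus) or stim.ild is None:
            raise ValidationError("ILD curves need binaural tone stimuli")
        ipsi_levels.add(stim.level_ipsi)
        ilds.append(stim.ild)
        rates.append(window_rate(extract_trains(sweeps, **detect_kwargs), win))
        n_reps = max(n_reps, len(sweeps))
    if len(ipsi_levels) > 1:
        raise ValidationError("ipsi level must be fixed across an ILD series")
    order = np.argsort(ilds)
    return ILDCurve(
        ild=np.asarray(ilds)[order],
        rate=np.asarray(rates)[order],
        window=win,
        window_name=name,
        n_reps=n_reps,
    )


def _logistic(x: np.ndarray, floor: float, ceiling: float, mid: float, width: float):
    return floor + (ceiling - floor) / (1.0 + np.exp((x - mid) / width))


def fit_ild_sigmoid(curve: ILDCurve, span: Tuple[float, float] = (0.2, 0.8)) -> SigmoidFit:
    """Least-squares decreasing 4-parameter logistic fit of an ILD curve.

    Initialization is deterministic (data quantiles); the fit is done in
    ILD coordinates centred on the median ILD, which makes the fitted
    midpoint exactly equivariant under a common shift of all levels.  The
    ``span`` pair sets the reported slope range (20-80% by default).
    """
    x = np.asarray(curve.ild, dtype=float)
    y = np.asarray(curve.rate, dtype=float)
    if np.unique(x).size < 4:
        raise ValidationError("need at least 4 distinct ILDs")
    if np.allclose(y, y[0]):
        raise ValidationError("flat curve: rates do not vary with ILD")
    x0 = float(np.median(x))
    xc = x - x0
    lo, hi = float(y.min()), float(y.max())
    mid_level = 0.5 * (lo + hi)
    # first downward crossing of the mid level, linearly interpolated
    mid_guess = float(xc[np.argmin(np.abs(y - mid_level))])
    for i in range(len(y) - 1):
        if (y[i] - mid_level) * (y[i + 1] - mid_level) <= 0 and y[i] != y[i + 1]:
            mid_guess = float(
                xc[i] + (y[i] - mid_level) / (y[i] - y[i + 1]) * (xc[i + 1] - xc[i])
            )
            break
    width_guess = max((xc.max() - xc.min()) / 8.0, 0.5)
    p0 = [lo, hi, mid_guess, width_guess]
    bounds = (
        [-np.inf, -np.inf, xc.min() - 50.0, 0.05],
        [np.inf, np.inf, xc.max() + 50.0, 10.0 * (xc.max() - xc.min())],
    )
    try:
        popt, _ = curve_fit(_logistic, xc, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        fit = SigmoidFit(
            floor=lo, ceiling=hi, midpoint=None, width=None,
            range_20_80=None, converged=False, rmse=float("nan"),
        )
        curve.fit = fit
        return fit
    floor, ceiling, midc, width = popt
    if ceiling < floor:  # enforce the decreasing orientation bookkeeping
        floor, ceiling = ceiling, floor
    resid = y - _logistic(xc, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    mid = float(midc + x0)
    ln_hi = math.log(span[1] / (1.0 - span[1]))
    ln_lo = math.log(span[0] / (1.0 - span[0]))
    # rate crosses floor + span*height going downward
    r_lo = mid - ln_hi * width  # high-rate (80%) side, more ipsi
    r_hi = mid - ln_lo * width  # low-rate (20%) side, more contra
    fit = SigmoidFit(
        floor=float(floor),
        ceiling=float(ceiling),
        midpoint=mid,
        width=float(width),
        range_20_80=(min(r_lo, r_hi), max(r_lo, r_hi)),
        converged=True,
        rmse=rmse,
    )
    curve.fit = fit
    return fit
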