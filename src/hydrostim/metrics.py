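"""Characterization formulas for the hydrogel and its electrode behaviour.

Implements the standard bench metrics: Young's modulus from oscillatory
shear moduli, four-point-probe conductivity, charge storage capacity (CSC)
from cyclic voltammetry, charge injection capacity (CIC) from biphasic
current pulses, gel-point detection from a rheological time sweep, current
density J = I/A, and the calcium-imaging activation rule
(max dF/F0 >= 50%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.signal import medfilt

from .trace import TimeSeriesTrace


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Electrode area (cm^2) and, for four-point bars, L x W x H in metres."""

    area_cm2: float | None = None
    length: float | None = None
    width: float | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        for name in ("area_cm2", "length", "width", "height"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")


def young_modulus(g_storage: float, g_loss: float, poisson: float = 0.5) -> float:
    """E = 2*sqrt(G'^2 + G''^2)*(1 + nu), Pa.

    An incompressible material (nu = 0.5, the default for hydrogels) gives
    E = 3|G*|.
    """
    if g_storage < 0 or g_loss < 0:
        raise ValueError("moduli must be >= 0")
    if not 0.0 <= poisson <= 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    return 2.0 * math.hypot(g_storage, g_loss) * (1.0 + poisson)


def four_point_conductivity(u: float, i: float, geom: ElectrodeGeometry) -> float:
    """sigma = L*I / (W*H*U), S m-1, for a rectangular bar sample."""
    if geom.length is None or geom.width is None or geom.height is None:
        raise ValueError("four-point measurement needs bar dimensions L, W, H")
    if u <= 0:
        raise ValueError("voltage must be > 0")
    return geom.length * i / (geom.width * geom.height * u)


def csc_from_cv(
    cv: TimeSeriesTrace,
    scan_rate: float,
    area_cm2: float,
    rectify: str = "abs",
) -> float:
    """Charge storage capacity from one closed CV cycle, mC cm-2.

    Trapezoidal integral of the current over the traversed potential,
    divided by 2*v*A.  ``rectify="abs"`` (default, standard practice)
    integrates |i| so anodic and cathodic branches add; ``"as-printed"``
    integrates the signed current over the same traversed window, so the
    branches of a symmetric loop cancel to near zero.
    """
    if cv.abscissa_kind != "potential":
        raise ValueError("CSC needs a current-vs-potential trace")
    if scan_rate <= 0 or area_cm2 <= 0:
        raise ValueError("scan rate and area must be > 0")
    if rectify not in ("abs", "as-printed"):
        raise ValueError(f"unknown rectify mode {rectify!r}")
    e = cv.abscissa
    i = cv.ordinate
    if len(e) < 4:
        raise ValueError("CV trace too short")
    window = e.max() - e.min()
    if window <= 0:
        raise ValueError("CV trace has zero potential window")
    if abs(e[0] - e[-1]) > 0.02 * window:
        raise ValueError(
            "CV trace is not a closed cycle (start and end potentials differ)"
        )
    de = np.diff(e)
    i_mid = 0.5 * (i[1:] + i[:-1])
    if rectify == "abs":
        integral = float(np.sum(np.abs(i_mid) * np.abs(de)))
    else:
        integral = float(np.sum(i_mid * np.abs(de)))
    csc_c_per_cm2 = integral / (2.0 * scan_rate * area_cm2)
    return csc_c_per_cm2 * 1e3  # C -> mC


def cic_from_pulse(pulse: TimeSeriesTrace, area_cm2: float) -> float:
    """Charge injection capacity from one biphasic pulse, uC cm-2.

    CIC = (|Q_anodic| + |Q_cathodic|)/A, each phase charge obtained by
    trapezoidal integration.  Phase segmentation uses the sign of a
    median-filtered (window 3) copy of the current, which is robust to
    isolated noisy samples; a trace lacking either polarity is rejected.
    """
    if pulse.abscissa_kind != "time":
        raise ValueError("CIC needs a current-vs-time trace")
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    t = pulse.abscissa
    i = pulse.ordinate
    if len(t) < 4:
        raise ValueError("pulse trace too short")
    smoothed = medfilt(i, kernel_size=3)
    has_pos = np.any(smoothed > 0)
    has_neg = np.any(smoothed < 0)
    if not (has_pos and has_neg):
        raise ValueError(
            "monophasic trace: a biphasic pulse needs both an anodic and a "
            "cathodic phase"
        )
    pos = np.where(smoothed > 0, i, 0.0)
    neg = np.where(smoothed < 0, i, 0.0)
    q_a = abs(float(np.trapezoid(pos, t)))
    q_c = abs(float(np.trapezoid(neg, t)))
    return (q_a + q_c) / area_cm2 * 1e6  # C -> uC


def gel_point(
    g_storage: TimeSeriesTrace, g_loss: TimeSeriesTrace
) -> float | None:
    """Gelation time: first upward crossover of G' over G'', seconds.

    Linearly interpolated between samples.  Returns ``None`` when G' starts
    above G'' (already gelled) or never reaches it (no gelation).
    """
    if g_storage.abscissa_kind != "time" or g_loss.abscissa_kind != "time":
        raise ValueError("gel point needs time sweeps")
    t = g_storage.abscissa
    if len(t) != len(g_loss.abscissa) or not np.allclose(t, g_loss.abscissa):
        raise ValueError("G' and G'' must share one time grid")
    d = g_storage.ordinate - g_loss.ordinate
    if d[0] >= 0:
        return None  # already gelled at the start of the sweep
    below = d < 0
    crossings = np.where(below[:-1] & (d[1:] >= 0))[0]
    if crossings.size == 0:
        return None
    k = int(crossings[0])
    # linear interpolation of the sign change between samples k and k+1
    frac = -d[k] / (d[k + 1] - d[k])
    return float(t[k] + frac * (t[k + 1] - t[k]))


def current_density(i: float, area_cm2: float) -> float:
    """J = I/A converted to mA cm-2."""
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    return i / area_cm2 * 1e3


def calcium_activation_fraction(
    traces: Iterable[TimeSeriesTrace], threshold: float = 0.5
) -> float:
    """Fraction of cells whose peak dF/F0 reaches ``threshold`` (default 50%)."""
    traces = list(traces)
    if not traces:
        raise ValueError("no calcium traces given")
    activated = sum(1 for tr in traces if float(np.max(tr.ordinate)) >= threshold)
    return activated / len(traces)
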