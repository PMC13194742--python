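"""Frequency-dependent electrical properties of tissues and the hydrogel.

Every medium is described by its conductivity sigma (S m-1) and relative
permittivity eps_r, either as frequency-independent constants or tabulated
on a frequency grid.  The quantity the rest of the package consumes is the
complex admittivity

    Y(f) = sigma + j * omega * eps0 * eps_r,      omega = 2 pi f,

which combines conduction and displacement currents, and the dielectric
relaxation time tau = eps0 * eps_r / sigma whose mismatch between two media
drives Maxwell-Wagner interfacial polarization.

The bundled :func:`default_table` carries the hydrogel and brain values the
package's reference scenarios use (brain sigma = 0.27 S m-1, eps_r = 670 at
5 MHz; hydrogel sigma = 30 S m-1, eps_r = 1.35), plus literature-style
default dispersions for scalp and skull, all overridable from a user CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Vacuum permittivity, F m-1 (value used consistently throughout the model).
EPS0 = 8.85e-12


@dataclass(frozen=True)
class TissueMedium:
    """Electrical properties of one material.

    ``conductivity`` / ``relative_permittivity`` are scalars for a
    frequency-independent medium, or arrays on the ``frequencies`` grid for
    a dispersive one.  Tabulated media are interpolated linearly in
    log-frequency and refuse extrapolation.
    """

    name: str
    conductivity: float | np.ndarray
    relative_permittivity: float | np.ndarray
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            s = np.asarray(self.conductivity, dtype=float)
            e = np.asarray(self.relative_permittivity, dtype=float)
            if f.ndim != 1 or f.size < 2:
                raise ValueError(f"{self.name}: frequency grid needs >= 2 points")
            if not np.all(np.diff(f) > 0) or not np.all(f > 0):
                raise ValueError(
                    f"{self.name}: frequency grid must be strictly increasing and > 0"
                )
            if s.shape != f.shape or e.shape != f.shape:
                raise ValueError(f"{self.name}: sigma/eps arrays must match the grid")
            object.__setattr__(self, "frequencies", f)
            object.__setattr__(self, "conductivity", s)
            object.__setattr__(self, "relative_permittivity", e)
        if np.any(np.asarray(self.conductivity) < 0):
            raise ValueError(f"{self.name}: conductivity must be >= 0")
        if np.any(np.asarray(self.relative_permittivity) <= 0):
            raise ValueError(f"{self.name}: relative permittivity must be > 0")

    @property
    def is_tabulated(self) -> bool:
        return self.frequencies is not None

    def properties_at(self, frequency: float) -> tuple[float, float]:
        """(sigma, eps_r) at ``frequency``, interpolating tabulated media.

        Interpolation is linear in log10(frequency), exact at grid points;
        queries outside the tabulated span raise ``ValueError``.
        """
        if not self.is_tabulated:
            return float(self.conductivity), float(self.relative_permittivity)
        f = self.frequencies
        if frequency < f[0] or frequency > f[-1]:
            raise ValueError(
                f"{self.name}: frequency {frequency:g} Hz outside tabulated span "
                f"[{f[0]:g}, {f[-1]:g}] Hz (extrapolation refused)"
            )
        logf = np.log10(f)
        lq = math.log10(frequency)
        sigma = float(np.interp(lq, logf, self.conductivity))
        eps = float(np.interp(lq, logf, self.relative_permittivity))
        return sigma, eps


def complex_admittivity(medium: TissueMedium, frequency: float) -> complex:
    """Complex admittivity sigma + j*omega*eps0*eps_r in S m-1.

    ``frequency = 0`` returns the DC limit sigma + 0j.  For tabulated media
    the query must fall inside the tabulated span (DC excepted: constants
    only).
    """
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    if frequency == 0:
        if medium.is_tabulated:
            raise ValueError(
                f"{medium.name}: DC limit undefined for a tabulated medium "
                f"(span starts at {medium.frequencies[0]:g} Hz)"
            )
        return complex(float(medium.conductivity), 0.0)
    sigma, eps = medium.properties_at(frequency)
    omega = 2.0 * math.pi * frequency
    return complex(sigma, omega * EPS0 * eps)


def relaxation_time(medium: TissueMedium, frequency: float) -> float:
    """Dielectric relaxation time tau = eps0*eps_r / sigma in seconds.

    Uses the absolute permittivity eps0*eps_r so that equality of tau
    between two media is exactly the condition for zero Maxwell-Wagner
    interfacial charge.  sigma = 0 returns ``math.inf``.
    """
    if frequency <= 0 and medium.is_tabulated:
        raise ValueError(
            f"{medium.name}: DC relaxation time undefined for a tabulated medium"
        )
    sigma, eps = medium.properties_at(frequency) if frequency > 0 else (
        float(medium.conductivity),
        float(medium.relative_permittivity),
    )
    if sigma == 0.0:
        return math.inf
    return EPS0 * eps / sigma


@dataclass
class DielectricTable:
    """A named collection of media with (tissue, frequency) lookup."""

    media: Mapping[str, TissueMedium] = field(default_factory=dict)

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.media

    def __getitem__(self, tissue: str) -> TissueMedium:
        try:
            return self.media[tissue]
        except KeyError:
            raise KeyError(
                f"unknown tissue {tissue!r}; available: {sorted(self.media)}"
            ) from None

    def lookup(self, tissue: str, frequency: float) -> tuple[float, float]:
        """(sigma, eps_r) for ``tissue`` at ``frequency``."""
        return self[tissue].properties_at(frequency)

    @classmethod
    def from_csv(cls, path) -> "DielectricTable":
        """Read a table from CSV with columns
        tissue,frequency_hz,conductivity_s_per_m,relative_permittivity."""
        df = pd.read_csv(path)
        required = {
            "tissue",
            "frequency_hz",
            "conductivity_s_per_m",
            "relative_permittivity",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dielectric CSV missing columns: {sorted(missing)}")
        media = {}
        for tissue, grp in df.groupby("tissue"):
            grp = grp.sort_values("frequency_hz")
            if len(grp) == 1:
                row = grp.iloc[0]
                media[tissue] = TissueMedium(
                    name=tissue,
                    conductivity=float(row["conductivity_s_per_m"]),
                    relative_permittivity=float(row["relative_permittivity"]),
                )
            else:
                media[tissue] = TissueMedium(
                    name=tissue,
                    conductivity=grp["conductivity_s_per_m"].to_numpy(),
                    relative_permittivity=grp["relative_permittivity"].to_numpy(),
                    frequencies=grp["frequency_hz"].to_numpy(),
                )
        return cls(media=media)


def interpolate_spectrum(
    table: DielectricTable, tissue: str, frequency: float
) -> tuple[float, float]:
    """(sigma, eps_r) for a tissue at a frequency; see ``TissueMedium.properties_at``."""
    return table.lookup(tissue, frequency)


# Reference media ------------------------------------------------------------

#: Conductive hydrogel: measured bulk values (four-point probe / capacitance).
HYDROGEL = TissueMedium("hydrogel", conductivity=30.0, relative_permittivity=1.35)

#: Brain tissue at 5 MHz (dielectric database values used by the model).
BRAIN_5MHZ = TissueMedium("brain", conductivity=0.27, relative_permittivity=670.0)

# Grid shared by the default dispersive entries, 100 kHz - 10 MHz.
_DEFAULT_GRID = np.array([1e5, 1e6, 5e6, 1e7])


def default_table() -> DielectricTable:
    """Bundled dielectric table.

    The brain entry passes exactly through (0.27 S m-1, 670) at 5 MHz; the
    remaining grid points, and the scalp and skull dispersions entirely, are
    package defaults in the style of standard tissue-property databases --
    override them with :meth:`DielectricTable.from_csv` for quantitative
    work at other frequencies.
    """
    media = {
        "hydrogel": HYDROGEL,
        "insulation": TissueMedium(
            "insulation", conductivity=0.0, relative_permittivity=3.0
        ),
        "brain": TissueMedium(
            "brain",
            conductivity=np.array([0.13, 0.18, 0.27, 0.30]),
            relative_permittivity=np.array([3200.0, 1100.0, 670.0, 320.0]),
            frequencies=_DEFAULT_GRID,
        ),
        # default entries (not database-attributed): plausible soft-tissue
        # and cortical-bone dispersions over the operating band
        "scalp": TissueMedium(
            "scalp",
            conductivity=np.array([0.15, 0.25, 0.40, 0.45]),
            relative_permittivity=np.array([5000.0, 1800.0, 900.0, 600.0]),
            frequencies=_DEFAULT_GRID,
        ),
        "skull": TissueMedium(
            "skull",
            conductivity=np.array([0.021, 0.024, 0.035, 0.043]),
            relative_permittivity=np.array([228.0, 145.0, 70.0, 37.0]),
            frequencies=_DEFAULT_GRID,
        ),
    }
    return DielectricTable(media=media)
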