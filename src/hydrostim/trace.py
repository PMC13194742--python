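"""Sampled measurement traces shared by the metrics and generator modules.

A :class:`TimeSeriesTrace` is a thin, validated wrapper around two numpy
arrays: an abscissa (time in seconds, or electrode potential in volts for
voltammograms) and an ordinate (current, modulus, or a dimensionless
normalized signal).  The abscissa kind is declared so downstream metrics can
refuse traces sampled on the wrong axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ABSCISSA_KINDS = ("time", "potential")


@dataclass
class TimeSeriesTrace:
    """A sampled 1-D measurement.

    Parameters
    ----------
    abscissa : array-like
        Sample locations.  Strictly monotone for time axes; potential axes
        may be piecewise monotone (a cyclic voltammetry sweep reverses at
        the vertices).
    ordinate : array-like
        Sample values, same length as ``abscissa``.
    abscissa_kind : {"time", "potential"}
    ordinate_label : str
        Free-form unit label, e.g. ``"current_a"`` or ``"g_storage_pa"``.
    """

    abscissa: np.ndarray
    ordinate: np.ndarray
    abscissa_kind: str = "time"
    ordinate_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        if self.abscissa.ndim != 1 or self.ordinate.ndim != 1:
            raise ValueError("trace arrays must be one-dimensional")
        if self.abscissa.size != self.ordinate.size:
            raise ValueError(
                f"abscissa ({self.abscissa.size}) and ordinate "
                f"({self.ordinate.size}) lengths differ"
            )
        if self.abscissa_kind not in ABSCISSA_KINDS:
            raise ValueError(
                f"abscissa_kind must be one of {ABSCISSA_KINDS}, "
                f"got {self.abscissa_kind!r}"
            )
        if self.abscissa_kind == "time":
            if self.abscissa.size > 1 and not np.all(np.diff(self.abscissa) > 0):
                raise ValueError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return self.abscissa.size

    def to_frame(self) -> pd.DataFrame:
        abscissa_col = "time_s" if self.abscissa_kind == "time" else "potential_v"
        ordinate_col = self.ordinate_label or "value"
        return pd.DataFrame({abscissa_col: self.abscissa, ordinate_col: self.ordinate})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesTrace":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("trace CSV needs at least two columns")
        abscissa_col = df.columns[0]
        kind = "potential" if "potential" in abscissa_col.lower() else "time"
        return cls(
            abscissa=df.iloc[:, 0].to_numpy(),
            ordinate=df.iloc[:, 1].to_numpy(),
            abscissa_kind=kind,
            ordinate_label=df.columns[1],
        )
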