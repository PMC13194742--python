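"""Burst stimulation waveform: a high-frequency sine carrier gated into
rectangular pulses.

The drive used throughout the reference scenarios is a 5 MHz carrier gated
into 60 us pulses repeating at 130 Hz with +/-2.5 V amplitude.  Its duty
cycle is ``pulse_width * repetition_rate`` and the root-mean-square voltage
of the gated waveform is

    V_rms = (A / sqrt(2)) * sqrt(duty),

which is what the capacitive-coupling circuit model consumes.  A continuous
(ungated) carrier has duty 1 and V_rms = A/sqrt(2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .trace import TimeSeriesTrace


@dataclass(frozen=True)
class DriveSignal:
    """Description of the capacitive drive waveform.

    ``mode`` is ``"burst"`` (carrier gated by pulse_width/repetition_rate)
    or ``"continuous"`` (duty exactly 1).
    """

    carrier_frequency: float  # Hz
    amplitude: float          # V, peak (symmetric +/-)
    pulse_width: float = 0.0       # s (burst mode)
    repetition_rate: float = 0.0   # Hz (burst mode)
    mode: str = "burst"

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise ValueError("carrier frequency must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.mode not in ("burst", "continuous"):
            raise ValueError(f"unknown drive mode {self.mode!r}")
        if self.mode == "burst":
            if self.pulse_width <= 0 or self.repetition_rate <= 0:
                raise ValueError("burst mode needs pulse_width and repetition_rate > 0")
            if self.duty > 1.0 + 1e-12:
                raise ValueError(
                    f"invalid burst: duty {self.duty:g} > 1 "
                    f"(pulse_width * repetition_rate must be <= 1)"
                )

    @property
    def duty(self) -> float:
        """Fraction of time the carrier is on, in (0, 1]."""
        if self.mode == "continuous":
            return 1.0
        return self.pulse_width * self.repetition_rate

    @property
    def v_rms(self) -> float:
        """RMS voltage of the gated waveform (duty-cycled)."""
        return self.amplitude / math.sqrt(2.0) * math.sqrt(self.duty)

    @property
    def v_rms_continuous(self) -> float:
        """RMS voltage as if the carrier ran continuously (duty ignored)."""
        return self.amplitude / math.sqrt(2.0)

    def with_carrier(self, frequency: float) -> "DriveSignal":
        """Copy of this drive at a different carrier frequency (for sweeps)."""
        return DriveSignal(
            carrier_frequency=frequency,
            amplitude=self.amplitude,
            pulse_width=self.pulse_width,
            repetition_rate=self.repetition_rate,
            mode=self.mode,
        )


def make_drive(
    carrier: float, amplitude: float, pulse_width: float, rate: float
) -> DriveSignal:
    """Validated burst drive; warns when a pulse holds fewer than 10 carrier cycles."""
    if pulse_width > 0 and carrier * pulse_width < 10:
        warnings.warn(
            f"pulse holds only {carrier * pulse_width:.1f} carrier cycles (<10); "
            "the gated-RMS description is inaccurate for so few cycles",
            stacklevel=2,
        )
    return DriveSignal(
        carrier_frequency=carrier,
        amplitude=amplitude,
        pulse_width=pulse_width,
        repetition_rate=rate,
        mode="burst",
    )


def continuous_drive(carrier: float, amplitude: float) -> DriveSignal:
    return DriveSignal(carrier_frequency=carrier, amplitude=amplitude, mode="continuous")


def sample_waveform(
    drive: DriveSignal, duration: float, sample_rate: float
) -> TimeSeriesTrace:
    """Sample the gated sine waveform.

    The carrier phase restarts at 0 at each pulse onset and traces are fully
    deterministic.  ``sample_rate`` must be at least 10x the carrier to
    avoid aliasing.  The empirical RMS of a trace spanning whole repetition
    periods converges to ``drive.v_rms``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if sample_rate < 10.0 * drive.carrier_frequency:
        raise ValueError(
            f"sample rate {sample_rate:g} Hz would alias the "
            f"{drive.carrier_frequency:g} Hz carrier (need >= 10x)"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if drive.mode == "continuous":
        gate = np.ones_like(t)
        t_in_pulse = t
    else:
        period = 1.0 / drive.repetition_rate
        t_in_pulse = np.mod(t, period)
        gate = (t_in_pulse < drive.pulse_width).astype(float)
    v = drive.amplitude * gate * np.sin(2.0 * math.pi * drive.carrier_frequency * t_in_pulse)
    return TimeSeriesTrace(
        abscissa=t, ordinate=v, abscissa_kind="time", ordinate_label="voltage_v"
    )
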