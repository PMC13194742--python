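"""Synthetic measurement traces with known ground truth.

Every generator draws from one ``numpy.random.default_rng(seed)`` stream
created inside the call (no global state), so an identical parameter set
including the seed reproduces a bit-identical trace.  With ``noise_sd = 0``
outputs follow the stated closed forms exactly, which is what the metric
round-trip tests rely on:

* :func:`gen_cv` - series-RC cyclic voltammogram; for R = 0 the abs-mode
  CSC is exactly C*dE/A.
* :func:`gen_biphasic_pulse` - square biphasic current pulse with phase
  charge amplitude*phase_width per phase.
* :func:`gen_rheology` - logistic storage-modulus rise against a constant
  loss modulus, with an analytic crossover time.
* :func:`gen_potential_pairs` - wire-pair potential-difference readings
  dU = E*r + noise.
* :func:`gen_calcium` - per-cell dF/F0 traces with a known responder
  fraction.

Defaults mirror the reference measurement conditions: CV swept -0.5..0.5 V
at 50 mV s-1, biphasic pulses of 60 us per phase, gelation within about a
minute, responder amplitude ~2.0 (a ~200% dF/F0 peak) with a 45% responder
fraction.
"""

from __future__ import annotations

import math

import numpy as np

from .trace import TimeSeriesTrace


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_cv(
    capacitance: float,
    series_resistance: float = 0.0,
    window: tuple[float, float] = (-0.5, 0.5),
    scan_rate: float = 0.05,
    samples_per_cycle: int = 2000,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> TimeSeriesTrace:
    """One steady-state CV cycle of a series-RC electrode model.

    The drive is a triangular potential sweep between the window vertices at
    ``scan_rate`` (V s-1).  For an ideal capacitor (R = 0) the current is
    +/- C*scan_rate and the abs-mode CSC over the cycle is C*dE/A exactly.
    A nonzero series resistance adds the exact exponential transient after
    each vertex (computed segment-by-segment in closed form); two warm-up
    cycles are discarded so the returned loop is periodic.
    """
    if capacitance <= 0:
        raise ValueError("capacitance must be > 0")
    if series_resistance < 0:
        raise ValueError("series resistance must be >= 0")
    if samples_per_cycle < 8:
        raise ValueError("need at least 8 samples per cycle")
    e_lo, e_hi = min(window), max(window)
    if e_hi <= e_lo:
        raise ValueError("potential window must have nonzero span")
    span = e_hi - e_lo
    half = samples_per_cycle // 2
    # potential path: lo -> hi -> lo, closed
    e_up = e_lo + span * np.arange(half) / half
    e_dn = e_hi - span * np.arange(half) / half
    e = np.concatenate([e_up, e_dn, [e_lo]])
    dt = span / scan_rate / half

    if series_resistance == 0.0:
        i = capacitance * scan_rate * np.concatenate(
            [np.ones(half), -np.ones(half), [-1.0]]
        )
    else:
        tau = series_resistance * capacitance
        # exact per-sample recursion for piecewise-linear drive:
        # V_c' = (E - V_c)/tau; on a ramp of slope r the steady current is
        # C*r with an exponential approach after each vertex.
        n_total = (2 * half) * 3 + 1  # two warm-up cycles + returned cycle
        path = np.empty(n_total)
        one_cycle = np.concatenate([e_up, e_dn])
        path[:-1] = np.tile(one_cycle, 3)
        path[-1] = e_lo
        vc = e_lo  # start relaxed at the lower vertex
        decay = math.exp(-dt / tau)
        i_full = np.empty(n_total)
        i_full[0] = (path[0] - vc) / series_resistance
        for k in range(n_total - 1):
            r = (path[k + 1] - path[k]) / dt
            # exact ramp response over one step
            vc = path[k + 1] - r * tau + (vc - path[k] + r * tau) * decay
            i_full[k + 1] = (path[k + 1] - vc) / series_resistance
        i = i_full[-(2 * half + 1):]
        e = np.concatenate([one_cycle, [e_lo]])
    if noise_sd > 0:
        i = i + _rng(seed).normal(0.0, noise_sd, size=i.size)
    return TimeSeriesTrace(
        abscissa=e,
        ordinate=i,
        abscissa_kind="potential",
        ordinate_label="current_a",
        meta={"capacitance_f": capacitance, "scan_rate_v_per_s": scan_rate},
    )


def gen_biphasic_pulse(
    amplitude: float = 100e-6,
    phase_width: float = 60e-6,
    interphase_gap: float = 0.0,
    sample_rate: float = 10e6,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> TimeSeriesTrace:
    """One square biphasic current pulse (anodic then cathodic).

    Ground truth: each phase carries |Q| = amplitude * phase_width.  A
    positive ``interphase_gap`` inserts a zero-current interval that leaves
    the phase charges unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if phase_width <= 0 or sample_rate <= 0:
        raise ValueError("phase width and sample rate must be > 0")
    if interphase_gap < 0:
        raise ValueError("interphase gap must be >= 0")
    margin = phase_width  # zero-padding before and after the pulse
    total = 2 * margin + 2 * phase_width + interphase_gap
    n = max(int(round(total * sample_rate)), 8)
    t = np.arange(n) / sample_rate
    i = np.zeros(n)
    a0, a1 = margin, margin + phase_width
    c0, c1 = a1 + interphase_gap, a1 + interphase_gap + phase_width
    i[(t >= a0) & (t < a1)] = amplitude
    i[(t >= c0) & (t < c1)] = -amplitude
    if noise_sd > 0:
        i = i + _rng(seed).normal(0.0, noise_sd, size=n)
    return TimeSeriesTrace(
        abscissa=t,
        ordinate=i,
        abscissa_kind="time",
        ordinate_label="current_a",
        meta={"phase_charge_c": amplitude * phase_width},
    )


def rheology_crossover_time(
    g_plateau: float, g_loss_const: float, gel_rate: float, t_mid: float
) -> float | None:
    """Analytic G'/G'' crossover of the logistic gelation model, or None."""
    if not 0 < g_loss_const < g_plateau:
        return None
    return t_mid - math.log(g_plateau / g_loss_const - 1.0) / gel_rate


def gen_rheology(
    g_plateau: float = 160.0,
    g_loss_const: float = 20.0,
    gel_rate: float = 0.1,
    t_mid: float = 60.0,
    duration: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[TimeSeriesTrace, TimeSeriesTrace]:
    """Rheological time sweep: logistic G'(t) against constant G''.

    G'(t) = g_plateau / (1 + exp(-gel_rate*(t - t_mid))); the analytic
    crossover with G'' is given by :func:`rheology_crossover_time`.
    Defaults emulate gelation completing within the first minutes of the
    sweep with a plateau storage modulus in the few-hundred-Pa range of
    brain-soft hydrogels.
    """
    if g_plateau <= 0 or g_loss_const <= 0:
        raise ValueError("moduli must be > 0")
    if gel_rate <= 0 or duration <= 0 or dt <= 0:
        raise ValueError("rate, duration and dt must be > 0")
    t = np.arange(0.0, duration + dt / 2, dt)
    g_s = g_plateau / (1.0 + np.exp(-gel_rate * (t - t_mid)))
    g_l = np.full_like(t, g_loss_const)
    if noise_sd > 0:
        rng = _rng(seed)
        g_s = g_s + rng.normal(0.0, noise_sd, size=t.size)
        g_l = g_l + rng.normal(0.0, noise_sd, size=t.size)
    return (
        TimeSeriesTrace(t, g_s, "time", "g_storage_pa"),
        TimeSeriesTrace(t, g_l, "time", "g_loss_pa"),
    )


def gen_potential_pairs(
    true_e: float = 329.0,
    radius: float = 0.85e-3,
    noise_sd: float = 0.0,
    n: int = 5,
    seed: int | None = 0,
) -> np.ndarray:
    """Wire-pair potential-difference readings, shape (n, 2) of (dU, radius).

    dU = true_e * radius + Gaussian noise, so the mean recovered field
    mean(dU)/radius is an unbiased estimate of ``true_e``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n <= 0:
        raise ValueError("need at least one reading")
    du = np.full(n, true_e * radius)
    if noise_sd > 0:
        du = du + _rng(seed).normal(0.0, noise_sd, size=n)
    return np.column_stack([du, np.full(n, radius)])


def gen_calcium(
    n_cells: int = 100,
    frac_responders: float = 0.45,
    peak_amp: float = 2.0,
    decay_tau: float = 10.0,
    noise_sd: float = 0.02,
    duration: float = 50.0,
    dt: float = 0.1,
    onset: float = 5.0,
    seed: int | None = 0,
) -> list[TimeSeriesTrace]:
    """Per-cell dF/F0 traces with a known responder fraction.

    ``round(frac_responders * n_cells)`` cells receive an exponential-decay
    calcium transient of peak ``peak_amp`` (default 2.0, i.e. a ~200% dF/F0
    peak) starting at ``onset``; the rest stay at baseline.  With noise well
    below the activation threshold, the activation rule recovers
    ``frac_responders`` exactly at matching ``n_cells``.
    """
    if n_cells <= 0:
        raise ValueError("need at least one cell")
    if not 0.0 <= frac_responders <= 1.0:
        raise ValueError("responder fraction must be in [0, 1]")
    rng = _rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    n_resp = int(round(frac_responders * n_cells))
    transient = np.where(t >= onset, peak_amp * np.exp(-(t - onset) / decay_tau), 0.0)
    traces = []
    for c in range(n_cells):
        base = transient if c < n_resp else np.zeros_like(t)
        y = base + (rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0)
        traces.append(TimeSeriesTrace(t, y, "time", "df_over_f0"))
    return traces
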