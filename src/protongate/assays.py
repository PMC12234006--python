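"""Proteoliposome assay signal processing.

Pyranine fluorescence traces report intraliposomal pH: traces are
normalized to their time-zero value, a paired no-gradient trace is
subtracted to expose the transport signal (including the burst that
develops in the dead time before the first read), and the proton-leak
time course is fit to burst + A·(1 − e^(−rate·t)).

SSME current traces are baseline-corrected against the final stretch of
the initial buffer equilibration and integrated over the perfusion
window to the transported charge (nA·s = nC). Replicate comparisons use
Welch two-sided t-tests with the conventional star labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .gates import GroupComparison, star_label
from scipy import stats

__all__ = [
    "AssayTrace",
    "ChargeResult",
    "normalize_to_t0",
    "baseline_subtract",
    "LeakKineticsFitter",
    "fit_leak",
    "integrate_charge",
    "group_stats",
]


@dataclass
class AssayTrace:
    """A time series of fluorescence (a.u.) or current (nA)."""

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError(
                f"time and signal lengths differ ({len(self.time)} vs {len(self.signal)})"
            )
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly ascending")


@dataclass
class ChargeResult:
    """Integrated transported charge over a perfusion window."""

    charge: float
    baseline_current: float
    window: tuple


def normalize_to_t0(trace: AssayTrace) -> AssayTrace:
    """Divide a trace by its first value; the divisor is recorded in metadata."""
    first = float(trace.signal[0])
    if first == 0.0:
        raise ValueError("cannot normalize: signal at time zero is 0")
    return AssayTrace(
        time=trace.time.copy(),
        signal=trace.signal / first,
        metadata={**trace.metadata, "normalization_divisor": first},
    )


def baseline_subtract(transport: AssayTrace, baseline: AssayTrace) -> AssayTrace:
    """Pointwise transport − baseline on the transport time grid.

    A baseline on a different grid is linearly interpolated onto the
    transport grid (the largest interpolation gap is recorded); disjoint
    time ranges are rejected. The value at the first point is preserved —
    it carries the burst information from the acquisition dead time.
    """
    t = transport.time
    if t[0] > baseline.time[-1] or t[-1] < baseline.time[0]:
        raise ValueError("transport and baseline traces cover disjoint time ranges")
    span_t = t[-1] - t[0]
    span_b = baseline.time[-1] - baseline.time[0]
    if span_b > 0 and abs(span_t - span_b) / max(span_t, span_b) > 0.10:
        raise ValueError(
            f"trace spans differ by more than 10% ({span_t:.3g} vs {span_b:.3g} s); "
            "refusing to interpolate"
        )
    if len(t) == len(baseline.time) and np.allclose(t, baseline.time):
        base = baseline.signal
        max_gap = 0.0
    else:
        base = np.interp(t, baseline.time, baseline.signal)
        max_gap = float(np.max(np.diff(baseline.time)))
    return AssayTrace(
        time=t.copy(),
        signal=transport.signal - base,
        metadata={**transport.metadata, "baseline_subtracted": True, "max_interp_gap": max_gap},
    )


class LeakKineticsFitter(BaseEstimator):
    """Least-squares fit of a leak time course to burst + A·(1 − e^(−rate·t)).

    The burst is an instantaneous offset (the pH change that occurs in
    the dead time before the first read); rate ≥ 0 is enforced. A flat
    trace yields A ≈ 0 with an unidentifiable rate, flagged rather than
    raised.

    Attributes (after ``fit``): ``rate_``, ``amplitude_``, ``burst_``,
    ``rate_ci_`` (±1 SD from covariance), ``identifiable_``.
    """

    def __init__(self, rate_guess: float | None = None):
        self.rate_guess = rate_guess

    def fit(self, trace: AssayTrace, y=None):
        t = trace.time - trace.time[0]
        s = trace.signal
        if len(t) < 10:
            raise ValueError(f"leak fit needs ≥ 10 points (got {len(t)})")
        span = float(s.max() - s.min())
        rate0 = self.rate_guess
        if rate0 is None:
            # time to reach half the span, as a crude rate scale
            half = s[0] + 0.5 * (s[-1] - s[0])
            idx = np.argmin(np.abs(s - half))
            t_half = max(float(t[idx]), float(t[1]))
            rate0 = np.log(2.0) / t_half
        p0 = [float(s[0]), float(s[-1] - s[0]), float(rate0)]

        def model(tt, burst, amp, rate):
            return burst + amp * (1.0 - np.exp(-rate * tt))

        try:
            popt, pcov = optimize.curve_fit(
                model, t, s, p0=p0, bounds=([-np.inf, -np.inf, 0.0], np.inf), maxfev=20000
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"leak fit failed to converge (initial guess {p0}): {exc}"
            ) from exc
        burst, amp, rate = (float(v) for v in popt)
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
        noise = float(np.std(s - model(t, *popt)))
        identifiable = abs(amp) > max(3.0 * noise, 1e-12) and span > 0
        self.burst_ = burst
        self.amplitude_ = amp
        self.rate_ = rate
        self.rate_ci_ = float(perr[2])
        self.identifiable_ = bool(identifiable)
        self.residual_sd_ = noise
        return self


def fit_leak(trace: AssayTrace) -> dict:
    """Thin functional wrapper over :class:`LeakKineticsFitter`."""
    f = LeakKineticsFitter().fit(trace)
    return {
        "rate": f.rate_,
        "amplitude": f.amplitude_,
        "burst_offset": f.burst_,
        "rate_sd": f.rate_ci_,
        "identifiable": f.identifiable_,
    }


def integrate_charge(
    trace: AssayTrace,
    perfusion_window: tuple,
    baseline_window: tuple | None = None,
) -> ChargeResult:
    """Trapezoid integral of baseline-corrected current over perfusion (nC).

    The baseline current is the mean over ``baseline_window``; by default
    the final 100 ms of the equilibration immediately before perfusion.
    """
    t0, t1 = float(perfusion_window[0]), float(perfusion_window[1])
    t = trace.time
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(
            f"perfusion window [{t0}, {t1}] outside trace extent [{t[0]}, {t[-1]}]"
        )
    if baseline_window is None:
        baseline_window = (t0 - 0.1, t0)
    b0, b1 = float(baseline_window[0]), float(baseline_window[1])
    if not (t[0] <= b0 < b1 <= t[-1]):
        raise ValueError(
            f"baseline window [{b0}, {b1}] outside trace extent [{t[0]}, {t[-1]}]"
        )
    # half-open on the right: the sample at perfusion onset belongs to the
    # transport phase, not the equilibration baseline
    base_mask = (t >= b0) & (t < b1)
    if not base_mask.any():
        raise ValueError(f"baseline window [{b0}, {b1}] contains no samples")
    baseline = float(trace.signal[base_mask].mean())
    mask = (t >= t0) & (t <= t1)
    charge = float(np.trapezoid(trace.signal[mask] - baseline, t[mask]))
    return ChargeResult(charge=charge, baseline_current=baseline, window=(t0, t1))


def group_stats(
    values_by_group: Mapping[str, Sequence[float]],
    holm_correction: bool = False,
) -> list[GroupComparison]:
    """All pairwise Welch two-sided t-tests between replicate groups.

    Singleton groups are excluded with a warning. Raw p-values by default
    (matching the usual reporting convention); ``holm_correction``
    applies a Holm step-down adjustment before star labelling.
    """
    import warnings as _warnings

    usable = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 2:
            _warnings.warn(f"group {name!r} has n={len(arr)} < 2; excluded", stacklevel=2)
            continue
        usable[name] = arr
    names = list(usable)
    comparisons = []
    raw_p = []
    for i, a_name in enumerate(names):
        for b_name in names[i + 1 :]:
            a, b = usable[a_name], usable[b_name]
            if a.std() == 0.0 and b.std() == 0.0 and np.isclose(a.mean(), b.mean()):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(a, b, equal_var=False)
                t_stat, p = float(t_stat), float(p)
            raw_p.append(p)
            comparisons.append(
                GroupComparison(
                    label_a=a_name,
                    label_b=b_name,
                    mean_a=float(a.mean()),
                    mean_b=float(b.mean()),
                    sd_a=float(a.std(ddof=1)),
                    sd_b=float(b.std(ddof=1)),
                    n_a=len(a),
                    n_b=len(b),
                    t=t_stat,
                    p=p,
                    stars=star_label(p),
                    effect=float(a.mean() - b.mean()),
                )
            )
    if holm_correction and comparisons:
        order = np.argsort(raw_p)
        m = len(raw_p)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw_p[idx])
            adjusted[idx] = min(running, 1.0)
        for comp, p_adj in zip(comparisons, adjusted):
            comp.p = float(p_adj)
            comp.stars = star_label(comp.p)
    return comparisons
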