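"""Quantitative and weighted relaxometry maps from multi-echo GRE data.

The effective transverse relaxation time T2* is estimated per vertex from a
mono-exponential decay ``S(TE) = S0 * exp(-TE / T2*)`` fitted in the log
domain; the weighted counterpart T2*w is the late/early echo ratio, which
cancels receive-field bias.  R1 (= 1/T1) maps arrive from the longitudinal
measurement directly; ratio maps combine the two contrasts.

Masking contract
----------------
Vertices where an operation is undefined (non-positive signal, zero
denominator) are *unfittable*: their output value is NaN and they are
reported in an explicit boolean mask so downstream statistics can exclude
them reproducibly.  A non-decaying echo train yields a ``+inf`` T2* marker —
the vertex is fittable, the decay rate is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["DEFAULT_ECHO_TIMES", "EchoSeries", "T2StarFit", "fit_t2star",
           "t2star_weighted", "reciprocal_map", "ratio_maps", "exclusion_mask",
           "EXCLUSION_THRESHOLD_S"]

#: Default 4-echo GRE echo times (s): 2.53 / 7.03 / 12.55 / 20.35 ms.
DEFAULT_ECHO_TIMES = np.array([2.53e-3, 7.03e-3, 12.55e-3, 20.35e-3])

#: Average-T2* cutoff (s) below which vertices are excluded as
#: susceptibility-artifact dominated (large veins, air-tissue interfaces).
EXCLUSION_THRESHOLD_S = 0.024


@dataclass
class EchoSeries:
    """Multi-echo signals: ``echo_times`` (s, strictly increasing) and
    ``signal`` with shape (n_vertices, n_echoes), arbitrary units."""

    echo_times: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.echo_times.ndim != 1 or len(self.echo_times) < 2:
            raise InvalidArgumentError("need at least 2 echo times")
        if np.any(np.diff(self.echo_times) <= 0) or np.any(self.echo_times <= 0):
            raise InvalidArgumentError("echo_times must be positive and strictly increasing")
        if self.signal.shape[1] != len(self.echo_times):
            raise InvalidArgumentError("signal shape does not match echo_times")


class T2StarFit(NamedTuple):
    s0: np.ndarray        # a.u.; NaN where unfittable
    t2star: np.ndarray    # s; NaN where unfittable, +inf where no decay
    fittable: np.ndarray  # bool


def fit_t2star(echoes: EchoSeries, weighted: bool = False) -> T2StarFit:
    """Per-vertex mono-exponential fit of the echo train.

    Least squares of ``log(signal)`` against TE: slope = -1/T2*, intercept =
    log S0.  Exact in the noiseless limit.  With ``weighted=True`` the log
    residuals are weighted by the squared signal, which counteracts the noise
    amplification of the log transform at late, low-signal echoes.  Vertices
    with any non-positive signal are marked unfittable (NaN), not fitted.
    """
    te = echoes.echo_times
    sig = echoes.signal
    n = sig.shape[0]
    fittable = np.all(sig > 0, axis=1)

    s0 = np.full(n, np.nan)
    t2s = np.full(n, np.nan)
    if fittable.any():
        y = np.log(sig[fittable])
        w = sig[fittable] ** 2 if weighted else np.ones_like(y)
        sw = w.sum(axis=1)
        te_bar = (w * te).sum(axis=1) / sw
        y_bar = (w * y).sum(axis=1) / sw
        dte = te[None, :] - te_bar[:, None]
        slope = (w * dte * (y - y_bar[:, None])).sum(axis=1) / (w * dte * dte).sum(axis=1)
        intercept = y_bar - slope * te_bar
        with np.errstate(divide="ignore"):
            t2_fit = np.where(slope < 0, -1.0 / slope, np.inf)
        s0[fittable] = np.exp(intercept)
        t2s[fittable] = t2_fit
    return T2StarFit(s0, t2s, fittable)


def t2star_weighted(echoes: EchoSeries) -> np.ndarray:
    """T2*-weighted map: last echo divided by first echo (dimensionless).

    The shared receive profile cancels in the ratio.  Vertices with
    non-positive first-echo signal are unfittable (NaN).
    """
    first = echoes.signal[:, 0]
    last = echoes.signal[:, -1]
    out = np.full(first.shape, np.nan)
    ok = first > 0
    out[ok] = last[ok] / first[ok]
    return out


def reciprocal_map(values: np.ndarray) -> np.ndarray:
    """Elementwise 1/x with unit relabelling (T1 s <-> R1 s^-1, T2* <-> R2*).

    Non-positive entries are unfittable (NaN); NaN propagates.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    ok = np.isfinite(values) & (values > 0)
    out[ok] = 1.0 / values[ok]
    # +inf decay-time marker maps to rate 0
    out[np.isposinf(values)] = 0.0
    return out


def ratio_maps(t1w: np.ndarray, t2sw: np.ndarray, r1: np.ndarray,
               t2s: np.ndarray) -> tuple:
    """Contrast-enhancing ratio maps: (T1w/T2*w in a.u., R1/T2* in s^-2).

    Unfittable markers (NaN) from either parent map propagate; zero or
    negative denominators are unfittable.
    """
    def safe_div(num, den):
        num = np.asarray(num, dtype=float)
        den = np.asarray(den, dtype=float)
        out = np.full(num.shape, np.nan)
        ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
        out[ok] = num[ok] / den[ok]
        return out

    return safe_div(t1w, t2sw), safe_div(r1, t2s)


def exclusion_mask(t2s_avg: np.ndarray,
                   threshold: float = EXCLUSION_THRESHOLD_S) -> np.ndarray:
    """True (excluded) where the across-subject average T2* is below
    ``threshold`` or the vertex is unfittable."""
    t2s_avg = np.asarray(t2s_avg, dtype=float)
    return ~np.isfinite(t2s_avg) | (t2s_avg < threshold)
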