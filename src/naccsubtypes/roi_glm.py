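"""MID design matrix construction, OLS fitting and contrast extraction.

The task part of the design models the anticipation delay of each of the
five conditions with a variable-duration boxcar, the target onset and the
button press with delta functions, and the feedback period of each condition
with a boxcar, hits and misses separately (5 + 2 + 10 task regressors).
Event streams are laid out on a 0.1 s grid, convolved with a canonical
double-gamma hemodynamic response function and sampled at frame midpoints.
The nuisance block holds 6 motion parameters, their temporal derivatives,
Legendre polynomial drift regressors of order 0..4 and a cerebrospinal-fluid
mean time course (35 columns in the default single-session layout).

Signal preparation helpers implement percent-signal-change scaling relative
to the temporal mean and the drop of the pre-task leading volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .task_design import TRIAL_CONDITIONS, Trial

__all__ = [
    "DesignMatrix",
    "ContrastSet",
    "scale_percent_change",
    "drop_initial_volumes",
    "hrf",
    "build_design_matrix",
    "fit_glm",
    "compute_contrasts",
    "task_column_names",
]

_OVERSAMPLE_DT = 0.1

# canonical double-gamma: response peak ~5 s, undershoot ~15 s, 6:1 ratio
_PEAK_SHAPE, _PEAK_SCALE = 6.0, 1.0
_UNDER_SHAPE, _UNDER_SCALE = 16.0, 1.0
_UNDER_RATIO = 6.0


@dataclass
class DesignMatrix:
    values: np.ndarray  # n_vols x n_cols
    columns: list[str]
    frame_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


@dataclass
class ContrastSet:
    """Condition-versus-neutral contrasts: 4 anticipation betas and, for the
    outcome phase, gain contrasts from hit feedback and loss contrasts from
    miss feedback (condition order -$1.0, -$0.25, +$0.25, +$1.0 throughout,
    with the outcome vector mixing loss-miss and gain-hit contrasts)."""

    anticipation: dict[str, float]
    outcome_gain: dict[str, float]
    outcome_loss: dict[str, float]

    @property
    def outcome(self) -> dict[str, float]:
        return {**self.outcome_loss, **self.outcome_gain}


def scale_percent_change(series: np.ndarray) -> np.ndarray:
    """Scale a time course to percent of its temporal mean (output mean 100)."""
    series = np.asarray(series, dtype=float)
    m = series.mean()
    if abs(m) < 1e-12:
        raise ValueError("cannot percent-scale a zero-mean series")
    return 100.0 * series / m


def drop_initial_volumes(series: np.ndarray, n: int = 5, tr: float | None = None,
                         onsets: np.ndarray | None = None):
    """Drop the ``n`` leading pre-task volumes.

    Returns the trimmed series; when ``onsets`` and ``tr`` are given, also
    returns the onsets shifted earlier by ``n * tr`` to stay aligned.
    """
    series = np.asarray(series)
    if n < 0:
        raise ValueError("n must be non-negative")
    if len(series) <= n:
        raise ValueError(f"series of length {len(series)} cannot drop {n} volumes")
    trimmed = series[n:]
    if onsets is None:
        return trimmed
    if tr is None:
        raise ValueError("tr is required to shift onsets")
    return trimmed, np.asarray(onsets, dtype=float) - n * tr


def _double_gamma(t: np.ndarray) -> np.ndarray:
    peak = gamma_dist.pdf(t, _PEAK_SHAPE, scale=_PEAK_SCALE)
    under = gamma_dist.pdf(t, _UNDER_SHAPE, scale=_UNDER_SCALE)
    h = peak / gamma_dist.pdf((_PEAK_SHAPE - 1) * _PEAK_SCALE, _PEAK_SHAPE, scale=_PEAK_SCALE)
    h -= under / gamma_dist.pdf((_UNDER_SHAPE - 1) * _UNDER_SCALE, _UNDER_SHAPE,
                                scale=_UNDER_SCALE) / _UNDER_RATIO
    return np.where(t > 0, h, 0.0)


_HRF_PEAK = float(np.max(_double_gamma(np.arange(0.0, 32.0, 0.001))))


def hrf(t) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Positive lobe peaking near 5 s, undershoot near 15 s at one sixth the
    amplitude; zero for t <= 0.
    """
    return _double_gamma(np.asarray(t, dtype=float)) / _HRF_PEAK


def task_column_names() -> list[str]:
    names = [f"antic_{c}" for c in TRIAL_CONDITIONS]
    names += ["target_onset", "button_press"]
    for c in TRIAL_CONDITIONS:
        names.append(f"fb_{c}_hit")
    for c in TRIAL_CONDITIONS:
        names.append(f"fb_{c}_miss")
    return names


def _convolve_stream(stream: np.ndarray, dt: float, frame_times: np.ndarray,
                     grid: np.ndarray) -> np.ndarray:
    kernel = hrf(np.arange(0.0, 32.0 + dt, dt))
    conv = np.convolve(stream, kernel)[: len(grid)] * dt
    return np.interp(frame_times, grid, conv)


def build_design_matrix(
    trials: list[Trial],
    tr: float = 2.0,
    n_vols: int = 272,
    motion: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    poly_order: int = 4,
) -> DesignMatrix:
    """Assemble the full design (task + nuisance) sampled at frame midpoints.

    ``motion`` is an ``n_vols x 6`` array (zeros when absent) whose temporal
    derivatives are appended; ``csf`` is a single column.  All-zero columns
    (e.g. a condition with no miss trials) are retained here and flagged at
    fit time.
    """
    scan_end = n_vols * tr
    for t in trials:
        fb_end = t.onset + t.delay_duration + t.target_duration + t.feedback_duration
        if t.onset < 0 or fb_end > scan_end:
            raise ValueError(
                f"trial {t.index} (onset {t.onset:.2f}s, end {fb_end:.2f}s) "
                f"falls outside the {scan_end:.0f}s scan"
            )

    dt = _OVERSAMPLE_DT
    grid = np.arange(0.0, scan_end + dt, dt)
    frame_times = (np.arange(n_vols) + 0.5) * tr

    streams: dict[str, np.ndarray] = {name: np.zeros(len(grid)) for name in task_column_names()}

    def add_box(name, start, dur):
        i0 = int(np.round(start / dt))
        i1 = max(int(np.round((start + dur) / dt)), i0 + 1)
        streams[name][i0:i1] += 1.0

    def add_delta(name, at):
        streams[name][int(np.round(at / dt))] += 1.0 / dt

    for t in trials:
        add_box(f"antic_{t.condition}", t.onset, t.delay_duration)
        t_target = t.onset + t.delay_duration
        add_delta("target_onset", t_target)
        press = t_target + (t.response_time if t.response_time else 0.25)
        add_delta("button_press", min(press, scan_end - dt))
        if t.outcome in ("hit", "miss"):
            add_box(f"fb_{t.condition}_{t.outcome}", t_target + t.target_duration,
                    t.feedback_duration)

    cols, names = [], []
    for name in task_column_names():
        cols.append(_convolve_stream(streams[name], dt, frame_times, grid))
        names.append(name)

    if motion is None:
        motion = np.zeros((n_vols, 6))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_vols, 6):
        raise ValueError("motion must be n_vols x 6")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion_{j + 1}")
    for j in range(6):
        cols.append(deriv[:, j])
        names.append(f"motion_d{j + 1}")

    x = np.linspace(-1.0, 1.0, n_vols)
    for k in range(poly_order + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        cols.append(np.polynomial.legendre.legval(x, coef))
        names.append(f"poly_{k}")

    if csf is None:
        csf = np.zeros(n_vols)
    csf = np.asarray(csf, dtype=float)
    if csf.shape != (n_vols,):
        raise ValueError("csf must be a length n_vols vector")
    cols.append(csf)
    names.append("csf")

    return DesignMatrix(values=np.column_stack(cols), columns=names, frame_times=frame_times)


def fit_glm(series: np.ndarray, design: DesignMatrix):
    """Ordinary least squares on the non-degenerate design columns.

    All-zero columns are excluded from the fit and their names recorded (and
    warned about); the remaining design must be full column rank.  Returns
    ``(betas, sigma2, dropped)`` with betas as a name-indexed Series.
    """
    series = np.asarray(series, dtype=float)
    X = design.values
    keep = ~np.all(np.abs(X) < 1e-12, axis=0)
    dropped = [c for c, k in zip(design.columns, keep) if not k]
    if dropped:
        warnings.warn(f"excluding all-zero design columns: {dropped}", RuntimeWarning,
                      stacklevel=2)
    Xk = X[:, keep]
    names = [c for c, k in zip(design.columns, keep) if k]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(Xk, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        raise ValueError(
            "rank-deficient design after excluding zero columns; "
            f"aliased columns: {[names[j] for j in bad]}"
        )
    beta, res, _, _ = np.linalg.lstsq(Xk, series, rcond=None)
    resid = series - Xk @ beta
    dof = max(len(series) - Xk.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    return pd.Series(beta, index=names), sigma2, dropped


def compute_contrasts(betas: pd.Series) -> ContrastSet:
    """Condition-minus-neutral contrasts from a fitted beta vector.

    Anticipation contrasts subtract the $0 delay beta from each monetary
    delay beta; gain outcomes contrast hit feedback against $0 hit feedback;
    loss outcomes contrast miss feedback against $0 miss feedback.
    """
    def get(name):
        if name not in betas.index:
            raise ValueError(f"required beta {name!r} is missing (empty event cell?)")
        return float(betas[name])

    base = get("antic_$0")
    anticipation = {c: get(f"antic_{c}") - base for c in ("-$1.0", "-$0.25", "+$0.25", "+$1.0")}
    gain_base = get("fb_$0_hit")
    outcome_gain = {c: get(f"fb_{c}_hit") - gain_base for c in ("+$0.25", "+$1.0")}
    loss_base = get("fb_$0_miss")
    outcome_loss = {c: get(f"fb_{c}_miss") - loss_base for c in ("-$1.0", "-$0.25")}
    return ContrastSet(anticipation=anticipation, outcome_gain=outcome_gain,
                       outcome_loss=outcome_loss)
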