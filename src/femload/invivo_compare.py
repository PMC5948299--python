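"""Plausibility comparison against instrumented-prosthesis hip loads.

Peak extraction and frontal-plane inclination ranges from joint-load time
series in the implant coordinate system, mean/SD group summaries, a
Wilcoxon signed-rank test on paired CoV values, and a side-by-side
predicted-vs-in-vivo report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .load_prediction import frontal_inclination

__all__ = [
    "LoadTrace",
    "ComparisonReport",
    "traces_from_frame",
    "read_traces_csv",
    "write_traces_csv",
    "extract_peaks_and_range",
    "summarize",
    "wilcoxon_signed_rank",
    "compare",
]

TRACE_COLUMNS = ["subject", "activity", "time_s", "f_ml_N", "f_ap_N", "f_vert_N"]


@dataclass
class LoadTrace:
    """One activity recording: times (s) and force vectors (N, implant frame)."""

    subject: object
    activity: str
    time: np.ndarray  # (m,)
    forces: np.ndarray  # (m, 3) columns = (ml, ap, vert)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if len(self.time) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if self.forces.shape != (len(self.time), 3):
            raise ValueError("forces must have shape (n_samples, 3)")


def traces_from_frame(df: pd.DataFrame) -> list[LoadTrace]:
    """Split a trace table (see ``TRACE_COLUMNS``) into LoadTrace objects."""
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table lacks columns {missing}")
    traces = []
    for (subj, act), grp in df.groupby(["subject", "activity"], sort=True):
        traces.append(LoadTrace(
            subject=subj, activity=str(act),
            time=grp["time_s"].to_numpy(),
            forces=grp[["f_ml_N", "f_ap_N", "f_vert_N"]].to_numpy(),
        ))
    return traces


def read_traces_csv(path: str | Path) -> list[LoadTrace]:
    return traces_from_frame(pd.read_csv(path))


def write_traces_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=TRACE_COLUMNS)


def extract_peaks_and_range(
    traces: list[LoadTrace],
    min_magnitude: float = 1e-9,
) -> tuple[dict, tuple[float, float]]:
    """Per-subject peak force vectors and the overall inclination range.

    The subject peak is the sample of maximal resultant magnitude across
    all that subject's activities (ties: the earliest sample in input
    order wins). The range is (min, max) frontal-plane inclination over
    every sample of every trace; samples with negligible magnitude are
    excluded from the range, as their direction is undefined.
    """
    if not traces:
        raise ValueError("empty trace set")
    peaks: dict = {}
    best: dict = {}
    inc_min, inc_max = math.inf, -math.inf
    for tr in traces:
        mags = np.linalg.norm(tr.forces, axis=1)
        k = int(np.argmax(mags))  # first maximum = earliest sample
        if mags[k] > best.get(tr.subject, -math.inf):
            best[tr.subject] = mags[k]
            peaks[tr.subject] = tr.forces[k].copy()
        live = mags > min_magnitude
        if live.any():
            inc = np.rad2deg(np.arctan2(tr.forces[live, 0], tr.forces[live, 2]))
            inc_min = min(inc_min, float(inc.min()))
            inc_max = max(inc_max, float(inc.max()))
    return peaks, (inc_min, inc_max)


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    With fewer than two values the SD is undefined and returned as NaN
    (with a warning).
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("cannot summarise an empty list")
    mean = float(v.mean())
    if len(v) < 2:
        warnings.warn("sample SD undefined for fewer than 2 values")
        return mean, float("nan")
    return mean, float(v.std(ddof=1))


def wilcoxon_signed_rank(
    pairs: list[tuple[float, float]],
    method: str = "exact",
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on (before, after) pairs.

    Returns ``(W, p)`` where W is the smaller of the positive- and
    negative-difference rank sums. ``method='exact'`` uses the exact null
    distribution (supported up to n=25 non-zero differences);
    ``method='approx'`` uses the normal approximation (no continuity
    correction), as commonly reported by statistics packages.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a list of (before, after) tuples")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero; test undefined")
    if len(d) < 5:
        raise ValueError("need at least 5 non-zero differences")
    if method == "exact" and len(d) > 25:
        raise ValueError("exact method supported up to n=25; use method='approx'")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    W = min(w_pos, w_neg)
    scipy_method = "exact" if method == "exact" else "approx"
    res = stats.wilcoxon(arr[:, 0], arr[:, 1], zero_method="wilcox",
                         alternative="two-sided", correction=False,
                         method=scipy_method)
    return W, float(res.pvalue)


@dataclass
class ComparisonReport:
    """Predicted vs in-vivo peak loads and inclination ranges."""

    predicted_mag_mean: float
    predicted_mag_sd: float
    predicted_inc_mean: float
    predicted_inc_sd: float
    invivo_mag_mean: float
    invivo_mag_sd: float
    invivo_inc_mean: float
    invivo_inc_sd: float
    predicted_range_deg: tuple[float, float]
    invivo_range_deg: tuple[float, float]
    delta_mag_mean: float
    delta_inc_mean: float
    n_predicted: int
    n_invivo: int
    meta: dict = field(default_factory=dict)

    def to_text(self) -> str:
        pr, ir = self.predicted_range_deg, self.invivo_range_deg
        return (
            "Peak joint loads, predicted vs in vivo\n"
            f"  predicted: {self.predicted_mag_mean:.1f} +/- {self.predicted_mag_sd:.1f} N "
            f"at {self.predicted_inc_mean:.1f} +/- {self.predicted_inc_sd:.1f} deg "
            f"(n={self.n_predicted})\n"
            f"  in vivo:   {self.invivo_mag_mean:.1f} +/- {self.invivo_mag_sd:.1f} N "
            f"at {self.invivo_inc_mean:.1f} +/- {self.invivo_inc_sd:.1f} deg "
            f"(n={self.n_invivo})\n"
            f"  delta (pred - in vivo): {self.delta_mag_mean:.1f} N, "
            f"{self.delta_inc_mean:.1f} deg\n"
            f"  inclination range predicted: {pr[0]:.1f} to {pr[1]:.1f} deg\n"
            f"  inclination range in vivo:   {ir[0]:.1f} to {ir[1]:.1f} deg\n"
        )


def compare(
    predicted_peaks: list[np.ndarray],
    invivo_peaks: list[np.ndarray],
    invivo_range: tuple[float, float],
    predicted_range: tuple[float, float],
) -> ComparisonReport:
    """Side-by-side group summaries of peak vectors and direction ranges."""
    if len(predicted_peaks) == 0 or len(invivo_peaks) == 0:
        raise ValueError("both peak sets must be non-empty")
    for rng in (invivo_range, predicted_range):
        if rng[0] > rng[1]:
            raise ValueError(f"range minimum exceeds maximum: {rng}")

    def _mags_incs(vecs):
        vecs = np.asarray(vecs, dtype=float)
        mags = np.linalg.norm(vecs, axis=1)
        incs = np.array([frontal_inclination(v) for v in vecs])
        return mags, incs

    pm, pi = _mags_incs(predicted_peaks)
    im, ii = _mags_incs(invivo_peaks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pm_m, pm_s = summarize(pm)
        pi_m, pi_s = summarize(pi)
        im_m, im_s = summarize(im)
        ii_m, ii_s = summarize(ii)
    meta = {}
    if len(pm) < 2 or len(im) < 2:
        meta["sd_undefined"] = True
    return ComparisonReport(
        predicted_mag_mean=pm_m, predicted_mag_sd=pm_s,
        predicted_inc_mean=pi_m, predicted_inc_sd=pi_s,
        invivo_mag_mean=im_m, invivo_mag_sd=im_s,
        invivo_inc_mean=ii_m, invivo_inc_sd=ii_s,
        predicted_range_deg=tuple(predicted_range),
        invivo_range_deg=tuple(invivo_range),
        delta_mag_mean=pm_m - im_m,
        delta_inc_mean=pi_m - ii_m,
        n_predicted=len(pm), n_invivo=len(im),
        meta=meta,
    )
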