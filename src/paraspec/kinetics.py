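"""Phosphotransfer time-course analysis.

The observable is the band intensity of autophosphorylated histidine
kinase (HK~P): its rate of loss after mixing with a response regulator is
the standard proxy for the phosphotransfer rate.  With the RR in excess
(the assays use a 1:4 HK:RR molar ratio) and sub-saturating substrate,
HK~P decays approximately exponentially with rate (k_cat/K_M)·[RR], so
the ratio of two such rates measured under matched conditions estimates
the ratio of specificity constants — the fold-preference reported per
protein.  k_cat and K_M are never estimated separately here; only their
ratio is identifiable from these data.

Two rate estimators are provided:

* ``window`` — the two-point estimator used on gel quantifications:
  the fractional loss of HK~P between t=0 and a window end (30 s for
  cognate pairs, 5 min otherwise);
* ``loglinear`` — the slope of ln(intensity) vs time above an intensity
  floor; unbiased for exponential decay and the recommended default for
  simulated or densely sampled data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidInputError,
    MissingTimepointError,
    UndefinedRatioError,
)

#: default initial-rate windows, seconds
COGNATE_WINDOW_S = 30.0
NONCOGNATE_WINDOW_S = 300.0


@dataclass
class TimeCourse:
    """Phospho-HK intensity versus time for one HK -> RR reaction.

    ``pair`` is conventionally ``"<hk>:<rr>"``; times are seconds, strictly
    increasing from 0.  When ``normalized`` the intensity at t=0 is exactly 1.
    """

    pair: str
    times: np.ndarray
    intensity: np.ndarray
    normalized: bool = False
    cognate: bool | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise InvalidInputError("times and intensity must be equal-length 1-D")
        if len(t) == 0 or t[0] != 0.0:
            raise InvalidInputError(
                f"time course {self.pair!r} must start at t=0"
            )
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(
                f"times for {self.pair!r} must be strictly increasing"
            )
        if np.any(y < 0):
            raise InvalidInputError(f"negative intensity in {self.pair!r}")
        if self.normalized and y[0] != 1.0:
            raise InvalidInputError(
                f"{self.pair!r} marked normalized but I(0) = {y[0]}"
            )
        self.times = t
        self.intensity = y

    @property
    def hk(self) -> str:
        return self.pair.split(":", 1)[0]

    @property
    def rr(self) -> str:
        parts = self.pair.split(":", 1)
        return parts[1] if len(parts) == 2 else ""


@dataclass
class RateEstimate:
    """An initial phospho-HK loss rate, in s^-1."""

    value: float
    method: str  # "window" | "loglinear"
    pair: str = ""
    window_end: float | None = None
    n_points: int = 0
    warning: str | None = None


@dataclass
class SpecificityRatio:
    """Fold-preference between two reactions sharing a protein."""

    numerator: str
    denominator: str
    fold: float
    direction: str  # pair label of the faster reaction, or "none"
    rate_numerator: float
    rate_denominator: float


def normalize_timecourse(raw: TimeCourse) -> TimeCourse:
    """Divide all intensities by the t=0 intensity; idempotent."""
    i0 = raw.intensity[0]
    if i0 <= 0:
        raise InvalidInputError(
            f"cannot normalize {raw.pair!r}: intensity at t=0 is {i0}"
        )
    return replace(
        raw, intensity=raw.intensity / i0, normalized=True
    )


def initial_rate(
    tc: TimeCourse, window_end: float, time_tolerance: float = 0.2
) -> RateEstimate:
    """Two-point window estimator: fraction of HK~P lost per second.

    Uses the observation nearest ``window_end`` (within a relative
    tolerance, default 20%).  A negative value — the intensity rose, which
    noise can produce — is reported as-is with a warning flag rather than
    clamped.
    """
    if not tc.normalized:
        raise InvalidArgumentError(
            f"{tc.pair!r}: normalize the time course before estimating rates"
        )
    if window_end <= 0:
        raise InvalidArgumentError("window_end must be positive")
    later = tc.times > 0
    if not later.any():
        raise MissingTimepointError(f"{tc.pair!r} has no post-zero observation")
    times = tc.times[later]
    gaps = np.abs(times - window_end)
    best = int(np.argmin(gaps))
    if gaps[best] > time_tolerance * window_end:
        raise MissingTimepointError(
            f"{tc.pair!r}: no observation within {time_tolerance:.0%} of "
            f"{window_end} s (nearest at {times[best]} s)"
        )
    t_obs = times[best]
    i_obs = tc.intensity[later][best]
    value = (1.0 - i_obs) / t_obs
    warning = None
    if value < 0:
        warning = f"intensity rose to {i_obs:.3g} at {t_obs} s; negative rate"
    return RateEstimate(
        value=float(value),
        method="window",
        pair=tc.pair,
        window_end=float(window_end),
        n_points=2,
        warning=warning,
    )


def fit_decay_rate(tc: TimeCourse, floor: float = 0.1) -> RateEstimate:
    """Log-linear estimator: -slope of ln(intensity) vs time above ``floor``."""
    if not tc.normalized:
        raise InvalidArgumentError(
            f"{tc.pair!r}: normalize the time course before estimating rates"
        )
    usable = tc.intensity >= floor
    n = int(usable.sum())
    if n < 2:
        raise InsufficientDataError(
            f"{tc.pair!r}: {n} point(s) with intensity >= {floor}; need >= 2"
        )
    t = tc.times[usable]
    logy = np.log(tc.intensity[usable])
    slope = np.polyfit(t, logy, 1)[0]
    return RateEstimate(
        value=float(-slope),
        method="loglinear",
        pair=tc.pair,
        n_points=n,
    )


def specificity_ratio(rate_a: RateEstimate, rate_b: RateEstimate) -> SpecificityRatio:
    """Fold-preference between two rates; always >= 1 with a direction flag."""
    ra, rb = rate_a.value, rate_b.value
    if ra <= 0 or rb <= 0:
        raise UndefinedRatioError(
            f"specificity ratio undefined for non-positive rates "
            f"({rate_a.pair or 'a'}={ra:.4g}, {rate_b.pair or 'b'}={rb:.4g})"
        )
    if ra == rb:
        direction = "none"
    elif ra > rb:
        direction = rate_a.pair or "a"
    else:
        direction = rate_b.pair or "b"
    return SpecificityRatio(
        numerator=rate_a.pair or "a",
        denominator=rate_b.pair or "b",
        fold=float(max(ra, rb) / min(ra, rb)),
        direction=direction,
        rate_numerator=ra,
        rate_denominator=rb,
    )


@dataclass
class MatrixDesign:
    """Which reactions exist, which are cognate, and what to compare.

    ``hk_compare`` maps each HK to the ordered pair of RRs whose rates are
    contrasted (and symmetrically for ``rr_compare``).  When omitted, each
    protein observed with exactly two partners is compared across them.
    """

    cognate_pairs: frozenset[tuple[str, str]]
    hk_compare: Mapping[str, tuple[str, str]] | None = None
    rr_compare: Mapping[str, tuple[str, str]] | None = None

    def is_cognate(self, hk: str, rr: str) -> bool:
        return (hk, rr) in self.cognate_pairs


def _estimate(
    tc: TimeCourse, cognate: bool, method: str, floor: float
) -> RateEstimate:
    tc = normalize_timecourse(tc)
    if method == "window":
        window = COGNATE_WINDOW_S if cognate else NONCOGNATE_WINDOW_S
        return initial_rate(tc, window)
    if method == "loglinear":
        return fit_decay_rate(tc, floor=floor)
    raise InvalidArgumentError(f"unknown method {method!r}")


def specificity_matrix(
    timecourses: Iterable[TimeCourse],
    design: MatrixDesign,
    method: str = "window",
    floor: float = 0.1,
) -> pd.DataFrame:
    """Per-protein fold-preferences from a set of time courses.

    Returns one row per compared protein with the two component rates, the
    fold (>= 1) and the preferred partner.  Missing reactions required by
    the design raise, naming every absent pair.
    """
    courses: dict[tuple[str, str], TimeCourse] = {}
    for tc in timecourses:
        key = (tc.hk, tc.rr)
        if key in courses:
            raise InvalidInputError(f"duplicate time course for pair {tc.pair!r}")
        courses[key] = tc

    def default_compare(role: str) -> dict[str, tuple[str, str]]:
        partners: dict[str, list[str]] = {}
        for hk, rr in courses:
            me, other = (hk, rr) if role == "hk" else (rr, hk)
            partners.setdefault(me, []).append(other)
        return {
            p: (v[0], v[1]) for p, v in partners.items() if len(v) == 2
        }

    hk_compare = dict(design.hk_compare) if design.hk_compare else default_compare("hk")
    rr_compare = dict(design.rr_compare) if design.rr_compare else default_compare("rr")

    needed = [
        (hk, rr) for hk, (r1, r2) in hk_compare.items() for rr in (r1, r2)
    ] + [
        (hk, rr) for rr, (h1, h2) in rr_compare.items() for hk in (h1, h2)
    ]
    missing = sorted({p for p in needed if p not in courses})
    if missing:
        raise InvalidInputError(
            "missing time courses for pairs: "
            + ", ".join(f"{h}:{r}" for h, r in missing)
        )

    rates: dict[tuple[str, str], RateEstimate] = {}
    for key in sorted(set(needed)):
        tc = courses[key]
        rates[key] = _estimate(tc, design.is_cognate(*key), method, floor)

    rows = []
    for hk in sorted(hk_compare):
        r1, r2 = hk_compare[hk]
        ratio = specificity_ratio(rates[(hk, r1)], rates[(hk, r2)])
        rows.append(
            {
                "protein": hk,
                "role": "HK",
                "partner_1": r1,
                "partner_2": r2,
                "rate_1": ratio.rate_numerator,
                "rate_2": ratio.rate_denominator,
                "fold": ratio.fold,
                "preferred": "none"
                if ratio.direction == "none"
                else ratio.direction.split(":", 1)[1],
                "method": method,
            }
        )
    for rr in sorted(rr_compare):
        h1, h2 = rr_compare[rr]
        ratio = specificity_ratio(rates[(h1, rr)], rates[(h2, rr)])
        rows.append(
            {
                "protein": rr,
                "role": "RR",
                "partner_1": h1,
                "partner_2": h2,
                "rate_1": ratio.rate_numerator,
                "rate_2": ratio.rate_denominator,
                "fold": ratio.fold,
                "preferred": "none"
                if ratio.direction == "none"
                else ratio.direction.split(":", 1)[0],
                "method": method,
            }
        )
    return pd.DataFrame(rows)
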