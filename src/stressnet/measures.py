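"""Scoring of the raw instruments into analysis variables.

Covers the 69-item life-event survey (negative/positive/total scores),
the 51-item reinforcement-sensitivity questionnaire subscale sums,
inter-beat-interval filtering and RMSSD, the eight-site muscle
stiffness total with its coefficient-of-variation quality gate, and
the six-stance balance error score with limb asymmetry.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LESCA_N_ITEMS = 69
RSTPQ_N_ITEMS = 51

#: Default item -> subscale assignment for the 51-item questionnaire.
#: Item counts are chosen to be consistent with the observed subscale
#: score spans (a 17-item BIS spans 17-68, a 4-item RI spans 4-16).
RSTPQ_DEFAULT_MAP: dict[int, str] = {}
_counts = {"FFFS": 8, "BIS": 17, "RI": 4, "GDP": 7, "RR": 8, "I": 7}
_item = 1
for _sub, _c in _counts.items():
    for _ in range(_c):
        RSTPQ_DEFAULT_MAP[_item] = _sub
        _item += 1
del _item, _sub, _c

STIFFNESS_SITES = tuple(f"{m}_{s}" for m in ("RF", "BF", "MG", "LG") for s in ("left", "right"))
BESS_STANCES = ("dl_firm", "ndl_firm", "ts_firm", "dl_foam", "ndl_foam", "ts_foam")


# ---------------------------------------------------------------------------
# Life events
# ---------------------------------------------------------------------------

def score_lesca(ratings: Sequence[int | None]) -> tuple[int, int, int]:
    """Score one 69-item life-event response.

    Each entry is an integer impact rating in -4..4 (0 excluded by the
    instrument but tolerated) or ``None`` for "not experienced".
    Returns ``(NLE, PLE, TLE)``: the magnitude of the summed negative
    ratings, the sum of positive ratings, and their total (the sum of
    absolute values over all rated items).
    """
    if len(ratings) != LESCA_N_ITEMS:
        raise ValueError(f"expected {LESCA_N_ITEMS} item ratings, got {len(ratings)}")
    nle = ple = 0
    for r in ratings:
        if r is None:
            continue
        r = int(r)
        if not -4 <= r <= 4:
            raise ValueError(f"rating {r} outside -4..4")
        if r < 0:
            nle += -r
        else:
            ple += r
    return nle, ple, nle + ple


def score_rstpq(
    item_responses: Mapping[int, int],
    subscale_map: Mapping[int, str] | None = None,
) -> dict[str, int]:
    """Sum item responses (1..4) into subscale totals."""
    subscale_map = dict(subscale_map) if subscale_map is not None else dict(RSTPQ_DEFAULT_MAP)
    if len(subscale_map) != RSTPQ_N_ITEMS:
        raise ValueError(f"subscale map must cover {RSTPQ_N_ITEMS} items")
    sums: dict[str, int] = {s: 0 for s in dict.fromkeys(subscale_map.values())}
    for item, response in item_responses.items():
        if item not in subscale_map:
            raise KeyError(f"item {item} not mapped to a subscale")
        if not 1 <= int(response) <= 4:
            raise ValueError(f"response {response} for item {item} outside 1..4")
        sums[subscale_map[item]] += int(response)
    missing = set(subscale_map) - set(item_responses)
    if missing:
        raise ValueError(f"missing responses for items {sorted(missing)[:5]}...")
    return sums


# ---------------------------------------------------------------------------
# Heart rate variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IbiSeries:
    """Ordered inter-beat intervals in milliseconds."""

    intervals: np.ndarray
    duration: float | None = None  # seconds; defaults to the interval total

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("need at least two intervals")
        if np.any(arr <= 0):
            raise ValueError("all intervals must be positive")
        object.__setattr__(self, "intervals", arr)
        if self.duration is None:
            object.__setattr__(self, "duration", float(arr.sum() / 1000.0))

    def __len__(self) -> int:
        return int(self.intervals.size)


def read_ibi(path_or_buffer) -> IbiSeries:
    """Read a space-delimited IBI export (one interval in ms per line).

    A single leading non-numeric header line is tolerated.
    """
    if isinstance(path_or_buffer, (str, Path)):
        text = Path(path_or_buffer).read_text()
    else:
        text = path_or_buffer.read()
    values: list[float] = []
    for i, line in enumerate(io.StringIO(text)):
        line = line.strip()
        if not line:
            continue
        try:
            values.extend(float(tok) for tok in line.split())
        except ValueError:
            if i == 0:
                continue  # header
            raise
    return IbiSeries(np.asarray(values))


def write_ibi(series: IbiSeries, path) -> None:
    Path(path).write_text("\n".join(f"{v:.1f}" for v in series.intervals) + "\n")


def filter_ibi(series: IbiSeries, rel_tolerance: float = 0.2, window: int = 11) -> IbiSeries:
    """Remove artifact beats by a centred running-median rule.

    A beat is rejected when it deviates from the running median of its
    ``window``-beat neighbourhood by more than ``rel_tolerance`` of
    that median.  The rule is applied repeatedly until no beat is
    rejected, which makes the filter idempotent; the output is always a
    subsequence of the input.  Raises if every beat would be rejected.
    """
    if not 0 < rel_tolerance < 1:
        raise ValueError("rel_tolerance must lie in (0, 1)")
    x = series.intervals
    while True:
        med = pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
        keep = np.abs(x - med) <= rel_tolerance * med
        if keep.all():
            return IbiSeries(x, duration=series.duration)
        x = x[keep]
        if x.size < 2:
            raise ValueError("adaptive filter rejected (nearly) all beats; recording unusable")


def compute_rmssd(
    series: IbiSeries,
    trim_head: float = 180.0,
    trim_tail: float = 120.0,
) -> tuple[float, float]:
    """RMSSD (ms) and its natural log over the central analysis window.

    The first ``trim_head`` seconds and the last ``trim_tail`` seconds
    of the recording are discarded (default: 3 min and 2 min, leaving
    a 5-min window of a 10-min recording); the root mean square of
    successive differences is computed on the remaining intervals.
    A zero RMSSD yields ``-inf`` for the log.
    """
    rr = series.intervals
    t_end = np.cumsum(rr) / 1000.0  # seconds, time at the end of each interval
    total = float(series.duration)
    inside = (t_end > trim_head) & (t_end <= total - trim_tail)
    window = rr[inside]
    if window.size < 2:
        raise ValueError("analysis window contains fewer than two intervals")
    diffs = np.diff(window)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    ln_rmssd = math.log(rmssd) if rmssd > 0 else -math.inf
    return rmssd, ln_rmssd


def mean_rr(series: IbiSeries) -> float:
    """Arithmetic mean of the RR intervals (documented helper; this is
    the printed formula, distinct from the RMSSD implemented above)."""
    return float(series.intervals.mean())


# ---------------------------------------------------------------------------
# Muscle stiffness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StiffnessMeasurement:
    """Five consecutive impulse stiffness readings at one site."""

    site: str
    impulses: tuple[float, float, float, float, float]

    def __post_init__(self):
        if self.site not in STIFFNESS_SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {STIFFNESS_SITES}")
        if len(self.impulses) != 5:
            raise ValueError("exactly five impulses per measurement set")

    @property
    def median(self) -> float:
        return float(np.median(self.impulses))

    @property
    def cv(self) -> float:
        arr = np.asarray(self.impulses, dtype=float)
        return float(100.0 * arr.std(ddof=1) / arr.mean())


def total_stiffness(
    measurements: Iterable[StiffnessMeasurement],
    cv_limit: float = 3.0,
) -> tuple[float, dict[str, float]]:
    """Sum of the eight per-site medians, plus re-measurement flags.

    Every bilateral site must appear exactly once; sites whose five
    impulses have a coefficient of variation at or above ``cv_limit``
    (percent) are flagged with their CV value.
    """
    by_site = {}
    for m in measurements:
        if m.site in by_site:
            raise ValueError(f"duplicate site {m.site!r}")
        by_site[m.site] = m
    missing = set(STIFFNESS_SITES) - set(by_site)
    if missing:
        raise ValueError(f"missing sites: {sorted(missing)}")
    flags = {s: m.cv for s, m in by_site.items() if m.cv >= cv_limit}
    total = float(sum(m.median for m in by_site.values()))
    return total, flags


# ---------------------------------------------------------------------------
# Postural stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BessTrial:
    """Error counts for the six stances (each capped at 10 by the protocol).

    A stance abandoned for more than 5 s is entered as 10 by the caller.
    """

    dl_firm: int
    ndl_firm: int
    ts_firm: int
    dl_foam: int
    ndl_foam: int
    ts_foam: int

    def __post_init__(self):
        for stance in BESS_STANCES:
            v = getattr(self, stance)
            if not 0 <= int(v) <= 10:
                raise ValueError(f"{stance} count {v} outside 0..10")


def score_bess(trial: BessTrial) -> tuple[int, float]:
    """Total errors (0..60) and percentage asymmetry between limbs.

    Asymmetry is ``100 * |dominant - non-dominant| / mean`` over the
    single-leg stances (firm + foam); zero when both limb totals are 0.
    """
    total = sum(int(getattr(trial, s)) for s in BESS_STANCES)
    dom = trial.dl_firm + trial.dl_foam
    nondom = trial.ndl_firm + trial.ndl_foam
    if dom == 0 and nondom == 0:
        asym = 0.0
    else:
        asym = 100.0 * abs(dom - nondom) / ((dom + nondom) / 2.0)
    return total, asym
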