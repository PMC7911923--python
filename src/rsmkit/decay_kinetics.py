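"""Half-life estimation from rifampicin-chase qRT-PCR time courses.

After rifampicin blocks transcription initiation, the abundance of an RNA
decays (to first order) exponentially.  Relative abundance is obtained from
qPCR threshold cycles by the delta-delta-Ct method against a reference gene
(16S rRNA), the decay rate by ordinary least squares on ln(abundance) vs
time, and the half-life as ln2 / k.  RNAs whose decay is too slow to
quantify within the sampled window are reported as censored (">= bound"),
as is conventional for chase experiments.

Replicates are fitted independently and then summarized (mean +/- sample sd),
matching how triplicate chase experiments are tabulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

PAPER_TIMEPOINTS = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)
"""Chase sampling grid (minutes): t = 0 plus the 11 sampled times."""

DETECTION_FLOOR = 1e-3


@dataclass(frozen=True)
class Replicate:
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]


@dataclass(frozen=True)
class DecayTimeCourse:
    srna_id: str
    times: tuple[float, ...]
    replicates: tuple[Replicate, ...]
    efficiency: float = 2.0

    def __post_init__(self):
        t = np.asarray(self.times)
        if len(t) < 4:
            raise ValueError("need at least 4 time points")
        if len(set(self.times)) != len(self.times) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be unique and ascending")
        if t[0] != 0:
            raise ValueError("first time point must be 0 (normalization anchor)")
        if not self.replicates:
            raise ValueError("need at least one replicate")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("amplification efficiency must be in (1, 2]")
        for r in self.replicates:
            if len(r.ct_target) != len(t) or len(r.ct_reference) != len(t):
                raise ValueError("replicate series length must match times")


@dataclass(frozen=True)
class AbundanceSeries:
    times: tuple[float, ...]
    rel_abundance: tuple[float, ...]

    def __post_init__(self):
        if self.times[0] != 0 or not math.isclose(self.rel_abundance[0], 1.0):
            raise ValueError("series must be normalized to 1 at t = 0")
        if any(v <= 0 for v in self.rel_abundance):
            raise ValueError("relative abundances must be positive")


@dataclass(frozen=True)
class HalfLifeEstimate:
    t_half: float
    sd: float = float("nan")
    censored: bool = False
    censor_bound: float | None = None
    n_replicates: int = 1
    mixed: bool = False  # censored and uncensored replicates combined

    def __str__(self) -> str:
        if self.censored:
            return f">={self.censor_bound:g}"
        if math.isnan(self.sd):
            return f"{self.t_half:g}"
        return f"{self.t_half:g} +/- {self.sd:g}"


def relative_abundance(tc: DecayTimeCourse) -> list[AbundanceSeries]:
    """Delta-delta-Ct conversion, one series per replicate.

    rel(t) = efficiency ** -(dCt(t) - dCt(0)) with dCt = Ct_target - Ct_ref;
    rel(0) = 1 by construction.  Non-finite Ct values drop the point with a
    warning; a missing t = 0 measurement is an error.
    """
    out = []
    for ridx, rep in enumerate(tc.replicates):
        tgt = np.asarray(rep.ct_target, dtype=float)
        ref = np.asarray(rep.ct_reference, dtype=float)
        ok = np.isfinite(tgt) & np.isfinite(ref)
        if not ok[0]:
            raise ValueError(
                f"{tc.srna_id} replicate {ridx}: missing Ct at t = 0"
            )
        if not ok.all():
            logger.warning(
                "%s replicate %d: dropping %d non-finite point(s)",
                tc.srna_id, ridx, int((~ok).sum()),
            )
        dct = tgt[ok] - ref[ok]
        rel = tc.efficiency ** -(dct - dct[0])
        out.append(
            AbundanceSeries(
                tuple(np.asarray(tc.times)[ok]), tuple(rel)
            )
        )
    return out


def fit_halflife(
    series: AbundanceSeries,
    censor_at: float | None = None,
    floor: float = DETECTION_FLOOR,
) -> HalfLifeEstimate:
    """Log-linear least-squares half-life for one replicate.

    Points at or below the detection floor are excluded.  If the fitted decay
    rate is non-positive, or the implied half-life exceeds ``censor_at``
    (default: the last sampled time), the estimate is censored at that bound.
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.rel_abundance, dtype=float)
    if censor_at is None:
        censor_at = float(t[-1])
    keep = y > floor
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points above the detection floor")
    slope, _, _, _, _ = stats.linregress(t[keep], np.log(y[keep]))
    k = -slope
    if k <= 0:
        return HalfLifeEstimate(censor_at, censored=True, censor_bound=censor_at)
    t_half = math.log(2) / k
    if t_half > censor_at:
        return HalfLifeEstimate(censor_at, censored=True, censor_bound=censor_at)
    return HalfLifeEstimate(t_half)


def summarize_replicates(estimates: list[HalfLifeEstimate]) -> HalfLifeEstimate:
    """Combine per-replicate estimates into a mean +/- sample sd.

    If any replicate is censored, the summary is censored at the smallest
    replicate censor bound and flagged mixed when uncensored replicates are
    also present.
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    censored = [e for e in estimates if e.censored]
    uncensored = [e for e in estimates if not e.censored]
    n = len(estimates)
    if censored:
        bound = min(e.censor_bound for e in censored)
        return HalfLifeEstimate(
            bound,
            censored=True,
            censor_bound=bound,
            n_replicates=n,
            mixed=bool(uncensored),
        )
    vals = np.array([e.t_half for e in uncensored])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return HalfLifeEstimate(float(np.mean(vals)), sd=sd, n_replicates=n)


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    is_bound: bool = False  # ratio derived from a censored bound (">= ratio")

    def __str__(self) -> str:
        return f">={self.ratio:g}" if self.is_bound else f"{self.ratio:g}"


def fold_change(a: HalfLifeEstimate, b: HalfLifeEstimate) -> FoldChange:
    """Stability ratio a / b; censored inputs yield a flagged lower bound."""
    if a.censored and b.censored:
        raise ValueError("fold change between two censored estimates is undefined")
    return FoldChange(a.t_half / b.t_half, is_bound=a.censored or b.censored)


def rank_correlation(
    x: list[float], y: list[HalfLifeEstimate | float]
) -> float:
    """Spearman correlation (mid-ranks) tolerant of censored half-lives.

    Censored values rank above every uncensored value and among themselves by
    their bound.  Returns NaN when either variable is constant.
    """
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of at least 3")
    keys = []
    uncens_max = 0.0
    for v in y:
        if isinstance(v, HalfLifeEstimate):
            if not v.censored:
                uncens_max = max(uncens_max, v.t_half)
        else:
            uncens_max = max(uncens_max, float(v))
    offset = uncens_max + 1.0
    for v in y:
        if isinstance(v, HalfLifeEstimate):
            keys.append(v.censor_bound + offset if v.censored else v.t_half)
        else:
            keys.append(float(v))
    rx = stats.rankdata(x)
    ry = stats.rankdata(keys)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("rank correlation undefined for constant input")
        return float("nan")
    r, _ = stats.pearsonr(rx, ry)
    return float(r)
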