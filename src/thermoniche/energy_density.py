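"""Predator energy-density models and their calibration.

A predator's whole-body energy density (ED, kJ/g wet weight) is modelled as a
piecewise-linear function of body weight, typically with a single breakpoint
separating a fast-accumulating juvenile segment from a shallower adult
segment.  The model is invertible: total body energy E(W) = W * ED(W) is a
quadratic per segment, so weight can be recovered from energy in closed form,
which is what the daily growth step of the bioenergetics engine needs.

Calibration utilities cover the full path from raw lipid measurements to a
fitted model: lipid-to-energy conversions, rescaling of lipid-based estimates
against bomb calorimetry, and a profiled least-squares breakpoint search with
a pairs bootstrap for the breakpoint confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, FitError, SimulationError

#: Energy content of pure lipid (kJ per g), the Brody conversion constant.
BRODY_KJ_PER_G_LIPID = 39.5


@dataclass(frozen=True)
class EDSegment:
    """One linear piece ED(W) = intercept + slope * W over (w_lo, w_hi]."""

    intercept: float  # kJ/g
    slope: float      # kJ/g per g
    w_lo: float
    w_hi: float       # math.inf for the last segment


@dataclass(frozen=True)
class EnergyDensityModel:
    """Piecewise-linear energy density vs. weight, invertible to weight."""

    segments: tuple[EDSegment, ...]
    breakpoint: float | None = None
    breakpoint_ci: tuple[float, float] | None = None
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainError("model needs at least one segment")
        lo = 0.0
        for seg in self.segments:
            if not math.isclose(seg.w_lo, lo, rel_tol=0, abs_tol=1e-9):
                raise DomainError("segment weight ranges must partition (0, inf)")
            if seg.w_hi <= seg.w_lo:
                raise DomainError("segment weight range is empty")
            lo = seg.w_hi
        if not math.isinf(self.segments[-1].w_hi):
            raise DomainError("last segment must extend to infinity")

    # -- evaluation ---------------------------------------------------------

    def _segment_for_weight(self, w: float) -> EDSegment:
        for seg in self.segments[:-1]:
            if w <= seg.w_hi:
                return seg
        return self.segments[-1]

    def energy_density(self, w: float) -> float:
        """ED at weight ``w`` (g), in kJ/g."""
        if w <= 0:
            raise DomainError(f"weight must be positive, got {w}")
        seg = self._segment_for_weight(w)
        return seg.intercept + seg.slope * w

    def body_energy(self, w: float) -> float:
        """Total body energy at weight ``w``, in J."""
        return w * self.energy_density(w) * 1000.0

    # -- inversion ----------------------------------------------------------

    def _segment_energy_hi(self, seg: EDSegment) -> float:
        """Body energy (J) at the segment's upper weight bound."""
        if math.isinf(seg.w_hi):
            return math.inf
        return seg.w_hi * (seg.intercept + seg.slope * seg.w_hi) * 1000.0

    def _segment_energy_lo(self, seg: EDSegment) -> float:
        """Body energy (J) at the segment's lower weight bound."""
        return seg.w_lo * (seg.intercept + seg.slope * seg.w_lo) * 1000.0

    def weight_from_energy(self, energy: float) -> float:
        """Invert E(W) = 1000 * W * (a + b W): closed-form quadratic root.

        Segment selection brackets the energy against each segment's energy
        range; at a breakpoint tie the adult (next) segment wins.  Where the
        fitted segments are slightly discontinuous at the breakpoint, an
        energy falling in the gap between the segments' energy ranges maps to
        the breakpoint weight itself, keeping the inversion continuous and
        monotone in energy.
        """
        if energy <= 0:
            raise SimulationError(
                f"body energy {energy:.6g} J is non-positive (starvation collapse)"
            )
        seg = self.segments[-1]
        for cand, nxt in zip(self.segments[:-1], self.segments[1:]):
            if energy < self._segment_energy_hi(cand):
                seg = cand
                break
            if energy < self._segment_energy_lo(nxt):
                return cand.w_hi  # inside the discontinuity gap
        a = seg.intercept * 1000.0  # J/g
        b = seg.slope * 1000.0      # J/g^2
        if b == 0.0:
            return energy / a
        return (-a + math.sqrt(a * a + 4.0 * b * energy)) / (2.0 * b)

    def to_dict(self) -> dict:
        d: dict = {
            "segments": [
                {
                    "intercept_kJ_g": float(s.intercept),
                    "slope_kJ_g_per_g": float(s.slope),
                    "w_lo_g": float(s.w_lo),
                    "w_hi_g": None if math.isinf(s.w_hi) else float(s.w_hi),
                }
                for s in self.segments
            ],
            "breakpoint_g": None if self.breakpoint is None else float(self.breakpoint),
        }
        if self.breakpoint_ci is not None:
            d["breakpoint_ci_g"] = [float(v) for v in self.breakpoint_ci]
        if self.valid_range is not None:
            d["valid_range_g"] = [float(v) for v in self.valid_range]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyDensityModel":
        segs = tuple(
            EDSegment(
                intercept=float(s["intercept_kJ_g"]),
                slope=float(s["slope_kJ_g_per_g"]),
                w_lo=float(s["w_lo_g"]),
                w_hi=math.inf if s["w_hi_g"] is None else float(s["w_hi_g"]),
            )
            for s in d["segments"]
        )
        bp = d.get("breakpoint_g")
        ci = d.get("breakpoint_ci_g")
        vr = d.get("valid_range_g")
        return cls(
            segments=segs,
            breakpoint=None if bp is None else float(bp),
            breakpoint_ci=None if ci is None else (float(ci[0]), float(ci[1])),
            valid_range=None if vr is None else (float(vr[0]), float(vr[1])),
        )


def two_segment_model(
    intercept1: float,
    slope1: float,
    intercept2: float,
    slope2: float,
    breakpoint: float,
    **kwargs,
) -> EnergyDensityModel:
    """Convenience constructor for a one-breakpoint model."""
    return EnergyDensityModel(
        segments=(
            EDSegment(intercept1, slope1, 0.0, breakpoint),
            EDSegment(intercept2, slope2, breakpoint, math.inf),
        ),
        breakpoint=breakpoint,
        **kwargs,
    )


def default_models() -> dict[str, EnergyDensityModel]:
    """The packaged Lake Ontario energy-density models.

    Lake trout: two segments with a juvenile/adult transition at 1627 g
    (juvenile ED = 2.21 + 0.00328 W; adult ED = 6.74 + 0.000501 W), valid to
    8000 g.  Chinook salmon: a single segment ED = 6.11 + 0.0000983 W, valid
    for 200-15,000 g fish.
    """
    lake_trout = two_segment_model(
        2.21, 0.00328, 6.74, 0.000501, 1627.0, valid_range=(0.0, 8000.0)
    )
    chinook = EnergyDensityModel(
        segments=(EDSegment(6.11, 0.0000983, 0.0, math.inf),),
        valid_range=(200.0, 15000.0),
    )
    return {"lake_trout": lake_trout, "chinook_salmon": chinook}


# ---------------------------------------------------------------------------
# Lipid -> energy conversions

def lipid_energy_brody(lipid_fraction: float) -> float:
    """Energy density (kJ/g) from a lipid fraction via the 39.5 kJ/g constant."""
    if not 0.0 <= lipid_fraction <= 1.0:
        raise DomainError(f"lipid fraction must lie in [0, 1], got {lipid_fraction}")
    return BRODY_KJ_PER_G_LIPID * lipid_fraction


def lipid_energy_trudel(lipid_mg_g: float) -> float:
    """Energy density (kJ/g) from whole-body lipids (mg/g wet weight):
    ED = 3.60 + 0.047 * lipid."""
    if lipid_mg_g < 0:
        raise DomainError(f"lipid must be non-negative, got {lipid_mg_g}")
    return 3.60 + 0.047 * lipid_mg_g


def calorimetry_scale(
    estimates: Sequence[float], reference: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Rescale lipid-based ED estimates onto a calorimetry reference.

    The percent difference of the means, 100 * (mean(ref) - mean(est)) /
    mean(est), is applied multiplicatively to every estimate, so the scaled
    mean matches the reference mean exactly.  Returns (scaled, scale_pct).
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.size == 0 or ref.size == 0:
        raise DomainError("estimates and reference must be non-empty")
    if (est <= 0).any() or (ref <= 0).any():
        raise DomainError("energy densities must be positive")
    scale_pct = 100.0 * (ref.mean() - est.mean()) / est.mean()
    return est * (1.0 + scale_pct / 100.0), scale_pct


# ---------------------------------------------------------------------------
# Piecewise-linear breakpoint regression

def _prefix_rss(x: np.ndarray, y: np.ndarray):
    """Residual sums of squares of per-side OLS lines for every split of the
    sorted data, computed in O(n) with prefix sums.

    Returns (rss_left[i], rss_right[i]) where the left side is x[:i+1] and
    the right side x[i+1:], plus the single-line RSS over all points.
    """
    n = x.size
    cx = np.cumsum(x)
    cy = np.cumsum(y)
    cxx = np.cumsum(x * x)
    cxy = np.cumsum(x * y)
    cyy = np.cumsum(y * y)

    def side_rss(sx, sy, sxx, sxy, syy, m):
        sxx_c = sxx - sx * sx / m
        sxy_c = sxy - sx * sy / m
        syy_c = syy - sy * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = syy_c - np.where(sxx_c > 0, sxy_c * sxy_c / np.where(sxx_c > 0, sxx_c, 1.0), 0.0)
        return np.maximum(rss, 0.0)

    idx = np.arange(1, n + 1, dtype=float)
    rss_l = side_rss(cx, cy, cxx, cxy, cyy, idx)
    tot = (cx[-1], cy[-1], cxx[-1], cxy[-1], cyy[-1])
    m_r = n - idx
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_r = side_rss(
            tot[0] - cx, tot[1] - cy, tot[2] - cxx, tot[3] - cxy, tot[4] - cyy,
            np.where(m_r > 0, m_r, 1.0),
        )
    rss_single = float(side_rss(*(np.array([v]) for v in tot), np.array([float(n)]))[0])
    return rss_l, rss_r, rss_single


def _profile_breakpoint(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Best split of sorted (x, y): returns (breakpoint, piecewise RSS).

    Candidates are the distinct observed weights between the 5th and 95th
    weight percentiles, with at least two points on each side.
    """
    n = x.size
    rss_l, rss_r, _ = _prefix_rss(x, y)
    lo, hi = np.percentile(x, [5.0, 95.0])
    i = np.arange(n - 1)
    ok = (
        (x[i] >= lo)
        & (x[i] <= hi)
        & (x[i] < x[i + 1])  # split between distinct values
        & (i + 1 >= 2)
        & (n - i - 1 >= 2)
    )
    cand = i[ok]
    if cand.size == 0:
        raise FitError("no admissible breakpoint candidates (degenerate weight grid)")
    total = rss_l[cand] + rss_r[cand]
    best = cand[int(np.argmin(total))]
    return float(x[best]), float(total[np.argmin(total)])


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (intercept, slope)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise FitError("cannot fit a line: zero weight variance")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    return ym - slope * xm, slope


@dataclass(frozen=True)
class PiecewiseFit:
    """Result of :func:`fit_piecewise`."""

    model: EnergyDensityModel
    breakpoint: float | None
    breakpoint_ci: tuple[float, float] | None
    f_stat: float
    f_pvalue: float
    rss_single: float
    rss_piecewise: float
    n: int
    significant: bool


def fit_piecewise(
    weights: Sequence[float],
    eds: Sequence[float],
    iterations: int = 1000,
    alpha: float = 0.001,
    rng: np.random.Generator | int | None = None,
) -> PiecewiseFit:
    """Fit a piecewise-linear ED-vs-weight model with a profiled breakpoint.

    Every distinct observed weight between the 5th and 95th percentiles is a
    breakpoint candidate; for each, the two sides are fit by free (not
    continuity-constrained) least squares and the candidate minimising the
    total RSS wins.  A pairs bootstrap (``iterations`` resamples) yields the
    (1 - alpha) percentile interval for the breakpoint, and an F-style
    comparison against the single-line fit decides at level ``alpha``
    whether the break is kept.  Without a significant break the returned
    model is the single line and ``breakpoint`` is None.
    """
    x = np.asarray(weights, dtype=float)
    y = np.asarray(eds, dtype=float)
    if x.size != y.size:
        raise DomainError("weights and eds must have equal length")
    if x.size < 10:
        raise DomainError(f"need at least 10 points, got {x.size}")
    if iterations < 1:
        raise DomainError("iterations must be >= 1")
    if np.ptp(x) == 0:
        raise FitError("all weights identical: breakpoint grid is degenerate")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    bp, rss_pw = _profile_breakpoint(xs, ys)
    _, _, rss_single = _prefix_rss(xs, ys)
    n = xs.size
    vr = (float(xs.min()), float(xs.max()))

    # F-style comparison: the piecewise model spends 2 extra parameters
    # (second intercept and slope) beyond the single line.
    df2 = n - 4
    if rss_pw <= 0 or df2 <= 0:
        # perfect piecewise fit: a real break iff the single line leaves residue
        significant = rss_single > max(1e-12, 1e-12 * float(np.dot(ys, ys)))
        f_stat, f_pvalue = math.inf if significant else 0.0, 0.0 if significant else 1.0
    else:
        f_stat = ((rss_single - rss_pw) / 2.0) / (rss_pw / df2)
        f_pvalue = float(stats.f.sf(f_stat, 2, df2))
        significant = f_pvalue < alpha

    if not significant:
        ic, sl = _ols_line(xs, ys)
        model = EnergyDensityModel(
            segments=(EDSegment(ic, sl, 0.0, math.inf),), valid_range=vr
        )
        return PiecewiseFit(
            model, None, None, f_stat, f_pvalue, rss_single, rss_pw, n, False
        )

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    boot = np.empty(iterations)
    for b in range(iterations):
        take = rng.integers(0, n, size=n)
        xb = xs[take]
        yb = ys[take]
        o = np.argsort(xb, kind="stable")
        try:
            boot[b], _ = _profile_breakpoint(xb[o], yb[o])
        except FitError:
            boot[b] = np.nan
    boot = boot[~np.isnan(boot)]
    if boot.size == 0:
        raise FitError("all bootstrap replicates degenerate")
    ci = (
        float(np.percentile(boot, 100.0 * alpha / 2.0)),
        float(np.percentile(boot, 100.0 * (1.0 - alpha / 2.0))),
    )

    left = xs <= bp
    ic1, sl1 = _ols_line(xs[left], ys[left])
    ic2, sl2 = _ols_line(xs[~left], ys[~left])
    model = two_segment_model(
        ic1, sl1, ic2, sl2, bp, breakpoint_ci=ci, valid_range=vr
    )
    return PiecewiseFit(model, bp, ci, f_stat, f_pvalue, rss_single, rss_pw, n, True)
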