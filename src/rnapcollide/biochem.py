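"""Roadblock-efficiency (E_RB) quantification, complex-stability decay
fits, and condition-comparison statistics.

E_RB follows the densitometry convention: background-subtracted roadblock
band over background-subtracted scaffold band, anchored so the low-salt
lane equals 1 and background equals 0, with an optional second
normalisation so a chosen reference condition averages exactly 1 across
replicates.  Complex-stability time courses are normalised between a
-NTP control (fully intact) and a proteinase K control (background) and
fitted with a bi-exponential decay; the half-life is the time at which
the fitted curve reaches half its fitted t=0 value.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "LaneQuant",
    "TitrationSeries",
    "DecayCurve",
    "DecayFit",
    "compute_erb",
    "rescale_titration",
    "normalize_erb",
    "fraction_intact",
    "fit_biexponential",
    "compare_conditions",
]


@dataclasses.dataclass(frozen=True)
class LaneQuant:
    condition: str
    salt_mM: float
    roadblock_intensity: float
    scaffold_intensity: float
    background: float = 0.0

    def __post_init__(self) -> None:
        for name in ("roadblock_intensity", "scaffold_intensity", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclasses.dataclass(frozen=True)
class TitrationSeries:
    lanes: tuple[LaneQuant, ...]
    anchor_salt: float = 50.0  # mM; lane whose E_RB is defined as 1
    readout_salt: float = 300.0  # mM; lane used for cross-condition comparison

    def __post_init__(self) -> None:
        object.__setattr__(self, "lanes", tuple(self.lanes))
        if not any(lane.salt_mM == self.anchor_salt for lane in self.lanes):
            raise ValueError(f"no lane at anchor salt {self.anchor_salt} mM")


@dataclasses.dataclass(frozen=True)
class DecayCurve:
    timepoints: np.ndarray  # minutes, strictly increasing
    signal: np.ndarray  # arbitrary units
    no_ntp_control: float  # 100% intact
    pk_control: float  # background

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("timepoints and signal must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not self.no_ntp_control > self.pk_control:
            raise ValueError("-NTP control must exceed proteinase K control")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "signal", y)


@dataclasses.dataclass(frozen=True)
class DecayFit:
    a1: float
    a2: float
    k1: float  # min^-1, fast
    k2: float  # min^-1, slow
    half_life: float  # minutes
    ci95: tuple[float, float]  # minutes
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (self.k1 >= self.k2 >= 0):
            raise ValueError("rates must satisfy k1 >= k2 >= 0")
        if self.half_life <= 0:
            raise ValueError("half-life must be positive")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-self.k1 * t) + self.a2 * np.exp(-self.k2 * t)


def compute_erb(lane: LaneQuant) -> float:
    """Raw roadblock ratio: (roadblock - background) / (scaffold - background)."""
    denom = lane.scaffold_intensity - lane.background
    if denom <= 0:
        raise ValueError(
            f"lane {lane.condition!r} at {lane.salt_mM} mM: "
            "scaffold intensity does not exceed background"
        )
    return max(0.0, (lane.roadblock_intensity - lane.background) / denom)


def rescale_titration(series: TitrationSeries) -> list[tuple[float, float]]:
    """Per-lane (salt_mM, E_RB), anchored so the anchor-salt lane equals 1."""
    anchor = next(l for l in series.lanes if l.salt_mM == series.anchor_salt)
    anchor_ratio = compute_erb(anchor)
    if anchor_ratio <= 0:
        raise ValueError("anchor lane raw ratio must be positive")
    return [(lane.salt_mM, compute_erb(lane) / anchor_ratio) for lane in series.lanes]


def normalize_erb(
    values: Mapping[str, Sequence[float]], reference_condition: str
) -> dict[str, tuple[float, float]]:
    """Normalise replicate E_RB values so the reference-condition mean is 1.

    Returns per-condition (mean, SD) of the normalised replicates; SD is
    the sample standard deviation (ddof=1), or 0 for singletons.
    """
    if reference_condition not in values:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref = np.asarray(values[reference_condition], dtype=float)
    if ref.size == 0 or ref.mean() <= 0:
        raise ValueError("reference condition mean must be positive")
    scale = ref.mean()
    out: dict[str, tuple[float, float]] = {}
    for cond, reps in values.items():
        arr = np.asarray(reps, dtype=float) / scale
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[cond] = (float(arr.mean()), sd)
    return out


def fraction_intact(curve: DecayCurve) -> np.ndarray:
    """Signal normalised between the -NTP (1) and proteinase K (0) controls.

    Values are clipped to [0, 1]; clipping is logged, never silent.
    """
    frac = (curve.signal - curve.pk_control) / (curve.no_ntp_control - curve.pk_control)
    n_clip = int(np.sum((frac < 0) | (frac > 1)))
    if n_clip:
        logger.warning(
            "fraction_intact: clipped %d of %d points to [0, 1]", n_clip, frac.size
        )
    return np.clip(frac, 0.0, 1.0)


def _biexp(t: np.ndarray, a1: float, a2: float, k2: float, dk: float) -> np.ndarray:
    # parametrised so that k1 = k2 + dk >= k2 for any non-negative dk
    return a1 * np.exp(-(k2 + dk) * t) + a2 * np.exp(-k2 * t)


def _fit_once(
    t: np.ndarray, y: np.ndarray, p0: np.ndarray
) -> tuple[np.ndarray, float]:
    res = optimize.least_squares(
        lambda p: _biexp(t, *p) - y,
        p0,
        bounds=(np.zeros(4), np.full(4, np.inf)),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    return res.x, float(np.sum(res.fun**2))


def _half_life(a1: float, a2: float, k1: float, k2: float) -> float:
    """Time at which a1 e^{-k1 t} + a2 e^{-k2 t} falls to half its t=0 value."""
    y0 = a1 + a2
    if y0 <= 0 or (k1 <= 0 and k2 <= 0):
        raise ValueError("curve does not decay; half-life undefined")
    f = lambda t: a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) - 0.5 * y0
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("half-life beyond numerical range")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12))


def fit_biexponential(
    timepoints: Sequence[float],
    fractions: Sequence[float],
    seed: int = 0,
    n_starts: int = 8,
    n_boot: int = 1000,
) -> DecayFit:
    """Least-squares bi-exponential fit with multi-start and bootstrap CI.

    Fits ``a1 exp(-k1 t) + a2 exp(-k2 t)`` with a1, a2 >= 0 and
    k1 >= k2 >= 0, starting from a deterministic spread of initial rates
    plus seeded random restarts.  The 95% CI of the half-life comes from a
    parametric bootstrap: residual-sized Gaussian noise is added to the
    fitted curve and the fit repeated ``n_boot`` times.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 timepoints")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    t_scale = max(t[-1], 1e-9)
    y0 = max(y[0], 1e-3)
    starts = [
        np.array([0.5 * y0, 0.5 * y0, 0.1 / t_scale, 5.0 / t_scale]),
        np.array([0.8 * y0, 0.2 * y0, 0.01 / t_scale, 1.0 / t_scale]),
        np.array([0.2 * y0, 0.8 * y0, 1.0 / t_scale, 10.0 / t_scale]),
        np.array([y0, 1e-3, 0.0, 1.0 / t_scale]),
    ]
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    y0 * rng.uniform(0.1, 1.0),
                    y0 * rng.uniform(0.0, 1.0),
                    rng.uniform(0.0, 2.0) / t_scale,
                    rng.uniform(0.1, 20.0) / t_scale,
                ]
            )
        )

    best: tuple[np.ndarray, float] | None = None
    failures: list[str] = []
    for p0 in starts:
        try:
            p, cost = _fit_once(t, y, p0)
        except Exception as exc:  # pragma: no cover - optimiser edge cases
            failures.append(str(exc))
            continue
        if best is None or cost < best[1]:
            best = (p, cost)
    if best is None:
        raise RuntimeError(f"bi-exponential fit failed for all starts: {failures}")

    p, cost = best
    a1, a2, k2, dk = (float(v) for v in p)
    k1 = k2 + dk
    # equal rates are a single exponential in disguise: merge so the second
    # component is genuinely absent rather than an arbitrary split
    if dk <= 1e-6 * max(k1, 1e-12):
        a1, a2, k1, k2 = a1 + a2, 0.0, k1, 0.0
    half = _half_life(a1, a2, k1, k2)
    dof = max(t.size - 4, 1)
    resid_sd = float(np.sqrt(cost / dof))

    # parametric bootstrap on the half-life; the noise scale itself is
    # uncertain (estimated from few residual degrees of freedom), so each
    # replicate draws its sigma from the scaled inverse-chi-square sampling
    # distribution of the residual SD rather than treating it as known
    fitted = _biexp(t, *p)
    halves = []
    for _ in range(n_boot):
        sigma_b = resid_sd * np.sqrt(dof / rng.chisquare(dof))
        yb = np.clip(fitted + rng.normal(0.0, sigma_b, size=t.size), 0.0, 1.0)
        try:
            pb, _ = _fit_once(t, yb, p)
            halves.append(_half_life(pb[0], pb[1], pb[2] + pb[3], pb[2]))
        except Exception:
            continue
    if len(halves) >= max(10, n_boot // 2):
        lo, hi = np.percentile(halves, [2.5, 97.5])
    else:
        lo, hi = half, half
    return DecayFit(
        a1=float(a1),
        a2=float(a2),
        k1=float(k1),
        k2=float(k2),
        half_life=half,
        ci95=(float(lo), float(hi)),
        residual_sd=resid_sd,
    )


def compare_conditions(
    groups: Mapping[str, Sequence[float]],
    correct: bool = True,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[dict]:
    """Welch t-tests (two-tailed, unpaired) across condition pairs.

    ``pairs`` defaults to all unordered pairs in mapping order.  When
    ``correct`` is true, Benjamini-Hochberg adjustment is applied across
    the requested pairs.
    """
    labels = list(groups)
    if pairs is None:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    results = []
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("each group needs at least 2 values")
        tt = stats.ttest_ind(x, y, equal_var=False)
        results.append(
            {
                "pair": (a, b),
                "t": float(tt.statistic),
                "df": float(tt.df),
                "p": float(tt.pvalue),
            }
        )
    if correct and results:
        raw = [r["p"] for r in results]
        adj = multipletests(raw, method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r["p_adjusted"] = float(q)
    else:
        for r in results:
            r["p_adjusted"] = r["p"]
    return results
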