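"""Cohort selection by a hyperbolic quantile isopleth, and subphenotyping.

Because roughly 40% of low HDL-C is secondary to hypertriglyceridemia, a raw
HDL-C percentile cutoff over-selects hypertriglyceridemic subjects.  The
selection instead uses a quantile *isopleth* in the (TG, HDL-C) plane: a curve
``y = m1 + (m2*m3)/(m2 + x)`` (y HDL-C, x TG, constants m1/m2/m3 in mg/dl)
fitted so that a fraction ``q`` of the reference population lies below it,
honouring the hyperbolic inverse TG-HDL-C relationship.  Subjects strictly
below the fitted curve are selected.

Selected subjects are then partitioned into four dyslipidemia subphenotypes by
TG >= 150 mg/dl (NCEP ATP III hypertriglyceridemia) and LDL-C >= 160 mg/dl:

    group 1  isolated low HDL-C          (TG < 150, LDL < 160)
    group 2  low HDL-C + high LDL-C      (TG < 150, LDL >= 160)
    group 3  low HDL-C + high TG         (TG >= 150, LDL < 160)
    group 4  low HDL-C + combined        (TG >= 150, LDL >= 160)

Group summaries use Welch t-tests on transformed lipids (log for BMI/TC/TG,
square root for LDL-C) and Fisher's exact test for categorical variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .records import Participant

logger = logging.getLogger(__name__)

TG_HIGH_CUTOFF = 150.0  # mg/dl, NCEP ATP III
LDL_HIGH_CUTOFF = 160.0  # mg/dl, adult
FRIEDEWALD_TG_LIMIT = 400.0  # mg/dl; the estimate is invalid at or above this

#: transform applied to each continuous variable before t-testing
VARIABLE_TRANSFORMS = {
    "age": "none",
    "hdl": "none",
    "tc": "log",
    "ldl": "sqrt",
    "tg": "log",
    "bmi": "log",
    "prebeta_hdl": "none",
}


def friedewald_ldl(tc: float, hdl: float, tg: float) -> Optional[float]:
    """LDL-C estimate TC - HDL-C - TG/5 (mg/dl), or None when TG >= 400.

    The estimate assumes a fixed VLDL cholesterol:TG ratio of 1:5, which
    breaks down at high triglyceride levels.
    """
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError(f"lipid inputs must be >= 0, got ({tc}, {hdl}, {tg})")
    if tg >= FRIEDEWALD_TG_LIMIT:
        return None
    return tc - hdl - tg / 5.0


@dataclass
class IsoplethModel:
    """Fitted hyperbolic quantile curve ``y = m1 + m2*m3/(m2 + x)``."""

    m1: float
    m2: float
    m3: float
    q: float

    def __post_init__(self) -> None:
        if self.m2 <= 0:
            raise ValueError(f"m2 must be positive, got {self.m2}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"quantile level must be in (0,1), got {self.q}")

    def threshold(self, tg: float | np.ndarray) -> float | np.ndarray:
        return self.m1 + self.m2 * self.m3 / (self.m2 + tg)


def _hyperbola(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    m1, log_m2, m3 = params
    m2 = np.exp(log_m2)
    return m1 + m2 * m3 / (m2 + x)


def _pinball_loss(params: np.ndarray, x: np.ndarray, y: np.ndarray, q: float) -> float:
    r = y - _hyperbola(params, x)
    return float(np.sum(np.where(r >= 0, q * r, (q - 1.0) * r)))


def fit_isopleth(
    points: Sequence[tuple[float, float]] | np.ndarray, q: float
) -> IsoplethModel:
    """Fit the hyperbola so that ~q of (TG, HDL-C) points lie below it.

    The fit minimizes the pinball (quantile) loss at level ``q`` over
    (m1, m2, m3) with m2 constrained positive.  A nonlinear least-squares fit
    of the mean curve, shifted by the empirical q-quantile of its residuals,
    seeds a Nelder-Mead polish of the nonsmooth pinball objective from several
    starts.

    Raises ``ValueError`` for fewer than 30 points, for a degenerate cloud
    with all TG equal (m2 unidentifiable), or q outside (0,1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (tg, hdl) pairs")
    if len(pts) < 30:
        raise ValueError(f"need >= 30 points to fit an isopleth, got {len(pts)}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level must be in (0,1), got {q}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all TG values equal: m2 is unidentifiable")

    # Least-squares fit of the mean curve for initialization.  On noiseless
    # data this already recovers the generating constants.
    y_spread = max(np.ptp(y), 1.0)
    starts = []
    for m2_0 in (np.median(x) + 1.0, 50.0, 200.0):
        starts.append(np.array([np.min(y), np.log(m2_0), y_spread]))
    best_ls = None
    for s0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: y - _hyperbola(p, x), s0, xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:  # pragma: no cover - optimizer edge failure
            continue
        if best_ls is None or res.cost < best_ls.cost:
            best_ls = res
    if best_ls is None:  # pragma: no cover
        raise RuntimeError("least-squares initialization failed")

    ls_params = best_ls.x
    loss0 = _pinball_loss(ls_params, x, y, q)
    if loss0 <= 1e-10 * len(x):
        # Noiseless data exactly on one family member: the LS solution is the
        # quantile curve for every q; polishing a zero loss only adds noise.
        m1, log_m2, m3 = ls_params
        return IsoplethModel(m1=float(m1), m2=float(np.exp(log_m2)), m3=float(m3), q=q)

    # Shift the mean curve down/up to the residual q-quantile: a near-optimal
    # pinball start when noise is roughly level-independent.
    resid_q = np.quantile(y - _hyperbola(ls_params, x), q)
    seeds = [
        ls_params + np.array([resid_q, 0.0, 0.0]),
        ls_params,
        ls_params + np.array([resid_q, 0.3, 0.0]),
        ls_params + np.array([resid_q, -0.3, 0.0]),
    ]
    best = None
    for s0 in seeds:
        res = optimize.minimize(
            _pinball_loss,
            s0,
            args=(x, y, q),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    m1, log_m2, m3 = best.x
    return IsoplethModel(m1=float(m1), m2=float(np.exp(log_m2)), m3=float(m3), q=q)


def select_below_isopleth(
    participants: Iterable[Participant], model: IsoplethModel
) -> list[Participant]:
    """Participants with HDL-C strictly below the fitted curve at their TG.

    Records exactly on the curve are *not* selected (selection is "below" the
    percentile isopleth).  Participants missing TG or HDL-C are excluded with
    a logged warning rather than an error.
    """
    selected = []
    for p in participants:
        if p.tg is None or p.hdl is None:
            logger.warning("participant %s missing TG or HDL-C; excluded from selection", p.pid)
            continue
        if p.hdl < model.threshold(p.tg):
            selected.append(p)
    return selected


def assign_subphenotype(
    p: Participant,
    pediatric_ldl_cutoff: Optional[Callable[[Participant], float]] = None,
) -> Optional[int]:
    """Dyslipidemia group 1-4 from TG and LDL-C cutoffs; None if unassignable.

    LDL-C is taken from the record or, failing that, computed by Friedewald
    from TC/HDL-C/TG.  Under age 18 a caller-supplied sex/age percentile
    lookup may replace the adult 160 mg/dl cutoff; without one the adult
    cutoff applies (with a logged notice).
    """
    if p.tg is None:
        raise ValueError(f"participant {p.pid} has no TG; cannot assign subphenotype")
    ldl = p.ldl
    if ldl is None and p.tc is not None and p.hdl is not None:
        ldl = friedewald_ldl(p.tc, p.hdl, p.tg)
    if ldl is None:
        logger.warning("participant %s has no usable LDL-C; subphenotype unassigned", p.pid)
        return None
    ldl_cutoff = LDL_HIGH_CUTOFF
    if p.age < 18:
        if pediatric_ldl_cutoff is not None:
            ldl_cutoff = pediatric_ldl_cutoff(p)
        else:
            logger.info(
                "participant %s is under 18; applying adult LDL-C cutoff %g",
                p.pid,
                LDL_HIGH_CUTOFF,
            )
    high_tg = p.tg >= TG_HIGH_CUTOFF
    high_ldl = ldl >= ldl_cutoff
    return 1 + (2 if high_tg else 0) + (1 if high_ldl else 0)


def compare_distributions(
    a: Sequence[float], b: Sequence[float], transform: str = "none"
) -> float:
    """Two-sided Welch t-test p-value on transformed samples.

    ``transform`` is one of ``none``, ``log`` or ``sqrt``.  Skewed lipid
    variables are transformed before testing (log for BMI/TC/TG, sqrt for
    LDL-C).  Identical samples return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations for a t-test")
    if transform == "log":
        for name, arr in (("a", a), ("b", b)):
            if np.any(arr <= 0):
                idx = int(np.argmax(arr <= 0))
                raise ValueError(
                    f"log transform requires positive values; sample {name} "
                    f"element {idx} is {arr[idx]}"
                )
        a, b = np.log(a), np.log(b)
    elif transform == "sqrt":
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("sqrt transform requires non-negative values")
        a, b = np.sqrt(a), np.sqrt(b)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    se = np.sqrt(np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b))
    if se == 0:
        # degenerate: both samples constant
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # pragma: no cover - guarded by the se check above
        return 1.0
    return float(p)


def fisher_exact_2x2(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Fisher's exact p for a 2x2 count table (categorical comparisons)."""
    _, p = stats.fisher_exact(np.asarray(table, dtype=int), alternative=alternative)
    return float(p)


def summarize_groups(participants: Sequence[Participant]) -> pd.DataFrame:
    """Per-subphenotype summary table with comparisons against group 1.

    One row per group: n, percent of cohort (1 d.p.), female %, mean and sd of
    age/HDL-C/TC/LDL-C/TG/prebeta-HDL, and p-values versus group 1 (Welch
    t-test on transformed values; Fisher's exact for the sex split).  Means
    use per-variable complete-case denominators.  Empty groups get an n = 0
    row and no tests.
    """
    assigned = [p for p in participants if p.group is not None]
    if not assigned:
        raise ValueError("no participants with an assigned subphenotype group")
    total = len(assigned)
    by_group = {g: [p for p in assigned if p.group == g] for g in (1, 2, 3, 4)}
    variables = ["age", "hdl", "tc", "ldl", "tg", "prebeta_hdl"]

    def values(group: list[Participant], var: str) -> np.ndarray:
        vals = [getattr(p, var) for p in group]
        return np.array([v for v in vals if v is not None], dtype=float)

    rows = []
    ref = by_group[1]
    for g in (1, 2, 3, 4):
        members = by_group[g]
        row: dict[str, object] = {
            "group": g,
            "n": len(members),
            "percent": round(100.0 * len(members) / total, 1),
        }
        if members:
            n_female = sum(1 for p in members if p.sex == "F")
            row["female_percent"] = round(100.0 * n_female / len(members), 1)
        for var in variables:
            vals = values(members, var)
            row[f"{var}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{var}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        if g != 1 and members and ref:
            for var in variables:
                va, vb = values(ref, var), values(members, var)
                if len(va) >= 2 and len(vb) >= 2:
                    row[f"{var}_p"] = compare_distributions(
                        va, vb, VARIABLE_TRANSFORMS[var]
                    )
            ref_f = sum(1 for p in ref if p.sex == "F")
            mem_f = sum(1 for p in members if p.sex == "F")
            row["sex_p"] = fisher_exact_2x2(
                [[ref_f, len(ref) - ref_f], [mem_f, len(members) - mem_f]]
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
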