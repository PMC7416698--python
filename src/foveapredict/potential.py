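"""Treatment potential: prediction minus measurement, ETDRS-line arithmetic
and genotype-group comparisons."""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

Target = Literal["FS", "VA"]
Method = Literal["I", "II", "CF"]

#: Standard ETDRS chart denominators for "20/D" notation.
CHART_DENOMS = (10.0, 12.5, 16.0, 20.0, 25.0, 32.0, 40.0, 50.0, 63.0, 80.0,
                100.0, 125.0, 160.0, 200.0)

#: dB of sensitivity per log unit.
DB_PER_LOG_UNIT = 10.0


@dataclass
class TreatmentPotential:
    """Predicted-minus-measured functional gain for one subject and method.

    For FS, ``delta`` is in dB (``delta / 10`` gives log units) and a
    non-detectable measurement is floored at ``nd_floor_db`` before the
    subtraction.  For VA, ``delta`` is decimal and ``delta_logmar`` is the
    gain on the logMAR scale (positive = improvement).
    """

    subject_id: str
    target: Target
    method: Method
    measured: float | None
    measured_floored: float
    predicted_value: float
    half_width: float
    delta: float
    delta_logmar: float | None = None
    lines_gained: int | None = None
    snellen_predicted: str | None = None


def decimal_to_logmar(va: float) -> float:
    """logMAR = -log10(decimal acuity)."""
    if va <= 0:
        raise ValueError("decimal VA must be positive")
    return -math.log10(va)


def _round_to_chart_line(logmar: float) -> float:
    """Round a logMAR value to the nearest 0.1 chart line; half-grid ties
    round toward better acuity (lower logMAR)."""
    return math.floor(logmar * 10.0 + 0.5 - 1e-9) / 10.0


def etdrs_lines_gained(va_measured: float, va_predicted: float) -> int:
    """Lines gained on the ETDRS chart grid.

    Both acuities are converted to logMAR and rounded to the nearest 0.1
    (one chart line); the result is ``10 * (rounded measured - rounded
    predicted)``, positive when the prediction is better.
    """
    if va_measured <= 0 or va_predicted <= 0:
        raise ValueError("acuities must be positive")
    m = _round_to_chart_line(decimal_to_logmar(va_measured))
    p = _round_to_chart_line(decimal_to_logmar(va_predicted))
    return int(round(10.0 * (m - p)))


def nearest_chart_line(va: float) -> str:
    """Snellen "20/D" string for the chart line nearest to ``va``.

    Rounds logMAR to the 0.1 grid and snaps ``20 * 10**logmar`` to the
    standard denominators; outside the chart range the raw value is flagged.
    """
    if va <= 0:
        raise ValueError("decimal VA must be positive")
    logmar = _round_to_chart_line(decimal_to_logmar(va))
    denom = 20.0 * 10.0**logmar
    lo, hi = min(CHART_DENOMS), max(CHART_DENOMS)
    if denom < lo - 1e-9 or denom > hi + 1e-9:
        return f"20/{denom:g} (off-chart)"
    best = min(CHART_DENOMS, key=lambda d: abs(d - denom))
    return f"20/{best:g}"


def treatment_potential(
    measured: float | None,
    predicted,
    target: Target,
    method: Method = "CF",
    subject_id: str = "",
    nd_floor_db: float = 0.0,
) -> TreatmentPotential:
    """Compute predicted-minus-measured treatment potential.

    ``measured`` may be None (non-detectable) for FS only: it is floored at
    ``nd_floor_db`` exactly once, before the subtraction.  For VA the delta is
    computed on the logMAR scale as well as in decimal.  ``predicted`` is a
    :class:`~foveapredict.prediction.Prediction`.
    """
    if target not in ("FS", "VA"):
        raise ValueError(f"unknown target {target!r}")
    if target == "VA":
        if measured is None:
            raise ValueError("non-detectable VA is not defined")
        if measured <= 0:
            raise ValueError("measured VA must be positive")
        delta = predicted.value - measured
        if predicted.value > 0:
            delta_logmar = decimal_to_logmar(measured) - decimal_to_logmar(predicted.value)
            lines = etdrs_lines_gained(measured, predicted.value)
            snellen = nearest_chart_line(predicted.value)
        else:
            warnings.warn(
                f"predicted VA {predicted.value:.3f} not positive; logMAR delta undefined",
                stacklevel=2,
            )
            delta_logmar, lines, snellen = None, None, None
        return TreatmentPotential(
            subject_id=subject_id, target=target, method=method,
            measured=measured, measured_floored=measured,
            predicted_value=predicted.value, half_width=predicted.half_width,
            delta=delta, delta_logmar=delta_logmar,
            lines_gained=lines, snellen_predicted=snellen,
        )

    # FS
    floored = nd_floor_db if measured is None else measured
    delta = predicted.value - floored
    return TreatmentPotential(
        subject_id=subject_id, target=target, method=method,
        measured=measured, measured_floored=floored,
        predicted_value=predicted.value, half_width=predicted.half_width,
        delta=delta,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis from the rank formula
# ---------------------------------------------------------------------------

def _ranks_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    """Mid-ranks of ``pooled`` and the tie-correction factor
    ``1 - sum(t^3 - t) / (N^3 - N)``."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    tie_sum = 0.0
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        t = j - i + 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        tie_sum += t**3 - t
        i = j + 1
    N = pooled.size
    correction = 1.0 - tie_sum / (N**3 - N) if N > 1 else 1.0
    return ranks, correction


def kruskal_wallis_h(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction, implemented from the rank
    formula, and its chi-square p-value (df = k - 1).

    When every observation ties, H is defined as 0 and p as 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if g.size == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(gs)
    N = pooled.size
    ranks, correction = _ranks_with_ties(pooled)
    if correction <= 0:  # all observations tied
        return 0.0, 1.0
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (N + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (N * (N + 1))
    h /= correction
    p = float(chi2.sf(h, len(gs) - 1))
    return float(h), p


def kruskal_wallis_permutation_p(
    groups: Sequence[Sequence[float]],
    n_perm: int = 2000,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """Permutation p-value for the Kruskal-Wallis H statistic.

    ``exhaustive=True`` enumerates every distinct assignment of the pooled
    values to the group sizes (feasible only for tiny N); otherwise ``n_perm``
    seeded random permutations are used.  The observed assignment counts
    toward the null distribution (p is never 0).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    sizes = [g.size for g in gs]
    pooled = np.concatenate(gs)
    h_obs, _ = kruskal_wallis_h(gs)

    def h_of(perm: np.ndarray) -> float:
        parts, start = [], 0
        for s in sizes:
            parts.append(perm[start : start + s])
            start += s
        return kruskal_wallis_h(parts)[0]

    tol = 1e-9
    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(pooled):
            total += 1
            if h_of(np.asarray(perm)) >= h_obs - tol:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        if h_of(rng.permutation(pooled)) >= h_obs - tol:
            count += 1
    return count / (n_perm + 1)


def compare_groups(
    potentials: pd.DataFrame,
    value_col: str = "delta",
    group_col: str = "group",
    method_col: str = "method",
    n_perm: int = 2000,
    seed: int = 0,
) -> dict:
    """Per-genotype-group summaries and across-methods Kruskal-Wallis tests.

    ``potentials`` holds one row per (subject, method) with the potential in
    ``value_col``.  Returns per-(group, method) mean/SD/n, one KW test per
    genotype group comparing methods (chi-square and permutation p-values),
    and descriptive pairwise mean differences.
    """
    required = {value_col, group_col, method_col}
    if not required.issubset(potentials.columns):
        raise ValueError(f"potentials must have columns {sorted(required)}")
    groups = list(dict.fromkeys(potentials[group_col]))
    if len(groups) < 1:
        raise ValueError("no groups")

    summary = (
        potentials.groupby([group_col, method_col], sort=False)[value_col]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    tests = []
    for grp, sub in potentials.groupby(group_col, sort=False):
        methods = list(dict.fromkeys(sub[method_col]))
        if len(methods) < 2:
            continue
        samples = [sub.loc[sub[method_col] == m, value_col].to_numpy() for m in methods]
        if any(s.size < 2 for s in samples):
            raise ValueError(f"group {grp}: every method needs n >= 2")
        h, p_chi2 = kruskal_wallis_h(samples)
        p_perm = kruskal_wallis_permutation_p(samples, n_perm=n_perm, seed=seed)
        pairwise = [
            {
                "a": a, "b": b,
                "mean_diff": float(
                    sub.loc[sub[method_col] == a, value_col].mean()
                    - sub.loc[sub[method_col] == b, value_col].mean()
                ),
            }
            for a, b in itertools.combinations(methods, 2)
        ]
        tests.append(
            {
                "group": grp, "methods": methods, "H": h,
                "p_chi2": p_chi2, "p_permutation": p_perm,
                "significant": p_chi2 < 0.05, "pairwise_mean_diffs": pairwise,
            }
        )
    return {"summary": summary, "tests": tests}
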