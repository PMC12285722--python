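"""Retention efficiencies and the test of mutually dependent intron excision.

Given the four-pattern counts of exon-spanning reads, the per-intron retention
efficiencies (marginals) define a Punnett-square expectation: the class
distribution that would arise if the two flanking introns were excised
independently.  Departure from that expectation is quantified by a Pearson
goodness-of-fit statistic with one degree of freedom (four cells minus one
minus two estimated marginals) or by a conditional exact test, together with
the odds ratio of the 2x2 retention table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .read_classification import PatternCounts


class UndefinedEstimateError(ValueError):
    """No informative reads: marginals and the dependence test are undefined."""


class SmallExpectedCountWarning(UserWarning):
    """Some expected cell is below the Pearson validity rule of thumb."""


@dataclass(frozen=True)
class RetentionEstimate:
    """Marginal retention efficiencies of the two flanking introns."""

    p_up: float
    p_down: float
    n_informative: int
    se_up: float
    se_down: float


@dataclass(frozen=True)
class DependenceResult:
    """Dependence of intron co-retention versus the independence expectation.

    ``expected`` is keyed RR/RS/SR/SS and sums to the informative read count.
    """

    expected: dict[str, float]
    statistic: float
    df: int
    p_value: float
    odds_ratio: float
    log_or_se: float
    method: str
    warnings: tuple[str, ...] = field(default=())


def marginal_retention(counts: PatternCounts) -> RetentionEstimate:
    """Per-intron retention efficiencies with binomial standard errors.

    p_up = (RS + RR) / n_informative, p_down = (SR + RR) / n_informative.
    """
    n = counts.n_informative
    if n < 1:
        raise UndefinedEstimateError("no informative reads; marginals undefined")
    p_up = (counts.n_RS + counts.n_RR) / n
    p_down = (counts.n_SR + counts.n_RR) / n
    return RetentionEstimate(
        p_up=p_up,
        p_down=p_down,
        n_informative=n,
        se_up=math.sqrt(p_up * (1 - p_up) / n),
        se_down=math.sqrt(p_down * (1 - p_down) / n),
    )


def expected_under_independence(est: RetentionEstimate) -> dict[str, float]:
    """Punnett-square expected counts under independent excision."""
    n, pu, pd_ = est.n_informative, est.p_up, est.p_down
    return {
        "RR": n * pu * pd_,
        "RS": n * pu * (1 - pd_),
        "SR": n * (1 - pu) * pd_,
        "SS": n * (1 - pu) * (1 - pd_),
    }


def odds_ratio(counts: PatternCounts) -> tuple[float, float]:
    """Co-retention odds ratio (RR*SS)/(RS*SR) and the SE of its log.

    Haldane-Anscombe correction (+0.5 to every cell) is applied iff any cell
    is zero, which also defines the delta-method SE in that case.
    """
    if counts.n_informative < 1:
        raise UndefinedEstimateError("no informative reads; odds ratio undefined")
    cells = [counts.n_RR, counts.n_SS, counts.n_RS, counts.n_SR]
    if min(cells) == 0:
        cells = [c + 0.5 for c in cells]
    rr, ss, rs, sr = cells
    or_ = (rr * ss) / (rs * sr)
    se = math.sqrt(sum(1.0 / c for c in cells))
    return or_, se


def dependence_test(counts: PatternCounts, method: str = "pearson") -> DependenceResult:
    """Test the four observed pattern counts against independent excision.

    method 'pearson': goodness-of-fit chi-square versus the Punnett
    expectation, df = 1.  method 'exact': conditional (Fisher) test on the
    2x2 table {RR, RS; SR, SS}.  With any expected cell below 5 a warning is
    emitted and, for 'pearson', the exact p-value is computed alongside.
    """
    if method not in ("pearson", "exact"):
        raise ValueError(f"unknown method {method!r}")
    est = marginal_retention(counts)
    expected = expected_under_independence(est)
    observed = {
        "RR": counts.n_RR,
        "RS": counts.n_RS,
        "SR": counts.n_SR,
        "SS": counts.n_SS,
    }
    or_, log_or_se = odds_ratio(counts)
    warns: list[str] = []
    small = [k for k, v in expected.items() if v < 5]
    degenerate = any(v == 0 for v in expected.values())

    exact_p = float("nan")
    if method == "exact" or small or degenerate:
        table = np.array([[counts.n_RR, counts.n_RS], [counts.n_SR, counts.n_SS]])
        exact_p = stats.fisher_exact(table, alternative="two-sided")[1]

    if method == "exact":
        return DependenceResult(
            expected=expected,
            statistic=float("nan"),
            df=1,
            p_value=exact_p,
            odds_ratio=or_,
            log_or_se=log_or_se,
            method="exact",
            warnings=tuple(warns),
        )

    if degenerate:
        msg = (
            "an expected cell is exactly 0 (a marginal is 0 or 1); "
            "reporting the exact test instead"
        )
        warnings.warn(msg, SmallExpectedCountWarning, stacklevel=2)
        warns.append(msg)
        return DependenceResult(
            expected=expected,
            statistic=float("nan"),
            df=1,
            p_value=exact_p,
            odds_ratio=or_,
            log_or_se=log_or_se,
            method="exact",
            warnings=tuple(warns),
        )

    statistic = sum(
        (observed[k] - expected[k]) ** 2 / expected[k] for k in ("RR", "RS", "SR", "SS")
    )
    p_value = float(stats.chi2.sf(statistic, df=1))
    if small:
        msg = (
            f"expected cell(s) {','.join(sorted(small))} below 5; exact p-value "
            f"{exact_p:.4g} reported alongside"
        )
        warnings.warn(msg, SmallExpectedCountWarning, stacklevel=2)
        warns.append(msg)
    return DependenceResult(
        expected=expected,
        statistic=float(statistic),
        df=1,
        p_value=p_value,
        odds_ratio=or_,
        log_or_se=log_or_se,
        method="pearson",
        warnings=tuple(warns),
    )


def report(counts: PatternCounts, method: str = "pearson") -> dict:
    """JSON-ready summary: counts, marginals, expectation, test and odds ratio."""
    est = marginal_retention(counts)
    res = dependence_test(counts, method=method)
    return {
        "counts": counts.as_dict(),
        "n_informative": counts.n_informative,
        "marginals": {
            "p_up": est.p_up,
            "p_down": est.p_down,
            "se_up": est.se_up,
            "se_down": est.se_down,
        },
        "expected": res.expected,
        "statistic": None if math.isnan(res.statistic) else res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "odds_ratio": res.odds_ratio,
        "log_or_se": res.log_or_se,
        "method": res.method,
        "warnings": list(res.warnings),
    }
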