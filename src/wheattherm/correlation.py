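"""Index-versus-yield correlation analysis.

For each pairing of an aggregated thermal index (per-variety WSI_m or
WCI_m) with a yield component (grain yield, culm density, spike
density, total biomass) the analysis performs an ordinary least squares
fit y = a + b*x, computes the Pearson coefficient R, and tests R
against zero with a two-tailed Student t-test,

    t = R * sqrt(n - 2) / sqrt(1 - R^2),   df = n - 2.

p-values are reported both numerically and binned into the significance
levels conventionally quoted in field-trial reports (<0.001, <0.005,
<0.01, <0.025, <0.05, N.S.).  No multiple-testing correction is applied
by default, matching standard practice for these small variety panels;
pass holm=True to get Holm-adjusted p-values alongside.

An exact permutation test of R (full enumeration up to n = 9, Monte
Carlo beyond) is provided as an independent check of the t-based
p-values at these small sample sizes.

The modern-variety exclusion re-runs a pairing on the landraces and
mixtures only, dropping the recently bred cultivars; with nine
varieties this leaves n = 7.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, ValidationError
from .frames import YieldTable
from .indices import IndexTable

#: Significance bounds quoted in the study's figures, ascending.
SIGNIFICANCE_BOUNDS = (0.001, 0.005, 0.01, 0.025, 0.05)

YIELD_TARGETS = ("yield", "culms", "spikes", "biomass")
_TARGET_COLUMNS = {"yield": "yield_t_ha", "culms": "culms_m2",
                   "spikes": "spikes_m2", "biomass": "biomass_t_ha"}


def linear_fit(x, y) -> tuple[float, float]:
    """OLS intercept and slope: b = cov(x,y)/var(x), a = mean(y) - b*mean(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("x and y must be equal-length 1-D vectors, n >= 2")
    vx = np.var(x, ddof=1)
    if vx == 0:
        raise DegenerateFitError("cannot fit a line against a constant predictor")
    b = float(np.cov(x, y, ddof=1)[0, 1] / vx)
    a = float(y.mean() - b * x.mean())
    return a, b


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("x and y must be equal-length 1-D vectors, n >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateFitError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def significance_bin(p: float) -> str:
    """Smallest conventional bound exceeding p, or 'N.S.' when p >= 0.05."""
    for bound in SIGNIFICANCE_BOUNDS:
        if p < bound:
            return f"<{bound}"
    return "N.S."


def correlation_significance(r: float, n: int) -> tuple[float, int, float, str]:
    """Two-tailed t-test of a Pearson coefficient against zero.

    Returns (t_stat, df, p_two_tailed, significance_bin).  |r| = 1 gives
    p = 0 exactly (flagged by the infinite t statistic).
    """
    if n < 3:
        raise ValidationError("significance test requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    df = n - 2
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        return t, df, 0.0, significance_bin(0.0)
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p), significance_bin(p)


def permutation_pvalue(x, y, max_exact_n: int = 9, n_resamples: int = 100_000,
                       rng: np.random.Generator | int | None = 0) -> float:
    """Two-sided permutation p-value for the Pearson coefficient.

    All n! pairings are enumerated for n <= max_exact_n; larger samples
    are Monte Carlo sampled (with the +1 correction).  Independent of
    the t-approximation, hence usable as its oracle at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    r_obs = abs(pearson_r(x, y))
    xc = (x - x.mean()) / (x.std() * math.sqrt(n))
    yc = (y - y.mean()) / (y.std() * math.sqrt(n))
    if n <= max_exact_n:
        perms = np.array(list(itertools.permutations(range(n))))
        r_all = np.abs(yc[perms] @ xc)
        return float(np.mean(r_all >= r_obs - 1e-12))
    rng = np.random.default_rng(rng)
    hits = 0
    for _ in range(n_resamples):
        hits += abs(xc @ rng.permutation(yc)) >= r_obs - 1e-12
    return (hits + 1) / (n_resamples + 1)


@dataclass
class CorrelationResult:
    """One index-vs-yield-component pairing: estimates, test, provenance."""

    x_name: str
    y_name: str
    n: int
    a: float
    b: float
    r: float
    t_stat: float
    df: int
    p_two_tailed: float
    significance_bin: str
    excluded: list[str] = field(default_factory=list)
    p_holm: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05

    def as_dict(self) -> dict:
        return {"x": self.x_name, "y": self.y_name, "n": self.n,
                "a": self.a, "b": self.b, "r": self.r, "t": self.t_stat,
                "df": self.df, "p": self.p_two_tailed,
                "bin": self.significance_bin,
                "excluded": ";".join(self.excluded)}

    def summary(self) -> str:
        excl = f", excluding {'+'.join(self.excluded)}" if self.excluded else ""
        return (f"{self.y_name} = {self.a:.3g} + {self.b:.3g} * {self.x_name} "
                f"(n={self.n}{excl}): R={self.r:.3f}, t({self.df})={self.t_stat:.3f}, "
                f"p={self.p_two_tailed:.4g} [{self.significance_bin}]")


def correlate(x, y, x_name: str = "x", y_name: str = "y",
              excluded: list[str] | None = None) -> CorrelationResult:
    """Fit + Pearson + t-test for one (x, y) pairing."""
    a, b = linear_fit(x, y)
    r = pearson_r(x, y)
    t, df, p, bucket = correlation_significance(r, len(np.asarray(x)))
    return CorrelationResult(x_name=x_name, y_name=y_name, n=len(np.asarray(x)),
                             a=a, b=b, r=r, t_stat=t, df=df, p_two_tailed=p,
                             significance_bin=bucket, excluded=excluded or [])


def run_correlation_suite(index_table: IndexTable, yield_table: YieldTable,
                          targets: tuple[str, ...] = YIELD_TARGETS,
                          exclude_modern: bool = False,
                          holm: bool = False) -> list[CorrelationResult]:
    """All (index in {wsi_m, wci_m}) x target pairings for one species.

    With exclude_modern the recently bred cultivars are dropped before
    fitting; the remaining varieties' values are untouched.  Requires at
    least three varieties after exclusion.
    """
    if index_table.species != yield_table.species:
        raise ValidationError("index and yield tables are for different species")
    bad = set(targets) - set(YIELD_TARGETS)
    if bad:
        raise ValidationError(f"unknown yield target(s): {sorted(bad)}")
    ydf = yield_table.data
    varieties = [v for v in index_table.stage_matrix.index if v in ydf.index]
    if set(varieties) != set(index_table.stage_matrix.index):
        raise ValidationError("variety codes do not align between the two tables")
    excluded: list[str] = []
    if exclude_modern:
        excluded = [v for v in varieties if ydf.loc[v, "is_modern"]]
        varieties = [v for v in varieties if v not in excluded]
    if len(varieties) < 3:
        raise ValidationError("fewer than 3 varieties left after exclusion")
    # fixture tables correlate at the published 2-decimal precision;
    # computed tables at full precision
    indices = {"wsi_m": index_table.wsi_m_report, "wci_m": index_table.wci_m}
    results = []
    for index_name, series in indices.items():
        x = series.loc[varieties].to_numpy(dtype=float)
        for target in targets:
            y = ydf.loc[varieties, _TARGET_COLUMNS[target]].to_numpy(dtype=float)
            results.append(correlate(x, y, x_name=index_name, y_name=target,
                                     excluded=excluded))
    if holm:
        order = np.argsort([res.p_two_tailed for res in results])
        m = len(results)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * results[i].p_two_tailed)
            results[i].p_holm = min(1.0, running)
    return results


def suite_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular report of a correlation suite (one row per pairing)."""
    return pd.DataFrame([res.as_dict() for res in results])
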