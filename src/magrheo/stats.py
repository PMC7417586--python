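"""Population statistics for per-bead rheological fits.

Cell stiffness (1/J0) follows a log-normal distribution across a
population, so its average is the geometric mean and group comparisons are
made on the log-transformed values; fluidity (the power-law exponent) is
normally distributed and summarized by the arithmetic mean.  Group
comparisons use Welch's unequal-variance t-test with an explicit Bonferroni
family size, starred at p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleSet", "StiffnessSummary", "FluiditySummary", "ComparisonResult",
    "summarize_stiffness", "summarize_fluidity", "compare_groups",
    "fold_change", "significance_stars",
]


@dataclass
class SampleSet:
    """A labelled group of per-bead measurements.

    ``n`` is the number of beads/cells (list length); ``N`` the number of
    independent experiments the beads came from.
    """

    label: str
    stiffness_pa: np.ndarray
    fluidity: np.ndarray
    N_experiments: int | None = None

    def __post_init__(self):
        self.stiffness_pa = np.asarray(self.stiffness_pa, dtype=float)
        self.fluidity = np.asarray(self.fluidity, dtype=float)
        if np.any(self.stiffness_pa <= 0):
            raise ValueError("stiffness values must be positive")

    @property
    def n(self) -> int:
        return self.stiffness_pa.size


@dataclass(frozen=True)
class StiffnessSummary:
    geometric_mean_pa: float
    error_pa: float               # symmetrized GM * SEM(ln) approximation
    interval_low_pa: float        # asymmetric factor interval exp(mean ± SEM of logs)
    interval_high_pa: float
    n: int


@dataclass(frozen=True)
class FluiditySummary:
    mean: float
    sem: float
    n: int


def _values(s, attr):
    if isinstance(s, SampleSet):
        return getattr(s, attr)
    return np.asarray(s, dtype=float)


def summarize_stiffness(s) -> StiffnessSummary:
    """Geometric mean and error of the mean of a log-normal stiffness sample.

    The error is reported two ways: the asymmetric factor interval
    ``exp(mean(ln) ± SEM(ln))`` and the symmetrized ``GM * SEM(ln)``
    approximation for "± Pa" display.
    """
    v = _values(s, "stiffness_pa")
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(v <= 0):
        raise ValueError("stiffness values must be positive")
    logs = np.log(v)
    mu = float(np.mean(logs))
    sem = float(np.std(logs, ddof=1) / np.sqrt(v.size))
    gm = float(np.exp(mu))
    return StiffnessSummary(geometric_mean_pa=gm, error_pa=gm * sem,
                            interval_low_pa=float(np.exp(mu - sem)),
                            interval_high_pa=float(np.exp(mu + sem)),
                            n=v.size)


def summarize_fluidity(s) -> FluiditySummary:
    """Arithmetic mean and standard error of a normal fluidity sample."""
    v = _values(s, "fluidity")
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return FluiditySummary(mean=float(np.mean(v)),
                           sem=float(np.std(v, ddof=1) / np.sqrt(v.size)),
                           n=v.size)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    t_statistic: float
    df: float
    p_raw: float
    p_bonferroni: float
    stars: str
    metric: str
    labels: tuple[str, str] = ("a", "b")


def compare_groups(a, b, metric: str = "stiffness",
                   n_comparisons: int = 1) -> ComparisonResult:
    """Welch's t-test between two groups with Bonferroni correction.

    Stiffness is compared on log-transformed values (log-normal data);
    fluidity on raw values.  ``n_comparisons`` is the explicit Bonferroni
    family size m; the corrected p is min(1, m * p).  Stars are assigned
    from the corrected p-value.
    """
    if metric not in ("stiffness", "fluidity"):
        raise ValueError("metric must be 'stiffness' or 'fluidity'")
    attr = "stiffness_pa" if metric == "stiffness" else "fluidity"
    va = _values(a, attr)
    vb = _values(b, attr)
    if va.size < 2 or vb.size < 2:
        raise ValueError("both groups need at least 2 values")
    if metric == "stiffness":
        if np.any(va <= 0) or np.any(vb <= 0):
            raise ValueError("stiffness values must be positive")
        va, vb = np.log(va), np.log(vb)
    var_a, var_b = np.var(va, ddof=1), np.var(vb, ddof=1)
    if var_a == 0 and var_b == 0:
        p = 1.0 if np.mean(va) == np.mean(vb) else 0.0
        tstat, dof = 0.0 if p == 1.0 else np.inf, float(va.size + vb.size - 2)
    else:
        res = sps.ttest_ind(va, vb, equal_var=False)
        tstat, p = float(res.statistic), float(res.pvalue)
        dof = float(res.df)
    p_bonf = min(1.0, n_comparisons * p)
    la = a.label if isinstance(a, SampleSet) else "a"
    lb = b.label if isinstance(b, SampleSet) else "b"
    return ComparisonResult(t_statistic=tstat, df=dof, p_raw=p,
                            p_bonferroni=p_bonf,
                            stars=significance_stars(p_bonf),
                            metric=metric, labels=(la, lb))


def fold_change(values, errors=None) -> tuple[float, float]:
    """Last/first ratio of an ordered series of summaries, with first-order
    error propagation of the two end-point errors."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if not values[0] > 0:
        raise ValueError("first value must be positive")
    ratio = float(values[-1] / values[0])
    if errors is None:
        return ratio, np.nan
    errors = np.asarray(errors, dtype=float)
    err = abs(ratio) * np.hypot(errors[-1] / values[-1], errors[0] / values[0])
    return ratio, float(err)
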