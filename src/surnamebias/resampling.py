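"""Jackknife subsampling, source comparison, covariate regression, Bonferroni.

The jackknife here is delete-d-style repeated random subsampling: fixed
numbers of individuals (20, 50, and where the list allows, 100) are drawn
without replacement from a present-day repertoire many times (201 by
default) and the founder-sharing fraction (1 − SDB) and the S/N diversity
ratio of each subsample are computed under both kinship models. The mean
sharing fraction is expected to be nearly size-invariant while the min–max
spread shrinks as the subsample grows.

Source comparison quantifies whether two repertoires of the same community
drawn from different documentary sources (e.g. a phone directory vs a
municipal register) tell the same story: squared Pearson correlation of the
per-surname counts over the union of supports, and a chi-square homogeneity
test on binned counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError, ValidationError
from .metrics import sdb_census
from .repertoire import Repertoire
from .sampling import KinshipModel

__all__ = [
    "JackknifePlan",
    "JackknifeResult",
    "jackknife_subsample",
    "compare_sources",
    "regress_bias",
    "bonferroni",
]

# 4 strategies (R, LS, FQ, GP) x 2 kinship models x 4 covariates
DEFAULT_REGRESSION_FAMILY = 32


@dataclass(frozen=True)
class JackknifePlan:
    sizes: tuple[int, ...] = (20, 50, 100)
    replicates: int = 201
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not self.sizes or any(s < 1 for s in self.sizes):
            raise ValidationError("sizes must be positive and non-empty")


@dataclass(frozen=True)
class JackknifeResult:
    """Raw per-replicate statistics plus a tidy summary.

    ``raw`` has one row per (size, replicate) with columns
    ``share_lk, share_hk, s_over_n`` (share = 1 − SDB); ``summary()``
    aggregates mean/min/max per size and statistic.
    """

    raw: pd.DataFrame
    plan: JackknifePlan

    def summary(self) -> pd.DataFrame:
        long = self.raw.melt(
            id_vars=["size", "replicate"], var_name="stat", value_name="value"
        )
        out = (
            long.groupby(["size", "stat"])["value"]
            .agg(["mean", "min", "max"])
            .reset_index()
        )
        out["spread"] = out["max"] - out["min"]
        return out


def jackknife_subsample(
    rep: Repertoire, plan: JackknifePlan, historical: Repertoire
) -> JackknifeResult:
    """Repeated fixed-size subsampling of bearers, with per-subsample statistics.

    Sizes exceeding the repertoire's bearer total are dropped with a warning.
    Each replicate draws the requested number of bearers uniformly without
    replacement (a multivariate hypergeometric draw on the count vector) and
    records 1 − SDB under both models and the subsample's S/N.
    """
    sizes = tuple(s for s in plan.sizes if s <= rep.n)
    dropped = set(plan.sizes) - set(sizes)
    if dropped:
        warnings.warn(
            f"subsample sizes {sorted(dropped)} exceed N={rep.n} and were dropped",
            stacklevel=2,
        )
    if not sizes:
        raise ValidationError(f"no requested size fits a repertoire of N={rep.n}")

    rng = np.random.default_rng(plan.seed)
    names = list(rep.counts)
    counts = np.array([rep.counts[name] for name in names])
    support = historical.types
    in_hist = np.array([name in support for name in names])

    rows = []
    for size in sizes:
        for r in range(plan.replicates):
            drawn = rng.multivariate_hypergeometric(counts, size)
            present_mask = drawn > 0
            s_sub = int(present_mask.sum())
            shared_types = int((present_mask & in_hist).sum())
            shared_bearers = int(drawn[in_hist].sum())
            rows.append(
                {
                    "size": size,
                    "replicate": r + 1,
                    "share_lk": shared_types / s_sub,
                    "share_hk": shared_bearers / size,
                    "s_over_n": s_sub / size,
                }
            )
    return JackknifeResult(raw=pd.DataFrame(rows), plan=plan)


def _paired_counts(rep_a: Repertoire, rep_b: Repertoire) -> pd.DataFrame:
    union = sorted(set(rep_a.counts) | set(rep_b.counts))
    return pd.DataFrame(
        {
            "surname": union,
            "count_a": [rep_a.counts.get(s, 0) for s in union],
            "count_b": [rep_b.counts.get(s, 0) for s in union],
        }
    )


def compare_sources(rep_a: Repertoire, rep_b: Repertoire) -> dict[str, float]:
    """Agreement between two repertoires of the same community.

    Per-surname bearer counts are paired over the union of supports (absent
    = 0). Returns the squared Pearson correlation with its p-value, and the
    p-value (and statistic) of a chi-square homogeneity test on the 2×K
    binned table: surnames whose expected counts are at least 5 in both
    sources form individual bins, all others are pooled into one rest bin.
    """
    pairs = _paired_counts(rep_a, rep_b)
    overlap = int(((pairs.count_a > 0) & (pairs.count_b > 0)).sum())
    if overlap < 3:
        raise UndefinedStatisticError(
            f"only {overlap} shared surnames; correlation needs at least 3"
        )
    r, p = stats.pearsonr(pairs.count_a, pairs.count_b)

    a = pairs.count_a.to_numpy(dtype=float)
    b = pairs.count_b.to_numpy(dtype=float)
    na, nb = a.sum(), b.sum()
    pooled = a + b
    exp_a = pooled * na / (na + nb)
    exp_b = pooled * nb / (na + nb)
    own_bin = (exp_a >= 5) & (exp_b >= 5)
    bins_a = list(a[own_bin])
    bins_b = list(b[own_bin])
    if (~own_bin).any():
        bins_a.append(a[~own_bin].sum())
        bins_b.append(b[~own_bin].sum())
    table = np.array([bins_a, bins_b])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table)
    return {
        "r_squared": float(r**2),
        "pearson_p": float(p),
        "chi_square_stat": float(chi2_stat),
        "chi_square_p": float(chi2_p),
    }


def regress_bias(
    sdb_values: Sequence[float], covariate: Sequence[float]
) -> dict[str, float | str]:
    """Ordinary least-squares simple regression of per-community SDB on a covariate.

    Returns R², the slope sign ("+" or "-") and the two-sided p-value for
    the slope.
    """
    y = np.asarray(sdb_values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValidationError("sdb_values and covariate must have equal length")
    if len(y) < 3:
        raise ValidationError("regression needs at least 3 paired values")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("covariate has zero variance")
    if np.ptp(y) == 0:
        # A constant response carries no association: R^2 = 0 by convention.
        return {"r_squared": 0.0, "sign": "+", "p_value": 1.0, "slope": 0.0}
    fit = stats.linregress(x, y)
    return {
        "r_squared": float(fit.rvalue**2),
        "sign": "+" if fit.slope >= 0 else "-",
        "p_value": float(fit.pvalue),
        "slope": float(fit.slope),
    }


def bonferroni(
    p_values: Sequence[float], family_size: int | None = None
) -> list[float]:
    """Bonferroni adjustment: min(1, p × m) with m the testing-family size.

    ``family_size`` defaults to the length of the list; the covariate-screen
    design of this package tests 4 strategies × 2 models × 4 covariates, so
    pass ``family_size=32`` (`DEFAULT_REGRESSION_FAMILY`) when adjusting a
    partial set of those rows.
    """
    p = list(p_values)
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise ValidationError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else len(p)
    if m < 1:
        raise ValidationError("family_size must be >= 1")
    return [min(1.0, v * m) for v in p]
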