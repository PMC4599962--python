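"""Bias and diversity statistics: SDB, ΔSDB, isonymy.

The sampling-dependent bias (SDB) of a selection against a community's
oldest (historical) repertoire is

    SDB = 1 − shared_units / n_units,

where a unit is a surname type under the low-kinship model and a sampled
bearer under the high-kinship model, and a unit is *shared* when its surname
is attested in the historical list. SDB ranges from 1 (no surname shared)
to 0 (every sampled unit bears a historically documented surname); under
the null hypothesis of full adhesion to the founding distribution — as with
the founding-surnames strategy — its expectation is zero under both models.

ΔSDB = SDB_LK − SDB_HK measures how much admitting close kinship lowers the
bias for a given strategy in a given community.

Isonymy, the probability that two randomly chosen individuals share a
surname, is the random component of inbreeding in surname biodemography.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import UndefinedStatisticError, ValidationError
from .repertoire import Repertoire
from .sampling import KinshipModel, SampleSelection

__all__ = ["BiasResult", "IsonymyResult", "sdb", "sdb_census", "delta_sdb", "isonymy"]


@dataclass(frozen=True)
class BiasResult:
    """SDB with its bookkeeping: the selection size and the shared-unit count."""

    sdb: float
    strategy: str
    model: KinshipModel
    n_units: int
    shared_units: int

    def __post_init__(self) -> None:
        if not 0 <= self.shared_units <= self.n_units:
            raise ValidationError("shared_units must lie in [0, n_units]")


@dataclass(frozen=True)
class IsonymyResult:
    isonymy: float
    estimator: str  # "unbiased" or "plugin"


def sdb(selection: SampleSelection, historical: Repertoire) -> BiasResult:
    """Sampling-dependent bias of a selection against the historical repertoire.

    ``shared_units`` counts selection units (types under LK, bearer tokens
    under HK) whose surname lies in the historical support.
    """
    n_units = selection.n_units
    if n_units == 0:
        raise UndefinedStatisticError("SDB is undefined on an empty selection")
    support = historical.types
    shared = sum(mult for name, mult in selection.units.items() if name in support)
    return BiasResult(
        sdb=1.0 - shared / n_units,
        strategy=selection.strategy,
        model=selection.model,
        n_units=n_units,
        shared_units=shared,
    )


def sdb_census(
    present: Repertoire, historical: Repertoire, model: KinshipModel
) -> BiasResult:
    """SDB of the full present-day list (random-strategy census) vs the historical one.

    Equivalent to ``sdb(select_random(present, model, "all"), historical)``
    but computed directly from the repertoires; used heavily by the drift
    simulator and the resampling module.
    """
    model = KinshipModel(model)
    support = historical.types
    if model is KinshipModel.LK:
        n_units = present.s
        shared = sum(1 for name in present.counts if name in support)
    else:
        n_units = present.n
        shared = sum(c for name, c in present.counts.items() if name in support)
    return BiasResult(
        sdb=1.0 - shared / n_units,
        strategy="R",
        model=model,
        n_units=n_units,
        shared_units=shared,
    )


def delta_sdb(lk: BiasResult, hk: BiasResult) -> float:
    """ΔSDB = SDB_LK − SDB_HK for the same community and strategy.

    Positive values mean the high-kinship model lowers the bias — the
    empirically common direction, most pronounced where a few founding
    surnames hold many present-day bearers.
    """
    if lk.model is not KinshipModel.LK or hk.model is not KinshipModel.HK:
        raise ValidationError("arguments must be an LK result and an HK result")
    if lk.strategy != hk.strategy:
        raise ValidationError("ΔSDB compares the same strategy under the two models")
    return lk.sdb - hk.sdb


def _multiplicities(obj: Repertoire | SampleSelection) -> list[int]:
    if isinstance(obj, Repertoire):
        return list(obj.counts.values())
    return list(obj.units.values())


def isonymy(
    rep_or_selection: Repertoire | SampleSelection, estimator: str = "unbiased"
) -> IsonymyResult:
    """Within-group random isonymy.

    The default unbiased estimator is Σ nᵢ(nᵢ−1) / (N(N−1)) over surname
    multiplicities nᵢ — the probability that two individuals drawn without
    replacement share a surname; it equals 1 when a single surname holds all
    bearers and 0 when all are singletons. The plug-in alternative
    Σ (nᵢ/N)² (draws with replacement) is available for sensitivity checks.
    """
    mults = _multiplicities(rep_or_selection)
    n = sum(mults)
    if estimator == "unbiased":
        if n < 2:
            raise UndefinedStatisticError("unbiased isonymy needs at least 2 units")
        value = sum(m * (m - 1) for m in mults) / (n * (n - 1))
    elif estimator == "plugin":
        if n < 1:
            raise UndefinedStatisticError("isonymy is undefined on an empty input")
        value = sum((m / n) ** 2 for m in mults)
    else:
        raise ValidationError(f"unknown estimator {estimator!r}")
    return IsonymyResult(isonymy=value, estimator=estimator)
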