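"""Donor-selection strategies under low- and high-kinship models.

Five strategies used in surname-based recruitment for Y-chromosome studies
are simulated on a present-day repertoire:

``R``
    Random — the whole present-day list (or a random subsample of bearers).
``LS``
    Locally spread — only surnames whose geographic origin is unambiguously
    centred in the community's own province, excluding potentially
    polyphyletic, widely dispersed names.
``FQ``
    First quartile — surnames above the upper quartile of the present-day
    frequency distribution, assuming high frequency indicates long residency.
``GP``
    Grandparents — surnames also attested roughly two generations before the
    present source (a mid-era repertoire, e.g. 1845–1915 marriage acts).
``FS``
    Founding surnames — surnames attested in the oldest historical record;
    by construction a selection with zero sampling-dependent bias.

Each strategy is evaluated under two kinship models: ``LK`` (low kinship,
one individual per surname type — donors are maximally unrelated) and ``HK``
(high kinship, every bearer of a selected surname counts, multiplicities
allowed).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

from .exceptions import EmptySelectionError, SampleSizeError, ValidationError
from .repertoire import Repertoire

__all__ = [
    "KinshipModel",
    "SampleSelection",
    "OriginAnnotation",
    "select_random",
    "select_first_quartile",
    "select_locally_spread",
    "select_grandparents",
    "select_founders",
]

STRATEGIES = ("R", "LS", "FQ", "GP", "FS")


class KinshipModel(str, Enum):
    """LK counts one unit per surname type; HK counts every bearer."""

    LK = "LK"
    HK = "HK"


@dataclass(frozen=True)
class SampleSelection:
    """The multiset of sampled units produced by one strategy under one model.

    ``units`` maps each selected surname to its multiplicity: always 1 under
    LK; under HK the number of sampled bearers of that surname.
    """

    strategy: str
    model: KinshipModel
    units: Mapping[str, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        units = {k: int(v) for k, v in dict(self.units).items()}
        if any(v < 1 for v in units.values()):
            raise ValidationError("unit multiplicities must be positive")
        if self.model is KinshipModel.LK and any(v != 1 for v in units.values()):
            raise ValidationError("under LK every surname appears at most once")
        object.__setattr__(self, "units", units)

    @property
    def n_units(self) -> int:
        return sum(self.units.values())

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self.units)


@dataclass(frozen=True)
class OriginAnnotation:
    """Geographic origin annotation of surnames (an external input).

    ``origin`` maps a surname to the province its distribution is centred in;
    surnames absent from the map are of unknown origin. ``national_bearers``
    optionally gives the nationwide bearer count, used to exclude very common
    (hence likely polyphyletic) names.
    """

    origin: Mapping[str, str]
    national_bearers: Mapping[str, int] | None = None


def _from_types(
    present: Repertoire, selected: set[str], strategy: str, model: KinshipModel
) -> SampleSelection:
    """Build a census selection over `selected` types under the given model."""
    if model is KinshipModel.LK:
        units = {name: 1 for name in selected}
    else:
        units = {name: present.counts[name] for name in selected}
    return SampleSelection(strategy=strategy, model=model, units=units)


def select_random(
    present: Repertoire,
    model: KinshipModel,
    n: int | str = "all",
    seed: int | None = None,
) -> SampleSelection:
    """Random strategy (R): the whole present-day list, or a random subsample.

    With ``n="all"`` the selection is a deterministic census: every surname
    type once under LK, every bearer under HK. With numeric ``n``, bearers
    are drawn uniformly without replacement; under LK the draw continues
    until ``n`` distinct types are held (each contributing one unit).
    """
    model = KinshipModel(model)
    if n == "all":
        return _from_types(present, set(present.counts), "R", model)

    n = int(n)
    if n < 1:
        raise SampleSizeError("n must be >= 1")
    limit = present.s if model is KinshipModel.LK else present.n
    if n > limit:
        raise SampleSizeError(
            f"requested {n} units but only {limit} available under {model.value}"
        )
    rng = np.random.default_rng(seed)
    names = list(present.counts)
    counts = np.array([present.counts[name] for name in names])
    if model is KinshipModel.HK:
        drawn = rng.multivariate_hypergeometric(counts, n)
        units = {names[i]: int(c) for i, c in enumerate(drawn) if c > 0}
    else:
        # Draw bearers one by one (a random permutation of the bearer list),
        # keeping first occurrences until n distinct types are held.
        order = rng.permutation(np.repeat(np.arange(len(names)), counts))
        seen: dict[str, int] = {}
        for idx in order:
            seen.setdefault(names[idx], 1)
            if len(seen) == n:
                break
        units = seen
    return SampleSelection(strategy="R", model=model, units=units, seed=seed)


def select_first_quartile(present: Repertoire, model: KinshipModel) -> SampleSelection:
    """First-quartile strategy (FQ): surnames above the upper quartile.

    The 75th percentile of the per-surname count distribution is computed by
    linear interpolation on the sorted counts; surnames with count strictly
    greater are selected. If no count exceeds the quartile (flat or heavily
    tied spectra), the strategy falls back to all surnames tied at the
    maximum count and emits a warning.
    """
    model = KinshipModel(model)
    counts = np.array(sorted(present.counts.values()))
    q3 = float(np.percentile(counts, 75))  # linear interpolation
    selected = {name for name, c in present.counts.items() if c > q3}
    if not selected:
        cmax = counts.max()
        selected = {name for name, c in present.counts.items() if c == cmax}
        warnings.warn(
            "no surname count strictly above the upper quartile; "
            "falling back to surnames tied at the maximum count",
            stacklevel=2,
        )
    return _from_types(present, selected, "FQ", model)


def select_locally_spread(
    present: Repertoire,
    ann: OriginAnnotation,
    home_province: str,
    model: KinshipModel,
    max_national_bearers: int | None = None,
) -> SampleSelection:
    """Locally-spread strategy (LS): surnames originating in the home province.

    Surnames of unknown origin are excluded. If ``max_national_bearers`` is
    given, surnames with more nationwide bearers than the threshold are also
    excluded (very common names are likely polyphyletic).
    """
    model = KinshipModel(model)
    selected = set()
    for name in present.counts:
        if ann.origin.get(name) != home_province:
            continue
        if max_national_bearers is not None and ann.national_bearers is not None:
            if ann.national_bearers.get(name, 0) > max_national_bearers:
                continue
        selected.add(name)
    if not selected:
        raise EmptySelectionError(
            f"no present-day surname is annotated to province {home_province!r}"
        )
    return _from_types(present, selected, "LS", model)


def select_grandparents(
    present: Repertoire, midera: Repertoire, model: KinshipModel
) -> SampleSelection:
    """Grandparents strategy (GP): present-day surnames attested in a mid-era list."""
    model = KinshipModel(model)
    selected = set(present.counts) & set(midera.counts)
    if not selected:
        raise EmptySelectionError(
            "no present-day surname is attested in the mid-era repertoire"
        )
    return _from_types(present, selected, "GP", model)


def select_founders(
    present: Repertoire, historical: Repertoire, model: KinshipModel
) -> SampleSelection:
    """Founding-surnames strategy (FS): present surnames attested in the oldest list.

    Every selected unit bears a historically documented surname, so the
    sampling-dependent bias of this selection against that historical list is
    zero by construction — it is the reference template the other strategies
    are compared to.
    """
    model = KinshipModel(model)
    selected = set(present.counts) & set(historical.counts)
    if not selected:
        raise EmptySelectionError(
            "no present-day surname is attested in the historical repertoire"
        )
    return _from_types(present, selected, "FS", model)
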