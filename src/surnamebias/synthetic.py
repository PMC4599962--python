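"""Synthetic communities with known ground truth.

Real surname archives pair a founding list (a census or sacramental
register, 15th–18th century) with a present-day list (phone directory or
municipal register) whose overlap has been eroded by drift, immigration and
surname innovation. This module generates linked (founding, mid-era,
present) repertoires with that structure and — crucially — records the
*truth*: which present-day surnames are founding, immigrant-origin or
innovations, and what fraction of present-day bearers descend from
immigrants. That realized fraction is exactly what the census
high-kinship SDB estimates when immigrant surnames are novel, which makes
the generator + metrics pair testable as a parameter-recovery problem.

Founding frequency spectra follow a truncated discrete power law (surname
spectra are heavy-tailed); lineage transmission reuses the neutral
patrilineal scheme of :mod:`surnamebias.drift`, augmented with per-lineage
descent bookkeeping. Immigrants draw their surnames from a finite external
pool with its own heavy-tailed spectrum — immigration is a family- and
region-structured process, so the same foreign surnames recur across
immigration events and accumulate bearers, as in real repertoires. Pool
surnames never coincide with community ones (novel by construction), except
with a configurable collision probability that maps an immigrant onto an
existing type (polyphyly: identity by state rather than by descent).

Default parameters emulate the published 26-community design: founding
totals of a few hundred to a few thousand bearers, founding S/N between
roughly 0.1 and 0.45, foundation years 1447–1775 against a present around
1993 (10–18 generations at 30 years), growth rates from strong decline to
near-centennial growth, and altitudes from sea level to alpine villages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .repertoire import CommunityMeta, Repertoire, write_repertoire
from .sampling import OriginAnnotation

__all__ = [
    "SynthParams",
    "SyntheticTruth",
    "EvolvedCommunity",
    "SyntheticCommunity",
    "StudyDataset",
    "generate_founding",
    "evolve_community",
    "generate_study",
    "immigration_rate_for_fraction",
]

_PROVINCES = ("TN", "TO", "SP", "MO", "LU", "PI", "SI", "MS", "AQ", "BA", "RC")
_FOREIGN = ("EXT-A", "EXT-B", "EXT-C")


@dataclass(frozen=True)
class SynthParams:
    """Configuration of one synthetic community.

    ``growth_rate`` is on the (N_t − N_0)/N_t scale (must be < 1);
    ``immigration_rate`` is the per-generation expected fraction of the new
    generation that immigrates; ``innovation_rate`` the per-birth
    probability of a novel surname; immigrant surnames come from an external
    pool of ``pool_size`` types weighted by the same power law as the
    founding spectrum; ``collision_prob`` is the probability an immigrant's
    surname coincides with an existing community type instead of a pool one;
    ``annotated_fraction`` the fraction of immigrant-origin surnames whose
    (foreign) origin province is known to the annotation.
    """

    community_id: str = "SYNTH"
    s0: int = 100
    n0: int = 800
    spectrum_shape: float = 1.2
    generations: int = 10
    growth_rate: float = 0.3
    immigration_rate: float = 0.04
    innovation_rate: float = 0.001
    pool_size: int = 400
    collision_prob: float = 0.0
    annotated_fraction: float = 0.9
    home_province: str = "LU"
    oldest_year: int = 1693
    generation_time: float = 30.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.s0 <= self.n0:
            raise ConfigurationError("need 1 <= s0 <= n0")
        if self.growth_rate >= 1.0:
            raise ConfigurationError("growth_rate must be < 1 on the (Nt-N0)/Nt scale")
        for name in ("immigration_rate", "innovation_rate", "collision_prob",
                     "annotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if self.pool_size < 1:
            raise ConfigurationError("pool_size must be >= 1")

    @property
    def final_size(self) -> int:
        """Present-day bearer total implied by the growth-rate target."""
        return max(1, round(self.n0 / (1.0 - self.growth_rate)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth classification of the present-day support.

    ``table`` has one row per present-day surname with boolean columns
    ``founding, immigrant_origin, innovation`` (a partition) and an
    ``origin_province`` (the home province for founding surnames, a foreign
    label or "unknown" for immigrant-origin ones).
    ``immigrant_bearer_fraction`` is the realized fraction of present-day
    bearers whose patriline descends from an immigrant.
    """

    table: pd.DataFrame
    immigrant_bearer_fraction: float


@dataclass(frozen=True)
class EvolvedCommunity:
    midera: Repertoire
    present: Repertoire
    truth: SyntheticTruth
    annotation: OriginAnnotation


@dataclass(frozen=True)
class SyntheticCommunity:
    meta: CommunityMeta
    params: SynthParams
    founding: Repertoire
    midera: Repertoire
    present: Repertoire
    truth: SyntheticTruth
    annotation: OriginAnnotation


def immigration_rate_for_fraction(f: float, generations: int) -> float:
    """Per-generation immigration rate whose cumulative effect is fraction ``f``.

    With a fraction m of each new generation immigrating and the rest drawn
    from the resident pool, the expected immigrant-descent fraction after G
    generations is 1 − (1 − m)^G; inverting gives m = 1 − (1 − f)^(1/G).
    """
    if not 0.0 <= f < 1.0:
        raise ConfigurationError("target fraction must lie in [0, 1)")
    return 1.0 - (1.0 - f) ** (1.0 / generations)


def generate_founding(params: SynthParams, rng: np.random.Generator | None = None) -> Repertoire:
    """Founding repertoire with a truncated power-law frequency spectrum.

    Rank r (1..S0) receives weight r^(−shape); the N0 bearers are allocated
    by largest remainder with a floor of one bearer per type, so S = S0 and
    N = N0 exactly. The shape→∞ limit is one dominant surname plus
    singletons; shape = 0 is a flat spectrum.
    """
    s0, n0 = params.s0, params.n0
    ranks = np.arange(1, s0 + 1, dtype=float)
    weights = ranks ** (-params.spectrum_shape)
    weights /= weights.sum()
    extra = n0 - s0
    quota = weights * extra
    counts = np.ones(s0, dtype=int) + np.floor(quota).astype(int)
    remainder = extra - int(np.floor(quota).sum())
    if remainder:
        order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        counts[order[:remainder]] += 1
    names = [f"{params.community_id}-F{r:04d}" for r in range(1, s0 + 1)]
    return Repertoire(
        community_id=params.community_id,
        era_year=params.oldest_year,
        source_kind="synthetic",
        counts=dict(zip(names, counts.astype(int).tolist())),
    )


def _immigrant_pool(params: SynthParams) -> tuple[list[str], np.ndarray]:
    ranks = np.arange(1, params.pool_size + 1, dtype=float)
    weights = ranks ** (-params.spectrum_shape)
    names = [f"{params.community_id}-M{r:04d}" for r in range(1, params.pool_size + 1)]
    return names, weights / weights.sum()


def _keyed_step(
    keyed: dict[tuple[str, str], int],
    next_size: int,
    params: SynthParams,
    rng: np.random.Generator,
    registries: dict[str, set[str]],
    counters: dict[str, int],
    pool: tuple[list[str], np.ndarray],
) -> dict[tuple[str, str], int]:
    """One generation on (surname, descent-class) keyed counts.

    Children inherit the father's key; innovators inherit the father's
    descent class but take a novel surname; immigrants enter with descent
    class "immigrant" and a surname from the external pool (or, with
    ``collision_prob``, an existing community type).
    """
    n_imm = rng.binomial(next_size, params.immigration_rate) if params.immigration_rate else 0
    n_rest = next_size - n_imm
    n_innov = rng.binomial(n_rest, params.innovation_rate) if params.innovation_rate else 0
    n_native = n_rest - n_innov

    keys = list(keyed)
    weights = np.fromiter(keyed.values(), dtype=float, count=len(keys))
    probs = weights / weights.sum()
    out: dict[tuple[str, str], int] = {}
    if n_native:
        drawn = rng.multinomial(n_native, probs)
        for key, c in zip(keys, drawn):
            if c:
                out[key] = out.get(key, 0) + int(c)
    if n_innov:
        father_classes = rng.multinomial(n_innov, probs)
        for key, c in zip(keys, father_classes):
            for _ in range(int(c)):
                counters["innovation"] += 1
                name = f"{params.community_id}-X{counters['innovation']:05d}"
                registries["innovation"].add(name)
                out[(name, key[1])] = out.get((name, key[1]), 0) + 1
    if n_imm:
        existing_names = sorted({k[0] for k in keyed})
        n_collide = (
            rng.binomial(n_imm, params.collision_prob) if params.collision_prob else 0
        )
        for _ in range(n_collide):
            name = existing_names[rng.integers(len(existing_names))]
            out[(name, "immigrant")] = out.get((name, "immigrant"), 0) + 1
        pool_names, pool_probs = pool
        drawn = rng.multinomial(n_imm - n_collide, pool_probs)
        for name, c in zip(pool_names, drawn):
            if c:
                registries["immigrant"].add(name)
                out[(name, "immigrant")] = out.get((name, "immigrant"), 0) + int(c)
    return out


def _collapse(keyed: dict[tuple[str, str], int]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for (name, _cls), c in keyed.items():
        counts[name] = counts.get(name, 0) + c
    return counts


def evolve_community(
    founding: Repertoire,
    params: SynthParams,
    rng: np.random.Generator | None = None,
) -> EvolvedCommunity:
    """Evolve a founding repertoire to the present, recording ground truth.

    The population follows a geometric size trajectory from N0 to the
    growth-rate-implied present total over ``params.generations``
    generations of neutral patrilineal transmission with immigration and
    innovation. A mid-era snapshot is taken at the generation nearest four
    generations (~120 years, the grandparents' era of a ~1993 present)
    before the last, for testing the grandparents strategy.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    g_total = params.generations
    nf = params.final_size
    sizes = [max(1, round(founding.n * (nf / founding.n) ** (g / g_total)))
             for g in range(1, g_total + 1)]
    mid_index = max(1, g_total - round(113 / params.generation_time))  # 1-based

    registries: dict[str, set[str]] = {"immigrant": set(), "innovation": set()}
    counters = {"immigrant": 0, "innovation": 0}
    pool = _immigrant_pool(params)
    keyed: dict[tuple[str, str], int] = {
        (name, "native"): c for name, c in founding.counts.items()
    }
    midera_counts: dict[str, int] | None = None
    for g, next_size in enumerate(sizes, start=1):
        keyed = _keyed_step(keyed, next_size, params, rng, registries, counters, pool)
        if g == mid_index:
            midera_counts = _collapse(keyed)
    if midera_counts is None:  # single-generation chain
        midera_counts = _collapse(keyed)

    present_counts = _collapse(keyed)
    n_present = sum(present_counts.values())
    imm_bearers = sum(c for (name, cls), c in keyed.items() if cls == "immigrant")
    f_realized = imm_bearers / n_present

    mid_year = params.oldest_year + round(mid_index * params.generation_time)
    present_year = params.oldest_year + round(g_total * params.generation_time)
    midera = Repertoire(founding.community_id, mid_year, "synthetic", midera_counts)
    present = Repertoire(founding.community_id, present_year, "synthetic", present_counts)

    founding_support = founding.types
    rows = []
    origin: dict[str, str] = {}
    foreign = list(_FOREIGN)
    for name in sorted(present_counts):
        is_founding = name in founding_support
        is_imm = name in registries["immigrant"]
        is_innov = name in registries["innovation"]
        if is_founding:
            prov = params.home_province
        elif is_imm:
            if rng.random() < params.annotated_fraction:
                prov = foreign[rng.integers(len(foreign))]
            else:
                prov = "unknown"
        else:
            prov = "unknown"
        rows.append(
            {
                "surname": name,
                "founding": is_founding,
                "immigrant_origin": is_imm and not is_founding,
                "innovation": is_innov and not is_founding,
                "origin_province": prov,
            }
        )
        if prov != "unknown":
            origin[name] = prov
    truth = SyntheticTruth(
        table=pd.DataFrame(rows), immigrant_bearer_fraction=f_realized
    )
    annotation = OriginAnnotation(origin=origin)
    return EvolvedCommunity(midera=midera, present=present, truth=truth, annotation=annotation)


def generate_study(
    n_communities: int = 26,
    seed: int | None = None,
    n0_range: tuple[int, int] = (115, 17504),
    s_over_n0_range: tuple[float, float] = (0.08, 0.45),
    growth_range: tuple[float, float] = (-2.1, 0.95),
    altitude_range: tuple[int, int] = (0, 1300),
    oldest_year_range: tuple[int, int] = (1447, 1775),
    present_year: int = 1993,
    base_immigration: float = 0.06,
    altitude_coupling: float = 0.7,
    innovation_rate: float = 0.001,
    collision_prob: float = 0.0,
    spectrum_shape: float = 1.2,
    generation_time: float = 30.0,
) -> "StudyDataset":
    """A multi-community dataset shaped like the 26-community study design.

    Founding totals are log-uniform over ``n0_range``; founding S/N, growth
    rate, altitude and foundation year are uniform over their ranges.
    ``altitude_coupling`` scales the per-generation immigration rate down
    with altitude — ``m = base_immigration × (1 − coupling × alt/alt_max)``
    — so higher (more isolated) communities receive fewer immigrants,
    inducing the negative altitude–SDB correlation seen in the real design;
    a coupling of 0 decouples them for null testing.
    """
    if n_communities < 1:
        raise ConfigurationError("n_communities must be >= 1")
    rng = np.random.default_rng(seed)
    alt_max = max(altitude_range[1], 1)
    communities = []
    for i in range(1, n_communities + 1):
        cid = f"SYN{i:02d}"
        n0 = int(round(np.exp(rng.uniform(np.log(n0_range[0]), np.log(n0_range[1])))))
        s0 = max(1, min(n0, round(n0 * rng.uniform(*s_over_n0_range))))
        growth = float(rng.uniform(*growth_range))
        altitude = int(rng.integers(altitude_range[0], altitude_range[1] + 1))
        oldest_year = int(rng.integers(oldest_year_range[0], oldest_year_range[1] + 1))
        generations = max(1, round((present_year - oldest_year) / generation_time))
        m = base_immigration * (1.0 - altitude_coupling * altitude / alt_max)
        params = SynthParams(
            community_id=cid,
            s0=s0,
            n0=n0,
            spectrum_shape=spectrum_shape,
            generations=generations,
            growth_rate=growth,
            immigration_rate=float(np.clip(m, 0.0, 1.0)),
            innovation_rate=innovation_rate,
            collision_prob=collision_prob,
            home_province=_PROVINCES[i % len(_PROVINCES)],
            oldest_year=oldest_year,
            generation_time=generation_time,
        )
        founding = generate_founding(params, rng)
        evolved = evolve_community(founding, params, rng)
        meta = CommunityMeta(
            community_id=cid,
            region=f"Region-{_PROVINCES[i % len(_PROVINCES)]}",
            province=params.home_province,
            altitude_m=altitude,
            oldest_year=oldest_year,
            present_year=present_year,
        )
        communities.append(
            SyntheticCommunity(
                meta=meta,
                params=params,
                founding=founding,
                midera=evolved.midera,
                present=evolved.present,
                truth=evolved.truth,
                annotation=evolved.annotation,
            )
        )
    return StudyDataset(communities=communities, seed=seed)


@dataclass(frozen=True)
class StudyDataset:
    communities: list[SyntheticCommunity]
    seed: int | None = None

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.communities:
            rows.append(
                {
                    "community_id": c.meta.community_id,
                    "region": c.meta.region,
                    "province": c.meta.province,
                    "altitude_m": c.meta.altitude_m,
                    "oldest_year": c.meta.oldest_year,
                    "present_year": c.meta.present_year,
                    "n0": c.founding.n,
                    "nt": c.present.n,
                    "s0": c.founding.s,
                    "st": c.present.s,
                    "immigration_rate": c.params.immigration_rate,
                    "true_immigrant_fraction": c.truth.immigrant_bearer_fraction,
                }
            )
        return pd.DataFrame(rows)

    def to_directory(self, path: str | Path) -> None:
        """Write the dataset in the CSV dialects the readers understand."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.metadata_frame().to_csv(path / "communities.csv", index=False)
        for c in self.communities:
            cid = c.meta.community_id
            write_repertoire(c.founding, path / f"{cid}_founding.csv")
            write_repertoire(c.midera, path / f"{cid}_midera.csv")
            write_repertoire(c.present, path / f"{cid}_present.csv")
            c.truth.table.to_csv(path / f"{cid}_truth.csv", index=False)
            ann = pd.DataFrame(
                sorted(c.annotation.origin.items()),
                columns=["surname", "origin_province"],
            )
            ann.to_csv(path / f"{cid}_origins.csv", index=False)
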