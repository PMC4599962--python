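"""End-to-end orchestration: ingest → sample → metrics → simulate → report.

`run_study` takes a dataset (real repertoires loaded from a directory, or a
synthetic study) and a :class:`RunConfig`, runs every requested
(community, strategy, model) combination, and writes a tidy report bundle:

``bias_results.csv``
    one row per (community, strategy, model): n_units, shared_units, SDB,
    isonymy and S/N of the selection;
``strategy_summary.csv``
    min / mean / max / sd of SDB per (strategy, model) over communities;
``diversity_summary.csv``
    mean / sd of S/N and isonymy per (strategy, model);
``drift_comparison.csv``
    observed R/LK SDB vs the drift-expected value under the growth and
    stationary size models;
``jackknife.csv``
    per-size mean/min/max of the subsampled sharing fraction and S/N;
``regressions.csv``
    per (strategy, model, covariate) OLS R², slope sign, nominal and
    Bonferroni-adjusted p-values;
``run_log.txt``
    seeds, versions and any per-community stage errors.

A failure in one community/stage is logged and the remaining work proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drift import DriftParams, simulate_community
from .exceptions import SurnameBiasError, UndefinedStatisticError
from .metrics import isonymy, sdb
from .repertoire import CommunityMeta, Repertoire, growth_rate, read_repertoire
from .resampling import (
    DEFAULT_REGRESSION_FAMILY,
    JackknifePlan,
    bonferroni,
    jackknife_subsample,
    regress_bias,
)
from .sampling import (
    KinshipModel,
    OriginAnnotation,
    select_first_quartile,
    select_founders,
    select_grandparents,
    select_locally_spread,
    select_random,
)
from .synthetic import StudyDataset, SyntheticCommunity, generate_study

__all__ = ["RunConfig", "CommunityData", "load_dataset", "run_study"]

COVARIATES = ("altitude", "present_n", "foundation_year", "growth_rate")


@dataclass(frozen=True)
class CommunityData:
    """One community's inputs: metadata, repertoires, optional annotation."""

    meta: CommunityMeta
    founding: Repertoire
    present: Repertoire
    midera: Repertoire | None = None
    annotation: OriginAnnotation | None = None


@dataclass
class RunConfig:
    """What to run and where to put it.

    Either ``input_dir`` (a directory in the layout written by
    ``StudyDataset.to_directory``) or ``synthetic: true`` with
    ``n_communities``. Seeds are recorded in the run log.
    """

    output_dir: str = "study_output"
    input_dir: str | None = None
    synthetic: bool = True
    n_communities: int = 26
    strategies: tuple[str, ...] = ("R", "LS", "FQ", "GP", "FS")
    models: tuple[str, ...] = ("LK", "HK")
    seed: int = 0
    drift_enabled: bool = True
    drift_iterations: int = 100
    jackknife_enabled: bool = True
    jackknife_sizes: tuple[int, ...] = (20, 50, 100)
    jackknife_replicates: int = 201

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SurnameBiasError(f"unknown config keys: {sorted(unknown)}")
        for key in ("strategies", "models", "jackknife_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_dataset(path: str | Path) -> list[CommunityData]:
    """Load a study directory (communities.csv + per-community repertoire CSVs)."""
    path = Path(path)
    meta_frame = pd.read_csv(path / "communities.csv")
    communities = []
    for row in meta_frame.itertuples():
        cid = str(row.community_id)
        meta = CommunityMeta(
            community_id=cid,
            region=str(row.region),
            province=str(row.province),
            altitude_m=int(row.altitude_m),
            oldest_year=int(row.oldest_year),
            present_year=int(row.present_year),
        )
        founding = read_repertoire(
            path / f"{cid}_founding.csv", cid, meta.oldest_year, "synthetic"
        )
        present = read_repertoire(
            path / f"{cid}_present.csv", cid, meta.present_year, "synthetic"
        )
        midera_path = path / f"{cid}_midera.csv"
        midera = (
            read_repertoire(midera_path, cid, source_kind="synthetic")
            if midera_path.exists()
            else None
        )
        ann_path = path / f"{cid}_origins.csv"
        annotation = None
        if ann_path.exists():
            ann = pd.read_csv(ann_path)
            annotation = OriginAnnotation(
                origin=dict(zip(ann.surname.astype(str), ann.origin_province.astype(str)))
            )
        communities.append(
            CommunityData(
                meta=meta,
                founding=founding,
                present=present,
                midera=midera,
                annotation=annotation,
            )
        )
    return communities


def _as_community_data(c: SyntheticCommunity) -> CommunityData:
    return CommunityData(
        meta=c.meta,
        founding=c.founding,
        present=c.present,
        midera=c.midera,
        annotation=c.annotation,
    )


def _select(strategy: str, model: KinshipModel, data: CommunityData):
    if strategy == "R":
        return select_random(data.present, model, "all")
    if strategy == "FQ":
        return select_first_quartile(data.present, model)
    if strategy == "LS":
        if data.annotation is None:
            raise SurnameBiasError("LS strategy requires an origin annotation")
        return select_locally_spread(
            data.present, data.annotation, data.meta.province, model
        )
    if strategy == "GP":
        if data.midera is None:
            raise SurnameBiasError("GP strategy requires a mid-era repertoire")
        return select_grandparents(data.present, data.midera, model)
    if strategy == "FS":
        return select_founders(data.present, data.founding, model)
    raise SurnameBiasError(f"unknown strategy {strategy!r}")


def run_study(
    config: RunConfig, dataset: Sequence[CommunityData] | None = None
) -> dict[str, pd.DataFrame]:
    """Run the full study and write the report bundle to ``config.output_dir``.

    Returns the bundle tables keyed by name; a stage failing for one
    community is recorded in the error log and processing continues.
    """
    if dataset is None:
        if config.input_dir:
            dataset = load_dataset(config.input_dir)
        else:
            study = generate_study(config.n_communities, seed=config.seed)
            dataset = [_as_community_data(c) for c in study.communities]

    errors: list[str] = []
    bias_rows = []
    for data in dataset:
        cid = data.meta.community_id
        for strategy in config.strategies:
            for model_tag in config.models:
                model = KinshipModel(model_tag)
                try:
                    selection = _select(strategy, model, data)
                    result = sdb(selection, data.founding)
                    try:
                        iso = isonymy(selection).isonymy
                    except UndefinedStatisticError:
                        iso = float("nan")
                    bias_rows.append(
                        {
                            "community_id": cid,
                            "strategy": strategy,
                            "model": model.value,
                            "n_units": result.n_units,
                            "shared_units": result.shared_units,
                            "sdb": result.sdb,
                            "isonymy": iso,
                            "s_over_n": len(selection.types) / selection.n_units,
                        }
                    )
                except SurnameBiasError as exc:
                    errors.append(f"{cid}/{strategy}/{model_tag}: sampling: {exc}")
    bias = pd.DataFrame(bias_rows)

    if not bias.empty:
        strategy_summary = (
            bias.groupby(["strategy", "model"])["sdb"]
            .agg(["min", "mean", "max", "std"])
            .reset_index()
        )
        diversity_summary = (
            bias.groupby(["strategy", "model"])[["s_over_n", "isonymy"]]
            .agg(["mean", "std"])
            .reset_index()
        )
        diversity_summary.columns = [
            "_".join(filter(None, col)) for col in diversity_summary.columns
        ]
    else:
        strategy_summary = pd.DataFrame()
        diversity_summary = pd.DataFrame()

    drift_rows = []
    if config.drift_enabled:
        observed = bias[(bias.strategy == "R") & (bias.model == "LK")].set_index(
            "community_id"
        )["sdb"]
        for data in dataset:
            cid = data.meta.community_id
            years = data.meta.present_year - data.meta.oldest_year
            try:
                row: dict[str, object] = {
                    "community_id": cid,
                    "observed_r_lk_sdb": float(observed.get(cid, float("nan"))),
                }
                for size_model in ("growth", "stationary"):
                    params = DriftParams(
                        founding=data.founding,
                        years=years,
                        size_model=size_model,
                        final_size=data.present.n,
                        iterations=config.drift_iterations,
                        seed=config.seed,
                    )
                    res = simulate_community(params)
                    row[f"simulated_sdb_{size_model}"] = res.mean_sdb
                    row[f"retention_{size_model}"] = float(res.retention.mean())
                drift_rows.append(row)
            except SurnameBiasError as exc:
                errors.append(f"{cid}: drift: {exc}")
    drift_comparison = pd.DataFrame(drift_rows)

    jk_rows = []
    if config.jackknife_enabled:
        plan = JackknifePlan(
            sizes=config.jackknife_sizes,
            replicates=config.jackknife_replicates,
            seed=config.seed,
        )
        import warnings as _warnings

        for data in dataset:
            try:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    res = jackknife_subsample(data.present, plan, data.founding)
                summ = res.summary()
                summ.insert(0, "community_id", data.meta.community_id)
                jk_rows.append(summ)
            except SurnameBiasError as exc:
                errors.append(f"{data.meta.community_id}: jackknife: {exc}")
    jackknife = pd.concat(jk_rows, ignore_index=True) if jk_rows else pd.DataFrame()

    reg_rows = []
    meta_by_cid = {d.meta.community_id: d for d in dataset}
    if not bias.empty and len(dataset) >= 3:
        for (strategy, model_tag), group in bias.groupby(["strategy", "model"]):
            if strategy == "FS":  # SDB identically 0 by construction
                continue
            group = group.set_index("community_id")
            for covariate in COVARIATES:
                xs, ys = [], []
                for cid, row in group.iterrows():
                    d = meta_by_cid[cid]
                    value = {
                        "altitude": d.meta.altitude_m,
                        "present_n": d.present.n,
                        "foundation_year": d.meta.oldest_year,
                        "growth_rate": growth_rate(d.founding.n, d.present.n),
                    }[covariate]
                    xs.append(value)
                    ys.append(row.sdb)
                if len(ys) < 3 or np.ptp(xs) == 0:
                    continue
                fit = regress_bias(ys, xs)
                reg_rows.append(
                    {
                        "strategy": strategy,
                        "model": model_tag,
                        "covariate": covariate,
                        "r_squared": fit["r_squared"],
                        "sign": fit["sign"],
                        "p_value": fit["p_value"],
                    }
                )
    regressions = pd.DataFrame(reg_rows)
    if not regressions.empty:
        regressions["adjusted_p"] = bonferroni(
            regressions["p_value"].tolist(), family_size=DEFAULT_REGRESSION_FAMILY
        )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = {
        "bias_results": bias,
        "strategy_summary": strategy_summary,
        "diversity_summary": diversity_summary,
        "drift_comparison": drift_comparison,
        "jackknife": jackknife,
        "regressions": regressions,
    }
    for name, frame in bundle.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    log_lines = [
        f"surnamebias {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {config.seed}",
        f"communities {len(dataset)}",
        f"strategies {','.join(config.strategies)} models {','.join(config.models)}",
        f"errors {len(errors)}",
        *errors,
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return bundle
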