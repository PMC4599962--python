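"""Surname repertoires: data model, readers/writers, lemmatization, descriptors.

A *repertoire* is the complete surname frequency list of one community at one
era, from one documentary source (a census, a register of baptismal or
marriage acts, a phone directory, a municipal record, or a synthetic
generator). It is the elementary object of surname-based biodemography:
every downstream quantity — the sampling-dependent bias, isonymy, the S/N
diversity ratio — is a functional of one or two repertoires.

Surnames are kept in a single canonical form (trimmed, uppercased, internal
whitespace collapsed) so that the same token read from different sources
compares equal. Merging of genuine orthographic variants ("Bevlacqua" for
"Bevilacqua", double surnames reduced to the transmitted head) is *never*
automatic: it is driven by explicit per-community :class:`LemmaRule` lists,
reflecting the stringent criterion used in archival practice to avoid
collapsing distinct patrilineages (Rosso vs Rossi) by accident.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, RuleError, ValidationError

__all__ = [
    "SOURCE_KINDS",
    "LEMMA_RULE_KINDS",
    "canonical_surname",
    "Repertoire",
    "CommunityMeta",
    "LemmaRule",
    "read_repertoire",
    "write_repertoire",
    "read_lemma_rules",
    "apply_lemmatization",
    "s_over_n",
    "growth_rate",
    "aggregate_repertoires",
    "read_community_metadata",
    "load_study_communities",
]

SOURCE_KINDS = frozenset(
    {"census", "baptismal", "marriage", "phonebook", "municipal", "synthetic"}
)

LEMMA_RULE_KINDS = frozenset({"edit_correction", "variant_merge", "compound_reduction"})

_WS = re.compile(r"\s+")


def canonical_surname(raw: str) -> str:
    """Return the canonical form of a surname token.

    Canonicalization trims leading/trailing whitespace, collapses internal
    whitespace runs to a single space, and uppercases. It is idempotent.

    Raises
    ------
    ValidationError
        If the token is empty after trimming.
    """
    token = _WS.sub(" ", str(raw).strip()).upper()
    if not token:
        raise ValidationError("surname is empty after canonicalization")
    return token


@dataclass(frozen=True)
class Repertoire:
    """A community's surname frequency table at one era.

    Parameters
    ----------
    community_id : str
        Identifier of the community (municipality).
    era_year : int
        Year AD of the documentary source.
    source_kind : str
        One of ``census, baptismal, marriage, phonebook, municipal, synthetic``.
    counts : mapping of surname -> bearer count
        Surnames are canonicalized on construction; counts must be positive
        integers. Duplicate raw forms that canonicalize to the same surname
        are summed.

    Attributes
    ----------
    n : int
        Total bearers (sum of counts).
    s : int
        Number of distinct surnames.
    """

    community_id: str
    era_year: int
    source_kind: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise ValidationError(
                f"unknown source_kind {self.source_kind!r}; expected one of "
                f"{sorted(SOURCE_KINDS)}"
            )
        merged: dict[str, int] = {}
        for raw, count in dict(self.counts).items():
            name = canonical_surname(raw)
            c = int(count)
            if c != count or c < 1:
                raise ValidationError(
                    f"count for surname {name!r} must be a positive integer, got {count!r}"
                )
            merged[name] = merged.get(name, 0) + c
        if not merged:
            raise ValidationError("a repertoire must contain at least one surname")
        object.__setattr__(self, "counts", merged)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def s(self) -> int:
        return len(self.counts)

    @property
    def types(self) -> frozenset[str]:
        """The support: the set of distinct surnames."""
        return frozenset(self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Tidy two-column table (surname, count), sorted by count desc then name."""
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["surname", "count"])

    def with_counts(self, counts: Mapping[str, int], **overrides) -> "Repertoire":
        """A copy of this repertoire with new counts (and optional field overrides)."""
        kw = dict(
            community_id=self.community_id,
            era_year=self.era_year,
            source_kind=self.source_kind,
        )
        kw.update(overrides)
        return Repertoire(counts=counts, **kw)


@dataclass(frozen=True)
class CommunityMeta:
    """Descriptors of one community: where it sits and when it was recorded."""

    community_id: str
    region: str
    province: str
    altitude_m: int
    oldest_year: int
    present_year: int

    def __post_init__(self) -> None:
        if self.altitude_m < 0:
            raise ValidationError(f"{self.community_id}: altitude must be >= 0 m")
        if not self.oldest_year < self.present_year:
            raise ValidationError(
                f"{self.community_id}: oldest source year must precede the present one"
            )


@dataclass(frozen=True)
class LemmaRule:
    """One surname-merging rule.

    ``kind`` is one of ``edit_correction`` (fix a transcription mistake),
    ``variant_merge`` (merge a single-character variant) or
    ``compound_reduction`` (reduce a double surname to the transmitted head).
    ``pattern`` is the exact raw form to match (canonicalized), ``canonical``
    the form its bearers are moved to. Rules are per-community and are applied
    once each, in list order, non-recursively.
    """

    kind: str
    pattern: str
    canonical: str

    def __post_init__(self) -> None:
        if self.kind not in LEMMA_RULE_KINDS:
            raise RuleError(f"unknown rule kind {self.kind!r}")
        try:
            object.__setattr__(self, "pattern", canonical_surname(self.pattern))
            object.__setattr__(self, "canonical", canonical_surname(self.canonical))
        except ValidationError as exc:
            raise RuleError(f"malformed rule {self.kind}: {exc}") from exc


def _frame_to_counts(frame: pd.DataFrame, origin: str) -> dict[str, int]:
    cols = {c.strip().lower(): c for c in frame.columns}
    if "surname" not in cols:
        raise FormatError(f"{origin}: no 'surname' column (found {list(frame.columns)})")
    surnames = frame[cols["surname"]]
    if "count" in cols:
        counts_col = frame[cols["count"]]
    else:
        # No count column: each row records one bearer (per-event registers).
        counts_col = pd.Series([1] * len(frame), index=frame.index)
    counts: dict[str, int] = {}
    for i, (raw, cnt) in enumerate(zip(surnames, counts_col)):
        if pd.isna(raw):
            raise ValidationError(f"{origin}, row {i}: missing surname")
        if pd.isna(cnt) or int(cnt) != cnt or int(cnt) < 1:
            raise ValidationError(
                f"{origin}, row {i}: count must be a positive integer, got {cnt!r}"
            )
        name = canonical_surname(str(raw))
        counts[name] = counts.get(name, 0) + int(cnt)
    return counts


def read_repertoire(
    path: str | Path,
    community_id: str | None = None,
    era_year: int | None = None,
    source_kind: str = "census",
    fmt: str | None = None,
) -> Repertoire:
    """Read a repertoire from a delimited table or workbook.

    The table must have a ``surname`` column; a ``count`` column is optional
    (absent means each row is one bearer, as in per-event registers of
    marriage or baptismal acts). Duplicate surname rows are summed.

    Parameters
    ----------
    path : path
        CSV, TSV or XLSX file.
    community_id, era_year, source_kind :
        Metadata attached to the result; ``community_id`` defaults to the
        file stem.
    fmt : {"csv", "tsv", "xlsx"}, optional
        Forced format; by default inferred from the suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise FormatError(f"cannot infer format from suffix of {path.name!r}")
    if fmt == "csv":
        frame = pd.read_csv(path)
    elif fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
    elif fmt == "xlsx":
        frame = pd.read_excel(path)
    else:
        raise FormatError(f"unsupported format {fmt!r}")
    counts = _frame_to_counts(frame, origin=str(path))
    return Repertoire(
        community_id=community_id if community_id is not None else path.stem,
        era_year=era_year if era_year is not None else 0,
        source_kind=source_kind,
        counts=counts,
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as a two-column ``surname,count`` table (CSV/TSV/XLSX)."""
    path = Path(path)
    frame = rep.to_frame()
    suffix = path.suffix.lower()
    if suffix == ".csv":
        frame.to_csv(path, index=False)
    elif suffix in (".tsv", ".txt"):
        frame.to_csv(path, index=False, sep="\t")
    elif suffix == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        raise FormatError(f"unsupported output suffix {suffix!r}")


def read_lemma_rules(path: str | Path) -> list[LemmaRule]:
    """Read per-community lemma rules from a CSV with columns kind, pattern, canonical."""
    frame = pd.read_csv(path)
    needed = {"kind", "pattern", "canonical"}
    cols = {c.strip().lower() for c in frame.columns}
    if not needed <= cols:
        raise FormatError(f"{path}: rule file must have columns {sorted(needed)}")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return [
        LemmaRule(kind=row.kind, pattern=row.pattern, canonical=row.canonical)
        for row in frame.itertuples()
    ]


def apply_lemmatization(
    raw: Repertoire, rules: Sequence[LemmaRule]
) -> tuple[Repertoire, pd.DataFrame]:
    """Merge surname forms according to an explicit rule list.

    Each surname is rewritten by the *first* rule whose pattern matches it,
    once, non-recursively — a canonical form produced by one rule is not fed
    back through the list, which prevents merge cascades. Surnames matched by
    no rule pass through unchanged (the conservative contract: absent an
    explicit rule, forms such as Rosso and Rossi stay distinct).

    Returns
    -------
    (Repertoire, DataFrame)
        The merged repertoire and a report with columns
        ``raw_form, canonical_form, bearers_moved`` (one row per applied merge).
    """
    mapping: dict[str, str] = {}
    for rule in rules:
        mapping.setdefault(rule.pattern, rule.canonical)

    merged: dict[str, int] = {}
    report_rows: list[tuple[str, str, int]] = []
    for name, count in raw.counts.items():
        target = mapping.get(name, name)
        if target != name:
            report_rows.append((name, target, count))
        merged[target] = merged.get(target, 0) + count
    report = pd.DataFrame(
        report_rows, columns=["raw_form", "canonical_form", "bearers_moved"]
    )
    return raw.with_counts(merged), report


def s_over_n(rep: Repertoire) -> float:
    """Diversity ratio S/N: distinct surnames over total bearers, in (0, 1]."""
    return rep.s / rep.n


def growth_rate(n0: int, nt: int) -> float:
    """Relative growth rate (N_t − N_0) / N_t between two repertoire sizes.

    Positive when the community grew, negative when it shrank; unbounded
    below, bounded above by 1.
    """
    if n0 < 1 or nt < 1:
        raise ValidationError("bearer totals must be >= 1")
    return (nt - n0) / nt


def aggregate_repertoires(reps: Sequence[Repertoire], label: str) -> Repertoire:
    """Pool repertoires surname-wise (e.g. municipalities into a region).

    Counts are summed per surname over all members, so N is conserved
    (N_agg = ΣN_i) while shared surnames collapse (S_agg ≤ ΣS_i).
    """
    if not reps:
        raise ValidationError("cannot aggregate an empty list of repertoires")
    counts: dict[str, int] = {}
    for rep in reps:
        for name, count in rep.counts.items():
            counts[name] = counts.get(name, 0) + count
    return Repertoire(
        community_id=label,
        era_year=max(r.era_year for r in reps),
        source_kind=reps[0].source_kind,
        counts=counts,
    )


_META_COLUMNS = [
    "community_id",
    "region",
    "province",
    "altitude_m",
    "oldest_year",
    "present_year",
]


def read_community_metadata(path: str | Path) -> pd.DataFrame:
    """Read a community metadata table (one row per community).

    Required columns: community_id, region, province, altitude_m, oldest_year,
    present_year. Extra columns (e.g. bearer totals, printed growth rates)
    are preserved.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: metadata table lacks columns {missing}")
    for row in frame.itertuples():
        CommunityMeta(  # validates each row
            community_id=str(row.community_id),
            region=str(row.region),
            province=str(row.province),
            altitude_m=int(row.altitude_m),
            oldest_year=int(row.oldest_year),
            present_year=int(row.present_year),
        )
    return frame


def load_study_communities() -> pd.DataFrame:
    """Metadata of the 26 Italian study communities (years 1447–2001).

    The packaged table lists, for each municipality, its region and province,
    the kind and year of the oldest surname source and of the present-day one,
    the bearer totals (n0, nt) and distinct-surname totals (s0, st) of the two
    lists, the altitude in metres, and the growth rate as printed in the
    published community table (``printed_growth_rate`` — kept verbatim so that
    recomputed rates can be checked against it; the Montecarlo row is a known
    mismatch between the printed value and the formula applied to its own
    counts).
    """
    with resources.files("surnamebias").joinpath("data/study_communities.csv").open() as fh:
        frame = pd.read_csv(fh)
    return frame
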