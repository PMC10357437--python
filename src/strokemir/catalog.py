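"""Curated study catalog: ingest, miRNA name standardization, group qualification.

The catalog records one row per (study, reported miRNA) differential-expression
call from the published case-control literature on circulating miRNAs in
ischemic stroke.  Meta-analysis pools a miRNA only across studies that assayed
the same blood element (serum, plasma, whole blood, or PBMCs), so the central
product of this module is the list of "qualified groups": (canonical miRNA,
specimen) combinations reported by at least two independent studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

SPECIMENS = ("serum", "plasma", "whole_blood", "pbmc")

CATALOG_COLUMNS = [
    "study_id", "pmid", "first_author", "year", "country", "specimen",
    "n_case", "n_control", "technique", "mirna_reported", "direction",
]


class CatalogError(ValueError):
    """Raised for malformed catalog or alias inputs."""


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study of circulating miRNAs."""

    study_id: str
    first_author: str
    year: int
    specimen: str
    n_case: int
    n_control: int
    platform: str = ""

    def __post_init__(self):
        if self.specimen not in SPECIMENS:
            raise CatalogError(
                f"study {self.study_id!r}: unknown specimen {self.specimen!r} "
                f"(expected one of {SPECIMENS})"
            )
        if self.n_case < 1 or self.n_control < 1:
            raise CatalogError(
                f"study {self.study_id!r}: sample sizes must be >= 1 "
                f"(got {self.n_case}/{self.n_control})"
            )


@dataclass(frozen=True)
class MirnaReport:
    """One per-miRNA up/down call within a study."""

    study_id: str
    reported_name: str
    direction: str
    canonical_name: str = ""

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise CatalogError(
                f"report ({self.study_id}, {self.reported_name}): direction must "
                f"be 'up' or 'down', got {self.direction!r}"
            )


@dataclass(frozen=True)
class AliasMap:
    """Static reported-name -> canonical mature-name lookup (miRBase-style)."""

    entries: dict[str, str]

    def resolve(self, reported_name: str) -> str:
        return self.entries[reported_name]

    def __contains__(self, reported_name: str) -> bool:
        return reported_name in self.entries


@dataclass(frozen=True)
class QualifiedGroup:
    """A (canonical miRNA, specimen) stratum reported by >= 2 studies."""

    canonical_name: str
    specimen: str
    members: tuple[tuple[StudyRecord, MirnaReport], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.members) < 2:
            raise CatalogError(
                f"group ({self.canonical_name}, {self.specimen}): needs >= 2 members"
            )
        ids = [s.study_id for s, _ in self.members]
        if len(set(ids)) != len(ids):
            raise CatalogError(
                f"group ({self.canonical_name}, {self.specimen}): duplicate study"
            )
        for s, r in self.members:
            if s.specimen != self.specimen or r.canonical_name != self.canonical_name:
                raise CatalogError(
                    f"group ({self.canonical_name}, {self.specimen}): inconsistent member"
                )


def read_catalog(path) -> tuple[list[StudyRecord], list[MirnaReport]]:
    """Read a tab-separated study catalog.

    One row per (study, reported miRNA).  Study-level columns must be
    consistent across the rows of a study; duplicate (study, reported miRNA)
    rows are rejected as curation errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog {path}: missing columns {missing}")
    if df.empty:
        return [], []

    studies: dict[str, StudyRecord] = {}
    reports: list[MirnaReport] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        sid = row["study_id"]
        try:
            n_case, n_control = int(row["n_case"]), int(row["n_control"])
            year = int(row["year"])
        except (TypeError, ValueError) as exc:
            raise CatalogError(f"catalog row {idx} (study {sid!r}): {exc}") from None
        rec = StudyRecord(
            study_id=sid,
            first_author=row["first_author"],
            year=year,
            specimen=str(row["specimen"]),
            n_case=n_case,
            n_control=n_control,
            platform=row.get("technique", "") or "",
        )
        if sid in studies:
            if studies[sid] != rec:
                raise CatalogError(
                    f"catalog row {idx}: study {sid!r} has inconsistent study-level fields"
                )
        else:
            studies[sid] = rec
        key = (sid, row["mirna_reported"])
        if key in seen:
            raise CatalogError(
                f"catalog row {idx}: duplicate report {key} (same study, same miRNA)"
            )
        seen.add(key)
        reports.append(
            MirnaReport(
                study_id=sid,
                reported_name=row["mirna_reported"],
                direction=str(row["direction"]).lower(),
            )
        )
    return list(studies.values()), reports


def read_alias_map(path) -> AliasMap:
    """Read a two-column (reported_name, canonical_name) tab-separated table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("reported_name", "canonical_name"):
        if col not in df.columns:
            raise CatalogError(f"alias map {path}: missing column {col!r}")
    if df["reported_name"].duplicated().any():
        dups = df.loc[df["reported_name"].duplicated(), "reported_name"].tolist()
        raise CatalogError(f"alias map {path}: duplicate reported names {dups}")
    return AliasMap(entries=dict(zip(df["reported_name"], df["canonical_name"])))


def standardize_names(reports: list[MirnaReport], aliases: AliasMap) -> list[MirnaReport]:
    """Fill ``canonical_name`` for every report via the alias map.

    The alias map must cover every reported name; a partial map is a hard
    error listing everything it misses, so silent pass-through can never
    split a group.
    """
    missing = sorted({r.reported_name for r in reports if r.reported_name not in aliases})
    if missing:
        raise CatalogError(f"alias map does not cover reported names: {missing}")
    return [replace(r, canonical_name=aliases.resolve(r.reported_name)) for r in reports]


def qualify_groups(
    studies: list[StudyRecord], reports: list[MirnaReport]
) -> list[QualifiedGroup]:
    """Group standardized reports by (canonical miRNA, specimen); keep groups
    with at least two distinct member studies.

    Output order is deterministic (canonical name, then specimen) and
    independent of input row order.  A study may appear in at most one member
    slot per group (enforced at read time by the duplicate-report check).
    """
    by_id = {s.study_id: s for s in studies}
    buckets: dict[tuple[str, str], list[tuple[StudyRecord, MirnaReport]]] = {}
    for rep in reports:
        if not rep.canonical_name:
            raise CatalogError(
                f"report ({rep.study_id}, {rep.reported_name}) is not standardized"
            )
        study = by_id[rep.study_id]
        buckets.setdefault((rep.canonical_name, study.specimen), []).append((study, rep))
    groups = []
    for (name, specimen), members in sorted(buckets.items()):
        if len({s.study_id for s, _ in members}) >= 2:
            members = tuple(sorted(members, key=lambda m: (m[0].year, m[0].study_id)))
            groups.append(QualifiedGroup(name, specimen, members))
    return groups


def multi_study_mirnas(
    studies: list[StudyRecord], reports: list[MirnaReport]
) -> list[str]:
    """Canonical miRNAs reported by more than one study (any specimen)."""
    by_name: dict[str, set[str]] = {}
    for rep in reports:
        by_name.setdefault(rep.canonical_name or rep.reported_name, set()).add(rep.study_id)
    return sorted(name for name, sids in by_name.items() if len(sids) > 1)
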