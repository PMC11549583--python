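"""Domain types and three-table interchange format for egocentric study data.

A study is stored as three CSV tables (plus an optional fourth):

* ``egos.csv`` — one row per respondent (ego) with sociodemographics,
  vaccination status and the health-information media sources used;
* ``alters.csv`` — one row per nominated social contact (alter), keyed by
  ``ego_id`` + ``alter_id``, carrying alter attributes and the ego-alter tie
  attributes (emotional closeness, meeting frequency);
* ``ties.csv`` — one row per reported alter–alter relationship, keyed by
  ``ego_id`` + the two alter ids;
* ``referrals.csv`` — optional link-tracing recruitment edges
  (referrer ego → referred ego).

Ordinal answers are stored as canonical lowercase tokens (``very_close``,
``every_2_weeks``, ``casual_friend``, ...); 1-based numeric codes are accepted
on read.  Missing values are empty cells on disk and ``None`` in memory; this
layer never imputes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "MEDIA_SOURCES",
    "CLOSENESS_LEVELS",
    "MEET_FREQUENCY_LEVELS",
    "TIE_STRENGTH_LEVELS",
    "EgoRecord",
    "AlterRecord",
    "AlterTie",
    "PersonalNetwork",
    "StudyData",
    "NetworkReport",
    "ValidationReport",
    "load_study",
    "save_study",
    "validate_study",
    "export_graphml",
]

#: The five health-information source options offered to egos.  The first two
#: are legacy outlets, the last three internet-based ones.
MEDIA_SOURCES = (
    "central_tv",
    "local_press",
    "search_engines",
    "social_media",
    "influencers",
)

#: Emotional closeness of the ego to an alter (4-level ordinal).
CLOSENESS_LEVELS = ("not_at_all", "not_very", "close", "very_close")

#: Face-to-face meeting frequency between ego and alter (7-level ordinal).
MEET_FREQUENCY_LEVELS = (
    "lt_once_year",
    "once_year",
    "few_times_year",
    "once_month",
    "every_2_weeks",
    "weekly",
    "daily",
)

#: Reported strength of an alter–alter relationship (3-level ordinal).
TIE_STRENGTH_LEVELS = ("acquaintance", "casual_friend", "close_friend")

_MEDIA_COLUMNS = {
    "central_tv": "media_central_tv",
    "local_press": "media_local_press",
    "search_engines": "media_search",
    "social_media": "media_social",
    "influencers": "media_influencers",
}

_EGO_COLUMNS = [
    "ego_id", "sex", "age", "education", "single", "employed", "vaccinated",
    *_MEDIA_COLUMNS.values(),
]
_ALTER_COLUMNS = [
    "ego_id", "alter_id", "sex", "age", "education", "single", "vaccinated",
    "closeness", "meet_frequency",
]
_TIE_COLUMNS = ["ego_id", "a", "b", "strength"]
_REFERRAL_COLUMNS = ["referrer", "referred"]


@dataclass(frozen=True)
class EgoRecord:
    """A surveyed respondent (the center of one personal network)."""

    ego_id: str
    sex: Optional[int] = None            # 1 = female, 0 = male
    age_years: Optional[int] = None      # >= 18 by design
    education: Optional[int] = None      # ordinal 1-13 (no school .. PhD)
    single: Optional[int] = None
    employed: Optional[int] = None
    vaccinated: Optional[int] = None
    #: Sources consulted for health/prevention information; ``None`` when the
    #: question went unanswered, empty frozenset when explicitly none.
    media_sources: Optional[frozenset] = None


@dataclass(frozen=True)
class AlterRecord:
    """A social contact nominated by an ego, as reported by the ego."""

    alter_id: str
    sex: Optional[int] = None
    age_years: Optional[int] = None
    education: Optional[int] = None
    single: Optional[int] = None
    vaccinated: Optional[int] = None     # may be unknown to the ego
    closeness: Optional[str] = None      # token from CLOSENESS_LEVELS
    meet_frequency: Optional[str] = None  # token from MEET_FREQUENCY_LEVELS


@dataclass(frozen=True)
class AlterTie:
    """An undirected ego-reported relationship between two alters."""

    a: str
    b: str
    strength: Optional[str] = None       # token from TIE_STRENGTH_LEVELS

    def key(self) -> tuple:
        return (min(self.a, self.b), max(self.a, self.b))


@dataclass(frozen=True)
class PersonalNetwork:
    """One ego together with its alters and the alter–alter tie list.

    The ego itself is never a node of the alter graph; every structural
    measure downstream is computed on the alters alone.
    """

    ego: EgoRecord
    alters: tuple = ()
    ties: tuple = ()

    @property
    def ego_id(self) -> str:
        return self.ego.ego_id

    def alter_ids(self) -> list:
        return [a.alter_id for a in self.alters]

    def alter(self, alter_id: str) -> AlterRecord:
        for a in self.alters:
            if a.alter_id == alter_id:
                return a
        raise KeyError(alter_id)


@dataclass(frozen=True)
class StudyData:
    """A collection of personal networks plus the optional referral chain."""

    networks: tuple = ()
    referral_edges: Optional[tuple] = None  # (referrer ego_id, referred ego_id)

    def ego_ids(self) -> list:
        return [n.ego_id for n in self.networks]

    def network(self, ego_id: str) -> PersonalNetwork:
        for n in self.networks:
            if n.ego_id == ego_id:
                return n
        raise KeyError(ego_id)


@dataclass(frozen=True)
class NetworkReport:
    ego_id: str
    n_alters: int
    n_missing_vaccination: int
    n_isolates: int
    n_duplicate_ties: int


@dataclass(frozen=True)
class ValidationReport:
    networks: tuple = ()
    n_networks: int = 0

    def for_ego(self, ego_id: str) -> NetworkReport:
        for r in self.networks:
            if r.ego_id == ego_id:
                return r
        raise KeyError(ego_id)


# ---------------------------------------------------------------------------
# coercion helpers

def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA


def _coerce_int(value, column: str):
    if _is_missing(value) or (isinstance(value, str) and not value.strip()):
        return None
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"column {column!r}: cannot parse {value!r} as an integer")
    if as_float != int(as_float):
        raise FormatError(f"column {column!r}: cannot parse {value!r} as an integer")
    return int(as_float)


def _coerce_level(value, levels: Sequence[str], column: str):
    """Map a cell to a canonical ordinal token; numeric codes are 1-based."""
    if _is_missing(value) or (isinstance(value, str) and not value.strip()):
        return None
    if isinstance(value, str):
        token = value.strip().lower()
        if token in levels:
            return token
        if token.isdigit():
            value = int(token)
        else:
            return None  # unparseable label recorded as missing, not dropped
    if isinstance(value, (int, float)):
        code = int(value)
        if 1 <= code <= len(levels):
            return levels[code - 1]
    return None


def _read_table(path, columns: Sequence[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{name} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""],
                     comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{name} table {path} is missing column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# load / save / validate

def load_study(egos_path, alters_path, ties_path, referrals_path=None) -> StudyData:
    """Read a study from the three-table CSV format.

    Unparseable ordinal labels become missing values rather than being
    dropped.  Dangling tie endpoints and duplicate ego ids raise
    :class:`~pnavax.errors.IntegrityError`; duplicate undirected ties are
    collapsed with a warning (field data plausibly records both orientations).
    """
    egos_df = _read_table(egos_path, _EGO_COLUMNS, "egos")
    alters_df = _read_table(alters_path, _ALTER_COLUMNS, "alters")
    ties_df = _read_table(ties_path, _TIE_COLUMNS, "ties")

    ego_ids = list(egos_df["ego_id"])
    dupes = {e for e in ego_ids if ego_ids.count(e) > 1}
    if dupes:
        raise IntegrityError(f"duplicate ego_id(s): {sorted(dupes)}")

    alters_by_ego: dict = {e: [] for e in ego_ids}
    for row in alters_df.itertuples(index=False):
        rec = AlterRecord(
            alter_id=str(row.alter_id),
            sex=_coerce_int(row.sex, "sex"),
            age_years=_coerce_int(row.age, "age"),
            education=_coerce_int(row.education, "education"),
            single=_coerce_int(row.single, "single"),
            vaccinated=_coerce_int(row.vaccinated, "vaccinated"),
            closeness=_coerce_level(row.closeness, CLOSENESS_LEVELS, "closeness"),
            meet_frequency=_coerce_level(row.meet_frequency, MEET_FREQUENCY_LEVELS,
                                         "meet_frequency"),
        )
        if row.ego_id not in alters_by_ego:
            raise IntegrityError(f"alter {rec.alter_id!r} references unknown ego {row.ego_id!r}")
        alters_by_ego[row.ego_id].append(rec)

    ties_by_ego: dict = {e: [] for e in ego_ids}
    for row in ties_df.itertuples(index=False):
        if row.ego_id not in ties_by_ego:
            raise IntegrityError(f"tie ({row.a}, {row.b}) references unknown ego {row.ego_id!r}")
        known = {a.alter_id for a in alters_by_ego[row.ego_id]}
        for endpoint in (row.a, row.b):
            if str(endpoint) not in known:
                raise IntegrityError(
                    f"tie ({row.a}, {row.b}) of ego {row.ego_id!r} references "
                    f"unknown alter {endpoint!r}"
                )
        tie = AlterTie(a=str(row.a), b=str(row.b),
                       strength=_coerce_level(row.strength, TIE_STRENGTH_LEVELS, "strength"))
        if tie.a == tie.b:
            raise IntegrityError(f"self-tie ({tie.a}, {tie.b}) for ego {row.ego_id!r}")
        ties_by_ego[row.ego_id].append(tie)

    networks = []
    for row in egos_df.itertuples(index=False):
        sources = []
        any_answer = False
        for source, col in _MEDIA_COLUMNS.items():
            cell = getattr(row, col)
            flag = _coerce_int(cell, col)
            if flag is not None:
                any_answer = True
                if flag == 1:
                    sources.append(source)
        ego = EgoRecord(
            ego_id=str(row.ego_id),
            sex=_coerce_int(row.sex, "sex"),
            age_years=_coerce_int(row.age, "age"),
            education=_coerce_int(row.education, "education"),
            single=_coerce_int(row.single, "single"),
            employed=_coerce_int(row.employed, "employed"),
            vaccinated=_coerce_int(row.vaccinated, "vaccinated"),
            media_sources=frozenset(sources) if any_answer else None,
        )
        ties = _dedupe_ties(ties_by_ego[ego.ego_id], ego.ego_id)
        networks.append(PersonalNetwork(
            ego=ego,
            alters=tuple(alters_by_ego[ego.ego_id]),
            ties=ties,
        ))

    referral_edges = None
    if referrals_path is not None:
        ref_df = _read_table(referrals_path, _REFERRAL_COLUMNS, "referrals")
        referral_edges = tuple(
            (str(r.referrer), str(r.referred)) for r in ref_df.itertuples(index=False)
        )

    return StudyData(networks=tuple(networks), referral_edges=referral_edges)


def _dedupe_ties(ties: Iterable[AlterTie], ego_id: str) -> tuple:
    seen: dict = {}
    for tie in ties:
        key = tie.key()
        if key in seen:
            warnings.warn(
                f"ego {ego_id!r}: duplicate tie {key} collapsed", stacklevel=3
            )
            continue
        seen[key] = tie
    return tuple(seen.values())


def save_study(study: StudyData, out_dir) -> dict:
    """Write a study to ``out_dir`` in the three-table format.

    Returns a mapping of table name to path.  ``load_study(save_study(s))``
    is the identity on every typed field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def blank(v):
        return "" if v is None else v

    ego_rows = []
    alter_rows = []
    tie_rows = []
    for net in study.networks:
        e = net.ego
        row = {
            "ego_id": e.ego_id, "sex": blank(e.sex), "age": blank(e.age_years),
            "education": blank(e.education), "single": blank(e.single),
            "employed": blank(e.employed), "vaccinated": blank(e.vaccinated),
        }
        for source, col in _MEDIA_COLUMNS.items():
            if e.media_sources is None:
                row[col] = ""
            else:
                row[col] = int(source in e.media_sources)
        ego_rows.append(row)
        for a in net.alters:
            alter_rows.append({
                "ego_id": e.ego_id, "alter_id": a.alter_id, "sex": blank(a.sex),
                "age": blank(a.age_years), "education": blank(a.education),
                "single": blank(a.single), "vaccinated": blank(a.vaccinated),
                "closeness": blank(a.closeness),
                "meet_frequency": blank(a.meet_frequency),
            })
        for t in net.ties:
            tie_rows.append({"ego_id": e.ego_id, "a": t.a, "b": t.b,
                             "strength": blank(t.strength)})

    paths = {
        "egos": out_dir / "egos.csv",
        "alters": out_dir / "alters.csv",
        "ties": out_dir / "ties.csv",
    }
    pd.DataFrame(ego_rows, columns=_EGO_COLUMNS).to_csv(paths["egos"], index=False)
    pd.DataFrame(alter_rows, columns=_ALTER_COLUMNS).to_csv(paths["alters"], index=False)
    pd.DataFrame(tie_rows, columns=_TIE_COLUMNS).to_csv(paths["ties"], index=False)
    if study.referral_edges is not None:
        paths["referrals"] = out_dir / "referrals.csv"
        pd.DataFrame(study.referral_edges, columns=_REFERRAL_COLUMNS).to_csv(
            paths["referrals"], index=False)
    return paths


def validate_study(study: StudyData) -> ValidationReport:
    """Summarize per-network data quality without mutating the input."""
    reports = []
    for net in study.networks:
        ids = set(net.alter_ids())
        keys = [t.key() for t in net.ties]
        n_dup = len(keys) - len(set(keys))
        touched = set()
        for t in net.ties:
            touched.add(t.a)
            touched.add(t.b)
        n_isolates = len(ids - touched)
        n_missing = sum(1 for a in net.alters if a.vaccinated is None)
        reports.append(NetworkReport(
            ego_id=net.ego_id,
            n_alters=len(net.alters),
            n_missing_vaccination=n_missing,
            n_isolates=n_isolates,
            n_duplicate_ties=n_dup,
        ))
    return ValidationReport(networks=tuple(reports), n_networks=len(reports))


def export_graphml(network: PersonalNetwork, path) -> None:
    """Write the binarized alter graph of one network as GraphML."""
    from .structure import build_alter_graph

    g = build_alter_graph(network)
    for a in network.alters:
        if a.vaccinated is not None:
            g.nodes[a.alter_id]["vaccinated"] = int(a.vaccinated)
    nx.write_graphml(g, path)
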