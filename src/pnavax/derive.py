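"""Derived variables: media categorization, tie binarization, z-scoring.

The study codes the ego's health-information diet as a three-level factor —
``traditional`` (central TV and/or local press only), ``online`` (search
engines, social media and/or influencers only) and ``both`` — with
``traditional`` as the modeling reference level.  Ego–alter tie attributes
collapse to binaries: ``very_close`` (emotional closeness at its top level),
``meets_2x_month`` (face-to-face at least every two weeks) and their product,
the ego–alter ``intensity`` indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .network_model import (
    CLOSENESS_LEVELS,
    MEDIA_SOURCES,
    MEET_FREQUENCY_LEVELS,
    TIE_STRENGTH_LEVELS,
    PersonalNetwork,
    StudyData,
)

__all__ = [
    "MEDIA_CATEGORIES",
    "TRADITIONAL_SOURCES",
    "ONLINE_SOURCES",
    "categorize_media",
    "binarize_closeness",
    "binarize_meet_frequency",
    "binarize_tie",
    "intensity",
    "standardize",
    "unstandardize",
    "derive_alter_table",
    "derive_ego_table",
]

MEDIA_CATEGORIES = ("traditional", "online", "both", "missing")
TRADITIONAL_SOURCES = frozenset({"central_tv", "local_press"})
ONLINE_SOURCES = frozenset({"search_engines", "social_media", "influencers"})

# binarization boundary: "at least twice a month" starts at every_2_weeks
_FREQUENT_LEVELS = frozenset({"every_2_weeks", "weekly", "daily"})


def categorize_media(sources) -> str:
    """Collapse an ego's media-source set to traditional / online / both.

    ``None`` (question unanswered) and the empty set both map to ``missing``.
    """
    if sources is None:
        return "missing"
    sources = frozenset(sources)
    unknown = sources - frozenset(MEDIA_SOURCES)
    if unknown:
        raise ValueError(f"unknown media source token(s): {sorted(unknown)}")
    if not sources:
        return "missing"
    has_traditional = bool(sources & TRADITIONAL_SOURCES)
    has_online = bool(sources & ONLINE_SOURCES)
    if has_traditional and has_online:
        return "both"
    return "traditional" if has_traditional else "online"


def binarize_closeness(level: Optional[str]) -> Optional[int]:
    """1 iff the ego reports feeling *very close* to the alter."""
    if level is None:
        return None
    if level not in CLOSENESS_LEVELS:
        raise ValueError(f"unknown closeness level: {level!r}")
    return int(level == "very_close")


def binarize_meet_frequency(level: Optional[str]) -> Optional[int]:
    """1 iff ego and alter meet at least twice a month (every 2 weeks or more)."""
    if level is None:
        return None
    if level not in MEET_FREQUENCY_LEVELS:
        raise ValueError(f"unknown meet-frequency level: {level!r}")
    return int(level in _FREQUENT_LEVELS)


def binarize_tie(strength: Optional[str]) -> int:
    """1 for any reported relationship (acquaintance or stronger), 0 if absent."""
    if strength is None:
        return 0
    if strength not in TIE_STRENGTH_LEVELS:
        raise ValueError(f"unknown tie strength: {strength!r}")
    return 1


def intensity(closeness: Optional[str], meet_frequency: Optional[str]) -> Optional[int]:
    """Ego-alter intensity: very close AND meeting at least twice a month."""
    vc = binarize_closeness(closeness)
    mf = binarize_meet_frequency(meet_frequency)
    if vc is None or mf is None:
        return None
    return vc * mf


@dataclass(frozen=True)
class Standardization:
    mean: float
    sd: float


def standardize(values, ddof: int = 1):
    """Z-score a numeric vector, propagating missing values.

    Returns ``(z, Standardization(mean, sd))`` so the transform is
    invertible.  Requires at least two non-missing values with nonzero
    spread; the sample (``ddof=1``) standard deviation is the default.
    """
    arr = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    mask = ~np.isnan(arr)
    if mask.sum() < 2:
        raise DegenerateInputError("standardize needs >= 2 non-missing values")
    mean = float(arr[mask].mean())
    sd = float(arr[mask].std(ddof=ddof))
    if sd == 0.0:
        raise DegenerateInputError("standardize: zero spread")
    out = (arr - mean) / sd
    return out, Standardization(mean=mean, sd=sd)


def unstandardize(z, params: Standardization):
    arr = np.asarray(z, dtype=float)
    return arr * params.sd + params.mean


def derive_alter_table(study: StudyData) -> pd.DataFrame:
    """One row per alter with the binarized ego-alter tie variables."""
    rows = []
    for net in study.networks:
        for a in net.alters:
            vc = binarize_closeness(a.closeness)
            mf = binarize_meet_frequency(a.meet_frequency)
            rows.append({
                "ego_id": net.ego_id,
                "alter_id": a.alter_id,
                "sex": a.sex,
                "age": a.age_years,
                "education": a.education,
                "single": a.single,
                "vaccinated": a.vaccinated,
                "very_close": vc,
                "meets_2x_month": mf,
                "intensity": None if vc is None or mf is None else vc * mf,
            })
    return pd.DataFrame(rows)


def derive_ego_table(study: StudyData) -> pd.DataFrame:
    """One row per ego with the media-category factor added."""
    rows = []
    for net in study.networks:
        e = net.ego
        rows.append({
            "ego_id": e.ego_id,
            "sex": e.sex,
            "age": e.age_years,
            "education": e.education,
            "single": e.single,
            "employed": e.employed,
            "vaccinated": e.vaccinated,
            "media_category": categorize_media(e.media_sources),
        })
    return pd.DataFrame(rows)
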