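"""Cohort construction: eligibility, network filtering, and the model frame.

The analysis sample keeps only personal networks with at least ``min_alters``
alters that (a) have a known vaccination status and (b) are not isolates in
the binarized alter graph — isolates have no defined assortativity score.
The two-level model frame then takes one row per eligible alter, repeats the
ego-level columns within each network, drops egos whose media category is
missing and any remaining incomplete rows (complete-case analysis), and
z-scores the numeric predictors: alter-level numerics over the retained alter
rows, ego/network-level numerics over the retained egos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .assortativity import assortativity_table
from .derive import Standardization, derive_alter_table, derive_ego_table, standardize
from .errors import ConfigError, DegenerateInputError, EmptyFrameError
from .network_model import PersonalNetwork, StudyData
from .structure import build_alter_graph, structure_tables

__all__ = [
    "FilterReport",
    "ModelFrame",
    "eligible_alters",
    "filter_networks",
    "model_frame",
]

#: alter-level numerics z-scored over alter rows of the final frame
LEVEL1_NUMERICS = ("alter_education", "alter_age", "betweenness", "assortativity")
#: ego/network-level numerics z-scored over the distinct egos of the final frame
LEVEL2_NUMERICS = ("ego_education", "ego_age", "size", "density", "components")


@dataclass(frozen=True)
class EgoFunnelEntry:
    ego_id: str
    n_alters_raw: int
    n_alters_eligible: int
    included: bool
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class FilterReport:
    egos: tuple
    n_networks_in: int
    n_networks_out: int
    n_alter_rows_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.egos])


@dataclass
class ModelFrame:
    """Standardized two-level analysis table (one row per eligible alter)."""

    df: pd.DataFrame
    standardizations: dict = field(default_factory=dict)
    dropped_rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_groups(self) -> int:
        return self.df["ego_id"].nunique()


def eligible_alters(network: PersonalNetwork) -> list:
    """Alters with known vaccination status and degree >= 1 in the alter graph.

    Eligibility is evaluated once, on the original binarized graph; degrees
    are not recomputed after removing ineligible alters.
    """
    graph = build_alter_graph(network)
    return [a for a in network.alters
            if a.vaccinated is not None and graph.degree(a.alter_id) >= 1]


def filter_networks(study: StudyData, min_alters: int = 15) -> tuple:
    """Retain networks with >= ``min_alters`` eligible alters (inclusive bound).

    Returns ``(filtered StudyData, FilterReport)``.  Retained networks keep
    their full alter list; eligibility is re-derived downstream where needed.
    """
    if min_alters < 1:
        raise ConfigError(f"min_alters must be >= 1, got {min_alters}")
    entries = []
    kept = []
    n_rows = 0
    for net in study.networks:
        elig = eligible_alters(net)
        ok = len(elig) >= min_alters
        entries.append(EgoFunnelEntry(
            ego_id=net.ego_id,
            n_alters_raw=len(net.alters),
            n_alters_eligible=len(elig),
            included=ok,
            exclusion_reason=None if ok else "too_few_eligible_alters",
        ))
        if ok:
            kept.append(net)
            n_rows += len(elig)
    report = FilterReport(
        egos=tuple(entries),
        n_networks_in=len(study.networks),
        n_networks_out=len(kept),
        n_alter_rows_out=n_rows,
    )
    return StudyData(networks=tuple(kept),
                     referral_edges=study.referral_edges), report


def model_frame(study_filtered: StudyData, ddof: int = 1,
                standardize_numerics: bool = True) -> ModelFrame:
    """Assemble the standardized two-level analysis table.

    One row per eligible alter of each retained network, with the ego- and
    network-level columns repeated within networks.  Egos with a missing
    media category are dropped, as is any row still missing a model variable
    (complete case).  The outcome (alter vaccination) and binary indicators
    are left in their original units; numeric predictors are z-scored with
    the sample (``ddof=1``) SD by default.  The leave-one-out proportion of
    vaccinated alters (``loo_prop``) is computed over the frame's own rows.
    """
    alters = derive_alter_table(study_filtered)
    egos = derive_ego_table(study_filtered)
    ego_struct, alter_struct = structure_tables(study_filtered)
    assort = assortativity_table(study_filtered)

    if alters.empty:
        raise EmptyFrameError("no alters in filtered study")

    eligible_keys = set()
    for net in study_filtered.networks:
        for a in eligible_alters(net):
            eligible_keys.add((net.ego_id, a.alter_id))

    df = alters.rename(columns={
        "sex": "alter_sex", "age": "alter_age", "education": "alter_education",
        "single": "alter_single",
    })
    df = df.merge(alter_struct, on=["ego_id", "alter_id"], how="left")
    df = df.merge(assort[["ego_id", "alter_id", "score"]]
                  .rename(columns={"score": "assortativity"}),
                  on=["ego_id", "alter_id"], how="left")
    df = df.merge(egos.rename(columns={
        "sex": "ego_sex", "age": "ego_age", "education": "ego_education",
        "employed": "ego_employed", "vaccinated": "ego_vaccinated",
    })[["ego_id", "ego_sex", "ego_age", "ego_education", "ego_employed",
        "ego_vaccinated", "media_category"]], on="ego_id", how="left")
    df = df.merge(ego_struct, on="ego_id", how="left")

    keymask = df.apply(lambda r: (r["ego_id"], r["alter_id"]) in eligible_keys, axis=1)
    dropped = []
    ineligible = df[~keymask].copy()
    ineligible["drop_reason"] = "ineligible_alter"
    dropped.append(ineligible)
    df = df[keymask].copy()

    media_missing = df["media_category"] == "missing"
    d = df[media_missing].copy()
    d["drop_reason"] = "ego_media_missing"
    dropped.append(d)
    df = df[~media_missing].copy()

    model_cols = [
        "vaccinated", "alter_sex", "alter_education", "alter_single",
        "alter_age", "intensity", "betweenness", "assortativity",
        "ego_sex", "ego_education", "ego_age", "ego_employed",
        "ego_vaccinated", "media_category", "size", "density", "components",
    ]
    incomplete = df[model_cols].isna().any(axis=1)
    d = df[incomplete].copy()
    d["drop_reason"] = "incomplete_row"
    dropped.append(d)
    df = df[~incomplete].copy()

    if df.empty:
        raise EmptyFrameError("model frame is empty after filtering")

    # leave-one-out vaccinated proportion over the frame's own alters
    grp = df.groupby("ego_id")["vaccinated"]
    tot = grp.transform("sum")
    cnt = grp.transform("count")
    with np.errstate(invalid="ignore"):
        df["loo_prop"] = (tot - df["vaccinated"]) / (cnt - 1)

    df["media_online"] = (df["media_category"] == "online").astype(int)
    df["media_both"] = (df["media_category"] == "both").astype(int)

    # Constant columns (e.g. every retained network a single component) have
    # no z-scale; they enter centered at zero and are flagged as degenerate.
    def _z(values, col):
        try:
            z, params = standardize(values, ddof=ddof)
            return z, params
        except DegenerateInputError:
            warnings.warn(f"model_frame: {col!r} has no spread; "
                          "z-score set to 0", stacklevel=2)
            return np.zeros(len(values)), Standardization(
                mean=float(pd.to_numeric(pd.Series(values),
                                         errors="coerce").mean()),
                sd=float("nan"))

    standardizations = {}
    if standardize_numerics:
        for col in LEVEL1_NUMERICS:
            z, params = _z(df[col], col)
            df[col + "_z"] = z
            standardizations[col] = params
        ego_level = df.drop_duplicates("ego_id")
        for col in LEVEL2_NUMERICS:
            _, params = _z(ego_level[col], col)
            if np.isnan(params.sd):
                df[col + "_z"] = 0.0
            else:
                df[col + "_z"] = (df[col] - params.mean) / params.sd
            standardizations[col] = params
    else:
        for col in (*LEVEL1_NUMERICS, *LEVEL2_NUMERICS):
            df[col + "_z"] = df[col].astype(float)

    for col in ("vaccinated", "alter_sex", "alter_single", "intensity",
                "ego_sex", "ego_employed", "ego_vaccinated"):
        df[col] = df[col].astype(int)

    dropped_df = pd.concat(dropped, ignore_index=True) if dropped else pd.DataFrame()
    return ModelFrame(df=df.reset_index(drop=True),
                      standardizations=standardizations,
                      dropped_rows=dropped_df)
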