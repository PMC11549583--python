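"""Per-alter vaccination assortativity and referral-chain concordance.

The assortativity score of a focal alter *i* inside one personal network is
a difference of two proportions, both computed with *i* itself excluded:

.. math::

    s_i = \\frac{\\#\\{\\text{vaccinated network neighbors of } i\\}}
               {\\#\\{\\text{neighbors of } i\\}}
        - \\frac{\\#\\{\\text{vaccinated alters other than } i\\}}
               {\\#\\{\\text{alters other than } i\\}}

A positive score means the focal alter's direct contacts are vaccinated above
the network's own (leave-one-out) base rate — assortative mixing on the trait.
Scores live in [-1, 1].  Alters with unknown vaccination status are excluded
from numerator and denominator of **both** proportions; an alter with no
usable neighbor (an isolate, or one whose neighbors all have unknown status)
has no defined score and is reported as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .network_model import PersonalNetwork, StudyData
from .structure import build_alter_graph

__all__ = [
    "AssortativityResult",
    "DyadSummary",
    "alter_assortativity",
    "network_assortativity",
    "network_mean_assortativity",
    "assortativity_table",
    "referral_concordance",
]


@dataclass(frozen=True)
class AssortativityResult:
    alter_id: str
    neighbor_prop: Optional[float]
    overall_prop: Optional[float]
    score: Optional[float]
    reason_missing: Optional[str] = None


@dataclass(frozen=True)
class DyadSummary:
    """Directed referrer→referred dyads classified by both vaccination statuses."""

    n_dyads: int
    n_vv: int  # vaccinated referred vaccinated
    n_vu: int  # vaccinated referred unvaccinated
    n_uv: int  # unvaccinated referred vaccinated
    n_uu: int  # unvaccinated referred unvaccinated
    n_excluded: int  # dyads with either status unknown

    @property
    def concordant_vacc_pct(self) -> Optional[float]:
        if self.n_dyads == 0:
            return None
        return 100.0 * self.n_vv / self.n_dyads


def alter_assortativity(network: PersonalNetwork, focal: str,
                        graph=None) -> AssortativityResult:
    """Assortativity score for one focal alter; see the module docstring.

    ``graph`` may carry a prebuilt binarized alter graph to avoid rebuilding
    it per focal alter.
    """
    if graph is None:
        graph = build_alter_graph(network)
    status = {a.alter_id: a.vaccinated for a in network.alters}
    if focal not in status:
        raise KeyError(f"unknown alter {focal!r}")

    others = [a for a in status if a != focal and status[a] is not None]
    if len(others) < 1:
        return AssortativityResult(focal, None, None, None,
                                   reason_missing="no_other_known_status")
    neighbors = [v for v in graph.neighbors(focal) if status[v] is not None]
    if not neighbors:
        reason = "isolate" if graph.degree(focal) == 0 else "neighbors_status_unknown"
        return AssortativityResult(focal, None, None, None, reason_missing=reason)

    neighbor_prop = sum(status[v] for v in neighbors) / len(neighbors)
    overall_prop = sum(status[a] for a in others) / len(others)
    return AssortativityResult(focal, neighbor_prop, overall_prop,
                               neighbor_prop - overall_prop)


def network_assortativity(network: PersonalNetwork) -> list:
    """Scores for every alter of one network (shared graph build)."""
    graph = build_alter_graph(network)
    return [alter_assortativity(network, a.alter_id, graph=graph)
            for a in network.alters]


def network_mean_assortativity(network: PersonalNetwork) -> tuple:
    """Mean of the non-missing scores and the count contributing.

    Returns ``(mean, n)``; ``(None, 0)`` when no score is defined.
    """
    scores = [r.score for r in network_assortativity(network) if r.score is not None]
    if not scores:
        return None, 0
    return sum(scores) / len(scores), len(scores)


def assortativity_table(study: StudyData) -> pd.DataFrame:
    """Per-alter rows (ego_id, alter_id, neighbor_prop, overall_prop, score)."""
    rows = []
    for net in study.networks:
        for r in network_assortativity(net):
            rows.append({
                "ego_id": net.ego_id,
                "alter_id": r.alter_id,
                "neighbor_prop": r.neighbor_prop,
                "overall_prop": r.overall_prop,
                "score": r.score,
                "reason_missing": r.reason_missing,
            })
    return pd.DataFrame(rows)


def referral_concordance(referral_edges: Sequence,
                         vaccination: Mapping) -> DyadSummary:
    """Classify directed referral dyads by the vaccination status of both egos.

    ``vaccination`` maps ego_id to 0/1/None; dyads where either ego is absent
    from the map or has unknown status are excluded from the denominator.
    """
    counts = {"vv": 0, "vu": 0, "uv": 0, "uu": 0}
    excluded = 0
    for referrer, referred in referral_edges:
        s1 = vaccination.get(referrer)
        s2 = vaccination.get(referred)
        if s1 is None or s2 is None:
            excluded += 1
            continue
        key = ("v" if s1 else "u") + ("v" if s2 else "u")
        counts[key] += 1
    n = sum(counts.values())
    return DyadSummary(n_dyads=n, n_vv=counts["vv"], n_vu=counts["vu"],
                       n_uv=counts["uv"], n_uu=counts["uu"], n_excluded=excluded)
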