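import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pnavax.network_model import (
    AlterRecord, AlterTie, EgoRecord, PersonalNetwork, StudyData,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def make_network(ego_id="e1", vaccination=(1, 1, 0), ties=((0, 1),),
                 media=frozenset({"central_tv"}), ego_vaccinated=1,
                 closeness="very_close", meet="weekly", **ego_kwargs):
    """Small personal network with alters a1..aN and index-pair ties."""
    alters = tuple(
        AlterRecord(
            alter_id=f"a{i + 1}", sex=i % 2, age_years=30 + i,
            education=7 + (i % 5),
            single=0, vaccinated=v, closeness=closeness, meet_frequency=meet,
        )
        for i, v in enumerate(vaccination)
    )
    tie_recs = tuple(
        AlterTie(a=f"a{i + 1}", b=f"a{j + 1}", strength="casual_friend")
        for i, j in ties
    )
    ego = EgoRecord(
        ego_id=ego_id, sex=1, age_years=50, education=10, single=0,
        employed=1, vaccinated=ego_vaccinated, media_sources=media,
        **ego_kwargs,
    )
    return PersonalNetwork(ego=ego, alters=alters, ties=tie_recs)


def recovery_frame(study):
    """Model frame matching the generator's own covariate coding.

    Bypasses filtering/standardization: covariates are the exact ones the
    generator's two-level logistic used, so fitted coefficients are directly
    comparable to the generating ones.  Requires a study generated without
    missingness.
    """
    import pandas as pd
    from pnavax.derive import ONLINE_SOURCES, TRADITIONAL_SOURCES
    from pnavax.filtering import ModelFrame

    rows = []
    for net in study.networks:
        ms = net.ego.media_sources or frozenset()
        online = bool(ms & ONLINE_SOURCES)
        trad = bool(ms & TRADITIONAL_SOURCES)
        for a in net.alters:
            rows.append({
                "ego_id": net.ego_id,
                "vaccinated": a.vaccinated,
                "media_online": int(online and not trad),
                "media_both": int(online and trad),
                "ego_vaccinated": net.ego.vaccinated,
                "alter_single": a.single,
                "alter_education_z": (a.education - 9.35) / 1.93,
            })
    return ModelFrame(df=pd.DataFrame(rows))


GEN_PREDICTORS = ("alter_education_z", "alter_single", "media_online",
                  "media_both", "ego_vaccinated")


@pytest.fixture
def small_study():
    """Two egos, three alters each, two ties each."""
    n1 = make_network("e1", vaccination=(1, 0, 1), ties=((0, 1), (1, 2)))
    n2 = make_network("e2", vaccination=(0, 0, None), ties=((0, 1), (0, 2)),
                      media=frozenset({"social_media"}), ego_vaccinated=0)
    return StudyData(networks=(n1, n2),
                     referral_edges=(("e1", "e2"),))
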