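import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from dcnet import CohortSpec, EffectSpec, clean_subject, generate_cohort
from dcnet.inference import nodewise_anova, posthoc_pairwise
from dcnet.network import build_dc_table


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_per_group={"HC": 6, "SD": 6, "MDD": 6}, g=30, T=120, seed=11,
        effects=(EffectSpec("MDD", 3, 8, 0.3),),
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    records, truth = generate_cohort(small_spec)
    return records, truth


def prep_cohort(records, tr_seconds=2.5):
    """Clean every subject; returns (series dict, phenotype frame with
    mean_fd, motion summaries dict)."""
    series, rows, summaries = {}, [], {}
    for rec in records:
        clean, summary = clean_subject(rec, tr_seconds=tr_seconds)
        summaries[rec.subject_id] = summary
        if clean is not None:
            series[rec.subject_id] = clean.series
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "age": rec.age,
                    "sex": rec.sex,
                    "education": rec.education,
                    "mean_fd": summary.mean_fd,
                }
            )
    return series, pd.DataFrame(rows), summaries


def hub_recovery_outcome(seed, delta, hub=None, g=60, n=30, partners=20):
    """One parameter-recovery replicate: generate, prep, DC, ANOVA gate,
    post-hoc per pair.  Returns dict of hub hits per pair."""
    from dcnet import weakest_hub

    probe = CohortSpec(n_per_group={"HC": 2, "SD": 2, "MDD": 2}, g=g, T=200, seed=seed)
    if hub is None:
        hub = weakest_hub(probe)
    spec = CohortSpec(
        n_per_group={"HC": n, "SD": n, "MDD": n}, g=g, T=200, seed=seed,
        effects=(EffectSpec("MDD", hub, partners, delta),),
    )
    records, _ = generate_cohort(spec)
    series, pheno, _ = prep_cohort(records)
    dc = build_dc_table(series, 0.30)
    anova = nodewise_anova(dc, pheno)
    significant = list(anova.index[anova["significant"]])
    hub_label = dc.node_labels[hub]
    hits = {}
    for pair in (("MDD", "HC"), ("SD", "HC"), ("MDD", "SD")):
        ph = posthoc_pairwise(dc, pheno, pair, nodes=significant)
        hits[pair] = hub_label in set(ph.index[ph["significant"]])
    return hits


def rng_for(*key):
    return np.random.default_rng(list(key))
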