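"""Shared fixtures: one moderately sized synthetic cohort, generated once per
session, plus the downstream pipeline products derived from it."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

import cpgpairs as cp


@pytest.fixture(scope="session")
def cohort_cfg() -> cp.SimConfig:
    return cp.SimConfig(
        n_tumor=120,
        n_normal=60,
        n_probes=300,
        n_dms_planted=40,
        n_genes=2000,
        pair_signal=0.95,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(cohort_cfg):
    return cp.generate_cohort(cohort_cfg)


@dataclass
class Pipeline:
    tumor: pd.DataFrame  # filtered + imputed
    normal: pd.DataFrame
    annotation: pd.DataFrame
    clinical: pd.DataFrame
    truth: cp.GroundTruth
    dms_table: pd.DataFrame
    dms_probes: list
    scores: pd.DataFrame  # filtered pair-score matrix
    labels: pd.Series


@pytest.fixture(scope="session")
def pipeline(cohort) -> Pipeline:
    tumor, normal, annotation, clinical, truth = cohort
    t = cp.filter_probes(tumor, annotation)
    n = cp.filter_probes(normal, annotation)
    t = cp.knn_impute(t)
    n = n.loc[t.index]
    dms_table = cp.wilcoxon_dms(t, n)
    dms_probes = cp.selected_probes(dms_table)
    scores = cp.filter_constant_pairs(cp.score_pairs(t, cp.build_pairs(dms_probes)))
    labels = cp.hierarchical_cluster(scores, k=3)
    return Pipeline(
        tumor=t,
        normal=n,
        annotation=annotation,
        clinical=clinical,
        truth=truth,
        dms_table=dms_table,
        dms_probes=dms_probes,
        scores=scores,
        labels=labels,
    )


@pytest.fixture(scope="session")
def expression(cohort_cfg, cohort):
    _, _, _, _, truth = cohort
    return cp.generate_expression(cohort_cfg, truth)


@pytest.fixture(scope="session")
def alterations(cohort_cfg, cohort):
    _, _, _, _, truth = cohort
    return cp.generate_alterations(cohort_cfg, truth)
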