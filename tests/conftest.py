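"""Shared fixtures: synthetic cohorts are generated in memory once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from snvorigin.io_formats import BinIndex, GeneRegionTable, LabelTable, SampleVariants
from snvorigin.net import Hyperparams, IntegrationSpec, TrainingSchedule, build_model
from snvorigin.pipeline import prepare_cell
from snvorigin.evaluate import stratified_group_shuffle_split
from snvorigin.synthgen import (SyntheticConfig, SyntheticTruth, generate_cohort,
                                generate_reference)


@dataclass
class Cohort:
    config: SyntheticConfig
    genome: dict
    bins: BinIndex
    genes: GeneRegionTable
    samples: list[SampleVariants]
    labels: LabelTable
    truth: SyntheticTruth


def build_cohort(config: SyntheticConfig) -> Cohort:
    reference = generate_reference(config)
    samples, labels, truth = generate_cohort(config, reference=reference)
    genome, bins, genes = reference
    return Cohort(config, genome, bins, genes, samples, labels, truth)


@pytest.fixture(scope="session")
def tiny_cohort() -> Cohort:
    """4 classes x 20 samples on a 6 Mb genome; strong class separation."""
    return build_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    """The tiny cohort written to disk in the documented directory layout."""
    from snvorigin.synthgen import make_fixture

    out = tmp_path_factory.mktemp("tiny_fixture")
    make_fixture("tiny", out, seed=11)
    return out


@pytest.fixture(scope="session")
def trained_tiny(tiny_cohort):
    """An early-integration model trained on the tiny cohort's first split.

    Uses a smooth activation (tanh) so integrated-gradients completeness
    checks converge cleanly with the step count.
    """
    splits = stratified_group_shuffle_split(tiny_cohort.labels, 3, seed=5)
    data = prepare_cell({s.sample_id: s for s in tiny_cohort.samples}, splits[0],
                        1.0, 1, 5, tiny_cohort.bins, tiny_cohort.genes,
                        tiny_cohort.genome, ("bins", "tri", "drivers"))
    spec = IntegrationSpec("early", [Hyperparams(n_layers=2, n_nodes=32,
                                                 activation="tanh", dropout=0.0)])
    model = build_model(spec, [X.shape[1] for X in data.Xs_train],
                        len(data.class_names), data.class_names, seed=5)
    model.fit(data.Xs_train, data.y_train,
              schedule=TrainingSchedule(epochs=30), seed=5)
    return model, data
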