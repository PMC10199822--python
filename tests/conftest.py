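"""Shared fixtures: one full-size simulation (seed 7) and one small one.

The full fixture backs the recovery/acceptance tests; the small one keeps
unit and CLI tests fast.  Both are session-scoped — the generator is
deterministic, so sharing is safe.
"""

import numpy as np
import pytest

from hexatac.synthetic_hexaploid import SimConfig, simulate


@pytest.fixture(scope="session")
def sim7():
    """Default-size simulation at seed 7 (the acceptance fixture)."""
    return simulate(SimConfig(seed=7))


def small_config(**overrides):
    base = dict(
        seed=3,
        chrom_length=300_000,
        n_triads=30,
        n_singletons=12,
        acrs_per_pattern=8,
        targets_per_tf=3,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def analysis7(sim7):
    """Refinement + differential-accessibility analysis of the seed-7 sim."""
    from hexatac.cli_pipeline import (
        Inputs,
        PipelineConfig,
        diff_acr_analysis,
        refine_all_tissues,
    )

    cfg = PipelineConfig(seed=7)
    inputs = Inputs(
        genome=sim7.genome, genes=sim7.genes, triads=sim7.triads,
        signals=sim7.signals, sample_tissues=sim7.sample_tissues,
        raw_peaks=sim7.raw_peaks, blacklist=sim7.blacklist, organelle=[],
        expression=sim7.expression, motifs=sim7.motifs, variants=sim7.variants,
        tf_table=sim7.truth.tf_motifs,
    )
    per_tissue = refine_all_tissues(inputs, cfg)
    features, scores, pair_results, clusters = diff_acr_analysis(inputs, per_tissue, cfg)
    return {
        "cfg": cfg, "inputs": inputs, "per_tissue": per_tissue,
        "features": features, "scores": scores,
        "pair_results": pair_results, "clusters": clusters,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
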