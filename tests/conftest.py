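"""Shared fixtures: one seeded synthetic dataset and one funnel run per session."""

from __future__ import annotations

from types import SimpleNamespace

import pandas as pd
import pytest

from lohfunnel import data_io, synthetic_data
from lohfunnel.consequence import extract_cds
from lohfunnel.prioritize import FunnelConfig, run_funnel


@pytest.fixture(scope="session")
def sim_config():
    return synthetic_data.default_config(seed=0)


@pytest.fixture(scope="session")
def sim_paths(sim_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return synthetic_data.generate_all(sim_config, outdir)


@pytest.fixture(scope="session")
def bundle(sim_config, sim_paths):
    """Everything the funnel consumes, loaded through data_io."""
    genome = data_io.read_fasta(sim_paths["genome"])
    models = data_io.read_cds_models(sim_paths["cds"])
    proteins = data_io.read_fasta(sim_paths["proteins"])
    sample_to_pop = data_io.read_sample_map(sim_paths["samples"])
    variants = data_io.read_variants(sim_paths["variants"], sample_to_pop)
    structures = {
        key.split("_", 1)[1]: [data_io.read_structure(path)]
        for key, path in sim_paths.items()
        if key.startswith("structure_")
    }
    return SimpleNamespace(
        config=sim_config,
        genome=genome,
        models=models,
        proteins=proteins,
        sample_to_pop=sample_to_pop,
        variants=variants,
        cds_sequences={m.transcript_id: extract_cds(m, genome) for m in models},
        domains=data_io.read_domain_annotations(sim_paths["domains"]),
        structures=structures,
        expression=data_io.read_expression(sim_paths["expression"]),
        loh_table=data_io.read_loh_frequencies(sim_paths["loh_freq"]),
        truth=pd.read_csv(sim_paths["truth"], sep="\t", comment="#"),
        cohort=data_io.read_cohort(sim_paths["cohort"]),
        cohort_truth=pd.read_csv(sim_paths["cohort_truth"], sep="\t", comment="#"),
    )


@pytest.fixture(scope="session")
def funnel_result(bundle):
    return run_funnel(
        bundle.variants,
        bundle.models,
        bundle.cds_sequences,
        bundle.proteins,
        bundle.domains,
        bundle.structures,
        bundle.expression,
        bundle.loh_table,
        FunnelConfig(),
    )
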