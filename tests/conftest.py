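"""Shared fixtures: one mid-sized synthetic study reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from ltrpop.discovery import filter_by_tsd, find_full_length_copies
from ltrpop.pipeline import element_sequences
from ltrpop.popgen import build_consensus, call_variants, pairwise_snp_distance
from ltrpop.simulate import (
    SimulationConfig,
    generate_chip_tracks,
    generate_truth_set,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """5 Mb genome, 30 copies per family (60 implants), all decoy classes."""
    return SimulationConfig(seed=101, copies_per_family=30)


@pytest.fixture(scope="session")
def sim_study(sim_config):
    genome, truth = generate_truth_set(sim_config)
    return genome, truth


@pytest.fixture(scope="session")
def chip_tracks(sim_config, sim_study):
    genome, truth = sim_study
    return generate_chip_tracks(genome, truth, sim_config)


@pytest.fixture(scope="session")
def discovered(sim_study):
    """Discovery output per family, before and after the TSD filter."""
    genome, truth = sim_study
    out = {}
    for fam in truth.families:
        found = find_full_length_copies(genome, fam)
        out[fam.name] = {"found": found, "filtered": filter_by_tsd(found)}
    return out


@pytest.fixture(scope="session")
def family_population(sim_study):
    """Consensus, variant table and SNP distances for the first family,
    built from the truth copies (discovery-independent)."""
    genome, truth = sim_study
    fam = truth.families[0]
    copies = truth.non_decoys(fam.name)
    seqs = {c.id: c.sequence for c in copies}
    # orient minus-strand copies 5'->3'
    from ltrpop.models import revcomp

    seqs = {
        c.id: (revcomp(c.sequence) if c.interval.strand == "-" else c.sequence)
        for c in copies
    }
    consensus = build_consensus(seqs, sample_n=30, seed=7)
    table = call_variants(seqs, consensus, consensus_id=f"{fam.name}_consensus")
    distances = pairwise_snp_distance(table)
    positions = {c.id: c.interval.midpoint for c in copies}
    subfamilies = {c.id: c.subfamily for c in copies}
    ages = {c.id: c.true_age for c in copies}
    return {
        "family": fam,
        "consensus": consensus,
        "table": table,
        "distances": distances,
        "positions": positions,
        "subfamilies": subfamilies,
        "ages": ages,
        "centromere": truth.centromere,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
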