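"""Shared fixtures: small simulated cohorts exercised by many modules.

All fixtures are deterministic (fixed seeds) and generated at session scope
so the read-level simulation and calling run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hemoseq.calling import CallParams, call_sample
from hemoseq.panel import build_panel
from hemoseq.reads import BarcodeManifest, assign_barcodes, process_sample_reads
from hemoseq.sim import (BaseErrorModel, SimConfig, simulate_genotypes,
                         simulate_reads)


@pytest.fixture(scope="session")
def small_panel():
    """4 genes x 2 exons: big enough for both strands and both gene sets."""
    return build_panel(4, 2, seed=11, codons_per_gene=40)


@pytest.fixture(scope="session")
def default_panel():
    """The pipeline's default panel scale (10 genes x 3 exons)."""
    return build_panel(10, 3, seed=0)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_common_background=10,
        n_rare_background=12,
        n_deletion_sites=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel, small_config):
    truth = simulate_genotypes(small_panel, small_config)
    reads, stats = simulate_reads(small_panel, truth, small_config)
    return truth, reads, stats


@pytest.fixture(scope="session")
def errorfree_config():
    """Sequencing-error-free limit: Q90 bases, clean tags, full mapq."""
    return SimConfig(
        base_error_model=BaseErrorModel(quality_levels=(90,), weights=(1.0,)),
        tag_error_rate=0.0,
        low_mapq_fraction=0.0,
        n_common_background=10,
        n_rare_background=12,
        n_deletion_sites=0,
        seed=13,
    )


@pytest.fixture(scope="session")
def errorfree_cohort(small_panel, errorfree_config):
    truth = simulate_genotypes(small_panel, errorfree_config)
    reads, stats = simulate_reads(small_panel, truth, errorfree_config)
    return truth, reads, stats


def _demux_filter_call(panel, truth, reads, params=None):
    manifest = BarcodeManifest.from_truth(truth)
    assigned, _ = assign_barcodes(reads, manifest)
    callsets = {}
    for sample, grp in assigned.groupby("sample"):
        filtered = process_sample_reads(grp)
        callsets[sample] = call_sample(filtered, panel, sample, params or CallParams())
    return callsets


@pytest.fixture(scope="session")
def small_callsets(small_panel, small_cohort):
    truth, reads, _ = small_cohort
    return _demux_filter_call(small_panel, truth, reads)


@pytest.fixture(scope="session")
def errorfree_callsets(small_panel, errorfree_cohort):
    truth, reads, _ = errorfree_cohort
    return _demux_filter_call(small_panel, truth, reads)


@pytest.fixture(scope="session")
def small_matrix(small_callsets, small_cohort):
    from hemoseq.gmatrix import build_matrix

    truth, _, _ = small_cohort
    return build_matrix(small_callsets, truth.samples[["sample", "phenotype"]])


def make_matrix(case_genotypes, control_genotypes):
    """Hand-built GenotypeMatrix from per-sample genotype-code rows."""
    from hemoseq.gmatrix import GenotypeMatrix

    geno = np.array(list(case_genotypes) + list(control_genotypes), dtype=np.int8)
    n_sites = geno.shape[1]
    sites = pd.DataFrame(
        {
            "contig": "chrT",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "G",
            "site_id": [f"chrT:{j + 1}:A:G" for j in range(n_sites)],
        }
    )
    samples = pd.DataFrame(
        {
            "sample": [f"S{i}" for i in range(len(geno))],
            "phenotype": [2] * len(case_genotypes) + [1] * len(control_genotypes),
        }
    )
    m = GenotypeMatrix(sites, samples, geno)
    m.validate()
    return m
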