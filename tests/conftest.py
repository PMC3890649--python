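"""Shared fixtures: preset gene models and the full allele-diff pipeline.

Session scope amortizes the expensive pieces (reference construction with
background scrubbing; global alignments of full-length haplotypes) across
the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import gslkit
from gslkit.genemodel import annotate_regions
from gslkit.presets import PRESETS, gene_model_spec, region_variant_counts


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def gsl1_model():
    return gslkit.build_reference(gene_model_spec("gsl1", seed=1))


@pytest.fixture(scope="session")
def gsl2_model():
    return gslkit.build_reference(gene_model_spec("gsl2", seed=1))


@pytest.fixture(scope="session")
def table1_pipeline(gsl1_model, gsl2_model):
    """diff -> merge -> annotate -> summarize for both preset genes.

    Returns {gene: dict(model, regions, haplotypes, truth, merged,
    summaries)}.
    """
    out = {}
    for gene, model in [("gsl1", gsl1_model), ("gsl2", gsl2_model)]:
        regions = annotate_regions(
            model, promoter_bin_size=PRESETS[gene]["promoter_bin_size"]
        )
        counts = {r: region_variant_counts(gene)[(r.start, r.end)] for r in regions}
        haps, truth = gslkit.spawn_haplotypes(
            model,
            counts,
            indel_length_range=PRESETS[gene]["indel_length_range"],
            seed=2,
        )
        tables = [
            gslkit.diff_haplotype(
                model.sequence, h, tss_index=model.tss_index, carrier=f"h{k}"
            )
            for k, h in enumerate(haps)
            if k
        ]
        merged = gslkit.merge_variant_tables(tables)
        summaries = gslkit.summarize_regions(merged, regions)
        out[gene] = dict(
            model=model,
            regions=regions,
            haplotypes=haps,
            truth=truth,
            merged=merged,
            summaries=summaries,
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20140102)
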