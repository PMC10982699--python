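"""Shared fixtures: tiny hand-built inputs plus session-scoped simulations.

The simulation fixtures run at the default study conditions (200 origins,
library-scale depth, master seed 1) and return only the derived analysis
products, so the multi-gigabyte coverage vectors are freed eagerly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import espan
from espan import (
    GENOTYPE_PRESETS,
    GenomeSpec,
    GenotypeParams,
    OriginSet,
    StrandedFragmentSet,
    coverage_from_fragments,
)
from espan.espan_bias import compute_bias_profile, side_resolved_bias

SIM_SEED = 1


# ---------------------------------------------------------------------------
# small hand-built inputs
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_genome() -> GenomeSpec:
    return GenomeSpec(("chrI", "chrII"), (10000, 8000))


def make_fragments(
    records, sample_id="s", genotype="WT", mark="BrdU"
) -> StrandedFragmentSet:
    """records: iterable of (chrom, start, end, strand)."""
    records = list(records)
    frags = pd.DataFrame(
        records, columns=["chrom", "start", "end", "strand"]
    ) if records else pd.DataFrame(
        {"chrom": [], "start": [], "end": [], "strand": []}
    )
    frags["start"] = frags["start"].astype(np.int64)
    frags["end"] = frags["end"].astype(np.int64)
    return StrandedFragmentSet(sample_id, genotype, mark, frags)


def make_origins(records, genome=None) -> OriginSet:
    origins = OriginSet.from_records(records, "test")
    return origins.validate(genome) if genome is not None else origins


# ---------------------------------------------------------------------------
# session-scoped simulations (study conditions)
# ---------------------------------------------------------------------------

def _profile_for(config, samples, genotype, mark):
    espan_cov = coverage_from_fragments(samples[(genotype, mark)], config.genome)
    brdu_cov = coverage_from_fragments(samples[(genotype, "BrdU")], config.genome)
    profile = compute_bias_profile(espan_cov, brdu_cov, config.origins)
    folded = side_resolved_bias(
        profile.normalized_bias, profile.bin_centers, profile.origin_ids
    )
    return profile, folded


@pytest.fixture(scope="session")
def wt_run():
    """Wild-type preset (p_lead 0.5, r 1.0): the symmetric null."""
    config = espan.default_config(n_origins=200, seed=SIM_SEED)
    result = espan.simulate_experiment(
        config, [GENOTYPE_PRESETS["WT"]], marks=("H3K4me3",)
    )
    profile, folded = _profile_for(config, result.samples, "WT", "H3K4me3")
    return {"config": config, "profile": profile, "folded": folded,
            "manifest": result.manifest}


@pytest.fixture(scope="session")
def distorted_wt_run():
    """Same cells and seed as wt_run but 20% Watson under-recovery shared by
    all libraries — the technical artifact BrdU subtraction must cancel."""
    import dataclasses

    base = espan.default_config(n_origins=200, seed=SIM_SEED)
    config = dataclasses.replace(base, strand_recovery_w=0.8)
    result = espan.simulate_experiment(
        config, [GENOTYPE_PRESETS["WT"]], marks=("H3K4me3",)
    )
    profile, folded = _profile_for(config, result.samples, "WT", "H3K4me3")
    return {"config": config, "profile": profile, "folded": folded}


@pytest.fixture(scope="session")
def mutant_bias_runs():
    """Strongly leading- (p=0.8) and lagging-biased (p=0.25) genotypes with
    full recycling, profiled for the parental and the new-histone mark."""
    config = espan.default_config(n_origins=200, seed=SIM_SEED)
    genotypes = [
        GenotypeParams("lead08", p_lead=0.8, r_recycle=1.0),
        GenotypeParams("lag025", p_lead=0.25, r_recycle=1.0),
    ]
    result = espan.simulate_experiment(
        config, genotypes, marks=("H3K4me3", "H3K56ac")
    )
    out = {"config": config, "params": {g.label: g for g in genotypes}}
    for g in genotypes:
        for mark in ("H3K4me3", "H3K56ac"):
            profile, folded = _profile_for(config, result.samples, g.label, mark)
            out[(g.label, mark)] = {"profile": profile, "folded": folded}
    return out


GRID_PARAMS = [
    GenotypeParams(f"p{p}_r{r}", p_lead=p, r_recycle=r)
    for p in (0.25, 0.5, 0.85)
    for r in (0.4, 0.8, 1.0)
]


@pytest.fixture(scope="session")
def density_grid():
    """Parental-mark density table for WT, a 3x3 (p_lead, r) grid and the
    mcm2-2A-like preset, fitted genotype by genotype to bound memory."""
    from espan.histone_density import DensityTable, GenotypeSamplePair, density_table

    config = espan.default_config(n_origins=200, seed=SIM_SEED)
    genotypes = [GENOTYPE_PRESETS["WT"]] + GRID_PARAMS + [GENOTYPE_PRESETS["mcm2-2A"]]
    frames = []
    for params in genotypes:
        samples = espan.simulate_genotype(config, params, marks=("H3K4me3",))
        pair = GenotypeSamplePair(
            params.label,
            coverage_from_fragments(samples["H3K4me3"], config.genome),
            coverage_from_fragments(samples["BrdU"], config.genome),
        )
        frames.append(density_table([pair], config.origins).data)
    table = DensityTable(pd.concat(frames, ignore_index=True))
    table = espan.fold_change(table, "WT")
    return {"config": config, "table": table,
            "params": {g.label: g for g in genotypes}}


@pytest.fixture(scope="session")
def two_mark_densities():
    """Parental- and new-mark density tables for three genotypes (100
    origins): the substrate for the occupancy-complementarity check."""
    from espan.histone_density import DensityTable, GenotypeSamplePair, density_table

    config = espan.default_config(n_origins=100, seed=SIM_SEED)
    genotypes = [GENOTYPE_PRESETS[k] for k in ("WT", "mcm2-2A", "dpb4d")]
    frames = {"H3K4me3": [], "H3K56ac": []}
    for params in genotypes:
        samples = espan.simulate_genotype(
            config, params, marks=("H3K4me3", "H3K56ac")
        )
        brdu_cov = coverage_from_fragments(samples["BrdU"], config.genome)
        for mark in ("H3K4me3", "H3K56ac"):
            pair = GenotypeSamplePair(
                params.label,
                coverage_from_fragments(samples[mark], config.genome),
                brdu_cov,
            )
            frames[mark].append(density_table([pair], config.origins).data)
    return {
        "config": config,
        "parental": DensityTable(pd.concat(frames["H3K4me3"], ignore_index=True)),
        "new": DensityTable(pd.concat(frames["H3K56ac"], ignore_index=True)),
        "params": {g.label: g for g in genotypes},
    }
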