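"""Origin selection by consistent BrdU replication signal.

Analysis is restricted to origins that show consistent usage across the
reference genotype's BrdU-input samples: an origin passes one sample when its
local BrdU coverage (mean of W + C over +/-1 kb) is at least ``threshold``
times the sample's genome-wide mean coverage, and is kept only if it passes
in every reference sample. Both the halfwidth and the enrichment threshold
are configurable; the rule is monotone in the threshold and idempotent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .formats_io import Origin, OriginSet, EspanError
from .strand_coverage import StrandCoverage, window_sum

logger = logging.getLogger("espan")


def brdu_enrichment(brdu_cov: StrandCoverage, origin: Origin, halfwidth: int = 1000) -> float:
    """Local-over-global BrdU coverage ratio at one origin.

    ``(mean of w+c over [pos - halfwidth, pos + halfwidth)) / (genome-wide
    mean of w+c)``; the window is clipped at chromosome ends.
    """
    genome_bases = sum(brdu_cov.genome.chrom_lengths)
    genome_mean = brdu_cov.base_mass() / genome_bases
    if genome_mean <= 0:
        raise EspanError(f"sample {brdu_cov.sample_id!r} has zero genome-wide coverage")
    n = brdu_cov.genome.length_of(origin.chrom)
    start = max(origin.position - halfwidth, 0)
    end = min(origin.position + halfwidth, n)
    local = window_sum(brdu_cov, origin.chrom, start, end, "W") + window_sum(
        brdu_cov, origin.chrom, start, end, "C"
    )
    return (local / (end - start)) / genome_mean


def usage_report(
    origins: OriginSet,
    brdu_covs: list[StrandCoverage],
    halfwidth: int = 1000,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-origin enrichment across reference BrdU samples.

    Columns: origin_id, one enrichment and pass flag per sample, and
    ``consistent`` (pass in all samples).
    """
    if not brdu_covs:
        raise EspanError("at least one reference BrdU sample required")
    rows = []
    for o in origins:
        row: dict = {"origin_id": o.origin_id}
        consistent = True
        for cov in brdu_covs:
            sid = cov.sample_id or f"sample_{brdu_covs.index(cov)}"
            enr = brdu_enrichment(cov, o, halfwidth)
            passed = enr >= threshold
            row[f"enrichment_{sid}"] = enr
            row[f"pass_{sid}"] = passed
            consistent &= passed
        row["consistent"] = consistent
        rows.append(row)
    return pd.DataFrame(rows)


def select_origins(origins: OriginSet, report: pd.DataFrame) -> OriginSet:
    """Keep origins flagged consistent in the usage report."""
    keep = set(report.loc[report["consistent"], "origin_id"])
    filtered = origins.subset(sorted(keep))
    logger.info("origin filter: kept %d / %d origins", len(filtered), len(origins))
    return filtered


def filter_origins(
    origins: OriginSet,
    brdu_covs: list[StrandCoverage],
    halfwidth: int = 1000,
    threshold: float = 2.0,
) -> tuple[OriginSet, pd.DataFrame]:
    """One-call convenience: usage report plus the filtered origin set."""
    report = usage_report(origins, brdu_covs, halfwidth, threshold)
    return select_origins(origins, report), report
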