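"""Strand-partition bias around replication origins.

The bias statistic in a window is ``(W - C) / (W + C)`` where ``W`` and
``C`` are the Watson- and Crick-strand coverage totals of the window; it is
NaN where ``W + C = 0``. Profiles are computed per origin in 100-bp sliding
windows over [-radius, +radius], the matched BrdU-input bias is subtracted
to cancel technical strand asymmetries, and origins are aggregated as
mean +/- 2 standard errors per bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import CRICK, WATSON, OriginSet, ValidationError, write_matrix
from .strand_coverage import StrandCoverage

logger = logging.getLogger("espan")


@dataclass
class BiasProfile:
    """Per-origin bias matrices plus the across-origin aggregate curve.

    ``raw_bias`` and ``brdu_bias`` are origins x bins matrices of
    (W-C)/(W+C); ``normalized_bias`` is their elementwise difference.
    ``aggregate_mean`` / ``aggregate_halfwidth`` summarize the normalized
    matrix per bin (mean over finite entries, 2x standard error).
    """

    origin_ids: list[str]
    bin_centers: np.ndarray
    raw_bias: np.ndarray
    brdu_bias: np.ndarray | None = None
    normalized_bias: np.ndarray | None = None
    aggregate_mean: np.ndarray | None = None
    aggregate_halfwidth: np.ndarray | None = None
    n_origins_per_bin: np.ndarray | None = None

    @property
    def effective_matrix(self) -> np.ndarray:
        return self.normalized_bias if self.normalized_bias is not None else self.raw_bias


def bin_centers(radius: int = 10000, step: int = 10) -> np.ndarray:
    """Window-center offsets relative to the origin, inclusive of +/-radius."""
    return np.arange(-radius, radius + 1, step, dtype=np.int64)


def windowed_bias(
    cov: StrandCoverage,
    origins: OriginSet,
    radius: int = 10000,
    window: int = 100,
    step: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-origin sliding-window strand bias matrix.

    For each origin and each window center ``t`` on the step grid within
    [-radius, +radius], sums each strand over ``[t - window//2,
    t + window//2)`` and takes (W-C)/(W+C). Windows with zero total coverage,
    or extending past a chromosome end, are NaN.

    Returns ``(matrix, centers)`` with shape (n_origins, n_bins).
    """
    if window < 1 or step < 1 or radius < 1:
        raise ValidationError("radius, window and step must all be >= 1")
    centers = bin_centers(radius, step)
    half_lo = window // 2
    half_hi = window - half_lo
    out = np.full((len(origins), len(centers)), np.nan)
    for i, o in enumerate(origins):
        n = cov.genome.length_of(o.chrom)
        starts = o.position + centers - half_lo
        ends = o.position + centers + half_hi
        valid = (starts >= 0) & (ends <= n)
        if not valid.any():
            logger.warning("origin %s: bias window fully off-chromosome", o.origin_id)
            continue
        cum_w = cov.cumulative(o.chrom, WATSON)
        cum_c = cov.cumulative(o.chrom, CRICK)
        s, e = starts[valid], ends[valid]
        w = cum_w[e] - cum_w[s]
        c = cum_c[e] - cum_c[s]
        total = w + c
        row = np.full(len(s), np.nan)
        nz = total > 0
        row[nz] = (w[nz] - c[nz]) / total[nz]
        out[i, valid] = row
    return out, centers


def subtract_brdu(espan_matrix: np.ndarray, brdu_matrix: np.ndarray) -> np.ndarray:
    """BrdU-normalized bias: elementwise eSPAN minus matched BrdU bias.

    Cancels technical Watson/Crick recovery asymmetries shared by the two
    libraries. NaN in either operand propagates.
    """
    espan_matrix = np.asarray(espan_matrix, dtype=float)
    brdu_matrix = np.asarray(brdu_matrix, dtype=float)
    if espan_matrix.shape != brdu_matrix.shape:
        raise ValidationError(
            f"bias matrices not congruent: eSPAN {espan_matrix.shape} vs "
            f"BrdU {brdu_matrix.shape}"
        )
    return espan_matrix - brdu_matrix


def aggregate_bias(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-origin aggregate: per-bin mean, 2xSE halfwidth and n.

    Bins with fewer than two finite values are reported NaN. The 95% ribbon
    is operationalized as mean +/- 2*sd/sqrt(n).
    """
    matrix = np.asarray(matrix, dtype=float)
    finite = np.isfinite(matrix)
    n = finite.sum(axis=0)
    mean = np.full(matrix.shape[1], np.nan)
    half = np.full(matrix.shape[1], np.nan)
    ok = n >= 2
    if ok.any():
        masked = np.where(finite, matrix, np.nan)[:, ok]
        mean[ok] = np.nanmean(masked, axis=0)
        half[ok] = 2.0 * np.nanstd(masked, axis=0, ddof=1) / np.sqrt(n[ok])
    return mean, half, n


def side_resolved_bias(
    matrix: np.ndarray,
    centers: np.ndarray,
    origin_ids: list[str],
    exclude: int = 300,
) -> pd.DataFrame:
    """Per-origin scalar bias per side and the folded leading-strand bias.

    Averages finite bins of each side beyond +/-``exclude`` bp (where
    leading/lagging identity is well defined), then folds using the fork
    geometry (right of origin: Watson = leading):
    ``folded = (right_mean - left_mean) / 2``. Positive folded values mean
    leading-strand preference. Origins with one side entirely NaN are dropped
    with a warning.
    """
    left_cols = centers < -exclude
    right_cols = centers > exclude
    rows = []
    for i, oid in enumerate(origin_ids):
        left_vals = matrix[i, left_cols]
        right_vals = matrix[i, right_cols]
        nl = int(np.isfinite(left_vals).sum())
        nr = int(np.isfinite(right_vals).sum())
        if nl == 0 or nr == 0:
            logger.warning("origin %s dropped: one side has no finite bias bins", oid)
            continue
        lm = float(np.nanmean(left_vals))
        rm = float(np.nanmean(right_vals))
        rows.append(
            {"origin_id": oid, "left_mean": lm, "right_mean": rm,
             "folded": (rm - lm) / 2.0, "n_left": nl, "n_right": nr}
        )
    return pd.DataFrame(rows, columns=["origin_id", "left_mean", "right_mean",
                                       "folded", "n_left", "n_right"])


def compute_bias_profile(
    espan_cov: StrandCoverage,
    brdu_cov: StrandCoverage | None,
    origins: OriginSet,
    radius: int = 10000,
    window: int = 100,
    step: int = 10,
    allow_genotype_mismatch: bool = False,
) -> BiasProfile:
    """End-to-end profile: windowed bias, BrdU subtraction, aggregation.

    The BrdU sample must come from the same genotype as the eSPAN sample
    unless ``allow_genotype_mismatch`` explicitly overrides.
    """
    raw, centers = windowed_bias(espan_cov, origins, radius, window, step)
    brdu = None
    normalized = None
    if brdu_cov is not None:
        if (
            espan_cov.genotype
            and brdu_cov.genotype
            and espan_cov.genotype != brdu_cov.genotype
            and not allow_genotype_mismatch
        ):
            raise ValidationError(
                f"BrdU genotype {brdu_cov.genotype!r} does not match eSPAN genotype "
                f"{espan_cov.genotype!r}; pass allow_genotype_mismatch=True to override"
            )
        brdu, _ = windowed_bias(brdu_cov, origins, radius, window, step)
        normalized = subtract_brdu(raw, brdu)
    mean, half, n = aggregate_bias(normalized if normalized is not None else raw)
    return BiasProfile(
        origin_ids=[o.origin_id for o in origins],
        bin_centers=centers,
        raw_bias=raw,
        brdu_bias=brdu,
        normalized_bias=normalized,
        aggregate_mean=mean,
        aggregate_halfwidth=half,
        n_origins_per_bin=n,
    )


def bias_heatmap_matrix(
    profile: BiasProfile,
    path,
    sort_key: str = "folded",
    exclude: int = 300,
) -> list[str]:
    """Write the per-origin bias matrix as TSV, rows ordered for a heatmap.

    ``sort_key``: ``folded`` (descending folded leading-strand bias, the
    default) or ``origin`` (input order). Ties break stably by origin id.
    Returns the row order used.
    """
    matrix = profile.effective_matrix
    ids = profile.origin_ids
    if sort_key == "folded":
        folded = side_resolved_bias(matrix, profile.bin_centers, ids, exclude=exclude)
        fmap = dict(zip(folded["origin_id"], folded["folded"]))
        order = sorted(ids, key=lambda oid: (-fmap.get(oid, -np.inf), oid))
    elif sort_key == "origin":
        order = list(ids)
    else:
        raise ValidationError(f"unknown sort key {sort_key!r}; use 'folded' or 'origin'")
    index = {oid: i for i, oid in enumerate(ids)}
    rows = np.array([index[oid] for oid in order])
    write_matrix(path, order, profile.bin_centers.tolist(), matrix[rows])
    return order


def aggregate_table(profile: BiasProfile) -> pd.DataFrame:
    """Aggregate curve as a tidy table (bin, mean, halfwidth, n)."""
    return pd.DataFrame(
        {
            "bin_center": profile.bin_centers,
            "mean": profile.aggregate_mean,
            "halfwidth_2se": profile.aggregate_halfwidth,
            "n_origins": profile.n_origins_per_bin,
        }
    )
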