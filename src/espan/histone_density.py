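"""Strand-resolved parental-histone density and genotype fold changes.

Density is a per-origin, per-strand-class scalar: the no-intercept
least-squares coefficient ``c = sum(e*b) / sum(b^2)`` fitting the eSPAN
coverage ``e`` against the genotype-matched BrdU coverage ``b`` over 100-bp
bins within +/-2500 bp of the origin. Expressing the mark signal in units of
matched BrdU signal cancels per-origin variation in BrdU incorporation and
replication timing. Strand classes follow the fork geometry: the leading
class pools right-side Watson bins with left-side Crick bins, the lagging
class the complement; bins within +/-300 bp of the origin are excluded
because leading/lagging identity is undefined at the initiation point.

Fold change is density relative to a reference genotype at the same origin
and strand class; single-strand differences between genotypes are tested
with Welch's two-sample t-test across origins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import CRICK, WATSON, Origin, OriginSet, EspanError, ValidationError
from .strand_coverage import StrandCoverage, cpm_scale
from .synthetic_data import LAGGING, LEADING

logger = logging.getLogger("espan")

STRAND_CLASSES = (LEADING, LAGGING)

#: eSPAN depth normalization modes for density_table
#:   brdu-matched  — both samples scaled per million fragments of the
#:                   genotype's BrdU input, so density retains the absolute
#:                   eSPAN yield relative to replicated DNA (recommended;
#:                   recovers simulator ground truth)
#:   self          — each sample scaled by its own total (per-library CPM);
#:                   rescales every genotype's densities by an arbitrary
#:                   library-size factor, which is the normalization artifact
#:                   that can make overall density shifts uninterpretable
NORMALIZATION_MODES = ("brdu-matched", "self")


@dataclass
class DensityTable:
    """Long-format density measurements with fold changes.

    ``data`` columns: origin_id, genotype, strand_class, density, n_bins,
    and (after :func:`fold_change`) fold_change.
    """

    data: pd.DataFrame
    reference_genotype: str | None = None
    normalization: str = "brdu-matched"

    def densities(self, genotype: str, strand_class: str) -> np.ndarray:
        d = self.data
        sel = (d["genotype"] == genotype) & (d["strand_class"] == strand_class)
        return d.loc[sel, "density"].to_numpy(dtype=float)


def _class_bins(
    origin: Origin, strand_class: str, halfwidth: int, bin_size: int, exclude: int
) -> list[tuple[int, int, str]]:
    """(start, end, strand) genomic bins belonging to one strand class.

    leading = right-side Watson bins + left-side Crick bins;
    lagging = right-side Crick bins + left-side Watson bins.
    """
    if strand_class not in STRAND_CLASSES:
        raise ValidationError(f"strand_class must be one of {STRAND_CLASSES}")
    right_strand = WATSON if strand_class == LEADING else CRICK
    left_strand = CRICK if strand_class == LEADING else WATSON
    bins = []
    for s in range(exclude, halfwidth - bin_size + 1, bin_size):
        bins.append((origin.position + s, origin.position + s + bin_size, right_strand))
        bins.append((origin.position - s - bin_size, origin.position - s, left_strand))
    return bins


def fit_brdu_coefficient(
    espan_cov: StrandCoverage,
    brdu_cov: StrandCoverage,
    origin: Origin,
    strand_class: str,
    halfwidth: int = 2500,
    bin_size: int = 100,
    exclude: int = 300,
) -> tuple[float, int]:
    """No-intercept least-squares density coefficient for one origin/class.

    Minimizes ``sum((e_i - c * b_i)^2)`` over the class's bins, i.e.
    ``c = sum(e*b) / sum(b^2)``, clamped at zero. Bins with zero BrdU signal
    are dropped. Returns ``(coefficient, n_bins_used)``; coefficient is NaN
    when every BrdU bin is zero (unreplicated in window).
    """
    chrom_len = espan_cov.genome.length_of(origin.chrom)
    e_vals, b_vals = [], []
    for start, end, strand in _class_bins(origin, strand_class, halfwidth, bin_size, exclude):
        if start < 0 or end > chrom_len:
            continue
        ce = espan_cov.cumulative(origin.chrom, strand)
        cb = brdu_cov.cumulative(origin.chrom, strand)
        b = float(cb[end] - cb[start])
        if b <= 0:
            continue
        e_vals.append(float(ce[end] - ce[start]))
        b_vals.append(b)
    if not b_vals:
        logger.warning(
            "origin %s (%s): unreplicated in window, density dropped",
            origin.origin_id, strand_class,
        )
        return float("nan"), 0
    e = np.asarray(e_vals)
    b = np.asarray(b_vals)
    c = float(np.dot(e, b) / np.dot(b, b))
    return max(c, 0.0), len(b_vals)


@dataclass
class GenotypeSamplePair:
    """One genotype's eSPAN coverage with its matched BrdU-input coverage."""

    genotype: str
    espan: StrandCoverage
    brdu: StrandCoverage


def density_table(
    samples: list[GenotypeSamplePair],
    origins: OriginSet,
    halfwidth: int = 2500,
    bin_size: int = 100,
    exclude: int = 300,
    normalization: str = "brdu-matched",
) -> DensityTable:
    """Per-origin, per-strand-class density coefficients for every genotype.

    Every genotype must bring its own BrdU sample (two genotypes sharing one
    BrdU library is an error: the fit would correlate their densities and
    defeat the per-genotype incorporation correction). Coverage is depth-
    normalized per ``normalization`` (see :data:`NORMALIZATION_MODES`) before
    fitting.
    """
    if normalization not in NORMALIZATION_MODES:
        raise ValidationError(f"normalization must be one of {NORMALIZATION_MODES}")
    seen_brdu: dict[str, str] = {}
    for pair in samples:
        if pair.brdu is None:
            raise EspanError(f"genotype {pair.genotype!r} has no matched BrdU sample")
        key = pair.brdu.sample_id or id(pair.brdu)
        if key in seen_brdu:
            raise EspanError(
                f"genotypes {seen_brdu[key]!r} and {pair.genotype!r} share BrdU sample "
                f"{key!r}; each genotype needs its own BrdU input"
            )
        seen_brdu[key] = pair.genotype

    rows = []
    for pair in samples:
        if normalization == "brdu-matched":
            denom = pair.brdu.total_fragments
            espan = pair.espan if pair.espan.scaled else cpm_scale(pair.espan, per=denom)
            brdu = pair.brdu if pair.brdu.scaled else cpm_scale(pair.brdu, per=denom)
        else:
            espan = pair.espan if pair.espan.scaled else cpm_scale(pair.espan)
            brdu = pair.brdu if pair.brdu.scaled else cpm_scale(pair.brdu)
        for origin in origins:
            for strand_class in STRAND_CLASSES:
                c, n_bins = fit_brdu_coefficient(
                    espan, brdu, origin, strand_class, halfwidth, bin_size, exclude
                )
                rows.append(
                    {
                        "origin_id": origin.origin_id,
                        "genotype": pair.genotype,
                        "strand_class": strand_class,
                        "density": c,
                        "n_bins": n_bins,
                    }
                )
    data = pd.DataFrame(rows)
    dropped = int(data["density"].isna().sum())
    if dropped:
        logger.warning("%d origin/strand densities dropped (no BrdU signal)", dropped)
    return DensityTable(data=data, normalization=normalization)


def fold_change(table: DensityTable, reference_genotype: str) -> DensityTable:
    """Fill fold changes: density over the reference genotype's density at
    the same origin and strand class (mean across reference replicates if
    several). Zero reference density yields NaN with a warning.
    """
    d = table.data
    if reference_genotype not in set(d["genotype"]):
        raise ValidationError(f"reference genotype {reference_genotype!r} not in table")
    ref = (
        d.loc[d["genotype"] == reference_genotype]
        .groupby(["origin_id", "strand_class"])["density"]
        .mean()
    )
    key = pd.MultiIndex.from_frame(d[["origin_id", "strand_class"]])
    ref_vals = ref.reindex(key).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(ref_vals > 0, d["density"].to_numpy(dtype=float) / ref_vals, np.nan)
    n_zero = int((ref_vals == 0).sum())
    if n_zero:
        logger.warning("%d rows have zero reference density; fold change NaN", n_zero)
    out = d.copy()
    out["fold_change"] = fc
    return DensityTable(out, reference_genotype=reference_genotype,
                        normalization=table.normalization)


def fold_change_summary(table: DensityTable) -> pd.DataFrame:
    """Genotype-level fold-change summaries per strand class.

    ``mean_fold_change`` is the mean of per-origin fold changes;
    ``pooled_fold_change`` is the ratio of mean densities (genotype over
    reference). The pooled form estimates the ratio of expected densities
    directly and avoids the upward convexity bias that a noisy per-origin
    reference induces in the mean of ratios.
    """
    if "fold_change" not in table.data.columns:
        raise ValidationError("run fold_change() first")
    d = table.data
    mean_fc = (
        d.groupby(["genotype", "strand_class"])["fold_change"]
        .mean()
        .rename("mean_fold_change")
    )
    dens = d.groupby(["genotype", "strand_class"])["density"].mean()
    ref = dens.loc[table.reference_genotype]
    pooled = dens.div(ref, level="strand_class").rename("pooled_fold_change")
    return pd.concat([mean_fc, pooled], axis=1).reset_index()


def compare_density(
    table: DensityTable, genotype_a: str, genotype_b: str, strand_class: str
) -> tuple[float, float, int, int]:
    """Welch two-sample t-test on per-origin densities of one strand class.

    Returns ``(t, two-sided p, n_a, n_b)``; identical inputs give t = 0,
    p = 1 by convention.
    """
    a = table.densities(genotype_a, strand_class)
    b = table.densities(genotype_b, strand_class)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise EspanError(
            f"need >=2 origins per group, got {len(a)} ({genotype_a}) and "
            f"{len(b)} ({genotype_b})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # zero variance in both groups with equal means
        return 0.0, 1.0, len(a), len(b)
    return float(t), float(p), len(a), len(b)


def all_pairwise_tests(
    table: DensityTable, reference_genotype: str
) -> pd.DataFrame:
    """Reference-vs-each-genotype Welch tests per strand class.

    Raw two-sided p-values plus a Bonferroni column for transparency (no
    correction is applied to the primary report).
    """
    genotypes = [g for g in table.data["genotype"].unique() if g != reference_genotype]
    rows = []
    for g in genotypes:
        for sc in STRAND_CLASSES:
            t, p, na, nb = compare_density(table, g, reference_genotype, sc)
            rows.append(
                {"genotype": g, "reference": reference_genotype, "strand_class": sc,
                 "t": t, "p": p, "n": na, "n_ref": nb}
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df


def density_violin_export(table: DensityTable, path) -> pd.DataFrame:
    """Write the long-format density table (one row per measurement) as TSV.

    Columns: origin_id, genotype, strand_class, density, fold_change (NaN
    when fold changes have not been computed).
    """
    cols = ["origin_id", "genotype", "strand_class", "density"]
    out = table.data[cols].copy()
    out["fold_change"] = table.data.get("fold_change", np.nan)
    out.to_csv(path, sep="\t", index=False, na_rep="nan", float_format="%.10g")
    return out
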