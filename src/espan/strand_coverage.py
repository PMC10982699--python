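"""Per-base Watson/Crick coverage: the substrate for bias and density.

Coverage counts full-fragment overlap at 1-bp resolution: ``w[i]`` is the
number of Watson fragments overlapping base ``i`` (half-open), likewise
``c[i]`` for Crick. Base mass is conserved: summing ``w + c`` over the genome
equals the summed fragment lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    CRICK,
    WATSON,
    EspanError,
    GenomeSpec,
    StrandedFragmentSet,
    ValidationError,
)


@dataclass
class StrandCoverage:
    """Watson and Crick coverage vectors, one pair per chromosome.

    ``scaled`` flags counts-per-million normalization; cumulative sums for
    O(1) window queries are built lazily and cached.
    """

    genome: GenomeSpec
    w: dict[str, np.ndarray]
    c: dict[str, np.ndarray]
    total_fragments: int
    sample_id: str = ""
    mark: str = ""
    genotype: str = ""
    scaled: bool = False
    scale_factor: float = 1.0
    _cum: dict[tuple[str, str], np.ndarray] = field(default_factory=dict, repr=False)

    def vector(self, chrom: str, strand: str) -> np.ndarray:
        vecs = self.w if strand == WATSON else self.c if strand == CRICK else None
        if vecs is None:
            raise ValidationError(f"strand must be 'W' or 'C', got {strand!r}")
        if chrom not in vecs:
            raise ValidationError(f"chromosome {chrom!r} not in coverage")
        return vecs[chrom]

    def cumulative(self, chrom: str, strand: str) -> np.ndarray:
        """Prefix sums with a leading 0, so window sums are two lookups."""
        key = (chrom, strand)
        if key not in self._cum:
            v = self.vector(chrom, strand)
            cum = np.empty(len(v) + 1, dtype=np.float64)
            cum[0] = 0.0
            np.cumsum(v, out=cum[1:])
            self._cum[key] = cum
        return self._cum[key]

    def base_mass(self) -> float:
        """Sum of (w + c) over every base of the genome."""
        return float(
            sum(v.sum(dtype=np.float64) for v in self.w.values())
            + sum(v.sum(dtype=np.float64) for v in self.c.values())
        )


def coverage_from_fragments(
    frags: StrandedFragmentSet, genome: GenomeSpec
) -> StrandCoverage:
    """Accumulate per-base strand coverage from a validated fragment set.

    Order-independent: the result is invariant under any permutation of the
    input fragments.
    """
    frags.validate(genome)
    w = {ch: np.zeros(n, dtype=np.int64) for ch, n in genome.lengths.items()}
    c = {ch: np.zeros(n, dtype=np.int64) for ch, n in genome.lengths.items()}
    f = frags.fragments
    for (chrom, strand), sub in f.groupby(["chrom", "strand"], sort=False, observed=True):
        target = w if strand == WATSON else c
        n = genome.length_of(str(chrom))
        # difference-array trick: +1 at starts, -1 at ends, then prefix-sum
        diff = np.bincount(sub["start"].to_numpy(), minlength=n + 1) - np.bincount(
            sub["end"].to_numpy(), minlength=n + 1
        )
        target[str(chrom)] += np.cumsum(diff[:-1])
    return StrandCoverage(
        genome=genome,
        w=w,
        c=c,
        total_fragments=len(frags),
        sample_id=frags.sample_id,
        mark=frags.mark,
        genotype=frags.genotype_label,
    )


def cpm_scale(cov: StrandCoverage, per: float | None = None) -> StrandCoverage:
    """Scale coverage to counts per million fragments.

    ``per`` overrides the denominator (fragment count of another sample) when
    a shared normalization basis is wanted; default is the sample's own
    ``total_fragments``. Scaling an already-scaled coverage raises.
    """
    if cov.scaled:
        raise EspanError(f"sample {cov.sample_id!r} is already CPM-scaled")
    denom = cov.total_fragments if per is None else per
    if denom <= 0:
        raise EspanError(
            f"empty sample cannot be normalized (sample {cov.sample_id!r}, "
            f"denominator {denom})"
        )
    factor = 1e6 / float(denom)
    return StrandCoverage(
        genome=cov.genome,
        w={ch: v * factor for ch, v in cov.w.items()},
        c={ch: v * factor for ch, v in cov.c.items()},
        total_fragments=cov.total_fragments,
        sample_id=cov.sample_id,
        mark=cov.mark,
        genotype=cov.genotype,
        scaled=True,
        scale_factor=factor,
    )


def window_sum(cov: StrandCoverage, chrom: str, start: int, end: int, strand: str) -> float:
    """Total coverage of one strand over [start, end); exact, O(1) amortized."""
    n = cov.genome.length_of(chrom)
    if not (0 <= start < end <= n):
        raise ValidationError(f"window [{start}, {end}) outside [0, {n}) on {chrom}")
    cum = cov.cumulative(chrom, strand)
    return float(cum[end] - cum[start])
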