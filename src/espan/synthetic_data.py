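"""Replication-fork / histone-segregation simulator with known ground truth.

The model: each replication origin fires bidirectionally and each fork
travels ``replicated_halfwidth`` bp. Behind the fork, every parental
nucleosome position is a slot whose H3-H4 tetramer is disrupted; with
probability ``r_recycle`` it is recycled onto one of the two daughter
duplexes — the leading-strand daughter with probability ``p_lead`` — and
every daughter slot left without a parental tetramer is filled by a newly
synthesized tetramer. One tetramer per daughter per slot; no splitting.

Fork geometry fixes the mapping from daughter identity to reference strand:
right of the origin the leading daughter is the Watson strand, left of the
origin it is the Crick strand. Sequencing is emulated by Poisson read draws
per deposited tetramer (parental-mark samples such as H3K4me3/H3K9me3 report
recycled tetramers; H3K56ac reports new ones) plus a uniform BrdU input over
the replicated interval, with an optional multiplicative Watson-recovery
distortion shared by all samples of a run.

Expected values under the model (recorded in the ground-truth manifest):

* parental occupancy: leading ``r*p``, lagging ``r*(1-p)`` of capacity;
* parental-mark strand bias on the Watson-leading side: ``2p - 1``;
* new-histone strand bias on the same side: ``r(1-2p)/(2-r)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formats_io import (
    CRICK,
    NEW_MARKS,
    PARENTAL_MARKS,
    WATSON,
    ConfigError,
    GenomeSpec,
    Origin,
    OriginSet,
    StrandedFragmentSet,
    ValidationError,
)

LEADING = "leading"
LAGGING = "lagging"
LEFT = "left"
RIGHT = "right"

MIN_FRAGMENT_LENGTH = 50


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeParams:
    """Ground-truth chaperone parameters for one genotype.

    p_lead
        Probability that a recycled parental tetramer lands on the
        leading-strand daughter.
    r_recycle
        Probability that a disrupted parental tetramer is recycled at all.
    density_scale_new
        Relative sequencing yield of new-histone nucleosomes.
    """

    label: str
    p_lead: float
    r_recycle: float
    density_scale_new: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lead <= 1.0):
            raise ConfigError(f"p_lead must be in [0,1], got {self.p_lead}")
        if not (0.0 <= self.r_recycle <= 1.0):
            raise ConfigError(f"r_recycle must be in [0,1], got {self.r_recycle}")
        if self.density_scale_new < 0:
            raise ConfigError("density_scale_new must be >= 0")

    @property
    def expected_density_leading(self) -> float:
        return self.r_recycle * self.p_lead

    @property
    def expected_density_lagging(self) -> float:
        return self.r_recycle * (1.0 - self.p_lead)

    @property
    def expected_parental_bias(self) -> float:
        """Parental-mark (W-C)/(W+C) on the Watson-leading side."""
        return 2.0 * self.p_lead - 1.0

    @property
    def expected_new_bias(self) -> float:
        """New-histone-mark bias on the Watson-leading side."""
        return self.r_recycle * (1.0 - 2.0 * self.p_lead) / (2.0 - self.r_recycle)


#: Qualitative genotype presets; illustrative of mutant phenotype classes
#: (symmetric wild type, leading-biased, lagging-biased, recycling-impaired),
#: not fitted estimates of any strain's biology.
GENOTYPE_PRESETS: dict[str, GenotypeParams] = {
    "WT": GenotypeParams("WT", p_lead=0.5, r_recycle=1.0),
    "mcm2-2A": GenotypeParams("mcm2-2A", p_lead=0.85, r_recycle=0.6),
    "dpb4d": GenotypeParams("dpb4d", p_lead=0.25, r_recycle=0.8),
    "mcm2-2A_dpb4d": GenotypeParams("mcm2-2A_dpb4d", p_lead=0.55, r_recycle=0.45),
    "pob3d": GenotypeParams("pob3d", p_lead=0.5, r_recycle=0.35),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Genome geometry, origin positions, sequencing rates and the master seed.

    Defaults generate libraries comparable in local depth to the study
    conditions: ~160-bp nucleosome repeat, forks travelling 5 kb each way,
    mononucleosome-sized fragments, and matched BrdU-input depth.
    """

    genome: GenomeSpec
    origins: OriginSet
    replicated_halfwidth: int = 5000
    nucleosome_spacing: int = 160
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 15.0
    reads_per_nucleosome: float = 400.0
    brdu_reads_per_bp: float = 2.5
    cells_per_locus: int = 1000
    strand_recovery_w: float = 1.0
    seed: int = 0
    analysis_radius: int = 10000  # downstream bias window radius, for warnings

    def __post_init__(self) -> None:
        if self.nucleosome_spacing <= 0:
            raise ConfigError("nucleosome_spacing must be positive")
        if self.replicated_halfwidth <= 0:
            raise ConfigError("replicated_halfwidth must be positive")
        for name in ("fragment_length_mean", "fragment_length_sd",
                     "reads_per_nucleosome", "brdu_reads_per_bp",
                     "strand_recovery_w"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.cells_per_locus < 1:
            raise ConfigError("cells_per_locus must be >= 1")
        self.origins.validate(self.genome)

    @property
    def full_depth_radius(self) -> int:
        """Offset out to which origin-relative coverage is at full depth.

        Beyond ``replicated_halfwidth - nucleosome_spacing -
        fragment_length_mean`` the coverage tapers off toward the replication
        boundary; aggregate statistics evaluated per bin should mask bins
        outside this radius (as they must mask unreplicated bins whenever the
        analysis radius exceeds the replicated halfwidth).
        """
        return int(
            self.replicated_halfwidth - self.nucleosome_spacing - self.fragment_length_mean
        )


def default_genome(
    n_origins: int = 200,
    origin_spacing: int = 25000,
    n_chromosomes: int = 3,
    margin: int = 15000,
) -> tuple[GenomeSpec, OriginSet]:
    """A fission-yeast-like toy genome: a few chromosomes, evenly spaced origins.

    Spacing of 25 kb keeps each origin's +/-10 kb analysis window clear of its
    neighbours' replicated zones; the margin keeps windows on-chromosome.
    """
    per = [n_origins // n_chromosomes] * n_chromosomes
    for i in range(n_origins % n_chromosomes):
        per[i] += 1
    names, lengths, records = [], [], []
    k = 0
    for c, count in enumerate(per, start=1):
        chrom = f"chr{c}"
        names.append(chrom)
        lengths.append(margin * 2 + max(count - 1, 0) * origin_spacing)
        for j in range(count):
            k += 1
            records.append((chrom, margin + j * origin_spacing, f"origin_{k:03d}"))
    genome = GenomeSpec(tuple(names), tuple(lengths))
    return genome, OriginSet.from_records(records, "synthetic")


def default_config(n_origins: int = 200, seed: int = 0, **overrides) -> SimulationConfig:
    genome, origins = default_genome(n_origins=n_origins)
    return SimulationConfig(genome=genome, origins=origins, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Fork geometry
# ---------------------------------------------------------------------------

def nascent_strand_of(daughter: str, side: str) -> str:
    """Map (daughter identity, side of origin) to the reference strand.

    Right of a bidirectional origin the leading-strand daughter is Watson
    and the lagging-strand daughter is Crick; left of the origin the mapping
    is mirrored.
    """
    if daughter not in (LEADING, LAGGING):
        raise ValidationError(f"daughter must be leading/lagging, got {daughter!r}")
    if side not in (LEFT, RIGHT):
        raise ValidationError(f"side must be left/right, got {side!r}")
    if side == RIGHT:
        return WATSON if daughter == LEADING else CRICK
    return CRICK if daughter == LEADING else WATSON


def place_nucleosomes(config: SimulationConfig, origin: Origin) -> pd.DataFrame:
    """Deterministic nucleosome slot centers around one origin.

    Centers sit at origin +/- (k + 1/2) * spacing for k = 0, 1, ... while
    strictly inside the replicated halfwidth. Returns columns ``center``
    (absolute bp) and ``side`` (left/right).
    """
    s = config.nucleosome_spacing
    offsets = []
    k = 0
    while (k + 0.5) * s < config.replicated_halfwidth:
        offsets.append(int(round((k + 0.5) * s)))
        k += 1
    off = np.asarray(offsets, dtype=np.int64)
    centers = np.concatenate([origin.position - off[::-1], origin.position + off])
    sides = [LEFT] * len(off) + [RIGHT] * len(off)
    return pd.DataFrame({"center": centers, "side": sides})


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

def segregate_histones(
    centers: pd.DataFrame, params: GenotypeParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign one tetramer (parental or new) to each daughter at each slot.

    With probability ``r_recycle`` the slot's parental tetramer is recycled,
    landing on the leading daughter with probability ``p_lead``; each daughter
    slot without a parental tetramer receives a new tetramer. Exactly two
    depositions per slot (one per daughter).
    """
    n = len(centers)
    recycled = rng.random(n) < params.r_recycle
    to_leading = rng.random(n) < params.p_lead
    parental_on_leading = recycled & to_leading
    parental_on_lagging = recycled & ~to_leading

    rows = []
    for daughter, parental in ((LEADING, parental_on_leading), (LAGGING, parental_on_lagging)):
        rows.append(
            pd.DataFrame(
                {
                    "center": centers["center"].to_numpy(),
                    "side": centers["side"].to_numpy(),
                    "daughter": daughter,
                    "histone_class": np.where(parental, "parental", "new"),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def segregate_population(
    centers: pd.DataFrame,
    params: GenotypeParams,
    rng: np.random.Generator,
    cells: int,
) -> pd.DataFrame:
    """Population-averaged segregation: fractional occupancies over many cells.

    A sequencing library pools DNA from a large cell population; at each slot
    the per-cell outcomes of :func:`segregate_histones` marginalize to
    fractional tetramer occupancies. Per slot, the number of cells whose
    parental tetramer went to the leading (resp. lagging) daughter is
    multinomial(cells; r*p, r*(1-p), 1-r); occupancy weights are those counts
    over ``cells``. Returns 4 rows per slot — (daughter) x (histone class) —
    with a ``weight`` column; parental + new weight is exactly 1 for each
    daughter. ``cells=1`` reproduces single-cell Bernoulli occupancies.
    """
    n = len(centers)
    rp = params.r_recycle * params.p_lead
    rq = params.r_recycle * (1.0 - params.p_lead)
    k_lead = rng.binomial(cells, rp, n)
    rest = cells - k_lead
    # lagging count conditional on the leading draw (multinomial chain rule)
    p_cond = rq / (1.0 - rp) if rp < 1.0 else 0.0
    k_lag = rng.binomial(rest, p_cond)
    w_lead = k_lead / cells
    w_lag = k_lag / cells
    rows = []
    for daughter, w_par in ((LEADING, w_lead), (LAGGING, w_lag)):
        for klass, w in (("parental", w_par), ("new", 1.0 - w_par)):
            rows.append(
                pd.DataFrame(
                    {
                        "center": centers["center"].to_numpy(),
                        "side": centers["side"].to_numpy(),
                        "daughter": daughter,
                        "histone_class": klass,
                        "weight": w,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Fragment emission
# ---------------------------------------------------------------------------

def _draw_fragments_at(
    positions: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment (start, end) arrays centered at the given positions."""
    lengths = rng.normal(config.fragment_length_mean, config.fragment_length_sd, len(positions))
    lengths = np.maximum(np.rint(lengths), MIN_FRAGMENT_LENGTH).astype(np.int64)
    starts = positions - lengths // 2
    return starts, starts + lengths


def _apply_strand_recovery(codes, starts, ends, is_watson, w_factor, rng):
    """Thin (or duplicate) Watson fragments by the recovery distortion factor."""
    if w_factor == 1.0:
        return codes, starts, ends, is_watson
    if w_factor < 1.0:
        keep = ~is_watson | (rng.random(len(is_watson)) < w_factor)
        return codes[keep], starts[keep], ends[keep], is_watson[keep]
    extra = np.zeros(len(is_watson), dtype=np.int64)
    extra[is_watson] = rng.poisson(w_factor - 1.0, int(is_watson.sum()))
    rep = np.concatenate([np.arange(len(is_watson)), np.repeat(np.arange(len(is_watson)), extra)])
    return codes[rep], starts[rep], ends[rep], is_watson[rep]


def emit_fragments(
    depositions: pd.DataFrame,
    config: SimulationConfig,
    mark: str,
    rng: np.random.Generator,
    *,
    chrom_of_center: np.ndarray,
    genotype_label: str = "",
    sample_id: str = "",
    density_scale_new: float = 1.0,
    origins: OriginSet | None = None,
) -> StrandedFragmentSet:
    """Draw sequenced fragments for one sample from deposition records.

    Parental-class marks draw ``Poisson(reads_per_nucleosome)`` fragments per
    parental deposition; the new-histone mark does the same over new
    depositions scaled by ``density_scale_new``; BrdU ignores histones and
    scatters fragments uniformly over each origin's replicated interval on
    both strands at ``brdu_reads_per_bp``. Fragment lengths are
    Normal(mean, sd) clamped at 50 bp; strand follows the fork-geometry
    convention; the Watson-recovery distortion is applied last, identically
    for every mark.
    """
    chrom_code = {c: i for i, c in enumerate(config.genome.chrom_names)}
    chrom_names = np.asarray(config.genome.chrom_names, dtype=object)
    chrom_lens = np.asarray(config.genome.chrom_lengths, dtype=np.int64)

    if mark in PARENTAL_MARKS or mark in NEW_MARKS:
        target_class = "parental" if mark in PARENTAL_MARKS else "new"
        rate = config.reads_per_nucleosome * (
            density_scale_new if target_class == "new" else 1.0
        )
        sel = (depositions["histone_class"] == target_class).to_numpy()
        dep = depositions.loc[sel]
        dep_codes = np.asarray([chrom_code[c] for c in chrom_of_center[sel]])
        weight = (
            dep["weight"].to_numpy(dtype=float)
            if "weight" in dep.columns
            else np.ones(len(dep))
        )
        counts = rng.poisson(rate * weight)
        rep = np.repeat(np.arange(len(dep)), counts)
        positions = dep["center"].to_numpy()[rep]
        dep_watson = np.asarray(
            [nascent_strand_of(d, s) == WATSON for d, s in zip(dep["daughter"], dep["side"])]
        )
        is_watson = dep_watson[rep] if len(dep) else np.zeros(0, dtype=bool)
        codes = dep_codes[rep] if len(dep) else np.zeros(0, dtype=np.int64)
        starts, ends = _draw_fragments_at(positions, config, rng)
    elif mark == "BrdU":
        if origins is None:
            raise ValidationError("BrdU emission requires the origin set")
        hw = config.replicated_halfwidth
        code_list, pos_list, w_list = [], [], []
        for o in origins:
            n = rng.poisson(config.brdu_reads_per_bp * 2 * hw)
            pos = rng.integers(o.position - hw, o.position + hw, n)
            code_list.append(np.full(n, chrom_code[o.chrom], dtype=np.int64))
            pos_list.append(pos)
            w_list.append(rng.random(n) < 0.5)
        codes = np.concatenate(code_list) if code_list else np.zeros(0, dtype=np.int64)
        positions = np.concatenate(pos_list) if pos_list else np.zeros(0, dtype=np.int64)
        is_watson = np.concatenate(w_list) if w_list else np.zeros(0, dtype=bool)
        starts, ends = _draw_fragments_at(positions, config, rng)
    else:
        raise ValidationError(f"unknown mark {mark!r}")

    # clip at chromosome boundaries (fragments near the replicated edge)
    starts = np.maximum(starts, 0)
    ends = np.minimum(ends, chrom_lens[codes] if len(codes) else ends)
    keep = starts < ends
    codes, starts, ends, is_watson = codes[keep], starts[keep], ends[keep], is_watson[keep]

    # shared technical Watson-recovery distortion, then deterministic ordering
    codes, starts, ends, is_watson = _apply_strand_recovery(
        codes, starts, ends, is_watson, config.strand_recovery_w, rng
    )
    order = np.lexsort((~is_watson, ends, starts, codes))
    codes, starts, ends, is_watson = (
        codes[order], starts[order], ends[order], is_watson[order]
    )
    frags = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(codes, categories=list(chrom_names)),
            "start": starts,
            "end": ends,
            "strand": pd.Categorical.from_codes(
                (~is_watson).astype(np.int8), categories=[WATSON, CRICK]
            ),
        }
    )
    return StrandedFragmentSet(
        sample_id=sample_id or f"{genotype_label}_{mark}",
        genotype_label=genotype_label,
        mark=mark,
        fragments=frags,
    )


# ---------------------------------------------------------------------------
# Whole-experiment driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    samples: dict[tuple[str, str], StrandedFragmentSet]  # (genotype, mark) -> set
    manifest: pd.DataFrame
    config: SimulationConfig

    def sample(self, genotype: str, mark: str) -> StrandedFragmentSet:
        return self.samples[(genotype, mark)]


def _substream(seed: int, *labels: str) -> np.random.Generator:
    """Independent, label-addressed RNG substream of the master seed.

    Label hashing (not enumeration order) keys the stream, so adding a
    genotype or mark never perturbs another sample's draws.
    """
    key = tuple(zlib.crc32(s.encode()) for s in labels)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


def simulate_genotype(
    config: SimulationConfig,
    params: GenotypeParams,
    marks: tuple[str, ...] = ("H3K4me3", "H3K56ac"),
) -> dict[str, StrandedFragmentSet]:
    """Simulate one genotype: segregation once, then every mark plus BrdU.

    All mark samples of a genotype share the same segregation outcome (they
    observe the same cells), so parental- and new-histone read mass are
    exactly complementary slot by slot.
    """
    centers_list, chrom_list = [], []
    for o in config.origins:
        cdf = place_nucleosomes(config, o)
        centers_list.append(cdf)
        chrom_list.append(np.full(len(cdf), o.chrom, dtype=object))
    centers = pd.concat(centers_list, ignore_index=True)
    chrom_of_center = np.concatenate(chrom_list)

    rng_seg = _substream(config.seed, params.label, "segregation")
    dep = segregate_population(centers, params, rng_seg, config.cells_per_locus)
    # 4 deposition rows per slot: (leading, lagging) x (parental, new)
    dep_chroms = np.concatenate([chrom_of_center] * 4)

    out: dict[str, StrandedFragmentSet] = {}
    for mark in tuple(marks) + ("BrdU",):
        rng = _substream(config.seed, params.label, mark)
        out[mark] = emit_fragments(
            dep,
            config,
            mark,
            rng,
            chrom_of_center=dep_chroms,
            genotype_label=params.label,
            sample_id=f"{params.label}_{mark}",
            density_scale_new=params.density_scale_new,
            origins=config.origins,
        )
    return out


def simulate_experiment(
    config: SimulationConfig,
    genotypes: list[GenotypeParams],
    marks: tuple[str, ...] = ("H3K4me3", "H3K56ac"),
) -> SimulationResult:
    """Simulate every genotype and assemble the ground-truth manifest.

    The manifest records, per genotype, the generating parameters and their
    closed-form expectations: per-strand parental occupancy ``r*p`` /
    ``r*(1-p)``, parental-mark bias ``2p-1`` and new-histone bias
    ``r(1-2p)/(2-r)`` on the Watson-leading side. Deterministic under a fixed
    master seed.
    """
    if not genotypes:
        raise ValidationError("at least one genotype required")
    if not marks:
        raise ValidationError("at least one mark required")
    samples: dict[tuple[str, str], StrandedFragmentSet] = {}
    rows = []
    warning = ""
    if config.analysis_radius > config.replicated_halfwidth:
        warning = (
            f"analysis radius {config.analysis_radius} exceeds replicated halfwidth "
            f"{config.replicated_halfwidth}; unreplicated bins must be masked downstream"
        )
    for params in genotypes:
        for mark, fs in simulate_genotype(config, params, marks).items():
            samples[(params.label, mark)] = fs
        rows.append(
            {
                "genotype": params.label,
                "p_lead": params.p_lead,
                "r_recycle": params.r_recycle,
                "density_scale_new": params.density_scale_new,
                "expected_density_leading": params.expected_density_leading,
                "expected_density_lagging": params.expected_density_lagging,
                "expected_parental_bias": params.expected_parental_bias,
                "expected_new_bias": params.expected_new_bias,
                "warning": warning,
            }
        )
    return SimulationResult(samples=samples, manifest=pd.DataFrame(rows), config=config)
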