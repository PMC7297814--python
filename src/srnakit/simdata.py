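"""Synthetic blood small-RNA-seq study generator.

Emulates the statistical structure of a three-group (acute ruptured-aneurysm
RAA, chronic RAC, control C) blood sRNA-seq count study: per-sRNA baseline
abundances with a realistic dynamic range, negative-binomial counts with a
biological coefficient of variation, class-labelled loci on a single
synthetic chromosome, planted differential expression in eight
timepoint/direction patterns, planted ChIP-seq peaks at a chosen subset of
loci, and class-specific conservation levels.  Every output is a pure
function of the config (including its seed).

Defaults follow the study conditions: group sizes 19/20/20, mean per-sRNA
depth 676 counts, biological CV 0.47.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .quantify import CountMatrix, SRNA_CLASSES
from .tracks import CoverageTrack

__all__ = [
    "SimConfig",
    "ChipSpec",
    "SimulatedStudy",
    "generate_counts",
    "generate_annotation",
    "generate_chip_track",
    "generate_conservation_track",
    "simulate",
    "study_config",
    "PATTERNS",
]

#: Planted regulation patterns: (fold applied in RAA, fold applied in RAC),
#: expressed as exponents of the pattern's fold-change Delta.
PATTERNS = {
    "acute_up": (1, 0),
    "acute_down": (-1, 0),
    "chronic_up": (0, 1),
    "chronic_down": (0, -1),
    "both_up": (1, 1),
    "both_down": (-1, -1),
    "mixed_du": (-1, 1),  # down in acute, up in chronic
    "mixed_ud": (1, -1),
    "null": (0, 0),
}

#: Class mix shaped like a nonregulated blood sRNA pool (miRNA-rich, with
#: piRNA, rRNA fragments and scRNA as the other abundant classes).
DEFAULT_CLASS_PROPORTIONS = {
    "piRNA": 0.22,
    "rRNA_5S": 0.04,
    "rRNA_SSU": 0.05,
    "rRNA_LSU": 0.05,
    "miRNA_primary": 0.10,
    "mir_5p": 0.06,
    "mir_3p": 0.05,
    "scRNA": 0.12,
    "tRNA": 0.10,
    "tRF3": 0.05,
    "tRF5": 0.05,
    "snoRNA": 0.07,
    "snRNA": 0.03,
    "other": 0.01,
}

#: Typical locus lengths (bp) per class, sampled uniformly from the range.
CLASS_LENGTHS = {
    "piRNA": (26, 33),
    "rRNA_5S": (110, 125),
    "rRNA_SSU": (120, 200),
    "rRNA_LSU": (120, 200),
    "miRNA_primary": (60, 90),
    "mir_5p": (20, 24),
    "mir_3p": (20, 24),
    "scRNA": (90, 130),
    "tRNA": (70, 90),
    "tRF3": (16, 24),
    "tRF5": (16, 24),
    "snoRNA": (60, 120),
    "snRNA": (100, 180),
    "other": (30, 120),
}

#: Class-specific conservation means: housekeeping tRNA/piRNA/mature miRNA
#: arms high, tRNA fragments and scRNA low.
DEFAULT_CONSERVATION = {
    "tRNA": 0.85,
    "piRNA": 0.75,
    "mir_5p": 0.80,
    "mir_3p": 0.70,
    "miRNA_primary": 0.60,
    "snoRNA": 0.60,
    "snRNA": 0.55,
    "rRNA_5S": 0.50,
    "rRNA_SSU": 0.50,
    "rRNA_LSU": 0.50,
    "scRNA": 0.20,
    "tRF3": 0.15,
    "tRF5": 0.15,
    "other": 0.40,
}


@dataclass
class ChipSpec:
    """Planted ChIP-seq enrichment for one transcription factor track.

    ``target_pattern``/``n_enriched`` select which loci get a peak: the
    first ``n_enriched`` (in truth-table order, after a seeded shuffle) of
    the sRNAs whose true pattern matches ``target_pattern`` (a pattern name,
    or "down"/"up" to match any down-/upregulated pattern).  A Gaussian peak
    of height ``peak_height`` and s.d. ``window_bp/4`` is centred at the
    strand-aware 5' start of each enriched locus, on top of exponential
    background noise with mean ``noise_level`` in ``noise_bin`` bp bins.
    """

    target_pattern: str = "both_down"
    n_enriched: int = 61
    peak_height: float = 5.0
    window_bp: int = 200
    noise_level: float = 0.2
    noise_bin: int = 25
    class_bias: str | None = None  # prefer enriching loci of this class first

    def __post_init__(self) -> None:
        if self.peak_height < 0 or self.noise_level < 0:
            raise ValueError("peak height and noise level must be nonnegative")


@dataclass
class SimConfig:
    """Full description of one synthetic study."""

    n_per_group: tuple = (19, 20, 20)  # (RAA, RAC, C)
    n_srna: int = 1766
    depth_mean: float = 676.0
    cv: float = 0.47
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    de_spec: list = field(default_factory=list)  # (pattern, fraction, fold_change)
    chip_spec: dict = field(default_factory=dict)  # TF label -> ChipSpec
    conservation_spec: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSERVATION)
    )
    detectable_fraction: float = 1.0
    baseline_sdlog: float = 1.0
    depth_factor_range: tuple = (0.75, 1.25)
    genome_length: int | None = None  # default: 3000 bp of chromosome per locus
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("need at least 2 samples per group")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        de_total = sum(frac for _, frac, _ in self.de_spec)
        if de_total > 1.0 + 1e-9:
            raise ValueError("de_spec fractions sum to more than 1")
        for pat, _, fc in self.de_spec:
            if pat not in PATTERNS:
                raise ValueError(f"unknown pattern {pat!r}")
            if fc <= 1:
                raise ValueError("planted fold-changes must exceed 1")
        if not 0 < self.detectable_fraction <= 1:
            raise ValueError("detectable_fraction must be in (0, 1]")

    @property
    def effective_genome_length(self) -> int:
        return self.genome_length if self.genome_length else 3000 * self.n_srna

    def sample_ids(self) -> list:
        ids = []
        for g, n in zip(("RAA", "RAC", "C"), self.n_per_group):
            ids += [f"{g}{i + 1:02d}" for i in range(n)]
        return ids

    def groups(self) -> pd.Series:
        labels = []
        for g, n in zip(("RAA", "RAC", "C"), self.n_per_group):
            labels += [g] * n
        return pd.Series(labels, index=self.sample_ids(), name="group")


def study_config(seed: int = 0, fold_change: float = 2.0, **overrides) -> SimConfig:
    """Study-sized config with all eight regulation patterns planted.

    Pattern fractions are shaped like the observed timepoint partition
    (acute-only and chronic-only sets minor, the both-timepoints set
    dominant and mostly downregulated, with a small mixed tail).
    """
    de_spec = [
        ("acute_up", 0.025, fold_change),
        ("acute_down", 0.034, fold_change),
        ("chronic_up", 0.024, fold_change),
        ("chronic_down", 0.020, fold_change),
        ("both_up", 0.043, fold_change),
        ("both_down", 0.119, fold_change),
        ("mixed_du", 0.023, fold_change),
        ("mixed_ud", 0.004, fold_change),
    ]
    n_srna = overrides.get("n_srna", 1766)
    # GR enrichment scales with the both-down set: 61 of 210 loci at study size
    n_both_down = round(0.119 * n_srna)
    n_enriched = round(61 / 210 * n_both_down)
    cfg = dict(
        n_per_group=(19, 20, 20),
        n_srna=n_srna,
        depth_mean=676.0,
        cv=0.47,
        de_spec=de_spec,
        chip_spec={
            "GR": ChipSpec(n_enriched=n_enriched),
            "DECOY": ChipSpec(n_enriched=0, peak_height=0.0),
        },
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


# ---------------------------------------------------------------------------
# Seed fan-out: one config seed derives independent child streams per stage.
# ---------------------------------------------------------------------------


def _child_rng(seed: int, stage: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (unlike hash(), which is salted)
    import zlib

    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stage.encode()) & 0x7FFFFFFF])
    return np.random.default_rng(ss)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``fractions``."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    return base


# ---------------------------------------------------------------------------
# Counts + truth
# ---------------------------------------------------------------------------


def generate_counts(config: SimConfig):
    """Draw the count matrix and its ground-truth table.

    Counts for sRNA g in sample j are NB with mean
    ``mu_g * Delta_g(group_j) * f_j`` and variance ``m + cv^2 m^2``, where
    ``mu_g`` is a log-normal baseline centred so the grand mean matches
    ``depth_mean``, ``Delta`` the planted fold-change of g's pattern in that
    group, and ``f_j`` a per-sample sequencing-depth factor.  Planted
    regulation is restricted to the detectable stratum.
    """
    rng = _child_rng(config.seed, "counts")
    G = config.n_srna
    ids = [f"sRNA{i + 1:05d}" for i in range(G)]

    n_detect = int(round(config.detectable_fraction * G))
    detectable = np.zeros(G, dtype=bool)
    detectable[rng.permutation(G)[:n_detect]] = True

    # baselines: log-normal for detectable loci (grand mean = depth_mean),
    # uniformly tiny means for the undetectable stratum
    mu = np.empty(G)
    sdlog = config.baseline_sdlog
    meanlog = np.log(config.depth_mean) - 0.5 * sdlog**2
    mu[detectable] = rng.lognormal(meanlog, sdlog, size=n_detect)
    mu[~detectable] = rng.uniform(0.05, 0.8, size=G - n_detect)

    # pattern assignment within the detectable stratum
    pattern = np.array(["null"] * G, dtype=object)
    fc_true = np.ones((G, 2))  # acute, chronic
    det_idx = rng.permutation(np.flatnonzero(detectable))
    fracs = np.array([f for _, f, _ in config.de_spec])
    if len(fracs):
        alloc = _largest_remainder(fracs, n_detect)
        pos = 0
        for (pat, _, fc), k in zip(config.de_spec, alloc):
            take = det_idx[pos : pos + k]
            pos += k
            pattern[take] = pat
            ea, ec = PATTERNS[pat]
            fc_true[take, 0] = fc**ea
            fc_true[take, 1] = fc**ec

    sample_ids = config.sample_ids()
    groups = config.groups().to_numpy()
    f = rng.uniform(*config.depth_factor_range, size=len(sample_ids))

    mult = np.ones((G, len(sample_ids)))
    mult[:, groups == "RAA"] = fc_true[:, [0]]
    mult[:, groups == "RAC"] = fc_true[:, [1]]
    mean = mu[:, None] * mult * f[None, :]

    if config.cv == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.cv**2
        counts = rng.negative_binomial(r, r / (r + mean))

    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=sample_ids))
    truth = pd.DataFrame(
        {
            "pattern": pattern,
            "fc_acute_true": fc_true[:, 0],
            "fc_chronic_true": fc_true[:, 1],
            "baseline_mean": mu,
            "detectable": detectable,
        },
        index=pd.Index(ids, name="srna_id"),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def generate_annotation(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping stranded class-labelled loci on one synthetic chromosome.

    Realized class counts follow largest-remainder rounding of the requested
    proportions; locus order along the chromosome is a seeded shuffle and
    inter-locus gaps are multinomial, so spacing is irregular but exactly
    reproducible.
    """
    rng = _child_rng(config.seed, "annotation")
    classes = list(config.class_proportions)
    counts = _largest_remainder(
        np.array([config.class_proportions[c] for c in classes]), config.n_srna
    )
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    lengths = np.array(
        [rng.integers(*CLASS_LENGTHS.get(c, (30, 120))) for c in labels]
    )
    L = config.effective_genome_length
    free = L - int(lengths.sum())
    if free < config.n_srna:
        raise ValueError(
            f"genome of {L} bp too short for {config.n_srna} non-overlapping loci"
        )
    gaps = rng.multinomial(free - config.n_srna, np.full(config.n_srna + 1, 1.0 / (config.n_srna + 1)))
    starts = np.cumsum(gaps[:-1] + 1) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strands = rng.choice(["+", "-"], size=config.n_srna)

    ann = pd.DataFrame(
        {
            "class": labels,
            "chrom": config.chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
        },
        index=pd.Index([f"sRNA{i + 1:05d}" for i in range(config.n_srna)], name="srna_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# ChIP-seq and conservation tracks
# ---------------------------------------------------------------------------


def _enriched_loci(spec: ChipSpec, annotation, truth, rng) -> pd.Index:
    pat = spec.target_pattern
    if pat in ("down", "up"):
        mask = truth["pattern"].str.endswith(pat) & (truth["pattern"] != "null")
    else:
        mask = truth["pattern"] == pat
    pool = truth.index[mask]
    if spec.n_enriched > len(pool):
        raise ValueError(
            f"requested {spec.n_enriched} enriched loci but only {len(pool)} match "
            f"pattern {pat!r}"
        )
    order = rng.permutation(len(pool))
    pool = pool[order]
    if spec.class_bias is not None:
        biased = pool[annotation.loc[pool, "class"] == spec.class_bias]
        rest = pool[annotation.loc[pool, "class"] != spec.class_bias]
        pool = pd.Index(list(biased) + list(rest))
    return pool[: spec.n_enriched]


def generate_chip_track(
    config: SimConfig,
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    tf: str,
) -> tuple[CoverageTrack, pd.Index]:
    """Planted TF coverage: background noise plus peaks at enriched loci.

    Returns the track and the index of enriched loci (also flagged in the
    truth table by :func:`simulate` as ``chip_<TF>``).
    """
    if tf not in config.chip_spec:
        raise ValueError(f"no chip_spec entry for TF {tf!r}")
    spec = config.chip_spec[tf]
    rng = _child_rng(config.seed, f"chip:{tf}")
    L = config.effective_genome_length

    dense = np.zeros(L)
    if spec.noise_level > 0:
        nbins = -(-L // spec.noise_bin)
        noise = rng.exponential(spec.noise_level, size=nbins)
        dense += np.repeat(noise, spec.noise_bin)[:L]

    enriched = _enriched_loci(spec, annotation, truth, rng)
    if spec.peak_height > 0 and len(enriched):
        sd = max(spec.window_bp / 4.0, 1.0)
        half = int(4 * sd)
        offs = np.arange(-half, half + 1)
        shape = spec.peak_height * np.exp(-0.5 * (offs / sd) ** 2)
        for _, row in annotation.loc[enriched].iterrows():
            center = row["start"] if row["strand"] == "+" else row["end"] - 1
            a = max(center - half, 0)
            b = min(center + half + 1, L)
            dense[a:b] += shape[(a - center + half) : (b - center + half)]

    track = CoverageTrack.from_dense(np.round(dense, 6), chrom=config.chrom, label=tf)
    return track, enriched


def generate_conservation_track(
    config: SimConfig, annotation: pd.DataFrame
) -> tuple[CoverageTrack, pd.Series]:
    """Per-locus constant conservation scores around class-specific means.

    Each locus is fully covered at a score drawn from a normal around its
    class mean (s.d. 0.08, clipped to [0, 1]); the rest of the chromosome is
    uncovered, i.e. implicitly 0.  Returns the track and the true per-locus
    score.
    """
    rng = _child_rng(config.seed, "conservation")
    means = annotation["class"].map(config.conservation_spec).fillna(0.4)
    scores = np.clip(rng.normal(means.to_numpy(), 0.08), 0.0, 1.0)
    df = pd.DataFrame(
        {
            "chrom": annotation["chrom"].to_numpy(),
            "start": annotation["start"].to_numpy(),
            "end": annotation["end"].to_numpy(),
            "value": np.round(scores, 6),
        }
    )
    track = CoverageTrack(df.sort_values("start").reset_index(drop=True), label="phastcons")
    return track, pd.Series(np.round(scores, 6), index=annotation.index, name="cons_true")


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimConfig
    counts: CountMatrix
    truth: pd.DataFrame
    annotation: pd.DataFrame
    groups: pd.Series
    chip_tracks: dict
    conservation_track: CoverageTrack


def simulate(config: SimConfig) -> SimulatedStudy:
    """Generate the full synthetic study: counts, truth, annotation, tracks."""
    counts, truth = generate_counts(config)
    annotation = generate_annotation(config)
    truth = truth.join(annotation)
    tracks = {}
    for tf in config.chip_spec:
        track, enriched = generate_chip_track(config, annotation, truth, tf)
        tracks[tf] = track
        truth[f"chip_{tf}"] = truth.index.isin(enriched)
    cons_track, cons_true = generate_conservation_track(config, annotation)
    truth["cons_true"] = cons_true
    return SimulatedStudy(
        config=config,
        counts=counts,
        truth=truth,
        annotation=annotation,
        groups=config.groups(),
        chip_tracks=tracks,
        conservation_track=cons_track,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write counts/annotation/groups/truth/tracks plus a config echo (YAML)."""
    import pathlib

    import yaml

    from .quantify import write_annotation_bed, write_counts_tsv
    from .tracks import write_bedgraph

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(study.counts, out / "counts.tsv")
    write_annotation_bed(study.annotation, out / "annotation.bed")
    study.groups.rename_axis("sample_id").to_frame().to_csv(out / "groups.tsv", sep="\t")
    study.truth.to_csv(out / "truth.tsv", sep="\t")
    for tf, track in study.chip_tracks.items():
        write_bedgraph(track, out / f"{tf}.bedGraph")
    write_bedgraph(study.conservation_track, out / "phastcons.bedGraph")
    cfg = asdict(study.config)
    cfg["chip_spec"] = {tf: asdict(s) for tf, s in study.config.chip_spec.items()}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
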