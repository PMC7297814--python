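"""Count-matrix container, CPM normalization and the detectability filter.

Library sizes ("total clone counts") are the per-sample column totals of the
raw matrix.  They are computed once, before the detectability filter, so
that CPM values are stable under gene filtering; recomputing them afterwards
is available as an explicit switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SRNA_CLASSES",
    "compute_cpm",
    "filter_detectable",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_groups_tsv",
    "read_annotation",
    "write_annotation_bed",
    "validate_groups",
]

#: DASHR-style small-RNA class vocabulary.
SRNA_CLASSES = (
    "piRNA",
    "rRNA_5S",
    "rRNA_SSU",
    "rRNA_LSU",
    "miRNA_primary",
    "mir_5p",
    "mir_3p",
    "scRNA",
    "tRNA",
    "tRF3",
    "tRF5",
    "snoRNA",
    "snRNA",
    "other",
)


@dataclass
class CountMatrix:
    """Raw integer counts, sRNA x sample, plus per-sample library sizes.

    ``lib_sizes`` defaults to the column sums of ``counts``; when a filtered
    matrix is constructed the pre-filter totals are carried along so CPM
    stays referenced to the full library.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate sRNA ids in count matrix")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.lib_sizes is None:
            self.lib_sizes = c.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.reindex(c.columns).astype(float)
            if self.lib_sizes.isna().any():
                missing = self.lib_sizes.index[self.lib_sizes.isna()].tolist()
                raise ValueError(f"library sizes missing for samples {missing}")

    @property
    def srna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_srna(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def compute_cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts / library size * 1e6, per sample."""
    zero = m.lib_sizes[m.lib_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s) {zero.index.tolist()}")
    return m.counts.div(m.lib_sizes, axis=1) * 1e6


def filter_detectable(
    m: CountMatrix,
    cpm_threshold: float = 2.0,
    min_samples: int = 10,
    strict: bool = True,
    recompute_lib_sizes: bool = False,
) -> CountMatrix:
    """Keep sRNAs with CPM above threshold in at least ``min_samples`` samples.

    "Above" is a strict inequality by default (``strict=False`` switches to
    >=).  Library sizes are inherited from the input matrix unless
    ``recompute_lib_sizes`` is set.
    """
    if cpm_threshold <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    cpm = compute_cpm(m)
    passing = cpm > cpm_threshold if strict else cpm >= cpm_threshold
    keep = passing.sum(axis=1) >= min_samples
    sub = m.counts.loc[keep]
    lib = None if recompute_lib_sizes else m.lib_sizes.copy()
    return CountMatrix(sub, lib_sizes=lib)


# ---------------------------------------------------------------------------
# I/O: counts TSV, groups TSV, annotation (BED6+1 or GTF)
# ---------------------------------------------------------------------------


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.astype(np.int64))


def write_counts_tsv(m: CountMatrix, path) -> None:
    df = m.counts.copy()
    df.index.name = "srna_id"
    df.to_csv(path, sep="\t")


def read_groups_tsv(path) -> pd.Series:
    """Sample-to-group map from a two-column TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("groups file needs columns sample_id and group")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    s.index.name = "sample_id"
    return s


def validate_groups(m: CountMatrix, groups: pd.Series, min_per_group: int = 2) -> pd.Series:
    """Check every sample is assigned and each group has enough members."""
    groups = groups.reindex(m.sample_ids)
    if groups.isna().any():
        missing = groups.index[groups.isna()].tolist()
        raise ValueError(f"samples without a group assignment: {missing}")
    sizes = groups.value_counts()
    small = sizes[sizes < min_per_group]
    if len(small):
        raise ValueError(f"groups with fewer than {min_per_group} samples: {small.to_dict()}")
    return groups


def read_annotation(path) -> pd.DataFrame:
    """Per-sRNA class and genomic interval, from BED6+1 or GTF.

    BED6+1: chrom start end name score strand class (tab separated,
    0-based half-open).  GTF: 1-based inclusive coordinates; attributes must
    carry ``gene_id`` (or ``srna_id``) and ``class``.  Returns a DataFrame
    indexed by sRNA id with columns class, chrom, start, end, strand
    (0-based half-open).
    """
    path = str(path)
    if path.endswith((".gtf", ".gff")):
        return _read_annotation_gtf(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "srna_id", "score", "strand", "class"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "srna_id": str},
    )
    return _finalize_annotation(
        df[["srna_id", "class", "chrom", "start", "end", "strand"]]
    )


def _read_annotation_gtf(path) -> pd.DataFrame:
    import re

    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(re.findall(r'(\w+)\s+"([^"]*)"', f[8]))
            name = attrs.get("gene_id") or attrs.get("srna_id")
            if name is None:
                raise ValueError(f"GTF record without gene_id/srna_id: {line!r}")
            rows.append(
                {
                    "srna_id": name,
                    "class": attrs.get("class", "other"),
                    "chrom": f[0],
                    "start": int(f[3]) - 1,  # GTF is 1-based inclusive
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
    return _finalize_annotation(pd.DataFrame(rows))


def _finalize_annotation(df: pd.DataFrame) -> pd.DataFrame:
    if df["srna_id"].duplicated().any():
        raise ValueError("duplicate sRNA ids in annotation")
    if (df["end"] <= df["start"]).any():
        raise ValueError("annotation intervals must satisfy start < end")
    unknown = set(df["class"]) - set(SRNA_CLASSES)
    if unknown:
        warnings.warn(f"annotation classes outside the known vocabulary: {sorted(unknown)}")
    return df.set_index("srna_id")


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    out = annotation.reset_index()
    out["score"] = 0
    cols = ["chrom", "start", "end", "srna_id", "score", "strand", "class"]
    out[cols].to_csv(path, sep="\t", header=False, index=False)
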