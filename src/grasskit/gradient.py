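"""Leaf developmental-gradient expression analysis.

A monocot leaf matures from base (sink) to tip (source); sampling four
segments along the third leaf yields a developmental gradient.  This module
carries FPKM computation, the expressed-gene filter, sample-level
correlation matrices, hierarchical clustering with a replicate-coherence
report, and per-gene mean profiles on matched comparison stages so that
gradients sampled on different native segment grids can be compared across
species.  Absolute FPKM is never compared across species; only within-species
profiles leave this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import GrasskitError, InvalidSpecError

N_STAGES = 4


@dataclass
class GradientDataset:
    """Per-species FPKM tensor: genes x (segment, replicate).

    ``data`` has the gene ids as index and a two-level column MultiIndex
    (segment, replicate), both integer-coded from 1.
    """

    species: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise InvalidSpecError("data must have (segment, replicate) columns")
        if (self.data.to_numpy() < 0).any():
            raise InvalidSpecError("FPKM values must be non-negative")

    @property
    def genes(self):
        return self.data.index

    @property
    def segments(self):
        return sorted(self.data.columns.get_level_values(0).unique())

    def segment_means(self) -> pd.DataFrame:
        """Replicate-mean FPKM per gene and segment."""
        return self.data.T.groupby(level=0).mean().T

    def to_tsv(self, path):
        out = self.data.copy()
        out.columns = [
            f"{self.species}:{seg}:{rep}" for seg, rep in self.data.columns
        ]
        out.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, species: str | None = None) -> "GradientDataset":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        cols, sp = [], set()
        for c in raw.columns:
            s, seg, rep = c.split(":")
            sp.add(s)
            cols.append((int(seg), int(rep)))
        if species is None:
            if len(sp) != 1:
                raise InvalidSpecError(f"expected one species per file, got {sp}")
            species = sp.pop()
        raw.columns = pd.MultiIndex.from_tuples(cols, names=["segment", "replicate"])
        return cls(species, raw)


def compute_fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM(g, s) = counts(g, s) * 1e9 / (length(g) * library_size(s)).
    """
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise InvalidSpecError("every gene needs a positive length")
    if libs.isna().any() or (libs <= 0).any():
        raise InvalidSpecError("every sample needs a positive library size")
    return counts.mul(1e9).div(lengths, axis=0).div(libs, axis=1)


def filter_expressed(data: GradientDataset, threshold: float = 1.0) -> pd.Index:
    """Genes with FPKM >= threshold in at least one segment of any replicate."""
    return data.genes[(data.data >= threshold).any(axis=1)]


def segment_correlation(
    data: GradientDataset, method: str = "spearman"
) -> pd.DataFrame:
    """Sample-by-sample correlation matrix over genes.

    Spearman uses mid-ranks (ties averaged).  Constant sample vectors yield
    undefined correlations, reported as NaN with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise InvalidSpecError(f"unknown correlation method {method!r}")
    df = data.data
    if df.shape[1] < 2:
        raise InvalidSpecError("need at least two samples")
    constant = df.nunique(axis=0) <= 1
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant sample(s): correlations undefined"
        )
    corr = df.corr(method=method)
    corr.index = corr.index.copy()
    return corr


def _leafsets(link: np.ndarray, n: int):
    sets = {i: frozenset([i]) for i in range(n)}
    for idx, (a, b, _, _) in enumerate(link):
        sets[n + idx] = sets[int(a)] | sets[int(b)]
    return sets


def cluster_samples(corr: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of samples on distance 1 - correlation.

    Returns ``(linkage matrix, replicate-coherence report)``.  The report
    states, per segment, whether that segment's replicates form their own
    clade before joining any other segment's sample.
    """
    c = corr.to_numpy(dtype=float)
    if np.isnan(c).any():
        warnings.warn("missing correlations: using pairwise-complete averages")
        col_mean = np.nanmean(np.where(np.eye(len(c), dtype=bool), np.nan, c))
        c = np.where(np.isnan(c), col_mean, c)
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(dist), k=1)]
    link = hierarchy.linkage(condensed, method=method)
    sets = _leafsets(link, len(c))
    by_segment: dict = {}
    for i, col in enumerate(corr.columns):
        seg = col[0] if isinstance(col, tuple) else str(col).split(":")[-2:][0]
        by_segment.setdefault(seg, set()).add(i)
    coherence = {
        seg: frozenset(members) in sets.values()
        for seg, members in by_segment.items()
    }
    return link, coherence


def linkage_to_newick(link: np.ndarray, labels) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


@dataclass(frozen=True)
class SegmentMatchTable:
    """Mapping of native segment labels to the four comparison stages.

    ``stages[species]`` is a list of four entries; each entry lists the
    native segment labels whose replicate means are averaged into that
    comparison stage (base to tip).  A single native segment may feed a
    stage, or several may be pooled when one species' segment spans what
    another resolves into two (e.g. a base segment capturing both base and
    transition zones elsewhere).
    """

    stages: dict

    def __post_init__(self):
        for sp, entries in self.stages.items():
            if len(entries) != N_STAGES:
                raise InvalidSpecError(
                    f"{sp}: expected {N_STAGES} comparison stages, "
                    f"got {len(entries)}"
                )

    @classmethod
    def identity(cls, species, segments=(1, 2, 3, 4)) -> "SegmentMatchTable":
        return cls({sp: [[s] for s in segments] for sp in species})

    @classmethod
    def from_tsv(cls, path) -> "SegmentMatchTable":
        df = pd.read_csv(path, sep="\t")
        stages: dict = {}
        for _, row in df.iterrows():
            entry = [int(x) for x in str(row["segments"]).split("+")]
            stages.setdefault(row["species"], []).append(entry)
        return cls(stages)


def mean_profiles(
    data: GradientDataset, match: SegmentMatchTable | None = None
) -> pd.DataFrame:
    """Per-gene replicate-mean FPKM at the four matched comparison stages.

    Returns a genes x 4 DataFrame ordered base to tip.  When a stage pools
    several native segments, their replicate means are averaged.
    """
    if match is None:
        match = SegmentMatchTable.identity([data.species], data.segments[:N_STAGES])
    if data.species not in match.stages:
        raise GrasskitError(
            f"species {data.species!r} missing from the segment match table"
        )
    seg_means = data.segment_means()
    cols = {}
    for stage, native in enumerate(match.stages[data.species], start=1):
        missing = [s for s in native if s not in seg_means.columns]
        if missing:
            raise GrasskitError(
                f"{data.species}: native segment(s) {missing} absent from data"
            )
        cols[stage] = seg_means[native].mean(axis=1)
    return pd.DataFrame(cols)
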