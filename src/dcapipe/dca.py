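"""Differential clustering analysis (DCA) of two-genotype co-expression.

Given per-genotype log2(WS/WW) time-course profiles for a shared gene set,
the analysis clusters genes by Pearson correlation in a reference genotype,
re-examines each cluster's correlation structure in the other (target)
genotype, and assigns one of four conservation classes:

* ``full``    — the whole cluster stays co-correlated in the target;
* ``split``   — the cluster divides into two internally correlated but
  mutually uncorrelated subclusters;
* ``partial`` — only one subcluster stays co-correlated;
* ``absent``  — no co-correlation survives in the target.

Both genotypes are used as reference in turn, mirroring how the analysis is
run in practice on drought time courses of contrasting rootstocks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "RatioProfilePair",
    "ClusterPartition",
    "ConservationScores",
    "ConservationCall",
    "DifferentialClusteringAnalysis",
    "DCAResults",
    "ratio_profiles",
    "correlation_matrix",
    "primary_clusters",
    "subcluster_target",
    "conservation_scores",
    "classify_conservation",
    "run_dca",
    "divergent_genes",
]

CLASSES = ("full", "partial", "split", "absent")
DEFAULT_MIN_ABS_LFC = math.log2(1.5)


@dataclass
class RatioProfilePair:
    """Per-genotype gene × timepoint log2(WS/WW) matrices on one gene set."""

    genotypes: tuple[str, str]
    data: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if len(self.genotypes) != 2:
            raise ValueError("exactly two genotypes required")
        a, b = (self.data[g] for g in self.genotypes)
        if not a.index.equals(b.index) or not a.columns.equals(b.columns):
            raise ValueError("gene sets and timepoints must match across genotypes")
        for g, df in self.data.items():
            if not np.all(np.isfinite(df.to_numpy())):
                raise ValueError(f"non-finite profile values for genotype {g}")

    @property
    def genes(self) -> pd.Index:
        return self.data[self.genotypes[0]].index

    @property
    def timepoints(self) -> pd.Index:
        return self.data[self.genotypes[0]].columns

    def subset(self, genes: Sequence[str]) -> "RatioProfilePair":
        return RatioProfilePair(
            genotypes=self.genotypes,
            data={g: df.loc[list(genes)] for g, df in self.data.items()},
        )

    def other(self, genotype: str) -> str:
        a, b = self.genotypes
        return b if genotype == a else a

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        for g in self.genotypes:
            df = self.data[g].copy()
            df.insert(0, "genotype", g)
            frames.append(df.reset_index())
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "RatioProfilePair":
        genotypes = tuple(pd.unique(frame["genotype"]))
        if len(genotypes) != 2:
            raise ValueError("profile table must contain exactly two genotypes")
        tp_cols = [c for c in frame.columns if c not in ("gene_id", "genotype")]
        data = {
            g: frame[frame["genotype"] == g]
            .set_index("gene_id")[tp_cols]
            .astype(float)
            for g in genotypes
        }
        return cls(genotypes=genotypes, data=data)


# ---------------------------------------------------------------------------
# profiles and correlations
# ---------------------------------------------------------------------------


def ratio_profiles(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
    size_factors_: pd.Series | None = None,
    treatments: tuple[str, str] = ("WW", "WS"),
    exclude_timepoints: Sequence[str] = ("T0",),
) -> RatioProfilePair:
    """Per-genotype log2(WS/WW) profiles from replicate-mean normalized counts.

    Counts are divided by median-of-ratios size factors, averaged over
    replicates within each (genotype, treatment, timepoint) cell, and the
    stress/control ratio is taken per timepoint with ``pseudocount`` added to
    both means.
    """
    from .de import size_factors as _size_factors

    s = _size_factors(counts) if size_factors_ is None else size_factors_
    norm = counts / s
    used = samples[~samples["timepoint"].isin(exclude_timepoints)]
    genotypes = tuple(pd.unique(used["genotype"]))
    if len(genotypes) != 2:
        raise ValueError("expected exactly two genotypes")
    ctrl, stress = treatments
    timepoints = list(pd.unique(used["timepoint"]))
    data = {}
    for g in genotypes:
        cols = {}
        for tp in timepoints:
            cell = {}
            for trt in (ctrl, stress):
                ids = used.loc[
                    (used["genotype"] == g)
                    & (used["treatment"] == trt)
                    & (used["timepoint"] == tp),
                    "sample_id",
                ]
                if ids.empty:
                    raise ValueError(f"missing design cell: ({g}, {trt}, {tp})")
                cell[trt] = norm[list(ids)].mean(axis=1)
            cols[tp] = np.log2((cell[stress] + pseudocount) / (cell[ctrl] + pseudocount))
        data[g] = pd.DataFrame(cols)
    return RatioProfilePair(genotypes=genotypes, data=data)


def correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Gene × gene Pearson correlations across timepoints.

    Zero-variance profiles cannot be correlated; they are dropped from the
    matrix with a warning and are thereby excluded from clustering.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least three timepoints for correlations")
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = list(profiles.index[~keep])
        logger.warning("zero-variance profiles excluded from correlation: %s", dropped)
    kept = profiles.index[keep]
    corr = np.corrcoef(values[keep])
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=kept, columns=kept)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterPartition:
    clusters: list[list[str]]
    unassigned: list[str]


def _average_linkage_labels(corr: pd.DataFrame, n_groups: int | None, cut_h: float | None):
    dist = np.clip(1.0 - corr.to_numpy(dtype=float), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    if n_groups is not None:
        return fcluster(link, t=n_groups, criterion="maxclust")
    return fcluster(link, t=cut_h, criterion="distance")


def primary_clusters(
    corr: pd.DataFrame, cut_h: float = 0.5, min_cluster_size: int = 4
) -> ClusterPartition:
    """Average-linkage clusters of the reference correlation matrix.

    The tree on distance 1 - r is cut at height ``cut_h``; groups smaller
    than ``min_cluster_size`` are reported unassigned. Clusters are ordered
    by their lexicographically smallest member id, members sorted by id.
    """
    genes = list(corr.index)
    if len(genes) < min_cluster_size:
        logger.warning("fewer than min_cluster_size genes overall; empty partition")
        return ClusterPartition(clusters=[], unassigned=sorted(genes))
    labels = _average_linkage_labels(corr, n_groups=None, cut_h=cut_h)
    groups: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        groups.setdefault(int(lab), []).append(g)
    clusters = [sorted(m) for m in groups.values() if len(m) >= min_cluster_size]
    clusters.sort(key=lambda m: m[0])
    unassigned = sorted(g for m in groups.values() if len(m) < min_cluster_size for g in m)
    return ClusterPartition(clusters=clusters, unassigned=unassigned)


def _partition_objective(corr: np.ndarray, mask: np.ndarray) -> float:
    """Pooled mean within-group correlation minus mean between-group correlation."""
    n = corr.shape[0]
    idx_a = np.flatnonzero(mask)
    idx_b = np.flatnonzero(~mask)
    total = corr.sum() - n  # off-diagonal sum (diagonal is 1)
    sub_a = corr[np.ix_(idx_a, idx_a)]
    sub_b = corr[np.ix_(idx_b, idx_b)]
    within_sum = (sub_a.sum() - len(idx_a)) + (sub_b.sum() - len(idx_b))
    n_within = len(idx_a) * (len(idx_a) - 1) + len(idx_b) * (len(idx_b) - 1)
    n_between = 2 * len(idx_a) * len(idx_b)
    between_mean = (total - within_sum) / n_between
    within_mean = within_sum / n_within if n_within > 0 else 0.0
    return within_mean - between_mean


def _local_search(corr: np.ndarray, mask: np.ndarray, floor: int) -> np.ndarray:
    """Best-improvement flip/swap local search respecting the size floor.

    Swaps are essential: with a near-balance floor every single-gene flip
    from a balanced state is infeasible.
    """
    n = corr.shape[0]
    # repair an infeasible start, most-improving move first
    while mask.sum() < floor or (n - mask.sum()) < floor:
        small = mask if mask.sum() < floor else ~mask
        cands = np.flatnonzero(~small)
        best_j, best_v = cands[0], -np.inf
        for j in cands:
            trial = mask.copy()
            trial[j] = ~trial[j]
            v = _partition_objective(corr, trial)
            if v > best_v + 1e-12:
                best_j, best_v = j, v
        mask[best_j] = ~mask[best_j]
    improved = True
    while improved:
        improved = False
        best_trial, best_val = None, _partition_objective(corr, mask)
        moves = [(j,) for j in range(n)]
        moves += [(i, j) for i in np.flatnonzero(mask) for j in np.flatnonzero(~mask)]
        for move in moves:
            trial = mask.copy()
            for j in move:
                trial[j] = ~trial[j]
            size = int(trial.sum())
            if size < floor or n - size < floor:
                continue
            val = _partition_objective(corr, trial)
            if val > best_val + 1e-12:
                best_trial, best_val = trial, val
        if best_trial is not None:
            mask, improved = best_trial, True
    return mask


def min_subcluster_size(n: int) -> int:
    """Smallest admissible subcluster in a 2-partition of an n-gene cluster.

    The default policy is near-balance: both subclusters have at least
    ``n // 2`` genes, so their sizes differ by at most one. With the short
    profiles this analysis runs on (4-8 timepoints), mean correlations over
    small gene groups are dominated by chance structure — letting the
    optimizer carve off a chance-correlated pair dilutes the remaining
    subcluster's within mean and destabilizes the four-class call. Averaging
    over near-halves keeps the per-subcluster means as stable as the cluster
    allows; finer, genuinely unequal substructure is the province of
    recursive re-application rather than a single lopsided cut.
    """
    return n // 2


def subcluster_target(
    cluster: Sequence[str],
    corr_tgt: pd.DataFrame,
    exhaustive_limit: int = 12,
    size_floor: int | None = None,
) -> tuple[list[str], list[str]]:
    """Best 2-partition of a cluster under the target correlation structure.

    The objective is the pooled within-subcluster mean correlation minus the
    between-subcluster mean, over partitions whose subclusters both have at
    least ``size_floor`` genes (default :func:`min_subcluster_size`, i.e.
    near-balanced subclusters). Small clusters are solved exactly by
    enumeration; larger ones start from an average-linkage 2-cut and apply
    greedy single-gene moves to a local optimum. Ties break deterministically
    toward the enumeration order (gene ids sorted, first gene fixed in the
    first subcluster).
    """
    genes = sorted(cluster)
    n = len(genes)
    if n < 4:
        raise ValueError("subclustering needs at least four genes")
    corr = corr_tgt.loc[genes, genes].to_numpy(dtype=float)
    floor = min_subcluster_size(n) if size_floor is None else size_floor
    if floor < 1 or 2 * floor > n:
        raise ValueError(f"size_floor {floor} infeasible for {n} genes")

    if n <= exhaustive_limit:
        best_mask, best_val = None, -np.inf
        for bits in range(1, 2 ** (n - 1)):
            mask = np.zeros(n, dtype=bool)
            mask[0] = True
            for j in range(1, n):
                if bits & (1 << (j - 1)):
                    mask[j] = True
            size = int(mask.sum())
            if size < floor or n - size < floor:
                continue
            val = _partition_objective(corr, mask)
            if val > best_val + 1e-12:
                best_val, best_mask = val, mask
        mask = best_mask
    else:
        labels = _average_linkage_labels(
            pd.DataFrame(corr, index=genes, columns=genes), n_groups=2, cut_h=None
        )
        tree_mask = labels == labels[0]
        # deterministic multi-start: the tree cut plus seeded random balanced
        # starts, each refined by flip/swap local search
        rng = np.random.default_rng(n)
        starts = [tree_mask]
        for _ in range(8):
            perm = rng.permutation(n)
            m = np.zeros(n, dtype=bool)
            m[perm[: n // 2]] = True
            starts.append(m)
        best_mask, best_val = None, -np.inf
        for start in starts:
            mask = _local_search(corr, start.copy(), floor)
            val = _partition_objective(corr, mask)
            if val > best_val + 1e-12:
                best_mask, best_val = mask, val
        mask = best_mask
        if not mask[0]:
            mask = ~mask

    sub1 = [g for g, m in zip(genes, mask) if m]
    sub2 = [g for g, m in zip(genes, mask) if not m]
    return sub1, sub2


# ---------------------------------------------------------------------------
# scores and classification
# ---------------------------------------------------------------------------


@dataclass
class ConservationScores:
    """Mean pairwise correlations behind one conservation call.

    All means are over off-diagonal pairs only; a singleton subcluster has no
    pairs, and its within mean is recorded as NaN (treated as below any
    threshold by the classifier).
    """

    r_ref_within: float
    r_tgt_all: float
    r_tgt_diag: tuple[float, float]
    r_tgt_off: float


def _mean_offdiag(corr: pd.DataFrame, genes: Sequence[str]) -> float:
    if len(genes) < 2:
        return float("nan")
    sub = corr.loc[list(genes), list(genes)].to_numpy(dtype=float)
    n = len(genes)
    return float((sub.sum() - n) / (n * (n - 1)))


def _mean_cross(corr: pd.DataFrame, a: Sequence[str], b: Sequence[str]) -> float:
    sub = corr.loc[list(a), list(b)].to_numpy(dtype=float)
    return float(sub.mean())


def conservation_scores(
    cluster: Sequence[str],
    sub1: Sequence[str],
    sub2: Sequence[str],
    corr_ref: pd.DataFrame,
    corr_tgt: pd.DataFrame,
) -> ConservationScores:
    """The four correlation means that drive classification."""
    if sorted(cluster) != sorted(list(sub1) + list(sub2)):
        raise ValueError("subclusters must partition the cluster")
    return ConservationScores(
        r_ref_within=_mean_offdiag(corr_ref, cluster),
        r_tgt_all=_mean_offdiag(corr_tgt, cluster),
        r_tgt_diag=(_mean_offdiag(corr_tgt, sub1), _mean_offdiag(corr_tgt, sub2)),
        r_tgt_off=_mean_cross(corr_tgt, sub1, sub2),
    )


def classify_conservation(
    scores: ConservationScores, c_high: float = 0.6, c_low: float = 0.3
) -> str:
    """Precedence-ordered four-class rule: full > split > partial > absent."""
    if not c_low < c_high:
        raise ValueError("need c_low < c_high")
    d1, d2 = scores.r_tgt_diag
    d1_hi = not math.isnan(d1) and d1 >= c_high
    d2_hi = not math.isnan(d2) and d2 >= c_high
    if scores.r_tgt_all >= c_high:
        return "full"
    if d1_hi and d2_hi and scores.r_tgt_off <= c_low:
        return "split"
    if d1_hi != d2_hi:
        return "partial"
    return "absent"


@dataclass
class ConservationCall:
    cluster_id: str
    reference_genotype: str
    target_genotype: str
    conservation_class: str
    scores: ConservationScores
    members: list[str]
    subclusters: tuple[list[str], list[str]]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


@dataclass
class DCAResults:
    """Conservation calls plus heat-map-ready reordered correlation matrices."""

    calls: list[ConservationCall]
    matrices: dict[str, dict[str, pd.DataFrame]]  # reference -> genotype -> corr
    unassigned: dict[str, list[str]]
    params: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "reference": c.reference_genotype,
                    "target": c.target_genotype,
                    "class": c.conservation_class,
                    "r_ref_within": c.scores.r_ref_within,
                    "r_tgt_all": c.scores.r_tgt_all,
                    "r_tgt_diag1": c.scores.r_tgt_diag[0],
                    "r_tgt_diag2": c.scores.r_tgt_diag[1],
                    "r_tgt_off": c.scores.r_tgt_off,
                    "n_genes": len(c.members),
                    "members": ";".join(c.members),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "reference",
                "target",
                "class",
                "r_ref_within",
                "r_tgt_all",
                "r_tgt_diag1",
                "r_tgt_diag2",
                "r_tgt_off",
                "n_genes",
                "members",
            ],
        )

    def summary(self) -> str:
        lines = ["Differential clustering analysis", "=" * 34]
        for ref, count in pd.Series(
            [c.reference_genotype for c in self.calls]
        ).value_counts().items():
            lines.append(f"reference {ref}: {count} cluster(s)")
        for c in self.calls:
            d1, d2 = c.scores.r_tgt_diag
            lines.append(
                f"  {c.cluster_id} [{c.conservation_class}] n={len(c.members)} "
                f"r_tgt_all={c.scores.r_tgt_all:+.3f} diag=({d1:+.3f},{d2:+.3f}) "
                f"off={c.scores.r_tgt_off:+.3f}"
            )
        if not self.calls:
            lines.append("no clusters met the size threshold")
        return "\n".join(lines)


class DifferentialClusteringAnalysis:
    """Model-style front end: profiles in, :class:`DCAResults` out of fit().

    Parameters mirror the analysis knobs: tree-cut height ``cut_h`` on
    distance 1 - r, minimum primary-cluster size, and classification
    thresholds ``c_high``/``c_low``.
    """

    def __init__(
        self,
        profiles: RatioProfilePair,
        cut_h: float = 0.5,
        min_cluster_size: int = 4,
        c_high: float = 0.6,
        c_low: float = 0.3,
    ) -> None:
        self.profiles = profiles
        self.cut_h = cut_h
        self.min_cluster_size = min_cluster_size
        self.c_high = c_high
        self.c_low = c_low

    def fit(
        self,
        gene_set: Sequence[str] | None = None,
        references: Sequence[str] | None = None,
    ) -> DCAResults:
        profiles = self.profiles
        if gene_set is not None:
            missing = set(gene_set) - set(profiles.genes)
            if missing:
                raise ValueError(f"gene_set not in profiles: {sorted(missing)[:5]}")
            profiles = profiles.subset(list(gene_set))
        refs = list(references) if references is not None else list(profiles.genotypes)

        corr = {g: correlation_matrix(profiles.data[g]) for g in profiles.genotypes}
        calls: list[ConservationCall] = []
        matrices: dict[str, dict[str, pd.DataFrame]] = {}
        unassigned: dict[str, list[str]] = {}
        for ref in refs:
            tgt = profiles.other(ref)
            common = corr[ref].index.intersection(corr[tgt].index)
            c_ref = corr[ref].loc[common, common]
            c_tgt = corr[tgt].loc[common, common]
            part = primary_clusters(c_ref, self.cut_h, self.min_cluster_size)
            unassigned[ref] = part.unassigned
            order: list[str] = []
            for i, members in enumerate(part.clusters, start=1):
                sub1, sub2 = subcluster_target(members, c_tgt)
                scores = conservation_scores(members, sub1, sub2, c_ref, c_tgt)
                calls.append(
                    ConservationCall(
                        cluster_id=f"{ref}-C{i}",
                        reference_genotype=ref,
                        target_genotype=tgt,
                        conservation_class=classify_conservation(
                            scores, self.c_high, self.c_low
                        ),
                        scores=scores,
                        members=members,
                        subclusters=(sub1, sub2),
                    )
                )
                order.extend(sub1 + sub2)
            order.extend(part.unassigned)
            matrices[ref] = {g: corr[g].loc[order, order] for g in profiles.genotypes}
        return DCAResults(
            calls=calls,
            matrices=matrices,
            unassigned=unassigned,
            params={
                "cut_h": self.cut_h,
                "min_cluster_size": self.min_cluster_size,
                "c_high": self.c_high,
                "c_low": self.c_low,
            },
        )


def run_dca(
    profiles: RatioProfilePair,
    gene_set: Sequence[str] | None = None,
    cut_h: float = 0.5,
    min_cluster_size: int = 4,
    c_high: float = 0.6,
    c_low: float = 0.3,
    references: Sequence[str] | None = None,
) -> DCAResults:
    """Functional wrapper over :class:`DifferentialClusteringAnalysis`."""
    model = DifferentialClusteringAnalysis(
        profiles,
        cut_h=cut_h,
        min_cluster_size=min_cluster_size,
        c_high=c_high,
        c_low=c_low,
    )
    return model.fit(gene_set=gene_set, references=references)


def divergent_genes(
    profiles: RatioProfilePair, min_abs_lfc: float = DEFAULT_MIN_ABS_LFC
) -> pd.DataFrame:
    """Genes responding in opposite directions in the two genotypes.

    A (gene, timepoint) pair is reported when the two genotypes' log2 ratios
    have opposite signs and both magnitudes reach ``min_abs_lfc``
    (default log2 1.5).
    """
    if min_abs_lfc < 0:
        raise ValueError("min_abs_lfc must be >= 0")
    ref_g, tgt_g = profiles.genotypes
    a = profiles.data[ref_g]
    b = profiles.data[tgt_g]
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    hit = (
        (np.sign(av) * np.sign(bv) < 0)
        & (np.abs(av) >= min_abs_lfc)
        & (np.abs(bv) >= min_abs_lfc)
    )
    rows = []
    gi, ti = np.nonzero(hit)
    for i, j in zip(gi, ti):
        rows.append(
            {
                "gene_id": a.index[i],
                "timepoint": a.columns[j],
                f"lfc_{ref_g}": float(av[i, j]),
                f"lfc_{tgt_g}": float(bv[i, j]),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "timepoint", f"lfc_{ref_g}", f"lfc_{tgt_g}"]
    )
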