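"""Multifactor negative-binomial differential expression with Venn partitioning.

Per gene, an NB log-linear model with additive genotype (G), treatment (T)
and timepoint (P) terms is fitted to size-factor-normalized counts, and each
factor is scored with a likelihood-ratio test against the model without it
(chi-square reference, levels - 1 degrees of freedom). P-values are BH
adjusted per factor across genes; genes significant for at least one factor
are partitioned into the seven disjoint Venn regions.

The dispersion for each gene is a method-of-moments estimate shrunk 50/50
toward a 1/mean trend line, a deliberately simple stabilization for
small-replicate designs. All genes share one design matrix, so the IRLS
solver is vectorized across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "bh_adjust",
    "estimate_dispersions",
    "MultifactorDE",
    "MultifactorDEResults",
    "VennPartition",
    "test_multifactor",
    "venn_partition",
]

FACTORS = ("G", "T", "P")
_DISP_FLOOR = 1e-8
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# normalization and multiple testing
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame, pseudocount: float | None = None) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    s_j is the median over qualifying genes of count[g, j] divided by the
    gene's geometric mean across samples; genes with any zero count do not
    qualify. If no gene qualifies, pass a ``pseudocount`` to add to all
    counts before computing the factors.
    """
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    if pseudocount is not None:
        values = values + pseudocount
    positive = np.all(values > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has all-positive counts; rerun with a pseudocount "
            "(size_factors(counts, pseudocount=0.5))"
        )
    logs = np.log(values[positive])
    log_gm = logs.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with enforced monotonicity."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


def _design_cells(samples: pd.DataFrame) -> list[list[str]]:
    grouped = samples.groupby(["genotype", "treatment", "timepoint"], observed=True)
    return [g["sample_id"].tolist() for _, g in grouped]


def estimate_dispersions(
    counts: pd.DataFrame, samples: pd.DataFrame, sf: pd.Series
) -> pd.Series:
    """Per-gene NB dispersion: method-of-moments shrunk 50/50 to a 1/mu trend.

    The raw estimate uses the pooled within-cell variance of normalized
    counts with the sampling-noise term subtracted (Var = mu + alpha mu^2).
    A nonnegative trend alpha(mu) = a0 + a1/mu is fitted across genes and
    the final value is the even blend of raw and trend, floored at 1e-8.
    """
    q = (counts[samples["sample_id"]] / sf[samples["sample_id"]]).to_numpy(dtype=float)
    cells = _design_cells(samples)
    col_of = {sid: i for i, sid in enumerate(samples["sample_id"])}
    n, n_cells = q.shape[1], len(cells)
    if n - n_cells < 1:
        raise ValueError("need at least two replicates in some design cell")
    resid_ss = np.zeros(q.shape[0])
    for cell in cells:
        idx = [col_of[s] for s in cell]
        sub = q[:, idx]
        resid_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v = resid_ss / (n - n_cells)
    qbar = q.mean(axis=1)
    z = qbar * float((1.0 / sf[samples["sample_id"]]).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(qbar > 0, (v - z) / np.maximum(qbar, 1e-300) ** 2, _DISP_FLOOR)
    mom = np.maximum(mom, _DISP_FLOOR)

    informative = (qbar > 0) & (mom > _DISP_FLOOR)
    if informative.sum() >= 10:
        a = np.column_stack([np.ones(informative.sum()), 1.0 / qbar[informative]])
        coef, _ = nnls(a, mom[informative])
        trend = coef[0] + coef[1] / np.maximum(qbar, 1e-300)
    else:
        trend = np.full_like(mom, np.median(mom))
    trend = np.maximum(np.where(qbar > 0, trend, _DISP_FLOOR), _DISP_FLOOR)
    alpha = np.maximum(0.5 * mom + 0.5 * trend, _DISP_FLOOR)
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# batched NB GLM
# ---------------------------------------------------------------------------


def _nb_llf(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    size = 1.0 / alpha[:, None]
    p = size / (size + mu)
    return stats.nbinom.logpmf(y, size, p).sum(axis=1)


def _fit_nb_batch(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS for NB GLMs (log link, fixed per-gene dispersion), batched over genes.

    All genes share the design matrix ``x`` (n × k) and the log-size-factor
    ``offset``; returns per-gene coefficients and log-likelihoods.
    """
    n_genes, k = y.shape[0], x.shape[1]
    if beta0 is None:
        z0 = np.log(y + 0.5) - offset
        beta = z0 @ np.linalg.pinv(x).T
    else:
        beta = beta0.copy()
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = np.clip(beta @ x.T + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        z = (eta - offset) + (y - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", x, w, x, optimize=True)
        xtwx += 1e-10 * np.eye(k)
        xtwz = np.einsum("ni,gn->gi", x, w * z, optimize=True)
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        new_beta = np.clip(new_beta, -1e3, 1e3)
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        if delta < tol:
            break
    eta = np.clip(beta @ x.T + offset, -_ETA_CLIP, _ETA_CLIP)
    llf = _nb_llf(y, np.exp(eta), alpha)
    return beta, llf


def _dummy_columns(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(values))
    cols = [
        (values == lev).to_numpy(dtype=float) for lev in levels[1:]
    ]  # first level is reference
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0)), names


def _build_design(samples: pd.DataFrame) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Additive design matrix (intercept + G + T + P dummies) and factor → column map."""
    blocks = [np.ones((len(samples), 1))]
    col_map: dict[str, list[int]] = {}
    start = 1
    for factor, column in [("G", "genotype"), ("T", "treatment"), ("P", "timepoint")]:
        levels = pd.unique(samples[column])
        if len(levels) < 2:
            raise ValueError(
                f"factor {factor} ({column}) is collapsed to a single level "
                f"{list(levels)}; the design is singular"
            )
        block, _ = _dummy_columns(samples[column], factor)
        blocks.append(block)
        col_map[factor] = list(range(start, start + block.shape[1]))
        start += block.shape[1]
    return np.hstack(blocks), col_map


# ---------------------------------------------------------------------------
# model front end
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    """Seven disjoint effect components of genes significant for >= 1 factor."""

    regions: dict[str, set[str]]
    totals: dict[str, int]

    REGION_NAMES = ("G_only", "T_only", "P_only", "GT_only", "GP_only", "TP_only", "GTP")

    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.regions.values():
            out |= s
        return out

    def sizes(self) -> dict[str, int]:
        return {name: len(self.regions[name]) for name in self.REGION_NAMES}


def venn_partition(deg_table: pd.DataFrame) -> VennPartition:
    """Disjoint Venn regions from per-factor significance flags.

    Expects boolean columns sig_G, sig_T, sig_P indexed by gene id; also
    reports the per-factor totals (the parenthesized per-component counts of
    a three-set Venn diagram).
    """
    flags = {f: deg_table[f"sig_{f}"].astype(bool) for f in FACTORS}
    g, t, p = (flags[f] for f in FACTORS)
    idx = deg_table.index
    regions = {
        "G_only": set(idx[g & ~t & ~p]),
        "T_only": set(idx[~g & t & ~p]),
        "P_only": set(idx[~g & ~t & p]),
        "GT_only": set(idx[g & t & ~p]),
        "GP_only": set(idx[g & ~t & p]),
        "TP_only": set(idx[~g & t & p]),
        "GTP": set(idx[g & t & p]),
    }
    totals = {f: int(flags[f].sum()) for f in FACTORS}
    part = VennPartition(regions=regions, totals=totals)
    # internal consistency: per-factor total equals the sum of its four regions
    assert totals["G"] == sum(
        len(regions[r]) for r in ("G_only", "GT_only", "GP_only", "GTP")
    )
    assert totals["T"] == sum(
        len(regions[r]) for r in ("T_only", "GT_only", "TP_only", "GTP")
    )
    assert totals["P"] == sum(
        len(regions[r]) for r in ("P_only", "GP_only", "TP_only", "GTP")
    )
    return part


class MultifactorDE:
    """NB multifactor differential-expression model for a counts matrix.

    Parameters
    ----------
    counts : DataFrame
        Genes × samples integer counts.
    samples : DataFrame
        Sample sheet with columns sample_id, genotype, treatment, timepoint,
        replicate. Samples at timepoints in ``exclude_timepoints`` (default
        the unstressed baseline T0) are not used in the factor tests.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        exclude_timepoints: Sequence[str] = ("T0",),
    ) -> None:
        required = {"sample_id", "genotype", "treatment", "timepoint", "replicate"}
        missing = required - set(samples.columns)
        if missing:
            raise ValueError(f"sample sheet is missing columns {sorted(missing)}")
        if counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        used = samples[~samples["timepoint"].isin(exclude_timepoints)].reset_index(
            drop=True
        )
        unknown = set(used["sample_id"]) - set(counts.columns)
        if unknown:
            raise ValueError(f"samples missing from counts: {sorted(unknown)[:5]}")
        cell_sizes = used.groupby(
            ["genotype", "treatment", "timepoint"], observed=True
        ).size()
        if (cell_sizes < 2).any():
            bad = cell_sizes[cell_sizes < 2].index.tolist()
            raise ValueError(
                f"every used design cell needs >= 2 replicates for dispersion "
                f"estimation; short cells: {bad}"
            )
        self.counts = counts
        self.samples = used
        self._counts_used = counts[used["sample_id"].tolist()]

    @classmethod
    def from_tsv(cls, counts_path, samples_path, **kwargs) -> "MultifactorDE":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(counts, samples, **kwargs)

    def fit(self, alpha: float = 0.05, interactions: bool = False) -> "MultifactorDEResults":
        """Fit the additive NB model and LRT every factor; BH per factor.

        With ``interactions`` a second pass additionally tests each two- and
        three-way interaction against the additive model.
        """
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        counts = self._counts_used
        samples = self.samples
        y = counts.to_numpy(dtype=float)
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, samples, sf)
        offset = np.log(sf.to_numpy(dtype=float))
        x_full, col_map = _build_design(samples)

        nonzero = y.sum(axis=1) > 0
        yz = y[nonzero]
        az = disp.to_numpy()[nonzero]
        beta_full, llf_full = _fit_nb_batch(yz, x_full, offset, az)

        table = pd.DataFrame(index=counts.index)
        table.index.name = "gene_id"
        for factor in FACTORS:
            keep = [j for j in range(x_full.shape[1]) if j not in col_map[factor]]
            x_red = x_full[:, keep]
            beta_red, llf_red = _fit_nb_batch(yz, x_red, offset, az)
            # nested models: the reduced fit can only beat the full fit through
            # convergence failure; repair those genes from the reduced solution
            bad = np.flatnonzero(llf_red > llf_full + 1e-6)
            if bad.size:
                warm = np.zeros((bad.size, x_full.shape[1]))
                warm[:, keep] = beta_red[bad]
                beta_fix, llf_fix = _fit_nb_batch(
                    yz[bad], x_full, offset, az[bad], beta0=warm
                )
                better = llf_fix > llf_full[bad]
                llf_full[bad[better]] = llf_fix[better]
                beta_full[bad[better]] = beta_fix[better]
            stat = np.clip(2.0 * (llf_full - llf_red), 0.0, None)
            df = len(col_map[factor])
            pz = stats.chi2.sf(stat, df)
            p = np.ones(len(counts))
            p[nonzero] = pz
            table[f"p_{factor}"] = p
            table[f"padj_{factor}"] = bh_adjust(p)
            table[f"sig_{factor}"] = table[f"padj_{factor}"] < alpha
        table["degenerate"] = ~nonzero

        if interactions:
            self._add_interactions(table, yz, az, offset, nonzero, alpha)

        return MultifactorDEResults(
            table=table,
            alpha=alpha,
            size_factors=sf,
            dispersions=disp,
            n_samples=len(samples),
        )

    def _add_interactions(self, table, yz, az, offset, nonzero, alpha) -> None:
        samples = self.samples
        x_add, _ = _build_design(samples)
        _, llf_add = _fit_nb_batch(yz, x_add, offset, az)
        base_blocks = {
            "G": _dummy_columns(samples["genotype"], "G")[0],
            "T": _dummy_columns(samples["treatment"], "T")[0],
            "P": _dummy_columns(samples["timepoint"], "P")[0],
        }
        for name in ("G:T", "G:P", "T:P", "G:T:P"):
            parts = name.split(":")
            inter = base_blocks[parts[0]]
            for extra in parts[1:]:
                blk = base_blocks[extra]
                inter = np.einsum("ni,nj->nij", inter, blk).reshape(len(samples), -1)
            x_int = np.hstack([x_add, inter])
            _, llf_int = _fit_nb_batch(yz, x_int, offset, az)
            stat = np.clip(2.0 * (llf_int - llf_add), 0.0, None)
            pz = stats.chi2.sf(stat, inter.shape[1])
            col = name.replace(":", "x")
            p = np.ones(len(table))
            p[nonzero] = pz
            table[f"p_{col}"] = p
            table[f"padj_{col}"] = bh_adjust(p)
            table[f"sig_{col}"] = table[f"padj_{col}"] < alpha


@dataclass
class MultifactorDEResults:
    """Fitted per-gene, per-factor test results plus design-level diagnostics."""

    table: pd.DataFrame
    alpha: float
    size_factors: pd.Series
    dispersions: pd.Series
    n_samples: int

    def significant(self, factor: str) -> pd.Index:
        return self.table.index[self.table[f"sig_{factor}"]]

    def venn_partition(self) -> VennPartition:
        return venn_partition(self.table)

    def summary(self) -> str:
        venn = self.venn_partition()
        lines = [
            "Multifactor NB differential expression",
            "=" * 39,
            f"genes: {len(self.table)}   samples: {self.n_samples}   "
            f"alpha (BH): {self.alpha}",
            f"degenerate (all-zero) genes: {int(self.table['degenerate'].sum())}",
            "",
            "DEGs per factor (BH-adjusted p < alpha):",
        ]
        for f in FACTORS:
            lines.append(f"  {f}: {venn.totals[f]}")
        lines.append("")
        lines.append("Venn regions:")
        for name, size in venn.sizes().items():
            lines.append(f"  {name}: {size}")
        lines.append(f"  union: {len(venn.union())}")
        return "\n".join(lines)


def test_multifactor(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    interactions: bool = False,
) -> pd.DataFrame:
    """Functional wrapper: fit :class:`MultifactorDE` and return the DEG table."""
    return MultifactorDE(counts, samples).fit(alpha=alpha, interactions=interactions).table
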