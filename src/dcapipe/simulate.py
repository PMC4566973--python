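"""Synthetic inputs for the two-genotype drought pipeline.

Three generators produce everything the downstream stages consume, with the
planted truth returned alongside so recovery can be scored:

* :func:`simulate_counts` — negative-binomial count matrices for a
  two-genotype × two-treatment × multi-timepoint design with planted
  multiplicative genotype (G), treatment (T) and timepoint (P) effects;
* :func:`simulate_dca_geneset` — per-genotype log2(WS/WW) time-course
  profiles for one gene set with a planted co-expression conservation class
  (full / partial / split / absent);
* :func:`simulate_promoters` — random promoter sequences with planted
  W-box counts, optionally rejection-sampled so the planted count is the
  exact total count.

All generators are deterministic given their spec's seed; one root seed can
be fanned out to stage seeds with :func:`child_seeds`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dca import RatioProfilePair
from .motifs import WBOX_PATTERNS, PromoterSet, _count_wbox_rows, revcomp

__all__ = [
    "SimDesign",
    "EffectSpec",
    "DcaClassSpec",
    "PromoterSimSpec",
    "simulate_counts",
    "simulate_dca_geneset",
    "simulate_promoters",
    "simulate_category_map",
    "child_seeds",
    "DCA_CLASSES",
]

DCA_CLASSES = ("full", "partial", "split", "absent")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimDesign:
    """Factorial sample layout: genotypes × treatments × timepoints × replicates."""

    n_genes: int = 2000
    genotypes: tuple[str, str] = ("101.14", "M4")
    treatments: tuple[str, str] = ("WW", "WS")
    timepoints: tuple[str, ...] = ("T1", "T2", "T3", "T4")
    replicates_per_cell: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        for labels, name in [
            (self.genotypes, "genotypes"),
            (self.treatments, "treatments"),
            (self.timepoints, "timepoints"),
        ]:
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} labels must be unique")
        if len(self.genotypes) != 2 or len(self.treatments) != 2:
            raise ValueError("exactly two genotypes and two treatments are required")

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for g in self.genotypes:
            for t in self.treatments:
                for p in self.timepoints:
                    for r in range(1, self.replicates_per_cell + 1):
                        rows.append(
                            {
                                "sample_id": f"{g}_{t}_{p}_r{r}",
                                "genotype": g,
                                "treatment": t,
                                "timepoint": p,
                                "replicate": r,
                            }
                        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSpec:
    """Which fraction of genes carries each planted factor effect, and how big.

    ``effect_size`` is a multiplicative fold change applied to the non-reference
    genotype (G), the stressed treatment (T), or the later half of the
    timepoints (P). ``dispersion`` is the NB dispersion alpha in
    Var = mu + alpha * mu^2.

    ``direction`` controls the sign of each planted effect: "both" (default)
    draws induction or repression with equal probability per gene and factor,
    emulating stress responses that both induce and repress transcription;
    "up" and "down" force one direction. The drawn sign is recorded in the
    truth table.
    """

    frac_G: float = 0.1
    frac_T: float = 0.1
    frac_P: float = 0.1
    effect_size: float = 4.0
    dispersion: float = 0.05
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)
    direction: str = "both"

    def __post_init__(self) -> None:
        if self.direction not in ("both", "up", "down"):
            raise ValueError("direction must be 'both', 'up' or 'down'")
        for name in ("frac_G", "frac_T", "frac_P"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.effect_size < 1.0:
            raise ValueError("effect_size must be >= 1")
        if self.dispersion < 0.0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_mean_range must be a positive interval")


@dataclass
class SimulatedCounts:
    counts: pd.DataFrame  # genes × samples, integer
    samples: pd.DataFrame  # sample sheet
    truth: pd.DataFrame  # genes × {G, T, P} boolean effect labels


def simulate_counts(
    design: SimDesign, effects: EffectSpec, de_ready: bool = True
) -> SimulatedCounts:
    """Draw an NB count matrix with planted multiplicative factor effects.

    With ``de_ready=True`` (the default) designs with fewer than two
    replicates per cell are rejected, because downstream dispersion
    estimation needs within-cell replication.
    """
    if de_ready and design.replicates_per_cell < 2:
        raise ValueError(
            "replicates_per_cell must be >= 2 for DE-ready output "
            "(within-cell dispersion is not estimable otherwise)"
        )
    rng = np.random.default_rng(design.seed)
    samples = design.sample_sheet()
    n_s = len(samples)
    genes = [f"gene{i:05d}" for i in range(design.n_genes)]

    lo, hi = effects.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=design.n_genes))

    truth = pd.DataFrame(
        {
            f: rng.random(design.n_genes) < frac
            for f, frac in [
                ("G", effects.frac_G),
                ("T", effects.frac_T),
                ("P", effects.frac_P),
            ]
        },
        index=pd.Index(genes, name="gene_id"),
    )
    if effects.effect_size == 1.0:
        truth.loc[:, :] = False
    for f in ("G", "T", "P"):
        if effects.direction == "both":
            sign = np.where(rng.random(design.n_genes) < 0.5, 1, -1)
        else:
            sign = np.full(design.n_genes, 1 if effects.direction == "up" else -1)
        truth[f"sign_{f}"] = np.where(truth[f], sign, 0)

    # multiplicative design: G on the second genotype, T on the second
    # treatment (WS), P on the later half of the timepoints
    late = set(design.timepoints[len(design.timepoints) // 2 :])
    g_mask = (samples["genotype"] == design.genotypes[1]).to_numpy()
    t_mask = (samples["treatment"] == design.treatments[1]).to_numpy()
    p_mask = samples["timepoint"].isin(late).to_numpy()

    mu = np.tile(base[:, None], (1, n_s))
    for f, mask in [("G", g_mask), ("T", t_mask), ("P", p_mask)]:
        fold = effects.effect_size ** truth[f"sign_{f}"].to_numpy(dtype=float)
        mu[:, mask] *= fold[:, None]

    alpha = effects.dispersion
    if alpha < 1e-12:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index(genes, name="gene_id"),
        columns=samples["sample_id"].tolist(),
    )
    return SimulatedCounts(counts=counts_df, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# DCA gene-set simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DcaClassSpec:
    """One gene set with a planted co-expression conservation class.

    The reference genotype always follows one shared latent time course;
    the target genotype's behaviour encodes the class: ``full`` keeps the
    latent, ``split`` sends the two halves along anti-correlated latents,
    ``partial`` keeps the latent for one half and pure noise for the other,
    ``absent`` is pure noise throughout.
    """

    planted_class: str = "full"
    n_genes: int = 8
    n_timepoints: int = 8
    latent_amplitude: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0
    genotypes: tuple[str, str] = ("101.14", "M4")

    def __post_init__(self) -> None:
        if self.planted_class not in DCA_CLASSES:
            raise ValueError(f"planted_class must be one of {DCA_CLASSES}")
        if self.n_genes < 4:
            raise ValueError("n_genes must be >= 4 (subclustering undefined below)")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.latent_amplitude <= 0:
            raise ValueError("latent_amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimulatedDca:
    profiles: RatioProfilePair
    planted_class: str
    halves: tuple[list[str], list[str]]


def _latent_course(n_timepoints: int, amplitude: float) -> np.ndarray:
    # sinusoid plus linear trend: nonconstant, reproducible, no exact symmetry
    t = np.linspace(0.0, 1.0, n_timepoints)
    return amplitude * (np.sin(2.0 * np.pi * t) + 1.5 * t)


def simulate_dca_geneset(spec: DcaClassSpec) -> SimulatedDca:
    """Simulate a reference/target profile pair for one planted class."""
    rng = np.random.default_rng(spec.seed)
    latent = _latent_course(spec.n_timepoints, spec.latent_amplitude)
    n, m = spec.n_genes, spec.n_timepoints
    genes = [f"dca{i:03d}" for i in range(n)]
    half = n // 2
    halves = (genes[:half], genes[half:])

    # pure-noise genes need nonzero variance even when noise_sd == 0
    noise_scale = spec.noise_sd if spec.noise_sd > 0 else spec.latent_amplitude

    ref = np.tile(latent, (n, 1)) + rng.normal(0.0, spec.noise_sd, size=(n, m))

    tgt = np.empty((n, m))
    if spec.planted_class == "full":
        tgt[:] = np.tile(latent, (n, 1))
    elif spec.planted_class == "split":
        tgt[:half] = np.tile(latent, (half, 1))
        tgt[half:] = np.tile(-latent, (n - half, 1))  # latent corr = -1 <= 0
    elif spec.planted_class == "partial":
        tgt[:half] = np.tile(latent, (half, 1))
        tgt[half:] = rng.normal(0.0, noise_scale, size=(n - half, m))
    else:  # absent
        tgt[:] = rng.normal(0.0, noise_scale, size=(n, m))
    if spec.planted_class in ("full", "split"):
        tgt += rng.normal(0.0, spec.noise_sd, size=(n, m))
    elif spec.planted_class == "partial":
        tgt[:half] += rng.normal(0.0, spec.noise_sd, size=(half, m))

    timepoints = [f"T{i + 1}" for i in range(m)]
    idx = pd.Index(genes, name="gene_id")
    profiles = RatioProfilePair(
        genotypes=spec.genotypes,
        data={
            spec.genotypes[0]: pd.DataFrame(ref, index=idx, columns=timepoints),
            spec.genotypes[1]: pd.DataFrame(tgt, index=idx, columns=timepoints),
        },
    )
    return SimulatedDca(profiles=profiles, planted_class=spec.planted_class, halves=halves)


# ---------------------------------------------------------------------------
# promoter simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromoterSimSpec:
    """Random promoters with Poisson-planted W-box counts.

    ``exact_counts=True`` rejection-samples the background nucleotides so no
    chance W-box occurs outside the planted insertions: the planted count is
    then the exact scan count, which makes truth-recovery tests exact.
    """

    n_target: int = 30
    n_background: int = 10_000
    length: int = 1000
    gc: float = 0.4
    target_rate: float = 5.0
    background_rate: float = 1.0
    seed: int = 0
    exact_counts: bool = True
    patterns: tuple[str, ...] = WBOX_PATTERNS

    def __post_init__(self) -> None:
        if self.n_target < 1 or self.n_background < 1:
            raise ValueError("n_target and n_background must be positive")
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.target_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimulatedPromoters:
    target: PromoterSet
    background: PromoterSet
    truth: pd.DataFrame  # columns: promoter_id, group, planted_count


def _random_bases(rng: np.random.Generator, shape: tuple[int, int], gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=shape, p=probs)]


def _plant_motifs(
    rng: np.random.Generator,
    seqs: np.ndarray,
    planted: np.ndarray,
    patterns: Sequence[str],
    exact: bool,
    gc: float,
) -> None:
    """Insert ``planted[i]`` motif copies into row i at non-overlapping positions.

    With ``exact`` set, rows whose final scan count differs from the planted
    count (chance background matches, or a new match spanning an insertion
    boundary) are redrawn until the planted count is exact.
    """
    n, length = seqs.shape
    motif_len = max(len(p) for p in patterns)
    both = [p.encode() for p in patterns] + [revcomp(p).encode() for p in patterns]
    pat_arrays = [np.frombuffer(b, dtype=np.uint8) for b in both]
    if planted.max(initial=0) * motif_len > length:
        raise ValueError(
            f"length {length} too short to host {planted.max()} non-overlapping motifs"
        )

    pending = np.arange(n)
    for _ in range(1000):
        if pending.size == 0:
            return
        for i in pending:
            seqs[i] = _random_bases(rng, (1, length), gc)[0]
            k = int(planted[i])
            if k == 0:
                continue
            # sorted draws in a shrunk range, then spaced out: uniform
            # non-overlapping positions
            slack = length - motif_len * k
            pos = np.sort(rng.integers(0, slack + 1, size=k)) + motif_len * np.arange(k)
            for j, p in enumerate(pos):
                arr = pat_arrays[rng.integers(0, len(pat_arrays))]
                seqs[i, p : p + motif_len] = arr
        if not exact:
            return
        found = _count_wbox_rows(seqs[pending], patterns)
        pending = pending[found != planted[pending]]
    raise RuntimeError("rejection sampling failed to realize exact planted counts")


def simulate_promoters(spec: PromoterSimSpec) -> SimulatedPromoters:
    """Generate target and background promoter sets with planted W-box counts."""
    rng = np.random.default_rng(spec.seed)
    groups = []
    for name, n, rate in [
        ("target", spec.n_target, spec.target_rate),
        ("background", spec.n_background, spec.background_rate),
    ]:
        planted = rng.poisson(rate, size=n)
        seqs = np.empty((n, spec.length), dtype=np.uint8)
        _plant_motifs(rng, seqs, planted, spec.patterns, spec.exact_counts, spec.gc)
        prefix = "tgt" if name == "target" else "bg"
        ids = [f"{prefix}{i:05d}" for i in range(n)]
        strings = {pid: seqs[i].tobytes().decode() for i, pid in enumerate(ids)}
        groups.append((name, ids, planted, PromoterSet(strings)))

    truth = pd.concat(
        [
            pd.DataFrame({"promoter_id": ids, "group": name, "planted_count": planted})
            for name, ids, planted, _ in groups
        ],
        ignore_index=True,
    )
    return SimulatedPromoters(target=groups[0][3], background=groups[1][3], truth=truth)


# ---------------------------------------------------------------------------
# category-map simulation (pipeline plumbing)
# ---------------------------------------------------------------------------


def simulate_category_map(
    gene_ids: Sequence[str],
    vocabulary: Sequence[str],
    mean_labels: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene → macro-category assignments over a controlled vocabulary."""
    rng = np.random.default_rng(seed)
    vocab = list(vocabulary)
    rows = []
    for g in gene_ids:
        k = min(rng.poisson(mean_labels), len(vocab))
        for c in rng.choice(len(vocab), size=k, replace=False):
            rows.append({"gene_id": g, "category": vocab[c]})
    return pd.DataFrame(rows, columns=["gene_id", "category"])
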