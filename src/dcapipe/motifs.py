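"""Promoter extraction, W-box counting, k-mer census, enrichment and fits.

The W-box is the WRKY transcription-factor binding cis-element with core
TGAC and consensus (T)TGAC(C/T); the default exact pattern set is
``{"TTGACC", "TTGACT"}`` and every scan is strand-aware: a sequence is
searched for the patterns and for their reverse complements, overlaps
allowed, N never matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "WBOX_PATTERNS",
    "PromoterSet",
    "EnrichTestResult",
    "MotifExprFit",
    "revcomp",
    "count_wbox",
    "count_wbox_table",
    "extract_promoters",
    "kmer_census",
    "is_wbox_kmer",
    "wbox_enrichment",
    "motif_expression_fit",
]

WBOX_PATTERNS: tuple[str, str] = ("TTGACC", "TTGACT")
WBOX_CORE = "TGAC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset(b"ACGTN")

# base codes for the k-mer census: A=0 C=1 G=2 T=3 N=4 (base-5 window values)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_seq(seq: str) -> str:
    s = seq.upper()
    bad = set(s.encode()) - _VALID
    if bad:
        raise ValueError(
            f"sequence contains characters outside ACGTN: {sorted(chr(c) for c in bad)}"
        )
    return s


@dataclass
class PromoterSet:
    """Uppercase promoter sequences keyed by unique id, with optional provenance.

    ``provenance`` rows, when present, give (gene_id, contig, start, end,
    strand) with 1-based inclusive coordinates on the forward genome strand.
    """

    sequences: dict[str, str]
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sequences = {pid: _validate_seq(s) for pid, s in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def ids(self) -> list[str]:
        return list(self.sequences)

    def lengths(self) -> pd.Series:
        return pd.Series({pid: len(s) for pid, s in self.sequences.items()}, name="length")

    def to_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=pid, description="") for pid, s in self.sequences.items()
        ]
        seqio_write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PromoterSet":
        from Bio import SeqIO

        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate promoter id {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        return cls(seqs)


# ---------------------------------------------------------------------------
# W-box scanning
# ---------------------------------------------------------------------------


def _strand_patterns(patterns: Sequence[str]) -> list[np.ndarray]:
    """Pattern byte-arrays for both strands, deduplicated (palindromes once)."""
    seen: dict[str, np.ndarray] = {}
    for p in patterns:
        p = _validate_seq(p)
        if not p:
            raise ValueError("empty pattern")
        for q in (p, revcomp(p)):
            seen.setdefault(q, np.frombuffer(q.encode(), dtype=np.uint8))
    return [seen[k] for k in sorted(seen)]


def _encode_batch(seqs: Sequence[str]) -> np.ndarray:
    """Equal-length sequences as a (n, L) uint8 byte matrix."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("batch encoding requires equal-length sequences")
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def _count_wbox_rows(rows: np.ndarray, patterns: Sequence[str] = WBOX_PATTERNS) -> np.ndarray:
    """Per-row strand-aware overlapping match counts on a (n, L) byte matrix."""
    n, length = rows.shape
    total = np.zeros(n, dtype=np.int64)
    for pat in _strand_patterns(patterns):
        k = len(pat)
        if k > length:
            continue
        hit = np.ones((n, length - k + 1), dtype=bool)
        for j in range(k):
            hit &= rows[:, j : length - k + 1 + j] == pat[j]
        total += hit.sum(axis=1)
    return total


def count_wbox(seq: str, patterns: Sequence[str] = WBOX_PATTERNS) -> int:
    """Count W-box occurrences in one sequence, both strands, overlaps allowed."""
    s = _validate_seq(seq)
    if not s:
        raise ValueError("empty sequence")
    row = np.frombuffer(s.encode(), dtype=np.uint8)[None, :]
    return int(_count_wbox_rows(row, patterns)[0])


def count_wbox_table(
    promoters: PromoterSet, patterns: Sequence[str] = WBOX_PATTERNS
) -> pd.Series:
    """Per-promoter W-box counts as a Series indexed by promoter id."""
    counts = {pid: count_wbox(s, patterns) for pid, s in promoters.sequences.items()}
    return pd.Series(counts, name="wbox_count", dtype=np.int64)


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------


def extract_promoters(
    genome_fasta: str | Path,
    annotation_gff: str | Path,
    upstream_len: int = 1500,
    feature_type: str = "gene",
) -> PromoterSet:
    """Upstream promoter windows for every stranded gene in a GFF3 annotation.

    For a plus-strand gene starting at 1-based ``s`` the promoter is
    ``[max(1, s - upstream_len), s - 1]``; for a minus-strand gene ending at
    ``e`` it is the reverse complement of ``[e + 1, e + upstream_len]``,
    clipped at the contig end. Genes without a strand are skipped with a
    warning; a contig missing from the FASTA is an error.
    """
    import gffutils
    from Bio import SeqIO

    if upstream_len < 1:
        raise ValueError("upstream_len must be positive")
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(
        str(annotation_gff),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    seqs: dict[str, str] = {}
    prov_rows = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            logger.warning("gene %s has no strand; skipped", feat.id)
            continue
        if feat.seqid not in genome:
            raise ValueError(f"contig {feat.seqid!r} missing from the genome FASTA")
        contig = genome[feat.seqid]
        if feat.strand == "+":
            start = max(1, feat.start - upstream_len)
            end = feat.start - 1
            if end < start:
                logger.warning("gene %s starts at contig edge; no promoter", feat.id)
                continue
            seq = contig[start - 1 : end]
        else:
            start = feat.end + 1
            end = min(len(contig), feat.end + upstream_len)
            if end < start:
                logger.warning("gene %s ends at contig edge; no promoter", feat.id)
                continue
            seq = revcomp(contig[start - 1 : end])
        seqs[feat.id] = seq
        prov_rows.append(
            {
                "gene_id": feat.id,
                "contig": feat.seqid,
                "start": start,
                "end": end,
                "strand": feat.strand,
            }
        )
    return PromoterSet(seqs, provenance=pd.DataFrame(prov_rows))


# ---------------------------------------------------------------------------
# k-mer census
# ---------------------------------------------------------------------------


def is_wbox_kmer(kmer: str, patterns: Sequence[str] = WBOX_PATTERNS) -> bool:
    """Whether a k-mer carries the W-box core (and full consensus if it fits).

    A k-mer is flagged when TGAC occurs on either strand; from length 6 on it
    must additionally contain one of the full consensus patterns on either
    strand.
    """
    s = _validate_seq(kmer)
    rc = revcomp(s)
    core = WBOX_CORE in s or WBOX_CORE in rc
    if not core:
        return False
    if len(s) < min(len(p) for p in patterns):
        return True
    return any(p in s or p in rc for p in patterns)


def _decode_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        value, digit = divmod(value, 5)
        out.append("ACGTN"[digit])
    return "".join(reversed(out))


def kmer_census(
    promoters: PromoterSet,
    k_min: int = 4,
    k_max: int = 7,
    patterns: Sequence[str] = WBOX_PATTERNS,
) -> pd.DataFrame:
    """Strand-collapsed k-mer counts over a promoter set.

    Every window of each length is counted once under its canonical form
    (the lexicographically smaller of the k-mer and its reverse complement),
    so the per-k total equals sum(max(0, len - k + 1)) over promoters.
    """
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    rows = []
    for k in range(k_min, k_max + 1):
        weights = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        values: list[np.ndarray] = []
        for seq in promoters.sequences.values():
            if len(seq) < k:
                continue
            codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            fwd = win @ weights
            rc = _COMP_CODE[win[:, ::-1]].astype(np.int64) @ weights
            values.append(np.minimum(fwd, rc))
        if not values:
            continue
        uniq, counts = np.unique(np.concatenate(values), return_counts=True)
        for v, c in zip(uniq, counts):
            kmer = _decode_kmer(int(v), k)
            rows.append(
                {
                    "kmer": kmer,
                    "k": k,
                    "count": int(c),
                    "is_wbox": is_wbox_kmer(kmer, patterns),
                }
            )
    return pd.DataFrame(rows, columns=["kmer", "k", "count", "is_wbox"])


# ---------------------------------------------------------------------------
# enrichment test and expression fit
# ---------------------------------------------------------------------------


@dataclass
class EnrichTestResult:
    """Welch two-sample t comparison of per-promoter W-box frequencies."""

    statistic: float
    df: float
    pvalue: float
    mean_target: float
    mean_background: float
    n_target: int
    n_background: int
    unit: str = "count"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
            "mean_target": self.mean_target,
            "mean_background": self.mean_background,
            "n_target": self.n_target,
            "n_background": self.n_background,
            "unit": self.unit,
            "degenerate": self.degenerate,
        }


def _as_values(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        counts = pd.Series(counts)
    arr = np.asarray(counts, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("counts must be finite")
    return arr


def wbox_enrichment(
    target,
    background,
    target_lengths=None,
    background_lengths=None,
    per_kb: bool = False,
) -> EnrichTestResult:
    """Welch t-test of W-box frequency in a target set against a background.

    With ``per_kb`` the per-promoter counts are converted to counts per kb
    using the supplied lengths (required then); otherwise raw per-promoter
    counts are compared, which presumes equal promoter windows.
    """
    x = _as_values(target)
    y = _as_values(background)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least two promoters")
    unit = "count"
    if per_kb:
        if target_lengths is None or background_lengths is None:
            raise ValueError("per_kb=True requires promoter lengths for both groups")
        x = 1000.0 * x / _as_values(target_lengths)
        y = 1000.0 * y / _as_values(background_lengths)
        unit = "per_kb"

    mx, my = float(np.mean(x)), float(np.mean(y))
    vx = float(np.var(x, ddof=1)) / len(x)
    vy = float(np.var(y, ddof=1)) / len(y)
    base = EnrichTestResult(
        statistic=0.0,
        df=float(len(x) + len(y) - 2),
        pvalue=1.0,
        mean_target=mx,
        mean_background=my,
        n_target=len(x),
        n_background=len(y),
        unit=unit,
    )
    if vx + vy == 0.0:
        if mx == my:
            return base
        base.statistic = float(np.inf if mx > my else -np.inf)
        base.pvalue = 5e-324  # smallest positive subnormal: below machine threshold
        base.degenerate = True
        return base
    t = (mx - my) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    base.statistic = float(t)
    base.df = float(df)
    base.pvalue = float(2.0 * stats.t.sf(abs(t), df))
    return base


@dataclass
class MotifExprFit:
    """Least-squares line of expression on W-box count."""

    slope: float
    intercept: float
    r_squared: float


def motif_expression_fit(counts, expression) -> MotifExprFit:
    """OLS regression of per-gene expression on per-gene W-box count."""
    x = _as_values(counts)
    y = _as_values(expression)
    if len(x) != len(y):
        raise ValueError("counts and expression must align")
    if len(x) < 3:
        raise ValueError("need at least three genes")
    if np.var(x) == 0:
        raise ValueError("motif counts are constant; fit undefined")
    res = stats.linregress(x, y)
    return MotifExprFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
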