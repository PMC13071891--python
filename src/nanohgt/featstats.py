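"""Genomic-feature, expression and enrichment statistics for HGT vs native genes.

Comparisons supported, matching how transferred genes are profiled against
the host gene background:

* GC content and CDS length (Wilcoxon rank-sum, two-sided);
* intron-containing proportion (Pearson chi-square on a 2x2 table, no
  continuity correction);
* expression (TPM normalization, then Wilcoxon rank-sum);
* functional-term enrichment (hypergeometric upper tail with
  Benjamini-Hochberg FDR control);
* ORF translation under the Euplotid nuclear genetic code (UGA = Cys),
  and germline (MIC) scaffold-dispersion accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "TestResult",
    "EnrichmentRow",
    "gc_content",
    "wilcoxon_rank_sum",
    "chi_square_independence",
    "tpm",
    "hypergeometric_enrichment",
    "bh_adjust",
    "translate_orf",
    "mic_dispersion",
    "EUPLOTID_TABLE",
    "STANDARD_TABLE",
]

#: NCBI translation table ids
EUPLOTID_TABLE = 10  # Euplotid nuclear: UGA -> Cys; stops UAA/UAG only
STANDARD_TABLE = 1


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's enrichment: k of n study genes hit a term of size K in a
    universe of N genes."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


# ---------------------------------------------------------------------------
# sequence-level features
# ---------------------------------------------------------------------------


def gc_content(sequence: str) -> float:
    """Fraction of G+C among unambiguous bases (N excluded from both sides)."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def translate_orf(dna: str, genetic_code: int = EUPLOTID_TABLE) -> str:
    """Translate a stop-exclusive ORF; length must be a multiple of 3.

    The default code is the Euplotid nuclear variant (NCBI table 10), under
    which UGA encodes cysteine and only UAA/UAG terminate.  The ORF span is
    expected to exclude its stop codon, so any stop is an error naming the
    offending codon position (1-based).
    """
    seq = dna.upper().replace("U", "T")
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} is not a positive multiple of 3")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    protein = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in table.stop_codons:
            raise ValueError(
                f"stop codon {codon} at codon position {i // 3 + 1} "
                f"(translation table {genetic_code})"
            )
        try:
            protein.append(table.forward_table[codon])
        except KeyError as exc:
            raise ValueError(f"untranslatable codon {codon!r} at position {i // 3 + 1}") from exc
    return "".join(protein)


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------


def _exact_rank_sum_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) assignments
    of the pooled mid-ranks to group x.  Handles ties via mid-ranks.
    Returns (W, p) with p = min(1, 2 * min(P(W<=w), P(W>=w)))."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n = len(x)
    w_obs = float(np.sum(ranks[:n]))
    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for idx in combinations(range(len(pooled)), n):
        w = float(sum(ranks[i] for i in idx))
        total += 1
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return w_obs, p


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    mode='exact' enumerates the permutation distribution of the rank sum
    (mid-ranks under ties); mode='normal' uses the asymptotic normal
    approximation with tie and continuity corrections; mode='auto' picks
    exact when min(|x|, |y|) <= 8, the pooled sample is tie-free, and the
    enumeration is small enough to be instantaneous (C(n+m, min) <= 2e5 —
    for larger pools the normal approximation is already accurate).
    The statistic reported is W, the rank sum of ``x``.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in {"exact", "normal", "auto"}:
        raise ValueError(f"unknown mode {mode!r}")
    pooled = list(x) + list(y)
    tie_free = len(set(pooled)) == len(pooled)
    if mode == "auto":
        nmin = min(len(x), len(y))
        feasible = math.comb(len(pooled), nmin) <= 200_000
        mode = "exact" if (nmin <= 8 and tie_free and feasible) else "normal"

    ranks = stats.rankdata(pooled)
    w = float(np.sum(ranks[: len(x)]))
    if mode == "exact":
        w, p = _exact_rank_sum_p(x, y)
        return TestResult(statistic=w, p_value=p, method="wilcoxon_exact")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(statistic=w, p_value=float(res.pvalue), method="wilcoxon_normal")


def chi_square_independence(table_2x2: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 count table,
    without Yates continuity correction (df = 1, upper-tail p)."""
    obs = np.asarray(table_2x2, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), method="chi_square")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def tpm(counts: Sequence[float], lengths_bp: Sequence[float]) -> np.ndarray:
    """Transcripts-per-million from counts and effective lengths.

    tpm_i = 1e6 * (counts_i / lengths_i) / sum_j (counts_j / lengths_j);
    the result sums to one million by construction.
    """
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths_bp, dtype=float)
    if c.shape != l.shape or c.ndim != 1:
        raise ValueError("counts and lengths must be equal-length vectors")
    if np.any(l <= 0):
        raise ValueError("lengths must be positive")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    rate = c / l
    denom = rate.sum()
    if denom <= 0:
        raise ValueError("all-zero counts: TPM undefined")
    return 1e6 * rate / denom


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_enrichment(
    study_set: Iterable[str],
    annotation_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Term over-representation in a study set against a gene universe.

    For each term annotated to at least one universe gene, the upper-tail
    hypergeometric p = P(X >= k) with X ~ Hypergeom(N, K, n) is computed and
    BH-adjusted across all tested terms.  Rows are sorted by (p, term).
    """
    universe_set = set(universe)
    study = set(study_set)
    outside = study - universe_set
    if outside:
        raise ValueError(
            f"study genes outside the universe: {sorted(outside)[:5]}"
        )
    term_members: dict[str, set[str]] = {}
    for gene, terms in annotation_map.items():
        if gene not in universe_set:
            continue
        for term in terms:
            term_members.setdefault(term, set()).add(gene)
    if not term_members:
        return []
    N, n = len(universe_set), len(study)
    rows = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = len(members & study)
        # P(X >= k); sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    qs = bh_adjust([r[3] for r in rows])
    out = [
        EnrichmentRow(term=term, k=k, K=K, n=n, N=N, p=p, q=float(q))
        for (term, k, K, p), q in zip(rows, qs)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


# ---------------------------------------------------------------------------
# germline (MIC) dispersion
# ---------------------------------------------------------------------------


def mic_dispersion(gene_to_scaffold: Mapping[str, str]) -> tuple[int, int, int]:
    """Summarize how MAC genes disperse over germline scaffolds.

    Returns (genes mapped, distinct scaffolds, max genes on one scaffold).
    """
    if not gene_to_scaffold:
        raise ValueError("empty gene-to-scaffold map")
    scaffolds: dict[str, int] = {}
    for scaf in gene_to_scaffold.values():
        scaffolds[scaf] = scaffolds.get(scaf, 0) + 1
    return (len(gene_to_scaffold), len(scaffolds), max(scaffolds.values()))
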