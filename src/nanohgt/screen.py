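"""Hit-profile screening and the nanochromosome contamination filter.

A gene becomes an HGT *candidate* when

1. after discarding hits above the E-value cutoff and hits to the host's own
   genus, its best remaining hit is prokaryotic and strictly more than half
   of the remaining hits are prokaryotic (Bacteria or Archaea), and
2. the gene is demonstrably on a host nanochromosome rather than on a
   bacterial contaminant contig: the contig carries the host telomeric
   repeat (C4A4 / G4T4) at an end, OR the gene model contains at least one
   spliceosomal intron.  One of the two suffices.

Candidates then proceed to phylogenetic validation (:mod:`nanohgt.phylo`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seqio import GeneModel, HGTCall, Hit, Nanochromosome

__all__ = [
    "ScreenConfig",
    "detect_telomeres",
    "evaluate_hit_profile",
    "retained_hits",
    "best_hit",
    "contamination_filter",
    "screen_genome",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ScreenConfig:
    """Thresholds of the screening stage.

    evalue_cutoff
        Hits with E-value above this are discarded (default 1e-5).
    prokaryote_fraction_threshold
        The prokaryotic hit fraction must *strictly* exceed this (default
        0.5: "more than half").
    telomere_motifs
        Telomeric repeat units scanned at contig ends.  Reverse complements
        are added automatically, so the default C4A4/G4T4 pair covers both
        strand readings.
    telomere_window_bp
        A telomeric tract must start within this many bp of the contig end.
    telomere_min_units
        Minimum tandem copies of the unit for a positive call.
    self_taxon_excluded
        Hit genera treated as self-hits and removed before profiling.
    """

    evalue_cutoff: float = 1e-5
    prokaryote_fraction_threshold: float = 0.5
    telomere_motifs: tuple[str, ...] = ("CCCCAAAA", "GGGGTTTT")
    telomere_window_bp: int = 50
    telomere_min_units: int = 2
    self_taxon_excluded: frozenset[str] = frozenset({"Euplotes"})

    def __post_init__(self) -> None:
        if not 0.0 < self.prokaryote_fraction_threshold < 1.0:
            raise ValueError("prokaryote_fraction_threshold must be in (0, 1)")
        if self.telomere_min_units < 1:
            raise ValueError("telomere_min_units must be >= 1")
        if not self.telomere_motifs:
            raise ValueError("telomere_motifs must be non-empty")
        for m in self.telomere_motifs:
            if not m or set(m) - set("ACGT"):
                raise ValueError(f"bad telomere motif {m!r}")
        self.self_taxon_excluded = frozenset(self.self_taxon_excluded)

    @property
    def all_motifs(self) -> tuple[str, ...]:
        """Configured motifs plus their reverse complements, deduplicated."""
        seen: dict[str, None] = {}
        for m in self.telomere_motifs:
            seen.setdefault(m)
            seen.setdefault(reverse_complement(m))
        return tuple(seen)


# ---------------------------------------------------------------------------
# telomere detection
# ---------------------------------------------------------------------------


def _max_tandem_units(seq: str, motifs: Sequence[str], window: int) -> int:
    """Longest run of tandem motif copies anchored near the 5' end.

    The run may start at any offset within ``window`` bp, which also allows a
    ragged partial leading unit (macronuclear telomere boundaries are not
    flush with the assembled contig end).
    """
    best = 0
    limit = min(window, len(seq))
    for motif in motifs:
        k = len(motif)
        for pos in range(limit):
            count = 0
            p = pos
            while seq.startswith(motif, p):
                count += 1
                p += k
            if count > best:
                best = count
    return best


def detect_telomeres(contig: Nanochromosome, cfg: ScreenConfig | None = None) -> Nanochromosome:
    """Fill in tandem telomere-unit counts at both contig ends.

    The right end is scanned as the left end of the reverse complement, so
    reverse-complementing a contig exactly swaps the two counts.  A contig
    "has a telomere" when either count reaches ``cfg.telomere_min_units``.
    """
    cfg = cfg or ScreenConfig()
    motifs = cfg.all_motifs
    contig.left_telomere_units = _max_tandem_units(
        contig.sequence, motifs, cfg.telomere_window_bp
    )
    contig.right_telomere_units = _max_tandem_units(
        reverse_complement(contig.sequence), motifs, cfg.telomere_window_bp
    )
    return contig


def has_telomere(contig: Nanochromosome, cfg: ScreenConfig | None = None) -> bool:
    """One telomeric end suffices (nanochromosome ends are often truncated)."""
    cfg = cfg or ScreenConfig()
    return (
        max(contig.left_telomere_units, contig.right_telomere_units)
        >= cfg.telomere_min_units
    )


# ---------------------------------------------------------------------------
# hit-profile screening
# ---------------------------------------------------------------------------


def retained_hits(hits: Iterable[Hit], cfg: ScreenConfig) -> list[Hit]:
    """Hits surviving the E-value cutoff and the self-genus exclusion."""
    return [
        h
        for h in hits
        if h.evalue <= cfg.evalue_cutoff and h.genus not in cfg.self_taxon_excluded
    ]


def best_hit(hits: Sequence[Hit]) -> Hit:
    """Minimal E-value; ties broken by maximal bitscore, then subject id.

    Deterministic and independent of row order.
    """
    if not hits:
        raise ValueError("no hits")
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def evaluate_hit_profile(
    hits: Sequence[Hit], cfg: ScreenConfig | None = None
) -> tuple[bool, bool, float]:
    """Apply the best-hit and prokaryote-fraction rules to one gene's hits.

    Returns ``(passed_evalue, best_hit_prokaryotic, prokaryote_hit_fraction)``.
    ``passed_evalue`` means at least one hit survived filtering; with an
    empty retained set the profile fails and the fraction is reported as 0.
    The overall screen passes iff ``passed_evalue`` and the best hit is
    prokaryotic and the fraction strictly exceeds the threshold.
    """
    cfg = cfg or ScreenConfig()
    kept = retained_hits(hits, cfg)
    if not kept:
        return (False, False, 0.0)
    top = best_hit(kept)
    frac = sum(h.is_prokaryotic for h in kept) / len(kept)
    return (True, top.is_prokaryotic, frac)


def hit_profile_pass(
    profile: tuple[bool, bool, float], cfg: ScreenConfig | None = None
) -> bool:
    cfg = cfg or ScreenConfig()
    passed_evalue, best_prok, frac = profile
    return passed_evalue and best_prok and frac > cfg.prokaryote_fraction_threshold


# ---------------------------------------------------------------------------
# contamination filter
# ---------------------------------------------------------------------------


def contamination_filter(has_telomere: bool, intron_count: int) -> bool:
    """A gene is retained iff its contig is telomere-capped OR it has an
    intron — either mark of eukaryotic (host) origin suffices; genes with
    neither are treated as putative bacterial contamination."""
    return bool(has_telomere) or intron_count >= 1


# ---------------------------------------------------------------------------
# whole-genome screening
# ---------------------------------------------------------------------------


def screen_genome(
    contigs: Sequence[Nanochromosome],
    genes: Sequence[GeneModel],
    hit_tables: Mapping[str, Sequence[Hit]],
    cfg: ScreenConfig | None = None,
) -> list[HGTCall]:
    """Screen every gene; returns one HGTCall per gene with the screening
    and contamination fields populated and ``phylo_verdict`` unset.

    Genes absent from ``hit_tables`` have no retained hits and fail the
    profile.  A gene referencing a missing contig is an error.
    """
    cfg = cfg or ScreenConfig()
    by_id: dict[str, Nanochromosome] = {}
    for contig in contigs:
        by_id[contig.contig_id] = contig
        detect_telomeres(contig, cfg)

    calls: list[HGTCall] = []
    for gene in genes:
        contig = by_id.get(gene.contig_id)
        if contig is None:
            raise ValueError(
                f"gene {gene.gene_id!r} references missing contig {gene.contig_id!r}"
            )
        profile = evaluate_hit_profile(hit_tables.get(gene.gene_id, ()), cfg)
        call = HGTCall(
            gene_id=gene.gene_id,
            passed_evalue=profile[0],
            best_hit_prokaryotic=profile[1],
            prokaryote_hit_fraction=profile[2],
            screen_pass=hit_profile_pass(profile, cfg),
            has_telomere=has_telomere(contig, cfg),
            has_intron=gene.intron_count >= 1,
        )
        call.contamination_pass = contamination_filter(
            call.has_telomere, gene.intron_count
        )
        calls.append(call)
    return calls


def candidate_ids(calls: Iterable[HGTCall]) -> set[str]:
    """Genes passing both the hit-profile screen and the contamination filter."""
    return {c.gene_id for c in calls if c.is_candidate}
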