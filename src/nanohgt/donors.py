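"""Donor attribution, endosymbiont flagging, and cross-species HGT families.

The putative donor of a transferred gene is read off the taxonomy of its
best retained homology hit.  A gene is endosymbiont-derived when that
donor's genus matches a genus known to live endosymbiotically in the host
(case-insensitive; "Candidatus " prefixes stripped).  Families of
transferred genes across host species are built by single-linkage over
bidirectional-best-hit (BBH) edges of a pairwise score table — a
self-contained stand-in for full orthogroup inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .screen import ScreenConfig, best_hit, retained_hits
from .seqio import FormatError, Hit

__all__ = [
    "DonorAssignment",
    "GeneFamily",
    "assign_donor",
    "phylum_spectrum",
    "flag_endosymbiont_derived",
    "read_endosymbiont_genera",
    "cluster_families",
    "shared_family_counts",
]


@dataclass(frozen=True)
class DonorAssignment:
    gene_id: str
    donor_species: str
    donor_genus: str
    donor_phylum: str
    best_hit_id: str


@dataclass
class GeneFamily:
    """A cross-species family; members are (species_id, gene_id) pairs."""

    family_id: str
    members: frozenset[tuple[str, str]]

    @property
    def species_present(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.members)


def assign_donor(
    gene_id: str, hits: Sequence[Hit], cfg: ScreenConfig | None = None
) -> DonorAssignment:
    """Donor taxonomy = best retained hit's taxonomy (same E-value/self-genus
    filtering and tie-breaking as the screening stage).  Errors if the best
    retained hit is not prokaryotic — such genes should not reach this stage."""
    cfg = cfg or ScreenConfig()
    kept = retained_hits(hits, cfg)
    if not kept:
        raise ValueError(f"gene {gene_id!r}: no retained hits to assign a donor from")
    top = best_hit(kept)
    if not top.is_prokaryotic:
        raise ValueError(
            f"gene {gene_id!r}: best retained hit is {top.superkingdom}, "
            "not prokaryotic"
        )
    return DonorAssignment(
        gene_id=gene_id,
        donor_species=top.species,
        donor_genus=top.genus,
        donor_phylum=top.phylum,
        best_hit_id=top.subject_id,
    )


def phylum_spectrum(
    assignments_by_species: Mapping[str, Sequence[DonorAssignment]],
) -> dict[str, dict[str, float]]:
    """Per host species, the proportion of transferred genes attributed to
    each donor phylum (proportions sum to 1 per species)."""
    out: dict[str, dict[str, float]] = {}
    for species, assignments in assignments_by_species.items():
        if not assignments:
            raise ValueError(f"species {species!r} has no donor assignments")
        counts: dict[str, int] = {}
        for a in assignments:
            counts[a.donor_phylum] = counts.get(a.donor_phylum, 0) + 1
        total = len(assignments)
        out[species] = {ph: c / total for ph, c in sorted(counts.items())}
    return out


def _norm_genus(genus: str) -> str:
    g = genus.strip()
    if g.lower().startswith("candidatus "):
        g = g[len("candidatus ") :]
    return g.casefold()


def flag_endosymbiont_derived(
    assignment: DonorAssignment, endosymbiont_genera: Iterable[str]
) -> bool:
    """True when the donor genus matches a known endosymbiont genus
    (case-folded exact match after stripping any "Candidatus " prefix)."""
    genera = {_norm_genus(g) for g in endosymbiont_genera}
    genera.discard("")
    if not genera:
        raise ValueError("endosymbiont genus list is empty")
    return _norm_genus(assignment.donor_genus) in genera


def read_endosymbiont_genera(path: str | Path) -> list[str]:
    """One genus per line; '#' comments and blank lines allowed."""
    genera = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genera.append(line)
    if not genera:
        raise FormatError(f"{path}: no genera found")
    return genera


# ---------------------------------------------------------------------------
# cross-species families
# ---------------------------------------------------------------------------


def cluster_families(
    per_species_genes: Mapping[str, Iterable[str]],
    pairwise_scores: Mapping[tuple[str, str, str, str], float],
    link_threshold: float = 0.5,
) -> list[GeneFamily]:
    """Single-linkage families over bidirectional-best-hit edges.

    ``pairwise_scores`` maps (species_a, gene_a, species_b, gene_b) ->
    bitscore.  When a gene's self-score (same species, same gene) is
    present, scores out of that gene are normalized by it before the
    threshold is applied; otherwise raw scores are compared to
    ``link_threshold``.  For each gene and each *other* species, the best
    scoring partner is found (ties broken by gene id); an edge exists when
    the relation is mutual and both directed scores pass the threshold.
    Families are the connected components; every gene belongs to exactly
    one family, singletons included.  family_id is derived from the
    lexicographically smallest member.
    """
    genes: list[tuple[str, str]] = []
    for sp in sorted(per_species_genes):
        for g in sorted(set(per_species_genes[sp])):
            genes.append((sp, g))
    gene_set = set(genes)

    self_score: dict[tuple[str, str], float] = {}
    for (sa, ga, sb, gb), score in pairwise_scores.items():
        if sa == sb and ga == gb:
            self_score[(sa, ga)] = score

    def norm(sa: str, ga: str, score: float) -> float:
        s = self_score.get((sa, ga))
        return score / s if s else score

    # best partner of each gene in each other species
    best: dict[tuple[str, str, str], tuple[float, str]] = {}
    for (sa, ga, sb, gb), score in pairwise_scores.items():
        if sa == sb or (sa, ga) not in gene_set or (sb, gb) not in gene_set:
            continue
        key = (sa, ga, sb)
        cand = (norm(sa, ga, score), gb)
        prev = best.get(key)
        # higher score wins; on ties the lexicographically smaller gene id
        if prev is None or cand[0] > prev[0] or (cand[0] == prev[0] and cand[1] < prev[1]):
            best[key] = cand

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for (sa, ga, sb), (score_ab, gb) in best.items():
        back = best.get((sb, gb, sa))
        if back is None:
            continue
        score_ba, ga_back = back
        if ga_back != ga:
            continue
        if score_ab >= link_threshold and score_ba >= link_threshold:
            graph.add_edge((sa, ga), (sb, gb))

    families = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        anchor = min(members)
        families.append(
            GeneFamily(family_id=f"fam:{anchor[0]}:{anchor[1]}", members=members)
        )
    families.sort(key=lambda f: f.family_id)
    return families


def shared_family_counts(
    families: Sequence[GeneFamily], species_list: Sequence[str]
) -> tuple[dict[frozenset[str], int], int]:
    """Venn-style counts: each family lands in exactly one cell keyed by the
    set of species it spans; the core count is the cell covering every
    species in ``species_list``."""
    if not families:
        raise ValueError("no families given")
    cells: dict[frozenset[str], int] = {}
    for fam in families:
        key = fam.species_present
        cells[key] = cells.get(key, 0) + 1
    core = cells.get(frozenset(species_list), 0)
    return cells, core
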