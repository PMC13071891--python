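"""Synthetic macronuclear datasets with known truth labels.

The generator emulates the statistical structure the detection pipeline
assumes, at the layer the pipeline actually consumes (contigs, gene models,
taxonomy-annotated hit tables, gene trees, expression counts) — no
sequence-level homology search is simulated:

* native and transferred genes sit on telomere-capped nanochromosomes
  (C4A4...G4T4 at both ends) and may contain short (26 bp) spliceosomal
  introns, with the intron probability shared between the two classes;
* transferred (HGT) genes carry prokaryote-dominated hit profiles with a
  prokaryotic best hit, and are validated either by a prokaryote-only
  homolog count (> 5, no eukaryotes) or by a gene tree nesting the query
  inside prokaryotes with a eukaryotic outgroup;
* contaminant contigs are bacterial: prokaryotic hit profiles but no
  telomeres and no introns;
* expression counts are negative-binomial with the HGT class mean scaled
  down by a configurable multiplier;
* a cross-species family layer plants a configurable number of core
  families shared by all host species.

Every dataset self-validates at generation time: each planted class must
satisfy its own defining rules, so truth labels are correct by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import screen as _screen
from . import phylo as _phylo
from .seqio import (
    GeneModel,
    GeneTree,
    Hit,
    Nanochromosome,
    parse_newick,
    write_fasta,
    write_gff_genes,
    write_hit_table,
)

__all__ = ["SimConfig", "TruthLabels", "SimulatedDataset", "simulate_dataset",
           "simulate_expression"]

HOST_SPECIES = ("E_woodruffi", "E_aediculatus", "E_amieti", "E_octocarinatus",
                "E_vannus")

# small free-living donor taxonomy pool: phylum -> (genus, species) choices.
# Endosymbiont genera are kept out of this pool so the number of
# endosymbiont-derived genes equals the configured value exactly.
_DONOR_POOL: dict[str, tuple[tuple[str, str], ...]] = {
    "Pseudomonadota": (
        ("Escherichia", "Escherichia coli"),
        ("Pseudomonas", "Pseudomonas fluorescens"),
        ("Burkholderia", "Burkholderia cepacia"),
    ),
    "Bacteroidota": (
        ("Flavobacterium", "Flavobacterium johnsoniae"),
        ("Chryseobacterium", "Chryseobacterium gleum"),
    ),
    "Bacillota": (
        ("Bacillus", "Bacillus subtilis"),
        ("Clostridium", "Clostridium butyricum"),
    ),
    "Cyanobacteriota": (("Synechococcus", "Synechococcus elongatus"),),
}
_DONOR_PHYLA = tuple(_DONOR_POOL)
_DONOR_PHYLUM_WEIGHTS = (0.45, 0.25, 0.2, 0.1)

_EUK_POOL: tuple[tuple[str, str, str], ...] = (
    ("Ciliophora", "Paramecium", "Paramecium tetraurelia"),
    ("Ciliophora", "Tetrahymena", "Tetrahymena thermophila"),
    ("Ciliophora", "Oxytricha", "Oxytricha trifallax"),
    ("Chordata", "Homo", "Homo sapiens"),
    ("Streptophyta", "Arabidopsis", "Arabidopsis thaliana"),
)

#: genera with confirmed endosymbiotic representatives in the host
ENDOSYMBIONT_GENERA = (
    "Polynucleobacter",
    "Candidatus Protistobacter",
    "Candidatus Bandiella",
    "Caedimonas",
    "Devosia",
    "Francisella",
    "Rickettsia",
    "Anaplasma",
    "Wolbachia",
    "Holospora",
    "Paraholospora",
    "Sonderia",
    "Candidatus Euplotechlamydia",
    "Candidatus Cyrtobacter",
    "Candidatus Anadelfobacter",
    "Candidatus Midichloria",
    "Candidatus Nebulobacter",
    "Candidatus Fokinia",
)

TELOMERE_LEFT = "CCCCAAAA"
TELOMERE_RIGHT = "GGGGTTTT"


@dataclass
class SimConfig:
    """Study conditions of a synthetic dataset (defaults = the tested regime)."""

    seed: int = 1
    n_native: int = 200
    n_hgt: int = 20
    n_contaminant: int = 10
    gc_native: float = 0.35
    gc_hgt: float = 0.35
    intron_prob: float = 0.5            # shared by native and HGT classes
    intron_length_bp: int = 26
    hits_per_gene: int = 20
    prok_fraction_hgt: float = 0.9      # must exceed 0.5
    prok_fraction_native: float = 0.1   # must stay below 0.5
    hgt_expression_multiplier: float = 0.3
    expression_mean: float = 200.0      # native-class mean count per kb
    expression_dispersion: float = 0.3  # NB: var = mu + disp * mu^2
    telomere_units: int = 3             # tandem repeat copies per capped end
    tree_validated_fraction: float = 0.5  # HGT genes routed via the tree test
    n_core_families: int = 7
    n_private_families_per_species: int = 3
    n_species: int = 5
    n_mic_scaffolds: int = 50
    n_endosymbiont_hgt: int = 3         # HGT genes given endosymbiont donors

    def __post_init__(self) -> None:
        if min(self.n_native, self.n_hgt, self.n_contaminant) < 0:
            raise ValueError("gene counts must be non-negative")
        if not 0.5 < self.prok_fraction_hgt <= 1.0:
            raise ValueError("prok_fraction_hgt must exceed 0.5")
        if not 0.0 <= self.prok_fraction_native < 0.5:
            raise ValueError("prok_fraction_native must stay below 0.5")
        if not 0.0 < self.hgt_expression_multiplier <= 1.0:
            raise ValueError("hgt_expression_multiplier must lie in (0, 1]")
        for name in ("gc_native", "gc_hgt", "intron_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hits_per_gene < 2:
            raise ValueError("hits_per_gene must be at least 2")
        if not 1 <= self.n_species <= len(HOST_SPECIES):
            raise ValueError(f"n_species must be in 1..{len(HOST_SPECIES)}")
        if self.n_endosymbiont_hgt > self.n_hgt:
            raise ValueError("n_endosymbiont_hgt cannot exceed n_hgt")


@dataclass
class TruthLabels:
    """Ground truth of a simulated dataset."""

    gene_class: dict[str, str]                       # NATIVE / HGT / CONTAMINANT
    donor: dict[str, tuple[str, str, str]]           # gene -> (phylum, genus, species)
    endosymbiont_derived: set[str]
    family_of: dict[tuple[str, str], str]            # (species, gene) -> family id
    core_family_ids: set[str]
    mic_map: dict[str, str]                          # HGT gene -> MIC scaffold

    def genes_of_class(self, cls: str) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == cls}

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for gene in sorted(self.gene_class):
            phylum, genus, species = self.donor.get(gene, ("", "", ""))
            rows.append(
                {
                    "gene_id": gene,
                    "true_class": self.gene_class[gene],
                    "donor_phylum": phylum,
                    "donor_genus": genus,
                    "donor_species": species,
                    "endosymbiont_derived": int(gene in self.endosymbiont_derived),
                    "mic_scaffold": self.mic_map.get(gene, ""),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedDataset:
    """File paths plus the in-memory objects the files were written from."""

    outdir: Path
    config: SimConfig
    truth: TruthLabels
    contigs: list[Nanochromosome]
    genes: list[GeneModel]
    hits: dict[str, list[Hit]]
    homolog_counts: dict[str, tuple[int, int]]
    trees: dict[str, GeneTree]
    expression: pd.DataFrame
    annotations: dict[str, list[str]]
    family_genes: dict[str, list[str]]               # species -> gene ids
    family_scores: dict[tuple[str, str, str, str], float]

    @property
    def paths(self) -> dict[str, Path]:
        d = self.outdir
        return {
            "fasta": d / "genome.fasta",
            "gff": d / "genes.gff3",
            "hits": d / "hits.tsv",
            "homolog_counts": d / "homolog_counts.tsv",
            "trees": d / "trees",
            "expression": d / "expression.tsv",
            "annotations": d / "annotations.tsv",
            "endosymbionts": d / "endosymbiont_genera.tsv",
            "family_genes": d / "family_genes.tsv",
            "family_scores": d / "family_scores.tsv",
            "mic_map": d / "mic_map.tsv",
            "truth": d / "truth_labels.tsv",
            "config": d / "sim_config.json",
        }


# ---------------------------------------------------------------------------
# low-level generators
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _nb_draw(rng: np.random.Generator, mean: float, disp: float) -> int:
    """Negative binomial with var = mean + disp * mean^2; disp 0 -> mean."""
    if disp <= 0:
        return int(round(mean))
    size = 1.0 / disp
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _make_nanochromosome(
    rng: np.random.Generator,
    contig_id: str,
    gene_id: str,
    gc: float,
    intron_prob: float,
    intron_len: int,
    telomere_units: int,
    cds_len: int,
) -> tuple[Nanochromosome, GeneModel]:
    """One telomere-capped contig carrying one gene (possibly with introns)."""
    n_introns = int(rng.random() < intron_prob)
    # split the CDS into n_introns+1 exons at codon-multiple offsets
    if n_introns:
        cut = 3 * int(rng.integers(1, cds_len // 3))
        exon_spans = [cut, cds_len - cut]
    else:
        exon_spans = [cds_len]
    left = TELOMERE_LEFT * telomere_units
    right = TELOMERE_RIGHT * telomere_units
    spacer5 = _random_dna(rng, int(rng.integers(20, 40)), gc)
    spacer3 = _random_dna(rng, int(rng.integers(20, 40)), gc)
    seq_parts = [left, spacer5]
    pos = len(left) + len(spacer5) + 1  # 1-based start of first exon
    exons: list[tuple[int, int]] = []
    for i, span in enumerate(exon_spans):
        seq_parts.append(_random_dna(rng, span, gc))
        exons.append((pos, pos + span - 1))
        pos += span
        if i < len(exon_spans) - 1:
            seq_parts.append(_random_dna(rng, intron_len, gc))
            pos += intron_len
    seq_parts += [spacer3, right]
    contig = Nanochromosome(contig_id=contig_id, sequence="".join(seq_parts))
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel(gene_id=gene_id, contig_id=contig_id, strand=strand, exons=exons)
    return contig, gene


def _euk_hit(rng, gene_id, subj, evalue, bits) -> Hit:
    phylum, genus, species = _EUK_POOL[int(rng.integers(len(_EUK_POOL)))]
    return Hit(gene_id, subj, float(np.round(30 + 40 * rng.random(), 1)), evalue,
               bits, "Eukaryota", phylum, genus, species)


def _prok_hit(rng, gene_id, subj, evalue, bits, taxonomy=None) -> Hit:
    if taxonomy is None:
        phylum = str(rng.choice(_DONOR_PHYLA, p=_DONOR_PHYLUM_WEIGHTS))
        genus, species = _DONOR_POOL[phylum][int(rng.integers(len(_DONOR_POOL[phylum])))]
    else:
        phylum, genus, species = taxonomy
    return Hit(gene_id, subj, float(np.round(35 + 40 * rng.random(), 1)), evalue,
               bits, "Bacteria", phylum, genus, species)


def _self_hit(rng, gene_id, subj, evalue, bits) -> Hit:
    return Hit(gene_id, subj, float(np.round(95 + 5 * rng.random(), 1)), evalue,
               bits, "Eukaryota", "Ciliophora", "Euplotes", "Euplotes vannus")


def _evalue_ladder(rng: np.random.Generator, n: int) -> list[float]:
    """n distinct E-values below the cutoff, best (smallest) first."""
    exps = np.sort(rng.uniform(6.0, 60.0, size=n))[::-1]
    return [float(10.0 ** -e) for e in exps]


def _hgt_hits(rng, cfg: SimConfig, gene_id: str,
              donor: tuple[str, str, str]) -> list[Hit]:
    """Prokaryote-dominated profile; best hit = the donor; plus a self-hit
    (excluded downstream) that would otherwise outrank the donor."""
    n = cfg.hits_per_gene
    n_prok = max(int(np.ceil(cfg.prok_fraction_hgt * n)), 1)
    evs = _evalue_ladder(rng, n)
    hits = [_prok_hit(rng, gene_id, f"{gene_id}_s0", evs[0], 400.0, donor)]
    for i in range(1, n):
        subj, ev, bits = f"{gene_id}_s{i}", evs[i], float(400 - 5 * i)
        if i < n_prok:
            hits.append(_prok_hit(rng, gene_id, subj, ev, bits))
        else:
            hits.append(_euk_hit(rng, gene_id, subj, ev, bits))
    hits.append(_self_hit(rng, gene_id, f"{gene_id}_self", evs[0] / 10, 500.0))
    return hits


def _native_hits(rng, cfg: SimConfig, gene_id: str) -> list[Hit]:
    """Eukaryote-dominated profile with a eukaryotic best hit."""
    n = cfg.hits_per_gene
    n_prok = int(np.floor(cfg.prok_fraction_native * n))
    evs = _evalue_ladder(rng, n)
    hits = [_euk_hit(rng, gene_id, f"{gene_id}_s0", evs[0], 450.0)]
    for i in range(1, n):
        subj, ev, bits = f"{gene_id}_s{i}", evs[i], float(450 - 5 * i)
        if i <= n_prok:
            hits.append(_prok_hit(rng, gene_id, subj, ev, bits))
        else:
            hits.append(_euk_hit(rng, gene_id, subj, ev, bits))
    hits.append(_self_hit(rng, gene_id, f"{gene_id}_self", evs[0] / 10, 520.0))
    return hits


def _contaminant_hits(rng, cfg: SimConfig, gene_id: str) -> list[Hit]:
    evs = _evalue_ladder(rng, cfg.hits_per_gene)
    return [
        _prok_hit(rng, gene_id, f"{gene_id}_s{i}", evs[i], float(380 - 4 * i))
        for i in range(cfg.hits_per_gene)
    ]


def _supporting_tree(rng: np.random.Generator, gene_id: str) -> GeneTree:
    """Random tree nesting the query inside a prokaryote clade, with a
    eukaryote outgroup clade on the other side."""
    n_prok = int(rng.integers(3, 7))
    n_euk = int(rng.integers(2, 5))
    prok_tips = [f"PROK_{gene_id}_p{i}" for i in range(n_prok)]
    euk_tips = [f"EUK_{gene_id}_e{i}" for i in range(n_euk)]
    ingroup = _random_binary(rng, [f"QUERY_{gene_id}"] + prok_tips)
    outgroup = _random_binary(rng, euk_tips)
    return parse_newick(f"({ingroup},{outgroup});")


def _random_binary(rng: np.random.Generator, tips: list[str]) -> str:
    nodes = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: SimConfig,
    gene_class: Mapping[str, str],
    lengths_bp: Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial counts per gene; the HGT-class mean is the native
    mean scaled by ``hgt_expression_multiplier``.  Columns: gene_id, count,
    effective_length."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rows = []
    for gene in sorted(gene_class):
        length = lengths_bp[gene]
        mu = cfg.expression_mean * length / 1000.0
        if gene_class[gene] == "HGT":
            mu *= cfg.hgt_expression_multiplier
        elif gene_class[gene] == "CONTAMINANT":
            mu *= 0.05  # carried-over bacterial RNA, barely expressed
        rows.append(
            {
                "gene_id": gene,
                "count": _nb_draw(rng, mu, cfg.expression_dispersion),
                "effective_length": length,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-dataset generation
# ---------------------------------------------------------------------------


def simulate_dataset(cfg: SimConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Generate a complete dataset (optionally writing it under ``outdir``)
    and its truth labels.  Fixed seed => byte-identical files.

    Each planted class is checked against its own defining rules before the
    dataset is returned; a violation is a bug, not a data point.
    """
    rng = np.random.default_rng(cfg.seed)
    scfg = _screen.ScreenConfig()

    contigs: list[Nanochromosome] = []
    genes: list[GeneModel] = []
    hits: dict[str, list[Hit]] = {}
    homolog_counts: dict[str, tuple[int, int]] = {}
    trees: dict[str, GeneTree] = {}
    gene_class: dict[str, str] = {}
    donor_truth: dict[str, tuple[str, str, str]] = {}
    endo_truth: set[str] = set()
    annotations: dict[str, list[str]] = {}
    term_pool = [f"TERM_{i:03d}" for i in range(20)]
    enriched_term = "GH_mannanase"

    def draw_cds_len() -> int:
        return 3 * int(rng.integers(150, 500))  # 450..1497 bp, codon multiple

    # --- native genes ---------------------------------------------------
    for i in range(cfg.n_native):
        gid, cid = f"gene_nat_{i:04d}", f"ctg_nat_{i:04d}"
        contig, gene = _make_nanochromosome(
            rng, cid, gid, cfg.gc_native, cfg.intron_prob, cfg.intron_length_bp,
            cfg.telomere_units, draw_cds_len(),
        )
        contigs.append(contig)
        genes.append(gene)
        hits[gid] = _native_hits(rng, cfg, gid)
        homolog_counts[gid] = (int(rng.integers(0, 4)), int(rng.integers(20, 60)))
        gene_class[gid] = "NATIVE"
        annotations[gid] = list(rng.choice(term_pool, size=2, replace=False))
        if rng.random() < 0.02:
            annotations[gid].append(enriched_term)

    # --- transferred (HGT) genes ----------------------------------------
    endo_pool = [("Pseudomonadota", "Polynucleobacter", "Polynucleobacter necessarius"),
                 ("Pseudomonadota", "Caedimonas", "Caedimonas varicaedens")]
    n_tree = int(round(cfg.tree_validated_fraction * cfg.n_hgt))
    for i in range(cfg.n_hgt):
        gid, cid = f"gene_hgt_{i:04d}", f"ctg_hgt_{i:04d}"
        contig, gene = _make_nanochromosome(
            rng, cid, gid, cfg.gc_hgt, cfg.intron_prob, cfg.intron_length_bp,
            cfg.telomere_units, draw_cds_len(),
        )
        contigs.append(contig)
        genes.append(gene)
        if i < cfg.n_endosymbiont_hgt:
            donor = endo_pool[i % len(endo_pool)]
        else:
            phylum = str(rng.choice(_DONOR_PHYLA, p=_DONOR_PHYLUM_WEIGHTS))
            genus, species = _DONOR_POOL[phylum][
                int(rng.integers(len(_DONOR_POOL[phylum])))
            ]
            donor = (phylum, genus, species)
        donor_truth[gid] = donor
        hits[gid] = _hgt_hits(rng, cfg, gid, donor)
        gene_class[gid] = "HGT"
        if i < n_tree:
            homolog_counts[gid] = (int(rng.integers(6, 25)), int(rng.integers(2, 8)))
            trees[gid] = _supporting_tree(rng, gid)
        else:
            homolog_counts[gid] = (int(rng.integers(6, 25)), 0)
        annotations[gid] = list(rng.choice(term_pool, size=1))
        if rng.random() < 0.8:
            annotations[gid].append(enriched_term)

    # --- contaminant contigs --------------------------------------------
    for i in range(cfg.n_contaminant):
        gid, cid = f"gene_ctm_{i:04d}", f"ctg_ctm_{i:04d}"
        cds_len = draw_cds_len()
        while True:
            seq = _random_dna(rng, cds_len + 120, 0.5)
            contig = Nanochromosome(contig_id=cid, sequence=seq)
            _screen.detect_telomeres(contig, scfg)
            if not _screen.has_telomere(contig, scfg):
                break
        start = 61
        gene = GeneModel(gene_id=gid, contig_id=cid, strand="+",
                         exons=[(start, start + cds_len - 1)])
        contigs.append(contig)
        genes.append(gene)
        hits[gid] = _contaminant_hits(rng, cfg, gid)
        homolog_counts[gid] = (int(rng.integers(20, 60)), 0)
        gene_class[gid] = "CONTAMINANT"
        annotations[gid] = list(rng.choice(term_pool, size=1))

    # truth flag derived from realized donors: free-living donor draws can
    # also land on an endosymbiont genus, and those genes are flagged too
    endo_set = {g.lower().removeprefix("candidatus ") for g in ENDOSYMBIONT_GENERA}
    endo_truth = {
        gid
        for gid, (_, genus, _) in donor_truth.items()
        if genus.lower().removeprefix("candidatus ") in endo_set
    }

    # --- expression ------------------------------------------------------
    lengths = {g.gene_id: g.cds_length_bp for g in genes}
    expression = simulate_expression(cfg, gene_class, lengths, rng)

    # --- MIC dispersion map ----------------------------------------------
    mic_map = {
        gid: f"mic_scaf_{int(rng.integers(cfg.n_mic_scaffolds)):03d}"
        for gid in sorted(g for g, c in gene_class.items() if c == "HGT")
    }

    # --- cross-species family layer --------------------------------------
    species = list(HOST_SPECIES[: cfg.n_species])
    family_of: dict[tuple[str, str], str] = {}
    core_ids: set[str] = set()
    family_genes: dict[str, list[str]] = {sp: [] for sp in species}
    scores: dict[tuple[str, str, str, str], float] = {}
    fam_members: dict[str, list[tuple[str, str]]] = {}

    for f in range(cfg.n_core_families):
        fam = f"core_fam_{f:02d}"
        core_ids.add(fam)
        fam_members[fam] = []
        for sp in species:
            g = f"{sp}_hgt_{f:02d}"
            family_genes[sp].append(g)
            family_of[(sp, g)] = fam
            fam_members[fam].append((sp, g))
    for sp in species:
        for f in range(cfg.n_private_families_per_species):
            g = f"{sp}_priv_{f:02d}"
            fam = f"priv_{sp}_{f:02d}"
            family_genes[sp].append(g)
            family_of[(sp, g)] = fam
            fam_members[fam] = [(sp, g)]

    all_family_genes = [(sp, g) for sp in species for g in family_genes[sp]]
    for sp, g in all_family_genes:
        scores[(sp, g, sp, g)] = 500.0  # self-score
    for fam, members in fam_members.items():
        for sa, ga in members:
            for sb, gb in members:
                if (sa, ga) != (sb, gb):
                    scores[(sa, ga, sb, gb)] = 300.0
    # weak cross-family background hits (below the default 0.5 ratio)
    for (sa, ga) in all_family_genes:
        for (sb, gb) in all_family_genes:
            if sa != sb and (sa, ga, sb, gb) not in scores and rng.random() < 0.05:
                scores[(sa, ga, sb, gb)] = float(np.round(50 + 50 * rng.random(), 1))

    truth = TruthLabels(
        gene_class=gene_class,
        donor=donor_truth,
        endosymbiont_derived=endo_truth,
        family_of=family_of,
        core_family_ids=core_ids,
        mic_map=mic_map,
    )

    _self_validate(cfg, scfg, contigs, genes, hits, homolog_counts, trees, truth)

    dataset = SimulatedDataset(
        outdir=Path(outdir) if outdir is not None else Path("."),
        config=cfg,
        truth=truth,
        contigs=contigs,
        genes=genes,
        hits=hits,
        homolog_counts=homolog_counts,
        trees=trees,
        expression=expression,
        annotations=annotations,
        family_genes=family_genes,
        family_scores=scores,
    )
    if outdir is not None:
        _write_dataset(dataset)
    return dataset


def _self_validate(cfg, scfg, contigs, genes, hits, homolog_counts, trees, truth):
    """Planted classes must satisfy their own definitions."""
    by_contig = {c.contig_id: c for c in contigs}
    for gene in genes:
        cls = truth.gene_class[gene.gene_id]
        contig = by_contig[gene.contig_id]
        _screen.detect_telomeres(contig, scfg)
        telo = _screen.has_telomere(contig, scfg)
        profile = _screen.evaluate_hit_profile(hits[gene.gene_id], scfg)
        profile_pass = _screen.hit_profile_pass(profile, scfg)
        contam_pass = _screen.contamination_filter(telo, gene.intron_count)
        if cls == "HGT":
            assert profile_pass and telo and contam_pass, gene.gene_id
            prok, euk = homolog_counts[gene.gene_id]
            if euk:
                verdict = _phylo.tree_placement_test(trees[gene.gene_id]).verdict
                assert verdict == "HGT_TREE_SUPPORTED", gene.gene_id
            else:
                assert prok > 5, gene.gene_id
        elif cls == "NATIVE":
            assert not profile_pass, gene.gene_id
            assert telo and contam_pass, gene.gene_id
        else:  # CONTAMINANT
            assert profile_pass, gene.gene_id
            assert not telo and gene.intron_count == 0 and not contam_pass, gene.gene_id


def _write_dataset(ds: SimulatedDataset) -> None:
    paths = ds.paths
    ds.outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.contigs, paths["fasta"])
    write_gff_genes(ds.genes, paths["gff"])
    write_hit_table(ds.hits, paths["hits"])
    with open(paths["homolog_counts"], "w") as fh:
        fh.write("gene_id\tprok_homologs\teuk_homologs\n")
        for gid in sorted(ds.homolog_counts):
            p, e = ds.homolog_counts[gid]
            fh.write(f"{gid}\t{p}\t{e}\n")
    tree_dir = paths["trees"]
    tree_dir.mkdir(exist_ok=True)
    tip_rows = []
    for gid in sorted(ds.trees):
        gt = ds.trees[gid]
        gt.tree.write(path=str(tree_dir / f"{gid}.nwk"), schema="newick",
                      unquoted_underscores=True, suppress_rooting=True)
        assert gt.tip_class is not None
        for tip in sorted(gt.tip_class):
            tip_rows.append(f"{tip}\t{gt.tip_class[tip]}")
    (tree_dir / "tip_classes.tsv").write_text("\n".join(tip_rows) + "\n")
    ds.expression.to_csv(paths["expression"], sep="\t", index=False)
    with open(paths["annotations"], "w") as fh:
        fh.write("gene_id\tterm\n")
        for gid in sorted(ds.annotations):
            for term in ds.annotations[gid]:
                fh.write(f"{gid}\t{term}\n")
    paths["endosymbionts"].write_text(
        "# known host endosymbiont genera\n" + "\n".join(ENDOSYMBIONT_GENERA) + "\n"
    )
    with open(paths["family_genes"], "w") as fh:
        fh.write("species\tgene_id\n")
        for sp in sorted(ds.family_genes):
            for g in ds.family_genes[sp]:
                fh.write(f"{sp}\t{g}\n")
    with open(paths["family_scores"], "w") as fh:
        fh.write("species_a\tgene_a\tspecies_b\tgene_b\tbitscore\n")
        for (sa, ga, sb, gb) in sorted(ds.family_scores):
            fh.write(f"{sa}\t{ga}\t{sb}\t{gb}\t{ds.family_scores[(sa, ga, sb, gb)]:g}\n")
    with open(paths["mic_map"], "w") as fh:
        fh.write("gene_id\tmic_scaffold\n")
        for gid in sorted(ds.truth.mic_map):
            fh.write(f"{gid}\t{ds.truth.mic_map[gid]}\n")
    ds.truth.to_tsv(paths["truth"])
    paths["config"].write_text(json.dumps(asdict(ds.config), indent=2) + "\n")
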