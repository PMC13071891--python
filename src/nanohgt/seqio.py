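"""Domain types and file IO shared by every pipeline stage.

The pipeline consumes the *outputs* of standard homology/phylogenetics tools,
not raw reads: macronuclear contigs (FASTA), gene models (a GFF3 subset),
taxonomy-annotated homology hit tables (tabular-BLAST-like TSV), per-gene
trees (Newick) with tip-class maps, and writes a per-gene call report (TSV).

Coordinate convention: GFF3 throughout — 1-based, closed intervals.  The
intron between consecutive exons i and i+1 spans
``[exon_i.end + 1, exon_{i+1}.start - 1]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Nanochromosome",
    "GeneModel",
    "Hit",
    "HGTCall",
    "GeneTree",
    "PROKARYOTE_SUPERKINGDOMS",
    "SUPERKINGDOMS",
    "TIP_CLASSES",
    "HIT_TABLE_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_gff_genes",
    "read_hit_table",
    "read_tip_classes",
    "read_newick",
    "write_newick",
    "write_report",
    "read_report",
]

PROKARYOTE_SUPERKINGDOMS = frozenset({"Bacteria", "Archaea"})
SUPERKINGDOMS = frozenset({"Bacteria", "Archaea", "Eukaryota"})
TIP_CLASSES = frozenset({"QUERY", "PROKARYOTE", "EUKARYOTE"})

# tip-name prefixes understood when no companion class map is given
_TIP_PREFIXES = {"QUERY_": "QUERY", "PROK_": "PROKARYOTE", "EUK_": "EUKARYOTE"}

_DNA_ALPHABET = frozenset("ACGTN")

HIT_TABLE_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "evalue",
    "bitscore",
    "superkingdom",
    "phylum",
    "genus",
    "species",
]


class FormatError(ValueError):
    """Malformed or contract-violating input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Nanochromosome:
    """A macronuclear contig: ideally one gene capped by telomeric repeats.

    ``left_telomere_units``/``right_telomere_units`` count tandem copies of
    the telomere unit at each end; they are 0 until
    :func:`nanohgt.screen.detect_telomeres` fills them in.
    """

    contig_id: str
    sequence: str
    left_telomere_units: int = 0
    right_telomere_units: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene on a contig with its ordered exon intervals (1-based, closed)."""

    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_length_bp: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: no exons")
        exons = sorted(tuple(e) for e in self.exons)
        for start, end in exons:
            if end < start or start < 1:
                raise ValueError(
                    f"gene {self.gene_id!r}: bad exon interval [{start}, {end}]"
                )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")
        self.exons = exons
        self.cds_length_bp = sum(e - s + 1 for s, e in exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    def intron_intervals(self) -> list[tuple[int, int]]:
        """Introns between consecutive exons, 1-based closed."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def intron_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.intron_intervals()]


@dataclass(frozen=True)
class Hit:
    """One homology hit with the subject's taxonomy carried on the row."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    superkingdom: str
    phylum: str
    genus: str
    species: str

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: unsupported superkingdom "
                f"{self.superkingdom!r} (expected one of {sorted(SUPERKINGDOMS)})"
            )
        for name in ("phylum", "genus", "species"):
            if not getattr(self, name):
                raise ValueError(
                    f"hit {self.query_id}->{self.subject_id}: empty {name}"
                )
        if not (self.evalue >= 0.0 and self.evalue == self.evalue):
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: bad evalue {self.evalue}"
            )

    @property
    def is_prokaryotic(self) -> bool:
        return self.superkingdom in PROKARYOTE_SUPERKINGDOMS


#: verdicts of the phylogenetic-validation stage
PHYLO_VERDICTS = ("HGT_NO_TREE", "HGT_TREE_SUPPORTED", "REJECTED", "UNSUPPORTED")


@dataclass
class HGTCall:
    """Per-gene evidence ledger accumulated across the pipeline stages."""

    gene_id: str
    passed_evalue: bool = False
    best_hit_prokaryotic: bool = False
    prokaryote_hit_fraction: float = 0.0
    screen_pass: bool = False  # evalue + best-hit + fraction rules jointly
    has_telomere: bool = False
    has_intron: bool = False
    contamination_pass: bool = False
    phylo_verdict: str | None = None
    final_status: str | None = None

    @property
    def is_candidate(self) -> bool:
        return self.screen_pass and self.contamination_pass

    def finalize(self) -> None:
        """Derive final_status from the evidence fields (invariant of the type)."""
        self.final_status = (
            "HGT"
            if self.is_candidate
            and self.phylo_verdict in {"HGT_NO_TREE", "HGT_TREE_SUPPORTED"}
            else "NOT_HGT"
        )


@dataclass
class GeneTree:
    """An (un)rooted gene tree plus a tip -> {QUERY, PROKARYOTE, EUKARYOTE} map.

    ``tip_class`` may be None for fixture trees that have not been classified
    yet; the placement test requires it.
    """

    tree: dendropy.Tree
    tip_class: dict[str, str] | None = None

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def validate_classes(self) -> None:
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")
        if self.tip_class is None:
            raise ValueError("tree has no tip-class map")
        for label in labels:
            cls = self.tip_class.get(label)
            if cls is None:
                raise ValueError(f"tip {label!r} has no class mapping")
            if cls not in TIP_CLASSES:
                raise ValueError(f"tip {label!r}: unknown class {cls!r}")

    def tips_of_class(self, cls: str) -> set[str]:
        assert self.tip_class is not None
        return {t for t in self.tip_labels() if self.tip_class[t] == cls}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[Nanochromosome]:
    """Read DNA contigs from FASTA.

    Sequences are uppercased; only A/C/G/T/N are accepted (this is a DNA
    pipeline — U and IUPAC ambiguity codes are rejected, naming the contig).
    Duplicate ids and empty sequences are errors.
    """
    records: list[Nanochromosome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: contig {rec.id!r} has an empty sequence")
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: contig {rec.id!r} contains non-DNA characters "
                f"{sorted(bad)}"
            )
        records.append(Nanochromosome(contig_id=rec.id, sequence=seq))
    return records


def write_fasta(contigs: Iterable[Nanochromosome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.contig_id}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon/CDS subset)
# ---------------------------------------------------------------------------


def _gff_attributes(col9: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff_genes(
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Read gene models from a GFF3 subset (gene/mRNA/exon/CDS rows).

    Exon rows are grouped by their (grand)parent gene and sorted by start.
    If ``contig_lengths`` is given, every exon must lie within its contig.
    Overlapping exons within a gene and inverted intervals are errors.
    """
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}  # mRNA id -> gene id
    exon_rows: list[tuple[int, str, str, str, int, int]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
            if ftype not in {"gene", "mRNA", "exon", "CDS"}:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} < start {start}"
                )
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene row lacks ID")
                genes[gid] = {"contig": seqid, "strand": strand, "exons": []}
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise FormatError(f"{path}:{lineno}: mRNA row lacks ID/Parent")
                parent_of[mid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon row lacks Parent")
                exon_rows.append((lineno, seqid, strand, parent, start, end))
            # CDS rows are accepted but exon rows define the model

    models: list[GeneModel] = []
    for lineno, seqid, strand, parent, start, end in exon_rows:
        gid = parent_of.get(parent, parent)
        if gid not in genes:
            # exon attached directly to an undeclared gene: create it
            genes[gid] = {"contig": seqid, "strand": strand, "exons": []}
        if contig_lengths is not None:
            length = contig_lengths.get(seqid)
            if length is None:
                raise FormatError(f"{path}:{lineno}: unknown contig {seqid!r}")
            if end > length:
                raise FormatError(
                    f"{path}:{lineno}: exon [{start}, {end}] outside contig "
                    f"{seqid!r} (length {length})"
                )
        genes[gid]["exons"].append((start, end))

    for gid, info in genes.items():
        if not info["exons"]:
            continue  # gene row without exon rows: skip silently
        try:
            models.append(
                GeneModel(
                    gene_id=gid,
                    contig_id=info["contig"],
                    strand=info["strand"],
                    exons=info["exons"],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    models.sort(key=lambda m: m.gene_id)
    return models


def write_gff_genes(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/exon/CDS rows (GFF3 subset)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gstart, gend = m.exons[0][0], m.exons[-1][1]
            fh.write(
                f"{m.contig_id}\tnanohgt\tgene\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            mid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.contig_id}\tnanohgt\tmRNA\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={mid};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.contig_id}\tnanohgt\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )
                fh.write(
                    f"{m.contig_id}\tnanohgt\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> dict[str, list[Hit]]:
    """Read a taxonomy-extended tabular homology table, grouped per query.

    Columns (tab-separated, ``#`` comments allowed, no header required unless
    it matches the column names): qseqid, sseqid, pident, evalue, bitscore,
    superkingdom, phylum, genus, species.  File order is preserved within
    each query.
    """
    path = Path(path)
    text = path.read_text()
    hits: dict[str, list[Hit]] = {}
    lineno = 0
    for line in io.StringIO(text):
        lineno += 1
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(
                f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        if cols[0] == "qseqid":  # optional header row
            continue
        try:
            pident = float(cols[2])
            evalue = float(cols[3])
            bitscore = float(cols[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed numeric field") from exc
        try:
            hit = Hit(
                query_id=cols[0],
                subject_id=cols[1],
                percent_identity=pident,
                evalue=evalue,
                bitscore=bitscore,
                superkingdom=cols[5],
                phylum=cols[6],
                genus=cols[7],
                species=cols[8],
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        hits.setdefault(hit.query_id, []).append(hit)
    return hits


def write_hit_table(hits: Mapping[str, list[Hit]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for gene in hits:
            for h in hits[gene]:
                fh.write(
                    "\t".join(
                        [
                            h.query_id,
                            h.subject_id,
                            f"{h.percent_identity:g}",
                            f"{h.evalue:g}",
                            f"{h.bitscore:g}",
                            h.superkingdom,
                            h.phylum,
                            h.genus,
                            h.species,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Newick trees and tip classes
# ---------------------------------------------------------------------------


def read_tip_classes(path: str | Path) -> dict[str, str]:
    """Read a tip_id<TAB>class TSV (classes QUERY/PROKARYOTE/EUKARYOTE)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected tip_id<TAB>class")
            tip, cls = parts
            if cls not in TIP_CLASSES:
                raise FormatError(f"{path}:{lineno}: unknown class {cls!r}")
            out[tip] = cls
    return out


def classify_tip(label: str) -> str | None:
    """Resolve a tip class from QUERY_/PROK_/EUK_ name prefixes."""
    for prefix, cls in _TIP_PREFIXES.items():
        if label.startswith(prefix):
            return cls
    return None


def read_newick(
    path: str | Path,
    tip_classes: Mapping[str, str] | None = None,
) -> GeneTree:
    """Read one Newick tree; tip classes come from ``tip_classes`` or from
    QUERY_/PROK_/EUK_ tip-name prefixes.  Unclassifiable tips are errors."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return _classify_tree(tree, tip_classes)


def parse_newick(newick: str, tip_classes: Mapping[str, str] | None = None) -> GeneTree:
    """Like :func:`read_newick` but from a Newick string."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _classify_tree(tree, tip_classes)


def _classify_tree(tree: dendropy.Tree, tip_classes: Mapping[str, str] | None) -> GeneTree:
    classes: dict[str, str] = {}
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError("tree contains an unlabeled tip")
        label = leaf.taxon.label
        labels.append(label)
        if tip_classes is not None and label in tip_classes:
            classes[label] = tip_classes[label]
        else:
            cls = classify_tip(label)
            if cls is None:
                raise FormatError(
                    f"tip {label!r} has no class mapping and no QUERY_/PROK_/EUK_ prefix"
                )
            classes[label] = cls
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in tree")
    return GeneTree(tree=tree, tip_class=classes)


def write_newick(gene_tree: GeneTree, path: str | Path) -> None:
    gene_tree.tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


# ---------------------------------------------------------------------------
# call report
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "gene_id",
    "passed_evalue",
    "best_hit_prokaryotic",
    "prokaryote_hit_fraction",
    "screen_pass",
    "has_telomere",
    "has_intron",
    "contamination_pass",
    "phylo_verdict",
    "final_status",
]


def write_report(calls: Iterable[HGTCall], path: str | Path) -> None:
    """Write one HGTCall per row as TSV."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "passed_evalue": int(c.passed_evalue),
                "best_hit_prokaryotic": int(c.best_hit_prokaryotic),
                "prokaryote_hit_fraction": f"{c.prokaryote_hit_fraction:.6g}",
                "screen_pass": int(c.screen_pass),
                "has_telomere": int(c.has_telomere),
                "has_intron": int(c.has_intron),
                "contamination_pass": int(c.contamination_pass),
                "phylo_verdict": c.phylo_verdict or "",
                "final_status": c.final_status or "",
            }
        )
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> list[HGTCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    calls = []
    for _, r in df.iterrows():
        c = HGTCall(
            gene_id=r["gene_id"],
            passed_evalue=bool(int(r["passed_evalue"])),
            best_hit_prokaryotic=bool(int(r["best_hit_prokaryotic"])),
            prokaryote_hit_fraction=float(r["prokaryote_hit_fraction"]),
            screen_pass=bool(int(r["screen_pass"])),
            has_telomere=bool(int(r["has_telomere"])),
            has_intron=bool(int(r["has_intron"])),
            contamination_pass=bool(int(r["contamination_pass"])),
            phylo_verdict=r["phylo_verdict"] or None,
            final_status=r["final_status"] or None,
        )
        calls.append(c)
    return calls
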