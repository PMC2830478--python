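"""Sequence and tree I/O: FASTA and GenBank reading, CDS translation,
protein-guided codon alignments, region annotation, and Newick trees.

Codon coordinates are 1-based inclusive everywhere a user supplies them
(region ranges, reported site positions); internal arrays are 0-based.
The genetic code is the standard (universal) nuclear code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

from .codon_engine import CODON_INDEX, GAP_CODON, PhyloTree, STOP_CODONS

REGION_LABELS = ("signal", "mature", "pro", "unassigned")


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence: label, uppercase DNA, optional accession."""

    taxon_label: str
    nucleotides: str
    source_accession: str = ""

    def __post_init__(self):
        if len(self.nucleotides) < 3:
            raise ValueError(
                f"{self.taxon_label}: coding sequence shorter than one codon"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    def codons(self) -> list[str]:
        n = self.nucleotides
        if len(n) % 3:
            raise ValueError(f"{self.taxon_label}: length not divisible by 3")
        return [n[i:i + 3] for i in range(0, len(n), 3)]


@dataclass
class CodonAlignment:
    """Aligned codon matrix with an optional per-codon region annotation.

    ``columns[i]`` is the list of codons (3-mers, ``---`` for a gap codon)
    of taxon ``taxa[i]``; ``region_map[j]`` labels alignment codon j+1.
    """

    taxa: list[str]
    columns: list[list[str]]
    region_map: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.taxa) != len(self.columns):
            raise ValueError("one codon row required per taxon")
        lengths = {len(r) for r in self.columns}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal codon counts")
        for taxon, row in zip(self.taxa, self.columns):
            for j, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                if len(codon) != 3 or any(c == "-" for c in codon):
                    raise ValueError(
                        f"{taxon}: codon {j + 1} ({codon!r}) mixes gap and "
                        "nucleotide characters"
                    )
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"{taxon}: stop codon {codon} at alignment position {j + 1}"
                    )
                if codon not in CODON_INDEX:
                    raise ValueError(
                        f"{taxon}: ambiguous codon {codon!r} at position {j + 1}; "
                        "analyzed columns must be unambiguous sense codons"
                    )
        if not self.region_map:
            self.region_map = ["unassigned"] * self.n_codons
        elif len(self.region_map) != self.n_codons:
            raise ValueError("region_map length must equal codon count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.columns[0]) if self.columns else 0

    def row(self, taxon: str) -> list[str]:
        return self.columns[self.taxa.index(taxon)]

    def region_sites(self, label: str) -> list[int]:
        """0-based codon indices carrying a region label."""
        return [i for i, r in enumerate(self.region_map) if r == label]

    def subset_sites(self, sites: list[int]) -> "CodonAlignment":
        cols = [[row[i] for i in sites] for row in self.columns]
        return CodonAlignment(
            list(self.taxa), cols, [self.region_map[i] for i in sites]
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.columns):
                fh.write(f">{taxon}\n{''.join(row)}\n")

    @classmethod
    def from_sequences(cls, seqs: list[CodingSequence]) -> "CodonAlignment":
        """Treat equal-length gapless sequences as already aligned."""
        rows = [s.codons() for s in seqs]
        return cls([s.taxon_label for s in seqs], rows)


# ---------------------------------------------------------------------------
# FASTA / GenBank
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[CodingSequence]:
    """Read FASTA records as coding sequences (uppercased, U mapped to T)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence label {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(
            CodingSequence(rec.id, str(rec.seq).upper().replace("U", "T"))
        )
    return out


def write_fasta(seqs: list[CodingSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.taxon_label}\n{s.nucleotides}\n")


def read_fasta_alignment(path) -> CodonAlignment:
    """Read an aligned codon FASTA into a CodonAlignment."""
    records = read_fasta(path)
    rows = []
    for rec in records:
        n = rec.nucleotides
        if len(n) % 3:
            raise ValueError(f"{rec.taxon_label}: aligned length not divisible by 3")
        rows.append([n[i:i + 3] for i in range(0, len(n), 3)])
    return CodonAlignment([r.taxon_label for r in records], rows)


def read_genbank_cds(path) -> list[CodingSequence]:
    """Extract the CDS feature of each record in a GenBank flat file."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    out = []
    for rec in records:
        cds = [f for f in rec.features if f.type == "CDS"]
        if not cds:
            raise ValueError(f"{rec.id}: no CDS feature")
        seq = str(cds[0].extract(rec.seq)).upper().replace("U", "T")
        organism = rec.annotations.get("organism", rec.id)
        out.append(CodingSequence(organism.replace(" ", "_"), seq, rec.id))
    return out


# ---------------------------------------------------------------------------
# Translation and back-translation
# ---------------------------------------------------------------------------

def translate_cds(seq: CodingSequence, code: int = 1) -> str:
    """Translate a CDS with the standard code; a trailing stop is stripped,
    an internal stop is an error."""
    if len(seq) % 3:
        raise ValueError(f"{seq.taxon_label}: CDS length not divisible by 3")
    pep = str(Seq(seq.nucleotides).translate(table=code))
    if pep.endswith("*"):
        pep = pep[:-1]
    if "*" in pep:
        raise ValueError(
            f"{seq.taxon_label}: internal stop codon at residue {pep.index('*') + 1}"
        )
    return pep


def build_codon_alignment(cds: list[CodingSequence],
                          protein_alignment: dict[str, str] | list[str],
                          code: int = 1) -> CodonAlignment:
    """Expand an aligned protein matrix back to codons (pal2nal-style).

    Each peptide, with gaps removed, must equal the translation of its CDS;
    every residue column becomes the source codon, every gap ``---``.
    """
    if not isinstance(protein_alignment, dict):
        protein_alignment = {
            s.taxon_label: p for s, p in zip(cds, protein_alignment)
        }
    rows = []
    taxa = []
    for s in cds:
        pep_aln = protein_alignment[s.taxon_label]
        pep = translate_cds(s, code)
        degapped = pep_aln.replace("-", "")
        if degapped != pep:
            bad = next(
                (i for i, (a, b) in enumerate(zip(degapped, pep)) if a != b),
                min(len(degapped), len(pep)),
            )
            raise ValueError(
                f"{s.taxon_label}: aligned peptide does not match CDS "
                f"translation (first mismatch at residue {bad + 1})"
            )
        codons = s.codons()
        k = 0
        row = []
        for aa in pep_aln:
            if aa == "-":
                row.append(GAP_CODON)
            else:
                row.append(codons[k])
                k += 1
        rows.append(row)
        taxa.append(s.taxon_label)
    return CodonAlignment(taxa, rows)


def annotate_regions(aln: CodonAlignment,
                     ranges: list[tuple[str, int, int]]) -> CodonAlignment:
    """Attach region labels from 1-based inclusive codon ranges."""
    region = ["unassigned"] * aln.n_codons
    claimed = set()
    for label, start, end in ranges:
        if label not in REGION_LABELS:
            raise ValueError(f"unknown region label {label!r}")
        if start < 1 or end > aln.n_codons or start > end:
            raise ValueError(
                f"region {label}: range {start}-{end} out of bounds for "
                f"{aln.n_codons} codons"
            )
        span = set(range(start - 1, end))
        if span & claimed:
            raise ValueError(f"region {label}: overlaps a previous range")
        claimed |= span
        for i in span:
            region[i] = label
    return replace(aln, region_map=region)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path) -> PhyloTree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return PhyloTree.from_dendropy(tree)


def read_newick_string(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return PhyloTree.from_dendropy(tree)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def tree_to_newick(tree: PhyloTree) -> str:
    root = int(next(i for i in range(tree.n_nodes) if tree.parent[i] < 0))

    def render(i: int) -> str:
        kids = tree.children.get(i, [])
        if not kids:
            label = tree.leaf_names[i]
            if any(ch in label for ch in " ()[]:;,"):
                label = f"'{label}'"
            body = label
        else:
            body = "(" + ",".join(render(c) for c in kids) + ")"
        if tree.parent[i] < 0:
            return body
        return f"{body}:{tree.edge_length[i]:.10g}"

    return render(root) + ";"
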