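"""Readers and writers for the standard formats touched by the pipeline.

All coordinate handling is centralised here: the package works internally in
0-based half-open coordinates; GFF3 (1-based inclusive) is converted at the
boundary by :func:`gff_to_internal` / :func:`internal_to_gff`.

Sequences are normalised on read: uppercased, with any character outside
``{A,C,G,T,N,-}`` mapped to ``N`` and counted (ambiguity codes collapse to N
because downstream distances use pairwise deletion over N/-).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import dendropy
import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN-")

#: cell states of a PCR validation matrix
SUCCESS, FAILURE, NOT_ATTEMPTED = 1, 0, -1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start1 > end1:
        raise FormatError(f"interval start {start1} > end {end1}")
    return start1 - 1, end1


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if start0 >= end0:
        raise FormatError(f"empty or inverted interval [{start0}, {end0})")
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# sequence sets
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """An ordered set of named DNA sequences (uppercase, {A,C,G,T,N,-}).

    ``n_ambiguous_replaced`` counts characters coerced to N on construction,
    so parsed + warned always accounts for every input character.
    """

    records: list[tuple[str, str]] = field(default_factory=list)
    n_ambiguous_replaced: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rid, seq in self.records:
            if not rid:
                raise FormatError("empty sequence id")
            if rid in seen:
                raise FormatError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not seq:
                raise FormatError(f"record {rid!r} has an empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"record {rid!r} contains non-normalised characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def get(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase *raw* and map characters outside the alphabet to N.

    Returns the normalised sequence and the number of replaced characters.
    """
    up = raw.upper().replace(" ", "").replace("\t", "")
    out = []
    replaced = 0
    for ch in up:
        if ch in DNA_ALPHABET:
            out.append(ch)
        else:
            out.append("N")
            replaced += 1
    return "".join(out), replaced


def read_fasta(path: str | os.PathLike) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Lowercase bases are uppercased; IUPAC ambiguity codes other than N are
    mapped to N with a logged count. Malformed input (no ``>`` header, empty
    file, empty sequence) raises :class:`FormatError` naming the line.
    """
    path = os.fspath(path)
    with open(path) as fh:
        lines = fh.readlines()
    first_content = None
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    if not first_content[1].lstrip().startswith(">"):
        raise FormatError(
            f"{path}: line {first_content[0]}: expected FASTA header starting with '>'"
        )
    header_lines = {
        line.lstrip()[1:].split()[0] if line.lstrip()[1:].split() else "": lineno
        for lineno, line in enumerate(lines, start=1)
        if line.lstrip().startswith(">")
    }
    records: list[tuple[str, str]] = []
    replaced_total = 0
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header id")
        seq, replaced = normalize_sequence(str(rec.seq))
        replaced_total += replaced
        if not seq:
            lineno = header_lines.get(rec.id, "?")
            raise FormatError(f"{path}: line {lineno}: record {rec.id!r} has no sequence")
        records.append((rec.id, seq))
    if replaced_total:
        logger.warning("%s: replaced %d ambiguous characters with N", path, replaced_total)
    return SequenceSet(records=records, n_ambiguous_replaced=replaced_total)


def write_fasta(seqs: SequenceSet, path: str | os.PathLike, width: int = 70) -> None:
    """Write a :class:`SequenceSet` as wrapped FASTA (stable input order)."""
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in seqs.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# annotations (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """One exon feature in internal (0-based half-open) coordinates."""

    seq_id: str
    feature_type: str
    start0: int
    end0: int
    strand: str
    gene_id: str
    exon_id: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"invalid strand {self.strand!r} for {self.exon_id}")
        if self.start0 >= self.end0:
            raise FormatError(f"empty interval for {self.exon_id}")

    @property
    def start1(self) -> int:
        return internal_to_gff(self.start0, self.end0)[0]

    @property
    def end1(self) -> int:
        return internal_to_gff(self.start0, self.end0)[1]

    @property
    def length(self) -> int:
        return self.end0 - self.start0


@dataclass
class AnnotationSet:
    features: list[Feature] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


def read_gff3_exons(path: str | os.PathLike) -> AnnotationSet:
    """Read exon features (with parent gene linkage) from a GFF3 file.

    Exons lacking a resolvable Parent are skipped with a warning count;
    start > end raises :class:`FormatError`. Coordinates are converted to the
    internal 0-based half-open convention.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    skipped = 0
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        if exon.start > exon.end:
            raise FormatError(f"exon {exon.id}: start {exon.start} > end {exon.end}")
        parents = exon.attributes.get("Parent", [])
        gene_id = None
        if parents:
            pid = parents[0]
            gene_id = pid
            # walk up mRNA -> gene if the parent is itself a child feature
            try:
                parent_feat = db[pid]
                while parent_feat.featuretype != "gene" and parent_feat.attributes.get("Parent"):
                    parent_feat = db[parent_feat.attributes["Parent"][0]]
                if parent_feat.featuretype == "gene":
                    gene_id = parent_feat.id
            except gffutils.exceptions.FeatureNotFoundError:
                pass
        if gene_id is None:
            logger.warning("exon %s lacks a Parent attribute; skipped", exon.id)
            skipped += 1
            continue
        start0, end0 = gff_to_internal(exon.start, exon.end)
        features.append(
            Feature(
                seq_id=exon.seqid,
                feature_type="exon",
                start0=start0,
                end0=end0,
                strand=exon.strand if exon.strand in "+-" else "+",
                gene_id=gene_id,
                exon_id=exon.id,
            )
        )
    return AnnotationSet(features=features, n_skipped=skipped)


def write_gff3(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    """Write gene + exon features as GFF3 (1-based inclusive at the boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes: dict[str, tuple[str, int, int, str]] = {}
        for f in annotation:
            s1, e1 = internal_to_gff(f.start0, f.end0)
            if f.gene_id in genes:
                seq_id, gs, ge, strand = genes[f.gene_id]
                genes[f.gene_id] = (seq_id, min(gs, s1), max(ge, e1), strand)
            else:
                genes[f.gene_id] = (f.seq_id, s1, e1, f.strand)
        for gid, (seq_id, s1, e1, strand) in genes.items():
            fh.write(
                f"{seq_id}\tnpclkit\tgene\t{s1}\t{e1}\t.\t{strand}\t.\tID={gid}\n"
            )
            for f in annotation:
                if f.gene_id != gid:
                    continue
                fs1, fe1 = internal_to_gff(f.start0, f.end0)
                fh.write(
                    f"{f.seq_id}\tnpclkit\texon\t{fs1}\t{fe1}\t.\t{f.strand}\t.\t"
                    f"ID={f.exon_id};Parent={gid}\n"
                )


# ---------------------------------------------------------------------------
# validation matrices
# ---------------------------------------------------------------------------

@dataclass
class ValidationMatrix:
    """PCR validation results: markers x taxa, cells in {success, failure, NA}."""

    markers: list[str]
    taxa: list[tuple[str, str]]  # (species, order)
    cells: np.ndarray  # int8, values SUCCESS / FAILURE / NOT_ATTEMPTED

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.markers), len(self.taxa)):
            raise FormatError(
                f"matrix shape {self.cells.shape} != "
                f"({len(self.markers)}, {len(self.taxa)})"
            )
        valid = np.isin(self.cells, (SUCCESS, FAILURE, NOT_ATTEMPTED))
        if not valid.all():
            raise FormatError("validation matrix cells must be in {1, 0, NA}")

    def counts(self) -> dict[str, int]:
        return {
            "success": int((self.cells == SUCCESS).sum()),
            "failure": int((self.cells == FAILURE).sum()),
            "not_attempted": int((self.cells == NOT_ATTEMPTED).sum()),
        }


def read_validation_matrix(path: str | os.PathLike) -> ValidationMatrix:
    """Read a PCR validation matrix from TSV.

    Layout: header row ``marker<TAB>Species|Order<TAB>...``; cells in
    ``{1, 0, NA}``. Ragged rows raise :class:`FormatError`.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty validation matrix")
    header = lines[0].split("\t")
    taxa: list[tuple[str, str]] = []
    for cell in header[1:]:
        species, _, order = cell.partition("|")
        taxa.append((species, order))
    markers: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        markers.append(parts[0])
        row = []
        for value in parts[1:]:
            value = value.strip()
            if value == "1":
                row.append(SUCCESS)
            elif value == "0":
                row.append(FAILURE)
            elif value.upper() == "NA":
                row.append(NOT_ATTEMPTED)
            else:
                raise FormatError(f"{path}: line {lineno}: bad cell {value!r}")
        rows.append(row)
    return ValidationMatrix(markers=markers, taxa=taxa, cells=np.array(rows, dtype=np.int8))


def write_validation_matrix(vm: ValidationMatrix, path: str | os.PathLike) -> None:
    rev = {SUCCESS: "1", FAILURE: "0", NOT_ATTEMPTED: "NA"}
    with open(path, "w") as fh:
        fh.write("marker\t" + "\t".join(f"{sp}|{od}" for sp, od in vm.taxa) + "\n")
        for marker, row in zip(vm.markers, vm.cells):
            fh.write(marker + "\t" + "\t".join(rev[int(v)] for v in row) + "\n")


# ---------------------------------------------------------------------------
# PHYLIP / Newick / TSV writers
# ---------------------------------------------------------------------------

def write_phylip(seqs: SequenceSet, path: str | os.PathLike) -> None:
    """Write a relaxed PHYLIP alignment (names up to 64 chars, space-delimited)."""
    lengths = {len(s) for _, s in seqs.records}
    if len(lengths) != 1:
        raise FormatError("PHYLIP requires equal-length sequences")
    ncols = lengths.pop()
    width = 0
    for rid, _ in seqs.records:
        if len(rid) > 64:
            raise FormatError(f"taxon name {rid!r} exceeds 64 characters")
        width = max(width, len(rid))
    with open(path, "w") as fh:
        fh.write(f"{len(seqs)} {ncols}\n")
        for rid, seq in seqs.records:
            fh.write(f"{rid.ljust(width)}  {seq}\n")


def read_newick(source: str | os.PathLike) -> dendropy.Tree:
    """Parse a Newick tree (from a path or a literal string)."""
    text = source
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        with open(source) as fh:
            text = fh.read()
    return dendropy.Tree.get(data=str(text), schema="newick")


def write_newick(tree: dendropy.Tree | str, path: str | os.PathLike) -> None:
    if isinstance(tree, str):
        text = tree if tree.endswith(";") else tree + ";"
        with open(path, "w") as fh:
            fh.write(text + "\n")
    else:
        tree.write(path=os.fspath(path), schema="newick", suppress_rooting=True)


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as TSV with stable column order and no index."""
    frame.to_csv(path, sep="\t", index=False)
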