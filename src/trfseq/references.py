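"""Construction of the combined small-RNA alignment reference.

The pipeline aligns reads against four compartments: mature tRNA
transcripts, rRNA subunit sequences together with their genomic repeat
copies, other annotated small-RNA genes (miRNA, piRNA, snRNA, ...), and
unannotated background segments.  Mature tRNAs are derived from genomic
tRNA gene records by splicing out introns, appending the post-
transcriptional 3' CCA tail, and prepending the G-1 base carried by
histidine tRNAs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGT")

RRNA_SUBUNITS = ("18S", "28S", "5.8S", "5S", "mito_rRNA")

BIOTYPES = ("miRNA", "piRNA", "snRNA", "Y_RNA", "7SK", "other")

#: reference compartment labels, in category-precedence order
REF_CLASSES = ("tRNA", "rRNA", "annotated_gene", "background")


class ReferenceError(ValueError):
    """Raised for malformed gene records or inconsistent bundles."""


def _check_seq(seq: str, who: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ReferenceError(f"{who}: non-ACGT characters {sorted(bad)}")


@dataclass(frozen=True)
class TRNAGeneRecord:
    """A genomic tRNA gene with optional intron annotation.

    ``intron_intervals`` are 0-based half-open intervals on
    ``genomic_seq``; they must be sorted and non-overlapping.
    """

    gene_id: str
    isotype: str
    anticodon: str
    genomic_seq: str
    intron_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3:
            raise ReferenceError(
                f"{self.gene_id}: anticodon {self.anticodon!r} is not 3 nt"
            )
        _check_seq(self.genomic_seq, self.gene_id)
        object.__setattr__(
            self, "intron_intervals", tuple(map(tuple, self.intron_intervals))
        )
        prev_end = 0
        for start, end in self.intron_intervals:
            if not (0 <= start < end <= len(self.genomic_seq)):
                raise ReferenceError(
                    f"{self.gene_id}: intron ({start},{end}) outside gene"
                )
            if start < prev_end:
                raise ReferenceError(
                    f"{self.gene_id}: introns overlap or are unsorted"
                )
            prev_end = end


@dataclass(frozen=True)
class MatureTRNA:
    """A processed mature tRNA transcript used as alignment reference."""

    transcript_id: str
    isotype: str
    anticodon: str
    seq: str

    @property
    def decoder_key(self) -> str:
        """Isotype + anticodon, e.g. ``Gly-GCC`` (anticodon level)."""
        return f"{self.isotype}-{self.anticodon}"

    @property
    def acceptor_key(self) -> str:
        """Amino-acid acceptor type alone, e.g. ``Gly``."""
        return self.isotype


@dataclass(frozen=True)
class RRNAReference:
    """An rRNA subunit sequence or one of its genomic repeat copies."""

    ref_id: str
    subunit: str
    is_repeat: bool
    seq: str

    def __post_init__(self) -> None:
        if self.subunit not in RRNA_SUBUNITS:
            raise ReferenceError(
                f"{self.ref_id}: unknown rRNA subunit {self.subunit!r}"
            )
        if not self.seq:
            raise ReferenceError(f"{self.ref_id}: empty sequence")


@dataclass(frozen=True)
class AnnotatedGene:
    ref_id: str
    biotype: str
    seq: str


@dataclass
class ReferenceBundle:
    """All alignment references, grouped by compartment.

    ``ref_ids`` are unique across compartments.  Lookup tables are built
    once at construction and shared by the mapper and classifier.
    """

    mature_trnas: list[MatureTRNA]
    rrnas: list[RRNAReference] = field(default_factory=list)
    annotated_genes: list[AnnotatedGene] = field(default_factory=list)
    background: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ref_id in self.ref_ids():
            if ref_id in seen:
                raise ReferenceError(f"duplicate ref_id {ref_id!r}")
            seen.add(ref_id)
        self.trna_by_id = {t.transcript_id: t for t in self.mature_trnas}
        self.rrna_by_id = {r.ref_id: r for r in self.rrnas}
        self.gene_by_id = {g.ref_id: g for g in self.annotated_genes}

    def ref_ids(self) -> list[str]:
        return (
            [t.transcript_id for t in self.mature_trnas]
            + [r.ref_id for r in self.rrnas]
            + [g.ref_id for g in self.annotated_genes]
            + [ref_id for ref_id, _ in self.background]
        )

    def iter_refs(self) -> Iterable[tuple[str, str, str]]:
        """Yield (ref_id, ref_class, seq) over every reference."""
        for t in self.mature_trnas:
            yield t.transcript_id, "tRNA", t.seq
        for r in self.rrnas:
            yield r.ref_id, "rRNA", r.seq
        for g in self.annotated_genes:
            yield g.ref_id, "annotated_gene", g.seq
        for ref_id, seq in self.background:
            yield ref_id, "background", seq

    def ref_class(self, ref_id: str) -> str:
        if ref_id in self.trna_by_id:
            return "tRNA"
        if ref_id in self.rrna_by_id:
            return "rRNA"
        if ref_id in self.gene_by_id:
            return "annotated_gene"
        return "background"


def splice(seq: str, intron_intervals: Sequence[tuple[int, int]]) -> str:
    """Remove the given 0-based half-open intervals from ``seq``."""
    pieces = []
    pos = 0
    for start, end in intron_intervals:
        pieces.append(seq[pos:start])
        pos = end
    pieces.append(seq[pos:])
    return "".join(pieces)


def build_mature_trna(
    gene: TRNAGeneRecord, assume_cca_absent: bool = True
) -> MatureTRNA:
    """Process a genomic tRNA gene into its mature transcript.

    Introns are spliced out, a 3' CCA tail is appended, and histidine
    tRNAs receive the extra G at position -1.  With
    ``assume_cca_absent=False`` a gene already ending in CCA is left
    untailed (gene sets that store pre-tailed sequences).
    """
    body = splice(gene.genomic_seq, gene.intron_intervals)
    if assume_cca_absent or not body.endswith("CCA"):
        body = body + "CCA"
    if gene.isotype == "His":
        body = "G" + body
    return MatureTRNA(
        transcript_id=gene.gene_id,
        isotype=gene.isotype,
        anticodon=gene.anticodon,
        seq=body,
    )


def build_reference_bundle(
    trna_genes: Sequence[TRNAGeneRecord],
    rrnas: Sequence[RRNAReference] = (),
    annotated_genes: Sequence[AnnotatedGene] = (),
    background: Sequence[tuple[str, str]] = (),
    assume_cca_absent: bool = True,
) -> ReferenceBundle:
    """Assemble the combined bundle; every tRNA goes through
    :func:`build_mature_trna`."""
    if not trna_genes:
        raise ReferenceError("empty tRNA gene set")
    mature = [build_mature_trna(g, assume_cca_absent) for g in trna_genes]
    return ReferenceBundle(
        mature_trnas=mature,
        rrnas=list(rrnas),
        annotated_genes=list(annotated_genes),
        background=[tuple(b) for b in background],
    )


# ---------------------------------------------------------------------------
# I/O


def read_trna_gene_table(path: str | Path) -> list[TRNAGeneRecord]:
    """Read a tRNA gene TSV: gene_id, isotype, anticodon, seq, introns.

    Introns are encoded ``start-end;start-end`` (0-based half-open) or
    left empty.
    """
    genes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            intron_field = (row.get("introns") or "").strip()
            introns = []
            if intron_field:
                for part in intron_field.split(";"):
                    start, end = part.split("-")
                    introns.append((int(start), int(end)))
            genes.append(
                TRNAGeneRecord(
                    gene_id=row["gene_id"],
                    isotype=row["isotype"],
                    anticodon=row["anticodon"],
                    genomic_seq=row["seq"],
                    intron_intervals=tuple(introns),
                )
            )
    return genes


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_reference_fasta(
    bundle: ReferenceBundle,
    fasta_path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Write the combined FASTA plus a TSV manifest of every reference."""
    records = [
        SeqRecord(Seq(seq), id=ref_id, description="")
        for ref_id, _, seq in bundle.iter_refs()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["ref_id", "class", "subtype", "length"])
            for ref_id, ref_class, seq in bundle.iter_refs():
                if ref_class == "tRNA":
                    subtype = bundle.trna_by_id[ref_id].decoder_key
                elif ref_class == "rRNA":
                    r = bundle.rrna_by_id[ref_id]
                    subtype = r.subunit + ("_repeat" if r.is_repeat else "")
                elif ref_class == "annotated_gene":
                    subtype = bundle.gene_by_id[ref_id].biotype
                else:
                    subtype = "background"
                writer.writerow([ref_id, ref_class, subtype, len(seq)])
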