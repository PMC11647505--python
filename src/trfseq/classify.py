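"""Resolution of read hit sets to a single primary annotation.

Category precedence follows the biology of the reference compartments:
any best hit on a mature tRNA makes the read a tRNA read (non-tRNA hits
are discarded); otherwise any hit on an rRNA subunit or ribosomal repeat
makes it an rsRNA read; otherwise an annotated-gene hit assigns that
biotype; reads with only background hits are "unannotated" (Other); and
reads with no hits at all are unmapped.  Exactly one primary hit — the
first retained hit under the mapper's deterministic order — is kept per
read, so category percentages never double-count.

tRNA reads are further typed by the position of the alignment on the
mature transcript (whole / tRF_5p / tRF_3p / tRF_other, with asymmetric
5'/3' end tolerances of 3 and 5 nt) and by specificity: unique to one
transcript, to one isotype+anticodon (decoder), to one amino-acid
acceptor, or ambiguous.  Only transcript- and decoder-specific reads
enter decoder-level count tables by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mapper import AlignmentHit
from .preprocess import (
    DEFAULT_MIN_NON_TRNA_LEN,
    DEFAULT_MIN_TRNA_LEN,
    ProcessedRead,
)
from .references import MatureTRNA, ReferenceBundle


@dataclass(frozen=True)
class ClassifierParams:
    """End tolerances (nt) for fragment typing.

    A read is "whole" when its 5' end lies within ``whole_5p_tol`` of
    the mature 5' end and its 3' end within ``whole_3p_tol`` of the CCA
    terminus; the same tolerances mark tRF_5p / tRF_3p end-alignment.
    """

    whole_5p_tol: int = 3
    whole_3p_tol: int = 5
    end5_tol: int = 3
    end3_tol: int = 5

    def __post_init__(self) -> None:
        if min(self.whole_5p_tol, self.whole_3p_tol, self.end5_tol, self.end3_tol) < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class ReadAnnotation:
    read_id: str
    category: str  # tRNA | rsRNA | annotated_gene:<biotype> | unannotated | unmapped
    fragment_type: str = "NA"  # whole | tRF_5p | tRF_3p | tRF_other | NA
    specificity: str = "NA"  # transcript | decoder | acceptor | ambiguous | NA
    feature_key: str = "NA"
    primary_hit: AlignmentHit | None = None
    insert_len: int = 0
    retained_hits: list[AlignmentHit] = field(default_factory=list)
    dropped: bool = False  # short-read filter outcome
    drop_reason: str = ""


def resolve_category(
    hits: list[AlignmentHit], bundle: ReferenceBundle
) -> tuple[str, list[AlignmentHit], AlignmentHit | None]:
    """Apply category precedence to a best-hit set.

    Returns (category, retained hits, primary hit).  Reverse-strand
    tRNA hits do not count as tRNA evidence (antisense fragments are
    out of scope) and are demoted to background.
    """
    if not hits:
        return "unmapped", [], None
    trna_hits = [h for h in hits if h.ref_class == "tRNA" and h.strand == "+"]
    if trna_hits:
        return "tRNA", trna_hits, trna_hits[0]
    rrna_hits = [h for h in hits if h.ref_class == "rRNA"]
    if rrna_hits:
        return "rsRNA", rrna_hits, rrna_hits[0]
    gene_hits = [h for h in hits if h.ref_class == "annotated_gene"]
    if gene_hits:
        biotype = bundle.gene_by_id[gene_hits[0].ref_id].biotype
        return f"annotated_gene:{biotype}", gene_hits, gene_hits[0]
    return "unannotated", list(hits), hits[0]


def classify_trna_fragment(
    hit: AlignmentHit,
    trna: MatureTRNA,
    params: ClassifierParams = ClassifierParams(),
) -> str:
    """Type a tRNA-mapped read by its position on the mature transcript.

    Rules evaluated in order: whole, then tRF_5p, then tRF_3p, else
    tRF_other.  Distances are measured on the mature sequence, CCA tail
    included.
    """
    L = len(trna.seq)
    if not (0 <= hit.start < hit.end <= L):
        raise ValueError(
            f"hit ({hit.start},{hit.end}) outside mature tRNA of length {L}"
        )
    d5 = hit.start
    d3 = L - hit.end
    if d5 <= params.whole_5p_tol and d3 <= params.whole_3p_tol:
        return "whole"
    if d5 <= params.end5_tol:
        return "tRF_5p"
    if d3 <= params.end3_tol:
        return "tRF_3p"
    return "tRF_other"


def classify_trna_specificity(
    retained_hits: list[AlignmentHit], bundle: ReferenceBundle
) -> tuple[str, str]:
    """Specificity tier and counting key of a tRNA read's hit set.

    transcript/decoder-specific reads are keyed by decoder (isotype-
    anticodon); acceptor-specific reads carry the acceptor key but are
    excluded from decoder-level counts; reads spanning acceptors are
    ambiguous.
    """
    if not retained_hits:
        raise ValueError("no retained tRNA hits")
    trnas = [bundle.trna_by_id[h.ref_id] for h in retained_hits]
    transcripts = {t.transcript_id for t in trnas}
    decoders = {t.decoder_key for t in trnas}
    acceptors = {t.acceptor_key for t in trnas}
    if len(transcripts) == 1:
        return "transcript", trnas[0].decoder_key
    if len(decoders) == 1:
        return "decoder", trnas[0].decoder_key
    if len(acceptors) == 1:
        return "acceptor", trnas[0].acceptor_key
    return "ambiguous", "NA"


def classify_rsrna_subunit(
    retained_hits: list[AlignmentHit], bundle: ReferenceBundle
) -> str:
    """Collapse rRNA subunit references and their repeats to a subunit
    key; disagreeing hits become ``rsRNA_multi``."""
    subunits = {bundle.rrna_by_id[h.ref_id].subunit for h in retained_hits}
    if len(subunits) == 1:
        return subunits.pop()
    return "rsRNA_multi"


def annotate_read(
    read: ProcessedRead,
    hits: list[AlignmentHit],
    bundle: ReferenceBundle,
    params: ClassifierParams = ClassifierParams(),
    min_non_trna_len: int = DEFAULT_MIN_NON_TRNA_LEN,
    min_trna_len: int = DEFAULT_MIN_TRNA_LEN,
) -> ReadAnnotation:
    """Full per-read annotation, including the deferred length filter.

    Reads flagged short survive only when they resolve to the tRNA
    category (and still meet the absolute tRNA minimum length).
    """
    category, retained, primary = resolve_category(hits, bundle)
    ann = ReadAnnotation(
        read_id=read.read_id,
        category=category,
        primary_hit=primary,
        insert_len=len(read.insert_seq),
        retained_hits=retained,
    )
    if category == "tRNA":
        trna = bundle.trna_by_id[primary.ref_id]
        ann.fragment_type = classify_trna_fragment(primary, trna, params)
        ann.specificity, ann.feature_key = classify_trna_specificity(
            retained, bundle
        )
        if ann.insert_len < min_trna_len:
            ann.dropped = True
            ann.drop_reason = "short_trna"
    else:
        if category == "rsRNA":
            ann.feature_key = classify_rsrna_subunit(retained, bundle)
        elif category.startswith("annotated_gene") or category == "unannotated":
            ann.feature_key = primary.ref_id
        if ann.insert_len < min_non_trna_len:
            ann.dropped = True
            ann.drop_reason = "short_non_trna"
    return ann
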