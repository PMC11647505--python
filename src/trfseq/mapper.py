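"""Best-hit ungapped alignment of inserts against the reference bundle.

The downstream classification rules consume the *set of best mappings*
of each read, not alignment internals.  At tRF/rsRNA lengths an ungapped
end-to-end model with Hamming distance reproduces that contract: every
alignment of the full insert at every offset on either strand is scored
by mismatch count, and only the minimum-distance hits (within
``max_mismatches``) are returned.  Candidate offsets are found with a
pigeonhole chunk index (any alignment with at most m mismatches matches
one of m+1 read chunks exactly), so typical reads cost a few substring
searches over the concatenated reference.

Reads containing N score a mismatch at each N position, since N never
occurs in the reference alphabet.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .references import ReferenceBundle

_CLASS_RANK = {"tRNA": 0, "rRNA": 1, "annotated_gene": 2, "background": 3}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate mapping of a read onto a reference sequence."""

    read_id: str
    ref_id: str
    ref_class: str
    start: int
    end: int  # 0-based half-open on the reference
    strand: str  # "+" or "-"
    edit_distance: int


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count, short-circuiting once ``limit`` is exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


class ReadMapper:
    """Reusable best-hit mapper over a fixed :class:`ReferenceBundle`."""

    def __init__(
        self,
        bundle: ReferenceBundle,
        max_mismatches: int = 1,
        max_hits: int = 100,
    ) -> None:
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.bundle = bundle
        self.max_mismatches = max_mismatches
        self.max_hits = max_hits
        self._refs = list(bundle.iter_refs())  # (ref_id, class, seq)
        # concatenate with '#' separators so one C-level find scans all refs
        offsets = []
        parts = []
        pos = 0
        for ref_id, ref_class, seq in self._refs:
            offsets.append(pos)
            parts.append(seq)
            pos += len(seq) + 1
        self._cat = "#".join(parts)
        self._offsets = offsets

    def _ref_index_at(self, pos: int) -> int:
        return bisect.bisect_right(self._offsets, pos) - 1

    def _candidates(self, query: str) -> set[tuple[int, int]]:
        """(ref index, start-on-ref) pairs where ``query`` might align
        with <= max_mismatches, via pigeonhole chunks."""
        n = len(query)
        k = self.max_mismatches + 1
        chunk_len = n // k
        cands: set[tuple[int, int]] = set()
        if chunk_len == 0:
            # read shorter than chunk count: scan everything
            for idx, (_, _, seq) in enumerate(self._refs):
                cands.update((idx, s) for s in range(len(seq) - n + 1))
            return cands
        for c in range(k):
            c_start = c * chunk_len
            c_end = n if c == k - 1 else (c + 1) * chunk_len
            chunk = query[c_start:c_end]
            found = self._cat.find(chunk)
            while found != -1:
                idx = self._ref_index_at(found)
                ref_off = self._offsets[idx]
                ref_len = len(self._refs[idx][2])
                start = found - ref_off - c_start
                if 0 <= start and start + n <= ref_len:
                    cands.add((idx, start))
                found = self._cat.find(chunk, found + 1)
        return cands

    def map_read(self, insert: str, read_id: str = "") -> list[AlignmentHit]:
        """All minimum-edit-distance end-to-end hits of ``insert``.

        Hits are sorted by (class rank, ref_id, start, strand) and
        truncated at ``max_hits``; the class-ranked order guarantees a
        tRNA hit is never dropped in favor of a lower-precedence one.
        """
        if not insert:
            raise ValueError("empty insert")
        best: list[tuple[int, int, str, int]] = []  # (refidx, start, strand, d)
        best_d = self.max_mismatches + 1
        for strand, query in (("+", insert), ("-", revcomp(insert))):
            for idx, start in self._candidates(query):
                ref_seq = self._refs[idx][2]
                window = ref_seq[start : start + len(query)]
                d = _hamming(query, window, best_d)
                if d < best_d:
                    best_d = d
                    best = [(idx, start, strand, d)]
                elif d == best_d:
                    best.append((idx, start, strand, d))
        if best_d > self.max_mismatches:
            return []
        hits = []
        n = len(insert)
        for idx, start, strand, d in best:
            ref_id, ref_class, _ = self._refs[idx]
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    ref_id=ref_id,
                    ref_class=ref_class,
                    start=start,
                    end=start + n,
                    strand=strand,
                    edit_distance=d,
                )
            )
        hits.sort(
            key=lambda h: (_CLASS_RANK[h.ref_class], h.ref_id, h.start, h.strand)
        )
        # dedupe identical (ref,pos) reached on both strands (palindromes)
        seen = set()
        unique = []
        for h in hits:
            key = (h.ref_id, h.start, h.strand)
            if key not in seen:
                seen.add(key)
                unique.append(h)
        return unique[: self.max_hits]


def map_read(
    insert: str,
    bundle: ReferenceBundle,
    max_mismatches: int = 1,
    max_hits: int = 100,
    read_id: str = "",
) -> list[AlignmentHit]:
    """One-shot convenience wrapper around :class:`ReadMapper`."""
    return ReadMapper(bundle, max_mismatches, max_hits).map_read(insert, read_id)


# ---------------------------------------------------------------------------
# SAM interoperability (external aligners producing the same contract)


def write_sam(
    hits_by_read: dict[str, list[AlignmentHit]],
    bundle: ReferenceBundle,
    inserts: dict[str, str],
    path: str,
) -> None:
    """Write hits as SAM; the first hit per read is primary, the rest
    carry the secondary flag."""
    import pysam

    refs = list(bundle.iter_refs())
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r[0], "LN": len(r[2])} for r in refs],
    }
    tid = {r[0]: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read_id, hits in hits_by_read.items():
            seq = inserts[read_id]
            if not hits:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read_id
                rec.query_sequence = seq
                rec.flag = 4
                out.write(rec)
                continue
            for i, h in enumerate(hits):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read_id
                rec.query_sequence = seq if h.strand == "+" else revcomp(seq)
                rec.flag = (16 if h.strand == "-" else 0) | (256 if i else 0)
                rec.reference_id = tid[h.ref_id]
                rec.reference_start = h.start
                rec.cigartuples = [(0, len(seq))]
                rec.set_tag("NM", h.edit_distance)
                out.write(rec)


def read_sam(path: str, bundle: ReferenceBundle) -> dict[str, list[AlignmentHit]]:
    """Reconstruct per-read hit lists from a SAM produced by
    :func:`write_sam` or an external end-to-end aligner."""
    import pysam

    hits_by_read: dict[str, list[AlignmentHit]] = {}
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            hits_by_read.setdefault(rec.query_name, [])
            if rec.is_unmapped:
                continue
            ref_id = rec.reference_name
            hits_by_read[rec.query_name].append(
                AlignmentHit(
                    read_id=rec.query_name,
                    ref_id=ref_id,
                    ref_class=bundle.ref_class(ref_id),
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    edit_distance=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                )
            )
    for hits in hits_by_read.values():
        hits.sort(
            key=lambda h: (_CLASS_RANK[h.ref_class], h.ref_id, h.start, h.strand)
        )
    return hits_by_read
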