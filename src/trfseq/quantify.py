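"""Aggregation of read annotations into counts, class percentages and
the >40-nt length partition.

Count tables are keyed at the granularity the differential stage
consumes: tRNA reads at decoder (isotype-anticodon) x fragment type,
for transcript- or decoder-specific reads only; rsRNA reads by subunit;
annotated-gene reads by gene id.  Ambiguous tRNA reads, unannotated
reads and unmapped reads never enter feature rows but are tallied so
read accounting stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ReadAnnotation

#: class label of an annotation, as used in composition summaries
def read_class(ann: ReadAnnotation) -> str:
    if ann.category == "tRNA":
        return "whole_tRNA" if ann.fragment_type == "whole" else ann.fragment_type
    if ann.category == "rsRNA":
        return "rsRNA"
    if ann.category.startswith("annotated_gene:"):
        return ann.category.split(":", 1)[1]
    return ann.category  # unannotated | unmapped


TRF_CLASS_LABELS = ("tRF_5p", "tRF_3p", "tRF_other")


@dataclass
class CountTable:
    """Feature x sample integer counts plus per-sample tallies."""

    counts: pd.DataFrame  # index feature_key, columns sample ids
    feature_classes: pd.Series  # feature_key -> class label
    conditions: pd.Series  # sample_id -> condition
    tallies: pd.DataFrame  # per-sample ambiguous/unannotated/unmapped/dropped

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "class", self.feature_classes)
        out.to_csv(path, sep="\t")


def _feature_of(ann: ReadAnnotation, count_acceptor_level: bool) -> tuple[str, str] | None:
    """(feature_key, class) of a counted annotation, or None."""
    if ann.category == "tRNA":
        if ann.specificity in ("transcript", "decoder") or (
            count_acceptor_level and ann.specificity == "acceptor"
        ):
            suffix = "whole" if ann.fragment_type == "whole" else ann.fragment_type
            return f"{ann.feature_key}_{suffix}", read_class(ann)
        return None
    if ann.category == "rsRNA":
        return ann.feature_key, "rsRNA"
    if ann.category.startswith("annotated_gene:"):
        return ann.feature_key, read_class(ann)
    return None


def count_features(
    annotations: Mapping[str, Sequence[ReadAnnotation]],
    conditions: Mapping[str, str],
    count_acceptor_level: bool = False,
) -> CountTable:
    """Tally counted annotations per sample into a :class:`CountTable`.

    ``annotations`` maps sample_id to that sample's (non-discarded)
    annotations.  Dropped (short) reads are excluded from features and
    recorded in the tallies.
    """
    unknown = set(annotations) - set(conditions)
    if unknown:
        raise ValueError(f"unknown sample_id(s): {sorted(unknown)}")
    feat_counts: dict[str, dict[str, int]] = {}
    feat_class: dict[str, str] = {}
    tally_rows = {}
    for sample, anns in annotations.items():
        tally = {"ambiguous_trna": 0, "unannotated": 0, "unmapped": 0, "dropped_short": 0}
        for ann in anns:
            if ann.dropped:
                tally["dropped_short"] += 1
                continue
            keyed = _feature_of(ann, count_acceptor_level)
            if keyed is None:
                if ann.category == "tRNA":
                    tally["ambiguous_trna"] += 1
                elif ann.category == "unmapped":
                    tally["unmapped"] += 1
                else:
                    tally["unannotated"] += 1
                continue
            key, cls = keyed
            feat_class[key] = cls
            feat_counts.setdefault(key, {}).setdefault(sample, 0)
            feat_counts[key][sample] += 1
        tally_rows[sample] = tally
    samples = list(annotations)
    counts = pd.DataFrame(
        {
            s: [feat_counts.get(k, {}).get(s, 0) for k in sorted(feat_counts)]
            for s in samples
        },
        index=sorted(feat_counts),
        dtype=int,
    )
    counts.index.name = "feature_key"
    return CountTable(
        counts=counts,
        feature_classes=pd.Series(feat_class).reindex(counts.index),
        conditions=pd.Series({s: conditions[s] for s in samples}),
        tallies=pd.DataFrame(tally_rows).T,
    )


def class_percentages(
    annotations: Mapping[str, Sequence[ReadAnnotation]],
    basis: str = "all_mapped",
) -> pd.DataFrame:
    """Per-sample percentage of reads in each class.

    basis="all_mapped" includes unannotated (Other) reads in the
    denominator; basis="annotated_only" removes them and renormalizes.
    Unmapped and dropped reads are excluded under both bases.
    Percentages sum to 100 per sample.
    """
    if basis not in ("all_mapped", "annotated_only"):
        raise ValueError(f"unknown basis {basis!r}")
    rows = {}
    for sample, anns in annotations.items():
        counts: dict[str, int] = {}
        for ann in anns:
            if ann.dropped or ann.category == "unmapped":
                continue
            cls = read_class(ann)
            if basis == "annotated_only" and cls == "unannotated":
                continue
            counts[cls] = counts.get(cls, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"{sample}: no mapped reads")
        rows[sample] = {k: 100.0 * v / total for k, v in counts.items()}
    return pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)


def length_partition(
    annotations: Mapping[str, Sequence[ReadAnnotation]] | Iterable[ReadAnnotation],
    cutoff: int = 40,
) -> pd.DataFrame:
    """Fraction of reads longer than ``cutoff`` nt, per class.

    Reads of exactly ``cutoff`` nt fall in the short bucket (strict >).
    Returns a frame with columns long/short/frac_long per class, plus a
    "total" row over all non-dropped, mapped reads.
    """
    if isinstance(annotations, Mapping):
        anns = [a for sample in annotations.values() for a in sample]
    else:
        anns = list(annotations)
    buckets: dict[str, list[int]] = {}
    for ann in anns:
        if ann.dropped or ann.category == "unmapped":
            continue
        buckets.setdefault(read_class(ann), [0, 0])
        buckets[read_class(ann)][ann.insert_len > cutoff] += 1
        buckets.setdefault("total", [0, 0])
        buckets["total"][ann.insert_len > cutoff] += 1
    rows = {}
    for cls, (short, long_) in buckets.items():
        n = short + long_
        rows[cls] = {
            "short": short,
            "long": long_,
            "frac_long": (long_ / n) if n else float("nan"),
        }
    return pd.DataFrame(rows).T.sort_index()
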