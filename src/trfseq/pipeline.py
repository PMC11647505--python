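"""End-to-end orchestration: simulate/ingest -> trim -> map -> classify
-> quantify -> test, with a run manifest and read accounting.

Every stage's read counts are recorded so that conservation (raw =
kept + discarded; kept = categorized, including unmapped and
length-dropped reads) can be checked mechanically.  Identical inserts
share one mapping/classification result via a cache, which keeps the
fully synthetic runs fast without changing any per-read outcome.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierParams, ReadAnnotation, annotate_read
from .differential import DiffParams, nb_wald_test, size_factors
from .mapper import ReadMapper
from .preprocess import (
    DEFAULT_ADAPTER,
    DEFAULT_MIN_NON_TRNA_LEN,
    DEFAULT_MIN_TRNA_LEN,
    DEFAULT_TRAILING,
    DEFAULT_UMI_LEN,
    trim_fastq,
)
from .quantify import (
    CountTable,
    class_percentages,
    count_features,
    length_partition,
)
from .references import ReferenceBundle
from .simulate import SimConfig, SimTruth, default_reference_bundle, simulate_run

log = logging.getLogger("trfseq")


@dataclass
class RunConfig:
    outdir: str | Path
    seed: int = 1
    sim: SimConfig | None = None
    bundle: ReferenceBundle | None = None
    sample_sheet: str | Path | None = None  # sample_id, condition, fastq
    adapter: str = DEFAULT_ADAPTER
    umi_len: int = DEFAULT_UMI_LEN
    trailing: int = DEFAULT_TRAILING
    min_non_trna_len: int = DEFAULT_MIN_NON_TRNA_LEN
    min_trna_len: int = DEFAULT_MIN_TRNA_LEN
    max_mismatches: int = 1
    max_hits: int = 100
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    diff: DiffParams = field(default_factory=DiffParams)
    length_cutoff: int = 40


@dataclass
class PipelineResult:
    annotations: dict[str, list[ReadAnnotation]]
    count_table: CountTable
    class_pct_all: pd.DataFrame
    class_pct_annotated: pd.DataFrame
    lengths: pd.DataFrame
    diff_results: pd.DataFrame | None
    manifest: dict
    truth: SimTruth | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "fastq"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return sheet


def annotate_sample(
    processed,
    mapper: ReadMapper,
    bundle: ReferenceBundle,
    params: ClassifierParams,
    min_non_trna_len: int,
    min_trna_len: int,
    cache: dict | None = None,
) -> list[ReadAnnotation]:
    """Map and classify every kept read of one sample.

    ``cache`` (insert -> annotation template) may be shared across
    samples; annotation depends only on the insert sequence.
    """
    cache = {} if cache is None else cache
    annotations = []
    for read in processed:
        if read.discarded:
            continue
        template = cache.get(read.insert_seq)
        if template is None:
            hits = mapper.map_read(read.insert_seq, read.read_id)
            template = annotate_read(
                read, hits, bundle, params, min_non_trna_len, min_trna_len
            )
            cache[read.insert_seq] = template
        annotations.append(
            dataclasses.replace(template, read_id=read.read_id)
        )
    return annotations


def run_pipeline(config: RunConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "adapter": config.adapter,
            "umi_len": config.umi_len,
            "trailing": config.trailing,
            "min_non_trna_len": config.min_non_trna_len,
            "min_trna_len": config.min_trna_len,
            "max_mismatches": config.max_mismatches,
            "max_hits": config.max_hits,
            "classifier": dataclasses.asdict(config.classifier),
            "diff": dataclasses.asdict(config.diff),
            "length_cutoff": config.length_cutoff,
        },
        "samples": {},
    }

    bundle = config.bundle or default_reference_bundle()
    truth = None
    try:
        if config.sim is not None:
            simdir = outdir / "sim"
            truth = simulate_run(config.sim, bundle, simdir)
            sheet = pd.read_csv(simdir / "samples.tsv", sep="\t")
        elif config.sample_sheet is not None:
            sheet = _read_sample_sheet(config.sample_sheet)
        else:
            raise ValueError("RunConfig needs either sim or sample_sheet")
        for fq in sheet["fastq"]:
            if not Path(fq).exists():
                raise FileNotFoundError(fq)
    except Exception as exc:  # startup errors carry the stage name
        raise StageError("input", exc) from exc

    mapper = ReadMapper(bundle, config.max_mismatches, config.max_hits)
    annotations: dict[str, list[ReadAnnotation]] = {}
    conditions: dict[str, str] = {}
    cache: dict = {}
    for _, row in sheet.iterrows():
        sample = row["sample_id"]
        conditions[sample] = row["condition"]
        try:
            processed, stats = trim_fastq(
                row["fastq"],
                adapter=config.adapter,
                umi_len=config.umi_len,
                trailing=config.trailing,
                min_non_trna=config.min_non_trna_len,
            )
        except Exception as exc:
            raise StageError(f"trim[{sample}]", exc) from exc
        try:
            anns = annotate_sample(
                processed,
                mapper,
                bundle,
                config.classifier,
                config.min_non_trna_len,
                config.min_trna_len,
                cache,
            )
        except Exception as exc:
            raise StageError(f"classify[{sample}]", exc) from exc
        annotations[sample] = anns
        manifest["samples"][sample] = {
            "raw_reads": stats.total,
            "discarded_in_trim": stats.discarded,
            "kept_after_trim": stats.kept,
            "flagged_short": stats.flagged_short,
            "annotated": len(anns),
            "unmapped": sum(a.category == "unmapped" for a in anns),
            "dropped_short": sum(a.dropped for a in anns),
        }
        log.info("sample %s: %s", sample, manifest["samples"][sample])

    try:
        count_table = count_features(annotations, conditions)
        pct_all = class_percentages(annotations, basis="all_mapped")
        pct_ann = class_percentages(annotations, basis="annotated_only")
        lengths = length_partition(annotations, cutoff=config.length_cutoff)
    except Exception as exc:
        raise StageError("quantify", exc) from exc

    diff_results = None
    if len(set(conditions.values())) == 2:
        try:
            diff_results = nb_wald_test(
                count_table.counts,
                count_table.conditions,
                params=config.diff,
            )
        except Exception as exc:
            raise StageError("differential", exc) from exc

    count_table.to_tsv(outdir / "counts.tsv")
    pct_all.to_csv(outdir / "class_percentages_all_mapped.tsv", sep="\t")
    pct_ann.to_csv(outdir / "class_percentages_annotated.tsv", sep="\t")
    lengths.to_csv(outdir / "length_partition.tsv", sep="\t")
    ann_path = outdir / "annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write(
            "read_id\tsample\tcategory\tfragment_type\tspecificity\t"
            "feature_key\tref_id\tstart\tend\tinsert_len\tdropped\n"
        )
        for sample, anns in annotations.items():
            for a in anns:
                hit = a.primary_hit
                fh.write(
                    f"{a.read_id}\t{sample}\t{a.category}\t{a.fragment_type}\t"
                    f"{a.specificity}\t{a.feature_key}\t"
                    f"{hit.ref_id if hit else 'NA'}\t"
                    f"{hit.start if hit else 'NA'}\t{hit.end if hit else 'NA'}\t"
                    f"{a.insert_len}\t{int(a.dropped)}\n"
                )
    if diff_results is not None:
        diff_results.to_csv(outdir / "differential.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        annotations=annotations,
        count_table=count_table,
        class_pct_all=pct_all,
        class_pct_annotated=pct_ann,
        lengths=lengths,
        diff_results=diff_results,
        manifest=manifest,
        truth=truth,
    )


def validate_against_truth(
    result: PipelineResult, truth: SimTruth, lfc_cutoff: float = 1.0
) -> dict:
    """Compare a synthetic run's outputs to the generator's ground truth.

    Reports per-read category and fragment-type accuracy, size-factor
    relative error against the true library factors (both normalized to
    geometric mean 1), and DE sensitivity / false discovery fraction
    against the true nonzero-log2fc features.
    """
    truth_by_id = {r.read_id: r for r in truth.reads}
    ann_ids = {a.read_id for anns in result.annotations.values() for a in anns}
    extra = ann_ids - set(truth_by_id)
    if extra:
        raise ValueError(f"annotated read ids missing from truth: {sorted(extra)[:3]}")

    n = n_cat = n_trna = n_frag = 0
    for anns in result.annotations.values():
        for a in anns:
            t = truth_by_id[a.read_id]
            n += 1
            if a.category == t.category:
                n_cat += 1
            if t.category == "tRNA":
                n_trna += 1
                if a.fragment_type == t.fragment_type:
                    n_frag += 1
    report: dict = {
        "n_reads_annotated": n,
        "category_accuracy": n_cat / n if n else float("nan"),
        "fragment_accuracy": n_frag / n_trna if n_trna else float("nan"),
    }

    est_sf = size_factors(result.count_table.counts)
    true_sf = truth.lib_factors.reindex(est_sf.index)
    est_norm = est_sf / np.exp(np.log(est_sf).mean())
    true_norm = true_sf / np.exp(np.log(true_sf).mean())
    rel_err = (est_norm - true_norm).abs() / true_norm
    report["size_factor_max_rel_error"] = float(rel_err.max())

    if result.diff_results is not None:
        true_lfc = pd.Series(
            {f.feature_key: f.log2fc for f in truth.features}
        ).reindex(result.diff_results.index)
        called = result.diff_results["significant"].fillna(False)
        # sensitivity over features whose true effect clears the call
        # threshold; false discoveries over truly null features
        is_de = (true_lfc.abs() > lfc_cutoff).fillna(False)
        is_null = (true_lfc == 0).fillna(False)
        n_de = int(is_de.sum())
        n_called = int(called.sum())
        report["de_sensitivity"] = (
            int((called & is_de).sum()) / n_de if n_de else float("nan")
        )
        report["de_false_discovery_fraction"] = (
            int((called & is_null).sum()) / n_called if n_called else 0.0
        )
        report["n_de_truth"] = n_de
        report["n_de_called"] = n_called
    return report
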