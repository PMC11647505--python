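"""Synthetic WT-vs-KO small-RNA libraries with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
libraries dominated by tRNA-derived fragments and rRNA-derived small
RNAs, with per-feature negative-binomial counts, per-sample library-size
factors, and condition-dependent log2 fold changes (the "KO" preset
depletes tRF features, mimicking loss of the epididymal ribonucleases
that generate them).  Every emitted read carries the raw layout the
preprocessing stage inverts:

    [7-nt UMI] [insert] [1 untemplated base] [3' adapter]

and every insert is placed on its reference so that the classifier's
positional rules recover the intended fragment label exactly (tolerance
margins are respected by construction).  Ground truth — realized counts,
library factors, per-read labels — is returned and written alongside the
FASTQ files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER, DEFAULT_UMI_LEN, write_fastq
from .references import (
    AnnotatedGene,
    ReferenceBundle,
    RRNAReference,
    TRNAGeneRecord,
    build_reference_bundle,
)

TRF_CLASSES = ("tRF_5p", "tRF_3p", "tRF_other", "whole_tRNA")

#: per-class insert length ranges (inclusive), nt
DEFAULT_LEN_MODEL = {
    "tRF_5p": (28, 36),
    "tRF_3p": (18, 36),
    "tRF_other": (16, 40),
    "rsRNA": (20, 50),
    "unannotated": (16, 45),
}

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimFeature:
    """One simulated feature: a countable species with an NB count model.

    ``anchor`` names the reference the reads come from: a decoder key
    (isotype-anticodon) for tRNA classes, a subunit for rsRNA, a ref_id
    for miRNA/unannotated.
    """

    feature_key: str
    sim_class: str  # tRF_5p | tRF_3p | tRF_other | whole_tRNA | rsRNA:<subunit> | miRNA | unannotated
    anchor: str
    base_mean: float
    dispersion: float = 0.1
    log2fc: float = 0.0

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError(f"{self.feature_key}: base_mean must be > 0")
        if self.dispersion < 0:
            raise ValueError(f"{self.feature_key}: dispersion must be >= 0")


@dataclass
class SimConfig:
    seed: int
    features: list[SimFeature]
    n_per_condition: int = 3
    conditions: tuple[str, str] = ("WT", "KO")
    adapter: str = DEFAULT_ADAPTER
    umi_len: int = DEFAULT_UMI_LEN
    error_rate: float = 0.0
    lib_factor_range: tuple[float, float] = (0.5, 2.0)
    read_len_model: dict = field(default_factory=lambda: dict(DEFAULT_LEN_MODEL))

    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_{i + 1}"
            for cond in self.conditions
            for i in range(self.n_per_condition)
        ]

    def condition_of(self, sample_id: str) -> str:
        return sample_id.rsplit("_", 1)[0]


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    sample_id: str
    feature_key: str
    sim_class: str
    category: str  # what the classifier should call it
    fragment_type: str
    ref_id: str
    start: int
    end: int


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    counts: pd.DataFrame  # realized feature x sample integer counts
    lib_factors: pd.Series
    features: list[SimFeature]
    reads: list[ReadTruth] = field(default_factory=list)

    def reads_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.reads])


def _truth_category(sim_class: str) -> tuple[str, str]:
    """Map a simulated class to the (category, fragment_type) the
    classifier is expected to report."""
    if sim_class in ("tRF_5p", "tRF_3p", "tRF_other"):
        return "tRNA", sim_class
    if sim_class == "whole_tRNA":
        return "tRNA", "whole"
    if sim_class.startswith("rsRNA:"):
        return "rsRNA", "NA"
    if sim_class == "miRNA":
        return "annotated_gene:miRNA", "NA"
    return "unannotated", "NA"


# ---------------------------------------------------------------------------
# default synthetic reference bundle


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))

def default_reference_bundle(seed: int = 20_07) -> ReferenceBundle:
    """A compact synthetic reference set (~5 kb total).

    Layout mirrors a real small-RNA reference: multi-copy tRNA decoders
    (identical copies, so their reads are decoder- but not transcript-
    specific), a histidine tRNA (G-1 rule), an intron-containing gene,
    two distinct 28S records collapsing to one subunit, rRNA repeat
    copies that are exact substrings of their subunit, miRNA genes, and
    unannotated background segments.
    """
    rng = np.random.default_rng(seed)
    decoders = [
        ("Gly", "GCC", 2, 72),
        ("Gly", "CCC", 1, 71),
        ("Glu", "TTC", 2, 72),
        ("Val", "CAC", 1, 73),
        ("His", "GTG", 1, 72),
        ("Lys", "CTT", 1, 74),
    ]
    genes = []
    for isotype, anticodon, n_copies, length in decoders:
        body = _random_seq(rng, length)
        for copy in range(1, n_copies + 1):
            genes.append(
                TRNAGeneRecord(
                    gene_id=f"tRNA-{isotype}-{anticodon}-{copy}",
                    isotype=isotype,
                    anticodon=anticodon,
                    genomic_seq=body,
                )
            )
    # one intron-containing gene: mature body is the spliced sequence
    arg_body = _random_seq(rng, 82)
    genes.append(
        TRNAGeneRecord(
            gene_id="tRNA-Arg-TCT-1",
            isotype="Arg",
            anticodon="TCT",
            genomic_seq=arg_body,
            intron_intervals=((38, 48),),
        )
    )
    s18 = _random_seq(rng, 600)
    s28a = _random_seq(rng, 800)
    s28b = _random_seq(rng, 800)
    s58 = _random_seq(rng, 150)
    s5 = _random_seq(rng, 120)
    mito = _random_seq(rng, 300)
    rrnas = [
        RRNAReference("rRNA-18S", "18S", False, s18),
        RRNAReference("rRNA-28S-a", "28S", False, s28a),
        RRNAReference("rRNA-28S-b", "28S", False, s28b),
        RRNAReference("rRNA-5.8S", "5.8S", False, s58),
        RRNAReference("rRNA-5S", "5S", False, s5),
        RRNAReference("rRNA-mito", "mito_rRNA", False, mito),
        # genomic repeat copies: exact substrings of their subunit
        RRNAReference("rRNA-18S-repeat1", "18S", True, s18[100:300]),
        RRNAReference("rRNA-5S-repeat1", "5S", True, s5[:90]),
    ]
    # a sizeable block of miRNA genes: individually low-abundance and
    # condition-stable, they anchor median-of-ratios normalization the
    # way the bulk of non-depleted features does in real libraries
    mirnas = [
        AnnotatedGene(f"mir-{i + 1}", "miRNA", _random_seq(rng, int(rng.integers(21, 24))))
        for i in range(60)
    ]
    background = [(f"bg-{i + 1}", _random_seq(rng, 400)) for i in range(3)]
    return build_reference_bundle(genes, rrnas, mirnas, background)


def default_sim_config(
    seed: int = 1,
    n_per_condition: int = 3,
    total_reads: int = 50_000,
    trf_log2fc: float = -2.0,
    rsrna_log2fc: float = -1.0,
    dispersion: float = 0.1,
    error_rate: float = 0.0,
) -> SimConfig:
    """The WT-vs-KO preset used throughout validation.

    Composition is tRF-dominant (~56% of WT reads), with 30% rsRNA,
    6% miRNA (spread over 60 stable genes, so null features hold the
    normalization median) and ~7.6% unannotated; the KO condition
    depletes every tRF-class feature by ``trf_log2fc`` and rsRNA
    features by ``rsrna_log2fc``, leaving miRNA and unannotated
    features unchanged.
    """
    spec: list[tuple[str, str, float, float]] = []
    for decoder, frac in [
        ("Gly-GCC", 0.20), ("Glu-TTC", 0.10), ("Val-CAC", 0.06),
        ("His-GTG", 0.05), ("Lys-CTT", 0.04),
    ]:
        spec.append((f"{decoder}_tRF_5p", "tRF_5p", frac, trf_log2fc))
    for decoder, frac in [("Gly-GCC", 0.04), ("Glu-TTC", 0.03), ("Arg-TCT", 0.02)]:
        spec.append((f"{decoder}_tRF_3p", "tRF_3p", frac, trf_log2fc))
    for decoder, frac in [("Gly-CCC", 0.01), ("Val-CAC", 0.01)]:
        spec.append((f"{decoder}_tRF_other", "tRF_other", frac, trf_log2fc))
    for decoder, frac in [("Gly-GCC", 0.002), ("His-GTG", 0.002)]:
        spec.append((f"{decoder}_whole", "whole_tRNA", frac, trf_log2fc))
    for subunit, frac in [
        ("18S", 0.10), ("28S", 0.12), ("5.8S", 0.03), ("5S", 0.03),
        ("mito_rRNA", 0.02),
    ]:
        spec.append((subunit, f"rsRNA:{subunit}", frac, rsrna_log2fc))
    for i in range(60):
        spec.append((f"mir-{i + 1}", "miRNA", 0.001, 0.0))
    for ref, frac in [("bg-1", 0.03), ("bg-2", 0.03), ("bg-3", 0.016)]:
        spec.append((f"unann-{ref}", "unannotated", frac, 0.0))
    features = []
    for key, sim_class, frac, lfc in spec:
        anchor = key.rsplit("_", 1)[0] if sim_class in (
            "tRF_5p", "tRF_3p", "tRF_other", "whole_tRNA"
        ) else (
            sim_class.split(":", 1)[1] if sim_class.startswith("rsRNA:")
            else (key.split("unann-")[-1] if sim_class == "unannotated" else key)
        )
        if sim_class == "tRF_other":
            anchor = key.rsplit("_tRF_other", 1)[0]
        elif sim_class in ("tRF_5p", "tRF_3p"):
            anchor = key.rsplit("_tRF", 1)[0]
        elif sim_class == "whole_tRNA":
            anchor = key.rsplit("_whole", 1)[0]
        features.append(
            SimFeature(
                feature_key=key,
                sim_class=sim_class,
                anchor=anchor,
                base_mean=frac * total_reads,
                dispersion=dispersion,
                log2fc=lfc,
            )
        )
    return SimConfig(
        seed=seed,
        features=features,
        n_per_condition=n_per_condition,
        error_rate=error_rate,
    )


# ---------------------------------------------------------------------------
# count model


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    """One draw from NB with Var = mu + alpha * mu^2 (alpha=0: Poisson)."""
    if alpha <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / alpha
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_counts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimTruth:
    """Draw the feature x sample count table and library factors.

    counts_gj ~ NB(base_mean_g * 2^(log2fc_g * [condition == KO])
    * lib_factor_j, dispersion_g); deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = config.sample_ids()
    lo, hi = config.lib_factor_range
    factors = pd.Series(
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples))),
        index=samples,
    )
    ko_label = config.conditions[1]
    data = {}
    for sample in samples:
        is_ko = config.condition_of(sample) == ko_label
        col = []
        for feat in config.features:
            mean = feat.base_mean * factors[sample]
            if is_ko:
                mean *= 2.0 ** feat.log2fc
            col.append(_nb_draw(rng, mean, feat.dispersion))
        data[sample] = col
    counts = pd.DataFrame(
        data, index=[f.feature_key for f in config.features], dtype=int
    )
    counts.index.name = "feature_key"
    return SimTruth(counts=counts, lib_factors=factors, features=list(config.features))


# ---------------------------------------------------------------------------
# fragment placement


def _rand_len(rng: np.random.Generator, lo: int, hi: int, cap: int) -> int:
    hi = min(hi, cap)
    if hi < lo:
        return -1
    return int(rng.integers(lo, hi + 1))


def draw_fragment(
    feature: SimFeature,
    bundle: ReferenceBundle,
    rng: np.random.Generator,
    len_model: dict | None = None,
    max_attempts: int = 100,
) -> tuple[str, str, int, int]:
    """Place one insert for ``feature`` on its reference.

    Returns (insert_seq, ref_id, start, end).  Positional constraints
    guarantee the classifier recovers the intended label: tRF_5p starts
    within 3 nt of the 5' end and ends >5 nt from the 3' end, tRF_3p
    symmetrically, whole within both tolerances, tRF_other outside both.
    """
    len_model = len_model or DEFAULT_LEN_MODEL
    cls = feature.sim_class
    for _ in range(max_attempts):
        if cls in TRF_CLASSES:
            candidates = [
                t for t in bundle.mature_trnas if t.decoder_key == feature.anchor
            ]
            if not candidates:
                raise ValueError(f"no mature tRNA for decoder {feature.anchor}")
            trna = candidates[int(rng.integers(len(candidates)))]
            L = len(trna.seq)
            if cls == "whole_tRNA":
                d5 = int(rng.integers(0, 4))
                d3 = int(rng.integers(0, 6))
                start, end = d5, L - d3
            elif cls == "tRF_5p":
                lo, hi = len_model["tRF_5p"]
                start = int(rng.integers(0, 4))
                n = _rand_len(rng, lo, hi, L - start - 6)
                if n < 0:
                    continue
                end = start + n
            elif cls == "tRF_3p":
                lo, hi = len_model["tRF_3p"]
                d3 = int(rng.integers(0, 6))
                n = _rand_len(rng, lo, hi, L - d3 - 4)
                if n < 0:
                    continue
                end = L - d3
                start = end - n
            else:  # tRF_other: outside both end tolerances
                lo, hi = len_model["tRF_other"]
                n = _rand_len(rng, lo, hi, L - 10)
                if n < 0:
                    continue
                start = int(rng.integers(4, L - 6 - n + 1))
                end = start + n
            return trna.seq[start:end], trna.transcript_id, start, end
        if cls.startswith("rsRNA:"):
            subunit = cls.split(":", 1)[1]
            refs = [r for r in bundle.rrnas if r.subunit == subunit]
            if not refs:
                raise ValueError(f"no rRNA reference for subunit {subunit}")
            ref = refs[int(rng.integers(len(refs)))]
            lo, hi = len_model["rsRNA"]
            n = _rand_len(rng, lo, hi, len(ref.seq))
            if n < 0:
                continue
            start = int(rng.integers(0, len(ref.seq) - n + 1))
            return ref.seq[start : start + n], ref.ref_id, start, start + n
        if cls == "miRNA":
            gene = bundle.gene_by_id[feature.anchor]
            return gene.seq, gene.ref_id, 0, len(gene.seq)
        if cls == "unannotated":
            ref_id = feature.anchor
            seq = dict(bundle.background)[ref_id]
            lo, hi = len_model["unannotated"]
            n = _rand_len(rng, lo, hi, len(seq))
            if n < 0:
                continue
            start = int(rng.integers(0, len(seq) - n + 1))
            return seq[start : start + n], ref_id, start, start + n
        raise ValueError(f"unknown sim class {cls!r}")
    raise ValueError(
        f"{feature.feature_key}: no valid fragment after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# read emission


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < error_rate:
            choices = [b for b in "ACGT" if b != c]
            chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


def build_raw_read(
    insert: str, umi: str, extra_base: str, adapter: str
) -> str:
    """Raw read layout: UMI + insert + untemplated base + adapter."""
    return umi + insert + extra_base + adapter


def simulate_run(
    config: SimConfig,
    bundle: ReferenceBundle,
    outdir: str | Path | None = None,
) -> SimTruth:
    """Full generator: counts, fragments, raw FASTQ per sample.

    With ``outdir`` set, writes ``<sample>.fastq.gz``, a sample sheet,
    the realized count table and the per-read truth TSV.  Deterministic:
    the same config yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = simulate_counts(config, rng)
    feat_by_key = {f.feature_key: f for f in config.features}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    for sample in config.sample_ids():
        reads = []
        serial = 0
        for feature_key, count in truth.counts[sample].items():
            feat = feat_by_key[feature_key]
            category, fragment_type = _truth_category(feat.sim_class)
            for _ in range(int(count)):
                insert, ref_id, start, end = draw_fragment(
                    feat, bundle, rng, config.read_len_model
                )
                umi = _random_seq(rng, config.umi_len)
                extra = str(rng.choice(BASES))
                raw = build_raw_read(insert, umi, extra, config.adapter)
                raw = _mutate(raw, rng, config.error_rate)
                read_id = f"{sample}:{serial}"
                serial += 1
                reads.append((read_id, raw, "I" * len(raw)))
                truth.reads.append(
                    ReadTruth(
                        read_id=read_id,
                        sample_id=sample,
                        feature_key=feature_key,
                        sim_class=feat.sim_class,
                        category=category,
                        fragment_type=fragment_type,
                        ref_id=ref_id,
                        start=start,
                        end=end,
                    )
                )
        if outdir is not None:
            write_fastq(reads, outdir / f"{sample}.fastq.gz")
    if outdir is not None:
        sheet = pd.DataFrame(
            {
                "sample_id": config.sample_ids(),
                "condition": [config.condition_of(s) for s in config.sample_ids()],
                "fastq": [str(outdir / f"{s}.fastq.gz") for s in config.sample_ids()],
            }
        )
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        truth.counts.to_csv(outdir / "truth_counts.tsv", sep="\t")
        truth.lib_factors.rename("lib_factor").to_csv(
            outdir / "truth_lib_factors.tsv", sep="\t"
        )
        truth.reads_frame().to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    return truth
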