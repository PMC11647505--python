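"""Synthetic read generator: count model, fragment placement, layout."""

import numpy as np
import pytest

from trfseq.preprocess import trim_read, RawRead, read_fastq
from trfseq.simulate import (
    SimConfig,
    SimFeature,
    _nb_draw,
    default_sim_config,
    draw_fragment,
    simulate_counts,
    simulate_run,
)


def small_config(seed=3, **kwargs):
    total = kwargs.pop("total_reads", 2000)
    return default_sim_config(seed=seed, total_reads=total, **kwargs)


def test_nb_draw_poisson_limit():
    """alpha=0 degenerates to Poisson: empirical mean within 3 SE."""
    rng = np.random.default_rng(0)
    draws = [_nb_draw(rng, 100.0, 0.0) for _ in range(10_000)]
    se = np.sqrt(100.0 / 10_000)
    assert abs(np.mean(draws) - 100.0) < 3 * se


def test_nb_draw_overdispersion():
    """Var = mu + alpha mu^2 at alpha=0.1, mu=100 -> SD ~ sqrt(1100)."""
    rng = np.random.default_rng(1)
    draws = np.array([_nb_draw(rng, 100.0, 0.1) for _ in range(20_000)])
    assert abs(draws.mean() - 100.0) < 4 * np.sqrt(1100 / 20_000)
    assert 1000 < draws.var() < 1210  # true 1100, generous MC band


def test_ko_fold_change_expected_mean():
    """log2fc=-2 quarters the KO mean."""
    feat = SimFeature("f", "miRNA", "mir-1", base_mean=400.0, dispersion=0.0,
                      log2fc=-2.0)
    config = SimConfig(seed=11, features=[feat], n_per_condition=200,
                       lib_factor_range=(1.0, 1.0))
    truth = simulate_counts(config)
    wt = truth.counts[[c for c in truth.counts if c.startswith("WT")]]
    ko = truth.counts[[c for c in truth.counts if c.startswith("KO")]]
    assert abs(wt.values.mean() - 400.0) < 4 * np.sqrt(400 / 200)
    assert abs(ko.values.mean() - 100.0) < 4 * np.sqrt(100 / 200)


def test_zero_samples_degenerate():
    config = SimConfig(seed=1, features=default_sim_config().features,
                       n_per_condition=0)
    truth = simulate_counts(config)
    assert truth.counts.shape[1] == 0
    assert truth.reads == []


@pytest.mark.parametrize("sim_class", ["tRF_5p", "tRF_3p", "tRF_other", "whole_tRNA"])
def test_fragment_placement_respects_classifier_margins(bundle, sim_class):
    """Generated tRNA inserts obey the positional rules of their label."""
    rng = np.random.default_rng(7)
    feat = SimFeature("f", sim_class, "Gly-GCC", base_mean=1.0)
    for _ in range(300):
        insert, ref_id, start, end = draw_fragment(feat, bundle, rng)
        trna = bundle.trna_by_id[ref_id]
        L = len(trna.seq)
        d5, d3 = start, L - end
        assert trna.seq[start:end] == insert
        if sim_class == "whole_tRNA":
            assert d5 <= 3 and d3 <= 5
        elif sim_class == "tRF_5p":
            assert d5 <= 3 and d3 > 5
        elif sim_class == "tRF_3p":
            assert d3 <= 5 and d5 > 3
        else:
            assert d5 > 3 and d3 > 5


def test_fragment_placement_other_classes(bundle):
    rng = np.random.default_rng(8)
    rs = SimFeature("f", "rsRNA:18S", "18S", base_mean=1.0)
    for _ in range(100):
        insert, ref_id, start, end = draw_fragment(rs, bundle, rng)
        ref = bundle.rrna_by_id[ref_id]
        assert ref.subunit == "18S"
        assert ref.seq[start:end] == insert
    mi = SimFeature("f", "miRNA", "mir-1", base_mean=1.0)
    insert, ref_id, start, end = draw_fragment(mi, bundle, rng)
    assert insert == bundle.gene_by_id["mir-1"].seq


def test_fragment_impossible_length_errors(tiny_bundle):
    feat = SimFeature("f", "tRF_5p", "Gly-GCC", base_mean=1.0)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="attempts"):
        draw_fragment(feat, tiny_bundle, rng, len_model={"tRF_5p": (500, 600)})


def test_same_seed_byte_identical_fastq(tmp_path, bundle):
    config = small_config(seed=21)
    simulate_run(config, bundle, tmp_path / "a")
    simulate_run(config, bundle, tmp_path / "b")
    for sample in config.sample_ids():
        a = (tmp_path / "a" / f"{sample}.fastq.gz").read_bytes()
        b = (tmp_path / "b" / f"{sample}.fastq.gz").read_bytes()
        assert a == b


def test_truth_matches_emitted_reads(tmp_path, bundle):
    """Each FASTQ record has exactly one truth record; counts add up."""
    config = small_config(seed=22)
    truth = simulate_run(config, bundle, tmp_path)
    truth_ids = [r.read_id for r in truth.reads]
    assert len(truth_ids) == len(set(truth_ids))
    assert len(truth_ids) == int(truth.counts.values.sum())
    sample = config.sample_ids()[0]
    fastq_ids = [r.read_id for r in read_fastq(tmp_path / f"{sample}.fastq.gz")]
    assert fastq_ids == [r.read_id for r in truth.reads if r.sample_id == sample]


def test_emitted_layout_inverts_under_trimming(tmp_path, bundle):
    """Error-free raw reads round-trip: trim recovers the true insert."""
    config = small_config(seed=23)
    truth = simulate_run(config, bundle, tmp_path)
    truth_by_id = {r.read_id: r for r in truth.reads}
    ref_seq = {rid: seq for rid, _, seq in bundle.iter_refs()}
    sample = config.sample_ids()[0]
    for raw in read_fastq(tmp_path / f"{sample}.fastq.gz"):
        t = truth_by_id[raw.read_id]
        expected = ref_seq[t.ref_id][t.start : t.end]
        read = trim_read(RawRead(raw.read_id, raw.seq, raw.qual or "I" * len(raw.seq)))
        assert read.insert_seq == expected


def test_class_composition_matches_mixture(tmp_path, bundle):
    """Truth label fractions track configured read-mass fractions."""
    config = small_config(seed=24, total_reads=20_000)
    truth = simulate_run(config, bundle, tmp_path)
    frame = truth.reads_frame()
    wt = frame[frame.sample_id.str.startswith("WT")]
    trf_frac = wt.sim_class.isin(["tRF_5p", "tRF_3p", "tRF_other"]).mean()
    # configured tRF read mass is 56% of WT; NB noise + library factors
    # leave a few points of slack
    assert 0.48 < trf_frac < 0.64
    rs_frac = wt.sim_class.str.startswith("rsRNA").mean()
    assert 0.24 < rs_frac < 0.36
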