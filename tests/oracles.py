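"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by a different route than the
implementation: exhaustive numpy sliding-window search instead of the
pigeonhole index, and a literal restatement of the fragment-typing
rules instead of the classifier's control flow.
"""

import numpy as np

from trfseq.classify import ClassifierParams
from trfseq.mapper import revcomp


def brute_force_hits(insert, bundle, max_mismatches):
    """Exhaustive Hamming search over every reference window and strand;
    returns the set of (ref_id, start, strand, distance) best hits."""
    out = []
    for ref_id, ref_class, seq in bundle.iter_refs():
        if len(seq) < len(insert):
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        win = np.lib.stride_tricks.sliding_window_view(arr, len(insert))
        for strand, q in (("+", insert), ("-", revcomp(insert))):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            dists = (win != qa).sum(axis=1)
            for start in np.nonzero(dists <= max_mismatches)[0]:
                out.append((ref_id, int(start), strand, int(dists[start])))
    if not out:
        return set()
    dmin = min(d for *_, d in out)
    return {h for h in out if h[3] == dmin}


def brute_force_fragment_type(start, end, length, params=ClassifierParams()):
    """Literal restatement of the positional typing rules."""
    d5, d3 = start, length - end
    if d5 <= params.whole_5p_tol and d3 <= params.whole_3p_tol:
        return "whole"
    if d5 <= params.end5_tol:
        return "tRF_5p"
    if d3 <= params.end3_tol:
        return "tRF_3p"
    return "tRF_other"
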