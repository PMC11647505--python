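import numpy as np
import pytest

from trfseq.references import (
    AnnotatedGene,
    RRNAReference,
    TRNAGeneRecord,
    build_reference_bundle,
)
from trfseq.simulate import default_reference_bundle


@pytest.fixture(scope="session")
def bundle():
    """The package's default synthetic reference bundle (~6 kb)."""
    return default_reference_bundle()


@pytest.fixture(scope="session")
def tiny_bundle():
    """A hand-built bundle with known sequences for targeted cases.

    Two identical Gly-GCC copies, one Gly-CCC, one Val-CAC, one His;
    one 5S rRNA with an exact-substring repeat; one miRNA gene; one
    background segment.
    """
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))

    def seq(n):
        return "".join(rng.choice(bases, size=n))

    gly = seq(70)
    genes = [
        TRNAGeneRecord("Gly-GCC-1", "Gly", "GCC", gly),
        TRNAGeneRecord("Gly-GCC-2", "Gly", "GCC", gly),
        TRNAGeneRecord("Gly-CCC-1", "Gly", "CCC", seq(70)),
        TRNAGeneRecord("Val-CAC-1", "Val", "CAC", seq(73)),
        TRNAGeneRecord("His-GTG-1", "His", "GTG", seq(72)),
    ]
    s5 = seq(120)
    rrnas = [
        RRNAReference("5S", "5S", False, s5),
        RRNAReference("5S-rep", "5S", True, s5[10:100]),
        RRNAReference("18S", "18S", False, seq(300)),
    ]
    mirnas = [AnnotatedGene("mir-x", "miRNA", seq(22))]
    background = [("bg", seq(300))]
    return build_reference_bundle(genes, rrnas, mirnas, background)
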