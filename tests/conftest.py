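import numpy as np
import pytest

from immunoprog.repertoire import CloneRecord, CloneTable, assign_chain, assign_isotype

_CHAIN_GENES = {
    "IGH": (["IGHV3-23"], ["IGHJ4"]),
    "IGK": (["IGKV1-5"], ["IGKJ2"]),
    "IGL": (["IGLV2-14"], ["IGLJ2"]),
    "TRA": (["TRAV17"], ["TRAJ50"]),
    "TRB": (["TRBV5-1"], ["TRBJ2-5"]),
    "TRG": (["TRGV9"], ["TRGJ1"]),
    "TRD": (["TRDV1"], ["TRDJ1"]),
}


def make_clone(count, chain="IGK", cdr3=None, c_hits=None):
    """An assigned CloneRecord on the requested chain."""
    v, j = _CHAIN_GENES[chain]
    clone = CloneRecord(
        cdr3_nt=cdr3 or ("ACG" * 9),
        read_count=count,
        v_hits=list(v),
        j_hits=list(j),
        c_hits=list(c_hits or []),
    )
    assign_chain(clone)
    assign_isotype(clone)
    return clone


def make_table(counts, chain="IGK", total_mapped_reads=10_000):
    """A single-chain CloneTable with the given read counts, distinct CDR3s."""
    base = "ACGTACGTACGTACGTACGTACGT"
    digits = str.maketrans("0123", "ACGT")
    clones = [
        make_clone(c, chain=chain, cdr3=base + np.base_repr(i + 4, base=4).translate(digits))
        for i, c in enumerate(counts)
    ]
    return CloneTable("sample", clones, total_mapped_reads)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
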