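import numpy as np
import pytest

from midecay.corpus import TokenStream


@pytest.fixture
def alternating_stream():
    """Deterministic ABAB... stream of length 1000."""
    return TokenStream(tuple("AB" * 500))


@pytest.fixture
def iid_stream():
    """iid uniform 10-symbol stream of length 2000, fixed seed."""
    rng = np.random.default_rng(42)
    return TokenStream(tuple(f"s{i}" for i in rng.integers(0, 10, 2000)))


@pytest.fixture
def corpus_tsv(tmp_path):
    """Small two-individual corpus file in the canonical TSV schema."""
    rows = [
        "individual\tsequence_id\tcollection_index\torder\tmanipulation\tobject\tnut_episode",
        "amy\tseqB\t2\t0\tGrasp\tNut\tn1",
        "amy\tseqB\t2\t1\tPlace\tNut\tn1",
        "amy\tseqB\t2\t2\tStrike\tHammer\tn1",
        "amy\tseqA\t1\t0\tgrasp\tnut\tn2",
        "amy\tseqA\t1\t1\teat\tkernel\tn2",
        "ben\tseq1\t1\t0\tstrike\thammer\t",
        "ben\tseq1\t1\t1\tstrike\thammer\t",
        "ben\tseq1\t1\t2\teat\tkernel\t",
    ]
    path = tmp_path / "corpus.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path
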