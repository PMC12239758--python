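import gzip
from pathlib import Path

import numpy as np
import pytest

from kmersig import enumerate_kmers


@pytest.fixture(scope="session")
def spec3():
    return enumerate_kmers(3)


@pytest.fixture
def write_fastq(tmp_path):
    """Factory writing a FASTQ (optionally gzipped) from a list of sequences."""

    def _write(seqs, name="reads.fastq", gz=False, qual_char="I"):
        records = []
        for i, s in enumerate(seqs):
            records.append(f"@r{i}\n{s}\n+\n{qual_char * len(s)}\n")
        payload = "".join(records)
        path = tmp_path / (name + (".gz" if gz and not name.endswith(".gz") else ""))
        if gz:
            with gzip.open(path, "wt") as fh:
                fh.write(payload)
        else:
            path.write_text(payload)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
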