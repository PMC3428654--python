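"""Shared fixtures: an independent brute-force repeat scanner and small
reusable inputs."""

import numpy as np
import pytest

from ssrmine import TranscriptRecord


def _primitive(motif: str) -> bool:
    # independent of the package's doubling-trick implementation
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def brute_force_perfect(seq, unit_sizes=range(1, 7), min_tract_bp=0):
    """Enumerate maximal perfect tandem runs by testing every start position
    and unit size directly on the string.

    Returns a set of (start, end, motif) triples. A run is reported at the
    first position of its repeat region: the base immediately to the left
    must not continue the periodicity.
    """
    n = len(seq)
    out = set()
    for k in unit_sizes:
        for i in range(n - 2 * k + 1):
            motif = seq[i : i + k]
            if "N" in motif or not _primitive(motif):
                continue
            c = 1
            while seq[i + c * k : i + (c + 1) * k] == motif:
                c += 1
            if c < 2:
                continue
            if i > 0 and seq[i - 1] != "N" and seq[i - 1] == seq[i - 1 + k]:
                continue  # region extends left; not the anchor
            if c * k >= min_tract_bp:
                out.add((i, i + c * k, motif))
    return out


@pytest.fixture
def perfect_oracle():
    return brute_force_perfect


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_record(rng, length, rec_id="t", p=(0.3, 0.2, 0.2, 0.3)):
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    return TranscriptRecord(rec_id, "".join(bases))


@pytest.fixture
def make_random_record():
    return random_record
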