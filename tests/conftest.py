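import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from periscan.seqio import Alphabet, ParameterSet
from periscan.simrep import SyntheticRepeatSpec, generate

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DNA = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def dna_params() -> ParameterSet:
    return ParameterSet.dna()


@pytest.fixture(scope="session")
def protein_params() -> ParameterSet:
    return ParameterSet.protein()


def random_seq(rng: np.random.Generator, alphabet: Alphabet, n: int) -> str:
    letters = DNA if alphabet is Alphabet.NUCLEOTIDE else AA
    return "".join(rng.choice(list(letters), size=n))


def _is_primitive(unit: str) -> bool:
    """True when no proper cyclic shift maps the unit onto itself."""
    doubled = unit + unit
    return doubled.find(unit, 1, len(doubled) - 1) == -1


def _max_shift_match_run(unit: str, k: int) -> int:
    """Longest circular run of positions matching under any proper shift."""
    u = len(unit)
    worst = 0
    for shift in range(1, u):
        run = best = 0
        for j in range(2 * u):
            if unit[j % u] == unit[(j + shift) % u]:
                run = min(run + 1, u)
                best = max(best, run)
            else:
                run = 0
        worst = max(worst, best)
    return worst


def _flanks_clean(seq: str, region: tuple[int, int], k: int, w: int) -> bool:
    """No repeated k-mer within window range outside the planted region."""
    positions: dict[str, int] = {}
    t0, t1 = region
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        prev = positions.get(kmer)
        if prev is not None and i - prev < w:
            if not (t0 <= prev and i + k <= t1):
                return False
        positions[kmer] = i
    return True


def clean_tandem_fixture(unit_size: int, copies: int, seed_base: int,
                         alphabet: Alphabet = Alphabet.NUCLEOTIDE):
    """Tandem-repeat fixture whose ground truth is unambiguous.

    Validity is a property of the generated input, checked by direct string
    inspection before any detection runs: the unit is primitive (no proper
    cyclic symmetry and no shift self-match long enough to carry a k-mer),
    the flank letters adjacent to the array do not extend the periodicity,
    and the flanks contain no repeated k-mer within window range that could
    chain into the region.  Seeds advance deterministically until these
    hold.
    """
    params = ParameterSet.for_alphabet(alphabet)
    k, w = params.kmer_size, params.window_size
    for attempt in range(200):
        spec = SyntheticRepeatSpec(alphabet=alphabet, unit=unit_size,
                                   copies=copies, seed=seed_base + attempt)
        record, truth = generate(spec)
        unit = truth.unit_consensus
        if not _is_primitive(unit):
            continue
        if unit_size > k and _max_shift_match_run(unit, k) >= k:
            continue
        t0, t1 = truth.region
        seq = record.sequence
        if seq[t0 - 1] == unit[-1] or seq[t1] == unit[0]:
            continue
        if not _flanks_clean(seq, truth.region, k, w):
            continue
        return record, truth
    raise RuntimeError("no valid fixture found in 200 attempts")
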