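import numpy as np
import pytest
from hypothesis import settings

from capskit import caps, snp_caller, synth
from capskit.core import IUPAC_CODES, RestrictionEnzyme
from capskit.io import default_enzyme_table

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return synth.make_reference_panel(seed=0)


@pytest.fixture(scope="session")
def homolog_groups(panel):
    return snp_caller.build_diagnostic_signatures(panel)


@pytest.fixture(scope="session")
def enzymes():
    return {e.name: e for e in default_enzyme_table()}


@pytest.fixture(scope="session")
def amplicon_fixtures():
    return synth.make_amplicon_fixtures(seed=11)


@pytest.fixture(scope="session")
def designed_assays(amplicon_fixtures):
    fix = amplicon_fixtures
    return {
        1: caps.design_caps(fix.locus1_wt, fix.locus1_mut, fix.enzymes)[0],
        2: caps.design_caps(fix.locus2_wt, fix.locus2_mut, fix.enzymes)[0],
    }


def brute_force_cuts(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Independent site scanner: position-by-position degenerate
    comparison on both strands, same cut-mirroring convention."""
    from capskit.core import reverse_complement

    site = enzyme.recognition
    length = len(site)
    n = len(seq)

    def windows(s):
        hits = set()
        for i in range(len(s) - length + 1):
            if all(s[i + k] in IUPAC_CODES[site[k]] for k in range(length)):
                hits.add(i)
        return hits

    fwd = windows(seq)
    rev = {n - length - j for j in windows(reverse_complement(seq))}
    cuts = {i + enzyme.cut_offset for i in fwd}
    cuts |= {i + length - enzyme.cut_offset for i in rev - fwd}
    return sorted(c for c in cuts if 0 < c < n)


def random_enzyme(rng: np.random.Generator) -> RestrictionEnzyme:
    codes = list(IUPAC_CODES)
    length = int(rng.integers(4, 9))
    recognition = "".join(rng.choice(codes, size=length))
    return RestrictionEnzyme(
        name=f"rand_{recognition}",
        recognition=recognition,
        cut_offset=int(rng.integers(0, length + 1)),
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
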