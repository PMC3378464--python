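import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from nucstruct.profiles import StructuralProfile
from nucstruct.scales import StructuralScale, load_scales


@pytest.fixture(scope="session")
def all_scales():
    return load_scales()


@pytest.fixture
def gc_scale():
    """Toy dinucleotide scale: value = number of G/C bases in the step."""
    values = {
        a + b: float((a in "GC") + (b in "GC"))
        for a in "ACGT"
        for b in "ACGT"
    }
    return StructuralScale(
        name="gc_count", k=2, values=values, sign_class="positive"
    )


@pytest.fixture
def neg_scale(gc_scale):
    return StructuralScale(
        name="gc_neg", k=2, values=gc_scale.values, sign_class="negative"
    )


def make_profile(values, step_bp=10, window_bp=100, chrom="chrT", feature="f"):
    return StructuralProfile(
        chrom=chrom,
        values=np.asarray(values, dtype=float),
        origin_bp=0,
        step_bp=step_bp,
        window_bp=window_bp,
        feature=feature,
    )


@pytest.fixture
def profile_factory():
    return make_profile
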