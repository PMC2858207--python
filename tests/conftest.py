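import numpy as np
import pytest

import mitorho as m


@pytest.fixture(scope="session")
def ref():
    return m.load_packaged_reference()


@pytest.fixture(scope="session")
def rules(ref):
    return m.load_packaged_motif_rules(ref)


@pytest.fixture
def P(ref):
    """Shorthand: canonical label -> Variant."""
    return lambda lab: m.parse_variant(lab, ref)


def random_variant(rng: np.random.Generator, ref, kinds=("transition", "transversion", "insertion", "deletion")):
    """One random well-formed variant whose 3'-most normal form is itself."""
    from mitorho.variants import TRANSITION_PARTNER, Variant

    while True:
        pos = int(rng.integers(1, 16568))
        kind = kinds[int(rng.integers(len(kinds)))]
        refbase = ref.base(pos)
        if kind == "transition":
            return Variant(pos, "transition", TRANSITION_PARTNER[refbase])
        if kind == "transversion":
            options = [b for b in "ACGT" if b not in (refbase, TRANSITION_PARTNER[refbase])]
            return Variant(pos, "transversion", options[int(rng.integers(2))])
        if kind == "deletion":
            if ref.base(pos + 1) != refbase:
                return Variant(pos, "deletion")
            continue
        options = [b for b in "ACGT" if b != ref.base(pos + 1)]
        return Variant(pos, "insertion", options[int(rng.integers(len(options)))], 1)


def random_variant_set(rng, ref, n, min_spacing=4, **kw):
    """A conflict-free random variant set with positions spaced apart."""
    out = {}
    while len(out) < n:
        v = random_variant(rng, ref, **kw)
        if all(abs(v.position - p) >= min_spacing for p in out):
            out[v.position] = v
    return frozenset(out.values())
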