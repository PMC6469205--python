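import pytest

from framefix.fsalign import ScoringScheme
from framefix.taxbin import Taxonomy


@pytest.fixture(scope="session")
def scheme():
    """Default scoring scheme, shared so numba compiles once per session."""
    return ScoringScheme()


@pytest.fixture()
def taxonomy():
    """root -> phylum p1 -> genera g1,g2 -> species sA,sB (g1), sC (g2)."""
    rows = [
        ("root", "root", "no rank", "root"),
        ("p1", "root", "phylum", "Phylum one"),
        ("g1", "p1", "genus", "Genus one"),
        ("g2", "p1", "genus", "Genus two"),
        ("sA", "g1", "species", "Species A"),
        ("sB", "g1", "species", "Species B"),
        ("sC", "g2", "species", "Species C"),
    ]
    return Taxonomy(rows)
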