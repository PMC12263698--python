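import numpy as np
import pytest

from tumevo.deconvolution import CloneSet
from tumevo.io_formats import MutationProfile, SignatureCatalog
from tumevo.phylogeny import build_clone_phylogeny


def make_profile(alt, ref, sample_names=None, tri=None):
    """Build a small MutationProfile from alt/ref count matrices."""
    alt = np.asarray(alt, dtype=np.int64)
    ref = np.asarray(ref, dtype=np.int64)
    n, s = alt.shape
    sample_names = sample_names or [f"T{i + 1}" for i in range(s)]
    return MutationProfile(
        snv_ids=[f"S{i + 1}" for i in range(n)],
        ref_base=["C"] * n,
        alt_base=["T"] * n,
        trinucleotide=(tri or ["ACA"] * n),
        sample_names=sample_names,
        ref_count=ref,
        alt_count=alt,
    )


@pytest.fixture
def uniform_catalog():
    probs = np.full((96, 1), 1.0 / 96.0)
    return SignatureCatalog(["FLAT"], probs).validate()


@pytest.fixture
def two_peak_catalog():
    """Two well-separated synthetic signatures."""
    rng = np.random.default_rng(7)
    probs = np.zeros((96, 2))
    probs[:48, 0] = rng.dirichlet(np.ones(48))
    probs[48:, 1] = rng.dirichlet(np.ones(48))
    return SignatureCatalog(["P1", "P2"], probs).validate()


@pytest.fixture
def cherry_phylogeny():
    """((a,b),(c,d)) perfect phylogeny: trunk + 2 internal + 4 terminal
    branches, one mutation each (7 SNVs)."""
    #            t  ab cd a  b  c  d
    genotypes = {
        "a": np.array([1, 1, 0, 1, 0, 0, 0], dtype=np.uint8),
        "b": np.array([1, 1, 0, 0, 1, 0, 0], dtype=np.uint8),
        "c": np.array([1, 0, 1, 0, 0, 1, 0], dtype=np.uint8),
        "d": np.array([1, 0, 1, 0, 0, 0, 1], dtype=np.uint8),
    }
    snvs = ["t", "ab", "cd", "a", "b", "c", "d"]
    return build_clone_phylogeny(genotypes, snvs)


def clone_set_from(phylo, f, sample_names):
    names = sorted(phylo.clone_names())
    M = np.array([phylo.genotypes[c] for c in names])
    return CloneSet(
        M=M,
        f=np.asarray(f, dtype=float),
        clone_names=names,
        snv_ids=list(phylo.snv_ids),
        sample_names=list(sample_names),
    )
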