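import numpy as np
import pytest

from tumevo.io_formats import SignatureCatalog
from tumevo.phylogeny import MutationTree
from tumevo.signatures import (
    BranchSpectrum,
    SignatureParams,
    cosine,
    filter_spurious,
    fit_branches,
    harmonize_across_branches,
    refit_qp,
    spectrum_from_mutations,
)

from oracles import oracle_two_signature_grid


def chain_mtree(n=3):
    mtree = MutationTree()
    for i in range(n):
        mtree.nodes.append({"id": f"G{i + 1}", "branch": f"b{i + 1}",
                            "count": 0, "snvs": [], "drivers": []})
        if i:
            mtree.edges.append((f"G{i}", f"G{i + 1}"))
    return mtree


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def test_pyrimidine_mutation_counted():
    spec = spectrum_from_mutations([("C", "A", "ACA")])
    assert spec.counts[0] == 1 and spec.counts.sum() == 1


def test_purine_mutation_strand_normalized():
    a = spectrum_from_mutations([("C", "A", "ACA")])
    b = spectrum_from_mutations([("G", "T", "TGT")])
    np.testing.assert_array_equal(a.counts, b.counts)


def test_counts_sum_to_mutations():
    rng = np.random.default_rng(0)
    from tumevo.channels import channel_to_mutation
    muts = [channel_to_mutation(int(c)) for c in rng.integers(0, 96, size=10)]
    assert spectrum_from_mutations(muts).counts.sum() == 10


def test_bad_context_rejected():
    with pytest.raises(ValueError):
        spectrum_from_mutations([("C", "A", "ATA")])


# ---------------------------------------------------------------------------
# refit_qp
# ---------------------------------------------------------------------------


def test_pure_signature_recovered(two_peak_catalog):
    counts = np.rint(two_peak_catalog.probs[:, 0] * 10000)
    acts = refit_qp(counts, two_peak_catalog)
    assert acts["P1"] == pytest.approx(1.0, abs=1e-4)


def test_noiseless_mixture_recovered_exactly(two_peak_catalog):
    mix = 0.7 * two_peak_catalog.probs[:, 0] + 0.3 * two_peak_catalog.probs[:, 1]
    acts = refit_qp(mix * 1e6, two_peak_catalog)
    assert acts["P1"] == pytest.approx(0.7, abs=1e-6)
    assert acts["P2"] == pytest.approx(0.3, abs=1e-6)


def test_multinomial_sample_matches_grid_oracle(two_peak_catalog):
    rng = np.random.default_rng(1)
    mix = 0.5 * two_peak_catalog.probs[:, 0] + 0.5 * two_peak_catalog.probs[:, 1]
    counts = rng.multinomial(500, mix)
    acts = refit_qp(counts, two_peak_catalog)
    oracle = oracle_two_signature_grid(two_peak_catalog.probs, counts)
    assert abs(acts["P1"] - oracle) < 0.02  # same optimum as the 0.01 grid
    assert abs(acts["P1"] - 0.5) < 0.1


def test_activities_on_simplex(two_peak_catalog):
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 30, size=96)
    acts = refit_qp(counts, two_peak_catalog)
    vals = np.array(list(acts.values()))
    assert (vals >= 0).all()
    assert vals.sum() == pytest.approx(1.0, abs=1e-9)


def test_empty_spectrum_flagged(two_peak_catalog):
    mtree = chain_mtree(1)
    spec = BranchSpectrum("G1", np.zeros(96, dtype=np.int64))
    acts = fit_branches([spec], two_peak_catalog, mtree)
    assert "no_mutations" in acts[0].flags
    assert sum(acts[0].activities.values()) == 0.0


# ---------------------------------------------------------------------------
# filter_spurious
# ---------------------------------------------------------------------------


def test_zero_activity_signature_dropped(two_peak_catalog):
    counts = np.rint(two_peak_catalog.probs[:, 0] * 5000)
    retained, acts, _ = filter_spurious(counts, two_peak_catalog)
    assert retained == {"P1"}


def test_collinear_pair_reduced_to_one():
    rng = np.random.default_rng(3)
    base = rng.dirichlet(np.ones(96))
    near = 0.97 * base + 0.03 * rng.dirichlet(np.ones(96))
    cat = SignatureCatalog(["A", "B"], np.column_stack([base, near])).validate()
    assert cosine(cat.probs[:, 0], cat.probs[:, 1]) > 0.95
    counts = rng.multinomial(2000, base)
    retained, _, cos_v = filter_spurious(counts, cat, epsilon_cos=0.01)
    assert len(retained) == 1


def test_epsilon_zero_keeps_fit_unchanged(two_peak_catalog):
    mix = 0.6 * two_peak_catalog.probs[:, 0] + 0.4 * two_peak_catalog.probs[:, 1]
    counts = np.rint(mix * 1e5)
    retained, acts, cos_v = filter_spurious(counts, two_peak_catalog,
                                            epsilon_cos=0.0)
    # both signatures genuinely contribute: dropping either changes the fit
    assert retained == {"P1", "P2"}


def test_cosine_never_below_budget(two_peak_catalog):
    rng = np.random.default_rng(4)
    for _ in range(5):
        counts = rng.integers(0, 40, size=96)
        if counts.sum() == 0:
            continue
        sub = two_peak_catalog
        _, full_acts = None, refit_qp(counts, sub)
        recon = sub.probs @ np.array([full_acts[n] for n in sub.signature_names])
        full_cos = cosine(recon, counts / counts.sum())
        _, _, cos_v = filter_spurious(counts, sub, epsilon_cos=0.01)
        assert cos_v >= full_cos - 0.01 - 1e-9


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _mixture_counts(catalog, weights, n, rng):
    mix = catalog.probs @ np.asarray(weights)
    return rng.multinomial(n, mix / mix.sum())


def three_sig_catalog():
    rng = np.random.default_rng(8)
    probs = np.zeros((96, 3))
    probs[:32, 0] = rng.dirichlet(np.ones(32))
    probs[32:64, 1] = rng.dirichlet(np.ones(32))
    probs[64:, 2] = rng.dirichlet(np.ones(32))
    return SignatureCatalog(["X", "Y", "Z"], probs).validate()


def test_identical_retained_sets_fixed_point():
    cat = three_sig_catalog()
    rng = np.random.default_rng(5)
    mtree = chain_mtree(3)
    spectra = [
        BranchSpectrum(f"G{i + 1}", _mixture_counts(cat, [0.6, 0.4, 0.0], 400, rng))
        for i in range(3)
    ]
    acts = fit_branches(spectra, cat, mtree)
    out, log = harmonize_across_branches(mtree, acts, spectra, cat)
    assert log == []
    for before, after in zip(acts, out):
        assert before.retained == after.retained
        assert before.activities == after.activities


def test_isolated_weak_signature_removed():
    cat = three_sig_catalog()
    rng = np.random.default_rng(6)
    mtree = chain_mtree(3)
    spectra = [
        BranchSpectrum("G1", _mixture_counts(cat, [0.6, 0.4, 0.0], 500, rng)),
        BranchSpectrum("G2", _mixture_counts(cat, [0.57, 0.38, 0.05], 500, rng)),
        BranchSpectrum("G3", _mixture_counts(cat, [0.6, 0.4, 0.0], 500, rng)),
    ]
    acts = fit_branches(spectra, cat, mtree, SignatureParams(isolation_threshold=0.10))
    # force the constructed case: the middle branch retains an isolated
    # 5%-activity signature that its neighbors lack
    mid = [a for a in acts if a.branch == "G2"][0]
    mid.retained = {"X", "Y", "Z"}
    mid.activities = {"X": 0.57, "Y": 0.38, "Z": 0.05}
    out, log = harmonize_across_branches(mtree, acts, spectra, cat)
    mid_after = [a for a in out if a.branch == "G2"][0]
    assert "Z" not in mid_after.retained
    assert any(e["removed"] == "Z" for e in log)


def test_isolated_strong_signature_kept():
    cat = three_sig_catalog()
    rng = np.random.default_rng(7)
    mtree = chain_mtree(3)
    spectra = [
        BranchSpectrum("G1", _mixture_counts(cat, [0.6, 0.4, 0.0], 500, rng)),
        BranchSpectrum("G2", _mixture_counts(cat, [0.2, 0.2, 0.6], 500, rng)),
        BranchSpectrum("G3", _mixture_counts(cat, [0.6, 0.4, 0.0], 500, rng)),
    ]
    acts = fit_branches(spectra, cat, mtree)
    out, log = harmonize_across_branches(mtree, acts, spectra, cat)
    mid_after = [a for a in out if a.branch == "G2"][0]
    assert "Z" in mid_after.retained  # 60% activity: signal too strong to prune


def test_small_branch_inherits_parent_set():
    cat = three_sig_catalog()
    rng = np.random.default_rng(9)
    mtree = chain_mtree(2)
    spectra = [
        BranchSpectrum("G1", _mixture_counts(cat, [0.6, 0.4, 0.0], 500, rng)),
        BranchSpectrum("G2", _mixture_counts(cat, [0.6, 0.4, 0.0], 10, rng)),
    ]
    acts = fit_branches(spectra, cat, mtree,
                        SignatureParams(min_branch_mutations=20))
    small = [a for a in acts if a.branch == "G2"][0]
    parent = [a for a in acts if a.branch == "G1"][0]
    assert "low_confidence" in small.flags
    assert small.retained == parent.retained


def test_flat_vs_peaked_confounding_is_surfaced():
    # an SBS3-like flat column and an SBS8-like peaked column sharing the
    # dominant channels: retained sets flip between branches, but cosine
    # and spectra are reported so the instability is visible
    rng = np.random.default_rng(10)
    flat = np.full(96, 1.0 / 96.0)
    peaked = np.full(96, 0.2 / 92)
    peaked[:4] = 0.8 / 4  # shares its dominant channels with `flat` support
    cat = SignatureCatalog(["FLATY", "PEAKY"],
                           np.column_stack([flat, peaked])).validate()
    mtree = chain_mtree(4)
    spectra = [
        BranchSpectrum(f"G{i + 1}",
                       rng.multinomial(300, 0.5 * flat + 0.5 * peaked))
        for i in range(4)
    ]
    acts = fit_branches(spectra, cat, mtree)
    for a in acts:
        assert 0.0 <= a.fit_cosine <= 1.0  # fit quality is always exposed
        assert a.activities
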