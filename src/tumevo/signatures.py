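"""Branch-specific mutational signature analysis.

Builds a 96-channel spectrum per mutational-tree branch, refits catalog
signature activities by simplex-constrained quadratic programming,
removes spurious low-activity signatures by backward elimination against
a cosine-similarity budget, and harmonizes retained sets across
neighboring branches (signature gains/losses are assumed rare, so a
weak signature isolated to one branch is treated as noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import channel_index
from .io_formats import SignatureCatalog
from .optim import simplex_lsq
from .phylogeny import MutationTree


@dataclass
class SignatureParams:
    epsilon_cos: float = 0.01
    isolation_threshold: float = 0.10
    min_branch_mutations: int = 20


@dataclass
class BranchSpectrum:
    branch: str
    counts: np.ndarray  # 96 non-negative ints, canonical channel order
    driver_channels: list[int] = field(default_factory=list)


@dataclass
class SignatureActivity:
    branch: str
    activities: dict[str, float]
    retained: set[str]
    fit_cosine: float
    flags: set[str] = field(default_factory=set)


def spectrum_from_mutations(
    snvs: list[tuple[str, str, str]], branch: str = ""
) -> BranchSpectrum:
    """Accumulate (ref, alt, trinucleotide) mutations into 96 channels.

    Purine-reference SNVs are strand-normalized onto the pyrimidine
    channel (handled by :func:`channels.channel_index`).
    """
    counts = np.zeros(96, dtype=np.int64)
    for ref, alt, tri in snvs:
        counts[channel_index(ref, alt, tri)] += 1
    return BranchSpectrum(branch=branch, counts=counts)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def refit_qp(counts: np.ndarray, catalog: SignatureCatalog) -> dict[str, float]:
    """Activities minimizing ||C a - s||^2 over the probability simplex,
    where s is the spectrum normalized to sum 1."""
    total = counts.sum()
    if total == 0:
        return {name: 0.0 for name in catalog.signature_names}
    s = counts / total
    a = simplex_lsq(catalog.probs, s, sum_to_one=True)
    return dict(zip(catalog.signature_names, a))


def _fit(counts: np.ndarray, catalog: SignatureCatalog, names: list[str]):
    sub = catalog.subset(names)
    acts = refit_qp(counts, sub)
    recon = sub.probs @ np.array([acts[n] for n in names])
    return acts, cosine(recon, counts / counts.sum())


def filter_spurious(
    counts: np.ndarray,
    catalog: SignatureCatalog,
    epsilon_cos: float = 0.01,
) -> tuple[set[str], dict[str, float], float]:
    """Backward elimination of spurious signatures.

    Repeatedly drops the lowest-activity signature and refits; a drop is
    accepted while the reconstruction cosine stays within ``epsilon_cos``
    of the full-catalog fit.  Returns (retained set, activities, cosine).
    """
    names = list(catalog.signature_names)
    acts, full_cos = _fit(counts, catalog, names)
    cur_cos = full_cos
    while len(names) > 1:
        weakest = min(names, key=lambda n: (acts[n], n))
        trial = [n for n in names if n != weakest]
        t_acts, t_cos = _fit(counts, catalog, trial)
        if full_cos - t_cos < epsilon_cos + 1e-12:
            names, acts, cur_cos = trial, t_acts, t_cos
        else:
            break
    return set(names), acts, cur_cos


def fit_branches(
    spectra: list[BranchSpectrum],
    catalog: SignatureCatalog,
    mutation_tree: MutationTree,
    params: SignatureParams | None = None,
) -> list[SignatureActivity]:
    """Fit every branch; small branches inherit the parent's retained set
    and are flagged low-confidence instead of being fitted independently."""
    params = params or SignatureParams()
    by_branch = {sp.branch: sp for sp in spectra}
    results: dict[str, SignatureActivity] = {}
    parent_of = {c: p for p, c in mutation_tree.edges}

    def fit_one(gid: str) -> SignatureActivity:
        sp = by_branch[gid]
        total = int(sp.counts.sum())
        if total == 0:
            return SignatureActivity(gid, {n: 0.0 for n in catalog.signature_names},
                                     set(), 0.0, {"no_mutations"})
        if total < params.min_branch_mutations:
            parent = parent_of.get(gid)
            if parent is not None and parent in results and results[parent].retained:
                retained = sorted(results[parent].retained)
                acts, cos_v = _fit(sp.counts, catalog, retained)
                return SignatureActivity(gid, acts, set(retained), cos_v,
                                         {"low_confidence", "inherited_set"})
        retained, acts, cos_v = filter_spurious(sp.counts, catalog, params.epsilon_cos)
        flags = {"low_confidence"} if total < params.min_branch_mutations else set()
        return SignatureActivity(gid, acts, retained, cos_v, flags)

    for gid in _preorder_gids(mutation_tree):
        results[gid] = fit_one(gid)
    return [results[gid] for gid in _preorder_gids(mutation_tree)]


def _preorder_gids(mtree: MutationTree) -> list[str]:
    order: list[str] = []
    stack = sorted(mtree.roots(), reverse=True)
    while stack:
        gid = stack.pop()
        order.append(gid)
        stack.extend(sorted(mtree.children(gid), reverse=True))
    return order


def harmonize_across_branches(
    mutation_tree: MutationTree,
    activities: list[SignatureActivity],
    spectra: list[BranchSpectrum],
    catalog: SignatureCatalog,
    params: SignatureParams | None = None,
) -> tuple[list[SignatureActivity], list[dict]]:
    """One preorder pass removing isolated weak signatures.

    A signature retained on a branch but absent from both its parent and
    all children, with activity below ``isolation_threshold``, is removed
    and the branch refit.  Every removal is logged.
    """
    params = params or SignatureParams()
    by_branch = {a.branch: a for a in activities}
    sp_by_branch = {sp.branch: sp for sp in spectra}
    parent_of = {c: p for p, c in mutation_tree.edges}
    log: list[dict] = []
    for gid in _preorder_gids(mutation_tree):
        act = by_branch[gid]
        if not act.retained:
            continue
        parent = parent_of.get(gid)
        neighbor_sets = []
        if parent is not None:
            neighbor_sets.append(by_branch[parent].retained)
        neighbor_sets.extend(by_branch[c].retained for c in mutation_tree.children(gid))
        if not neighbor_sets:
            continue
        isolated = {
            sig
            for sig in act.retained
            if act.activities.get(sig, 0.0) < params.isolation_threshold
            and all(sig not in ns for ns in neighbor_sets)
        }
        if not isolated or isolated == act.retained:
            continue
        kept = sorted(act.retained - isolated)
        acts, cos_v = _fit(sp_by_branch[gid].counts, catalog, kept)
        for sig in sorted(isolated):
            log.append({"branch": gid, "removed": sig,
                        "activity": act.activities.get(sig, 0.0)})
        by_branch[gid] = SignatureActivity(
            gid, acts, set(kept), cos_v, act.flags | {"harmonized"}
        )
    return [by_branch[a.branch] for a in activities], log
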