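"""Synthetic patients with known ground truth for every pipeline stage.

The generator grows a random clone tree (each node is a clone, germline
at the root), assigns mutations to branches with channels drawn from
per-branch signature mixtures, evolves anatomical sites down the tree
with a migration probability, composes samples from localized clones
(each clone is the dominant, "resident" clone of at least one sample;
same-site ancestors are mixed in via a Dirichlet draw), and emits
binomial read counts at the requested coverage.

Homoplasy-free by default: each SNV arises on exactly one branch.  In
``noiseless`` mode compositions are drawn on a 1/64 grid and counts are
computed at an exactly-representable fixed depth, so the observed VAFs
equal 0.5 * f'M to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import channel_to_mutation, reverse_complement, COMPLEMENT
from .io_formats import DriverList, MutationProfile, SignatureCatalog
from .trees import Node, Tree

GRID = 64  # denominator for noiseless compositions
NOISELESS_DEPTH = 2 * GRID * GRID  # VAF * depth is integral on the grid


@dataclass
class SimulationParams:
    seed: int  # mandatory
    n_clones: int = 5
    n_samples: int = 6
    n_sites: int = 3
    mutations_per_branch: tuple[int, int] = (20, 60)
    depth: int = 1000
    p_true_migration: float = 0.2
    dirichlet_conc: float = 2.0
    n_signatures: int = 3
    signatures_per_branch: int = 2
    branch_mixtures: dict[str, dict[str, float]] | None = None
    n_drivers: int = 5
    homoplasy_rate: float = 0.0
    noiseless: bool = False
    max_ancestors_per_sample: int = 2

    def validate(self) -> "SimulationParams":
        if self.n_clones < 1 or self.n_samples < 4 or self.n_sites < 1:
            raise ValueError("need n_clones >= 1, n_samples >= 4, n_sites >= 1")
        if self.n_samples < self.n_clones:
            raise ValueError(
                "localized compositions require n_samples >= n_clones"
            )
        lo, hi = self.mutations_per_branch
        if lo < 1 or hi < lo:
            raise ValueError("mutations_per_branch range must be >= 1")
        if self.depth < 1 and not self.noiseless:
            raise ValueError("depth must be positive")
        if not 0 <= self.p_true_migration < 1:
            raise ValueError("p_true_migration must be in [0, 1)")
        return self


@dataclass
class GroundTruth:
    tree: Tree
    newick: str
    clone_names: list[str]
    snv_ids: list[str]
    M: np.ndarray  # clones x SNVs
    f: np.ndarray  # samples x clones
    branch_mutations: dict[str, list[str]]
    branch_mixtures: dict[str, dict[str, float]]
    branch_spectra: dict[str, np.ndarray]
    clone_sites: dict[str, str]
    sample_sites: dict[str, str]
    migration_edges: list[tuple[str, str, str, int]]  # (src, dst, clone, n_mut)
    catalog: SignatureCatalog
    normal_fractions: np.ndarray = field(default_factory=lambda: np.zeros(0))


def synthetic_catalog(n_signatures: int, rng: np.random.Generator) -> SignatureCatalog:
    """Peaked, mutually distinct 96-channel signatures."""
    probs = np.zeros((96, n_signatures))
    for k in range(n_signatures):
        peaks = rng.choice(96, size=8, replace=False)
        weights = rng.dirichlet(np.ones(8) * 0.8)
        probs[peaks, k] = weights * 0.9
        probs[:, k] += 0.1 / 96.0
        probs[:, k] /= probs[:, k].sum()
    names = [f"SIG{k + 1}" for k in range(n_signatures)]
    return SignatureCatalog(names, probs).validate()


def _grow_clone_tree(params: SimulationParams, rng) -> tuple[Tree, list[str]]:
    root = Node("Root")
    root.add_child(Node("Normal", length=0))
    names = [f"Clone{i + 1}" for i in range(params.n_clones)]
    nodes = {names[0]: root.add_child(Node(names[0]))}
    for name in names[1:]:
        parent = rng.choice(sorted(nodes))
        nodes[name] = nodes[parent].add_child(Node(name))
    return Tree(root), names


def simulate_patient(
    params: SimulationParams,
) -> tuple[MutationProfile, DriverList, GroundTruth]:
    """Generate one synthetic patient; everything derives from the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    catalog = synthetic_catalog(params.n_signatures, rng)
    tree, clone_names = _grow_clone_tree(params, rng)

    # per-branch signature mixtures
    mixtures: dict[str, dict[str, float]] = {}
    for clone in clone_names:
        if params.branch_mixtures and clone in params.branch_mixtures:
            mixtures[clone] = dict(params.branch_mixtures[clone])
        else:
            chosen = rng.choice(
                catalog.signature_names,
                size=min(params.signatures_per_branch, len(catalog.signature_names)),
                replace=False,
            )
            w = rng.dirichlet(np.ones(len(chosen)) * 3.0)
            mixtures[clone] = {sig: float(x) for sig, x in zip(chosen, w)}

    # mutations per branch
    lo, hi = params.mutations_per_branch
    snv_ids: list[str] = []
    snv_meta: list[tuple[str, str, str]] = []  # ref, alt, trinucleotide
    branch_mutations: dict[str, list[str]] = {c: [] for c in clone_names}
    branch_spectra: dict[str, np.ndarray] = {}
    snv_branches: dict[str, list[str]] = {}
    ancestry: dict[str, set[str]] = {}
    for node in Tree(tree.root).preorder():
        if node.name in branch_mutations:
            anc = set()
            p = node.parent
            while p is not None:
                anc.add(p.name)
                p = p.parent
            ancestry[node.name] = anc
    for clone in clone_names:
        n_mut = int(rng.integers(lo, hi + 1))
        spectrum = np.zeros(96, dtype=np.int64)
        mix = mixtures[clone]
        sigs = sorted(mix)
        pvec = np.array([mix[s] for s in sigs])
        pvec = pvec / pvec.sum()
        channel_probs = catalog.probs[:, [catalog.signature_names.index(s) for s in sigs]] @ pvec
        for _ in range(n_mut):
            if params.homoplasy_rate > 0 and snv_ids and rng.random() < params.homoplasy_rate:
                # reuse an SNV from an unrelated branch (multi-branch mapping)
                pool = [
                    sid for sid in snv_ids
                    if all(
                        b not in ancestry[clone] and b != clone
                        and clone not in ancestry[b]
                        for b in snv_branches[sid]
                    )
                ]
                if pool:
                    sid = pool[int(rng.integers(len(pool)))]
                    branch_mutations[clone].append(sid)
                    snv_branches[sid].append(clone)
                    ref, alt, tri = snv_meta[snv_ids.index(sid)]
                    from .channels import channel_index
                    spectrum[channel_index(ref, alt, tri)] += 1
                    continue
            ch = int(rng.choice(96, p=channel_probs))
            ref, alt, tri = channel_to_mutation(ch)
            if rng.random() < 0.5:  # report on the purine strand
                ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
                tri = reverse_complement(tri)
            sid = f"S{len(snv_ids) + 1}"
            snv_ids.append(sid)
            snv_meta.append((ref, alt, tri))
            branch_mutations[clone].append(sid)
            snv_branches[sid] = [clone]
            spectrum[ch] += 1
        branch_spectra[clone] = spectrum
        tree.find(clone).length = n_mut

    # genotypes: union of branch mutation sets along the root path
    snv_index = {sid: i for i, sid in enumerate(snv_ids)}
    M = np.zeros((params.n_clones, len(snv_ids)), dtype=np.uint8)
    for ci, clone in enumerate(clone_names):
        lineage = [clone] + [a for a in ancestry[clone] if a in branch_mutations]
        for b in lineage:
            for sid in branch_mutations[b]:
                M[ci, snv_index[sid]] = 1

    # anatomical sites evolve down the tree
    site_names = [f"Site{i + 1}" for i in range(params.n_sites)]
    clone_sites: dict[str, str] = {}
    migration_edges: list[tuple[str, str, str, int]] = []
    for node in tree.preorder():
        if node.name not in branch_mutations:
            continue
        parent_site = (
            clone_sites.get(node.parent.name, site_names[0])
            if node.parent is not None
            else site_names[0]
        )
        if node.parent is not None and node.parent.name in clone_sites and \
                params.n_sites > 1 and rng.random() < params.p_true_migration:
            others = [s for s in site_names if s != parent_site]
            site = others[int(rng.integers(len(others)))]
            migration_edges.append(
                (parent_site, site, node.name, len(branch_mutations[node.name]))
            )
        else:
            site = parent_site
        clone_sites[node.name] = site

    # sample compositions: resident clone + same-site contiguous ancestors
    f = np.zeros((params.n_samples, params.n_clones))
    sample_names = [f"T{i + 1}" for i in range(params.n_samples)]
    sample_sites: dict[str, str] = {}
    normal_fracs = np.zeros(params.n_samples)
    clone_idx = {c: i for i, c in enumerate(clone_names)}
    for si, sample in enumerate(sample_names):
        resident = clone_names[si % params.n_clones]
        site = clone_sites[resident]
        sample_sites[sample] = site
        members = [resident]
        node = tree.find(resident).parent
        while (
            node is not None
            and node.name in clone_sites
            and clone_sites[node.name] == site
            and len(members) < 1 + params.max_ancestors_per_sample
        ):
            members.append(node.name)
            node = node.parent
        if params.noiseless:
            purity = (GRID - int(rng.integers(int(0.1 * GRID), int(0.5 * GRID) + 1))) / GRID
            parts = np.sort(rng.multinomial(GRID - len(members),
                                            np.ones(len(members)) / len(members)))[::-1] + 1
            weights = parts / GRID
            f[si, [clone_idx[m] for m in members]] = weights * purity
        else:
            purity = 1.0 - rng.uniform(0.1, 0.5)
            weights = np.sort(rng.dirichlet(np.ones(len(members)) * params.dirichlet_conc))[::-1]
            f[si, [clone_idx[m] for m in members]] = weights * purity
        normal_fracs[si] = 1.0 - purity

    # read counts
    vaf = 0.5 * (f @ M)  # samples x snvs
    n_snv = len(snv_ids)
    if params.noiseless:
        depth = np.full((n_snv, params.n_samples), NOISELESS_DEPTH, dtype=np.int64)
        alt = np.rint(vaf.T * NOISELESS_DEPTH).astype(np.int64)
    else:
        depth = rng.poisson(params.depth, size=(n_snv, params.n_samples))
        alt = rng.binomial(depth, vaf.T)
    silent = (alt > 0).sum(axis=1) == 0
    if silent.any():  # guarantee every SNV is observed somewhere
        best = np.argmax(vaf.T, axis=1)
        for i in np.flatnonzero(silent):
            depth[i, best[i]] = max(depth[i, best[i]], 1)
            alt[i, best[i]] = 1
    ref = depth - alt

    profile = MutationProfile(
        snv_ids=list(snv_ids),
        ref_base=[m[0] for m in snv_meta],
        alt_base=[m[1] for m in snv_meta],
        trinucleotide=[m[2] for m in snv_meta],
        sample_names=sample_names,
        ref_count=ref,
        alt_count=alt,
    ).validate()

    n_drivers = min(params.n_drivers, len(snv_ids))
    driver_snvs = sorted(rng.choice(snv_ids, size=n_drivers, replace=False),
                         key=lambda s: int(s[1:]))
    drivers = DriverList(
        [(sid, f"GENE{k + 1}", f"D{k + 1}") for k, sid in enumerate(driver_snvs)]
    ).validate(profile)

    truth = GroundTruth(
        tree=tree,
        newick=tree.to_newick(),
        clone_names=clone_names,
        snv_ids=list(snv_ids),
        M=M,
        f=f,
        branch_mutations=branch_mutations,
        branch_mixtures=mixtures,
        branch_spectra=branch_spectra,
        clone_sites=clone_sites,
        sample_sites=sample_sites,
        migration_edges=migration_edges,
        catalog=catalog,
        normal_fractions=normal_fracs,
    )
    return profile, drivers, truth
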