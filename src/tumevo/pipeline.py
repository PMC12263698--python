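"""End-to-end orchestration of the tumor-evolution analysis."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import (
    deconvolution,
    io_formats,
    migration,
    phylogeny,
    render,
    sample_tree,
    signatures,
)
from .channels import channel_index


@dataclass
class PipelineParams:
    seed: int = 0
    presence_threshold: float = 0.02
    min_alt: int = 3
    error_rate: float = 1e-3
    presence_pvalue: float = 0.01
    max_iter: int = 10
    epsilon_cos: float = 0.01
    isolation_threshold: float = 0.10
    min_branch_mutations: int = 20
    p_mig: float = 0.1
    origin_posterior_threshold: float = 0.3
    distance_metric: str = "unifrac"

    @classmethod
    def from_config(cls, overrides: dict[str, str]) -> "PipelineParams":
        params = cls()
        for key, raw in overrides.items():
            if not hasattr(params, key):
                raise io_formats.FormatError(f"unknown config key '{key}'")
            current = getattr(params, key)
            if isinstance(current, bool):
                value = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            else:
                value = raw
            setattr(params, key, value)
        return params


@dataclass
class PipelineResult:
    clones: deconvolution.CloneSet
    phylogeny: phylogeny.ClonePhylogeny
    mutation_tree: phylogeny.MutationTree
    spectra: list[signatures.BranchSpectrum]
    activities: list[signatures.SignatureActivity]
    harmonization_log: list[dict]
    observation_tree: migration.ObservationTree
    posteriors: migration.LocationPosterior
    migration: migration.MigrationGraph
    sample_distances: sample_tree.SampleDistanceMatrix
    sample_distances_mntd: sample_tree.SampleDistanceMatrix
    sample_tree: sample_tree.SampleTree
    figures: dict[str, str]
    manifest: io_formats.RunManifest
    params: PipelineParams = field(default_factory=PipelineParams)


def branch_spectra(
    profile, mutation_tree, drivers=None
) -> list[signatures.BranchSpectrum]:
    """96-channel spectrum per mutational-tree branch, driver channels
    recorded for highlighting."""
    meta = {
        sid: (r, a, t)
        for sid, r, a, t in zip(
            profile.snv_ids, profile.ref_base, profile.alt_base,
            profile.trinucleotide,
        )
    }
    driver_snvs = {sid for sid, _, _ in drivers.entries} if drivers else set()
    out = []
    for node in mutation_tree.nodes:
        snvs = [meta[s] for s in node["snvs"]]
        spec = signatures.spectrum_from_mutations(snvs, branch=node["id"])
        spec.driver_channels = sorted(
            {channel_index(*meta[s]) for s in node["snvs"] if s in driver_snvs}
        )
        out.append(spec)
    return out


def run_pipeline(
    profile,
    drivers,
    catalog,
    params: PipelineParams | None = None,
    sample_sites: dict[str, str] | None = None,
    input_paths: dict[str, str | Path] | None = None,
) -> PipelineResult:
    """Run every stage; ``sample_sites`` maps sample name to anatomical
    site (default: each sample is its own site)."""
    params = params or PipelineParams()
    profile.validate()
    if drivers is not None:
        drivers.validate(profile)
    catalog.validate()
    if sample_sites is None:
        sample_sites = {s: s for s in profile.sample_names}

    dparams = deconvolution.DeconvolutionParams(
        presence_threshold=params.presence_threshold,
        min_alt=params.min_alt,
        error_rate=params.error_rate,
        presence_pvalue=params.presence_pvalue,
        max_iter=params.max_iter,
    )
    clones, phylo = deconvolution.infer_clones(profile, dparams)
    mtree = phylogeny.build_mutation_tree(phylo, drivers)

    spectra = branch_spectra(profile, mtree, drivers)
    sparams = signatures.SignatureParams(
        epsilon_cos=params.epsilon_cos,
        isolation_threshold=params.isolation_threshold,
        min_branch_mutations=params.min_branch_mutations,
    )
    acts = signatures.fit_branches(spectra, catalog, mtree, sparams)
    acts, harmonization_log = signatures.harmonize_across_branches(
        mtree, acts, spectra, catalog, sparams
    )

    obs = migration.expand_tips(phylo, clones, sample_sites,
                                params.presence_threshold)
    post = migration.infer_locations(obs, params.p_mig)
    mig = migration.build_migration_graph(obs, post,
                                          params.origin_posterior_threshold)

    dist = sample_tree.sample_distance_matrix(
        phylo, clones, metric=params.distance_metric,
        presence_threshold=params.presence_threshold,
    )
    dist_mntd = sample_tree.sample_distance_matrix(
        phylo, clones, metric="mntd",
        presence_threshold=params.presence_threshold,
    )
    stree = sample_tree.nj_tree(dist)

    figures = {
        "clone_tree_frequencies": render.render_clone_tree_with_frequencies(
            phylo, clones
        ),
        "mutation_tree": render.render_mutation_tree(mtree),
        "migration_graph": render.render_migration_graph(mig),
        "sample_tree": render.render_sample_tree(stree),
    }
    figures.update(render.render_signature_layers(mtree, acts, spectra, drivers))

    manifest = io_formats.make_manifest(
        parameters=asdict(params), seed=params.seed, input_paths=input_paths
    )
    return PipelineResult(
        clones=clones,
        phylogeny=phylo,
        mutation_tree=mtree,
        spectra=spectra,
        activities=acts,
        harmonization_log=harmonization_log,
        observation_tree=obs,
        posteriors=post,
        migration=mig,
        sample_distances=dist,
        sample_distances_mntd=dist_mntd,
        sample_tree=stree,
        figures=figures,
        manifest=manifest,
        params=params,
    )
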