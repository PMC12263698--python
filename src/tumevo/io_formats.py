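"""On-disk dialects: mutation profiles, driver lists, signature catalogs,
run manifests, and the pipeline output file set.

Dialects
--------
Mutation profile: tab-separated, one SNV per row; fixed columns
``snv_id, ref, alt, trinucleotide`` (optional ``chrom:pos`` metadata),
then per-sample count pairs ``<sample>:ref`` and ``<sample>:alt``.

Driver list: ``snv_id<TAB>gene<TAB>label``.

Signature catalog: COSMIC-style SBS table with a ``Type`` column of
channel labels like ``A[C>A]A`` and one column per signature.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import BASES, CHANNELS

MIN_SAMPLES = 4
_MIN_SAMPLES_MSG = "at least four tumor samples required"


class FormatError(ValueError):
    """Structural problem with an input file (missing column, bad shape)."""


class ValidationError(ValueError):
    """Content violates a domain-type invariant; offending records named."""


class PreconditionError(ValueError):
    """Input violates a pipeline precondition (e.g. too few samples)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MutationProfile:
    """Per-SNV bases and per-sample read counts; the pipeline's sole
    required input.

    Matrices are SNVs x samples; sample column order is preserved from
    the input file.
    """

    snv_ids: list[str]
    ref_base: list[str]
    alt_base: list[str]
    trinucleotide: list[str]
    sample_names: list[str]
    ref_count: np.ndarray
    alt_count: np.ndarray
    positions: list[str] | None = None  # optional "chrom:pos" metadata

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def validate(self) -> "MutationProfile":
        if len(set(self.snv_ids)) != len(self.snv_ids):
            dupes = sorted({s for s in self.snv_ids if self.snv_ids.count(s) > 1})
            raise ValidationError(f"duplicate snv_ids: {dupes}")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValidationError("duplicate sample names")
        if self.n_samples < MIN_SAMPLES:
            raise PreconditionError(
                f"{_MIN_SAMPLES_MSG} (got {self.n_samples})"
            )
        bad_base = [
            sid
            for sid, r, a in zip(self.snv_ids, self.ref_base, self.alt_base)
            if r not in BASES or a not in BASES or r == a
        ]
        if bad_base:
            raise ValidationError(f"invalid ref/alt bases for SNVs: {bad_base}")
        bad_tri = [
            sid
            for sid, r, t in zip(self.snv_ids, self.ref_base, self.trinucleotide)
            if len(t) != 3 or any(b not in BASES for b in t) or t[1] != r
        ]
        if bad_tri:
            raise ValidationError(
                f"trinucleotide middle base does not match ref for SNVs: {bad_tri}"
            )
        if self.ref_count.shape != (self.n_snvs, self.n_samples):
            raise ValidationError("ref_count shape mismatch")
        if self.alt_count.shape != (self.n_snvs, self.n_samples):
            raise ValidationError("alt_count shape mismatch")
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValidationError("negative read counts")
        silent = np.flatnonzero((self.alt_count > 0).sum(axis=1) == 0)
        if silent.size:
            ids = [self.snv_ids[i] for i in silent]
            raise ValidationError(f"SNVs with no mutant reads in any sample: {ids}")
        return self


@dataclass
class DriverList:
    """User-designated driver SNVs to be timed on the mutational tree."""

    entries: list[tuple[str, str, str]]  # (snv_id, gene, display_label)

    def validate(self, profile: MutationProfile) -> "DriverList":
        known = set(profile.snv_ids)
        missing = [sid for sid, _, _ in self.entries if sid not in known]
        if missing:
            raise ValidationError(f"driver snv_ids absent from profile: {missing}")
        labels = [lab for _, _, lab in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError("driver display labels are not unique")
        return self


@dataclass
class SignatureCatalog:
    """96-channel SBS probability vectors, one column per signature."""

    signature_names: list[str]
    probs: np.ndarray  # (96, n_signatures)
    channel_order: tuple[str, ...] = CHANNELS

    def validate(self) -> "SignatureCatalog":
        if self.probs.shape != (96, len(self.signature_names)):
            raise ValidationError("catalog probability matrix must be 96 x signatures")
        if (self.probs < 0).any():
            raise ValidationError("negative probabilities in catalog")
        sums = self.probs.sum(axis=0)
        off = np.flatnonzero(np.abs(sums - 1.0) > 1e-3)
        if off.size:
            names = [self.signature_names[i] for i in off]
            raise ValidationError(f"catalog columns do not sum to 1: {names}")
        self.probs = self.probs / sums  # renormalize small drift
        return self

    def column(self, name: str) -> np.ndarray:
        return self.probs[:, self.signature_names.index(name)]

    def subset(self, names: list[str]) -> "SignatureCatalog":
        idx = [self.signature_names.index(n) for n in names]
        return SignatureCatalog(list(names), self.probs[:, idx])


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: version, inputs, parameters."""

    tool_version: str
    timestamp: str
    input_digests: dict[str, str]
    parameters: dict
    seed: int | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "timestamp": self.timestamp,
                "input_digests": self.input_digests,
                "parameters": self.parameters,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(
            tool_version=d["tool_version"],
            timestamp=d["timestamp"],
            input_digests=d["input_digests"],
            parameters=d["parameters"],
            seed=d["seed"],
        )


def sha256_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def make_manifest(parameters: dict, seed: int | None,
                  input_paths: dict[str, str | Path] | None = None) -> RunManifest:
    from . import __version__

    digests = {
        name: sha256_digest(p) for name, p in (input_paths or {}).items()
    }
    return RunManifest(
        tool_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        input_digests=digests,
        parameters=parameters,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# mutation profile I/O
# ---------------------------------------------------------------------------

_FIXED_COLS = ["snv_id", "ref", "alt", "trinucleotide"]


def read_mutation_profile(path: str | Path) -> MutationProfile:
    """Read and validate a tab-separated mutation profile.

    Raises :class:`FormatError` for missing columns,
    :class:`ValidationError` for invariant violations (offending SNV ids
    listed), and :class:`PreconditionError` for fewer than four samples.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _FIXED_COLS:
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}'")
    count_cols = [c for c in df.columns if ":" in c and c != "chrom:pos"]
    samples: list[str] = []
    for col in count_cols:
        name, kind = col.rsplit(":", 1)
        if kind not in ("ref", "alt"):
            raise FormatError(f"unrecognized count column '{col}'")
        if name not in samples:
            samples.append(name)
    for s in samples:
        for kind in ("ref", "alt"):
            if f"{s}:{kind}" not in df.columns:
                raise FormatError(f"missing required column '{s}:{kind}'")
    if len(samples) < MIN_SAMPLES:
        raise PreconditionError(f"{_MIN_SAMPLES_MSG} (got {len(samples)})")
    try:
        ref_count = df[[f"{s}:ref" for s in samples]].to_numpy(dtype=np.int64)
        alt_count = df[[f"{s}:alt" for s in samples]].to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"non-integer read count: {exc}") from exc
    profile = MutationProfile(
        snv_ids=df["snv_id"].tolist(),
        ref_base=df["ref"].tolist(),
        alt_base=df["alt"].tolist(),
        trinucleotide=df["trinucleotide"].tolist(),
        sample_names=samples,
        ref_count=ref_count,
        alt_count=alt_count,
        positions=df["chrom:pos"].tolist() if "chrom:pos" in df.columns else None,
    )
    return profile.validate()


def write_mutation_profile(profile: MutationProfile, path: str | Path) -> None:
    data = {
        "snv_id": profile.snv_ids,
        "ref": profile.ref_base,
        "alt": profile.alt_base,
        "trinucleotide": profile.trinucleotide,
    }
    if profile.positions is not None:
        data["chrom:pos"] = profile.positions
    for j, s in enumerate(profile.sample_names):
        data[f"{s}:ref"] = profile.ref_count[:, j]
        data[f"{s}:alt"] = profile.alt_count[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# driver list I/O
# ---------------------------------------------------------------------------


def read_driver_list(path: str | Path) -> DriverList:
    df = pd.read_csv(path, sep="\t", dtype=str,
                     names=["snv_id", "gene", "label"], header=0)
    entries = [
        (row.snv_id, row.gene, row.label if isinstance(row.label, str) else row.snv_id)
        for row in df.itertuples()
    ]
    return DriverList(entries)


def write_driver_list(drivers: DriverList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snv_id\tgene\tlabel\n")
        for sid, gene, label in drivers.entries:
            fh.write(f"{sid}\t{gene}\t{label}\n")


# ---------------------------------------------------------------------------
# signature catalog I/O
# ---------------------------------------------------------------------------


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-format SBS table (``Type`` column + signature columns).

    Rows may appear in any order; they are reindexed into canonical
    channel order.  Columns within 1e-3 of summing to 1 are renormalized;
    anything further off is an error.
    """
    df = pd.read_csv(path, sep="\t")
    if "Type" not in df.columns:
        raise FormatError("missing required column 'Type'")
    if len(df) != 96:
        raise FormatError(f"expected 96 channel rows, got {len(df)}")
    unknown = set(df["Type"]) - set(CHANNELS)
    if unknown:
        raise FormatError(f"unrecognized channel labels: {sorted(unknown)}")
    df = df.set_index("Type").reindex(list(CHANNELS))
    if df.isna().any().any():
        raise FormatError("duplicate or missing channel rows")
    names = list(df.columns)
    if not names:
        raise FormatError("catalog has no signature columns")
    probs = df.to_numpy(dtype=float)
    return SignatureCatalog(names, probs).validate()


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(catalog.probs, columns=catalog.signature_names)
    df.insert(0, "Type", list(CHANNELS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key=value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"bad config line (expected key=value): {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# pipeline output file set
# ---------------------------------------------------------------------------


def write_clone_tables(clones, outdir: Path) -> None:
    geno = pd.DataFrame(
        clones.M.astype(int), index=clones.clone_names, columns=clones.snv_ids
    )
    geno.index.name = "clone"
    geno.to_csv(outdir / "clones.tsv", sep="\t")
    freq = pd.DataFrame(
        np.round(clones.f, 6), index=clones.sample_names, columns=clones.clone_names
    )
    freq.index.name = "sample"
    freq.to_csv(outdir / "frequencies.tsv", sep="\t")


def write_outputs(results, outdir: str | Path) -> list[Path]:
    """Write the complete result file set; returns the paths written.

    Re-running on identical inputs and seed reproduces byte-identical
    files except for the manifest timestamp.
    """
    outdir = Path(outdir)
    if results.clones is None or len(results.clones.clone_names) == 0:
        raise ValidationError("empty clone set; nothing to write")
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        written.append(p)

    write_clone_tables(results.clones, outdir)
    written += [outdir / "clones.tsv", outdir / "frequencies.tsv"]

    emit("clone_tree.nwk", results.phylogeny.tree.to_newick() + "\n")
    emit("mutation_tree.json",
         json.dumps(results.mutation_tree.to_dict(), indent=2, sort_keys=True))

    rows = ["branch\tsignature\tactivity\tfit_cosine\tflags"]
    for act in results.activities:
        flags = ",".join(sorted(act.flags)) if act.flags else "-"
        for sig in sorted(act.activities):
            rows.append(
                f"{act.branch}\t{sig}\t{act.activities[sig]:.6f}"
                f"\t{act.fit_cosine:.6f}\t{flags}"
            )
    emit("branch_activities.tsv", "\n".join(rows) + "\n")

    spec_rows = ["branch\tchannel\tcount"]
    for spec in results.spectra:
        for ch, c in zip(CHANNELS, spec.counts):
            if c:
                spec_rows.append(f"{spec.branch}\t{ch}\t{int(c)}")
    emit("branch_spectra.tsv", "\n".join(spec_rows) + "\n")

    emit("migration_graph.json",
         json.dumps(results.migration.to_dict(), indent=2, sort_keys=True))
    emit("migration_graph.dot", results.migration.to_dot())

    post_rows = ["node\t" + "\t".join(results.posteriors.sites)]
    for node in sorted(results.posteriors.marginals):
        probs = results.posteriors.marginals[node]
        post_rows.append(node + "\t" + "\t".join(f"{p:.6f}" for p in probs))
    emit("location_posteriors.tsv", "\n".join(post_rows) + "\n")

    def distance_text(dist) -> str:
        drows = ["sample\t" + "\t".join(dist.sample_names)]
        for i, s in enumerate(dist.sample_names):
            drows.append(s + "\t" + "\t".join(f"{x:.6f}" for x in dist.matrix[i]))
        return "\n".join(drows) + "\n"

    emit("sample_distances.tsv", distance_text(results.sample_distances))
    emit("sample_distances_mntd.tsv", distance_text(results.sample_distances_mntd))
    emit("sample_tree.nwk", results.sample_tree.tree.to_newick() + "\n")

    for name, svg in results.figures.items():
        emit(f"{name}.svg", svg)

    emit("manifest.json", results.manifest.to_json())
    return written
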