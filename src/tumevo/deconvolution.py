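"""Clone genotype/frequency deconvolution from observed variant frequencies.

Model: samples are mixtures of clones related by a shared phylogeny, SNVs
are heterozygous and CNA-free, so observed VAFs satisfy V = 0.5 * f' M
with f the per-sample cancer-cell fractions (sum <= 1; the remainder is
the normal-cell fraction).

The search alternates candidate-clone proposal (per-sample presence
binarization, maximum-parsimony ancestral genotypes, residual-driven
splits) with constrained least-squares frequency estimation, pruning
redundant and low-frequency candidates until the clone set stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import phylogeny
from .io_formats import MutationProfile, PreconditionError, ValidationError
from .optim import simplex_lsq


@dataclass
class DeconvolutionParams:
    presence_threshold: float = 0.02
    min_alt: int = 3
    error_rate: float = 1e-3
    presence_pvalue: float = 0.01
    max_iter: int = 10
    split_min_snvs: int = 4
    split_min_separation: float = 0.05


@dataclass
class VafMatrix:
    """Observed variant allele frequencies with depth and missingness."""

    V: np.ndarray  # (snvs, samples), 0 where missing
    depth: np.ndarray  # (snvs, samples)
    missing: np.ndarray  # boolean mask, True where depth == 0


@dataclass
class CloneSet:
    """Binary genotypes M (clones x SNVs) and frequencies f (samples x clones)."""

    M: np.ndarray
    f: np.ndarray
    clone_names: list[str]
    snv_ids: list[str]
    sample_names: list[str]

    def validate(self, presence_threshold: float = 0.02) -> "CloneSet":
        if self.M.size == 0:
            raise ValidationError("empty clone set")
        if not np.isin(self.M, (0, 1)).all():
            raise ValidationError("clone genotypes must be binary")
        if len({row.tobytes() for row in self.M}) != self.M.shape[0]:
            raise ValidationError("duplicate clone genotypes")
        if (self.M.sum(axis=1) == 0).any():
            raise ValidationError("all-zero clone genotype")
        if (self.f < 0).any():
            raise ValidationError("negative clone frequency")
        if (self.f.sum(axis=1) > 1 + 1e-9).any():
            raise ValidationError("sample clone frequencies exceed 1")
        if (self.f.max(axis=0) <= presence_threshold).any():
            raise ValidationError("clone below presence threshold everywhere")
        return self

    def genotypes(self) -> phylogeny.Genotypes:
        return {
            name: self.M[i].astype(np.uint8)
            for i, name in enumerate(self.clone_names)
        }


def compute_vaf(profile: MutationProfile) -> VafMatrix:
    """V = alt / (alt + ref); entries with zero depth flagged missing."""
    depth = profile.ref_count + profile.alt_count
    missing = depth == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where(missing, 0.0, profile.alt_count / np.maximum(depth, 1))
    return VafMatrix(V=V, depth=depth, missing=missing)


def estimate_frequencies(
    M: np.ndarray, V_s: np.ndarray, depth_s: np.ndarray
) -> np.ndarray:
    """Per-sample clone frequencies minimizing the depth-weighted squared
    residual of 0.5 * f'M against the observed VAFs, subject to f >= 0 and
    sum(f) <= 1.

    Entries with zero depth are ignored.  For rank-deficient M the
    smallest-norm minimizer is returned (documented tie-break).
    """
    if M.size == 0:
        raise ValueError("empty clone matrix")
    observed = depth_s > 0
    A = 0.5 * M.T[observed]
    return simplex_lsq(A, V_s[observed], sum_to_one=False,
                       weights=depth_s[observed].astype(float))


def _fit_all(M: np.ndarray, vaf: VafMatrix) -> tuple[np.ndarray, float]:
    n_samples = vaf.V.shape[1]
    f = np.zeros((n_samples, M.shape[0]))
    residual = 0.0
    for s in range(n_samples):
        f[s] = estimate_frequencies(M, vaf.V[:, s], vaf.depth[:, s])
        obs = vaf.depth[:, s] > 0
        r = 0.5 * (M.T[obs] @ f[s]) - vaf.V[obs, s]
        residual += float((vaf.depth[obs, s] * r * r).sum())
    return f, residual


def presence_matrix(profile: MutationProfile, params: DeconvolutionParams) -> np.ndarray:
    """Boolean SNV-by-sample presence: alt >= min_alt and a one-sided
    binomial test against the sequencing error rate at presence_pvalue."""
    depth = profile.ref_count + profile.alt_count
    pvals = stats.binom.sf(profile.alt_count - 1, np.maximum(depth, 1),
                           params.error_rate)
    return (profile.alt_count >= params.min_alt) & (pvals < params.presence_pvalue)


def _unique_rows(rows: list[np.ndarray]) -> list[np.ndarray]:
    seen: dict[bytes, np.ndarray] = {}
    for row in rows:
        if row.any():
            seen.setdefault(row.astype(np.uint8).tobytes(), row.astype(np.uint8))
    # deterministic: (mutation count, lexicographic genotype)
    return sorted(seen.values(), key=lambda r: (int(r.sum()), r.tobytes()))


def _ancestral_candidates(candidates: list[np.ndarray], snv_ids: list[str]) -> list[np.ndarray]:
    genotypes = {f"C{i}": row for i, row in enumerate(candidates)}
    phylo = phylogeny.build_clone_phylogeny(genotypes, snv_ids)
    return [g.astype(np.uint8) for name, g in phylo.genotypes.items() if g.any()]


def _split_candidates(
    M: np.ndarray, f: np.ndarray, vaf: VafMatrix, params: DeconvolutionParams
) -> list[np.ndarray]:
    """Propose ancestor genotypes where one clone's SNVs form two VAF
    clusters in one sample (BIC-backed 1- vs 2-mean fit; the high-VAF
    cluster is the inherited, i.e. ancestral, part)."""
    out = []
    for c in range(M.shape[0]):
        snvs = np.flatnonzero(M[c])
        for s in range(f.shape[0]):
            if f[s, c] <= params.presence_threshold:
                continue
            usable = snvs[~vaf.missing[snvs, s]]
            if usable.size < params.split_min_snvs:
                continue
            v = np.sort(vaf.V[usable, s])
            n = v.size
            ss1 = float(((v - v.mean()) ** 2).sum())
            best = None
            for k in range(2, n - 1):  # >= 2 points per cluster
                lo, hi = v[:k], v[k:]
                ss2 = float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
                sep = hi.mean() - lo.mean()
                if best is None or ss2 < best[0]:
                    best = (ss2, sep, k)
            ss2, sep, k = best
            eps = 1e-12
            bic1 = n * np.log(ss1 / n + eps) + 2 * np.log(n)
            bic2 = n * np.log(ss2 / n + eps) + 3 * np.log(n)
            if bic2 < bic1 and sep >= params.split_min_separation:
                low_set = np.isin(np.arange(M.shape[1]), usable[np.argsort(vaf.V[usable, s])[:k]])
                ancestor = M[c].copy()
                ancestor[low_set] = 0
                if ancestor.any():
                    out.append(ancestor.astype(np.uint8))
    return out


def _prune_redundant(
    candidates: list[np.ndarray], vaf: VafMatrix
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Backward elimination: drop candidates whose removal leaves the total
    depth-weighted residual (numerically) unchanged; larger genotypes are
    tried first so spurious union/hybrid clones go before real ones."""
    M = np.array(candidates)
    f, residual = _fit_all(M, vaf)
    tol = 1e-7 * float((vaf.depth * vaf.V**2).sum()) + 1e-9
    order = sorted(range(len(candidates)),
                   key=lambda i: (-int(candidates[i].sum()), candidates[i].tobytes()))
    keep = list(range(len(candidates)))
    for i in order:
        if len(keep) == 1:
            break
        trial = [j for j in keep if j != i]
        f_t, res_t = _fit_all(M[trial], vaf)
        if res_t <= residual + tol:
            keep = trial
            residual = res_t
    kept = [candidates[j] for j in keep]
    f, residual = _fit_all(np.array(kept), vaf)
    return kept, f, residual


def infer_clones(
    profile: MutationProfile, params: DeconvolutionParams | None = None
) -> tuple[CloneSet, phylogeny.ClonePhylogeny]:
    """Infer the clone set and its phylogeny from a mutation profile.

    See the module docstring for the iterative procedure.  Raises
    :class:`PreconditionError` if no SNV passes the presence test in any
    sample ("no clonal signal").
    """
    params = params or DeconvolutionParams()
    profile.validate()
    vaf = compute_vaf(profile)
    present = presence_matrix(profile, params)
    if not present.any():
        raise PreconditionError("no clonal signal: no SNV passes the presence test")

    candidates = _unique_rows([present[:, s] for s in range(profile.n_samples)])
    prev_key: frozenset | None = None
    prev_residual = np.inf
    state = None
    for _ in range(params.max_iter):
        if len(candidates) >= 2:
            candidates = _unique_rows(
                candidates + _ancestral_candidates(candidates, profile.snv_ids)
            )
        candidates, f, residual = _prune_redundant(candidates, vaf)
        # drop clones never above the presence threshold
        M = np.array(candidates)
        above = f.max(axis=0) > params.presence_threshold
        if not above.all() and above.any():
            candidates = [c for c, a in zip(candidates, above) if a]
            M = np.array(candidates)
            f, residual = _fit_all(M, vaf)
        if residual > prev_residual + 1e-9 and state is not None:
            candidates, f, residual = state  # revert: residual must not increase
            break
        state = (list(candidates), f, residual)
        prev_residual = residual
        key = frozenset(c.tobytes() for c in candidates)
        if key == prev_key:
            break
        prev_key = key
        candidates = _unique_rows(
            candidates + _split_candidates(M, f, vaf, params)
        )
    candidates, f, residual = state
    names = [f"Clone{i + 1}" for i in range(len(candidates))]
    clones = CloneSet(
        M=np.array(candidates, dtype=np.uint8),
        f=f,
        clone_names=names,
        snv_ids=list(profile.snv_ids),
        sample_names=list(profile.sample_names),
    ).validate(params.presence_threshold)
    phylo = phylogeny.build_clone_phylogeny(clones.genotypes(), clones.snv_ids)
    return clones, phylo
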