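"""Community statistics on ASV tables: rarefaction, relative abundance,
alpha diversity, unweighted UniFrac, principal coordinates, and the
bootstrap core-microbiome procedure.

These are authored here rather than delegated so that every numerical choice
(hypergeometric rarefaction, natural-log Shannon, branch-set UniFrac,
double-centred PCoA, sample-level bootstrap for the core) is explicit and
testable against independent oracles.

Core microbiome
---------------
The core is detected by bootstrap over *samples*: each of ``n_resamples``
resamples draws n sample ids with replacement from the n samples; an ASV
"prevails" in a resample when its count is positive in every drawn sample.
ASVs prevailing in at least ``threshold`` (default 95%) of resamples form
the core. An ASV present in every sample always prevails; an ASV absent
from even one sample prevails only in resamples that happen to avoid all
samples it is missing from — for a single missing sample that probability
is ((n-1)/n)^n <= 1/e, far below the 95% bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import ASVTable, DistanceMatrix, Taxonomy
from .errors import DomainError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 50_000
DEFAULT_CORE_RESAMPLES = 1000
DEFAULT_CORE_THRESHOLD = 0.95


@dataclass(frozen=True)
class CoreMicrobiomeResult:
    core_asv_ids: frozenset[str]
    prevalence_fraction: Mapping[str, float]
    n_resamples: int
    threshold: float
    seed: Optional[int]


@dataclass(frozen=True)
class DiversityResult:
    """Per-sample richness and Shannon index, with overall medians."""

    per_sample: pd.DataFrame  # index sample_id, columns observed_asvs, shannon
    median_observed: float
    median_shannon: float


def rarefy(table: ASVTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: Optional[int] = None) -> ASVTable:
    """Subsample each sample without replacement to exactly ``depth`` counts.

    Each retained sample's rarefied counts follow the multivariate
    hypergeometric distribution given its observed composition. Samples whose
    total is below ``depth`` are dropped with a warning. Deterministic under
    a fixed seed.
    """
    if depth <= 0:
        raise DomainError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    keep_ids, rows = [], []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = int(row.sum())
        if total < depth:
            logger.warning("sample %s total %d < depth %d; dropped", sid, total, depth)
            continue
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        keep_ids.append(sid)
    if not keep_ids:
        raise InsufficientDataError(f"no sample reaches rarefaction depth {depth}")
    return ASVTable(
        keep_ids,
        table.asv_ids,
        np.vstack(rows),
        {s: table.sample_metadata[s] for s in keep_ids},
    )


def relative_abundance(table: ASVTable, taxonomy: Taxonomy, rank: str) -> pd.DataFrame:
    """Aggregate counts by taxonomic rank and scale to percent per sample.

    Returns a DataFrame (rank labels x samples) whose columns each sum to
    100; ASVs without an assignment at ``rank`` pool under "Unassigned".
    """
    totals = table.sample_totals()
    empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if empty:
        raise ValidationError(f"empty sample(s): {empty}")
    labels = [taxonomy.rank_label(a, rank) for a in table.asv_ids]
    df = pd.DataFrame(table.counts.T, index=pd.Index(labels, name=rank), columns=table.sample_ids)
    agg = df.groupby(level=0).sum()
    return 100.0 * agg / agg.sum(axis=0)


def shannon_index(counts: np.ndarray, base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive proportions.

    Natural log by default (``base=None``); pass e.g. ``base=2`` for bits.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DomainError("Shannon undefined for an all-zero sample")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def alpha_diversity(table: ASVTable, base: Optional[float] = None) -> DiversityResult:
    """Observed ASV richness and Shannon index per sample, with medians."""
    rows = {}
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        if row.sum() == 0:
            raise DomainError(f"sample {sid} has no counts")
        rows[sid] = {
            "observed_asvs": int((row > 0).sum()),
            "shannon": shannon_index(row, base=base),
        }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    return DiversityResult(
        per_sample=per_sample,
        median_observed=float(per_sample["observed_asvs"].median()),
        median_shannon=float(per_sample["shannon"].median()),
    )


# ---------------------------------------------------------------------------
# Unweighted UniFrac
# ---------------------------------------------------------------------------

def _branch_table(tree: TreeNode, asv_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lengths and leaf-descendancy indicators for the given ASVs.

    Returns ``(lengths, descend)`` where row b of ``descend`` marks which of
    the ``asv_ids`` sit below branch b (the edge above each non-root node).
    """
    index = {a: j for j, a in enumerate(asv_ids)}
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise ValidationError(f"ASV(s) not found as tree leaves: {missing[:10]}")
    lengths, rows = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(asv_ids), dtype=bool)
            j = index.get(node.name)
            if j is not None:
                mask[j] = True
        else:
            mask = np.zeros(len(asv_ids), dtype=bool)
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if node.parent is not None:  # the edge above this node
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.asarray(lengths), np.vstack(rows) if rows else np.zeros((0, len(asv_ids)), bool)


def unweighted_unifrac(
    tree: TreeNode, sample_a: Iterable[str], sample_b: Iterable[str]
) -> float:
    """Unweighted UniFrac distance between two presence sets of ASVs.

    The fraction of branch length, over all branches leading to at least one
    observed taxon, that leads exclusively to taxa of one sample. Bounded in
    [0, 1]; 0 for identical sets, 1 for phylogenetically disjoint ones.
    """
    set_a, set_b = set(sample_a), set(sample_b)
    if not set_a or not set_b:
        raise DomainError("each sample must contain at least one present taxon")
    asv_ids = sorted(set_a | set_b)
    lengths, descend = _branch_table(tree, asv_ids)
    in_a = descend[:, [asv_ids.index(a) for a in sorted(set_a)]].any(axis=1)
    in_b = descend[:, [asv_ids.index(b) for b in sorted(set_b)]].any(axis=1)
    either = in_a | in_b
    unique = in_a ^ in_b
    denom = float(lengths[either].sum())
    if denom == 0:
        return 0.0
    return float(lengths[unique].sum()) / denom


def unifrac_distance_matrix(tree: TreeNode, table: ASVTable) -> DistanceMatrix:
    """Pairwise unweighted UniFrac over all samples of an ASV table.

    Branch descendancy is computed once for the full ASV set and reused for
    every pair, so the cost is one tree traversal plus O(n^2) boolean work.
    """
    lengths, descend = _branch_table(tree, table.asv_ids)
    presence = table.presence()  # samples x ASVs
    if np.any(~presence.any(axis=1)):
        empty = [s for s, p in zip(table.sample_ids, presence) if not p.any()]
        raise DomainError(f"sample(s) with no present taxa: {empty}")
    # branch b observed in sample s iff any descendant ASV present
    observed = (descend.astype(np.int8) @ presence.T.astype(np.int8)) > 0  # branches x samples
    n = len(table.sample_ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            either = observed[:, i] | observed[:, j]
            unique = observed[:, i] ^ observed[:, j]
            denom = lengths[either].sum()
            dm[i, j] = dm[j, i] = (lengths[unique].sum() / denom) if denom > 0 else 0.0
    return DistanceMatrix(tuple(table.sample_ids), dm)


# ---------------------------------------------------------------------------
# Principal coordinate analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCoAResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x axes, ordered by eigenvalue
    explained: tuple[float, ...]  # proportion of positive-eigenvalue variance
    negative_eigenvalues: tuple[float, ...]


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Double-centres the squared distances (Gower's B = -J D^2 J / 2) and
    eigendecomposes; axes are ordered by eigenvalue, scaled by sqrt(lambda).
    Negative eigenvalues (non-Euclidean input) are reported and their axes
    dropped.
    """
    D = dm.data
    n = len(dm.ids)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(evals).max(initial=0.0)))
    positive = evals > tol
    negative = tuple(float(e) for e in evals[evals < -tol])
    pos_vals = evals[positive]
    pos_vecs = evecs[:, positive]
    k = min(n_axes, pos_vals.size)
    coords = pos_vecs[:, :k] * np.sqrt(pos_vals[:k])
    if k < n_axes:
        coords = np.hstack([coords, np.zeros((n, n_axes - k))])
    total = pos_vals.sum()
    explained = tuple(float(v / total) if total > 0 else 0.0 for v in pos_vals[:k])
    return PCoAResult(tuple(dm.ids), coords, explained, negative)


# ---------------------------------------------------------------------------
# Bootstrap core microbiome
# ---------------------------------------------------------------------------

def core_microbiome(
    table: ASVTable,
    n_resamples: int = DEFAULT_CORE_RESAMPLES,
    threshold: float = DEFAULT_CORE_THRESHOLD,
    seed: Optional[int] = None,
) -> CoreMicrobiomeResult:
    """Bootstrap-prevalence core detection (see module docstring)."""
    if n_resamples < 1:
        raise DomainError(f"n_resamples must be >= 1, got {n_resamples}")
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"threshold must lie in (0, 1], got {threshold}")
    n = len(table.sample_ids)
    if n < 2:
        raise InsufficientDataError("core detection needs >= 2 samples")
    rng = np.random.default_rng(seed)
    presence = table.presence()
    draws = rng.integers(0, n, size=(n_resamples, n))
    # prevail[r, a] = ASV a present in every sample drawn in resample r
    prevail = presence[draws].all(axis=1)
    fractions = prevail.mean(axis=0)
    prevalence = {a: float(f) for a, f in zip(table.asv_ids, fractions)}
    core = frozenset(a for a, f in prevalence.items() if f >= threshold)
    return CoreMicrobiomeResult(
        core_asv_ids=core,
        prevalence_fraction=prevalence,
        n_resamples=n_resamples,
        threshold=threshold,
        seed=seed,
    )
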