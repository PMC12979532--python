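"""Pedigree-based additive relationship matrix and genotype clustering.

The A matrix (numerator relationship matrix) is built with the classical
tabular method; `gene_drop_a_matrix` provides an algorithmically independent
Monte-Carlo estimate (simulated Mendelian allele transmission) used as an
oracle in validation.  Genotypes are then clustered by K-means on their
kinship row concatenated with mean location yield, mirroring how breeding
programs group lines of similar genetic background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class KinshipMatrix:
    """Additive relationship matrix with its genotype ordering.

    Entries are expected twice-kinship: diagonal 1 + F (inbreeding
    coefficient), parent-offspring 0.5 for unrelated non-inbred parents.
    """

    genotypes: list[str]
    values: np.ndarray

    def index_of(self, genotype: str) -> int:
        return self.genotypes.index(genotype)

    def validate(self, tol: float = 1e-8) -> None:
        A = self.values
        if not np.allclose(A, A.T, atol=tol):
            raise ValueError("A matrix must be symmetric")
        d = np.diag(A)
        if np.any(d < 1.0 - tol) or np.any(d > 2.0 + tol):
            raise ValueError("diagonal entries must lie in [1, 2]")


@dataclass
class ClusterAssignment:
    genotypes: list[str]
    labels: np.ndarray
    k: int
    inertia: float

    def as_mapping(self) -> dict[str, int]:
        return dict(zip(self.genotypes, (int(c) for c in self.labels)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genotype_id": self.genotypes, "cluster": self.labels})


def _topological_check(pedigree: pd.DataFrame) -> dict[str, int]:
    """Map individual -> row position; raise on unknown or out-of-order parents."""
    ids = pedigree["individual"].tolist()
    pos = {ind: i for i, ind in enumerate(ids)}
    if len(pos) != len(ids):
        raise ValueError("duplicate individuals in pedigree")
    for i, row in enumerate(pedigree.itertuples(index=False)):
        for parent in (row.sire, row.dam):
            if parent in ("", None) or (isinstance(parent, float) and np.isnan(parent)):
                continue
            if parent not in pos:
                raise ValueError(f"unknown parent {parent!r} for {row.individual!r}")
            if pos[parent] >= i:
                raise ValueError(
                    f"pedigree not topologically sorted (or cyclic) at {row.individual!r}")
    return pos


def _parents(pedigree: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (ids, sire index array, dam index array); -1 = unknown."""
    pos = _topological_check(pedigree)
    ids = pedigree["individual"].tolist()

    def idx(p):
        if p in ("", None) or (isinstance(p, float) and np.isnan(p)):
            return -1
        return pos[p]

    sire = np.array([idx(p) for p in pedigree["sire"]], dtype=int)
    dam = np.array([idx(p) for p in pedigree["dam"]], dtype=int)
    return ids, sire, dam


def a_matrix(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Tabular-method additive relationship matrix.

    Recursions (unknown parents contribute 0)::

        A[i, i] = 1 + 0.5 * A[sire_i, dam_i]
        A[i, j] = 0.5 * (A[j, sire_i] + A[j, dam_i])    for j earlier than i

    Founders with no recorded parents are treated as unrelated and
    non-inbred.
    """
    ids, sire, dam = _parents(pedigree)
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            j = np.arange(i)
            row = np.zeros(i)
            if s >= 0:
                row += A[j, s]
            if d >= 0:
                row += A[j, d]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return KinshipMatrix(genotypes=ids, values=A)


def gene_drop_a_matrix(
    pedigree: pd.DataFrame, n_replicates: int = 100_000, seed: int = 0
) -> KinshipMatrix:
    """Monte-Carlo estimate of the A matrix by gene dropping.

    Each founder receives two unique allele labels; every descendant
    inherits one random parental allele per gamete, independently across
    replicates.  A[i, j] is estimated as twice the probability that an
    allele drawn from i and one drawn from j are identical by descent.
    Independent of the tabular recursion, hence usable as an oracle.
    """
    ids, sire, dam = _parents(pedigree)
    n = len(ids)
    rng = np.random.default_rng(seed)
    # alleles[i, r, 0/1]: allele labels of individual i in replicate r
    alleles = np.empty((n, n_replicates, 2), dtype=np.int32)
    next_label = 0
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            alleles[i, :, 0] = next_label
            alleles[i, :, 1] = next_label + 1
            next_label += 2
        else:
            for slot, p in enumerate((s, d)):
                if p < 0:
                    alleles[i, :, slot] = next_label
                    next_label += 1
                else:
                    pick = rng.integers(0, 2, size=n_replicates)
                    alleles[i, :, slot] = alleles[p, np.arange(n_replicates), pick]
    A = np.empty((n, n))
    for i in range(n):
        ai = alleles[i]
        for j in range(i, n):
            aj = alleles[j]
            # P(random allele of i IBD to random allele of j), averaged
            # over the four allele pairings, doubled.
            match = sum(
                (ai[:, a] == aj[:, b]).mean() for a in (0, 1) for b in (0, 1))
            if i == j:
                # Self-kinship: drawing the same allele twice is IBD by
                # definition; the 4-pairing average counts each allele pair
                # twice, so the diagonal needs the within-individual form.
                f = (ai[:, 0] == ai[:, 1]).mean()  # inbreeding coefficient
                A[i, i] = 1.0 + f
            else:
                A[i, j] = A[j, i] = match / 2.0
    return KinshipMatrix(genotypes=ids, values=A)


def cluster_features(A: KinshipMatrix, records: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype features: kinship row + mean yield across environments.

    Genotypes without trial records get the global mean yield.  Columns are
    standardized (zero mean, unit variance; degenerate columns left at 0).
    """
    if records.empty:
        raise ValueError("record set is empty")
    mean_yield = records.groupby("genotype_id")["yield"].mean()
    global_mean = records["yield"].mean()
    my = np.array([mean_yield.get(g, global_mean) for g in A.genotypes])
    feats = np.column_stack([A.values, my])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((feats - mu) / sd, index=A.genotypes)


def cluster_genotypes(features: pd.DataFrame, k: int, seed: int = 0) -> ClusterAssignment:
    """K-means (k-means++ init, fixed seed) over the feature table."""
    n = len(features)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(features.to_numpy())
    return ClusterAssignment(genotypes=list(features.index), labels=labels,
                             k=k, inertia=float(km.inertia_))


def select_k(
    features: pd.DataFrame, candidate_ks: list[int], seed: int = 0
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count maximizing mean silhouette.

    Returns the chosen k and a diagnostics table (k, inertia, silhouette)
    so a user can override the choice.
    """
    if not candidate_ks:
        raise ValueError("candidate k list is empty")
    rows = []
    X = features.to_numpy()
    for k in candidate_ks:
        assign = cluster_genotypes(features, k, seed=seed)
        if 1 < k < len(features):
            sil = float(silhouette_score(X, assign.labels))
        else:
            sil = float("nan")
        rows.append({"k": k, "inertia": assign.inertia, "silhouette": sil})
    diag = pd.DataFrame(rows)
    if diag["silhouette"].notna().any():
        best = int(diag.loc[diag["silhouette"].idxmax(), "k"])
    else:
        best = int(candidate_ks[0])
    return best, diag


def write_kinship_csv(A: KinshipMatrix, path) -> None:
    pd.DataFrame(A.values, index=A.genotypes, columns=A.genotypes).to_csv(path)
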