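"""Nucleotide-composition characterization of probe sets.

Each probe is summarized by 22 features: the 4 mononucleotide
frequencies, the 16 overlapping-dinucleotide frequencies, and the
overall G/C and A/T fractions. Group structure among platform-exclusive
probe sets is tested with a distance-based permutation MANOVA
(pseudo-F on Euclidean distances of z-scored features), explored with a
correlation-matrix PCA, and dissected with per-feature post-hoc ANOVAs
under Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._seq import stage_rng
from .exceptions import DataError, InsufficientDataError

MONONUCLEOTIDES = tuple("ACGT")
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")
#: feature order: 4 mono + 16 dinucleotide frequencies + overall G/C and A/T
FEATURES = MONONUCLEOTIDES + DINUCLEOTIDES + ("G/C", "A/T")


def composition(seq: str) -> pd.Series:
    """22-feature composition vector of one sequence (length >= 2, ACGT only)."""
    if len(seq) < 2:
        raise DataError("sequence must have length >= 2")
    if set(seq) - set("ACGT"):
        raise DataError(f"non-ACGT symbol in sequence: {sorted(set(seq) - set('ACGT'))}")
    L = len(seq)
    vals = {b: seq.count(b) / L for b in MONONUCLEOTIDES}
    ndi = L - 1
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(ndi):
        counts[seq[i : i + 2]] += 1
    for d in DINUCLEOTIDES:
        vals[d] = counts[d] / ndi
    vals["G/C"] = vals["G"] + vals["C"]
    vals["A/T"] = vals["A"] + vals["T"]
    return pd.Series([vals[f] for f in FEATURES], index=list(FEATURES))


def composition_matrix(seqs, index=None) -> pd.DataFrame:
    """Stack composition vectors for an iterable of sequences."""
    df = pd.DataFrame([composition(s) for s in seqs])
    if index is not None:
        df.index = index
    return df


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    dropped_features: list[str]


def pca(X: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Principal components of the composition matrix.

    By default features are z-scored (correlation PCA) because bounded
    frequencies have very different variances. Zero-variance features
    are dropped with a warning. Component signs are fixed so the largest
    absolute loading of each component is positive.
    """
    if len(X) < 2:
        raise InsufficientDataError("need at least 2 rows for PCA")
    sd = X.std(axis=0, ddof=0)
    dropped = list(X.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    Xk = X[[c for c in X.columns if c not in dropped]]
    M = Xk.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    if scale:
        M = M / Xk.std(axis=0, ddof=0).to_numpy()
    model = PCA()
    scores = model.fit_transform(M)
    loadings = model.components_.T  # features x comps
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        loadings=pd.DataFrame(loadings, index=Xk.columns, columns=names),
        explained_variance_ratio=model.explained_variance_ratio_,
        dropped_features=dropped,
    )


def composition_distance(X: pd.DataFrame, standardize: bool = True) -> np.ndarray:
    """Square Euclidean distance matrix on (optionally z-scored) features."""
    M = X.to_numpy(dtype=float)
    if standardize:
        sd = M.std(axis=0)
        keep = sd > 0
        M = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    return squareform(pdist(M, metric="euclidean"))


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = len(labels)
    sst = d2.sum() / (2.0 * n)
    ssw = 0.0
    for g in uniq:
        m = labels == g
        ng = int(m.sum())
        ssw += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    k = len(uniq)
    return ((sst - ssw) / (k - 1)) / (ssw / (n - k))


def permutation_manova(
    dist: np.ndarray, labels, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """Distance-based MANOVA (PERMANOVA) with label-permutation p-value.

    pseudo-F = [(SS_total - SS_within)/(k-1)] / [SS_within/(N-k)] with
    sums of squared distances; p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise DataError("distance matrix must be symmetric with zero diagonal")
    labels = np.asarray(labels)
    if len(labels) != d.shape[0]:
        raise DataError("labels length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise InsufficientDataError("need >= 2 groups, each with >= 2 members")
    d2 = d**2
    f_obs = _pseudo_f(d2, labels, uniq)
    rng = stage_rng(seed, "permanova")
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, uniq) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), int(n_permutations), int(seed))


def pairwise_permanova(
    X: pd.DataFrame,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Pairwise PERMANOVAs among groups with BH-FDR-adjusted p-values.

    Columns: group1, group2, pseudo_f, p, p_fdr.
    """
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    rows = []
    for g1, g2 in combinations(groups, 2):
        mask = (labels == g1) | (labels == g2)
        sub = X[mask]
        res = permutation_manova(
            composition_distance(sub, standardize=standardize),
            labels[mask],
            n_permutations=n_permutations,
            seed=seed,
        )
        rows.append({"group1": g1, "group2": g2, "pseudo_f": res.pseudo_f, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def posthoc_anovas(X: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-feature one-way ANOVAs with Bonferroni correction.

    The Bonferroni factor is the number of features tested. Columns:
    feature, F, p, p_bonferroni.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise InsufficientDataError("need at least 2 groups")
    n_features = X.shape[1]
    rows = []
    for feat in X.columns:
        groups = [X.loc[labels == g, feat].to_numpy(dtype=float) for g in uniq]
        if any(len(g) < 2 for g in groups):
            raise InsufficientDataError(f"a group has < 2 members for feature {feat}")
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            f, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*groups)
            if np.isnan(f):  # constant within the pooled tolerance
                f, p = 0.0, 1.0
        rows.append(
            {
                "feature": feat,
                "F": float(f),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * n_features)),
            }
        )
    return pd.DataFrame(rows)
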