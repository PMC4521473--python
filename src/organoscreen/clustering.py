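"""Phenotypic clustering and dose-sequence classification.

Per-dose treatment profiles (replicate-averaged z-scored vectors on the
selected features) are grouped by Ward hierarchical clustering; the number
of clusters is chosen from the Davies–Bouldin index (Calinski–Harabasz is
computed alongside as a second opinion).  Each class gets a signed
signature: the mean z-score vector F and partition sizes
%(i) = F_i / Σ_j F_j (both signed; values outside [0, 100 %] are legal).
Each treatment's doses are then assigned to the nearest class centroid —
profiles below an effect floor get a distinguished "no-effect" label — and
a general class is derived from the prevalence of labels across the dose
range.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

__all__ = [
    "DoseProfile",
    "ClusterModel",
    "ClassSequence",
    "NO_EFFECT",
    "build_dose_profiles",
    "ward_cluster",
    "cross_half_stability",
    "choose_k",
    "class_signature",
    "fit_cluster_model",
    "assign_dose_labels",
    "assign_general_class",
]

NO_EFFECT = "no-effect"


@dataclass
class DoseProfile:
    """Replicate-averaged feature vector of one (treatment, dose)."""

    treatment: str
    dose: float
    values: pd.Series


def build_dose_profiles(
    normalized: pd.DataFrame,
    plate_map: pd.DataFrame,
    features: list[str],
) -> pd.DataFrame:
    """Average replicate wells into one observation per (treatment, dose).

    Returns a (treatment, dose)-indexed table over the selected features;
    replicates are averaged before clustering, doses are kept separate.
    """
    pm = plate_map.set_index("well")
    treat = pm[pm["role"] == "treatment"]
    rows = {}
    for (t, d), grp in treat.groupby(["treatment", "dose"], sort=True):
        wells = [w for w in grp.index if w in normalized.index]
        if not wells:
            continue
        rows[(t, float(d))] = normalized.loc[wells, features].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["treatment", "dose"])
    return out.sort_index()


def ward_cluster(profiles: pd.DataFrame, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage agglomerative clustering cut at k clusters.

    Returns (labels in 1..k, linkage matrix).  Euclidean distance on the
    (already z-scored) selected features.
    """
    x = np.asarray(profiles, dtype=float)
    if np.isnan(x).any():
        raise ValueError("clustering requires complete observations")
    n = len(x)
    if k < 2 or k > n - 1:
        raise ValueError(f"k must be in [2, n-1]; got k={k} with n={n}")
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return labels, z


def cross_half_stability(profiles: pd.DataFrame, k: int, n_splits: int = 5,
                         seed: int = 0) -> float:
    """2-fold stability diagnostic for a Ward clustering at k.

    Observations are split into halves; each half is clustered on its own
    and the other half's points are attached to the nearest centroid.  The
    score is the mean agreement (over splits) between the two induced full
    labelings, measured on co-clustered pairs (Rand-style).  Reported as a
    diagnostic; it does not alter the choice of k.
    """
    x = np.asarray(profiles, dtype=float)
    n = len(x)
    if n < 2 * k + 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        halves = perm[: n // 2], perm[n // 2:]
        full_labels = []
        for half in halves:
            lab, _ = ward_cluster(profiles.iloc[half], k)
            centroids = np.vstack([x[half][lab == c].mean(axis=0)
                                   for c in range(1, k + 1)])
            d = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            full_labels.append(d.argmin(axis=1))
        a, b = full_labels
        same_a = a[:, None] == a[None, :]
        same_b = b[:, None] == b[None, :]
        iu = np.triu_indices(n, 1)
        scores.append(float((same_a[iu] == same_b[iu]).mean()))
    return float(np.mean(scores))


def choose_k(
    profiles: pd.DataFrame,
    k_range: tuple[int, int] = (2, 10),
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count from internal validity indices.

    Computes the Davies–Bouldin (lower better) and Calinski–Harabasz
    (higher better) indices for each k in ``k_range`` on Ward labelings and
    returns the k minimising Davies–Bouldin, together with both index
    curves.  On disagreement both curves are still reported and the
    Davies–Bouldin choice is taken.
    """
    n = len(profiles)
    lo, hi = k_range
    hi = min(hi, n - 1)
    if n <= lo:
        raise ValueError("need more observations than the smallest k")
    x = np.asarray(profiles, dtype=float)
    records = []
    for k in range(lo, hi + 1):
        labels, _ = ward_cluster(profiles, k)
        if len(np.unique(labels)) < 2:
            records.append((k, np.inf, -np.inf))
            continue
        records.append((
            k,
            davies_bouldin_score(x, labels),
            calinski_harabasz_score(x, labels),
        ))
    curves = pd.DataFrame(records, columns=["k", "davies_bouldin", "calinski_harabasz"])
    curves = curves.set_index("k")
    best = int(curves["davies_bouldin"].idxmin())
    return best, curves


def class_signature(members: pd.DataFrame) -> tuple[pd.Series, pd.Series | None]:
    """Signed class signature: F and partition sizes %(i).

    F_i is the mean z-score of feature i over the class members;
    %(i) = F_i / Σ_j F_j (signed, as a percentage).  When Σ_j F_j = 0 the
    partition sizes are undefined and None is returned for them, with the
    raw F still reported.
    """
    if len(members) < 1:
        raise ValueError("a class signature needs at least one member")
    f = members.mean(axis=0)
    total = float(f.sum())
    if total == 0:
        return f, None
    return f, 100.0 * f / total


@dataclass
class ClusterModel:
    """Fitted phenotypic class definitions."""

    k: int
    features: list[str]
    labels: pd.Series  # (treatment, dose) -> class letter
    centroids: pd.DataFrame  # class letter × features
    signatures: dict[str, tuple[pd.Series, pd.Series | None]]
    index_curves: pd.DataFrame
    linkage: np.ndarray
    stability: float = float("nan")
    effect_floor: float = 1.0

    @property
    def class_names(self) -> list[str]:
        return list(self.centroids.index)


def _letters(k: int) -> list[str]:
    alphabet = string.ascii_uppercase
    return [alphabet[i % 26] * (i // 26 + 1) for i in range(k)]


def fit_cluster_model(
    profiles: pd.DataFrame,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
    effect_floor: float = 1.0,
    stability_seed: int = 0,
) -> ClusterModel:
    """Cluster dose profiles into phenotypic classes A, B, ...

    If ``k`` is None it is chosen by :func:`choose_k`.  Classes are
    lettered by decreasing size (ties by first occurrence).  A cross-half
    stability diagnostic is attached.
    """
    best_k, curves = choose_k(profiles, k_range)
    if k is None:
        k = best_k
    labels, z = ward_cluster(profiles, k)
    order = []
    sizes = {c: int((labels == c).sum()) for c in range(1, k + 1)}
    first_pos = {c: int(np.argmax(labels == c)) for c in range(1, k + 1)}
    for c in sorted(sizes, key=lambda c: (-sizes[c], first_pos[c])):
        order.append(c)
    letter_of = {c: letter for c, letter in zip(order, _letters(k))}
    lettered = pd.Series([letter_of[c] for c in labels], index=profiles.index)
    centroids = pd.DataFrame(
        {letter_of[c]: profiles[labels == c].mean(axis=0) for c in order}
    ).T
    signatures = {
        letter_of[c]: class_signature(profiles[labels == c]) for c in order
    }
    return ClusterModel(
        k=k,
        features=list(profiles.columns),
        labels=lettered,
        centroids=centroids,
        signatures=signatures,
        index_curves=curves,
        linkage=z,
        stability=cross_half_stability(profiles, k, seed=stability_seed),
        effect_floor=effect_floor,
    )


@dataclass
class ClassSequence:
    """Ordered (low → high dose) class labels of one treatment."""

    treatment: str
    doses: list[float]
    labels: list[str]
    general_class: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.labels):
            raise ValueError("one label per dose")
        self.general_class = assign_general_class(self.labels)


def assign_dose_labels(
    treatment: str,
    profiles: pd.DataFrame,
    model: ClusterModel,
    effect_floor: float | None = None,
) -> ClassSequence:
    """Label each dose of a treatment with the nearest class centroid.

    A dose profile whose root-mean-square z-score over the selected
    features falls below the effect floor (default 1 z-unit) receives the
    distinguished "no-effect" label; the RMS form keeps the floor
    comparable across selected-feature-set sizes.
    """
    if effect_floor is None:
        effect_floor = model.effect_floor
    sub = profiles.loc[treatment]
    doses = sorted(float(d) for d in sub.index)
    cent = model.centroids[model.features]
    labels = []
    for d in doses:
        vec = sub.loc[d, model.features].to_numpy(dtype=float)
        if float(np.linalg.norm(vec)) / math.sqrt(len(vec)) < effect_floor:
            labels.append(NO_EFFECT)
            continue
        dist = ((cent.to_numpy() - vec[None, :]) ** 2).sum(axis=1)
        labels.append(cent.index[int(dist.argmin())])
    return ClassSequence(treatment=treatment, doses=doses, labels=labels)


def assign_general_class(labels: list[str]) -> str:
    """Prevalence-based general class of a dose-label sequence.

    The most frequent non-"no-effect" label wins; ties go to the tied label
    occurring at the highest dose; an all-"no-effect" sequence stays
    "no-effect".
    """
    if not labels:
        raise ValueError("empty label sequence")
    effect = [lab for lab in labels if lab != NO_EFFECT]
    if not effect:
        return NO_EFFECT
    counts: dict[str, int] = {}
    for lab in effect:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == top}
    if len(tied) == 1:
        return tied.pop()
    for lab in reversed(labels):  # highest dose last
        if lab in tied:
            return lab
    raise AssertionError("unreachable")
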