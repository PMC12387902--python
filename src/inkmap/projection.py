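"""2-D projection of subjects and linear group-separation counting.

Subjects are embedded on a plane so that inter-point distances
approximate the multivariate distances between their scaled coding
profiles (classical metric multidimensional scaling).  Group
separability is then quantified by exhaustively searching linear
separators in the plane and counting the minimum number of subjects
on the wrong side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cohort import ScaledMatrix


@dataclass
class Embedding2D:
    subject_ids: list[str]
    groups: list[str]
    coords: np.ndarray  # (n, 2)
    stress: float
    method: str

    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


def project_mds(
    scaled: ScaledMatrix,
    metric: str = "euclidean",
    mode: str = "classical",
    seed: int | None = 0,
) -> Embedding2D:
    """Project subjects to 2-D by metric multidimensional scaling.

    ``mode='classical'`` is Torgerson's method: square the distance
    matrix, double-center to recover a Gram matrix, and take the top two
    eigenvectors scaled by the square roots of their eigenvalues.  It is
    deterministic up to the sign of each axis; each axis is oriented so
    the first subject's coordinate is >= 0.  ``mode='smacof'`` runs
    iterative stress majorization with a fixed seed.

    Parameters
    ----------
    metric : str
        Distance between scaled rows: ``'euclidean'`` (default) or
        ``'manhattan'``.
    """
    n = scaled.values.shape[0]
    if n < 3:
        raise ValueError("projection needs at least 3 subjects")
    metric_ = {"euclidean": "euclidean", "manhattan": "cityblock"}.get(metric)
    if metric_ is None:
        raise ValueError(f"unknown metric {metric!r}")
    D = squareform(pdist(scaled.values, metric_))

    if mode == "classical":
        J = np.eye(n) - 1.0 / n
        B = -0.5 * J @ (D ** 2) @ J
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1][:2]
        lam = np.clip(eigval[order], 0.0, None)  # rank-deficient -> zero-padded axis
        coords = eigvec[:, order] * np.sqrt(lam)
    elif mode == "smacof":
        from sklearn.manifold import MDS

        mds = MDS(
            n_components=2, dissimilarity="precomputed",
            normalized_stress=False, random_state=seed,
        )
        coords = mds.fit_transform(D)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # axis-sign convention: first subject's coordinate >= 0 on each axis
    for k in range(2):
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]

    De = squareform(pdist(coords))
    denom = (D ** 2).sum()
    stress = float(np.sqrt(((D - De) ** 2).sum() / denom)) if denom > 0 else 0.0
    return Embedding2D(
        list(scaled.subject_ids), list(scaled.groups), coords, stress,
        method=f"{mode}-{metric}",
    )


@dataclass
class SeparationResult:
    misplaced_count: int
    misplaced_ids: list[str]
    direction: tuple[float, float]
    offset: float


def _candidate_directions(coords: np.ndarray) -> list[np.ndarray]:
    dirs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[j] - coords[i]
            if np.allclose(d, 0):
                continue
            dirs.append(d)
            dirs.append(np.array([-d[1], d[0]]))
    return dirs


def linear_separation_count(emb: Embedding2D) -> SeparationResult:
    """Minimum misclassification over all linear separators of the plane.

    Candidate separator normals are the axis directions plus, for every
    pair of embedded points, their difference vector and its
    perpendicular; for each normal all thresholds between consecutive
    projections are swept.  Among minimum-error separators, ties break
    toward fewer misplaced INPH subjects, then toward the
    lexicographically smallest misplaced-id list.
    """
    groups = np.asarray(emb.groups)
    ids = np.asarray(emb.subject_ids)
    n = len(ids)
    for g in ("AD", "INPH"):
        if not (groups == g).any():
            raise ValueError(f"group {g!r} is empty")

    is_inph = (groups == "INPH").astype(int)
    total_inph = int(is_inph.sum())
    best: tuple | None = None

    for d in _candidate_directions(emb.coords):
        proj = emb.coords @ d
        order = np.argsort(proj, kind="stable")
        cum_inph = np.concatenate([[0], np.cumsum(is_inph[order])])
        for k in range(n + 1):
            left_inph = int(cum_inph[k])
            left_ad = k - left_inph
            # left side assigned to AD: misplace left INPH + right AD
            for left_group in ("AD", "INPH"):
                if left_group == "AD":
                    mis = left_inph + (n - k) - (total_inph - left_inph)
                else:
                    mis = left_ad + (total_inph - left_inph)
                if best is not None and mis > best[0][0]:
                    continue
                if left_group == "AD":
                    wrong = [
                        *(ids[s] for s in order[:k] if groups[s] == "INPH"),
                        *(ids[s] for s in order[k:] if groups[s] == "AD"),
                    ]
                else:
                    wrong = [
                        *(ids[s] for s in order[:k] if groups[s] == "AD"),
                        *(ids[s] for s in order[k:] if groups[s] == "INPH"),
                    ]
                mis_inph = int(np.sum(groups[np.isin(ids, wrong)] == "INPH")) if wrong else 0
                key = (mis, mis_inph, tuple(sorted(map(str, wrong))))
                if best is None or key < best[0]:
                    if k == 0:
                        thr = float(proj[order[0]] - 1.0) if n else 0.0
                    elif k == n:
                        thr = float(proj[order[-1]] + 1.0)
                    else:
                        thr = float((proj[order[k - 1]] + proj[order[k]]) / 2.0)
                    best = (key, d / np.linalg.norm(d), thr)

    (mis, _, wrong), d, thr = best
    return SeparationResult(int(mis), list(wrong), (float(d[0]), float(d[1])), thr)
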