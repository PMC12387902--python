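"""5x5 self-organizing map over the scaled cohort.

A Kohonen map clusters subjects on a small rectangular grid: each grid
unit carries a codebook vector in variable space, records are presented
one at a time, the best-matching unit (BMU, nearest codebook by
Euclidean distance) and its grid neighborhood are pulled toward the
record, and the learning rate and neighborhood radius anneal over
epochs.  With 19 subjects on a 5x5 grid a well-converged map gives
almost every subject its own class; subjects with identical codings
necessarily share one.

Classes are named ``"row.col"`` with 1-based indices, so the top-left
unit is class 1.1 and the bottom-left unit class 5.1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .cohort import ScaledMatrix


@dataclass
class SOMConfig:
    rows: int = 5
    cols: int = 5
    epochs: int = 1000
    lr_initial: float = 0.5
    lr_final: float = 0.02
    radius_initial: float = 1.5
    radius_final: float = 0.02
    decay: str = "exponential"  # or "linear"
    init: str = "random"  # or "pca"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols) < 1 or self.epochs < 1:
            raise ValueError("grid size and epochs must be positive")
        for lo, hi in [(self.lr_final, self.lr_initial),
                       (self.radius_final, self.radius_initial)]:
            if not (0 < lo <= hi):
                raise ValueError("rates and radii must be positive and non-increasing")
        if self.decay not in ("exponential", "linear"):
            raise ValueError(f"unknown decay {self.decay!r}")


@dataclass
class SOMModel:
    config: SOMConfig
    codebook: np.ndarray  # (rows*cols, n_variables)
    variable_names: list[str]
    quantization_errors: list[float] = field(default_factory=list)

    def grid_coords(self) -> np.ndarray:
        r, c = self.config.rows, self.config.cols
        return np.array([(i, j) for i in range(r) for j in range(c)], dtype=float)

    def bmu(self, x: np.ndarray) -> int:
        """Index of the best-matching unit; ties go to the lowest
        (row, col) because the codebook is stored row-major."""
        return int(np.argmin(((self.codebook - x) ** 2).sum(axis=1)))


def _schedule(cfg: SOMConfig, epoch: int) -> tuple[float, float]:
    t = epoch / max(cfg.epochs - 1, 1)
    if cfg.decay == "linear":
        lr = cfg.lr_initial + (cfg.lr_final - cfg.lr_initial) * t
        rad = cfg.radius_initial + (cfg.radius_final - cfg.radius_initial) * t
    else:
        lr = cfg.lr_initial * (cfg.lr_final / cfg.lr_initial) ** t
        rad = cfg.radius_initial * (cfg.radius_final / cfg.radius_initial) ** t
    return lr, rad


def _pca_init(X: np.ndarray, grid: np.ndarray, cfg: SOMConfig) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    g1 = (grid[:, 0] - (cfg.rows - 1) / 2) / max((cfg.rows - 1) / 2, 1)
    g2 = (grid[:, 1] - (cfg.cols - 1) / 2) / max((cfg.cols - 1) / 2, 1)
    W = X.mean(axis=0) + np.outer(g1, vt[0] * sv[0]) / np.sqrt(len(X))
    if len(sv) > 1:
        W = W + np.outer(g2, vt[1] * sv[1]) / np.sqrt(len(X))
    return W


def train_som(scaled: ScaledMatrix, config: SOMConfig | None = None) -> SOMModel:
    """Online Kohonen training with a Gaussian neighborhood.

    Reproducible for a fixed seed: both the codebook initialization and
    the per-epoch record presentation order (a seeded shuffle) are drawn
    from one generator.
    """
    cfg = config or SOMConfig()
    X = np.asarray(scaled.values, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    rng = np.random.default_rng(cfg.seed)
    n_units = cfg.rows * cfg.cols
    grid = np.array([(i, j) for i in range(cfg.rows) for j in range(cfg.cols)], dtype=float)
    if cfg.init == "pca":
        W = _pca_init(X, grid, cfg)
    else:
        W = rng.uniform(0.0, 1.0, size=(n_units, X.shape[1]))
    def _qe(W_):
        return float(
            np.mean(np.sqrt(((W_[None, :, :] - X[:, None, :]) ** 2).sum(-1).min(1)))
        )

    qe_history = [_qe(W)]  # entry 0: the untrained codebook
    for epoch in range(cfg.epochs):
        lr, rad = _schedule(cfg, epoch)
        for i in rng.permutation(len(X)):
            x = X[i]
            bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            d2 = ((grid - grid[bmu]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * rad * rad))
            W += lr * h[:, None] * (x - W)
        qe_history.append(_qe(W))
    return SOMModel(cfg, W, list(scaled.variable_names), qe_history)


@dataclass
class SOMAssignment:
    classes: dict[str, str]  # subject_id -> "row.col"
    occupants: dict[str, list[str]]  # class label -> subject ids


def class_label(unit: int, cfg: SOMConfig) -> str:
    return f"{unit // cfg.cols + 1}.{unit % cfg.cols + 1}"


def assign_classes(model: SOMModel, scaled: ScaledMatrix) -> SOMAssignment:
    """Map each subject to the class of its best-matching unit."""
    if scaled.values.shape[1] != model.codebook.shape[1]:
        raise ValueError("variable dimension mismatch between model and data")
    classes: dict[str, str] = {}
    occupants: dict[str, list[str]] = {}
    for sid, x in zip(scaled.subject_ids, scaled.values):
        lab = class_label(model.bmu(np.asarray(x, float)), model.config)
        classes[sid] = lab
        occupants.setdefault(lab, []).append(sid)
    return SOMAssignment(classes, occupants)


def class_sharing_count(assign: SOMAssignment) -> int:
    """Number of grid cells occupied by two or more subjects."""
    return sum(1 for subs in assign.occupants.values() if len(subs) >= 2)


def component_plane(model: SOMModel, variable: str) -> tuple[np.ndarray, float]:
    """Codebook values of one variable arranged on the grid.

    Returns the (rows, cols) matrix and a concentration score, the
    maximum cell value minus the grid mean: near zero for variables
    spread evenly over the map, large for variables peaking in a few
    classes only.
    """
    try:
        j = model.variable_names.index(variable)
    except ValueError:
        raise KeyError(f"unknown variable {variable!r}") from None
    plane = model.codebook[:, j].reshape(model.config.rows, model.config.cols)
    concentration = float(plane.max() - plane.mean())
    return plane, concentration


def sharing_counts_over_seeds(
    scaled: ScaledMatrix, seeds, config: SOMConfig | None = None
) -> list[int]:
    """Train one map per seed and collect shared-class counts."""
    base = config or SOMConfig()
    out = []
    for s in seeds:
        cfg = SOMConfig(**{**vars(base), "seed": int(s)})
        model = train_som(scaled, cfg)
        out.append(class_sharing_count(assign_classes(model, scaled)))
    return out


def modal_sharing_count(counts) -> int:
    return Counter(counts).most_common(1)[0][0]
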