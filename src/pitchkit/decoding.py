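"""Tilt-evoked fluorescence analysis and population decoding of tilt direction.

Each Purkinje cell is recorded over repeated rapid pitch tilts, nose-up and
nose-down.  Traces are normalized to a baseline (dF/F), summarized per trial
either as the integral over the 15 s stimulus (eccentric +/-30 deg protocol)
or as the peak dF/F in the first second after return (+/-19 deg return
protocol).  A directionality index

    DI = (mean_up - mean_down) / (mean_up + mean_down)

classifies cells as tuned (|DI| > 0.35) or untuned.  Even untuned cells can
carry direction information collectively: trials x cells response matrices
are visualized with PCA and decoded with a linear support vector machine
under stratified k-fold cross-validation, against a null distribution from
100 label shuffles.  Pseudo-populations of increasing size quantify how
decoding accuracy grows with ensemble size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, KFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DI_CUTOFF = 0.35
N_SHUFFLES = 100
K_FOLDS = 5
DEFAULT_SIZES = (3, 5, 7, 10, 13)


def dff(trace: np.ndarray, baseline_mean: float) -> np.ndarray:
    """(F - F0) / F0 per sample; the baseline must be positive."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    trace = np.asarray(trace, dtype=float)
    return (trace - baseline_mean) / baseline_mean


def integrated_response(
    dff_trace: np.ndarray, fs: float = 3.82, stimulus_window: float = 15.0
) -> float:
    """Trapezoidal integral of dF/F over the stimulus window [dFF*s].

    The window starts at the first sample; it must fit inside the trace.
    """
    dff_trace = np.asarray(dff_trace, dtype=float)
    n = int(np.floor(stimulus_window * fs)) + 1
    if n > dff_trace.size:
        raise ValueError(
            f"stimulus window of {stimulus_window} s needs {n} samples at "
            f"{fs} volumes/s, trace has {dff_trace.size}"
        )
    return float(np.trapezoid(dff_trace[:n], dx=1.0 / fs))


def peak_first_second(dff_trace: np.ndarray, fs: float = 3.82,
                      return_index: int = 0) -> float:
    """Maximum dF/F within (0, 1] s after the return sample.

    At 3.82 volumes/s that is a maximum over 3 samples.
    """
    dff_trace = np.asarray(dff_trace, dtype=float)
    k = int(np.floor(fs * 1.0))
    lo, hi = return_index + 1, return_index + k + 1
    if hi > dff_trace.size:
        raise ValueError("fewer than 1 s of post-return samples")
    return float(np.max(dff_trace[lo:hi]))


def directionality_index(mean_up: float, mean_down: float) -> float:
    """DI = (mean_up - mean_down) / (mean_up + mean_down); nose-up positive.

    A non-positive denominator (possible with negative integrals) makes the
    index unbounded; such cells are unclassifiable and should be excluded.
    """
    denom = mean_up + mean_down
    if denom <= 0:
        raise ValueError("non-positive response sum; cell unclassifiable")
    return (mean_up - mean_down) / denom


def classify_tuning(di: float, cutoff: float = DI_CUTOFF) -> str:
    """tuned_up iff DI > cutoff, tuned_down iff DI < -cutoff, else untuned.

    The boundary is strict: |DI| exactly at the cutoff is untuned.
    """
    if not np.isfinite(di):
        raise ValueError("DI must be finite")
    if di > cutoff:
        return "tuned_up"
    if di < -cutoff:
        return "tuned_down"
    return "untuned"


@dataclass
class CellResponse:
    """Per-trial responses of one cell with its direction tuning summary."""

    cell_id: str
    responses: np.ndarray  # per-trial statistic, dFF*s
    directions: np.ndarray  # "up"/"down" per trial
    mean_up: float
    mean_down: float
    di: float
    tuning_class: str


def build_cell_response(
    cell_id: str,
    responses: np.ndarray,
    directions: np.ndarray,
    cutoff: float = DI_CUTOFF,
) -> CellResponse | None:
    """Summarize one cell; returns None (logged) if the DI is degenerate."""
    responses = np.asarray(responses, dtype=float)
    directions = np.asarray(directions, dtype=object)
    up = responses[directions == "up"]
    down = responses[directions == "down"]
    if up.size < 2 or down.size < 2:
        raise ValueError("need at least 2 trials per direction")
    mean_up, mean_down = float(np.mean(up)), float(np.mean(down))
    try:
        di = directionality_index(mean_up, mean_down)
    except ValueError:
        logger.warning("cell %s: non-positive response sum; excluded", cell_id)
        return None
    return CellResponse(
        cell_id=cell_id,
        responses=responses,
        directions=directions,
        mean_up=mean_up,
        mean_down=mean_down,
        di=float(di),
        tuning_class=classify_tuning(di, cutoff=cutoff),
    )


def response_matrix(cells: list[CellResponse]) -> tuple[np.ndarray, np.ndarray]:
    """Stack cells into a trials x cells matrix with direction labels.

    Cells need not have been recorded simultaneously: trials are aligned by
    type (all up trials first, then all down), which is exactly the
    pseudo-population construction.  Trial counts per direction must match
    across cells.
    """
    if not cells:
        raise ValueError("no cells")
    n_up = int(np.sum(cells[0].directions == "up"))
    n_down = int(np.sum(cells[0].directions == "down"))
    cols = []
    for c in cells:
        up = c.responses[c.directions == "up"]
        down = c.responses[c.directions == "down"]
        if up.size != n_up or down.size != n_down:
            raise ValueError("trial counts per direction differ across cells")
        cols.append(np.concatenate([up, down]))
    M = np.column_stack(cols)
    labels = np.array(["up"] * n_up + ["down"] * n_down, dtype=object)
    return M, labels


def pca_projection(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered PCA of a trials x cells matrix.

    Returns trial scores on the first two components (zero-padded when the
    matrix has rank < 2) and the per-component variance fractions.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 3:
        raise ValueError("need at least 3 trials and 2 cells")
    n_comp = min(M.shape[0] - 1, M.shape[1])
    pca = PCA(n_components=n_comp)
    scores_full = pca.fit_transform(M)
    scores = np.zeros((M.shape[0], 2))
    scores[:, : min(2, n_comp)] = scores_full[:, : min(2, n_comp)]
    return scores, pca.explained_variance_ratio_


class TiltDecoder(BaseEstimator, ClassifierMixin):
    """Linear-kernel SVM over standardized integrated responses.

    A thin sklearn estimator (features are standardized inside the pipeline,
    so cross-validation standardizes on each training fold only) exposing the
    conventional unit regularization strength as a parameter.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def _pipeline(self):
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=self.C))

    def fit(self, X, y) -> "TiltDecoder":
        X = np.asarray(X, dtype=float)
        self.pipeline_ = self._pipeline().fit(X, y)
        self.classes_ = self.pipeline_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self.pipeline_.predict(np.asarray(X, dtype=float))


def decode_accuracy(
    matrix: np.ndarray,
    labels: np.ndarray,
    k: int = K_FOLDS,
    seed: int = 0,
    C: float = 1.0,
    stratified: bool = True,
) -> float:
    """Mean held-out accuracy of the linear SVM under k-fold CV.

    Folds are stratified (balanced up/down per fold) by default, matching
    the balanced trial design; accuracy is 1 minus the mean 0-1
    classification loss on held-out folds.  If a class has fewer than k
    trials, k is reduced with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    counts = [int(np.sum(labels == c)) for c in np.unique(labels)]
    min_count = min(counts)
    if min_count < 2:
        raise ValueError("each class needs at least 2 trials")
    if min_count < k:
        warnings.warn(
            f"class with {min_count} trials < k={k}; reducing k to {min_count}"
        )
        k = min_count
    cv_cls = StratifiedKFold if stratified else KFold
    cv = cv_cls(n_splits=k, shuffle=True, random_state=seed)
    scores = cross_val_score(
        TiltDecoder(C=C), matrix, labels, cv=cv, scoring="accuracy"
    )
    return float(np.mean(scores))


def shuffle_null(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = N_SHUFFLES,
    k: int = K_FOLDS,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Null accuracies from decoding with permuted trial identities."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(labels.size)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        null[s] = decode_accuracy(matrix, labels[perm], k=k, seed=fold_seed, C=C)
    return null


def shuffle_null_pvalue(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p: fraction of null accuracies >= observed."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (null.size + 1))


@dataclass
class DecodingResult:
    population_size: int
    accuracies: np.ndarray  # one per pseudo-population draw
    k_folds: int
    seed: int

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accuracies, [25, 75])
        return float(lo), float(hi)


def pseudo_population_decode(
    cells: list[CellResponse],
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    n_draws: int = 20,
    k: int = K_FOLDS,
    seed: int = 0,
    C: float = 1.0,
) -> dict[int, DecodingResult]:
    """Decoding accuracy versus pseudo-population size.

    For each size, ``n_draws`` random cell subsets are drawn; each subset's
    pseudo-population matrix aligns trials by type (the spread across draws
    reflects different sets of neurons).  Sizes exceeding the pool are
    truncated with a warning; at the full pool size there is a single
    possible subset and zero spread.
    """
    pool = len(cells)
    usable = tuple(s for s in sizes if s <= pool)
    if len(usable) < len(sizes):
        warnings.warn(f"pool of {pool} cells; truncating sizes to {usable}")
    rng = np.random.default_rng(seed)
    results: dict[int, DecodingResult] = {}
    for size in usable:
        accs = np.empty(n_draws)
        for d in range(n_draws):
            idx = np.sort(rng.choice(pool, size=size, replace=False))
            subset = [cells[i] for i in idx]
            M, labels = response_matrix(subset)
            fold_seed = seed if size == pool else int(rng.integers(0, 2**31 - 1))
            accs[d] = decode_accuracy(M, labels, k=k, seed=fold_seed, C=C)
        results[size] = DecodingResult(
            population_size=size, accuracies=accs, k_folds=k, seed=seed
        )
    return results


def per_fish_decode(
    cells_by_fish: dict[str, list[CellResponse]],
    k: int = K_FOLDS,
    seed: int = 0,
    C: float = 1.0,
) -> dict[str, float]:
    """One decoding accuracy per fish, from its simultaneously recorded cells.

    Used for comparisons across ages; the same shuffle-null machinery applies
    to each fish's matrix.
    """
    out: dict[str, float] = {}
    for i, (fish, cells) in enumerate(sorted(cells_by_fish.items())):
        M, labels = response_matrix(cells)
        out[fish] = decode_accuracy(M, labels, k=k, seed=seed + i, C=C)
    return out


def least_tuned_subset(cells: list[CellResponse], n: int) -> list[CellResponse]:
    """The n cells with smallest |DI|, ties broken by cell_id."""
    if n > len(cells):
        raise ValueError("n exceeds the pool size")
    ordered = sorted(cells, key=lambda c: (abs(c.di), c.cell_id))
    return ordered[:n]
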