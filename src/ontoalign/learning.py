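"""Delta-rule learning of the four aspect weights from expert pairs.

The learner is a two-layer linear unit: inputs are the four aspect
similarities of a concept pair, output is their weighted sum, and the free
parameters are the aspect weights.  The training signal comes from a
handful of expert-declared equivalent concept pairs: each such pair marks a
cell of the similarity matrix that ought to be the maximum of both its row
and its column.  The training error is therefore

    E = 1/2 * sum_d [ (rowmax_d - v_d)^2 + (colmax_d - v_d)^2 ]

over training cells ``d``, where ``v_d`` is the cell's overall similarity
and ``rowmax_d`` / ``colmax_d`` are the maxima of its full row and column
(the cell itself included, so residuals are nonnegative and E is zero
exactly when every training cell dominates its row and column).

Gradient descent treats the row/column maxima as constants within an
iteration (the delta-rule analogue) and projects the weights back onto the
probability simplex after every update, matching the convention that the
aspect weights form a convex combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .lexical import SynonymLexicon
from .model import ConceptGraph
from .similarity import (
    DEFAULT_THETA_MATCH,
    SimilarityMatrix,
    UNIFORM_WEIGHTS,
    WeightVector,
    build_matrix,
)

__all__ = [
    "TrainingExample",
    "LearningConfig",
    "LearningTrace",
    "NoSignalError",
    "NotConvergedError",
    "training_error",
    "learn_weights",
    "learn_weights_on_matrix",
    "iterations_to_converge",
]


class NoSignalError(ValueError):
    """The component grid is identically zero; no weight can be learned."""


class NotConvergedError(RuntimeError):
    """The trace ended at max_iterations without meeting the tolerance."""


@dataclass(frozen=True)
class TrainingExample:
    """An expert-declared equivalent concept pair (source in A, target in B)."""

    source: str
    target: str


@dataclass
class LearningConfig:
    """Hyper-parameters of the weight learner.

    eta:
        Learning rate; convergence speed grows with it.
    max_iterations:
        Hard cap on gradient-descent iterations.
    tolerance:
        Stop once no weight moves by more than this between iterations.
    initial_weights:
        Starting point on the simplex; uniform 0.25 by default.
    """

    eta: float = 0.1
    max_iterations: int = 5000
    tolerance: float = 1e-4
    initial_weights: WeightVector = UNIFORM_WEIGHTS

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class TraceRecord:
    iteration: int
    weights: WeightVector
    error: float


@dataclass
class LearningTrace:
    """Per-iteration history of weights and training error."""

    records: List[TraceRecord] = field(default_factory=list)
    converged: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def append(self, iteration: int, weights: WeightVector, error: float) -> None:
        self.records.append(TraceRecord(iteration, weights, error))

    def to_rows(self) -> List[Tuple[int, float, float, float, float, float]]:
        """Rows (iteration, w1..w4, E) for CSV export."""
        return [
            (r.iteration, r.weights.w1, r.weights.w2, r.weights.w3, r.weights.w4, r.error)
            for r in self.records
        ]


def _training_cells(
    matrix: SimilarityMatrix, examples: Sequence[TrainingExample]
) -> List[Tuple[int, int]]:
    return [matrix.cell(ex.source, ex.target) for ex in examples]


def training_error(
    matrix: SimilarityMatrix, examples: Sequence[TrainingExample]
) -> float:
    """Row/column-maximum squared error over the training cells."""
    cells = _training_cells(matrix, examples)
    grid = matrix.overall
    total = 0.0
    for i, j in cells:
        v = grid[i, j]
        rmax = grid[i, :].max()
        cmax = grid[:, j].max()
        total += (rmax - v) ** 2 + (cmax - v) ** 2
    return 0.5 * total


def _project_simplex(w: np.ndarray) -> np.ndarray:
    """Clamp negatives to zero and renormalise to sum 1."""
    w = np.clip(w, 0.0, None)
    s = w.sum()
    if s == 0.0:
        # All weights pushed to zero: fall back to uniform.
        return np.full_like(w, 1.0 / len(w))
    return w / s


def learn_weights_on_matrix(
    matrix: SimilarityMatrix,
    examples: Sequence[TrainingExample],
    config: LearningConfig | None = None,
) -> Tuple[WeightVector, LearningTrace]:
    """Run delta-rule gradient descent on a pre-built similarity matrix.

    Each iteration: (1) recompute the overall grid under the current
    weights; (2) take the row/column maxima of every training cell as
    constants; (3) step every weight by
    ``eta * sum_d [(rowmax_d - v_d) + (colmax_d - v_d)] * x_kd`` where
    ``x_kd`` is aspect ``k`` of training cell ``d``; (4) project back onto
    the simplex.  Stops when the largest per-weight change falls below the
    tolerance or at ``max_iterations``.

    The matrix is left reweighted with the final weights.
    """
    cfg = config or LearningConfig()
    if not examples:
        raise ValueError("at least one training example is required")
    cells = _training_cells(matrix, examples)
    comps = matrix.components
    if not np.any(comps):
        raise NoSignalError("all aspect components are zero; nothing to learn")

    x = np.array([comps[i, j, :] for i, j in cells])  # d x 4
    w = cfg.initial_weights.as_array().copy()
    trace = LearningTrace()

    for iteration in range(1, cfg.max_iterations + 1):
        matrix.reweight(WeightVector.from_array(w))
        grid = matrix.overall
        v = np.array([grid[i, j] for i, j in cells])
        rmax = np.array([grid[i, :].max() for i, _j in cells])
        cmax = np.array([grid[:, j].max() for _i, j in cells])
        residual = (rmax - v) + (cmax - v)  # d
        error = 0.5 * float(((rmax - v) ** 2 + (cmax - v) ** 2).sum())

        w_new = _project_simplex(w + cfg.eta * (residual @ x))
        delta = np.abs(w_new - w).max()
        w = w_new
        trace.append(iteration, WeightVector.from_array(w), error)
        if delta < cfg.tolerance:
            trace.converged = True
            break

    final = WeightVector.from_array(w)
    matrix.reweight(final)
    return final, trace


def learn_weights(
    g1: ConceptGraph,
    g2: ConceptGraph,
    examples: Sequence[TrainingExample],
    config: LearningConfig | None = None,
    lexicon: SynonymLexicon | None = None,
    theta_match: float = DEFAULT_THETA_MATCH,
) -> Tuple[WeightVector, LearningTrace, SimilarityMatrix]:
    """Build the similarity matrix for two graphs and learn aspect weights.

    Returns the learned weights, the full iteration trace, and the matrix
    reweighted with the final weights (ready for clustering).
    """
    cfg = config or LearningConfig()
    matrix = build_matrix(g1, g2, cfg.initial_weights, lexicon, theta_match)
    weights, trace = learn_weights_on_matrix(matrix, examples, cfg)
    return weights, trace, matrix


def iterations_to_converge(trace: LearningTrace) -> int:
    """Index of the first iteration that met the tolerance criterion."""
    if not trace.converged:
        raise NotConvergedError(
            f"learning did not converge within {len(trace)} iterations"
        )
    return trace.records[-1].iteration
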