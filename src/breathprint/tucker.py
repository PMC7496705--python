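"""Tucker3 tensor compression of stacked breath-print cohorts.

A cohort is stacked into a 3-way array of shape
(n_measurements, n_temp * n_sensors, n_cycles): mode 2 concatenates the
three sensors' 36 temperature samples sensor-major (entries 0-35 sensor 0,
36-71 sensor 1, 72-107 sensor 2). Tucker3 factorizes this array into a
small core multiplied by one column-orthonormal factor per mode; the fit is
computed by higher-order orthogonal iteration (HOOI) initialized from the
truncated higher-order SVD (HOSVD). Per-subject feature vectors are the
projections U2^T X_i U3 of each measurement slice onto the mode-2/mode-3
factor subspaces, vectorized row-major.

In the pipeline the subject mode is never compressed (r1 = n_measurements),
so the decomposition acts purely as a per-subject feature extractor; the
:class:`TuckerCompressor` estimator wraps this as an sklearn transformer
operating on flattened (n, 108 * 64) matrices so it composes with pipelines
and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import Cohort, N_CYCLES, N_SENSORS, N_TEMP

DEFAULT_MODE2 = N_TEMP * N_SENSORS  # 108
DEFAULT_MODE3 = N_CYCLES  # 64

#: Rank lattice searched by :func:`choose_ranks` (clipped to mode extents).
RANK_LATTICE = (1, 2, 3, 4, 6, 8, 12, 16)


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding (Kolda-Bader convention)."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold`."""
    full_shape = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(matrix.reshape(full_shape), 0, mode)


def nmode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product: contracts ``matrix`` columns with the tensor."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"matrix of shape {matrix.shape} cannot contract mode {mode} of "
            f"extent {tensor.shape[mode]}"
        )
    out_shape = list(tensor.shape)
    out_shape[mode] = matrix.shape[0]
    return fold(matrix @ unfold(tensor, mode), mode, tuple(out_shape))


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-|entry| is positive (ties: lowest index)."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _leading_subspace(mat: np.ndarray, rank: int) -> np.ndarray:
    """Top-``rank`` left singular vectors of ``mat`` via the Gram eigenproblem."""
    gram = mat @ mat.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:rank]
    return _fix_signs(vecs[:, order])


@dataclass
class StackedTensor:
    """Cohort measurements stacked into one 3-way array with a scaling record."""

    data: np.ndarray  # (n_meas, n_temp*n_sensors, n_cycles)
    subject_ids: list[str]
    scaling: "FiberScaling"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class FiberScaling:
    """Record of the per-(mode2, mode3) fiber transform fitted on training data."""

    option: str  # 'none' | 'zscore_fiber'
    mean: np.ndarray | None = None  # (d2, d3)
    sd: np.ndarray | None = None  # (d2, d3); zero-variance fibers keep sd 0

    def apply(self, slices: np.ndarray) -> np.ndarray:
        """Apply to measurement slices of shape (..., d2, d3)."""
        if self.option == "none":
            return slices
        out = slices - self.mean
        safe = np.where(self.sd > 0, self.sd, 1.0)
        out = out / safe
        return np.where(self.sd > 0, out, 0.0)


def measurement_slice(tensor: np.ndarray) -> np.ndarray:
    """Reorder one (n_temp, n_cycles, n_sensors) tensor to a (108, 64) slice."""
    t, c, s = tensor.shape
    return np.transpose(tensor, (2, 0, 1)).reshape(s * t, c)


def stack(cohort: Cohort, scaling_option: str = "none") -> StackedTensor:
    """Stack a cohort into a (n, 108, 64) array, optionally z-scoring fibers.

    ``zscore_fiber`` standardizes every (temperature-sensor, cycle) fiber
    across measurements; fibers with zero variance map to 0. The fitted
    means/sds are recorded so the identical transform can be applied to
    held-out measurements.
    """
    shapes = {m.tensor.shape for m in cohort}
    if len(shapes) > 1:
        bad = [m.subject_id for m in cohort if m.tensor.shape != next(iter(shapes))]
        raise ValueError(f"inconsistent tensor shapes; offending subjects include {bad[:3]}")
    data = np.stack([measurement_slice(m.tensor) for m in cohort])
    if scaling_option == "none":
        scaling = FiberScaling("none")
    elif scaling_option == "zscore_fiber":
        mean = data.mean(axis=0)
        sd = data.std(axis=0)
        scaling = FiberScaling("zscore_fiber", mean=mean, sd=sd)
        data = scaling.apply(data)
    else:
        raise ValueError(f"unknown stack scaling option {scaling_option!r}")
    return StackedTensor(
        data=data, subject_ids=[m.subject_id for m in cohort], scaling=scaling
    )


@dataclass
class TuckerModel:
    """Fitted Tucker3 decomposition: factors, core, fit and scaling record."""

    ranks: tuple[int, int, int]
    factors: tuple[np.ndarray, np.ndarray, np.ndarray]
    core: np.ndarray
    fit: float
    fit_history: list[float] = field(default_factory=list)
    scaling: FiberScaling = field(default_factory=lambda: FiberScaling("none"))
    n_iter: int = 0

    def reconstruct(self) -> np.ndarray:
        out = self.core
        for mode, U in enumerate(self.factors):
            out = nmode_product(out, U, mode)
        return out


def _hooi(
    data: np.ndarray,
    ranks: tuple[int, int, int],
    max_iter: int,
    tol: float,
) -> tuple[list[np.ndarray], np.ndarray, list[float]]:
    """HOSVD-initialized HOOI. Full-rank modes keep the identity factor."""
    shape = data.shape
    total = float(np.tensordot(data, data, axes=3))
    if total == 0.0:
        factors = [np.eye(shape[k])[:, : ranks[k]] for k in range(3)]
        core = np.zeros(ranks)
        return factors, core, [1.0]

    free = [k for k in range(3) if ranks[k] < shape[k]]
    factors = [np.eye(shape[k]) for k in range(3)]
    # HOSVD init for compressed modes
    for k in free:
        factors[k] = _leading_subspace(unfold(data, k), ranks[k])

    def core_of(fs):
        out = data
        for mode in range(3):
            if ranks[mode] < shape[mode]:
                out = nmode_product(out, fs[mode].T, mode)
        return out

    core = core_of(factors)
    history = [float(np.tensordot(core, core, axes=3)) / total]
    for _ in range(max_iter):
        if not free:
            break
        for k in free:
            partial = data
            for mode in range(3):
                if mode != k and ranks[mode] < shape[mode]:
                    partial = nmode_product(partial, factors[mode].T, mode)
            factors[k] = _leading_subspace(unfold(partial, k), ranks[k])
        core = core_of(factors)
        history.append(float(np.tensordot(core, core, axes=3)) / total)
        if history[-1] - history[-2] < tol:
            break
    return factors, core, history


def fit_tucker(
    stacked: StackedTensor | np.ndarray,
    ranks: tuple[int, int, int],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> TuckerModel:
    """Fit a Tucker3 model of the given ranks by HOSVD-initialized HOOI.

    ``fit`` is the explained-variance fraction
    1 - ||data - reconstruction||^2 / ||data||^2, equal to
    ||core||^2 / ||data||^2 for orthonormal factors; it is non-decreasing
    over HOOI sweeps and the iteration stops when the improvement drops
    below ``tol`` or after ``max_iter`` sweeps.
    """
    if isinstance(stacked, StackedTensor):
        data, scaling = stacked.data, stacked.scaling
    else:
        data, scaling = np.asarray(stacked, dtype=float), FiberScaling("none")
    if data.ndim != 3:
        raise ValueError("expected a 3-way array")
    if not np.isfinite(data).all():
        raise ValueError("non-finite entries in input tensor")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    for k in range(3):
        if not 1 <= ranks[k] <= data.shape[k]:
            raise ValueError(
                f"rank {ranks[k]} invalid for mode {k} of extent {data.shape[k]}"
            )
    factors, core, history = _hooi(data, tuple(ranks), max_iter, tol)
    return TuckerModel(
        ranks=tuple(ranks),
        factors=tuple(factors),  # type: ignore[arg-type]
        core=core,
        fit=history[-1],
        fit_history=history,
        scaling=scaling,
        n_iter=len(history) - 1,
    )


def project(slice_2d: np.ndarray, model: TuckerModel) -> np.ndarray:
    """Project one (d2, d3) measurement slice to its Tucker feature vector.

    Applies the training scaling record, then computes U2^T S U3 and
    vectorizes row-major; length r2 * r3.
    """
    _, U2, U3 = model.factors
    slice_2d = np.asarray(slice_2d, dtype=float)
    if slice_2d.shape != (U2.shape[0], U3.shape[0]):
        raise ValueError(
            f"slice shape {slice_2d.shape} != ({U2.shape[0]}, {U3.shape[0]})"
        )
    scaled = model.scaling.apply(slice_2d)
    return (U2.T @ scaled @ U3).ravel()


def choose_ranks(
    stacked: StackedTensor | np.ndarray,
    target_fit: float = 0.99,
    lattice: tuple[int, ...] = RANK_LATTICE,
) -> tuple[tuple[int, int, int], bool]:
    """Smallest (r2, r3) on the lattice reaching the target fit; r1 = n.

    The lattice is screened with exact truncated-HOSVD fits (computed in one
    pass from the energies of the full HOSVD core), ordered by r2*r3 then
    lexicographically; HOOI can only improve on HOSVD, so the first lattice
    point passing the screen meets the target. Returns the lattice maximum
    with ``reached=False`` when no point does.
    """
    if not 0 < target_fit <= 1:
        raise ValueError("target_fit must be in (0, 1]")
    data = stacked.data if isinstance(stacked, StackedTensor) else np.asarray(stacked)
    n, d2, d3 = data.shape
    lat2 = sorted({r for r in lattice if r < d2} | {d2} if d2 <= max(lattice) else
                  {r for r in lattice if r <= d2})
    lat3 = sorted({r for r in lattice if r < d3} | {d3} if d3 <= max(lattice) else
                  {r for r in lattice if r <= d3})

    U2 = _leading_subspace(unfold(data, 1), d2)
    U3 = _leading_subspace(unfold(data, 2), d3)
    core = nmode_product(nmode_product(data, U2.T, 1), U3.T, 2)
    energy = (core**2).sum(axis=0)  # (d2, d3)
    total = energy.sum()
    if total == 0.0:
        return (n, 1, 1), True
    cum = energy.cumsum(axis=0).cumsum(axis=1) / total

    candidates = sorted(
        ((r2, r3) for r2 in lat2 for r3 in lat3), key=lambda rr: (rr[0] * rr[1], rr)
    )
    for r2, r3 in candidates:
        if cum[r2 - 1, r3 - 1] >= target_fit - 1e-12:
            return (n, r2, r3), True
    warnings.warn(
        f"target fit {target_fit} unreachable on rank lattice; returning maximum "
        f"({lat2[-1]}, {lat3[-1]})",
        stacklevel=2,
    )
    return (n, lat2[-1], lat3[-1]), False


class TuckerCompressor(TransformerMixin, BaseEstimator):
    """sklearn transformer: flattened breath-print slices -> Tucker features.

    Accepts X of shape (n_measurements, d2 * d3) — each row a flattened
    (d2, d3) measurement slice — so the compressor composes with sklearn
    pipelines. ``fit`` optionally z-scores fibers, picks (r2, r3) from a
    target explained-variance fraction unless explicit ranks are given, and
    runs HOOI with the subject mode uncompressed. ``transform`` projects
    (training or held-out) slices with the fitted factors and the training
    scaling record only.

    Parameters
    ----------
    ranks : (r2, r3) or None
        Explicit mode-2/3 ranks; None selects them via ``target_fit``.
    target_fit : float
        Explained-variance target for rank selection.
    scaling : 'none' or 'zscore_fiber'
        Tensor-level fiber scaling fitted on the training stack.
    slice_shape : (d2, d3)
        Shape of one measurement slice (default (108, 64)).
    """

    def __init__(
        self,
        ranks: tuple[int, int] | None = None,
        target_fit: float = 0.99,
        scaling: str = "none",
        max_iter: int = 100,
        tol: float = 1e-6,
        slice_shape: tuple[int, int] = (DEFAULT_MODE2, DEFAULT_MODE3),
    ):
        self.ranks = ranks
        self.target_fit = target_fit
        self.scaling = scaling
        self.max_iter = max_iter
        self.tol = tol
        self.slice_shape = slice_shape

    def _to_slices(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2, d3 = self.slice_shape
        if X.ndim == 2 and X.shape[1] == d2 * d3:
            return X.reshape(-1, d2, d3)
        if X.ndim == 3 and X.shape[1:] == (d2, d3):
            return X
        raise ValueError(f"expected (n, {d2 * d3}) or (n, {d2}, {d3}), got {X.shape}")

    def fit(self, X, y=None):
        data = self._to_slices(X)
        if not np.isfinite(data).all():
            raise ValueError("non-finite entries in input")
        n = data.shape[0]
        if self.scaling == "zscore_fiber":
            scaling = FiberScaling(
                "zscore_fiber", mean=data.mean(axis=0), sd=data.std(axis=0)
            )
            data = scaling.apply(data)
        elif self.scaling == "none":
            scaling = FiberScaling("none")
        else:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        stacked = StackedTensor(data=data, subject_ids=[], scaling=scaling)
        self.rank_warning_ = False
        if self.ranks is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full_ranks, reached = choose_ranks(stacked, self.target_fit)
            self.rank_warning_ = not reached
        else:
            full_ranks = (n, *self.ranks)
        self.model_ = fit_tucker(stacked, full_ranks, self.max_iter, self.tol)
        self.ranks_ = self.model_.ranks
        self.fit_ = self.model_.fit
        self.n_features_out_ = full_ranks[1] * full_ranks[2]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        data = self._to_slices(X)
        scaled = self.model_.scaling.apply(data)
        _, U2, U3 = self.model_.factors
        out = np.einsum("ia,nij,jb->nab", U2, scaled, U3, optimize=True)
        return out.reshape(data.shape[0], -1)
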