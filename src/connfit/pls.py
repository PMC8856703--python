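"""Partial least squares for brain-design and brain-behaviour covariance.

Two flavours, both resolved by a singular value decomposition of a small
cross-block matrix R:

* mean-centering PLS — R is the groups x variables matrix of group means
  with the grand (column) mean across groups removed. Latent variables are
  optimal group contrasts in the brain measures.
* behavioural PLS — within each group, every behaviour column is Pearson-
  correlated with every brain column; the per-group correlation blocks are
  stacked and decomposed. Latent variables are joint brain/behaviour
  profiles.

For R = U S V^T the columns of V are brain saliences, U holds design or
behaviour saliences, and singular values measure the covariance captured
(d_i^2 / sum d^2 is the fraction of cross-block covariance explained).
Subject brain scores are X V. Inference is nonparametric: latent-variable
significance by permutation of subject rows, salience reliability by
stratified bootstrap with Procrustes re-alignment of each resample's
singular vectors; a bootstrap ratio (original salience over bootstrap SE)
above 2 in magnitude is conventionally read as reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "PLSResult",
    "MeanCenteredPLS",
    "BehavioralPLS",
    "mean_centering_pls",
    "behavioral_pls",
    "compare_saliences",
    "salience_z_difference",
]


@dataclass
class PLSResult:
    """Container mirroring the fitted attributes of the PLS estimators."""

    singular_values: np.ndarray
    brain_saliences: np.ndarray
    design_saliences: np.ndarray
    brain_scores: np.ndarray
    covariance_explained: np.ndarray
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None
    salience_ci: np.ndarray | None = None
    brain_salience_ci: np.ndarray | None = None


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each brain-salience column's largest-|.| element positive."""
    for k in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, k])), k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return U, V


def _svd_cross_block(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)
    return U, s, V


def _group_indices(groups: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    labels = np.unique(groups)
    idx = [np.flatnonzero(groups == g) for g in labels]
    return labels, idx


def _mean_centered_matrix(X: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    M = np.vstack([X[idx].mean(axis=0) for idx in group_idx])
    return M - M.mean(axis=0)


def _behavior_corr_matrix(
    X: np.ndarray, Y: np.ndarray, group_idx: list[np.ndarray]
) -> np.ndarray:
    blocks = []
    for gi, idx in enumerate(group_idx):
        Xg, Yg = X[idx], Y[idx]
        sx = Xg.std(axis=0)
        sy = Yg.std(axis=0)
        if np.any(sy == 0):
            bad = np.flatnonzero(sy == 0).tolist()
            raise ValueError(
                f"behaviour column(s) {bad} have zero variance within group {gi}"
            )
        if np.any(sx == 0):
            bad = np.flatnonzero(sx == 0).tolist()
            raise ValueError(
                f"brain column(s) {bad} have zero variance within group {gi}"
            )
        Xc = (Xg - Xg.mean(axis=0)) / sx
        Yc = (Yg - Yg.mean(axis=0)) / sy
        blocks.append(Yc.T @ Xc / len(idx))  # q x p Pearson correlations
    return np.vstack(blocks)


def _procrustes_rotation(scaled_ref: np.ndarray, scaled_boot: np.ndarray) -> np.ndarray:
    """Orthogonal k x k rotation aligning bootstrap saliences to the original."""
    u, _, vt = np.linalg.svd(scaled_boot.T @ scaled_ref)
    return u @ vt


class _BasePLS(BaseEstimator):
    """Shared permutation / bootstrap machinery for both PLS flavours."""

    def __init__(self, n_perm=1000, n_boot=1000, random_state=0, ci_level=95.0,
                 perm_correction=False):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.random_state = random_state
        self.ci_level = ci_level
        self.perm_correction = perm_correction

    # subclasses define _cross_block(X, Y, group_idx) and _permute(rng, ...)

    def _decompose(self, R: np.ndarray):
        U, s, V = _svd_cross_block(R)
        return U, s, V

    def _fit_common(self, X, Y, groups):
        X = np.asarray(X, dtype=float)
        groups = (
            np.zeros(len(X), dtype=int) if groups is None else np.asarray(groups)
        )
        if len(groups) != len(X):
            raise ValueError("groups length does not match the brain matrix")
        labels, group_idx = _group_indices(groups)
        for lab, idx in zip(labels, group_idx):
            if idx.size < 1:
                raise ValueError(f"group {lab} has no subjects")
        R = self._cross_block(X, Y, group_idx)
        U, s, V = self._decompose(R)
        self.group_labels_ = labels
        self.singular_values_ = s
        self.brain_saliences_ = V
        self.design_saliences_ = U
        self.brain_scores_ = X @ V
        total = float(np.sum(s**2))
        self.covariance_explained_ = s**2 / total if total > 0 else s * 0.0
        rng = np.random.default_rng(self.random_state)
        self._run_permutations(rng, X, Y, groups, group_idx, s)
        self._run_bootstrap(rng, X, Y, groups, group_idx, U, s, V)
        return self

    def _run_permutations(self, rng, X, Y, groups, group_idx, s_obs):
        if self.n_perm < 1:
            self.perm_pvalues_ = None
            return
        k = s_obs.size
        exceed = np.zeros(k)
        for _ in range(self.n_perm):
            R = self._permuted_cross_block(rng, X, Y, groups)
            s_perm = np.linalg.svd(R, compute_uv=False)[:k]
            exceed += s_perm >= s_obs
        if self.perm_correction:
            self.perm_pvalues_ = (exceed + 1) / (self.n_perm + 1)
        else:
            # literal proportion of permuted singular values at least as large
            self.perm_pvalues_ = exceed / self.n_perm

    def _run_bootstrap(self, rng, X, Y, groups, group_idx, U, s, V):
        if self.n_boot < 1:
            self.bootstrap_ratios_ = None
            self.salience_ci_ = None
            self.brain_salience_ci_ = None
            return
        scaled_V = V * s  # p x k
        scaled_U = U * s
        boot_V = np.empty((self.n_boot,) + scaled_V.shape)
        boot_U = np.empty((self.n_boot,) + scaled_U.shape)
        for b in range(self.n_boot):
            idx = np.concatenate(
                [rng.choice(gidx, size=gidx.size, replace=True) for gidx in group_idx]
            )
            sub_groups = groups[idx]
            _, sub_idx = _group_indices(sub_groups)
            Rb = self._cross_block(
                X[idx], None if Y is None else Y[idx], sub_idx
            )
            Ub, sb, Vb = _svd_cross_block(Rb)
            k = s.size
            Q = _procrustes_rotation(scaled_V, Vb[:, :k] * sb[:k])
            boot_V[b] = (Vb[:, :k] * sb[:k]) @ Q
            boot_U[b] = (Ub[:, :k] * sb[:k]) @ Q
        se = boot_V.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = scaled_V / se
        if np.any(se == 0):
            warnings.warn("bootstrap SE of some saliences is 0; BSR set to +/-inf")
            zero = se == 0
            bsr[zero] = np.sign(scaled_V[zero]) * np.inf
        lo = (100.0 - self.ci_level) / 2.0
        hi = 100.0 - lo
        self.bootstrap_ratios_ = bsr
        self.salience_ci_ = np.stack(
            [np.percentile(boot_U, lo, axis=0), np.percentile(boot_U, hi, axis=0)]
        )
        self.brain_salience_ci_ = np.stack(
            [np.percentile(boot_V, lo, axis=0), np.percentile(boot_V, hi, axis=0)]
        )

    def to_result(self) -> PLSResult:
        return PLSResult(
            singular_values=self.singular_values_,
            brain_saliences=self.brain_saliences_,
            design_saliences=self.design_saliences_,
            brain_scores=self.brain_scores_,
            covariance_explained=self.covariance_explained_,
            perm_p=self.perm_pvalues_,
            bootstrap_ratios=self.bootstrap_ratios_,
            salience_ci=self.salience_ci_,
            brain_salience_ci=self.brain_salience_ci_,
        )

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project subjects onto the brain saliences (brain scores)."""
        return np.asarray(X, dtype=float) @ self.brain_saliences_


class MeanCenteredPLS(_BasePLS):
    """Mean-centering PLS: optimal group contrasts in brain measures.

    ``fit(X, groups)`` decomposes the grand-mean-centered group-mean matrix.
    Permutations shuffle the group labels across subjects; bootstrap
    resamples subjects within groups.
    """

    def _cross_block(self, X, Y, group_idx):
        return _mean_centered_matrix(X, group_idx)

    def _permuted_cross_block(self, rng, X, Y, groups):
        perm_groups = groups[rng.permutation(len(groups))]
        _, idx = _group_indices(perm_groups)
        return _mean_centered_matrix(X, idx)

    def fit(self, X, groups):
        groups = np.asarray(groups)
        if np.unique(groups).size < 2:
            raise ValueError("mean-centering PLS needs at least 2 groups")
        return self._fit_common(X, None, groups)


class BehavioralPLS(_BasePLS):
    """Behavioural PLS: covariance of brain measures with behaviour scores.

    ``fit(X, Y, groups=None)`` stacks within-group behaviour-brain
    correlation blocks and decomposes them. Permutations reorder behaviour
    rows across the whole sample; bootstrap resampling respects groups.
    """

    def _cross_block(self, X, Y, group_idx):
        return _behavior_corr_matrix(X, Y, group_idx)

    def _permuted_cross_block(self, rng, X, Y, groups):
        Yp = Y[rng.permutation(len(Y))]
        _, idx = _group_indices(groups)
        return _behavior_corr_matrix(X, Yp, idx)

    def fit(self, X, Y, groups=None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if len(Y) != len(X):
            raise ValueError("behaviour matrix length does not match brain matrix")
        return self._fit_common(X, Y, groups)


def mean_centering_pls(
    X, groups, n_perm=1000, n_boot=1000, random_state=0
) -> PLSResult:
    """Functional wrapper over :class:`MeanCenteredPLS`."""
    est = MeanCenteredPLS(n_perm=n_perm, n_boot=n_boot, random_state=random_state)
    return est.fit(X, groups).to_result()


def behavioral_pls(
    X, Y, groups=None, n_perm=1000, n_boot=1000, random_state=0
) -> PLSResult:
    """Functional wrapper over :class:`BehavioralPLS`."""
    est = BehavioralPLS(n_perm=n_perm, n_boot=n_boot, random_state=random_state)
    return est.fit(X, Y, groups=groups).to_result()


def compare_saliences(
    v_a: np.ndarray, v_b: np.ndarray, n_effective: int | None = None
) -> tuple[float, float]:
    """Cosine similarity of two salience vectors, with an optional Fisher z.

    Returns ``(similarity, z)`` where z = atanh(similarity) * sqrt(n_eff - 3)
    treats the normalized dot product like a correlation over ``n_effective``
    independent observations; z is NaN when n_effective is not given.
    """
    a = np.asarray(v_a, dtype=float).ravel()
    b = np.asarray(v_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("salience vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm salience vector")
    r = float(np.dot(a, b) / (na * nb))
    if n_effective is None:
        return r, float("nan")
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) * np.sqrt(n_effective - 3)
    return r, float(z)


def salience_z_difference(r1: float, r2: float, n_effective: int) -> float:
    """Fisher z test statistic for the difference of two cosine similarities.

    Both similarities are assumed to rest on the same effective sample size.
    """
    z1 = np.arctanh(np.clip(r1, -1 + 1e-15, 1 - 1e-15))
    z2 = np.arctanh(np.clip(r2, -1 + 1e-15, 1 - 1e-15))
    return float((z1 - z2) / np.sqrt(2.0 / (n_effective - 3)))
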