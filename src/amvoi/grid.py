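"""Regular discretization of the belief simplex with barycentric interpolation.

Dynamic programming over a continuous model state ``q`` requires a finite
grid.  The grid is the regular simplex lattice with spacing ``h``: all
probability vectors whose coordinates are integer multiples of ``h``.  Values
stored at lattice points are extended to arbitrary beliefs by interpolation
over the Freudenthal (Kuhn) triangulation of the lattice, computed in
cumulative-sum coordinates so that every interpolation vertex stays inside
the simplex.  For ``K = 2`` this reduces to ordinary piecewise-linear
interpolation in ``q(0)``; it is exact at lattice points and reproduces
affine functions of ``q`` exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import ValidationError, as_belief

__all__ = ["BeliefGrid", "build_belief_grid", "interpolate_value"]

_SNAP = 1e-9  # snap-to-lattice tolerance in scaled (integer) coordinates


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, parts - 1):
            yield (head, *rest)


class BeliefGrid:
    """Simplex lattice over ``K`` models with spacing ``step = 1/n``.

    Attributes
    ----------
    points : ndarray of shape (G, K)
        All lattice beliefs, in lexicographic order of their integer
        coordinate vectors; for ``K = 2`` this means ``q(0)`` ascending.
    """

    def __init__(self, n_models: int, step: float):
        if n_models < 1:
            raise ValidationError("need at least one model")
        n = int(round(1.0 / step))
        if n < 1 or abs(n * step - 1.0) > 1e-9:
            raise ValidationError(
                f"grid step {step} does not divide 1 (nearest subdivision {n})"
            )
        self.n_models = int(n_models)
        self.step = float(step)
        self.n_subdivisions = n
        counts = np.array(list(_compositions(n, n_models)), dtype=np.int64)
        self.points = counts / float(n)
        self._counts = counts
        # integer encoding of lattice points for vectorized lookup
        base = n + 1
        if base ** n_models < 2**62:
            self._base_powers = base ** np.arange(n_models, dtype=np.int64)
            keys = counts @ self._base_powers
            order = np.argsort(keys)
            self._sorted_keys = keys[order]
            self._sorted_to_index = order
            self._key_dict = None
        else:  # huge K with coarse grids: fall back to a dict
            self._base_powers = None
            self._key_dict = {tuple(c): i for i, c in enumerate(counts)}

    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def vertex_index(self, model: int) -> int:
        """Index of the degenerate belief ``e_k`` in :attr:`points`."""
        counts = np.zeros(self.n_models, dtype=np.int64)
        counts[model] = self.n_subdivisions
        return int(self._lookup(counts[None, :])[0])

    def _lookup(self, counts: np.ndarray) -> np.ndarray:
        if self._base_powers is not None:
            keys = counts @ self._base_powers
            pos = np.searchsorted(self._sorted_keys, keys)
            pos = np.clip(pos, 0, self._sorted_keys.size - 1)
            found = self._sorted_keys[pos] == keys
            idx = self._sorted_to_index[pos]
            idx = np.where(found, idx, -1)
            return idx
        return np.array(
            [self._key_dict.get(tuple(c), -1) for c in counts], dtype=np.int64
        )

    # ------------------------------------------------------------------
    def weights(self, beliefs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolation vertices and convex weights for each query belief.

        Parameters
        ----------
        beliefs : ndarray of shape (M, K)
            Query beliefs (rows sum to one).

        Returns
        -------
        idx : int ndarray of shape (M, K)
            Indices into :attr:`points` of the vertices of the containing
            lattice simplex (``K`` vertices; duplicates possible at faces).
        w : ndarray of shape (M, K)
            Nonnegative barycentric weights summing to one per row.
        """
        Q = np.atleast_2d(np.asarray(beliefs, dtype=float))
        M, K = Q.shape
        if K != self.n_models:
            raise ValidationError(f"beliefs have {K} entries, grid expects {self.n_models}")
        n = self.n_subdivisions
        if K == 1:
            return np.zeros((M, 1), dtype=np.int64), np.ones((M, 1))

        # cumulative coordinates: v_i = n * sum_{j >= i} q_j, v_0 = n
        tail = n * np.cumsum(Q[:, ::-1], axis=1)[:, ::-1]  # (M, K), tail[:,0] ~ n
        u = tail[:, 1:]  # free coordinates, shape (M, K-1), nonincreasing rows
        u = np.clip(u, 0.0, float(n))
        nearest = np.rint(u)
        u = np.where(np.abs(u - nearest) <= _SNAP, nearest, u)

        b = np.floor(u)
        r = u - b  # residuals in [0, 1)
        d = K - 1
        order = np.argsort(-r, axis=1, kind="stable")  # descending residuals
        rs = np.take_along_axis(r, order, axis=1)

        # barycentric weights over the Kuhn simplex
        w = np.empty((M, K))
        w[:, 0] = 1.0 - rs[:, 0]
        if d > 1:
            w[:, 1:d] = rs[:, : d - 1] - rs[:, 1:]
        w[:, d] = rs[:, d - 1]

        # vertex u-coordinates: start at b, add unit steps in residual order
        uv = np.empty((M, K, d))
        uv[:, 0, :] = b
        steps = np.zeros((M, d, d))
        np.put_along_axis(steps, order[:, :, None], 1.0, axis=2)
        uv[:, 1:, :] = b[:, None, :] + np.cumsum(steps, axis=1)

        # back to lattice counts: c_i = v_i - v_{i+1} with v_0 = n, v_K = 0
        full = np.empty((M, K, K + 1))
        full[:, :, 0] = n
        full[:, :, 1:K] = uv
        full[:, :, K] = 0.0
        counts = np.rint(full[:, :, :-1] - full[:, :, 1:]).astype(np.int64)

        idx = self._lookup(counts.reshape(M * K, K)).reshape(M, K)
        bad = idx < 0
        if np.any(bad):
            # vertices outside the lattice can only carry (numerically) zero
            # weight; fold them onto the base vertex
            if np.any(np.abs(w[bad]) > 1e-9):
                raise ValidationError("interpolation produced an off-lattice vertex")
            w = np.where(bad, 0.0, w)
            fill = np.broadcast_to(idx[:, :1], idx.shape)
            idx = np.where(bad, fill, idx)
        w = np.clip(w, 0.0, None)
        w /= w.sum(axis=1, keepdims=True)
        return idx, w

    def interpolate(self, values: np.ndarray, beliefs: np.ndarray) -> np.ndarray:
        """Interpolate grid-stored ``values`` (shape ``(G,)``) at ``beliefs``."""
        values = np.asarray(values, dtype=float)
        idx, w = self.weights(beliefs)
        return (values[idx] * w).sum(axis=1)


def build_belief_grid(n_models: int, step: float) -> BeliefGrid:
    """Construct the simplex lattice with the given spacing (``step | 1``)."""
    return BeliefGrid(n_models, step)


def interpolate_value(
    grid: BeliefGrid, values: np.ndarray, belief: Sequence[float]
) -> float:
    """Value of a single (possibly off-lattice) belief under grid ``values``."""
    q = as_belief(belief, grid.n_models)
    return float(grid.interpolate(values, q[None, :])[0])
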