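"""Self-organizing map clustering of stage expression profiles.

Expression vectors (one row per CTSS or consensus promoter, one column
per developmental stage) are scaled to relative expression (divided by
their maximum) and assigned to units of a small rectangular SOM grid,
labelled "row_col" (e.g. "4_4" for the bottom-right unit of a 5x5 map).
Training is a plain online Kohonen algorithm with a Gaussian
neighbourhood and linearly decaying radius and learning rate, fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class SelfOrganizingMap:
    """Rectangular-grid Kohonen map.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (default 5x5 = 25 units).
    n_epochs : int
        Full passes over the data (default 100).
    sigma0 : float or None
        Initial neighbourhood radius; defaults to half the larger grid
        dimension. Decays linearly to 0.5.
    lr0, lr1 : float
        Initial/final learning rate, linear decay.
    seed : int
        Seeds weight initialisation and the per-epoch sample order.
    """

    def __init__(self, n_rows: int = 5, n_cols: int = 5, n_epochs: int = 100,
                 sigma0: float | None = None, lr0: float = 0.5,
                 lr1: float = 0.01, seed: int = 0):
        self.n_rows, self.n_cols = n_rows, n_cols
        self.n_epochs = n_epochs
        self.sigma0 = sigma0 if sigma0 is not None else max(n_rows, n_cols) / 2.0
        self.lr0, self.lr1 = lr0, lr1
        self.seed = seed
        self.weights_: np.ndarray | None = None
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        self._grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        n_units = self.n_rows * self.n_cols
        if n < n_units:
            raise ValueError(
                f"{n} rows < {n_units} units; use a smaller grid")
        rng = np.random.default_rng(self.seed)
        W = X[rng.choice(n, n_units, replace=False)].copy()
        total = self.n_epochs * n
        step = 0
        for _ in range(self.n_epochs):
            for i in rng.permutation(n):
                frac = step / total
                sigma = self.sigma0 + (0.5 - self.sigma0) * frac
                lr = self.lr0 + (self.lr1 - self.lr0) * frac
                x = X[i]
                bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
                dist2 = ((self._grid - self._grid[bmu]) ** 2).sum(axis=1)
                h = np.exp(-dist2 / (2.0 * sigma * sigma))
                W += lr * h[:, None] * (x - W)
                step += 1
        self.weights_ = W
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit index (flattened row-major) per row."""
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.weights_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def unit_label(self, flat_index: int) -> str:
        return f"{flat_index // self.n_cols}_{flat_index % self.n_cols}"


def scale_rows(X: np.ndarray, method: str = "max") -> np.ndarray:
    """Scale each expression profile: "max" -> divide by row maximum
    (0-1 relative expression), "z" -> standardise. All-zero rows are the
    caller's responsibility (see :func:`som_cluster`)."""
    X = np.asarray(X, dtype=float)
    if method == "max":
        return X / X.max(axis=1, keepdims=True)
    if method == "z":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd
    raise ValueError(f"unknown scaling {method!r}")


def som_cluster(matrix, grid: tuple[int, int] = (5, 5), seed: int = 0,
                n_epochs: int = 100, scale: str = "max") -> pd.DataFrame:
    """Cluster expression profiles onto a SOM grid.

    ``matrix`` is (rows = CTSSes or consensus promoters) x (cols = 6
    stages); a DataFrame index is preserved in the output. All-zero
    rows are excluded with a listed reason. Returns a DataFrame with
    columns ``unit`` ("row_col" labels), ``row``, ``col``.
    """
    index = matrix.index if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, dtype=float)
    if index is None:
        index = pd.RangeIndex(len(X))
    keep = X.max(axis=1) > 0
    X, index = X[keep], index[keep]
    n_units = grid[0] * grid[1]
    if len(X) < n_units:
        raise ValueError(
            f"only {len(X)} non-zero profiles for a {grid[0]}x{grid[1]} grid "
            f"({n_units} units); use a smaller grid")
    Xs = scale_rows(X, scale)
    som = SelfOrganizingMap(grid[0], grid[1], n_epochs=n_epochs, seed=seed)
    som.fit(Xs)
    flat = som.predict(Xs)
    return pd.DataFrame({
        "unit": [som.unit_label(i) for i in flat],
        "row": flat // grid[1],
        "col": flat % grid[1],
    }, index=index)
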