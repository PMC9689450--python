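"""Labeled symmetric distance matrices.

All between-population comparisons in this package (F_ST, Nei distance,
Q_ST, geographic and climate distances) flow through one container so that
label alignment, symmetry checks and masked (undefined) cells are handled
uniformly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]

_SYM_TOL = 1e-12


class DistanceMatrix:
    """Square symmetric matrix over ordered population labels.

    Parameters
    ----------
    labels
        Ordered population labels.
    values
        Square array; must be symmetric within 1e-12 with zero diagonal.
    mask
        Optional boolean array, True where a cell is undefined (e.g. a
        non-converged pairwise Q_ST fit or a log of a zero distance).
        Masked cells are excluded by :meth:`paired_triangles`.
    """

    def __init__(self, labels, values, mask=None):
        self.labels = [str(x) for x in labels]
        values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} != ({n}, {n})")
        finite = np.isfinite(values)
        both = finite & finite.T
        if not np.allclose(values[both], values.T[both], atol=_SYM_TOL, rtol=0.0):
            raise ValueError("matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(values)[np.isfinite(np.diag(values))], 0.0):
            raise ValueError("diagonal must be zero")
        self.values = values
        if mask is None:
            mask = ~np.isfinite(values)
            np.fill_diagonal(mask, False)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (n, n):
                raise ValueError("mask shape mismatch")
        self.mask = mask | mask.T

    # -- basic protocol ----------------------------------------------------
    def __len__(self):
        return len(self.labels)

    def __getitem__(self, pair):
        i = self.labels.index(str(pair[0]))
        j = self.labels.index(str(pair[1]))
        return self.values[i, j]

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.labels, self.values.copy(), self.mask.copy())

    # -- transforms --------------------------------------------------------
    def map(self, fn, mask_nonfinite: bool = True) -> "DistanceMatrix":
        """Apply ``fn`` elementwise to off-diagonal cells.

        Cells that come out non-finite (e.g. ``log`` of a zero distance)
        are masked rather than propagated.
        """
        out = np.array(self.values, dtype=float)
        off = ~np.eye(len(self), dtype=bool)
        with np.errstate(all="ignore"):
            out[off] = fn(out[off])
        np.fill_diagonal(out, 0.0)
        mask = self.mask.copy()
        if mask_nonfinite:
            bad = ~np.isfinite(out)
            np.fill_diagonal(bad, False)
            mask |= bad
            out[bad] = np.nan
        return DistanceMatrix(self.labels, out, mask)

    def clipped(self, lo: float = 0.0) -> "DistanceMatrix":
        """Truncate entries below ``lo`` (negative F_ST used as a distance)."""
        return self.map(lambda v: np.maximum(v, lo))

    def reorder(self, labels) -> "DistanceMatrix":
        labels = [str(x) for x in labels]
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)],
                              self.mask[np.ix_(idx, idx)])

    # -- triangle extraction ----------------------------------------------
    def triangle(self) -> np.ndarray:
        """Lower-triangle values in row-major (i > j) order, NaN where masked."""
        i, j = np.tril_indices(len(self), k=-1)
        vals = self.values[i, j].astype(float)
        vals[self.mask[i, j]] = np.nan
        return vals

    @staticmethod
    def paired_triangles(a: "DistanceMatrix", b: "DistanceMatrix"):
        """Aligned lower triangles of two matrices with pairwise deletion.

        Returns ``(x, y, n_dropped)``; raises if the label sets differ.
        """
        if set(a.labels) != set(b.labels):
            raise ValueError("label sets differ")
        b = b.reorder(a.labels)
        x, y = a.triangle(), b.triangle()
        keep = np.isfinite(x) & np.isfinite(y)
        return x[keep], y[keep], int((~keep).sum())

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.mask] = np.nan
        return pd.DataFrame(vals, index=self.labels, columns=self.labels)

    def write_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_dataframe().to_csv(fh, index_label="population")

    @classmethod
    def read_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        vals = df.to_numpy(dtype=float)
        mask = ~np.isfinite(vals)
        np.fill_diagonal(mask, False)
        vals = np.where(mask, np.nan, vals)
        np.fill_diagonal(vals, 0.0)
        return cls(list(df.index), vals, mask)

    def write_phylip(self, path) -> None:
        """Square PHYLIP-style matrix (for external tree software)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self)}\n")
            for lab, row in zip(self.labels, self.values):
                name = lab[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    def __repr__(self):
        return f"DistanceMatrix(n={len(self)}, masked={int(self.mask.sum() // 2)})"
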