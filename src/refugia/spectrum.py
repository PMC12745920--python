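"""Two-dimensional site-frequency spectra.

A :class:`Spectrum2D` is an ``(n1+1, n2+1)`` array whose entry ``(i, j)``
counts (or, for model expectations, gives the expected density of) variant
sites at which the derived/minor allele was seen ``i`` times in the sample
from the first population and ``j`` times in the sample from the second.
The fixed corners ``(0, 0)`` and ``(n1, n2)`` carry no polymorphism
information and are always masked; folded spectra additionally mask the
half of the array beyond the minor-allele fold.

The plain-text serialization is a three-line dialect::

    <n1+1> <n2+1> <folded|unfolded>
    <row-major entries>
    <row-major mask bits>
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.special import gammaln


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric down-sampling matrix ``H`` with ``H[i', i]`` the
    probability that a subsample of ``n_to`` of ``n_from`` alleles contains
    ``i'`` copies given the full sample contains ``i``.

    Columns sum to one; projection of a spectrum along one axis is ``H @ s``.
    """
    if n_to > n_from:
        raise ValueError(f"cannot project upward: {n_from} -> {n_to}")
    i = np.arange(n_from + 1)[None, :]
    ip = np.arange(n_to + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            _log_comb(i, ip)
            + _log_comb(n_from - i, n_to - ip)
            - _log_comb(n_from, n_to)
        )
    H = np.where((ip <= i) & (n_to - ip <= n_from - i), np.exp(logp), 0.0)
    return H


class Spectrum2D:
    """Joint site-frequency spectrum for a pair of population samples.

    Parameters
    ----------
    data:
        ``(n1+1, n2+1)`` nonnegative array of site counts or densities.
    mask:
        Boolean array of the same shape, ``True`` for entries excluded from
        all sums and likelihoods.  The fixed corners are forced to masked.
    folded:
        Whether the spectrum is oriented by minor combined allele count.
    pop_labels:
        Ordered pair of population names.
    """

    def __init__(self, data, mask=None, folded: bool = False,
                 pop_labels: tuple[str, str] = ("pop1", "pop2")):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("spectrum data must be two-dimensional")
        if mask is None:
            mask = np.zeros(data.shape, dtype=bool)
        mask = np.array(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError("mask shape does not match data shape")
        mask[0, 0] = True
        mask[-1, -1] = True
        if folded:
            mask |= self._beyond_fold_mask(data.shape)
        if np.any(data[~mask] < 0):
            raise ValueError("unmasked spectrum entries must be nonnegative")
        self.data = data
        self.mask = mask
        self.folded = bool(folded)
        self.pop_labels = tuple(pop_labels)

    # -- basic properties -------------------------------------------------

    @property
    def n1(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.data.shape[1] - 1

    @property
    def shape(self):
        return self.data.shape

    def sum(self) -> float:
        """Total unmasked mass (number of usable segregating sites)."""
        return float(self.data[~self.mask].sum())

    def copy(self) -> "Spectrum2D":
        return Spectrum2D(self.data.copy(), self.mask.copy(), self.folded,
                          self.pop_labels)

    def transpose(self) -> "Spectrum2D":
        """Swap the two populations."""
        return Spectrum2D(self.data.T.copy(), self.mask.T.copy(), self.folded,
                          (self.pop_labels[1], self.pop_labels[0]))

    def __repr__(self):
        return (f"Spectrum2D(n1={self.n1}, n2={self.n2}, "
                f"folded={self.folded}, pops={self.pop_labels}, "
                f"S={self.sum():.4g})")

    @staticmethod
    def _beyond_fold_mask(shape) -> np.ndarray:
        """Entries masked in a folded spectrum: combined count beyond the
        fold, plus the redundant member of each complementary pair on the
        mid-line."""
        n1, n2 = shape[0] - 1, shape[1] - 1
        i = np.arange(n1 + 1)[:, None]
        j = np.arange(n2 + 1)[None, :]
        tot = i + j
        half = (n1 + n2) / 2.0
        beyond = tot > half
        on_line = tot == half
        # on the mid-line keep (i, j) over its image (n1-i, n2-j):
        # keep the cell with the smaller first index (ties: smaller second).
        keep_line = on_line & ((i < n1 - i) | ((i == n1 - i) & (j <= n2 - j)))
        return beyond | (on_line & ~keep_line)

    # -- algebra ----------------------------------------------------------

    def fold(self) -> "Spectrum2D":
        """Collapse onto minor-combined-allele orientation.

        Each kept entry accumulates its complementary cell
        ``(n1-i, n2-j)``; a mid-line cell that is its own image keeps half
        of the doubled sum, i.e. its original value.  Unmasked total mass
        is preserved.
        """
        if self.folded:
            raise ValueError("spectrum is already folded")
        n1, n2 = self.n1, self.n2
        rev = self.data[::-1, ::-1]
        rev_mask = self.mask[::-1, ::-1]
        folded = self.data + rev
        i = np.arange(n1 + 1)[:, None]
        j = np.arange(n2 + 1)[None, :]
        self_image = (i == n1 - i) & (j == n2 - j)
        folded = np.where(self_image, folded / 2.0, folded)
        mask = self.mask | rev_mask | self._beyond_fold_mask(self.shape)
        out = folded.copy()
        out[mask] = 0.0
        return Spectrum2D(out, mask, folded=True, pop_labels=self.pop_labels)

    def project(self, n1p: int, n2p: int) -> "Spectrum2D":
        """Hypergeometric down-projection to sample sizes ``(n1p, n2p)``.

        Folded spectra cannot be projected (orientation is ill-defined);
        project first, then fold.  Projection to the current sizes is the
        identity.  Masked entries contribute nothing.
        """
        if self.folded:
            raise ValueError("project an unfolded spectrum, then fold")
        if n1p > self.n1 or n2p > self.n2:
            raise ValueError("cannot project to larger sample sizes")
        if (n1p, n2p) == (self.n1, self.n2):
            return self.copy()
        H1 = projection_matrix(self.n1, n1p)
        H2 = projection_matrix(self.n2, n2p)
        data = np.where(self.mask, 0.0, self.data)
        proj = H1 @ data @ H2.T
        return Spectrum2D(proj, folded=False, pop_labels=self.pop_labels)

    # -- i/o ---------------------------------------------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n1 + 1} {self.n2 + 1} "
                     f"{'folded' if self.folded else 'unfolded'}\n")
            fh.write(" ".join(f"{v:.12g}" for v in self.data.ravel()) + "\n")
            fh.write(" ".join("1" if m else "0"
                              for m in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "Spectrum2D":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 3 or header[2] not in ("folded", "unfolded"):
                raise ValueError(f"malformed spectrum header in {path}")
            d1, d2 = int(header[0]), int(header[1])
            data = np.array(fh.readline().split(),
                            dtype=float).reshape(d1, d2)
            mask = np.array(fh.readline().split(),
                            dtype=float).reshape(d1, d2).astype(bool)
        return cls(data, mask, folded=header[2] == "folded")


def poisson_sample(expected: Spectrum2D, theta_hat: float,
                   seed: int) -> Spectrum2D:
    """Draw an observed spectrum: independent Poisson counts with mean
    ``theta_hat`` times each unmasked expected entry (parametric bootstrap
    draw).  Masked entries are zero."""
    if theta_hat < 0:
        raise ValueError("theta_hat must be nonnegative")
    rng = np.random.default_rng(seed)
    lam = np.where(expected.mask, 0.0, theta_hat * expected.data)
    counts = rng.poisson(lam).astype(float)
    counts[expected.mask] = 0.0
    return Spectrum2D(counts, expected.mask.copy(), expected.folded,
                      expected.pop_labels)
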