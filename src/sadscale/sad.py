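"""Octave binning and moment descriptors of species abundance distributions.

A species abundance distribution (SAD) is summarised here in two equivalent
ways: as the vector of per-species abundances (one positive integer per
species) and as a Preston-style octave histogram in which class ``i`` holds
the species with between ``2**i`` and ``2**(i+1) - 1`` individuals (1; 2-3;
4-7; ...).

All moment descriptors operate on base-2 logarithms of abundance,
``x_j = log2(n_j)``, and use the population convention (division by the
number of species S, no Bessel correction):

* raw moment          ``M_n = (1/S) sum_j x_j**n``
* central moment      ``C_n = (1/S) sum_j (x_j - mean)**n``
* standardized moment ``T_n = (1/S) sum_j ((x_j - mean)/sd)**n``

The skewness of a SAD is ``T_3``; positive skewness means a distribution
leaning to the left with a pronounced right tail (many rare species),
which is the typical shape of small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbundanceVector",
    "BinnedSAD",
    "MomentSummary",
    "DegenerateDistributionError",
    "as_abundance_vector",
    "bin_abundances",
    "raw_moment",
    "central_moment",
    "standardized_moment",
    "skewness",
    "binned_raw_moment",
    "binned_standardized_moment",
    "binned_skewness",
    "moment_summary",
]


class DegenerateDistributionError(ValueError):
    """Raised when a moment is undefined (e.g. zero spread for ``T_n``)."""


@dataclass
class AbundanceVector:
    """Per-species abundances of one pooled sample.

    Parameters
    ----------
    abundances
        Positive integers, one per species.  Order is irrelevant for every
        descriptor computed from the vector.
    """

    abundances: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances)
        if a.ndim != 1:
            raise ValueError("abundances must be one-dimensional")
        if a.size and not np.issubdtype(a.dtype, np.integer):
            if not np.all(np.mod(a, 1) == 0):
                raise ValueError("abundances must be integers")
            a = a.astype(np.int64)
        if np.any(a < 1):
            bad = np.flatnonzero(a < 1)
            raise ValueError(
                f"abundances must be >= 1; offending positions {bad.tolist()}"
            )
        self.abundances = a.astype(np.int64, copy=False)

    @property
    def log2_abundances(self) -> np.ndarray:
        """``x_j = log2(n_j)``, element-wise."""
        return np.log2(self.abundances.astype(float))

    @property
    def species_count(self) -> int:
        """Number of species S."""
        return int(self.abundances.size)

    @property
    def total_individuals(self) -> int:
        return int(self.abundances.sum())

    @property
    def max_abundance(self) -> int:
        """Abundance of the most abundant species, ``N_max``."""
        if self.abundances.size == 0:
            raise ValueError("empty abundance vector has no maximum")
        return int(self.abundances.max())


def as_abundance_vector(v) -> AbundanceVector:
    """Coerce an array-like of positive integers to :class:`AbundanceVector`."""
    if isinstance(v, AbundanceVector):
        return v
    return AbundanceVector(np.asarray(v))


@dataclass
class BinnedSAD:
    """Octave-class histogram of a SAD.

    ``class_counts[i]`` is the number of species with abundance in
    ``[2**i, 2**(i+1) - 1]``.  Counts are stored as floats because averaged
    histograms (over tiles or transect orderings) are fractional; histograms
    produced directly by :func:`bin_abundances` are whole numbers.
    Interior empty classes are retained as zeros so the support is always
    the contiguous lattice ``{0, ..., num_classes - 1}``.
    """

    class_counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.class_counts, dtype=float)
        if c.ndim != 1:
            raise ValueError("class_counts must be one-dimensional")
        if np.any(c < 0):
            raise ValueError("class counts must be nonnegative")
        self.class_counts = c

    @property
    def num_classes(self) -> int:
        """Number of octave classes NB."""
        return int(self.class_counts.size)

    @property
    def species_count(self) -> float:
        return float(self.class_counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """``p_i``, the proportion of species in class i (sums to 1)."""
        s = self.class_counts.sum()
        if s <= 0:
            raise DegenerateDistributionError("empty histogram has no proportions")
        return self.class_counts / s

    def to_text(self, path, delimiter: str = ",") -> None:
        """Write the histogram as two-column text (class_index, species_count)."""
        idx = np.arange(self.num_classes)
        np.savetxt(
            path,
            np.column_stack([idx, self.class_counts]),
            fmt=["%d", "%.10g"],
            delimiter=delimiter,
            header=f"class_index{delimiter}species_count",
            comments="",
        )

    @classmethod
    def from_text(cls, path, delimiter: str = ",") -> "BinnedSAD":
        data = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
        idx = data[:, 0].astype(int)
        counts = np.zeros(idx.max() + 1 if idx.size else 0)
        counts[idx] = data[:, 1]
        return cls(counts)


def bin_abundances(v) -> BinnedSAD:
    """Bin a vector of abundances into doubling octave classes.

    Class ``i`` covers abundances ``2**i .. 2**(i+1) - 1`` so the class of a
    species with ``n`` individuals is ``floor(log2(n))``.  An empty vector
    yields an empty histogram (``num_classes == 0``).
    """
    v = as_abundance_vector(v)
    if v.species_count == 0:
        return BinnedSAD(np.zeros(0))
    classes = np.floor(np.log2(v.abundances.astype(float))).astype(int)
    # exact at powers of two: log2 of an int64 power of two is exact in binary
    counts = np.bincount(classes)
    return BinnedSAD(counts.astype(float))


def _require_nonempty(v: AbundanceVector) -> None:
    if v.species_count == 0:
        raise ValueError("moment of an empty abundance vector is undefined")


def raw_moment(v, n: int) -> float:
    """Raw moment ``M_n = (1/S) sum_j x_j**n`` of the log2 abundances."""
    v = as_abundance_vector(v)
    _require_nonempty(v)
    if n < 0 or int(n) != n:
        raise ValueError("moment order must be a nonnegative integer")
    return float(np.mean(v.log2_abundances ** n))


def central_moment(v, n: int) -> float:
    """Central moment ``C_n = (1/S) sum_j (x_j - mean)**n``."""
    v = as_abundance_vector(v)
    _require_nonempty(v)
    x = v.log2_abundances
    return float(np.mean((x - x.mean()) ** n))


def standardized_moment(v, n: int) -> float:
    """Standardized moment ``T_n = (1/S) sum_j ((x_j - mean)/sd)**n``.

    Raises
    ------
    DegenerateDistributionError
        If the population standard deviation of the log2 abundances is zero
        (all species equally abundant), for which ``T_n`` is undefined.
    """
    v = as_abundance_vector(v)
    _require_nonempty(v)
    x = v.log2_abundances
    sd = x.std()  # population convention
    if sd == 0:
        raise DegenerateDistributionError(
            "standardized moment undefined: zero spread in log2 abundances"
        )
    return float(np.mean(((x - x.mean()) / sd) ** n))


def skewness(v) -> float:
    """Skewness of the SAD: the third standardized moment ``T_3``."""
    return standardized_moment(v, 3)


def binned_raw_moment(b: BinnedSAD, n: int) -> float:
    """Raw moment of the class-index distribution: ``sum_i p_i * i**n``.

    This is the histogram form of the raw moment with the abscissa taken as
    the integer octave-class index ``i = 0 .. NB-1``; with this convention
    the moments determine the histogram exactly (see the Tchebichef
    reconstruction module).
    """
    if b.num_classes < 1:
        raise ValueError("moment of an empty histogram is undefined")
    i = np.arange(b.num_classes, dtype=float)
    return float(np.sum(b.proportions * i**n))


def binned_standardized_moment(b: BinnedSAD, n: int) -> float:
    """Standardized moment of the class-index distribution weighted by p_i."""
    if b.num_classes < 1:
        raise ValueError("moment of an empty histogram is undefined")
    p = b.proportions
    if np.count_nonzero(p) < 2:
        raise DegenerateDistributionError(
            "standardized moment undefined: histogram mass in a single class"
        )
    i = np.arange(b.num_classes, dtype=float)
    mean = np.sum(p * i)
    var = np.sum(p * (i - mean) ** 2)
    return float(np.sum(p * ((i - mean) / np.sqrt(var)) ** n))


def binned_skewness(b: BinnedSAD) -> float:
    """Skewness (``T_3``) of a bin-level SAD."""
    return binned_standardized_moment(b, 3)


@dataclass
class MomentSummary:
    """Raw, central and standardized moments of one SAD up to ``n_max``.

    ``standardized`` entries are NaN when undefined (zero spread); in that
    case ``degenerate`` is set.
    """

    raw: np.ndarray
    central: np.ndarray
    standardized: np.ndarray
    degenerate: bool = field(default=False)

    @property
    def mean(self) -> float:
        return float(self.raw[1])

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.central[2]))

    @property
    def skewness(self) -> float:
        return float(self.standardized[3])


def moment_summary(v, n_max: int = 10) -> MomentSummary:
    """Compute ``M_n``, ``C_n`` and ``T_n`` for ``n = 0 .. n_max``."""
    v = as_abundance_vector(v)
    _require_nonempty(v)
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    x = v.log2_abundances
    orders = np.arange(n_max + 1)
    raw = np.array([np.mean(x**n) for n in orders])
    c = x - x.mean()
    central = np.array([np.mean(c**n) for n in orders])
    sd = x.std()
    if sd == 0:
        standardized = np.full(n_max + 1, np.nan)
        standardized[0] = 1.0
        return MomentSummary(raw, central, standardized, degenerate=True)
    standardized = np.array([np.mean((c / sd) ** n) for n in orders])
    return MomentSummary(raw, central, standardized)
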