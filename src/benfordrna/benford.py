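"""First-significant-digit extraction and Benford-law conformity statistics.

Benford's law (the first-digit law) states that in many naturally occurring
count-rich datasets the leading decimal digit d occurs with probability
log10(1 + 1/d), so digit 1 leads about 30.1% of the time while digit 9 leads
under 5%. Lognormally distributed quantities that span several orders of
magnitude — such as gene expression counts — follow the law closely, which
is what makes per-gene conformity scoring informative.

This module provides the pure-computation layer: the reference distribution,
digit extraction, digit tabulation with explicit exclusion accounting, the
mean-absolute-error (MAE) conformity score

    MAE = (1/9) * sum_d |A_d - E_d|

between observed digit frequencies A_d and expected frequencies E_d, and a
Pearson chi-squared goodness-of-fit test against the Benford expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DIGITS",
    "BenfordReference",
    "DigitDistribution",
    "UndefinedScoreError",
    "expected_frequencies",
    "uniform_reference",
    "first_significant_digit",
    "first_significant_digits",
    "digit_distribution",
    "mae",
    "mae_from_frequencies",
    "chisq_gof",
]

#: The nine possible first significant digits.
DIGITS = np.arange(1, 10)

# Total-variation bound on MAE: sum_d |A_d - E_d| <= 2 for any two
# probability vectors, so MAE <= 2/9 regardless of the reference.
MAE_UPPER_BOUND = 2.0 / 9.0


class UndefinedScoreError(ValueError):
    """Raised when a conformity score is requested for an empty digit set.

    A gene (or pooled category) whose values are all excluded — all zero, or
    all below one under the sub-unity exclusion rule — has no digit
    distribution. Such rows must be filtered deliberately by the caller;
    silently returning NaN would let all-zero genes contaminate rankings.
    """


@dataclass(frozen=True)
class BenfordReference:
    """Expected leading-digit frequencies E_1..E_9 for a null distribution.

    Parameters
    ----------
    probabilities
        Length-9 array, index ``d - 1`` holding the expected frequency of
        first digit ``d``. Must be positive and sum to 1.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (9,):
            raise ValueError("reference needs exactly 9 digit probabilities")
        if not np.all(p > 0):
            raise ValueError("digit probabilities must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("digit probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)

    def __getitem__(self, digit: int) -> float:
        """Expected frequency of ``digit`` (1..9)."""
        if not 1 <= digit <= 9:
            raise KeyError(f"first digit must be in 1..9, got {digit}")
        return float(self.probabilities[digit - 1])


def expected_frequencies() -> BenfordReference:
    """The Benford reference: E_d = log10(1 + 1/d) for d = 1..9.

    E_1 = log10(2) = 0.30103, decreasing to E_9 = log10(10/9) ~ 0.0458.
    """
    return BenfordReference(np.log10(1.0 + 1.0 / DIGITS))


def uniform_reference() -> BenfordReference:
    """The uniform null: every digit equally likely (E_d = 1/9)."""
    return BenfordReference(np.full(9, 1.0 / 9.0))


def first_significant_digits(values: np.ndarray) -> np.ndarray:
    """Vectorised first significant digit of strictly positive finite values.

    The first significant digit of x > 0 is ``floor(x / 10**floor(log10 x))``
    — the leading non-zero character of the decimal representation, so both
    234 and 0.0023 map to 2. Raises ``ValueError`` on non-positive, NaN or
    infinite input; zeros are an exclusion concern one level up
    (see :func:`digit_distribution`), not a digit.
    """
    x = np.asarray(values, dtype=float)
    if x.size and (not np.all(np.isfinite(x)) or np.any(x <= 0)):
        raise ValueError("first significant digit requires positive finite values")

    def scaled(exponent: np.ndarray) -> np.ndarray:
        # Sub-unity values are scaled up by multiplication with exactly
        # representable positive powers of ten (in two steps for extreme
        # exponents): dividing 0.7 by 10**-1 yields 6.999... in binary
        # floating point and would misread the digit.
        up = np.clip(-exponent, 0, None)
        down = np.clip(exponent, 0, None)
        return x * np.power(10.0, np.minimum(up, 150)) * np.power(
            10.0, np.clip(up - 150, 0, None)
        ) / np.power(10.0, np.minimum(down, 150)) / np.power(
            10.0, np.clip(down - 150, 0, None)
        )

    exponent = np.floor(np.log10(x))
    mantissa = scaled(exponent)
    # log10 rounding can land an exact power of ten one bin off; re-check by
    # multiplication and shift the exponent.
    low = mantissa < 1.0
    if np.any(low):
        exponent = np.where(low, exponent - 1, exponent)
        mantissa = scaled(exponent)
    high = mantissa >= 10.0
    if np.any(high):
        exponent = np.where(high, exponent + 1, exponent)
        mantissa = scaled(exponent)
    digits = np.floor(mantissa).astype(np.int64)
    # Guard: a mantissa within ~1e-9 of the digit boundary above it is in
    # floating-point no-man's-land (e.g. 6.999999999999999 from scaling a
    # value that prints as 0.7); resolve those few from the value's shortest
    # decimal representation, the semantics the digit is defined by.
    near = (np.ceil(mantissa) - mantissa) < 1e-9
    near &= mantissa != np.floor(mantissa)
    if np.any(near):
        flat_digits = digits.reshape(-1)
        flat_x = x.reshape(-1)
        for idx in np.flatnonzero(near.reshape(-1)):
            text = np.format_float_positional(flat_x[idx], trim="-")
            flat_digits[idx] = int(next(c for c in text if c in "123456789"))
        digits = flat_digits.reshape(digits.shape)
    return digits


def first_significant_digit(x: float) -> int:
    """First significant digit of a single positive value (scalar form)."""
    return int(first_significant_digits(np.asarray([x]))[0])


@dataclass(frozen=True)
class DigitDistribution:
    """Observed leading-digit counts for a collection of values.

    Attributes
    ----------
    counts
        Length-9 integer array; ``counts[d - 1]`` is the number of usable
        values whose first significant digit is ``d``.
    n_used
        Number of values that contributed a digit (= ``counts.sum()``).
    n_excluded_zero
        Number of exact zeros excluded (zeros carry no leading digit).
    n_excluded_below_one
        Number of values in (0, 1) excluded under the sub-unity rule.
    """

    counts: np.ndarray
    n_used: int
    n_excluded_zero: int = 0
    n_excluded_below_one: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (9,) or np.any(c < 0):
            raise ValueError("counts must be 9 non-negative integers")
        if int(c.sum()) != self.n_used:
            raise ValueError("counts must sum to n_used")
        object.__setattr__(self, "counts", c)

    @property
    def defined(self) -> bool:
        """Whether any value contributed a digit."""
        return self.n_used > 0

    @property
    def frequencies(self) -> np.ndarray:
        """Observed frequencies A_d = counts_d / n_used.

        Raises :class:`UndefinedScoreError` when no value was usable, so an
        all-zero gene can never silently score as "all digits at frequency 0".
        """
        if self.n_used == 0:
            raise UndefinedScoreError(
                "digit frequencies are undefined: no usable (non-excluded) values"
            )
        return self.counts / self.n_used


def digit_distribution(
    values: np.ndarray, exclude_below_one: bool = False
) -> DigitDistribution:
    """Tabulate first significant digits of a collection of non-negative values.

    Zeros are always excluded (they have no leading digit) and tallied in
    ``n_excluded_zero``. When ``exclude_below_one`` is set, values in (0, 1)
    are also excluded and tallied separately — the rule that restores the
    Benford pattern for per-million-scaled metrics (CPM/TPM), where lowly
    expressed genes produce a flood of sub-unity decimals whose leading
    digits reflect the scaling constant rather than the data.

    Negative values raise ``ValueError``: expression data is non-negative by
    construction, so a negative signals corrupt input rather than a value to
    skip.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.any(x < 0):
        raise ValueError("negative values are invalid in expression data")
    zero = x == 0
    n_zero = int(zero.sum())
    if exclude_below_one:
        below = (x > 0) & (x < 1)
        n_below = int(below.sum())
        usable = x[~zero & ~below]
    else:
        n_below = 0
        usable = x[~zero]
    if usable.size:
        digits = first_significant_digits(usable)
        counts = np.bincount(digits, minlength=10)[1:10]
    else:
        counts = np.zeros(9, dtype=np.int64)
    return DigitDistribution(
        counts=counts,
        n_used=int(usable.size),
        n_excluded_zero=n_zero,
        n_excluded_below_one=n_below,
    )


def mae_from_frequencies(
    frequencies: np.ndarray, reference: BenfordReference | None = None
) -> float:
    """MAE between a length-9 frequency vector and a reference distribution."""
    if reference is None:
        reference = expected_frequencies()
    a = np.asarray(frequencies, dtype=float)
    if a.shape != (9,):
        raise ValueError("expected 9 digit frequencies")
    return float(np.abs(a - reference.probabilities).mean())


def mae(
    observed: DigitDistribution, reference: BenfordReference | None = None
) -> float:
    """Mean absolute error between observed digit frequencies and a reference.

    MAE = (1/9) * sum_{d=1..9} |A_d - E_d|. Zero iff the observed frequencies
    equal the reference; bounded above by 2/9 (total variation), with the
    Benford-specific maximum 2(1 - E_9)/9 ~ 0.212 at a point mass on digit 9.
    Raises :class:`UndefinedScoreError` when ``observed`` has no usable
    values.
    """
    return mae_from_frequencies(observed.frequencies, reference)


def chisq_gof(
    observed: DigitDistribution, reference: BenfordReference | None = None
) -> tuple[float, float]:
    """Pearson chi-squared goodness-of-fit test against a digit reference.

    Returns ``(statistic, p_value)`` where the statistic is
    sum_d (counts_d - n * E_d)^2 / (n * E_d) on 8 degrees of freedom. The
    null hypothesis is that the values' first digits follow the reference,
    so by convention p > 0.05 is read as adherence to Benford's law.
    """
    if reference is None:
        reference = expected_frequencies()
    if observed.n_used == 0:
        raise UndefinedScoreError("chi-squared test undefined: no usable values")
    expected = observed.n_used * reference.probabilities
    statistic, p_value = stats.chisquare(observed.counts, f_exp=expected)
    return float(statistic), float(p_value)
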