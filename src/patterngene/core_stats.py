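"""Pattern-gene statistics on nonnegative expression profiles.

An expression profile over ``n`` samples is treated as a vector
``X = (x_1, ..., x_n)`` of nonnegative intensities.  All statistics here
are functions of the direction of ``X`` only (they are invariant under
positive rescaling of the whole profile):

SPM
    Specificity of expression in sample ``i``: the cosine of the angle
    between ``X`` and its one-sample projection ``X_i`` (the vector equal
    to ``X`` at position ``i`` and zero elsewhere),
    ``SPM_i = x_i / ||X||_2``.  1 means all expression mass sits in
    sample ``i``; the full SPM profile lies on the unit sphere,
    ``sum_i SPM_i^2 = 1``.
DPM
    Dispersion of the SPM profile in unitary form: the sample standard
    deviation (divisor ``n - 1``) of the SPM values, scaled by
    ``sqrt(n)`` so that a perfectly uniform profile scores 0 and a
    single-sample spike scores exactly 1.
CTM
    Contribution of a sample subset: ``sqrt(sum_{i in subset} SPM_i^2)``,
    the cosine between the projection of ``X`` onto the subset and ``X``
    itself.  Reduces to SPM for a singleton subset and to 1 for the full
    sample set.
RPM
    Repression of a putative low-expression group: the ratio of the
    maximum SPM inside the repressed group to the minimum SPM of the
    remaining (expression) group.  0 means the repressed samples are
    fully silent; values near 1 mean no real repression.
r / SUM
    The conventional fractional baseline ``r_i = x_i / sum_j x_j`` and its
    subset sum.  Since ``||X||_2 <= ||X||_1``, ``SPM_i >= r_i`` always,
    which is why the cosine statistics are the more sensitive detector of
    specific/selective expression.

Functions accept any 1-D sequence of nonnegative numbers; sample indices
are 0-based (callers that format user-facing output are responsible for
the 1-based / label presentation).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np

__all__ = [
    "UndefinedStatisticError",
    "ProfileValidationError",
    "as_profile",
    "spm",
    "spm_profile",
    "dpm",
    "ctm",
    "ctm_from_spm",
    "rpm",
    "proportion",
    "proportion_profile",
    "sum_fraction",
]


class ProfileValidationError(ValueError):
    """The input violates a structural precondition (negative values, bad index, ...)."""


class UndefinedStatisticError(ValueError):
    """The statistic is mathematically undefined for this input (e.g. all-zero profile)."""


def as_profile(values: Sequence[float] | np.ndarray, *, clamp_negatives: bool = False) -> np.ndarray:
    """Validate and coerce an expression profile to a float array.

    Parameters
    ----------
    values
        Nonnegative expression levels, length >= 2.
    clamp_negatives
        Floor negative values at 0 instead of raising.  Off by default:
        negative intensities usually mean log-ratio data was supplied by
        mistake, and the cosine geometry presumes nonnegative values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ProfileValidationError(f"profile must be 1-D, got shape {x.shape}")
    if x.size < 2:
        raise ProfileValidationError(f"profile needs at least 2 samples, got {x.size}")
    if np.isnan(x).any():
        raise ProfileValidationError("profile contains missing values; resolve them in preprocessing")
    if (x < 0).any():
        if clamp_negatives:
            x = np.clip(x, 0.0, None)
        else:
            bad = int(np.argmax(x < 0))
            raise ProfileValidationError(
                f"negative expression value {x[bad]} at position {bad}; "
                "pass clamp_negatives=True to floor at 0"
            )
    return x


def _unit(x: np.ndarray) -> np.ndarray:
    """X / ||X||_2; profiles of extreme magnitude are pre-scaled by max(X)
    so the squared norm can neither underflow nor overflow."""
    m = float(x.max())
    if m == 0.0:
        raise UndefinedStatisticError("all-zero profile: SPM-family statistics are undefined")
    if not 2.0**-500 < m < 2.0**500:
        x = x / m
    return x / float(np.linalg.norm(x))


def _check_index(i: int, n: int) -> int:
    i = int(i)
    if not 0 <= i < n:
        raise ProfileValidationError(f"sample index {i} out of range for {n} samples")
    return i


def _check_subset(subset: Iterable[int], n: int) -> np.ndarray:
    idx = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
    if idx.size == 0:
        raise ProfileValidationError("sample subset must be nonempty")
    if idx[0] < 0 or idx[-1] >= n:
        raise ProfileValidationError(f"subset indices {idx.tolist()} out of range for {n} samples")
    return idx


def spm(values: Sequence[float], i: int, *, clamp_negatives: bool = False) -> float:
    """Specificity of expression in sample ``i``: ``x_i / ||X||_2``."""
    x = as_profile(values, clamp_negatives=clamp_negatives)
    i = _check_index(i, x.size)
    return float(_unit(x)[i])


def spm_profile(values: Sequence[float], *, clamp_negatives: bool = False) -> np.ndarray:
    """The full SPM profile ``X / ||X||_2`` — the unit-sphere representation of ``X``."""
    x = as_profile(values, clamp_negatives=clamp_negatives)
    return _unit(x)


def dpm(values: Sequence[float], *, clamp_negatives: bool = False) -> float:
    """Dispersion of the SPM profile: sample SD (ddof=1) times ``sqrt(n)``.

    The ``sqrt(n)`` factor is the unique affine scaling under which the
    most dispersed unit-sphere profile (a single spike, SD ``1/sqrt(n)``)
    scores exactly 1 while a uniform profile scores 0.
    """
    s = spm_profile(values, clamp_negatives=clamp_negatives)
    return float(np.std(s, ddof=1) * np.sqrt(s.size))


def ctm(values: Sequence[float], subset: Iterable[int], *, clamp_negatives: bool = False) -> float:
    """Contribution of ``subset`` to the profile: ``||X_subset||_2 / ||X||_2``."""
    s = spm_profile(values, clamp_negatives=clamp_negatives)
    idx = _check_subset(subset, s.size)
    return ctm_from_spm(s[idx])

def ctm_from_spm(spm_values: Sequence[float]) -> float:
    """CTM from the subset's SPM components alone: ``sqrt(sum SPM_i^2)``.

    Useful when only the per-sample SPM values of the enriched samples are
    reported (the residual SPM mass outside the subset does not enter).
    """
    s = np.asarray(spm_values, dtype=float)
    if s.size == 0:
        raise ProfileValidationError("need at least one SPM component")
    if (s < 0).any() or (s > 1).any():
        raise ProfileValidationError("SPM components must lie in [0, 1]")
    return float(np.sqrt(np.sum(s * s)))


def rpm(
    values: Sequence[float],
    repressed: Iterable[int],
    *,
    clamp_negatives: bool = False,
) -> float:
    """Repression measure: ``max(SPM repressed group) / min(SPM expression group)``.

    The repressed group should hold the profile's lowest expressions
    (ties broken by column order); a warning is emitted otherwise, since
    the ratio is then no longer guaranteed to stay within [0, 1].

    Raises
    ------
    UndefinedStatisticError
        If the expression group contains a zero (the ratio's denominator
        vanishes) or the profile is all-zero.
    ProfileValidationError
        If the repressed group is empty or covers all samples.
    """
    s = spm_profile(values, clamp_negatives=clamp_negatives)
    rep = _check_subset(repressed, s.size)
    if rep.size >= s.size:
        raise ProfileValidationError("repressed group must leave a nonempty expression group")
    mask = np.zeros(s.size, dtype=bool)
    mask[rep] = True
    exp_min = float(np.min(s[~mask]))
    rep_max = float(np.max(s[mask]))
    if exp_min == 0.0:
        raise UndefinedStatisticError(
            "expression group contains a zero-expression sample; RPM is undefined"
        )
    if rep_max > exp_min:
        warnings.warn(
            "repressed group does not hold the lowest expressions; RPM may exceed 1",
            stacklevel=2,
        )
    return rep_max / exp_min


def proportion(values: Sequence[float], i: int, *, clamp_negatives: bool = False) -> float:
    """Fractional expression in sample ``i``: ``x_i / sum_j x_j``."""
    x = as_profile(values, clamp_negatives=clamp_negatives)
    i = _check_index(i, x.size)
    total = float(x.sum())
    if total == 0.0:
        raise UndefinedStatisticError("all-zero profile: fractional expression is undefined")
    return float(x[i] / total)


def proportion_profile(values: Sequence[float], *, clamp_negatives: bool = False) -> np.ndarray:
    """All fractional expressions at once; sums to 1."""
    x = as_profile(values, clamp_negatives=clamp_negatives)
    total = float(x.sum())
    if total == 0.0:
        raise UndefinedStatisticError("all-zero profile: fractional expression is undefined")
    return x / total


def sum_fraction(values: Sequence[float], subset: Iterable[int], *, clamp_negatives: bool = False) -> float:
    """Summed fractional expression over ``subset`` — the selectivity baseline SUM."""
    r = proportion_profile(values, clamp_negatives=clamp_negatives)
    idx = _check_subset(subset, r.size)
    return float(r[idx].sum())
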