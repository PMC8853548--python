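"""Compositional and count transforms applied before noise correction.

The centered log-ratio (CLR) transform maps a strictly positive composition
x to ``clr(x)_i = ln x_i - ln G(x)`` with ``G(x)`` the geometric mean of the
row; its image is the zero-sum hyperplane, and its (pseudo-)inverse is the
softmax. Zeros are handled beforehand by multiplicative replacement with a
pseudocount equal to ``factor`` times the smallest non-zero relative
abundance in the whole table (default factor 0.65).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import FeatureTable, FeatureTableError

DEFAULT_PSEUDOCOUNT_FACTOR = 0.65
DEFAULT_LOGCPM_PRIOR = 0.5


@dataclass
class TransformSpec:
    """Declarative description of the pre-correction transform."""

    method: str = "clr"  # clr | logcpm | none
    pseudocount_factor: float = DEFAULT_PSEUDOCOUNT_FACTOR
    logcpm_prior: float = DEFAULT_LOGCPM_PRIOR

    def __post_init__(self) -> None:
        if self.method not in ("clr", "logcpm", "none"):
            raise FeatureTableError(f"unknown transform method {self.method!r}")
        if self.pseudocount_factor <= 0:
            raise FeatureTableError("pseudocount_factor must be positive")
        if self.logcpm_prior <= 0:
            raise FeatureTableError("logcpm_prior must be positive")


def pseudocount_value(table: FeatureTable, factor: float = DEFAULT_PSEUDOCOUNT_FACTOR) -> float:
    """factor x (global minimum non-zero value of the table)."""
    if factor <= 0:
        raise FeatureTableError("pseudocount factor must be positive")
    positive = table.values[table.values > 0]
    if positive.size == 0:
        raise FeatureTableError("table has no positive values; cannot derive a pseudocount")
    return float(factor * positive.min())


def add_pseudocount(
    table: FeatureTable,
    factor: float = DEFAULT_PSEUDOCOUNT_FACTOR,
    value: float | None = None,
) -> FeatureTable:
    """Replace zeros by a small positive pseudocount and re-close rows.

    The replacement value is ``factor`` times the global minimum non-zero
    relative abundance (or an explicit ``value``, e.g. one fitted on
    training data). Non-zero cells are left untouched before re-closure, so
    within-row rankings of positive values are preserved.
    """
    if table.space != "relative":
        raise FeatureTableError(
            f"add_pseudocount expects relative abundances, got space={table.space!r}"
        )
    pc = pseudocount_value(table, factor) if value is None else float(value)
    if pc <= 0:
        raise FeatureTableError("pseudocount must be positive")
    values = table.values.copy()
    values[values == 0] = pc
    values /= values.sum(axis=1)[:, None]
    return table.with_values(values, "relative", f"add_pseudocount(value={pc:.6g})")


def clr_transform(table: FeatureTable) -> FeatureTable:
    """CLR: per row, log values minus the log geometric mean of the row."""
    if np.any(table.values <= 0):
        raise FeatureTableError(
            "clr_transform requires strictly positive values; call add_pseudocount first"
        )
    logs = np.log(table.values)
    out = logs - logs.mean(axis=1)[:, None]
    return table.with_values(out, "clr", "clr")


def inverse_clr(table: FeatureTable) -> FeatureTable:
    """Softmax per row: the inverse of CLR on the simplex.

    Invariant to adding a per-row constant; the row maximum is subtracted
    before exponentiation to guard against overflow (mathematically a
    no-op).
    """
    if not np.all(np.isfinite(table.values)):
        raise FeatureTableError("inverse_clr requires finite values")
    shifted = table.values - table.values.max(axis=1)[:, None]
    expd = np.exp(shifted)
    out = expd / expd.sum(axis=1)[:, None]
    return table.with_values(out, "relative", "inverse_clr")


def log_cpm(table: FeatureTable, prior: float = DEFAULT_LOGCPM_PRIOR) -> FeatureTable:
    """log2 counts-per-million with a symmetric prior count.

    For a cell c in a sample with library size L:
    ``log2((c + prior) / (L + 2 * prior) * 1e6)``.
    """
    if table.space != "counts":
        raise FeatureTableError(f"log_cpm expects counts, got space={table.space!r}")
    if prior <= 0:
        raise FeatureTableError("logCPM prior must be positive")
    lib = table.values.sum(axis=1)
    if np.any(lib <= 0):
        bad = table.sample_ids[int(np.argmax(lib <= 0))]
        raise FeatureTableError(f"sample {bad!r} has zero library size")
    out = np.log2((table.values + prior) / (lib + 2 * prior)[:, None] * 1e6)
    return table.with_values(out, "log", f"log_cpm(prior={prior})")
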