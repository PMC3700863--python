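"""Correlation-based elimination of redundant bioclimatic variables.

Pairs of layers with |Pearson r| at or above a threshold (default 0.75) carry
largely redundant information; a greedy sweep over an explicit priority list
keeps the first member of each correlated cluster. The priority list is the
reproducible stand-in for the expert's "biologically meaningful" choice: by
default the eight variables such studies typically retain come first (BIO4,
BIO1, BIO15, BIO12, BIO14, BIO8, BIO2, BIO3), then the remaining layers in
ascending order.

For migratory species, annual-scale variables are swapped for their
warm-season counterparts (BIO1 -> BIO10, BIO14 -> BIO18), since migrants only
experience the breeding season on these grounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from rangeshift.bioclim import BIOCLIM_NAMES, BioclimStack

#: Default within-pair preference: commonly retained variables first.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "BIO4",
    "BIO1",
    "BIO15",
    "BIO12",
    "BIO14",
    "BIO8",
    "BIO2",
    "BIO3",
) + tuple(
    name
    for name in BIOCLIM_NAMES
    if name not in {"BIO4", "BIO1", "BIO15", "BIO12", "BIO14", "BIO8", "BIO2", "BIO3"}
)

CORRELATION_THRESHOLD = 0.75

#: Migrant substitution: annual-scale variable -> warm-season counterpart.
MIGRANT_SUBSTITUTION = {"BIO1": "BIO10", "BIO14": "BIO18"}


@dataclass
class VariableSelection:
    """Ordered retained variables plus the rule that produced them."""

    variables: list[str]
    threshold: float = CORRELATION_THRESHOLD
    priority: tuple[str, ...] = DEFAULT_PRIORITY


def pearson_matrix(stack: BioclimStack, variables: Sequence[str] = BIOCLIM_NAMES) -> pd.DataFrame:
    """Pairwise Pearson r across unmasked cells, pairwise-complete.

    A zero-variance layer has undefined correlations; those entries are NaN
    (and are treated as "not correlated" downstream).
    """
    columns = {name: stack[name].ravel() for name in variables}
    df = pd.DataFrame(columns)
    if len(df.dropna(how="all")) < 2:
        raise ValueError("need at least two unmasked cells for correlations")
    corr = df.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def eliminate_correlated(
    matrix: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    priority: Sequence[str] | None = None,
) -> VariableSelection:
    """Greedy sweep in priority order; |r| >= threshold counts as correlated.

    A candidate is accepted iff its |r| with every already-accepted variable
    is strictly below the threshold (NaN correlations do not block). The
    result is deterministic given the priority order.
    """
    if priority is None:
        priority = [v for v in DEFAULT_PRIORITY if v in matrix.columns]
    unknown = set(matrix.columns) - set(priority)
    if unknown:
        raise ValueError(f"priority list does not cover candidates: {sorted(unknown)}")
    retained: list[str] = []
    for candidate in priority:
        if candidate not in matrix.columns or candidate in retained:
            continue
        r = matrix.loc[candidate, retained].abs() if retained else pd.Series(dtype=float)
        if not (r.dropna() >= threshold).any():
            retained.append(candidate)
    return VariableSelection(retained, threshold=threshold, priority=tuple(priority))


def migrant_substitution(selection: VariableSelection) -> VariableSelection:
    """Swap BIO1 -> BIO10 and BIO14 -> BIO18, preserving order, no duplicates."""
    out: list[str] = []
    for name in selection.variables:
        replacement = MIGRANT_SUBSTITUTION.get(name, name)
        if replacement not in out:
            out.append(replacement)
    return VariableSelection(out, threshold=selection.threshold, priority=selection.priority)
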