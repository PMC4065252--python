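"""Expression-proxy phenotype construction.

The focal gene's RPKM is used as a quantitative stand-in for the trait of
interest (here, drug resistance). Two binnings are provided:

* a binary high/low split against the arithmetic population mean — the GWAS
  phenotype ("high" = strictly above the mean; ties with the mean go "low",
  since equality is not *higher* than average);
* a four-group split on fixed RPKM cut points (default <25, [25,50), [50,75),
  >=75) used for descriptive group comparisons.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, PreconditionError
from .types import HIGH, LOW, BinaryPhenotype, ExpressionMatrix

DEFAULT_BREAKS = (25.0, 50.0, 75.0)


def bin_by_mean(expr: ExpressionMatrix, focal_gene: str) -> BinaryPhenotype:
    """Split strains into high/low by the focal gene's mean RPKM.

    Raises ``KeyError`` if the focal gene is absent and
    :class:`DegenerateDataError` when every strain ties with the mean (all
    values identical), in which case no split exists.
    """
    values = expr.row(focal_gene)
    if expr.n_strains < 2:
        raise PreconditionError("bin_by_mean requires at least 2 strains")
    mean = float(values.mean())
    if np.all(values == values[0]):
        raise DegenerateDataError(
            f"all strains have identical {focal_gene!r} expression "
            f"({values[0]}); the mean split is degenerate"
        )
    bins = {
        strain: (HIGH if v > mean else LOW)
        for strain, v in zip(expr.strains, values)
    }
    return BinaryPhenotype(focal_gene=focal_gene, mean_value=mean, bins=bins)


def group_labels(breaks: Sequence[float]) -> list[str]:
    """Human-readable labels for the groups defined by ``breaks``."""
    breaks = [_fmt(b) for b in breaks]
    labels = [f"<{breaks[0]}"]
    labels += [f"[{a},{b})" for a, b in zip(breaks[:-1], breaks[1:])]
    labels.append(f">={breaks[-1]}")
    return labels


def bin_by_breaks(
    expr: ExpressionMatrix,
    focal_gene: str,
    breaks: Sequence[float] = DEFAULT_BREAKS,
) -> dict[str, str]:
    """Assign each strain to an RPKM interval of the focal gene.

    Interior intervals are left-closed/right-open, so a value exactly on a
    cut point joins the interval above it.
    """
    breaks = list(breaks)
    if not breaks:
        raise PreconditionError("breaks must be non-empty")
    if any(b >= c for b, c in zip(breaks[:-1], breaks[1:])):
        raise PreconditionError(f"breaks must be strictly ascending, got {breaks}")
    values = expr.row(focal_gene)
    labels = group_labels(breaks)
    idx = np.searchsorted(breaks, values, side="right")
    return {strain: labels[i] for strain, i in zip(expr.strains, idx)}


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))
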