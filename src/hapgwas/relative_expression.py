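"""qPCR relative quantification (Livak 2^-ddCt and calibrator-free 2^-dCt).

Threshold-cycle (Ct) triplicates are accepted only when every replicate lies
within +/-0.5 cycles of the triplicate median; accepted triplicates are
summarised by their arithmetic mean. Quantification assumes an amplification
efficiency of 2 (doubling per cycle): dCt = Ct(target) - Ct(reference), and
fold change relative to a calibrator sample is 2^-(dCt_sample - dCt_cal).
The reference gene is an actin-like control measured in the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, TriplicateRejectionError, ValidationError

DEFAULT_TOLERANCE = 0.5


@dataclass(frozen=True)
class QpcrMeasurement:
    """Target and reference-gene Ct triplicates for one sample."""

    sample: str
    target_ct: tuple[float, float, float]
    reference_ct: tuple[float, float, float]

    def __post_init__(self):
        for name, trip in (("target", self.target_ct), ("reference", self.reference_ct)):
            if len(trip) != 3:
                raise ValidationError(
                    f"sample {self.sample!r}: {name} triplicate has {len(trip)} values"
                )
            if any(not np.isfinite(c) or c <= 0 for c in trip):
                raise ValidationError(
                    f"sample {self.sample!r}: {name} Ct values must be positive reals"
                )


def triplicate_qc(
    cts: Sequence[float], tolerance: float = DEFAULT_TOLERANCE
) -> float:
    """Mean Ct of an accepted triplicate.

    Accepted iff every replicate lies within +/-``tolerance`` cycles of the
    triplicate median; otherwise a :class:`TriplicateRejectionError` carrying
    the offending replicate indices is raised.
    """
    cts = np.asarray(cts, dtype=float)
    if cts.shape != (3,):
        raise ValidationError(f"expected a triplicate, got {cts.size} values")
    center = float(np.median(cts))
    off = tuple(int(i) for i in np.flatnonzero(np.abs(cts - center) > tolerance))
    if off:
        raise TriplicateRejectionError(
            f"replicates {[i + 1 for i in off]} deviate more than "
            f"{tolerance} cycles from the median {center}",
            indices=off,
        )
    return float(cts.mean())


def delta_ct(sample: QpcrMeasurement, tolerance: float = DEFAULT_TOLERANCE) -> float:
    """Calibrator-free relative level 2^-(mean target Ct - mean reference Ct)."""
    d = _mean_delta(sample, tolerance)
    return float(2.0 ** (-d))


def delta_delta_ct(
    sample: QpcrMeasurement,
    calibrator: QpcrMeasurement,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Fold change of ``sample`` relative to ``calibrator`` by 2^-ddCt."""
    dd = _mean_delta(sample, tolerance) - _mean_delta(calibrator, tolerance)
    return float(2.0 ** (-dd))


def _mean_delta(m: QpcrMeasurement, tolerance: float) -> float:
    try:
        t = triplicate_qc(m.target_ct, tolerance)
        r = triplicate_qc(m.reference_ct, tolerance)
    except TriplicateRejectionError as exc:
        raise TriplicateRejectionError(
            f"sample {m.sample!r}: {exc}", indices=exc.indices
        ) from None
    return t - r


# ---------------------------------------------------------------------------
# table-level interface (CLI)
# ---------------------------------------------------------------------------

def read_ct_table(path, reference_gene: str) -> dict[str, QpcrMeasurement]:
    """Read ``sample  gene  ct1  ct2  ct3`` rows into per-sample measurements.

    Each sample must have exactly one target-gene row and one row for the
    reference gene.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:5]) != ["sample", "gene", "ct1", "ct2", "ct3"]:
        raise FormatError(
            f"{path}: expected columns ['sample', 'gene', 'ct1', 'ct2', 'ct3']"
        )
    rows: dict[str, dict[str, tuple[float, float, float]]] = {}
    for r in df.itertuples(index=False):
        try:
            trip = (float(r.ct1), float(r.ct2), float(r.ct3))
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric Ct for sample {r.sample!r}, gene {r.gene!r}"
            ) from None
        rows.setdefault(r.sample, {})[r.gene] = trip
    out = {}
    for sample, genes in rows.items():
        targets = [g for g in genes if g != reference_gene]
        if reference_gene not in genes or len(targets) != 1:
            raise FormatError(
                f"{path}: sample {sample!r} needs one target row and one "
                f"{reference_gene!r} row"
            )
        out[sample] = QpcrMeasurement(
            sample=sample,
            target_ct=genes[targets[0]],
            reference_ct=genes[reference_gene],
        )
    return out


def fold_change_table(
    measurements: dict[str, QpcrMeasurement],
    calibrator: str | None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Fold changes for every sample; 2^-ddCt vs the calibrator when one is
    named, otherwise calibrator-free 2^-dCt."""
    if calibrator is not None and calibrator not in measurements:
        raise ValidationError(f"calibrator sample {calibrator!r} not in table")
    rows = []
    for sample, m in measurements.items():
        if calibrator is None:
            value = delta_ct(m, tolerance)
            method = "2^-dCt"
        else:
            value = delta_delta_ct(m, measurements[calibrator], tolerance)
            method = "2^-ddCt"
        rows.append({"sample": sample, "method": method, "fold": value})
    return pd.DataFrame(rows)
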