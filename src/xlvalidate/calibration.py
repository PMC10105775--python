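"""PAE-ranked cross-link violation calibration curve.

If the predicted aligned error is well calibrated, cross-links between
residue pairs with low mutual PAE should rarely be violated and the
violation rate should rise with PAE.  The curve is built by ranking all
mapped cross-links by their (symmetrized) PAE value, cutting the ranking
into fixed-size bins, and reporting per bin the mean +/- sd PAE and the
proportion of violated links.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .crosslinks import CrossLink
from .errors import UndefinedValueError
from .structure_io import PAEMatrix
from .violations import Assessment, VIOLATED

__all__ = [
    "CalibrationBin",
    "link_pae",
    "bin_by_pae",
    "low_pae_violation_check",
    "LowPAEReport",
    "write_calibration",
]

DEFAULT_BIN_SIZE = 25


@dataclass(frozen=True)
class CalibrationBin:
    """One fixed-size bin of PAE-ranked cross-links."""

    bin_index: int
    n: int
    mean_pae: float
    sd_pae: float
    violation_proportion: float
    partial: bool = False


def link_pae(pae: PAEMatrix, link: CrossLink) -> float:
    """Symmetrized PAE value at the link's residue pair."""
    if not pae.symmetric:
        raise ValueError("link_pae expects a symmetrized PAE matrix")
    i, j = link.residue_a, link.residue_b
    if not (1 <= i <= pae.n and 1 <= j <= pae.n):
        raise IndexError(f"link residues ({i}, {j}) outside 1..{pae.n}")
    return float(pae.values[i - 1, j - 1])


def bin_by_pae(
    assessments: Sequence[Assessment], bin_size: int = DEFAULT_BIN_SIZE
) -> list[CalibrationBin]:
    """Rank assessments by PAE and cut into consecutive fixed-size bins.

    Unmapped links are excluded (they have no violation status); every
    remaining assessment must carry a PAE value.  Ties in PAE are broken
    by link identity so the binning is deterministic.  A final partial
    bin is kept and flagged.  Population (not sample) standard
    deviations are reported.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    mapped = [a for a in assessments if a.mapped]
    if not mapped:
        raise UndefinedValueError("no mapped assessments to bin")
    if any(a.pae_value is None for a in mapped):
        raise ValueError("every mapped assessment must carry a PAE value")
    ranked = sorted(mapped, key=lambda a: (a.pae_value, a.link.key))

    bins: list[CalibrationBin] = []
    for start in range(0, len(ranked), bin_size):
        chunk = ranked[start : start + bin_size]
        paes = np.array([a.pae_value for a in chunk], dtype=float)
        n_viol = sum(a.status == VIOLATED for a in chunk)
        bins.append(
            CalibrationBin(
                bin_index=len(bins) + 1,
                n=len(chunk),
                mean_pae=float(paes.mean()),
                sd_pae=float(paes.std()),  # population sd
                violation_proportion=n_viol / len(chunk),
                partial=len(chunk) < bin_size,
            )
        )
    return bins


@dataclass(frozen=True)
class LowPAEReport:
    """Violation count among links at or below a PAE cutoff."""

    pae_cutoff: float
    n_links: int
    n_violations: int

    @property
    def clean(self) -> bool:
        return self.n_violations == 0


def low_pae_violation_check(
    assessments: Sequence[Assessment], pae_cutoff: float = 3.5
) -> LowPAEReport:
    """Count violations among mapped links with PAE <= cutoff.

    A well-calibrated predictor should show none in the lowest PAE
    range; ``clean`` flags whether that holds.
    """
    low = [
        a
        for a in assessments
        if a.mapped and a.pae_value is not None and a.pae_value <= pae_cutoff
    ]
    n_viol = sum(a.status == VIOLATED for a in low)
    return LowPAEReport(pae_cutoff=pae_cutoff, n_links=len(low), n_violations=n_viol)


def write_calibration(bins: Sequence[CalibrationBin], path: str | Path) -> None:
    """Calibration TSV: bin_index, n, mean_pae, sd_pae, violation_proportion."""
    pd.DataFrame(
        [
            {
                "bin_index": b.bin_index,
                "n": b.n,
                "mean_pae": round(b.mean_pae, 4),
                "sd_pae": round(b.sd_pae, 4),
                "violation_proportion": round(b.violation_proportion, 4),
                "partial": b.partial,
            }
            for b in bins
        ]
    ).to_csv(path, sep="\t", index=False)
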