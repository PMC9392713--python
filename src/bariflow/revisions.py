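"""Dynamic decision-tree reoperation model.

Each primary procedure either generates exactly one revision within the
following ten years or none (two health states). The chance of revision
depends on the procedure performed; the procedure mix blends the
per-procedure 10-year revision probabilities into a single expected rate.

Two views of the resulting revision stream are computed:

* ``attributed`` — revisions credited to the fiscal year of their primary
  (the 10-year total a cohort of primaries will generate); the reporting
  surface for demand tables.
* ``occurrence`` — revisions placed in the calendar year they happen, using
  each procedure's year-offset distribution (uniform over offsets 1..10 by
  default); the costing surface.

Over any horizon long enough to contain every offset, the two views conserve
the same total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ProcedureMix, RevisionMatrix, REVISION_WINDOW
from .demand_supply import DemandSchedule


@dataclass
class RevisionSchedule:
    """Revision streams from one demand schedule.

    ``attributed`` is indexed by origin year; ``occurrence`` by the year the
    revision takes place (it extends ``REVISION_WINDOW`` years beyond the
    last origin year so nothing is truncated).
    """

    attributed: pd.Series
    occurrence: pd.Series

    @property
    def total_attributed(self) -> float:
        return float(self.attributed.sum())

    @property
    def total_occurrence(self) -> float:
        return float(self.occurrence.sum())


def blended_rate(mix: ProcedureMix, matrix: RevisionMatrix) -> float:
    """Mix-weighted 10-year revision probability, Σ_p mix_p × prob_p."""
    missing = set(mix.shares) - set(matrix.prob_10yr)
    if missing:
        raise KeyError(f"procedure(s) {sorted(missing)} in mix but absent from revision matrix")
    return float(sum(share * matrix.prob_10yr[proc] for proc, share in mix.shares.items()))


def attributed_stream(
    primaries: DemandSchedule, mix: ProcedureMix, matrix: RevisionMatrix
) -> pd.Series:
    """Ten-year revision total credited to each origin year of primaries.

    attributed(y) = primaries(y) × blended rate; linear in primaries.
    """
    rate = blended_rate(mix, matrix)
    out = primaries.total * rate
    out.name = "revisions_attributed"
    return out


def occurrence_stream(
    primaries: DemandSchedule, mix: ProcedureMix, matrix: RevisionMatrix
) -> pd.Series:
    """Revisions by the year they occur.

    occurrence(t) = Σ_y Σ_p primaries(y) × mix_p × prob_p × offset_p(t − y)
    for offsets 1..10. Computed as a per-procedure convolution of the primary
    series with the offset distribution.
    """
    years = primaries.years
    if not years:
        return pd.Series(dtype=float, name="revisions_occurring")
    volumes = primaries.total.to_numpy(dtype=float)
    acc = np.zeros(len(years) + REVISION_WINDOW)
    for proc, share in mix.shares.items():
        if share == 0.0:
            continue
        prob = matrix.prob_10yr[proc]
        if prob == 0.0:
            continue
        offsets = np.asarray(matrix.offset_distribution(proc), dtype=float)
        # kernel index k ↔ offset k+1 years after the primary
        acc[1:] += np.convolve(volumes * share * prob, offsets)
    index = pd.Index(range(years[0], years[0] + len(acc)), name="year")
    return pd.Series(acc, index=index, name="revisions_occurring")


def revision_schedule(
    primaries: DemandSchedule, mix: ProcedureMix, matrix: RevisionMatrix
) -> RevisionSchedule:
    """Both views of the revision stream for one demand schedule."""
    return RevisionSchedule(
        attributed=attributed_stream(primaries, mix, matrix),
        occurrence=occurrence_stream(primaries, mix, matrix),
    )
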