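"""Centroid m/z observations -> per-peptide deuterated fractions.

The normalization is ``D = (Mex - Mex0) / (Mex100 - Mex0)`` where ``Mex0``
is the average undeuterated peptide mass and ``Mex100`` either the
out-exchange control mass (single-protein runs) or the theoretical maximum
(complex runs). D is never clamped; values outside [0, 1] pass through and
are flagged so back-exchange anomalies remain visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .constants import DEUTERIUM_MASS_SHIFT, PROTON_MASS
from .errors import (
    DegenerateReferenceError,
    DomainError,
    IncompleteReferenceError,
    NoDataError,
)
from .peptides import ExchangeDataset, max_exchangeable_amides

ReferencePolicy = Literal["out-exchange", "theoretical"]


def mass_from_mz(centroid_mz: float, charge: int) -> float:
    """Neutral mass from a centroid m/z and charge state."""
    if charge < 1:
        raise DomainError("charge must be >= 1")
    if not centroid_mz > 0:
        raise DomainError("m/z must be positive")
    return charge * (centroid_mz - PROTON_MASS)


def deuterated_fraction(mex: float, mex0: float, mex100: float) -> float:
    """(Mex - Mex0) / (Mex100 - Mex0), evaluated exactly, no clamping."""
    denom = mex100 - mex0
    if denom == 0:
        raise DegenerateReferenceError(
            f"Mex100 == Mex0 == {mex0}; deuterated fraction undefined"
        )
    return (mex - mex0) / denom


def theoretical_max_mass(
    sequence: str, mex0: float, d2o_fraction: float, fast_loss: int = 1
) -> float:
    """Mass at maximal theoretical exchange of the observable amides."""
    n = max_exchangeable_amides(sequence, fast_loss)
    return mex0 + n * d2o_fraction * DEUTERIUM_MASS_SHIFT


@dataclass(frozen=True)
class PeptideKey:
    protein: str
    start: int
    end: int
    sequence: str


@dataclass
class TimepointStats:
    exposure: float
    values: tuple[float, ...]  # per-replicate D, replicate order

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float | None:
        """Sample SD (n-1 denominator); None when n < 2."""
        if self.n < 2:
            return None
        return float(np.std(self.values, ddof=1))


@dataclass
class UptakeCurve:
    """Replicate-resolved deuterated fractions of one peptide in one state."""

    peptide: PeptideKey
    state: str
    timepoints: list[TimepointStats] = field(default_factory=list)
    reference: ReferencePolicy = "out-exchange"
    flagged: bool = False  # any D outside [0, 1]

    def exposures(self) -> list[float]:
        return [tp.exposure for tp in self.timepoints]

    def at(self, exposure: float) -> TimepointStats:
        for tp in self.timepoints:
            if tp.exposure == exposure:
                return tp
        raise KeyError(exposure)


def aggregate_replicates(
    dataset: ExchangeDataset,
    reference_policy: ReferencePolicy = "out-exchange",
    *,
    d2o_fraction: float = 0.9,
    fast_loss: int = 1,
) -> list[UptakeCurve]:
    """Collapse a centroid table into per-state uptake curves.

    Per replicate, charge-state masses are first averaged (unweighted) to one
    neutral mass; D is then computed per replicate; mean/SD/n are derived
    from the replicate D values per timepoint. ``Mex0`` is the mean neutral
    mass over all undeuterated records of the peptide (all states pooled).
    """
    if len(dataset) == 0:
        raise NoDataError("empty dataset")
    df = dataset.frame.copy()
    df["neutral_mass"] = df["charge"] * (df["centroid_mz"] - PROTON_MASS)

    curves: list[UptakeCurve] = []
    for (protein, start, end, sequence), pep_df in df.groupby(
        ["protein", "start", "end", "sequence"], sort=True
    ):
        key = PeptideKey(protein, int(start), int(end), sequence)
        zero = pep_df[pep_df["exposure"] == 0.0]
        if zero.empty:
            raise IncompleteReferenceError(
                f"no undeuterated (exposure 0) record for peptide "
                f"{protein} {start}-{end}"
            )
        # average over charges within replicate first, then over replicates
        mex0 = float(
            zero.groupby(["state", "replicate"])["neutral_mass"].mean().mean()
        )

        for state, state_df in pep_df.groupby("state", sort=True):
            if reference_policy == "theoretical":
                mex100 = theoretical_max_mass(sequence, mex0, d2o_fraction, fast_loss)
            else:
                ctrl = state_df[np.isinf(state_df["exposure"])]
                if ctrl.empty:
                    # fall back to controls from any state of this peptide
                    ctrl = pep_df[np.isinf(pep_df["exposure"])]
                if ctrl.empty:
                    raise IncompleteReferenceError(
                        f"no out-exchange control for peptide "
                        f"{protein} {start}-{end} state {state!r}"
                    )
                mex100 = float(
                    ctrl.groupby("replicate")["neutral_mass"].mean().mean()
                )

            curve = UptakeCurve(key, str(state), reference=reference_policy)
            timed = state_df[
                (state_df["exposure"] > 0) & np.isfinite(state_df["exposure"])
            ]
            for exposure, tp_df in timed.groupby("exposure", sort=True):
                per_rep = tp_df.groupby("replicate", sort=True)["neutral_mass"].mean()
                values = tuple(
                    deuterated_fraction(m, mex0, mex100) for m in per_rep
                )
                curve.timepoints.append(TimepointStats(float(exposure), values))
                if any(not 0.0 <= v <= 1.0 for v in values):
                    curve.flagged = True
            if curve.timepoints:
                curves.append(curve)
    return curves


def curves_to_frame(curves: Iterable[UptakeCurve]) -> pd.DataFrame:
    """Tabular export: one row per peptide x state x exposure."""
    rows = []
    for c in curves:
        for tp in c.timepoints:
            sd = tp.sd
            rows.append(
                (
                    c.peptide.protein, c.peptide.start, c.peptide.end,
                    c.peptide.sequence, c.state, tp.exposure,
                    tp.mean, math.nan if sd is None else sd, tp.n,
                    ";".join(f"{v:.6g}" for v in tp.values),
                    c.reference, c.flagged,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein", "start", "end", "sequence", "state", "exposure",
            "d_mean", "d_sd", "n", "d_values", "reference", "flagged",
        ],
    )


def write_uptake_tsv(
    curves: Iterable[UptakeCurve], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        curves_to_frame(curves).to_csv(fh, sep="\t", index=False)
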