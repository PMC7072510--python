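"""Per-well micronucleus frequencies, dose-response summaries, fold changes.

The frequency statistic for a well is the ratio of totals pooled over all
its fields — total micronuclei divided by total nuclei — not the mean of
per-field ratios, so fields with few cells do not get outsized weight and
the statistic is robust to confluency differences between conditions.

Dose-response points are mean ± sample SD over technical replicates,
presented relative to the vehicle control; gene-silencing results are fold
changes of each replicate over the mean siControl frequency (so siControl
fold changes average to 1 by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config_io import PlateLayout, WellSpec
from .exclusion_filters import NucleusRecord, retained_counts

__all__ = [
    "WellResult",
    "DoseResponsePoint",
    "FoldChangeResult",
    "score_well",
    "dose_response",
    "fold_change",
    "wells_table",
    "dose_response_table",
    "fold_change_table",
]


@dataclass(frozen=True)
class WellResult:
    """Counts and micronucleus frequency for one well.

    ``frequency`` is the exact ratio of the two pooled integer counts; it is
    ``None`` (and ``flagged`` is set) when no nuclei were retained, e.g. at
    cytotoxic doses where dying cells lift off the plate. Flagged wells are
    excluded from downstream statistics rather than scored as zero, which
    would bias dose-response curves downward exactly where cytotoxicity is
    highest.
    """

    well_id: str
    n_fields: int
    n_nuclei: int
    n_micronuclei: int
    condition: str = ""
    dose: float | None = None
    dose_units: str | None = None
    replicate: int = 1
    role: str = "untreated"

    @property
    def frequency(self) -> float | None:
        if self.n_nuclei == 0:
            return None
        return self.n_micronuclei / self.n_nuclei

    @property
    def frequency_percent(self) -> float | None:
        f = self.frequency
        return None if f is None else 100.0 * f

    @property
    def flagged(self) -> bool:
        return self.n_nuclei == 0


def score_well(
    well_id: str,
    field_counts: Sequence[tuple[int, int] | Sequence["NucleusRecord"]],
    well: WellSpec | None = None,
) -> WellResult:
    """Aggregate per-field results into one :class:`WellResult`.

    *field_counts* holds, per field, either a ``(n_nuclei, n_micronuclei)``
    pair of retained counts or the list of :class:`NucleusRecord` for that
    field (counted here). Counts are summed over fields **before** division.
    """
    if len(field_counts) == 0:
        raise ValueError("a well requires at least one field")
    totals_n = 0
    totals_mn = 0
    for entry in field_counts:
        if (
            isinstance(entry, tuple)
            and len(entry) == 2
            and all(isinstance(v, (int, np.integer)) for v in entry)
        ):
            n, mn = entry
        else:
            n, mn = retained_counts(entry)  # type: ignore[arg-type]
        totals_n += int(n)
        totals_mn += int(mn)
    meta = dict(condition="", dose=None, dose_units=None, replicate=1, role="untreated")
    if well is not None:
        meta = dict(condition=well.condition, dose=well.dose,
                    dose_units=well.dose_units, replicate=well.replicate,
                    role=well.role)
    result = WellResult(
        well_id=well_id,
        n_fields=len(field_counts),
        n_nuclei=totals_n,
        n_micronuclei=totals_mn,
        **meta,
    )
    if result.flagged:
        warnings.warn(
            f"well {well_id}: no retained nuclei; frequency undefined, "
            "well excluded from downstream statistics",
            stacklevel=2,
        )
    return result


@dataclass(frozen=True)
class DoseResponsePoint:
    """Replicate summary for one dose, relative to the vehicle control.

    ``sd`` is the sample (n−1) standard deviation and is ``None`` (flagged
    undefined) with fewer than two replicates. The vehicle control's own
    ``relative_mean`` is 1 by construction.
    """

    dose: float
    dose_units: str | None
    frequencies: tuple[float, ...]
    mean: float
    sd: float | None
    relative_mean: float
    is_vehicle: bool = False

    @property
    def n_replicates(self) -> int:
        return len(self.frequencies)


def _defined(wells: Sequence[WellResult]) -> list[WellResult]:
    return [w for w in wells if not w.flagged]


def dose_response(wells: Sequence[WellResult],
                  layout: PlateLayout | None = None) -> list[DoseResponsePoint]:
    """Per-dose mean ± SD relative to the vehicle control, doses ascending.

    Wells with role ``vehicle-control`` form the normalisation baseline (its
    dose is reported as 0 when unspecified); wells with role ``treatment``
    are grouped by dose.
    """
    wells = _defined(list(wells))
    vehicle = [w for w in wells if w.role == "vehicle-control"]
    treated = [w for w in wells if w.role == "treatment"]
    if not vehicle:
        raise ValueError("dose_response requires at least one vehicle-control well")
    vehicle_freqs = tuple(w.frequency for w in vehicle)
    vehicle_mean = float(np.mean(vehicle_freqs))
    if vehicle_mean == 0:
        raise ValueError("vehicle-control mean frequency is zero; relative "
                         "dose-response undefined")

    def make_point(dose, units, freqs, is_vehicle):
        freqs = tuple(float(f) for f in freqs)
        mean = float(np.mean(freqs))
        sd = float(np.std(freqs, ddof=1)) if len(freqs) >= 2 else None
        rel = 1.0 if is_vehicle else mean / vehicle_mean
        return DoseResponsePoint(dose=dose, dose_units=units, frequencies=freqs,
                                 mean=mean, sd=sd, relative_mean=rel,
                                 is_vehicle=is_vehicle)

    points = [make_point(vehicle[0].dose if vehicle[0].dose is not None else 0.0,
                         vehicle[0].dose_units, vehicle_freqs, True)]
    by_dose: dict[float, list[WellResult]] = {}
    for w in treated:
        if w.dose is None:
            raise ValueError(f"treatment well {w.well_id} has no dose")
        by_dose.setdefault(float(w.dose), []).append(w)
    for dose in sorted(by_dose):
        group = by_dose[dose]
        points.append(
            make_point(dose, group[0].dose_units,
                       [w.frequency for w in group], False)
        )
    return points


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-replicate fold changes over the mean siControl frequency.

    Invariant: the mean of the siControl fold changes is exactly 1.
    """

    fold_changes: dict[str, tuple[float, ...]]  # condition -> per-replicate folds
    sicontrol_condition: str
    sicontrol_mean_frequency: float


def fold_change(wells: Sequence[WellResult],
                layout: PlateLayout | None = None) -> FoldChangeResult:
    """Normalise every replicate frequency by the mean siControl frequency."""
    wells = _defined(list(wells))
    controls = [w for w in wells if w.role == "siControl"]
    if not controls:
        raise ValueError("fold_change requires at least one siControl well")
    control_mean = float(np.mean([w.frequency for w in controls]))
    if control_mean == 0:
        raise ValueError("mean siControl frequency is zero; fold change undefined")
    folds: dict[str, list[float]] = {}
    for w in wells:
        folds.setdefault(w.condition, []).append(w.frequency / control_mean)
    return FoldChangeResult(
        fold_changes={k: tuple(v) for k, v in folds.items()},
        sicontrol_condition=controls[0].condition,
        sicontrol_mean_frequency=control_mean,
    )


# ---------------------------------------------------------------------------
# tabular views
# ---------------------------------------------------------------------------


def wells_table(wells: Sequence[WellResult]) -> pd.DataFrame:
    rows = []
    for w in wells:
        rows.append(
            dict(
                well_id=w.well_id, condition=w.condition, dose=w.dose,
                dose_units=w.dose_units, replicate=w.replicate, role=w.role,
                n_fields=w.n_fields, n_nuclei=w.n_nuclei,
                n_micronuclei=w.n_micronuclei, frequency=w.frequency,
                frequency_percent=w.frequency_percent,
                flags="no_retained_nuclei" if w.flagged else "",
            )
        )
    return pd.DataFrame(rows)


def dose_response_table(points: Sequence[DoseResponsePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            dose=p.dose, dose_units=p.dose_units, n_replicates=p.n_replicates,
            mean=p.mean, sd=p.sd, relative_mean=p.relative_mean,
            is_vehicle=p.is_vehicle,
        )
        for p in points
    )


def fold_change_table(result: FoldChangeResult) -> pd.DataFrame:
    rows = []
    for condition, folds in result.fold_changes.items():
        for i, f in enumerate(folds, start=1):
            rows.append(dict(condition=condition, replicate=i, fold_change=f,
                             is_sicontrol=condition == result.sicontrol_condition))
    return pd.DataFrame(rows)
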