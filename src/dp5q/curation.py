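"""Corpus curation filters for structure–spectrum training records.

The filters run in a fixed order and mirror standard cleaning of a
carbon-NMR corpus: drop entries without a ¹³C spectrum, drop
multi-fragment species (salts), drop molecules containing elements
outside the 11-element set {H, B, C, N, O, F, P, S, Cl, Br, I}, and
drop records whose observed shifts disagree with a reference prediction
by more than a threshold (default 50 ppm) at any single position —
the signature of a misassigned or misinterpreted spectrum.

The outlier filter is per-atom maximum deviation with a strict boundary
(deviation exactly at the threshold is kept).  The source of reference
predictions is pluggable: any per-record shift list of the same length
as the observed peak list, paired positionally.  Duplicate records are
deliberately retained — they are treated as independent entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem_io import MoleculeRecord, ShiftSpectrum
from .synthetic import ALLOWED_ELEMENTS

__all__ = [
    "CorpusRecord",
    "CurationReport",
    "filter_has_carbon_spectrum",
    "filter_single_fragment",
    "filter_elements",
    "filter_shift_outliers",
    "curate",
]


@dataclass
class CorpusRecord:
    """One raw corpus entry: a structure with an optional peak list.

    ``reference_shifts`` (optional) holds a reference-predicted shift
    for each observed peak, used only by the outlier filter.
    """

    molecule: MoleculeRecord
    spectrum: ShiftSpectrum | None = None
    reference_shifts: list[float] | None = None


@dataclass
class CurationReport:
    records_in: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {
            "no_carbon_spectrum": 0,
            "multi_fragment": 0,
            "disallowed_element": 0,
            "shift_outlier": 0,
        }
    )
    records_out: int = 0

    def check(self) -> None:
        assert self.records_out == self.records_in - sum(self.removed.values())


def filter_has_carbon_spectrum(records: list[CorpusRecord]) -> list[CorpusRecord]:
    """Keep records that carry a non-empty ¹³C peak list."""
    return [r for r in records if r.spectrum is not None and len(r.spectrum) > 0]


def filter_single_fragment(records: list[CorpusRecord]) -> list[CorpusRecord]:
    """Remove species whose bond graph has more than one component."""
    return [r for r in records if r.molecule.n_fragments == 1]


def filter_elements(records: list[CorpusRecord]) -> list[CorpusRecord]:
    """Remove molecules containing elements outside the allowed set."""
    return [
        r
        for r in records
        if all(sym in ALLOWED_ELEMENTS for sym, _ in r.molecule.atoms)
    ]


def filter_shift_outliers(
    records: list[CorpusRecord], threshold: float = 50.0
) -> list[CorpusRecord]:
    """Remove records with any |predicted − observed| above ``threshold`` ppm.

    The comparison is positional over the record's ``reference_shifts``;
    records without reference predictions pass unexamined.  A deviation
    exactly equal to the threshold is tolerated.
    """
    kept: list[CorpusRecord] = []
    for r in records:
        if r.reference_shifts is None or r.spectrum is None:
            kept.append(r)
            continue
        if len(r.reference_shifts) != len(r.spectrum.shifts):
            raise ValueError(
                f"record {r.molecule.name!r}: {len(r.reference_shifts)} reference "
                f"predictions for {len(r.spectrum.shifts)} observed shifts"
            )
        if math.isinf(threshold):
            kept.append(r)
            continue
        dev = max(
            abs(p - o) for p, o in zip(r.reference_shifts, r.spectrum.shifts)
        )
        if dev <= threshold:
            kept.append(r)
    return kept


def curate(
    records: list[CorpusRecord], threshold: float = 50.0
) -> tuple[list[CorpusRecord], CurationReport]:
    """Apply the four filters in order and account for every record."""
    report = CurationReport(records_in=len(records))
    stage = filter_has_carbon_spectrum(records)
    report.removed["no_carbon_spectrum"] = len(records) - len(stage)
    prev = stage
    stage = filter_single_fragment(prev)
    report.removed["multi_fragment"] = len(prev) - len(stage)
    prev = stage
    stage = filter_elements(prev)
    report.removed["disallowed_element"] = len(prev) - len(stage)
    prev = stage
    stage = filter_shift_outliers(prev, threshold=threshold)
    report.removed["shift_outlier"] = len(prev) - len(stage)
    report.records_out = len(stage)
    report.check()
    return stage, report
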