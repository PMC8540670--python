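"""Cohort-level summaries: allele frequencies, reproducibility (RSD)
tables, null-combination inventory and the good-quality-combination
screen."""

from __future__ import annotations

import dataclasses
import warnings
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import (
    FLAG_HET,
    FLAG_UNRESOLVED,
    FLAG_UNRESOLVED_7,
    GenotypeCall,
)
from .reference import LOCI, ReferenceLibrary, default_library

#: allele combinations associated with good bread-making quality
GOOD_QUALITY_ALLELES = {
    "Glu-A1": (frozenset({"1Ax1"}), frozenset({"1Ax2*"})),
    "Glu-B1": (
        frozenset({"1Bx7", "1By8"}),
        frozenset({"1Bx17", "1By18"}),
        frozenset({"1Bx7OE", "1By8*"}),
        frozenset({"1Bx7OE", "1By9"}),
    ),
    "Glu-D1": (frozenset({"1Dx5", "1Dy10"}),),
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the printed-table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def frequencies_from_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Percentage frequencies (half-up, 2 decimals) from raw allele counts."""
    if not counts:
        raise ValueError("empty count table")
    n = sum(counts.values())
    rows = [
        {"allele": allele, "count": c,
         "frequency_pct": round_half_up(100.0 * c / n)}
        for allele, c in counts.items()
    ]
    return pd.DataFrame(rows)


@dataclasses.dataclass
class CohortSummary:
    table: pd.DataFrame
    n_total: int
    excluded: dict


def allele_frequency_table(
    calls: Sequence[GenotypeCall],
    exclude_heterozygous: bool = True,
) -> CohortSummary:
    """Per-locus allele counts and percentage frequencies.

    Heterozygous lines are excluded (with a reported excluded count)
    rather than contributing fractional counts; lines with an unresolved
    1Bx7/1Bx7OE call are tabulated under their combined pseudo-allele
    display rather than guessed.
    """
    if not calls:
        raise ValueError("empty genotype list")
    rows = []
    excluded = {"heterozygous": 0}
    for locus in LOCI:
        counts: dict[tuple, int] = {}
        n_locus = 0
        for call in calls:
            if exclude_heterozygous and FLAG_HET in call.flags:
                continue
            key = (call.displays[locus], call.symbols[locus])
            counts[key] = counts.get(key, 0) + 1
            n_locus += 1
        for (display, symbol), c in sorted(counts.items()):
            rows.append({
                "locus": locus, "display": display, "symbol": symbol,
                "count": c,
                "frequency_pct": round_half_up(100.0 * c / n_locus),
            })
    excluded["heterozygous"] = sum(
        1 for call in calls if FLAG_HET in call.flags
    ) if exclude_heterozygous else 0
    return CohortSummary(table=pd.DataFrame(rows), n_total=len(calls),
                         excluded=excluded)


def rsd_table(
    replicate_assignments: Sequence[Sequence[tuple]],
    library: ReferenceLibrary | None = None,
) -> pd.DataFrame:
    """Per-subunit RT / area reproducibility over technical replicates.

    Input: one list of ``(subunit, apex_rt, area)`` tuples per replicate
    (see :func:`hmwgs.calling.assign_peaks_to_subunits`). RSD% is
    ``100 * sample SD / mean`` (ddof=1). Subunits observed in fewer than
    two replicates are excluded with a warning.
    """
    if len(replicate_assignments) < 2:
        raise ValueError("need at least 2 replicates")
    library = library or default_library()
    rts: dict[str, list] = {}
    areas: dict[str, list] = {}
    for rep in replicate_assignments:
        for name, rt, area in rep:
            rts.setdefault(name, []).append(rt)
            areas.setdefault(name, []).append(area)
    rows = []
    for name in sorted(rts, key=lambda n: library.get(n).mean_rt):
        vals = np.array(rts[name])
        if len(vals) < 2:
            warnings.warn(
                f"{name}: present in fewer than 2 replicates; excluded"
            )
            continue
        ar = np.array(areas[name])
        rows.append({
            "subunit": name,
            "n": len(vals),
            "mean_rt": float(vals.mean()),
            "rt_rsd_pct": float(100.0 * vals.std(ddof=1) / vals.mean()),
            "mean_area": float(ar.mean()),
            "area_rsd_pct": float(100.0 * ar.std(ddof=1) / ar.mean()),
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class QualityScreenResult:
    matching_ids: list
    pct: float
    excluded_ids: list


def quality_screen(calls: Sequence[GenotypeCall]) -> QualityScreenResult:
    """Lines whose genotype carries good-quality alleles at all three loci:
    1Ax1 or 1Ax2*; one of 7+8, 17+18, 7OE+8*, 7OE+9; and 5+10.

    Lines with unresolved candidate sets are excluded (reported
    separately), never optimistically counted.
    """
    matching, excluded = [], []
    for call in calls:
        if FLAG_UNRESOLVED_7 in call.flags or FLAG_UNRESOLVED in call.flags:
            excluded.append(call.line_id)
            continue
        ok = all(
            call.subunits[locus] in GOOD_QUALITY_ALLELES[locus]
            for locus in LOCI
        )
        if ok:
            matching.append(call.line_id)
    n = len(calls)
    pct = round_half_up(100.0 * len(matching) / n) if n else 0.0
    return QualityScreenResult(matching, pct, excluded)


def null_inventory(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    """Tabulate x- or y-null lines at Glu-B1/Glu-D1 (and Glu-A1 locus
    nulls are not inventoried here — they are an ordinary catalogued
    allele) by the surviving partner subunit."""
    counts: dict[tuple, int] = {}
    spec = [
        ("Glu-B1", "1Bx null", "bx_null"),
        ("Glu-B1", "1By null", "by_null"),
        ("Glu-D1", "1Dx null", "dx_null"),
        ("Glu-D1", "1Dy null", "dy_null"),
    ]
    for call in calls:
        for locus, label, flag in spec:
            if flag not in call.flags:
                continue
            partners = call.subunits[locus]
            partner = ";".join(sorted(partners)) if partners else "(none)"
            key = (locus, label, partner)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"locus": locus, "null_type": label, "partner": partner, "count": c}
        for (locus, label, partner), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["locus", "null_type", "partner", "count"])
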