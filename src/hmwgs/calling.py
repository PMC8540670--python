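"""Peak-to-subunit matching, ambiguity resolution and genotype assembly.

The caller assigns each detected peak the set of subunits whose RT
tolerance windows contain its apex. When several subunits claim one peak,
the decision depends on whether they are *curated-ambiguous* (members of a
known RT-overlap group needing orthogonal evidence) or merely have
adjacent windows (in which case retention time itself discriminates and
the nearest reference wins). Curated ambiguity is then resolved in a fixed
order — x/y linkage, SDS-PAGE band identity, 1Bx7OE junction-marker PCR —
and whatever remains is reported as an unresolved candidate set, never
guessed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .chromatogram import Chromatogram
from .peaks import Peak, correct_baseline, detect_peaks
from .reference import LOCI, ReferenceLibrary, default_library
from .simulate import (
    AuxiliaryEvidence,
    PCR_NEGATIVE,
    PCR_POSITIVE,
)

STATUS_UNAMBIGUOUS = "unambiguous"
STATUS_LINKAGE = "resolved_by_linkage"
STATUS_GEL = "resolved_by_gel"
STATUS_PCR = "resolved_by_pcr"
STATUS_AREA = "resolved_by_area_ratio"
STATUS_UNRESOLVED = "unresolved"
STATUS_UNKNOWN = "unknown"

FLAG_A1_NULL = "a1_null"
FLAG_BX_NULL = "bx_null"
FLAG_BY_NULL = "by_null"
FLAG_DX_NULL = "dx_null"
FLAG_DY_NULL = "dy_null"
FLAG_HET = "heterozygous"
FLAG_ATYPICAL = "subunit_count_atypical"
FLAG_UNRESOLVED_7 = "unresolved_7_7OE"
FLAG_UNRESOLVED = "unresolved"
FLAG_UNKNOWN_COMBO = "unknown_combination"
FLAG_INCONSISTENT = "inconsistent"

_PCR_PAIR = frozenset({"1Bx7", "1Bx7OE"})


@dataclasses.dataclass
class CallConfig:
    """Settings for the detection + calling pipeline.

    ``k`` scales the matching windows (mean ± k·SD); ``min_rsd_pct`` floors
    the RSD used for window widths so that subunits catalogued from few
    cultivars (tiny between-cultivar RSD) still get windows wide enough for
    run-to-run jitter — the floor is the instrument's published replicate
    RT reproducibility bound (0.21%). Area-ratio inference for 1Bx7OE is
    available but off by default; the junction-marker PCR is authoritative.
    """

    k: float = 3.0
    min_rsd_pct: float = 0.21
    min_height: float = 2.5
    min_separation: float = 0.02
    max_half_width: float = 0.048
    baseline_edge_window: float = 0.5
    use_linkage: bool = True
    use_gel: bool = True
    use_pcr: bool = True
    use_area_ratio: bool = False
    area_ratio_threshold: float = 1.5


@dataclasses.dataclass
class SubunitCall:
    """One peak's final interpretation."""

    candidates: frozenset
    apex_rt: float
    area: float
    status: str
    evidence_note: str = ""
    merged: bool = False

    @property
    def resolved(self) -> bool:
        return len(self.candidates) == 1 and self.status != STATUS_UNKNOWN

    @property
    def subunit(self) -> str | None:
        return next(iter(self.candidates)) if self.resolved else None


@dataclasses.dataclass
class PeakAssignment:
    peak: Peak
    candidates: frozenset
    note: str = ""


@dataclasses.dataclass
class GenotypeCall:
    """Per-line locus genotypes, allele symbols, flags and evidence trail."""

    line_id: str
    subunits: dict
    unresolved: dict
    symbols: dict
    displays: dict
    flags: frozenset
    evidence_notes: tuple
    calls: tuple = ()

    def symbol(self, locus: str) -> str:
        return self.symbols[locus]


# ---------------------------------------------------------------------------
# matching


def _distance(apex: float, ref) -> float:
    return abs(apex - ref.mean_rt)


def match_peaks(peaks: Sequence[Peak], library: ReferenceLibrary | None = None,
                k: float = 3.0, min_rsd_pct: float = 0.21) -> list[PeakAssignment]:
    """Candidate subunits per peak from k-SD RT windows.

    A peak inside several windows is reduced to the nearest reference
    (by absolute RT distance) unless that reference belongs to a curated
    ambiguity component, in which case the whole component is attached as
    the candidate set. Merged peaks keep every window hit. A peak inside
    no window is labelled unknown (empty candidate set); when two peaks
    claim the same singleton reference the nearer one (|apex − mean|/SD)
    wins and the other reverts to unknown.
    """
    library = library or default_library()
    out: list[PeakAssignment] = []
    for peak in sorted(peaks, key=lambda p: p.apex_rt):
        hits = [
            name for name in library.names
            if (lambda w: w[0] <= peak.apex_rt <= w[1])(
                library.rt_window(name, k, min_rsd_pct))
        ]
        if not hits:
            out.append(PeakAssignment(peak, frozenset(), note="no window match"))
            continue
        if peak.merged and len(hits) > 1:
            out.append(PeakAssignment(peak, frozenset(hits),
                                      note="merged peak; all window hits kept"))
            continue
        nearest = min(hits, key=lambda n: (_distance(peak.apex_rt, library.get(n)), n))
        component = library.ambiguity_component(nearest)
        if component is not None:
            out.append(PeakAssignment(peak, component,
                                      note=f"ambiguity group via {nearest}"))
        else:
            out.append(PeakAssignment(peak, frozenset({nearest})))

    # arbitration: one singleton reference claimed by several peaks
    best: dict[str, PeakAssignment] = {}
    for a in out:
        if len(a.candidates) != 1:
            continue
        name = next(iter(a.candidates))
        ref = library.get(name)
        sd = ref.mean_rt * max(ref.rsd_pct, min_rsd_pct) / 100.0
        if name not in best:
            best[name] = a
            continue
        incumbent = best[name]
        if abs(a.peak.apex_rt - ref.mean_rt) / sd < \
                abs(incumbent.peak.apex_rt - ref.mean_rt) / sd:
            incumbent.candidates = frozenset()
            incumbent.note = f"outcompeted for {name}"
            best[name] = a
        else:
            a.candidates = frozenset()
            a.note = f"outcompeted for {name}"
    return out


# ---------------------------------------------------------------------------
# evidence resolution


def resolve_ambiguities(
    assignments: Sequence[PeakAssignment],
    evidence: AuxiliaryEvidence | None,
    library: ReferenceLibrary | None = None,
    config: CallConfig | None = None,
) -> tuple[list[SubunitCall], list[str]]:
    """Turn candidate assignments into subunit calls.

    Deterministic resolution order: (1) linked-pair rules (an unambiguous
    x-type anchor selects its implied y-type partner); (2) SDS-PAGE band
    identities, intersected with the candidate set at gel mobility
    resolution (1Bx7 and 1Bx7OE co-migrate); (3) the 1Bx7OE junction PCR,
    splitting a residual {1Bx7, 1Bx7OE} pair. Whatever stays ambiguous is
    returned unresolved with the full candidate set. Gel evidence naming a
    subunit outside every candidate set is reported as a conflict, never
    silently overridden.
    """
    library = library or default_library()
    config = config or CallConfig()
    notes: list[str] = []

    calls: list[SubunitCall] = []
    for a in assignments:
        if not a.candidates:
            calls.append(SubunitCall(frozenset(), a.peak.apex_rt, a.peak.area,
                                     STATUS_UNKNOWN, a.note, a.peak.merged))
        elif len(a.candidates) == 1:
            calls.append(SubunitCall(a.candidates, a.peak.apex_rt, a.peak.area,
                                     STATUS_UNAMBIGUOUS, a.note, a.peak.merged))
        else:
            calls.append(SubunitCall(a.candidates, a.peak.apex_rt, a.peak.area,
                                     STATUS_UNRESOLVED, a.note, a.peak.merged))

    def unambiguous_names() -> set:
        return {c.subunit for c in calls
                if c.resolved and c.status == STATUS_UNAMBIGUOUS}

    # (1) linkage
    if config.use_linkage:
        anchors = unambiguous_names()
        for rule in library.linked_pairs:
            if rule.anchor not in anchors:
                continue
            targets = [c for c in calls
                       if len(c.candidates) > 1 and rule.implied in c.candidates]
            if not targets:
                continue
            implied_ref = library.get(rule.implied)
            target = min(targets, key=lambda c: abs(c.apex_rt - implied_ref.mean_rt))
            target.candidates = frozenset({rule.implied})
            target.status = STATUS_LINKAGE
            target.evidence_note = (
                f"implied by linked pair {rule.anchor} + {rule.implied}"
            )

    # (2) gel
    if config.use_gel and evidence is not None and evidence.gel_confirmed:
        all_candidates = frozenset().union(*(c.candidates for c in calls)) \
            if calls else frozenset()
        stray = evidence.gel_confirmed - all_candidates
        if stray:
            notes.append(
                "gel evidence conflict: band(s) "
                + ", ".join(sorted(stray))
                + " match no candidate peak"
            )
        gel_classes = frozenset().union(
            *(library.gel_equivalents(n) for n in evidence.gel_confirmed)
        )
        for c in calls:
            if len(c.candidates) <= 1:
                continue
            inter = c.candidates & gel_classes
            if not inter:
                continue
            if len(inter) == 1:
                c.candidates = inter
                c.status = STATUS_GEL
                c.evidence_note = f"SDS-PAGE band {next(iter(inter))}"
            elif inter < c.candidates:
                c.candidates = inter
                c.evidence_note = "narrowed by SDS-PAGE"

    # (3) PCR for the 1Bx7 / 1Bx7OE split
    for c in calls:
        if c.candidates != _PCR_PAIR:
            continue
        if config.use_pcr and evidence is not None and \
                evidence.pcr_7oe in (PCR_POSITIVE, PCR_NEGATIVE):
            chosen = "1Bx7OE" if evidence.pcr_7oe == PCR_POSITIVE else "1Bx7"
            c.candidates = frozenset({chosen})
            c.status = STATUS_PCR
            c.evidence_note = f"junction-marker PCR {evidence.pcr_7oe}"
        elif config.use_area_ratio:
            others = [o.area for o in calls if o is not c and o.candidates]
            if others:
                ref_area = sorted(others)[len(others) // 2]
                ratio = c.area / ref_area if ref_area > 0 else 0.0
                chosen = "1Bx7OE" if ratio >= config.area_ratio_threshold \
                    else "1Bx7"
                c.candidates = frozenset({chosen})
                c.status = STATUS_AREA
                c.evidence_note = f"area ratio {ratio:.2f} vs median peak"
    return calls, notes


# ---------------------------------------------------------------------------
# genotype assembly


def _short_name(name: str) -> str:
    """Catalog-style short label: '1Bx7OE' -> '7OE', '1Dx2.2' -> '2.2'."""
    for prefix in ("1Ax", "1Bx", "1By", "1Dx", "1Dy"):
        if name.startswith(prefix):
            short = name[len(prefix):]
            break
    else:
        return name
    if name == "1Bx20x":
        return "20"
    return short


def _display(library: ReferenceLibrary, subunits: Iterable[str]) -> str:
    subs = sorted(subunits, key=lambda n: (not library.get(n).is_x_type,
                                           library.get(n).mean_rt, n))
    return " + ".join(_short_name(n) for n in subs) if subs else "Null"


def assemble_genotype(
    line_id: str,
    calls: Sequence[SubunitCall],
    library: ReferenceLibrary | None = None,
    extra_notes: Iterable[str] = (),
) -> GenotypeCall:
    """Partition subunit calls by locus and assign allele symbols.

    An absent 1Ax subunit yields the locus-null *Glu-A1c*; a missing x or
    y partner at *Glu-B1*/*Glu-D1* sets the corresponding null flag and the
    single-subunit allele symbol. Two complete allele sets at one locus
    yield the heterozygous flag with both symbols joined "A/B". Totals
    outside the typical 3–5 subunit profile are flagged atypical.
    """
    library = library or default_library()
    flags: set = set()
    notes = list(extra_notes)

    resolved: dict[str, set] = {locus: set() for locus in LOCI}
    unresolved: dict[str, list] = {locus: [] for locus in LOCI}
    for c in calls:
        if c.resolved:
            locus = library.get(c.subunit).locus
            resolved[locus].add(c.subunit)
        elif c.candidates:
            loci = {library.get(n).locus for n in c.candidates}
            locus = loci.pop() if len(loci) == 1 else None
            if locus is None:
                notes.append(
                    f"peak at {c.apex_rt:.3f} min ambiguous across loci"
                )
                continue
            unresolved[locus].append(frozenset(c.candidates))
            if c.candidates == _PCR_PAIR:
                flags.add(FLAG_UNRESOLVED_7)
            else:
                flags.add(FLAG_UNRESOLVED)
        else:
            notes.append(f"unassigned peak at {c.apex_rt:.3f} min")

    symbols: dict[str, str] = {}
    displays: dict[str, str] = {}
    for locus in LOCI:
        subs = frozenset(resolved[locus])
        pending = tuple(unresolved[locus])
        xs = {n for n in subs if library.get(n).is_x_type}
        ys = subs - xs

        het_pair = _heterozygous_partition(library, locus, subs) \
            if (len(xs) > 1 or len(ys) > 1 or
                (locus == "Glu-A1" and len(subs) > 1)) else None
        if het_pair is not None:
            flags.add(FLAG_HET)
            recs = [library.lookup_allele_symbol(locus, s) for s in het_pair]
            recs.sort(key=lambda r: r.symbol)
            symbols[locus] = "/".join(r.symbol for r in recs)
            displays[locus] = "/".join(r.display for r in recs)
            continue
        if (len(xs) > 1 or len(ys) > 1):
            flags.add(FLAG_INCONSISTENT)
            notes.append(
                f"{locus}: {len(xs)} x-type and {len(ys)} y-type calls "
                "without heterozygous structure"
            )

        if pending:
            # fold the unresolved candidate set into a pseudo-allele display
            parts = []
            for cand in pending:
                parts.append("/".join(_short_name(n) for n in sorted(cand)))
            known = [_short_name(n) for n in sorted(
                subs, key=lambda n: (not library.get(n).is_x_type,
                                     library.get(n).mean_rt))]
            label = " + ".join(parts + known) if (parts or known) else "Null"
            symbols[locus] = f"unresolved({label})"
            displays[locus] = label
            continue

        rec = library.lookup_allele_symbol(locus, subs)
        symbols[locus] = rec.symbol
        displays[locus] = rec.display if rec.in_catalog \
            else _display(library, subs)
        if not rec.in_catalog and subs:
            flags.add(FLAG_UNKNOWN_COMBO)

        if locus == "Glu-A1":
            if not subs:
                flags.add(FLAG_A1_NULL)
        else:
            x_flag = FLAG_BX_NULL if locus == "Glu-B1" else FLAG_DX_NULL
            y_flag = FLAG_BY_NULL if locus == "Glu-B1" else FLAG_DY_NULL
            if not xs:
                flags.add(x_flag)
            if not ys:
                flags.add(y_flag)

    n_subunits = sum(len(resolved[locus]) for locus in LOCI) \
        + sum(len(unresolved[locus]) for locus in LOCI)
    if not 3 <= n_subunits <= 5:
        flags.add(FLAG_ATYPICAL)

    notes.extend(c.evidence_note for c in calls if c.evidence_note)
    return GenotypeCall(
        line_id=line_id,
        subunits={locus: frozenset(resolved[locus]) for locus in LOCI},
        unresolved={locus: tuple(unresolved[locus]) for locus in LOCI},
        symbols=symbols,
        displays=displays,
        flags=frozenset(flags),
        evidence_notes=tuple(notes),
        calls=tuple(calls),
    )


def _heterozygous_partition(library: ReferenceLibrary, locus: str,
                            subs: frozenset) -> tuple | None:
    """Split ``subs`` into two disjoint catalogued allele sets, if possible."""
    if library.allele_map is None:
        return None
    entries = [r for r in library.allele_map.records()
               if r.locus == locus and r.subunits and r.subunits <= subs]
    for i, first in enumerate(entries):
        for second in entries[i + 1:]:
            if first.subunits | second.subunits == subs and \
                    not (first.subunits & second.subunits):
                return (first.subunits, second.subunits)
    return None


# ---------------------------------------------------------------------------
# end-to-end


def call_line(
    chrom: Chromatogram,
    evidence: AuxiliaryEvidence | None = None,
    library: ReferenceLibrary | None = None,
    config: CallConfig | None = None,
) -> GenotypeCall:
    """Full single-line pipeline: baseline correction, peak detection,
    window matching, evidence resolution and genotype assembly."""
    library = library or default_library()
    config = config or CallConfig()
    corrected = correct_baseline(chrom, edge_window=config.baseline_edge_window)
    peaks = detect_peaks(corrected, min_height=config.min_height,
                         min_separation=config.min_separation,
                         max_half_width=config.max_half_width)
    assignments = match_peaks(peaks, library, k=config.k,
                              min_rsd_pct=config.min_rsd_pct)
    calls, notes = resolve_ambiguities(assignments, evidence, library, config)
    return assemble_genotype(chrom.line_id, calls, library, extra_notes=notes)


def assign_peaks_to_subunits(
    peaks: Sequence[Peak],
    subunit_names: Sequence[str],
    library: ReferenceLibrary | None = None,
) -> list[tuple]:
    """Nearest-mean assignment of detected peaks to a *known* subunit set.

    Used for replicate QC where the genotype is given: each subunit takes
    the nearest unclaimed peak apex. Returns (name, apex_rt, area) tuples;
    subunits with no remaining peak are skipped.
    """
    library = library or default_library()
    available = list(peaks)
    out = []
    for name in sorted(subunit_names, key=lambda n: library.get(n).mean_rt):
        if not available:
            break
        ref = library.get(name)
        best = min(available, key=lambda p: abs(p.apex_rt - ref.mean_rt))
        available.remove(best)
        out.append((name, best.apex_rt, best.area))
    return out
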