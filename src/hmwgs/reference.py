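"""Retention-time reference library for wheat HMW glutenin subunits.

The library holds one record per subunit — its *Glu-1* locus, x/y family,
mean RP-UPLC retention time (RT, minutes) and the relative standard
deviation of that RT across cultivars — together with three pieces of
curated knowledge used by the allele caller:

* **ambiguity groups**: sets of subunits whose RT windows overlap so that
  RT alone cannot separate them, annotated with the orthogonal evidence
  channel (SDS-PAGE gel mobility, PCR junction markers, or x/y linkage)
  that resolves them;
* **linked-pair rules**: x-type anchors whose unambiguous presence implies
  the identity of the co-inherited y-type partner (1Bx17 implies 1By18);
* **allele catalog**: the mapping from a per-locus subunit set to the
  catalogued allele symbol and display name (e.g. {1Bx17, 1By18} at
  *Glu-B1* is *Glu-B1i*, printed "17 + 18").
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

LOCI = ("Glu-A1", "Glu-B1", "Glu-D1")
FAMILIES = ("Ax", "Bx", "By", "Dx", "Dy")
FAMILY_LOCUS = {
    "Ax": "Glu-A1",
    "Bx": "Glu-B1",
    "By": "Glu-B1",
    "Dx": "Glu-D1",
    "Dy": "Glu-D1",
}
#: canonical elution order of subunit families, fastest (earliest RT) first
ELUTION_ORDER = ("Dy", "By", "Dx", "Bx", "Ax")
X_FAMILIES = frozenset({"Ax", "Bx", "Dx"})

GEL = "gel"
PCR = "pcr"
LINKAGE = "linkage"
RESOLUTION_CHANNELS = (GEL, PCR, LINKAGE)

UNKNOWN_SYMBOL = "unknown"


class LibraryError(ValueError):
    """Invalid reference-library content."""


class LibraryFormatError(LibraryError):
    """Malformed reference-library file."""


class UnknownSubunitError(KeyError):
    """Lookup of a subunit name absent from the library."""


@dataclasses.dataclass(frozen=True)
class SubunitRef:
    """One subunit's identity and RT statistics.

    ``sd_rt`` is derived as ``mean_rt * rsd_pct / 100`` (minutes).
    """

    name: str
    locus: str
    family: str
    mean_rt: float
    rsd_pct: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise LibraryError(f"{self.name}: unknown family {self.family!r}")
        if FAMILY_LOCUS[self.family] != self.locus:
            raise LibraryError(
                f"{self.name}: family {self.family} inconsistent with locus {self.locus}"
            )
        if not self.mean_rt > 0:
            raise LibraryError(f"{self.name}: mean RT must be positive")
        if not 0 <= self.rsd_pct < 5:
            raise LibraryError(f"{self.name}: RSD% out of range [0, 5)")

    @property
    def sd_rt(self) -> float:
        return self.mean_rt * self.rsd_pct / 100.0

    @property
    def is_x_type(self) -> bool:
        return self.family in X_FAMILIES


@dataclasses.dataclass(frozen=True)
class AmbiguityGroup:
    members: frozenset
    resolution_channel: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise LibraryError("ambiguity group needs at least two members")
        if self.resolution_channel not in RESOLUTION_CHANNELS:
            raise LibraryError(
                f"unknown resolution channel {self.resolution_channel!r}"
            )


@dataclasses.dataclass(frozen=True)
class LinkedPairRule:
    anchor: str
    implied: str
    locus: str


@dataclasses.dataclass(frozen=True)
class AlleleRecord:
    locus: str
    subunits: frozenset
    symbol: str
    display: str
    in_catalog: bool = True


# Subunits that SDS-PAGE cannot tell apart (identical electrophoretic
# mobility class): 1Bx7 and its overexpressing duplication variant.
GEL_COMOBILE = (frozenset({"1Bx7", "1Bx7OE"}),)

DEFAULT_AMBIGUITY_GROUPS = (
    AmbiguityGroup(frozenset({"1Bx7", "1Bx7OE", "1Bx14"}), GEL),
    AmbiguityGroup(frozenset({"1By8*", "1By9", "1By15"}), GEL),
    AmbiguityGroup(frozenset({"1Bx7", "1Bx7OE"}), PCR),
    AmbiguityGroup(frozenset({"1By8*", "1By9", "1By15", "1By18"}), LINKAGE),
)

DEFAULT_LINKED_PAIRS = (LinkedPairRule("1Bx17", "1By18", "Glu-B1"),)

#: x/y pairings used as consistency checks only (never to create calls)
CONSISTENCY_PAIRS = (
    ("1Bx13", "1By16"),
    ("1Bx14", "1By15"),
    ("1Bx20x", "1By20y"),
)


class AlleleSymbolMap:
    """Bijective map between (locus, subunit set) and allele symbols."""

    def __init__(self, records: Sequence[AlleleRecord],
                 reference_counts: Mapping[tuple, int] | None = None) -> None:
        self._by_key: dict[tuple, AlleleRecord] = {}
        for rec in records:
            key = (rec.locus, rec.subunits)
            if key in self._by_key:
                raise LibraryError(f"duplicate allele entry for {key}")
            self._by_key[key] = rec
        self.reference_counts = dict(reference_counts or {})

    def __len__(self) -> int:
        return len(self._by_key)

    def records(self) -> list[AlleleRecord]:
        return list(self._by_key.values())

    def lookup(self, locus: str, subunits: Iterable[str]) -> AlleleRecord:
        """Return the catalogued allele for a per-locus subunit set.

        A combination absent from the catalog comes back with the sentinel
        symbol ``"unknown"`` and ``in_catalog=False``; subunits belonging to
        a different locus raise :class:`LibraryError`.
        """
        subs = frozenset(subunits)
        if locus not in LOCI:
            raise LibraryError(f"unknown locus {locus!r}")
        for other_locus, members in self._locus_membership().items():
            if other_locus != locus and subs & members:
                raise LibraryError(
                    f"subunits {sorted(subs & members)} do not belong to {locus}"
                )
        rec = self._by_key.get((locus, subs))
        if rec is not None:
            return rec
        return AlleleRecord(locus, subs, UNKNOWN_SYMBOL,
                            display=None, in_catalog=False)

    def _locus_membership(self) -> dict[str, frozenset]:
        out: dict[str, set] = {locus: set() for locus in LOCI}
        for (locus, subs) in self._by_key:
            out[locus].update(subs)
        return {locus: frozenset(s) for locus, s in out.items()}


class ReferenceLibrary:
    """Validated container for the subunit RT library plus curated rules."""

    def __init__(
        self,
        subunits: Sequence[SubunitRef],
        ambiguity_groups: Sequence[AmbiguityGroup] = DEFAULT_AMBIGUITY_GROUPS,
        linked_pairs: Sequence[LinkedPairRule] = DEFAULT_LINKED_PAIRS,
        allele_map: AlleleSymbolMap | None = None,
    ) -> None:
        self._refs: dict[str, SubunitRef] = {}
        for ref in subunits:
            if ref.name in self._refs:
                raise LibraryError(f"duplicate subunit {ref.name!r}")
            self._refs[ref.name] = ref
        for group in ambiguity_groups:
            missing = group.members - self._refs.keys()
            if missing:
                raise LibraryError(
                    f"ambiguity group member(s) {sorted(missing)} not in library"
                )
        self.ambiguity_groups = tuple(ambiguity_groups)
        self.linked_pairs = tuple(linked_pairs)
        self.allele_map = allele_map
        self._components = self._curated_components()

    # -- basic access -------------------------------------------------

    @property
    def names(self) -> tuple:
        return tuple(self._refs)

    def __contains__(self, name: str) -> bool:
        return name in self._refs

    def __len__(self) -> int:
        return len(self._refs)

    def __iter__(self):
        return iter(self._refs.values())

    def get(self, name: str) -> SubunitRef:
        try:
            return self._refs[name]
        except KeyError:
            raise UnknownSubunitError(name) from None

    def by_family(self, family: str) -> list[SubunitRef]:
        return [r for r in self._refs.values() if r.family == family]

    def family_sizes(self) -> dict[str, int]:
        out = {f: 0 for f in FAMILIES}
        for ref in self._refs.values():
            out[ref.family] += 1
        return out

    # -- RT windows and ambiguity -------------------------------------

    def rt_window(self, name: str, k: float, min_rsd_pct: float = 0.0) -> tuple:
        """Symmetric tolerance window ``mean_rt ± k * sd`` in minutes.

        ``min_rsd_pct`` floors the RSD used for the window half-width so
        that subunits whose catalogued between-cultivar RSD is smaller than
        the instrument's run-to-run reproducibility still get a window wide
        enough to capture replicate jitter.
        """
        if k < 0:
            raise ValueError("k must be non-negative")
        ref = self.get(name)
        sd = ref.mean_rt * max(ref.rsd_pct, min_rsd_pct) / 100.0
        return (ref.mean_rt - k * sd, ref.mean_rt + k * sd)

    def derive_ambiguity_groups(self, k: float,
                                min_rsd_pct: float = 0.0) -> list[frozenset]:
        """Connected components of the k-SD window-overlap graph.

        Two subunits are joined when their ``mean ± k*sd`` intervals
        intersect; the result is a diagnostic to compare against the
        curated ambiguity groups. Singletons are included.
        """
        names = list(self._refs)
        windows = {n: self.rt_window(n, k, min_rsd_pct) for n in names}
        parent = {n: n for n in names}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, a in enumerate(names):
            lo_a, hi_a = windows[a]
            for b in names[i + 1:]:
                lo_b, hi_b = windows[b]
                if lo_a <= hi_b and lo_b <= hi_a:
                    parent[find(a)] = find(b)
        comps: dict[str, set] = {}
        for n in names:
            comps.setdefault(find(n), set()).add(n)
        return sorted((frozenset(c) for c in comps.values()),
                      key=lambda c: min(self.get(n).mean_rt for n in c))

    def _curated_components(self) -> dict[str, frozenset]:
        """Connected components of the curated-group membership graph."""
        parent: dict[str, str] = {}
        for group in self.ambiguity_groups:
            members = sorted(group.members)
            for m in members:
                parent.setdefault(m, m)

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for group in self.ambiguity_groups:
            members = sorted(group.members)
            for m in members[1:]:
                parent[find(members[0])] = find(m)
        comps: dict[str, set] = {}
        for n in parent:
            comps.setdefault(find(n), set()).add(n)
        return {n: frozenset(comps[find(n)]) for n in parent}

    def ambiguity_component(self, name: str) -> frozenset | None:
        """Curated ambiguity component containing ``name``, if any."""
        return self._components.get(name)

    @property
    def gel_confirmable(self) -> frozenset:
        """Subunits whose identity SDS-PAGE can attest to."""
        out: set = set()
        for group in self.ambiguity_groups:
            if group.resolution_channel == GEL:
                out |= group.members
        return frozenset(out)

    def gel_equivalents(self, name: str) -> frozenset:
        """Gel mobility class of ``name`` (subunits gel cannot separate)."""
        for cls in GEL_COMOBILE:
            if name in cls:
                return cls
        return frozenset({name})

    # -- elution order -------------------------------------------------

    def elution_order_violations(self) -> list[str]:
        """Subunits breaking the canonical Dy < By < Dx < Bx < Ax order.

        Computed by repeatedly removing the subunit involved in the most
        cross-family order inversions until the remaining family RT ranges
        are disjoint and canonically ordered.
        """
        rank = {fam: i for i, fam in enumerate(ELUTION_ORDER)}
        remaining = dict(self._refs)
        violators: list[str] = []
        while True:
            inversions: dict[str, int] = {n: 0 for n in remaining}
            refs = list(remaining.values())
            for i, a in enumerate(refs):
                for b in refs[i + 1:]:
                    ra, rb = rank[a.family], rank[b.family]
                    if ra == rb:
                        continue
                    early, late = (a, b) if ra < rb else (b, a)
                    if early.mean_rt >= late.mean_rt:
                        inversions[a.name] += 1
                        inversions[b.name] += 1
            worst = max(inversions.values(), default=0)
            if worst == 0:
                return sorted(violators)
            # deterministic tie-break: inversion count, then name
            offender = min(
                (n for n, c in inversions.items() if c == worst)
            )
            violators.append(offender)
            del remaining[offender]

    # -- allele symbols -----------------------------------------------

    def lookup_allele_symbol(self, locus: str,
                             subunits: Iterable[str]) -> AlleleRecord:
        if self.allele_map is None:
            raise LibraryError("library has no allele catalog attached")
        return self.allele_map.lookup(locus, subunits)


# ---------------------------------------------------------------------------
# loading


_REQUIRED_LIB_COLS = ("subunit", "locus", "family", "mean_rt_min", "rsd_pct")
_REQUIRED_MAP_COLS = ("locus", "subunits", "symbol", "display")


def _bundled(name: str) -> Path:
    return Path(resources.files("hmwgs.data") / name)


def load_allele_map(path: str | Path | None = None) -> AlleleSymbolMap:
    """Load the allele catalog TSV (optionally with a reference-count column)."""
    path = _bundled("allele_catalog.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype=str, keep_default_na=False)
    missing = set(_REQUIRED_MAP_COLS) - set(df.columns)
    if missing:
        raise LibraryFormatError(f"allele catalog missing column(s) {sorted(missing)}")
    records, counts = [], {}
    for row in df.itertuples(index=False):
        subs = frozenset(s for s in row.subunits.split(";") if s)
        rec = AlleleRecord(row.locus, subs, row.symbol, row.display)
        records.append(rec)
        if "reference_count" in df.columns and row.reference_count != "":
            counts[(row.locus, subs)] = int(row.reference_count)
    return AlleleSymbolMap(records, reference_counts=counts)


def load_reference_library(
    path: str | Path | None = None,
    *,
    ambiguity_groups: Sequence[AmbiguityGroup] = DEFAULT_AMBIGUITY_GROUPS,
    linked_pairs: Sequence[LinkedPairRule] = DEFAULT_LINKED_PAIRS,
    allele_map_path: str | Path | None = None,
) -> ReferenceLibrary:
    """Load and validate the subunit RT library from a TSV file.

    With no ``path`` the bundled default library (22 subunits) and allele
    catalog are used.
    """
    path = _bundled("reference_library.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_REQUIRED_LIB_COLS) - set(df.columns)
    if missing:
        raise LibraryFormatError(
            f"reference library missing column(s) {sorted(missing)}"
        )
    refs = [
        SubunitRef(row.subunit, row.locus, row.family,
                   float(row.mean_rt_min), float(row.rsd_pct))
        for row in df.itertuples(index=False)
    ]
    return ReferenceLibrary(
        refs,
        ambiguity_groups=ambiguity_groups,
        linked_pairs=linked_pairs,
        allele_map=load_allele_map(allele_map_path),
    )


_DEFAULT_LIBRARY: ReferenceLibrary | None = None


def default_library() -> ReferenceLibrary:
    """Bundled 22-subunit library with the default curated rules (cached)."""
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = load_reference_library()
    return _DEFAULT_LIBRARY
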