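"""Synthetic RP-UPLC chromatogram generator.

Emulates the final-gradient RT landscape of the optimized separation: one
Gaussian elution peak per expressed subunit centred at the library mean RT
with within-line (injection-to-injection) jitter, multiplicative peak-area
variation, a slow linear baseline drift and white detector noise. Whole
cohorts can be materialized from per-locus allele counts, with the exact
requested marginals and a truth table for scoring.

What the generator deliberately does *not* model: the acetonitrile
gradient program itself, low-molecular-weight glutenin / gliadin
background peaks, peak tailing, and gel images (auxiliary evidence is
emitted directly as symbolic records).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram
from .reference import (
    LOCI,
    ReferenceLibrary,
    UnknownSubunitError,
    default_library,
)

PCR_POSITIVE = "positive"
PCR_NEGATIVE = "negative"
PCR_UNTESTED = "untested"

#: simulation-only abundance multiplier for the overexpressing 1Bx7 variant,
#: which carries two functional gene copies
DEFAULT_AREA_SCALE: Mapping[str, float] = {"1Bx7OE": 2.0}


@dataclasses.dataclass
class SimConfig:
    """Simulator settings.

    Times are minutes, intensities arbitrary units. The within-line RT
    jitter and peak-area CVs are calibrated to the instrument study's
    replicate reproducibility (10-injection RT RSD under 0.21%, area RSD
    under 1.18%): the generating CVs sit low enough that the *observed*
    maximum sample RSD over a typical subunit complement stays below those
    bounds with high probability. ``between_line_rt_offset_pct`` bounds a
    uniform per-line RT shift (percent of mean RT, applied to every subunit
    of the line) emulating between-cultivar spread; it is zero by default.
    """

    t_start: float = 0.0
    t_end: float = 12.0
    dt: float = 0.002
    peak_sigma: float = 0.012
    within_line_rt_cv_pct: float = 0.13
    area_cv_pct: float = 0.75
    base_area: float = 1000.0
    noise_sd: float = 0.5
    baseline_slope: float = 0.2
    between_line_rt_offset_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.peak_sigma < 2 * self.dt:
            raise ValueError("peak_sigma must be at least 2*dt")
        if min(self.within_line_rt_cv_pct, self.area_cv_pct,
               self.between_line_rt_offset_pct) < 0:
            raise ValueError("CVs and offsets must be non-negative")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)


@dataclasses.dataclass(frozen=True)
class LineGenotype:
    """Per-locus subunit complement of one wheat line.

    ``het_*`` sets describe the second allele of a heterozygous line; its
    subunits are rendered at half area. ``area_scale`` multiplies peak
    areas per subunit (default: 2x for 1Bx7OE).
    """

    line_id: str
    glu_a1: frozenset = frozenset()
    glu_b1: frozenset = frozenset()
    glu_d1: frozenset = frozenset()
    het_a1: frozenset | None = None
    het_b1: frozenset | None = None
    het_d1: frozenset | None = None
    area_scale: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_AREA_SCALE)
    )

    @property
    def subunits(self) -> frozenset:
        return self.glu_a1 | self.glu_b1 | self.glu_d1

    @property
    def het_subunits(self) -> frozenset:
        out: set = set()
        for s in (self.het_a1, self.het_b1, self.het_d1):
            if s:
                out |= s
        return frozenset(out)

    @property
    def all_subunits(self) -> frozenset:
        return self.subunits | self.het_subunits

    @property
    def is_heterozygous(self) -> bool:
        return bool(self.het_subunits)

    def locus_subunits(self, locus: str) -> frozenset:
        return {"Glu-A1": self.glu_a1,
                "Glu-B1": self.glu_b1,
                "Glu-D1": self.glu_d1}[locus]


def make_genotype(line_id: str, a1: Iterable[str] = (), b1: Iterable[str] = (),
                  d1: Iterable[str] = (), **kwargs) -> LineGenotype:
    return LineGenotype(line_id, frozenset(a1), frozenset(b1), frozenset(d1),
                        **kwargs)


#: genotypes of the 16 standard cultivars used as external standards
STANDARD_CULTIVARS: dict[str, LineGenotype] = {
    name: make_genotype(name, a1, b1, d1)
    for name, a1, b1, d1 in [
        ("Anbaek", (), ("1Bx7", "1By9"), ("1Dx2", "1Dy12")),
        ("Baekjoong", ("1Ax2*",), ("1Bx13", "1By16"), ("1Dx2.2", "1Dy12")),
        ("Brimstone", (), ("1Bx6", "1By8*"), ("1Dx2", "1Dy12")),
        ("Cheyenne", ("1Ax2*",), ("1Bx7", "1By9"), ("1Dx5", "1Dy10")),
        ("Chinese Spring", (), ("1Bx7", "1By8"), ("1Dx2", "1Dy12")),
        ("Clement", (), ("1Bx6", "1By8*"), ("1Dx2", "1Dy12")),
        ("Dajoong", ("1Ax2*",), ("1Bx13", "1By16"), ("1Dx2.2", "1Dy12")),
        ("Glenlea", ("1Ax2*",), ("1Bx7OE", "1By8*"), ("1Dx5", "1Dy10")),
        ("Gobun", (), ("1Bx7", "1By9"), ("1Dx2", "1Dy12")),
        ("Hanno", ("1Ax1",), ("1Bx14", "1By15"), ("1Dx5", "1Dy10")),
        ("Imbros", ("1Ax1",), ("1Bx14", "1By15"), ("1Dx2", "1Dy12")),
        ("Insignia", ("1Ax1",), ("1Bx20x", "1By20y"), ("1Dx5", "1Dy10")),
        ("IT166460", ("1Ax1",), ("1Bx7OE", "1By8*"), ("1Dx2", "1Dy12")),
        ("Joongmo 2008", (), ("1Bx17", "1By18"), ("1Dx5", "1Dy10")),
        ("Manital", ("1Ax2*",), ("1Bx17", "1By18"), ("1Dx2", "1Dy12")),
        ("Nanbu-komugi", ("1Ax1",), ("1Bx7", "1By8"), ("1Dx4", "1Dy12")),
    ]
}


@dataclasses.dataclass(frozen=True)
class AuxiliaryEvidence:
    """Symbolic auxiliary-assay record for one line.

    ``gel_confirmed`` holds subunit identities attested by SDS-PAGE band
    mobility; ``pcr_7oe`` is the tri-state junction-marker result for the
    1Bx7 duplication.
    """

    gel_confirmed: frozenset = frozenset()
    pcr_7oe: str = PCR_UNTESTED

    def __post_init__(self) -> None:
        if self.pcr_7oe not in (PCR_POSITIVE, PCR_NEGATIVE, PCR_UNTESTED):
            raise ValueError(f"bad PCR state {self.pcr_7oe!r}")


def _gaussian(t: np.ndarray, center: float, area: float, sigma: float) -> np.ndarray:
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((t - center) / sigma) ** 2
    )


def _render(genotype: LineGenotype, library: ReferenceLibrary,
            config: SimConfig, rng: np.random.Generator,
            rt_shift_pct: float) -> Chromatogram:
    """One injection. Draw order per replicate: RT jitters for all rendered
    subunits in library order (primary allele first, then heterozygous
    second allele), then area factors in the same order, then the noise
    vector."""
    for name in genotype.all_subunits:
        if name not in library:
            raise UnknownSubunitError(name)
    primary = [n for n in library.names if n in genotype.subunits]
    second = [n for n in library.names if n in genotype.het_subunits]
    ordered = [(n, 1.0) for n in primary] + [(n, 0.5) for n in second]

    rt_sd = config.within_line_rt_cv_pct / 100.0
    centers = []
    for name, _ in ordered:
        mean = library.get(name).mean_rt
        centers.append(mean * (1.0 + rt_shift_pct / 100.0)
                       + rng.normal(0.0, mean * rt_sd))
    areas = []
    for name, dose in ordered:
        scale = genotype.area_scale.get(name, 1.0)
        areas.append(config.base_area * scale * dose
                     * rng.normal(1.0, config.area_cv_pct / 100.0))

    t = config.grid()
    y = config.baseline_slope * t
    for center, area in zip(centers, areas):
        y = y + _gaussian(t, center, area, config.peak_sigma)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=t.shape)
    return Chromatogram(t, y, line_id=genotype.line_id)


def simulate_chromatogram(
    genotype: LineGenotype,
    library: ReferenceLibrary | None = None,
    config: SimConfig | None = None,
    seed: int | None = None,
    rt_shift_pct: float = 0.0,
) -> Chromatogram:
    """Simulate one injection of one line (deterministic for a fixed seed)."""
    library = library or default_library()
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _render(genotype, library, config, rng, rt_shift_pct)


def simulate_replicates(
    genotype: LineGenotype,
    n: int,
    library: ReferenceLibrary | None = None,
    config: SimConfig | None = None,
    seed: int | None = None,
    rt_shift_pct: float = 0.0,
) -> list[Chromatogram]:
    """Simulate ``n >= 2`` technical replicates from one RNG stream."""
    if n < 2:
        raise ValueError("need at least 2 replicates")
    library = library or default_library()
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [_render(genotype, library, config, rng, rt_shift_pct)
            for _ in range(n)]


def simulate_auxiliary_evidence(
    genotype: LineGenotype,
    library: ReferenceLibrary | None = None,
) -> AuxiliaryEvidence:
    """Auxiliary assays implied by the (true) genotype.

    SDS-PAGE confirms exactly those carried subunits that belong to a
    gel-resolved ambiguity group; the 1Bx7OE junction-marker PCR is run
    (and positive) when the line carries 1Bx7OE, run and negative when it
    carries plain 1Bx7, and untested otherwise.
    """
    library = library or default_library()
    carried = genotype.all_subunits
    gel = carried & library.gel_confirmable
    if "1Bx7OE" in carried:
        pcr = PCR_POSITIVE
    elif "1Bx7" in carried:
        pcr = PCR_NEGATIVE
    else:
        pcr = PCR_UNTESTED
    return AuxiliaryEvidence(gel_confirmed=frozenset(gel), pcr_7oe=pcr)


# ---------------------------------------------------------------------------
# cohorts


class CohortSpecError(ValueError):
    pass


@dataclasses.dataclass
class CohortSpec:
    """Cohort description: either explicit genotypes, or per-locus allele
    counts (subunit-set -> line count) whose per-locus totals must agree."""

    allele_counts: Mapping[str, Mapping[frozenset, int]] | None = None
    genotypes: Sequence[LineGenotype] | None = None

    def __post_init__(self) -> None:
        if (self.allele_counts is None) == (self.genotypes is None):
            raise CohortSpecError(
                "specify exactly one of allele_counts or genotypes"
            )
        if self.allele_counts is not None:
            totals = {locus: sum(self.allele_counts.get(locus, {}).values())
                      for locus in LOCI}
            if len(set(totals.values())) != 1:
                raise CohortSpecError(
                    f"per-locus counts must sum to the same cohort size: {totals}"
                )

    @property
    def n_lines(self) -> int:
        if self.genotypes is not None:
            return len(self.genotypes)
        return sum(next(iter(self.allele_counts.values())).values())

    @classmethod
    def from_reference_counts(cls, library: ReferenceLibrary | None = None) -> "CohortSpec":
        """Cohort spec matching the allele catalog's reference count column
        (the 1787-line germplasm survey)."""
        library = library or default_library()
        counts: dict[str, dict[frozenset, int]] = {locus: {} for locus in LOCI}
        for (locus, subs), n in library.allele_map.reference_counts.items():
            counts[locus][subs] = n
        return cls(allele_counts=counts)


def cohort_genotypes(spec: CohortSpec, seed: int = 0) -> list[LineGenotype]:
    """Materialize genotypes with exactly the requested per-allele counts.

    Per-locus allele lists are expanded to line length, independently
    permuted under a fixed seed-derived permutation and zipped, so the
    marginal counts equal the spec exactly while locus combinations are
    (pseudo)randomly paired.
    """
    if spec.genotypes is not None:
        return list(spec.genotypes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7EA]))
    n = spec.n_lines
    columns: dict[str, list[frozenset]] = {}
    for locus in LOCI:
        expanded: list[frozenset] = []
        for subs, count in sorted(spec.allele_counts.get(locus, {}).items(),
                                  key=lambda kv: sorted(kv[0])):
            expanded.extend([subs] * count)
        if len(expanded) != n:
            raise CohortSpecError(f"{locus}: counts sum to {len(expanded)} != {n}")
        order = rng.permutation(n)
        columns[locus] = [expanded[i] for i in order]
    width = len(str(n))
    return [
        LineGenotype(
            line_id=f"L{i + 1:0{width}d}",
            glu_a1=columns["Glu-A1"][i],
            glu_b1=columns["Glu-B1"][i],
            glu_d1=columns["Glu-D1"][i],
        )
        for i in range(n)
    ]


@dataclasses.dataclass
class SimulatedLine:
    genotype: LineGenotype
    chromatogram: Chromatogram
    evidence: AuxiliaryEvidence


def simulate_cohort(
    spec: CohortSpec,
    library: ReferenceLibrary | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
) -> Iterator[SimulatedLine]:
    """Lazily yield one simulated injection plus evidence per cohort line.

    Each line gets an independent child RNG stream derived from ``seed``,
    so results do not depend on how much of the iterator is consumed.
    If ``config.between_line_rt_offset_pct`` is positive, each line draws a
    uniform RT shift in ±that bound (percent of mean RT) shared by all its
    subunits.
    """
    library = library or default_library()
    config = config or SimConfig()
    genotypes = cohort_genotypes(spec, seed=seed)
    children = np.random.SeedSequence([seed, 0x5EED]).spawn(len(genotypes))
    for genotype, child in zip(genotypes, children):
        rng = np.random.default_rng(child)
        shift = 0.0
        bound = config.between_line_rt_offset_pct
        if bound > 0:
            shift = rng.uniform(-bound, bound)
        chrom = _render(genotype, library, config, rng, shift)
        yield SimulatedLine(genotype, chrom,
                            simulate_auxiliary_evidence(genotype, library))


def truth_table(genotypes: Sequence[LineGenotype],
                library: ReferenceLibrary | None = None) -> pd.DataFrame:
    """Per-line truth table (subunit sets and catalog symbols) for scoring."""
    library = library or default_library()

    def fmt(subs: frozenset) -> str:
        return ";".join(n for n in library.names if n in subs)

    rows = []
    for g in genotypes:
        row = {"line_id": g.line_id}
        for locus, subs in [("Glu-A1", g.glu_a1), ("Glu-B1", g.glu_b1),
                            ("Glu-D1", g.glu_d1)]:
            key = locus.split("-")[1].lower()  # a1 / b1 / d1
            rec = library.lookup_allele_symbol(locus, subs)
            row[f"{key}_subunits"] = fmt(subs)
            row[f"{key}_symbol"] = rec.symbol
            row[f"{key}_display"] = rec.display if rec.in_catalog else ""
        row["heterozygous"] = g.is_heterozygous
        rows.append(row)
    return pd.DataFrame(rows)
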