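"""Founder haplotypes, observed haplotypes, and the parsimony mosaic classifier.

An observed haplotype in a population founded by a handful of animals is
modelled as a mosaic of the founding haplotypes: runs of consecutive markers
copied from one founder, separated by crossover switches.  Because
microsatellite alleles are widely shared between founders, the observed
allele vector usually constrains the mosaic only loosely; the classifier
therefore reports the *minimum* number of switches needed to explain the
vector (a lower bound on the true crossover history), the founder candidates
for each segment, and the marker interval within which each switch can float.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MarkerPanel",
    "FounderSet",
    "HaplotypeObservation",
    "GenotypeRecord",
    "CompatibilityMatrix",
    "MosaicDecomposition",
    "RecombinationCountVector",
    "PopulationClassification",
    "OrphanPolicy",
    "build_compatibility",
    "min_recombinations",
    "classify_population",
    "flanking_founder_distribution",
    "homogeneity_chi2",
    "naive_phase",
]

_INF = np.iinfo(np.int32).max // 2


class OrphanPolicy(str, Enum):
    """How to treat an allele found in no founder (a putative mutation).

    ``MUTATION``  treat the marker as a wildcard and record it as a mutation
                  (rare alleles in an isolated founded population are most
                  plausibly post-founding mutations);
    ``WILDCARD``  treat the marker as a wildcard silently;
    ``ERROR``     refuse the haplotype.
    """

    MUTATION = "mutation"
    WILDCARD = "wildcard"
    ERROR = "error"


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker map, telomere to centromere."""

    markers: tuple[str, ...]
    positions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError("a marker panel needs at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if self.positions is not None:
            if len(self.positions) != len(self.markers):
                raise ValueError("positions must match markers in length")
            if not all(a < b for a, b in zip(self.positions, self.positions[1:])):
                raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.markers)

    def index(self, marker: str) -> int:
        return self.markers.index(marker)


@dataclass(frozen=True)
class FounderSet:
    """Per-founder compatible allele sets at every panel marker.

    ``alleles[founder][marker]`` is a non-empty frozenset of fragment lengths
    (bp).  Multi-allele cells encode both genuine co-amplified fragments and
    documented intra-founder variants, so compatibility is set membership.
    """

    founders: tuple[str, ...]
    alleles: Mapping[str, Mapping[str, frozenset[int]]]

    def __post_init__(self) -> None:
        if len(self.founders) == 0:
            raise ValueError("need at least one founder")
        for f in self.founders:
            if f not in self.alleles:
                raise ValueError(f"founder {f!r} has no allele table")
            for m, s in self.alleles[f].items():
                if not s:
                    raise ValueError(f"empty allele set for {f}/{m}")
                if any(int(a) <= 0 for a in s):
                    raise ValueError(f"non-positive allele length for {f}/{m}")

    def allele_set(self, founder: str, marker: str) -> frozenset[int]:
        return self.alleles[founder][marker]

    def haplotype_of(self, founder: str, panel: MarkerPanel) -> "HaplotypeObservation":
        """Canonical allele vector of a founder (first listed allele per cell)."""
        return HaplotypeObservation(
            tuple(min(self.alleles[founder][m]) for m in panel.markers)
        )

    def lookup_tables(self, panel: MarkerPanel) -> list[dict[int, np.ndarray]]:
        """Per-marker allele -> boolean founder-mask lookup (classification fast path)."""
        tables: list[dict[int, np.ndarray]] = []
        for m in panel.markers:
            table: dict[int, np.ndarray] = {}
            for j, f in enumerate(self.founders):
                for a in self.alleles[f][m]:
                    mask = table.setdefault(a, np.zeros(len(self.founders), dtype=bool))
                    mask[j] = True
            tables.append(table)
        return tables


@dataclass(frozen=True)
class HaplotypeObservation:
    """A phased haplotype: one allele per panel marker, ``None`` for missing."""

    alleles: tuple[int | None, ...]

    def missing_fraction(self) -> float:
        return sum(a is None for a in self.alleles) / len(self.alleles)


@dataclass(frozen=True)
class GenotypeRecord:
    """Unphased diploid genotype: an unordered allele pair per marker."""

    sample_id: str
    pairs: tuple[tuple[int | None, int | None], ...]


@dataclass(frozen=True)
class CompatibilityMatrix:
    """Marker x founder boolean grid: can this founder carry the observed allele?

    Missing alleles give all-true rows (uninformative); a row that is
    all-false before policy application is flagged as an orphan (the allele
    exists in no founder).
    """

    matrix: np.ndarray  # (n_markers, n_founders) bool
    orphan: np.ndarray  # (n_markers,) bool
    panel: MarkerPanel
    founders: tuple[str, ...]


@dataclass(frozen=True)
class MosaicDecomposition:
    """Most-parsimonious founder mosaic of one haplotype.

    ``segments`` tile the panel as half-open marker-index ranges, each with
    the set of founders that can carry that whole segment in an optimal
    mosaic.  ``breakpoints`` hold, for each of the ``h`` switches, the
    half-open range of gap indices where the crossover may lie (gap ``g``
    separates markers ``g`` and ``g + 1``).
    """

    h: int
    segments: tuple[tuple[tuple[int, int], frozenset[str]], ...]
    breakpoints: tuple[tuple[int, int], ...]
    orphan_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.h != len(self.segments) - 1 or self.h != len(self.breakpoints):
            raise ValueError("segment/breakpoint bookkeeping inconsistent with h")


@dataclass(frozen=True)
class RecombinationCountVector:
    """The recombinant-haplotype spectrum: n_k haplotypes with k switches."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) == 0 or any(c < 0 for c in self.counts):
            raise ValueError("counts must be a non-empty vector of non-negatives")
        if self.n == 0:
            raise ValueError("spectrum must contain at least one haplotype")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def k_max(self) -> int:
        return len(self.counts) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class PopulationClassification:
    """classify_population output: the spectrum plus per-haplotype detail."""

    spectrum: RecombinationCountVector
    decompositions: tuple[MosaicDecomposition, ...]
    distinct_types: Mapping[int, int]  # k -> number of distinct allele vectors


def build_compatibility(
    panel: MarkerPanel, founders: FounderSet, hap: HaplotypeObservation
) -> CompatibilityMatrix:
    """Tabulate which founders can carry each observed allele.

    Missing alleles are uninformative and match every founder; an allele in
    no founder's set flags the marker as an orphan (the row is left all-false
    here — orphan policy is applied downstream).
    """
    if len(hap.alleles) != len(panel):
        raise ValueError(
            f"haplotype has {len(hap.alleles)} alleles for a {len(panel)}-marker panel"
        )
    n_m, n_f = len(panel), len(founders.founders)
    mat = np.zeros((n_m, n_f), dtype=bool)
    for i, (m, a) in enumerate(zip(panel.markers, hap.alleles)):
        if a is None:
            mat[i, :] = True
        else:
            for j, f in enumerate(founders.founders):
                mat[i, j] = a in founders.allele_set(f, m)
    orphan = ~mat.any(axis=1)
    return CompatibilityMatrix(mat, orphan, panel, founders.founders)


def _effective_matrix(
    compat: CompatibilityMatrix, policy: OrphanPolicy
) -> tuple[np.ndarray, tuple[str, ...]]:
    mat = compat.matrix.copy()
    orphans: tuple[str, ...] = ()
    if compat.orphan.any():
        if policy is OrphanPolicy.ERROR:
            bad = [compat.panel.markers[i] for i in np.flatnonzero(compat.orphan)]
            raise ValueError(f"alleles at {bad} match no founder")
        mat[compat.orphan, :] = True
        if policy is OrphanPolicy.MUTATION:
            orphans = tuple(
                compat.panel.markers[i] for i in np.flatnonzero(compat.orphan)
            )
    return mat, orphans


def min_recombinations(
    compat: CompatibilityMatrix,
    policy: OrphanPolicy | str = OrphanPolicy.MUTATION,
) -> MosaicDecomposition:
    """Minimum-switch founder mosaic by dynamic programming over markers.

    ``best[m, f]`` is the fewest switches needed to explain markers ``0..m``
    with founder ``f`` carrying marker ``m``:

        best[m, f] = penalty(m, f) + min(best[m-1, f], 1 + min_g best[m-1, g])

    with an infinite penalty where founder ``f`` cannot carry marker ``m``.
    Segments and floating breakpoint intervals come from the equivalent
    greedy maximal-run segmentation (both attain the same optimum, which the
    test suite cross-checks against exhaustive mosaic enumeration).
    """
    policy = OrphanPolicy(policy)
    mat, orphan_markers = _effective_matrix(compat, policy)
    n_m, n_f = mat.shape

    penalty = np.where(mat, 0, _INF)
    best = penalty[0].copy()
    for m in range(1, n_m):
        best = penalty[m] + np.minimum(best, 1 + best.min())
    h = int(best.min())

    # Greedy maximal segments: extend each run as far as one founder allows.
    segments: list[tuple[tuple[int, int], frozenset[str]]] = []
    bounds: list[tuple[int, int]] = []
    start = 0
    while start < n_m:
        cover = mat[start].copy()
        end = start + 1
        while end < n_m and (cover & mat[end]).any():
            cover &= mat[end]
            end += 1
        cands = frozenset(compat.founders[j] for j in np.flatnonzero(cover))
        segments.append(((start, end), cands))
        bounds.append((start, end))
        start = end
    if len(segments) - 1 != h:  # pragma: no cover - both paths are optimal
        raise AssertionError("greedy segmentation disagrees with DP optimum")

    # Breakpoint intervals: the switch between segments i and i+1 may lie at
    # any gap g such that some left candidate covers [s_i, g] and some right
    # candidate covers [g+1, e_{i+1}).  Left candidates reach e_i - 1 by
    # maximality; right candidates are walked leftwards.
    breakpoints: list[tuple[int, int]] = []
    for i in range(h):
        (s_i, e_i), _ = segments[i]
        (s_r, e_r), cands_r = segments[i + 1]
        b_min = s_r
        for f in cands_r:
            j = compat.founders.index(f)
            b = s_r
            while b - 1 > s_i and mat[b - 1, j]:
                b -= 1
            b_min = min(b_min, b)
        breakpoints.append((b_min - 1, e_i))
    return MosaicDecomposition(
        h=h,
        segments=tuple(segments),
        breakpoints=tuple(breakpoints),
        orphan_markers=orphan_markers,
    )


def _compat_from_lookup(
    alleles: Sequence[int | None],
    tables: list[dict[int, np.ndarray]],
    panel: MarkerPanel,
    founders: tuple[str, ...],
) -> CompatibilityMatrix:
    n_f = len(founders)
    mat = np.zeros((len(alleles), n_f), dtype=bool)
    for i, a in enumerate(alleles):
        if a is None:
            mat[i, :] = True
        else:
            mask = tables[i].get(int(a))
            if mask is not None:
                mat[i] = mask
    orphan = ~mat.any(axis=1)
    return CompatibilityMatrix(mat, orphan, panel, founders)


def classify_population(
    panel: MarkerPanel,
    founders: FounderSet,
    haplotypes: Iterable[HaplotypeObservation],
    policy: OrphanPolicy | str = OrphanPolicy.MUTATION,
    max_missing: float = 0.5,
) -> PopulationClassification:
    """Classify every phased haplotype and tally the recombination spectrum.

    Haplotypes with more than ``max_missing`` missing markers are rejected
    (too little signal to anchor a mosaic).  Identical allele vectors are
    decomposed once and the result reused, which also yields the
    distinct-type tally per recombination class.
    """
    haps = list(haplotypes)
    if not haps:
        raise ValueError("no haplotypes to classify")
    for hp in haps:
        if len(hp.alleles) != len(panel):
            raise ValueError("haplotype length does not match panel")
        if hp.missing_fraction() > max_missing:
            raise ValueError(
                f"haplotype with {hp.missing_fraction():.0%} missing markers "
                f"exceeds the {max_missing:.0%} threshold"
            )
    tables = founders.lookup_tables(panel)
    cache: dict[tuple[int | None, ...], MosaicDecomposition] = {}
    decomps: list[MosaicDecomposition] = []
    for hp in haps:
        key = hp.alleles
        dec = cache.get(key)
        if dec is None:
            compat = _compat_from_lookup(key, tables, panel, founders.founders)
            dec = min_recombinations(compat, policy)
            cache[key] = dec
        decomps.append(dec)
    k_max = max(d.h for d in decomps)
    counts = [0] * (k_max + 1)
    for d in decomps:
        counts[d.h] += 1
    types = Counter(dec.h for dec in cache.values())
    return PopulationClassification(
        spectrum=RecombinationCountVector(tuple(counts)),
        decompositions=tuple(decomps),
        distinct_types=dict(sorted(types.items())),
    )


def flanking_founder_distribution(
    decompositions: Sequence[MosaicDecomposition],
    part: str,
    founders: Sequence[str],
    tie_policy: str = "fractional",
) -> np.ndarray:
    """Founder frequency vector at one part of recombinant mosaics.

    ``part`` is ``"telomeric"`` (first segment), ``"centromeric"`` (last) or
    ``"central"`` (middle segment of double recombinants).  Where several
    founders can carry the segment, ``"fractional"`` splits the haplotype's
    unit mass equally among them; ``"drop"`` discards the ambiguous
    haplotype.  Returns counts aligned to ``founders`` order; the total is
    the number of usable decompositions.
    """
    if part not in {"telomeric", "central", "centromeric"}:
        raise ValueError(f"unknown part {part!r}")
    if tie_policy not in {"fractional", "drop"}:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    out = np.zeros(len(founders), dtype=float)
    index = {f: i for i, f in enumerate(founders)}
    for dec in decompositions:
        if part == "central":
            if dec.h != 2:
                raise ValueError("central part is defined for double recombinants only")
            cands = dec.segments[1][1]
        else:
            if dec.h < 1:
                raise ValueError("flanking parts are defined for recombinants only")
            cands = dec.segments[0][1] if part == "telomeric" else dec.segments[-1][1]
        if len(cands) == 1:
            out[index[next(iter(cands))]] += 1.0
        elif tie_policy == "fractional":
            w = 1.0 / len(cands)
            for f in cands:
                out[index[f]] += w
    return out


def homogeneity_chi2(
    observed: Sequence[float], reference: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-square of observed counts against reference frequencies.

    Used to compare the founder distribution at recombinant flanks with the
    overall founding-haplotype distribution.  df = categories - 1.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("observed and reference must have the same length")
    if not np.isclose(ref.sum(), 1.0):
        raise ValueError("reference frequencies must sum to 1")
    if np.any((ref == 0) & (obs > 0)):
        raise ValueError("observed count in a zero-frequency reference category")
    keep = ref > 0
    expected = obs.sum() * ref
    stat, p = stats.chisquare(obs[keep], expected[keep])
    return float(stat), int(keep.sum() - 1), float(p)


def naive_phase(
    panel: MarkerPanel, founders: FounderSet, record: GenotypeRecord
) -> tuple[HaplotypeObservation, HaplotypeObservation] | None:
    """Phase a genotype when one haplotype is an intact founder.

    For each founder, try to pick one allele per marker from the genotype
    that the founder can carry; the leftovers form the partner haplotype.
    Returns ``None`` when no founder anchors the genotype — statistical
    phasing is deliberately out of scope, this exists for simulator
    round-trips where most haplotypes are intact.
    """
    if len(record.pairs) != len(panel):
        raise ValueError("genotype length does not match panel")
    for f in founders.founders:
        anchored: list[int | None] = []
        partner: list[int | None] = []
        ok = True
        for m, (a, b) in zip(panel.markers, record.pairs):
            fset = founders.allele_set(f, m)
            if a is None and b is None:
                anchored.append(None)
                partner.append(None)
            elif a is not None and a in fset:
                anchored.append(a)
                partner.append(b)
            elif b is not None and b in fset:
                anchored.append(b)
                partner.append(a)
            else:
                ok = False
                break
        if ok:
            return (
                HaplotypeObservation(tuple(anchored)),
                HaplotypeObservation(tuple(partner)),
            )
    return None
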