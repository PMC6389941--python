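"""Quartet site-pattern classification and regional substitution tallies.

For an aligned column over the four roles (species A paralogue a, A-b,
species B paralogue a, B-b) the variable patterns of interest are:

* ``orthologue_conserved`` — letters (P, Q, P, Q) with P != Q: each
  paralogue keeps its own state across species, the signature expected
  when the duplication predates speciation and no homogenization has
  occurred.
* ``paralogue_conserved`` — letters (P, P, Q, Q) with P != Q: the two
  paralogues agree within each species but differ between species, the
  signature of post-speciation gene conversion (or improbably parallel
  mutation).

Everything else is ``invariant``, ``gapped`` (any ``-``), or ``other``
(singletons, triallelic columns, ambiguity codes).  Coding substitutions
are additionally classified synonymous/non-synonymous site-by-site.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .seqio import GAP, QuartetAlignment, RegionMap

__all__ = [
    "SitePattern",
    "SitePatternTrack",
    "PatternTally",
    "SubstitutionClass",
    "PATTERN_LABELS",
    "classify_column",
    "classify_alignment",
    "tally_by_region",
    "pairwise_identity",
    "classify_coding_substitutions",
]

PATTERN_LABELS = (
    "invariant",
    "orthologue_conserved",
    "paralogue_conserved",
    "other",
    "gapped",
)

_VALID = set("ACGTN-")
_BASES = set("ACGT")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass(frozen=True)
class SitePattern:
    label: str
    alleles: tuple[str, str, str, str]


@dataclass
class SitePatternTrack:
    """Per-column pattern labels aligned to a :class:`QuartetAlignment`."""

    patterns: list[SitePattern]
    cds_position: list[int | None]
    region_kind: list[str]
    locus_position: list[int | None] | None = None

    def __post_init__(self) -> None:
        if not (len(self.patterns) == len(self.cds_position) == len(self.region_kind)):
            raise ValueError("track annotation lengths differ")

    def __len__(self) -> int:
        return len(self.patterns)

    def label_counts(self) -> Counter:
        return Counter(p.label for p in self.patterns)

    def position(self, j: int) -> int:
        """Best available 1-based coordinate of column j (locus, else column index)."""
        if self.locus_position is not None and self.locus_position[j] is not None:
            return self.locus_position[j]  # type: ignore[return-value]
        return j + 1


@dataclass
class PatternTally:
    """Counts of each pattern label per region, with indel columns reported separately."""

    counts: dict[str, Counter] = field(default_factory=dict)
    indels: dict[str, int] = field(default_factory=dict)

    def region_total(self, region: str) -> int:
        return sum(self.counts.get(region, Counter()).values()) + self.indels.get(region, 0)

    def total(self, label: str) -> int:
        return sum(c.get(label, 0) for c in self.counts.values())

    def total_indels(self) -> int:
        return sum(self.indels.values())


def classify_column(letters: tuple[str, str, str, str]) -> SitePattern:
    """Classify one aligned column given letters in fixed role order.

    Role order is (spA-para-a, spA-para-b, spB-para-a, spB-para-b).  Any
    gap makes the column ``gapped``; any N (or other ambiguity, which is
    rejected upstream) makes it ``other`` rather than guessing a state.
    """
    letters = tuple(x.upper() for x in letters)  # type: ignore[assignment]
    bad = set(letters) - _VALID
    if bad:
        raise ValueError(f"letters outside A/C/G/T/N/-: {sorted(bad)!r}")
    if GAP in letters:
        return SitePattern("gapped", letters)
    if "N" in letters:
        return SitePattern("other", letters)
    a1, b1, a2, b2 = letters
    if len(set(letters)) == 1:
        return SitePattern("invariant", letters)
    if a1 == a2 and b1 == b2 and a1 != b1:
        return SitePattern("orthologue_conserved", letters)
    if a1 == b1 and a2 == b2 and a1 != a2:
        return SitePattern("paralogue_conserved", letters)
    return SitePattern("other", letters)


def classify_alignment(aln: QuartetAlignment) -> SitePatternTrack:
    """Label every column of a quartet alignment."""
    patterns = [classify_column(aln.column(j)) for j in range(len(aln))]
    return SitePatternTrack(
        patterns=patterns,
        cds_position=list(aln.cds_position),
        region_kind=list(aln.region_kind),
        locus_position=list(aln.locus_position) if aln.locus_position else None,
    )


def tally_by_region(track: SitePatternTrack, regions: RegionMap | None = None) -> PatternTally:
    """Tally pattern labels per region.

    When ``regions`` is given, columns are grouped by the region *name*
    covering their locus coordinate (reproducing the per-exon layout of
    the substitution tables); otherwise the track's own region kinds are
    used.  Gapped columns are counted in the separate inserted/deleted
    row, never among substitutions.  Columns with no annotation fall
    under ``"unassigned"`` with a warning.
    """
    tally = PatternTally()
    unassigned = 0
    for j, pat in enumerate(track.patterns):
        if regions is not None and track.locus_position is not None and track.locus_position[j] is not None:
            region = regions.name_at(track.locus_position[j])  # type: ignore[arg-type]
        else:
            region = track.region_kind[j]
        if region == "unassigned":
            unassigned += 1
        if pat.label == "gapped":
            tally.indels[region] = tally.indels.get(region, 0) + 1
            continue
        tally.counts.setdefault(region, Counter())[pat.label] += 1
    if unassigned:
        warnings.warn(f"{unassigned} column(s) without region annotation counted as 'unassigned'")
    return tally


def pairwise_identity(seq_x: str, seq_y: str) -> tuple[int, int, float]:
    """Identity between two equal-length (possibly gapped) strings.

    Returns ``(identical, compared, percent)`` where columns containing a
    gap in either string are excluded from both numerator and
    denominator.  Percent is rounded to one decimal, the reporting
    convention behind figures such as 1,064/1,071 = 99.3%.
    """
    if len(seq_x) != len(seq_y):
        raise ValueError(f"length mismatch: {len(seq_x)} vs {len(seq_y)}")
    identical = compared = 0
    for cx, cy in zip(seq_x.upper(), seq_y.upper()):
        if cx == GAP or cy == GAP:
            continue
        compared += 1
        if cx == cy:
            identical += 1
    percent = round(100.0 * identical / compared, 1) if compared else 0.0
    return identical, compared, percent


@dataclass(frozen=True)
class SubstitutionClass:
    cds_position: int  # 1-based from translation-initiation site
    codon_number: int  # 1-based
    kind: str  # "synonymous" | "non_synonymous"
    aa_change: str | None  # e.g. "Y128N", None if synonymous
    multi_hit: bool = False  # codon carried >1 differing site


def classify_coding_substitutions(
    cds_x: str, cds_y: str, regions: RegionMap | None = None
) -> tuple[list[SubstitutionClass], dict[str, Counter]]:
    """Classify every differing CDS site as synonymous or non-synonymous.

    Both inputs are gap-free CDSs of equal length divisible by 3,
    starting at the translation-initiation site.  Each differing site is
    judged independently by substituting that site alone into the partner
    codon context, so a codon with two hits contributes two site classes
    (flagged ``multi_hit``).  Returns the site classes plus per-exon
    synonymous/non-synonymous counters when a region map is supplied
    (keyed by exon name, CDS coordinates mapped through the map's exons).
    """
    cds_x, cds_y = cds_x.upper(), cds_y.upper()
    if len(cds_x) != len(cds_y):
        raise ValueError("CDS lengths differ")
    if len(cds_x) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_x)} not a multiple of 3")
    if GAP in cds_x or GAP in cds_y:
        raise ValueError("CDS inputs must be gap-free")

    exon_of_cds_pos: dict[int, str] = {}
    if regions is not None:
        offset = 0
        for exon in regions.exons():
            for k in range(len(exon)):
                exon_of_cds_pos[offset + k + 1] = exon.name
            offset += len(exon)

    classes: list[SubstitutionClass] = []
    per_exon: dict[str, Counter] = {}
    n_codons = len(cds_x) // 3
    for c in range(n_codons):
        codon_x = cds_x[3 * c : 3 * c + 3]
        codon_y = cds_y[3 * c : 3 * c + 3]
        if codon_x == codon_y:
            continue
        aa_x, aa_y = _translate_codon(codon_x), _translate_codon(codon_y)
        if "*" in (aa_x, aa_y) and c < n_codons - 1:
            warnings.warn(f"internal stop codon at codon {c + 1}; classification continues")
        diff_sites = [k for k in range(3) if codon_x[k] != codon_y[k]]
        multi = len(diff_sites) > 1
        for k in diff_sites:
            # judge this site alone in the partner codon context
            mutated = codon_y[:k] + codon_x[k] + codon_y[k + 1 :]
            aa_mut = _translate_codon(mutated)
            pos = 3 * c + k + 1
            if aa_mut == aa_y:
                cls = SubstitutionClass(pos, c + 1, "synonymous", None, multi)
            else:
                cls = SubstitutionClass(pos, c + 1, "non_synonymous", f"{aa_y}{c + 1}{aa_mut}", multi)
            classes.append(cls)
            exon = exon_of_cds_pos.get(pos, "unassigned")
            per_exon.setdefault(exon, Counter())[cls.kind] += 1
    return classes, per_exon
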