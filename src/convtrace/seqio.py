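"""Sequence and region-map I/O for duplicate-locus quartets.

A *locus quartet* is the central input of this package: the two tandem
paralogues (``a`` and ``b``) of a gene sampled in two sister species, four
homologous sequences in all.  This module reads and writes the sequences
(FASTA) and their annotation (a tab-separated region map), builds the
four-way alignment the pattern classifier consumes, and maps residue
indices between homologous proteins.

Coordinate convention
---------------------
All coordinates are 1-based and inclusive, and CDS positions count from
the A of the ATG start codon.  The region-map file is "BED-like" only in
shape (one region per row); it is **not** BED — BED is 0-based
half-open, this format is 1-based inclusive.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "Region",
    "RegionMap",
    "PairwiseAlignment",
    "LocusQuartet",
    "QuartetAlignment",
    "ROLE_ORDER",
    "read_fasta",
    "write_fasta",
    "read_region_map",
    "write_region_map",
    "global_align",
    "build_quartet_alignment",
    "map_residue_index",
]

DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZ*")
GAP = "-"

REGION_KINDS = ("exon", "intron", "utr5", "utr3", "intergenic")

#: Fixed role order of quartet columns: species A paralogue a, species A
#: paralogue b, species B paralogue a, species B paralogue b.
ROLE_ORDER = (("A", "a"), ("A", "b"), ("B", "a"), ("B", "b"))


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; names the offending line."""


@dataclass
class SequenceRecord:
    """A named sequence with its quartet role labels.

    ``species`` and ``paralogue`` are free-text role labels (e.g.
    ``"latipes"``/``"sakaizumii"`` and ``"a"``/``"b"``); they only need to
    be consistent within one quartet.
    """

    id: str
    residues: str
    species: str = ""
    paralogue: str = ""
    alphabet: Literal["dna", "protein"] = "dna"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues.upper()) - allowed - {GAP}
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC symbol(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Region:
    name: str
    kind: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"region {self.name!r}: bad interval {self.start}..{self.end}")
        if self.kind == "exon" and self.frame_offset not in (0, 1, 2):
            raise ValueError(f"region {self.name!r}: frame_offset must be 0-2")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionMap:
    """Sorted, non-overlapping annotation of a locus.

    The exon regions, concatenated 5'→3', must form a CDS whose length is
    a multiple of 3 (stop codon excluded, matching the convention in
    which the medaka *LWS* CDS is 1,071 bp over six exons).
    """

    regions: list[Region]

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: r.start)
        prev_end = 0
        for r in self.regions:
            if r.start <= prev_end:
                raise ValueError(f"region {r.name!r} overlaps previous region")
            prev_end = r.end
        if self.exons() and self.cds_length() % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length()} is not a multiple of 3"
            )

    def exons(self) -> list[Region]:
        return [r for r in self.regions if r.kind == "exon"]

    def cds_length(self) -> int:
        return sum(len(r) for r in self.exons())

    def exon_lengths(self) -> list[int]:
        return [len(r) for r in self.exons()]

    def kind_at(self, pos: int) -> str:
        """Region kind covering 1-based locus position ``pos`` ("unassigned" if none)."""
        for r in self.regions:
            if r.start <= pos <= r.end:
                return r.kind
        return "unassigned"

    def name_at(self, pos: int) -> str:
        for r in self.regions:
            if r.start <= pos <= r.end:
                return r.name
        return "unassigned"

    def cds_positions(self) -> list[int]:
        """Locus positions of CDS sites in 5'→3' order (CDS position k is element k-1)."""
        out: list[int] = []
        for r in self.exons():
            out.extend(range(r.start, r.end + 1))
        return out

    @property
    def span(self) -> int:
        return self.regions[-1].end if self.regions else 0


def read_fasta(path: str | Path, alphabet: Literal["dna", "protein"] = "dna") -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    Malformed input raises :class:`FastaParseError` naming the first
    offending line; an empty file is an error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise FastaParseError(f"{path}: empty FASTA file")
    allowed = (DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET) | {GAP}
    seen_header = False
    for i, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            seen_header = True
            continue
        if not seen_header:
            raise FastaParseError(f"{path}: line {i}: sequence data before first '>' header")
        bad = set(s.upper()) - allowed
        if bad:
            raise FastaParseError(
                f"{path}: line {i}: non-IUPAC symbol(s) {sorted(bad)!r}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        species, paralogue = "", ""
        # optional role annotation: ">id species=latipes paralogue=a"
        for token in rec.description.split()[1:]:
            if token.startswith("species="):
                species = token.split("=", 1)[1]
            elif token.startswith("paralogue="):
                paralogue = token.split("=", 1)[1]
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                species=species,
                paralogue=paralogue,
                alphabet=alphabet,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        desc = ""
        if r.species or r.paralogue:
            desc = f"species={r.species} paralogue={r.paralogue}"
        bio.append(_BioSeqRecord(Seq(r.residues), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


REGION_COLUMNS = ("name", "kind", "start", "end", "frame_offset")


def read_region_map(path: str | Path) -> RegionMap:
    """Read a tab-separated region table (name, kind, start, end[, frame_offset]).

    Coordinates are 1-based inclusive.  Lines starting with ``#`` are
    comments; a header row repeating the column names is tolerated.
    """
    path = Path(path)
    regions = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t")
        if parts[0] == "name":
            continue
        if len(parts) < 4:
            raise ValueError(f"{path}: line {i}: expected >=4 tab-separated columns")
        frame = int(parts[4]) if len(parts) > 4 and parts[4] != "" else 0
        regions.append(Region(parts[0], parts[1], int(parts[2]), int(parts[3]), frame))
    return RegionMap(regions)


def write_region_map(rmap: RegionMap, path: str | Path) -> None:
    lines = ["#" + "\t".join(REGION_COLUMNS)]
    for r in rmap.regions:
        lines.append(f"{r.name}\t{r.kind}\t{r.start}\t{r.end}\t{r.frame_offset}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two equal-length gapped strings.

    ``map_a_to_b[i]`` gives, for 1-based position ``i`` of sequence A, the
    aligned 1-based position in B or ``None`` if A's residue sits against
    a gap (and symmetrically for ``map_b_to_a``).
    """

    aligned_a: str
    aligned_b: str
    score: float
    map_a_to_b: dict[int, int | None] = field(repr=False, default_factory=dict)
    map_b_to_a: dict[int, int | None] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if not self.map_a_to_b:
            self._build_maps()

    def _build_maps(self) -> None:
        pa = pb = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != GAP:
                pa += 1
            if cb != GAP:
                pb += 1
            if ca != GAP:
                self.map_a_to_b[pa] = pb if cb != GAP else None
            if cb != GAP:
                self.map_b_to_a[pb] = pa if ca != GAP else None

    def __len__(self) -> int:
        return len(self.aligned_a)


def _make_aligner(
    alphabet: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # Biopython's open_gap_score is charged for the first gap residue.
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment.

    Nucleotide scoring defaults to match +1 / mismatch -1 / gap open -4 /
    extend -1; protein pairs use BLOSUM62 with the given gap penalties
    (use e.g. -11/-1 for typical protein alignments).  Ties between
    co-optimal paths are broken deterministically (the aligner's first
    reported optimum).
    """
    if a.alphabet != b.alphabet:
        raise ValueError("cannot align sequences over different alphabets")
    if not a.ungapped or not b.ungapped:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(a.alphabet, match, mismatch, gap_open, gap_extend)
    alignments = aligner.align(a.ungapped, b.ungapped)
    best = alignments[0]
    sa, sb = str(best[0]), str(best[1])
    return PairwiseAlignment(aligned_a=sa, aligned_b=sb, score=float(best.score))


@dataclass
class LocusQuartet:
    """The four homologous locus sequences keyed by (species, paralogue) role.

    ``records`` maps abstract role keys ``("A"|"B", "a"|"b")`` to records;
    species label "A"/"B" order is fixed by the caller (conventionally the
    *latipes*-like species first).  ``region_maps`` holds one RegionMap
    per role.
    """

    records: dict[tuple[str, str], SequenceRecord]
    region_maps: dict[tuple[str, str], RegionMap]

    def __post_init__(self) -> None:
        missing = [k for k in ROLE_ORDER if k not in self.records]
        if missing or len(self.records) != 4:
            raise ValueError(
                f"quartet must contain exactly the four roles {ROLE_ORDER}; missing {missing}"
            )
        for k in ROLE_ORDER:
            if k not in self.region_maps:
                raise ValueError(f"missing region map for role {k}")

    def ordered_records(self) -> list[SequenceRecord]:
        return [self.records[k] for k in ROLE_ORDER]


@dataclass
class QuartetAlignment:
    """Four equal-length gapped strings in fixed role order plus column annotation.

    ``cds_position[j]`` is the 1-based position from the translation
    initiation site for coding columns (``None`` elsewhere);
    ``region_kind[j]`` is the annotated region kind of column ``j``
    (0-based column index), taken from the first role with a residue in
    that column.
    """

    rows: tuple[str, str, str, str]
    cds_position: list[int | None]
    region_kind: list[str]
    locus_position: list[int | None] | None = None

    def __post_init__(self) -> None:
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("quartet alignment rows differ in length")
        if len(self.cds_position) != n or len(self.region_kind) != n:
            raise ValueError("column annotation length mismatch")
        coding = [p for p in self.cds_position if p is not None]
        if any(b <= a for a, b in zip(coding, coding[1:])):
            raise ValueError("CDS positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> tuple[str, str, str, str]:
        return tuple(r[j] for r in self.rows)  # type: ignore[return-value]


def _extract_cds(rec: SequenceRecord, rmap: RegionMap) -> str:
    return "".join(rec.residues[p - 1] for p in rmap.cds_positions())


def build_quartet_alignment(
    quartet: LocusQuartet, anchor: Literal["cds_only", "full_locus"] = "cds_only"
) -> QuartetAlignment:
    """Build the four-way alignment of a locus quartet.

    ``cds_only`` concatenates each sequence's exons and stacks them
    column-by-column without gaps (all four CDS lengths must be equal, as
    they are for the medaka *LWS* quartet at 1,071 bp).  ``full_locus``
    runs a progressive multiple alignment (MAFFT) over the complete locus
    sequences.  Column annotations come from the species-A paralogue-a
    region map.
    """
    recs = quartet.ordered_records()
    ref_map = quartet.region_maps[ROLE_ORDER[0]]
    if anchor == "cds_only":
        cds = [_extract_cds(r, quartet.region_maps[k]) for k, r in zip(ROLE_ORDER, recs)]
        lengths = sorted({len(c) for c in cds})
        if len(lengths) != 1:
            raise ValueError(
                f"CDS lengths differ ({lengths}); use anchor='full_locus' for "
                "length-variable loci"
            )
        n = lengths[0]
        ref_positions = ref_map.cds_positions()
        return QuartetAlignment(
            rows=tuple(cds),  # type: ignore[arg-type]
            cds_position=list(range(1, n + 1)),
            region_kind=["exon"] * n,
            locus_position=list(ref_positions),
        )
    if anchor != "full_locus":
        raise ValueError(f"unknown anchor mode {anchor!r}")
    rows = _mafft_align([r.ungapped for r in recs])
    # annotate columns against the reference (first-role) sequence
    cds_set = set(ref_map.cds_positions())
    cds_rank = {p: i + 1 for i, p in enumerate(ref_map.cds_positions())}
    cds_position: list[int | None] = []
    region_kind: list[str] = []
    locus_position: list[int | None] = []
    ref_pos = 0
    for j in range(len(rows[0])):
        c = rows[0][j]
        if c == GAP:
            cds_position.append(None)
            region_kind.append("unassigned")
            locus_position.append(None)
            continue
        ref_pos += 1
        locus_position.append(ref_pos)
        region_kind.append(ref_map.kind_at(ref_pos))
        cds_position.append(cds_rank[ref_pos] if ref_pos in cds_set else None)
    return QuartetAlignment(
        rows=tuple(rows),  # type: ignore[arg-type]
        cds_position=cds_position,
        region_kind=region_kind,
        locus_position=locus_position,
    )


def _mafft_align(seqs: Sequence[str]) -> list[str]:
    if shutil.which("mafft") is None:  # pragma: no cover - environment guard
        raise RuntimeError("full_locus alignment requires the mafft executable on PATH")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fa"
        inp.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        out = subprocess.run(
            ["mafft", "--auto", "--quiet", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    aligned: dict[str, str] = {}
    key = None
    for line in out.splitlines():
        if line.startswith(">"):
            key = line[1:].strip()
            aligned[key] = ""
        elif key is not None:
            aligned[key] += line.strip().upper()
    return [aligned[f"s{i}"] for i in range(len(seqs))]


def map_residue_index(
    query: SequenceRecord,
    reference: SequenceRecord,
    index: int,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> int | None:
    """Map a 1-based residue index of ``query`` onto ``reference``.

    Proteins are globally aligned under BLOSUM62 and the aligned
    reference position is returned, or ``None`` when the query residue
    falls against a gap.  This is the operation behind statements like
    "residue 128 of medaka LWSa corresponds to residue 131 of human LWS".
    """
    if not (1 <= index <= len(query.ungapped)):
        raise IndexError(f"residue index {index} out of range 1..{len(query.ungapped)}")
    aln = global_align(query, reference, gap_open=gap_open, gap_extend=gap_extend)
    return aln.map_a_to_b[index]
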