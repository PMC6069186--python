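"""Sequence containers, FASTA I/O, six-frame translation, and protein-vs-DNA search.

This module provides the alignment layer of the CVe screen: genome contigs
are virtually translated in all six reading frames and searched with viral
probe polypeptides using exact local alignment (Smith-Waterman / Gotoh with
affine gaps), the in-repo stand-in for a heuristic translated BLAST search.
Exactness makes the screen fully deterministic and oracle-testable.

Coordinates are 0-based half-open on the forward strand throughout; 1-based
conventions appear only in exporters.
"""

from __future__ import annotations

import functools
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Alphabets and the genetic code
# ---------------------------------------------------------------------------

DNA_ALPHABET = set("ACGTN")
AA20 = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = set(AA20) | {"*", "X"}

#: IUPAC ambiguity codes (and anything else non-ACGT) collapse to N on ingestion.
_IUPAC_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _build_codon_table() -> dict[str, str]:
    table = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
    for codon in CodonTable.unambiguous_dna_by_id[1].stop_codons:
        table[codon] = "*"
    return table


#: Standard genetic code; any codon containing a non-ACGT character -> 'X'.
CODON_TABLE: dict[str, str] = _build_codon_table()

#: Synonymous codons per amino acid (used by the simulator's back-translation).
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] = CODONS_FOR_AA[_aa] + (_codon,)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence (one record of a genome assembly)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"contig {self.id!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Polypeptide:
    """An amino-acid sequence: a probe, a reference, or an extracted match."""

    id: str
    seq: str
    role: str = "reference"  # probe | reference | extracted

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"polypeptide {self.id!r}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"polypeptide {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.role not in ("probe", "reference", "extracted"):
            raise ValueError(f"polypeptide {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters for the translated search.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST-style
    penalties, both positive).  ``min_score`` is the raw-score reporting
    threshold of the screen; the default is set so that chance matches in
    ~10 Mb of random sequence are expected to number below one (a
    Karlin-Altschul estimate for BLOSUM62 with gap 11/1, checked
    empirically on simulated sequence).
    """

    matrix_name: str = "BLOSUM62X"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 100.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")


@functools.lru_cache(maxsize=4)
def load_matrix(name: str) -> substitution_matrices.Array:
    """Load a substitution matrix by name.

    ``BLOSUM62X`` is BLOSUM62 with the X row/column fixed at -1 against
    every residue (including X), so that translated runs of N never seed
    or extend a match.
    """
    if name == "BLOSUM62X":
        m = substitution_matrices.load("BLOSUM62").copy()
        for a in m.alphabet:
            m["X", a] = m[a, "X"] = -1.0
        return m
    return substitution_matrices.load(name)


@functools.lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = load_matrix(matrix_name)
    # Biopython charges open_gap_score for the first gap position; convert
    # from the open + k*extend convention used here.
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual translations of a contig.

    ``frame`` is +1/+2/+3 for the forward strand (starting at offset
    frame-1) and -1/-2/-3 for the reverse complement (starting at offset
    |frame|-1 of the reverse-complemented sequence).  ``nt_span`` maps a
    peptide interval back to forward-strand nucleotide coordinates.
    """

    contig_id: str
    frame: int
    peptide: Polypeptide
    contig_length: int

    def nt_span(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        if not (0 <= pep_start <= pep_end <= len(self.peptide.seq)):
            raise ValueError("peptide span out of range")
        off = abs(self.frame) - 1
        if self.frame > 0:
            return off + 3 * pep_start, off + 3 * pep_end
        L = self.contig_length
        return L - off - 3 * pep_end, L - off - 3 * pep_start

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass(frozen=True)
class Hit:
    """A reported local match of a probe against a translated contig frame.

    Nucleotide coordinates are 0-based half-open on the forward strand.
    ``matched_peptide`` is the contiguous translated segment of the contig
    covered by the alignment (target side, gaps removed).
    """

    contig_id: str
    nt_start: int
    nt_end: int
    strand: str
    frame: int
    score: float
    probe_id: str
    matched_peptide: Polypeptide

    def __post_init__(self) -> None:
        if not (0 <= self.nt_start < self.nt_end):
            raise ValueError("invalid hit span")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a query against a target peptide."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    query_aln: str = ""
    target_aln: str = ""

    @property
    def is_empty(self) -> bool:
        return self.score <= 0


# ---------------------------------------------------------------------------
# FASTA I/O (gzip-transparent)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_fasta_records(path: str | Path) -> Iterator[tuple[str, str]]:
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
            yield rec.id, seq
    if not seen:
        raise ValueError(f"no FASTA records in {path}")


def read_dna_fasta(path: str | Path) -> list[Contig]:
    """Read a DNA FASTA file into contigs.

    Sequences are upper-cased; IUPAC ambiguity codes other than N are
    collapsed to N.
    """
    return [
        Contig(id=rid, seq=seq.translate(_IUPAC_TO_N))
        for rid, seq in _read_fasta_records(path)
    ]


def read_protein_fasta(path: str | Path, role: str = "reference") -> list[Polypeptide]:
    """Read a protein FASTA file; sequences upper-cased."""
    return [Polypeptide(id=rid, seq=seq, role=role) for rid, seq in _read_fasta_records(path)]


def write_fasta(records: Iterable[Contig | Polypeptide], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


def translate_dna(seq: str) -> str:
    """Translate a forward reading frame; trailing partial codon dropped.

    Codons containing any non-ACGT character translate to 'X'.
    """
    n = len(seq) - len(seq) % 3
    return "".join(CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, n, 3))


def translate_six_frames(contig: Contig) -> list[FrameTranslation]:
    """Virtually translate a contig in all six reading frames.

    Frames whose trimmed sequence is shorter than one codon (possible only
    for contigs of length 3-4) are omitted.
    """
    if contig.length < 3:
        raise ValueError(f"contig {contig.id!r}: length {contig.length} < 3")
    out: list[FrameTranslation] = []
    rc = reverse_complement(contig.seq)
    for frame in (1, 2, 3, -1, -2, -3):
        src = contig.seq if frame > 0 else rc
        pep = translate_dna(src[abs(frame) - 1 :])
        if not pep:
            continue
        out.append(
            FrameTranslation(
                contig_id=contig.id,
                frame=frame,
                peptide=Polypeptide(
                    id=f"{contig.id}|frame{frame:+d}", seq=pep, role="extracted"
                ),
                contig_length=contig.length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------


def _align_strings(query: str, target: str, scheme: ScoringScheme) -> LocalAlignment:
    al = _aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend)
    score = al.score(query, target)
    if score <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0)
    alignment = al.align(query, target)[0]
    bq, bt = alignment.aligned
    qa_parts: list[str] = []
    ta_parts: list[str] = []
    prev_q, prev_t = bq[0][0], bt[0][0]
    for (qs, qe), (ts, te) in zip(bq, bt):
        if qs > prev_q:  # deletion in target
            qa_parts.append(query[prev_q:qs])
            ta_parts.append("-" * (qs - prev_q))
        if ts > prev_t:  # insertion relative to query
            qa_parts.append("-" * (ts - prev_t))
            ta_parts.append(target[prev_t:ts])
        qa_parts.append(query[qs:qe])
        ta_parts.append(target[ts:te])
        prev_q, prev_t = qe, te
    return LocalAlignment(
        score=float(score),
        query_start=int(bq[0][0]),
        query_end=int(bq[-1][1]),
        target_start=int(bt[0][0]),
        target_end=int(bt[-1][1]),
        query_aln="".join(qa_parts),
        target_aln="".join(ta_parts),
    )


def local_align_protein(
    query: Polypeptide, target: Polypeptide, scheme: ScoringScheme | None = None
) -> LocalAlignment:
    """Optimal local alignment (Smith-Waterman with affine gaps) of two peptides.

    Returns the maximum-scoring local alignment under the scheme; a zero
    score with empty spans when no positive-scoring alignment exists.
    """
    scheme = scheme or ScoringScheme()
    return _align_strings(query.seq, target.seq, scheme)


def _iter_frame_matches(
    probe: str, target: str, scheme: ScoringScheme
) -> list[LocalAlignment]:
    """All non-overlapping matches of probe in one frame translation.

    Greedy iterated masking: repeatedly take the best remaining local
    alignment with score >= min_score and remove its target span from the
    search space (splitting the segment), so reported matches can never
    overlap.  Ties in score break toward the smaller target start.
    """
    segments: list[tuple[int, int]] = [(0, len(target))]
    cache: dict[tuple[int, int], LocalAlignment] = {}
    found: list[LocalAlignment] = []
    while True:
        best: LocalAlignment | None = None
        best_seg: tuple[int, int] | None = None
        for seg in segments:
            res = cache.get(seg)
            if res is None:
                s, e = seg
                sub = _align_strings(probe, target[s:e], scheme)
                res = LocalAlignment(
                    sub.score,
                    sub.query_start,
                    sub.query_end,
                    sub.target_start + s,
                    sub.target_end + s,
                    sub.query_aln,
                    sub.target_aln,
                )
                cache[seg] = res
            if res.score >= scheme.min_score and (
                best is None
                or res.score > best.score
                or (res.score == best.score and res.target_start < best.target_start)
            ):
                best, best_seg = res, seg
        if best is None:
            break
        found.append(best)
        s, e = best_seg
        segments.remove(best_seg)
        if best.target_start - s >= 1:
            segments.append((s, best.target_start))
        if e - best.target_end >= 1:
            segments.append((best.target_end, e))
    return found


def search_translated_contig(
    contig: Contig, probe: Polypeptide, scheme: ScoringScheme | None = None
) -> list[Hit]:
    """Search all six frame translations of a contig with a probe polypeptide.

    Every non-overlapping per-frame match scoring >= ``scheme.min_score`` is
    reported as a Hit with forward-strand nucleotide coordinates.  Hits are
    sorted by (start, -score, '+' before '-', frame).
    """
    scheme = scheme or ScoringScheme()
    hits: list[Hit] = []
    for ft in translate_six_frames(contig):
        for m in _iter_frame_matches(probe.seq, ft.peptide.seq, scheme):
            nt_start, nt_end = ft.nt_span(m.target_start, m.target_end)
            matched = ft.peptide.seq[m.target_start : m.target_end]
            hits.append(
                Hit(
                    contig_id=contig.id,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    strand=ft.strand,
                    frame=ft.frame,
                    score=m.score,
                    probe_id=probe.id,
                    matched_peptide=Polypeptide(
                        id=f"{contig.id}:{nt_start}-{nt_end}({ft.strand})",
                        seq=matched,
                        role="extracted",
                    ),
                )
            )
    hits.sort(key=lambda h: (h.nt_start, -h.score, h.strand, h.frame))
    return hits
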