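"""The two-step paired screen.

Step 1 searches each genome assembly with viral probe polypeptides
(translated local alignment, see :mod:`cvescreen.sequence_core`); step 2
extracts each matching peptide and classifies it against a curated
reference polypeptide library, inheriting the best reference's gene and
genus-level group.  Results are captured in a flat, diffable TSV — one row
per classified hit — rather than a database backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_core import (
    Contig,
    Hit,
    Polypeptide,
    ScoringScheme,
    local_align_protein,
    read_dna_fasta,
    read_protein_fasta,
    search_translated_contig,
)

logger = logging.getLogger("cvescreen")

VALID_GENES = ("rep", "cap")
VALID_GROUPS = ("Circovirus", "Cyclovirus", "CRESS")
VALID_TIERS = ("cve", "isolate", "metagenomic")

#: Column order of the screen results table.
RESULT_COLUMNS = [
    "species",
    "contig",
    "start",
    "end",
    "strand",
    "frame",
    "score",
    "probe_id",
    "best_ref",
    "assigned_gene",
    "assigned_group",
]


@dataclass(frozen=True)
class ReferenceEntry:
    """A reference polypeptide with classification and host metadata.

    ``evidence_tier`` distinguishes sequences whose host association rests
    on more than sequencing alone: ``cve`` (germline element in a sequenced
    host genome) and ``isolate`` (virus isolated from a host) are
    "anchored" tiers; ``metagenomic`` labels rest only on sample origin.
    """

    id: str
    peptide: Polypeptide
    gene: str
    group: str
    host_association: str = "unknown"
    evidence_tier: str = "isolate"

    def __post_init__(self) -> None:
        if self.gene not in VALID_GENES:
            raise ValueError(f"reference {self.id!r}: gene must be one of {VALID_GENES}")
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"reference {self.id!r}: group must be one of {VALID_GROUPS}"
            )
        if self.evidence_tier not in VALID_TIERS:
            raise ValueError(
                f"reference {self.id!r}: evidence_tier must be one of {VALID_TIERS}"
            )


@dataclass(frozen=True)
class Classification:
    """Best-reference assignment of an extracted peptide."""

    best_ref_id: str
    assigned_gene: str
    assigned_group: str
    score: float
    runner_up_score: float  # best score among references of a *different* group


def load_reference_library(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[ReferenceEntry]:
    """Load a reference library from FASTA + metadata TSV.

    The TSV needs columns id, gene, group, host_association, evidence_tier;
    every FASTA record must have a metadata row.
    """
    peptides = {p.id: p for p in read_protein_fasta(fasta_path, role="reference")}
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"id", "gene", "group", "host_association", "evidence_tier"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"reference metadata missing columns: {sorted(missing)}")
    entries = []
    for row in meta.itertuples(index=False):
        if row.id not in peptides:
            raise ValueError(f"metadata row {row.id!r} has no FASTA record")
        entries.append(
            ReferenceEntry(
                id=row.id,
                peptide=peptides[row.id],
                gene=row.gene,
                group=row.group,
                host_association=row.host_association,
                evidence_tier=row.evidence_tier,
            )
        )
    absent = set(peptides) - {e.id for e in entries}
    if absent:
        raise ValueError(f"FASTA records without metadata: {sorted(absent)}")
    return entries


def classify_peptide(
    extracted: Polypeptide,
    library: Sequence[ReferenceEntry],
    scheme: ScoringScheme | None = None,
) -> Classification:
    """Classify an extracted peptide against the reference library (step 2).

    The winner is the highest-scoring reference (ties break to the
    lexicographically smaller id).  ``runner_up_score`` is the best score
    among references whose group differs from the winner's — a cross-group
    margin of classification confidence — or 0 if no other group scores.
    """
    if not library:
        raise ValueError("reference library is empty")
    scheme = scheme or ScoringScheme()
    scores = {
        ref.id: local_align_protein(extracted, ref.peptide, scheme).score
        for ref in library
    }
    by_id = {ref.id: ref for ref in library}
    best_id = min(scores, key=lambda rid: (-scores[rid], rid))
    best = by_id[best_id]
    runner_up = max(
        (scores[r.id] for r in library if r.group != best.group), default=0.0
    )
    return Classification(
        best_ref_id=best.id,
        assigned_gene=best.gene,
        assigned_group=best.group,
        score=scores[best_id],
        runner_up_score=runner_up,
    )


def screen_assembly(
    assembly: Sequence[Contig],
    probes: Sequence[Polypeptide],
    scheme: ScoringScheme | None = None,
) -> list[Hit]:
    """Step 1: search every contig of an assembly with every probe.

    Hits from different probes over the same region are all retained —
    deduplication is the locus-merging stage's job.  Output is sorted by
    (contig, start, -score) and fully deterministic.
    """
    if not probes:
        raise ValueError("probe set is empty")
    if not assembly:
        raise ValueError("assembly is empty")
    scheme = scheme or ScoringScheme()
    hits: list[Hit] = []
    for contig in assembly:
        if contig.length < 3:
            continue
        for probe in probes:
            hits.extend(search_translated_contig(contig, probe, scheme))
    hits.sort(key=lambda h: (h.contig_id, h.nt_start, -h.score, h.strand, h.frame))
    return hits


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read an assembly manifest TSV: species, fasta_path, species_code."""
    man = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "fasta_path", "species_code"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if man["species"].duplicated().any():
        dups = man.loc[man["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in manifest: {dups}")
    return man


def run_paired_screen(
    assemblies: Mapping[str, str | Path | Sequence[Contig]],
    probes: Sequence[Polypeptide],
    library: Sequence[ReferenceEntry],
    scheme: ScoringScheme | None = None,
    output_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full two-step screen over a set of species assemblies.

    ``assemblies`` maps species name to a FASTA path or an in-memory list
    of contigs.  Species are processed in sorted order; a species whose
    assembly fails to load is logged and skipped, and the run continues.
    When ``output_dir`` is given, writes ``screen_results.tsv`` and a
    per-species count log.  Re-running on identical inputs produces a
    byte-identical table.
    """
    if not probes:
        raise ValueError("probe set is empty")
    if not library:
        raise ValueError("reference library is empty")
    scheme = scheme or ScoringScheme()
    rows: list[dict] = []
    log_lines: list[str] = []
    for species in sorted(assemblies):
        source = assemblies[species]
        try:
            contigs = (
                read_dna_fasta(source)
                if isinstance(source, (str, Path))
                else list(source)
            )
            hits = screen_assembly(contigs, probes, scheme)
        except (ValueError, OSError) as exc:
            logger.error("species %s: %s", species, exc)
            log_lines.append(f"{species}\tERROR\t{exc}")
            continue
        for hit in hits:
            cls = classify_peptide(hit.matched_peptide, library, scheme)
            rows.append(
                {
                    "species": species,
                    "contig": hit.contig_id,
                    "start": hit.nt_start,
                    "end": hit.nt_end,
                    "strand": hit.strand,
                    "frame": hit.frame,
                    "score": hit.score,
                    "probe_id": hit.probe_id,
                    "best_ref": cls.best_ref_id,
                    "assigned_gene": cls.assigned_gene,
                    "assigned_group": cls.assigned_group,
                }
            )
        log_lines.append(f"{species}\tOK\t{len(hits)} hits")
        logger.info("species %s: %d hits", species, len(hits))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
        (outdir / "screen_log.txt").write_text("\n".join(log_lines) + "\n")
    return table
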