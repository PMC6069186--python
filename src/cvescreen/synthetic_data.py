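"""Synthetic study inputs: genomes with planted viral insertions, and labeled trees.

The real screen ran over hundreds of downloaded WGS assemblies; this module
generates desk-scale stand-ins with known ground truth so every stage of
the pipeline can be tested quantitatively:

* host genome assemblies (i.i.d. nucleotide sequence at a set GC content)
  carrying planted rep-derived elements subjected to a controlled decay
  model — non-synonymous codon substitutions, premature stop codons and
  frameshifting indels — with every applied mutation recorded in a truth
  table alongside the realized flank lengths, status and intactness;
* a reference polypeptide library and probe set with group structure
  (Circovirus / Cyclovirus / CRESS rep families plus a cap family) and an
  unrelated distractor protein family to exercise specificity;
* host-labeled phylogenies with a chosen number of planted host-group
  transitions and planted mislabeled metagenomic (contaminant) tips.

Every generator is a pure function of (config, seed): identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .sequence_core import (
    AA20,
    CODON_TABLE,
    CODONS_FOR_AA,
    Contig,
    Polypeptide,
    reverse_complement,
    write_fasta,
)
from .screening import ReferenceEntry
from .host_phylogenetics import AnnotatedTree

STOP_CODONS = ("TAA", "TAG", "TGA")

TRUTH_COLUMNS = [
    "species",
    "contig_id",
    "nt_start",
    "nt_end",
    "strand",
    "source_ref_id",
    "element_family",
    "n_subs",
    "n_stops",
    "n_shifts",
    "flank5",
    "flank3",
    "true_status",
    "true_intact",
    "stop_codon_indices",
    "shift_edits",
]

FLANK_THRESHOLD = 3000
MIN_INTACT_LEN = 200


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Decay model and truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayModel:
    """Post-insertion degradation applied to a planted element.

    ``aa_substitution_rate`` is the proportion of codons replaced by a
    codon of a different amino acid.  ``stop_rate`` and
    ``frameshift_rate`` are per-element counts (rounded to integers) of
    premature stop codons and indels of length not divisible by 3; counts
    are deterministic so boundary conditions (exactly 0 vs exactly 1) are
    realizable.
    """

    aa_substitution_rate: float = 0.0
    stop_rate: float = 0.0
    frameshift_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.aa_substitution_rate, self.stop_rate, self.frameshift_rate) < 0:
            raise ValueError("decay rates must be >= 0")
        if self.aa_substitution_rate > 1:
            raise ValueError("aa_substitution_rate must be <= 1")


@dataclass
class PlantRecord:
    """Ground truth for one planted element (one truth-table row).

    ``shift_edits`` records each frameshifting indel as ``pos:delta`` in
    final element coordinates (delta > 0 insertion, < 0 deletion), so the
    reading-frame structure of the decayed element can be reconstructed.
    """

    species: str
    contig_id: str
    nt_start: int
    nt_end: int
    strand: str
    source_ref_id: str
    element_family: str
    n_subs: int
    n_stops: int
    n_shifts: int
    flank5: int
    flank3: int
    true_status: str
    true_intact: bool
    stop_codon_indices: str = ""
    shift_edits: str = ""

    @property
    def span(self) -> int:
        return self.nt_end - self.nt_start


def truth_fragments(record: PlantRecord) -> list[tuple[int, int, int]]:
    """Element-relative (start, end, phase) segments between frameshifts.

    Phase is the cumulative indel offset mod 3 relative to the element
    start; a decayed element with any frameshift yields segments of more
    than one phase.
    """
    length = record.span
    edits = []
    if record.shift_edits:
        for part in record.shift_edits.split(";"):
            pos, delta = part.split(":")
            edits.append((int(pos), int(delta)))
    edits.sort()
    frags = []
    prev = 0
    phase = 0
    for pos, delta in edits:
        if pos > prev:
            frags.append((prev, pos, phase))
        phase = (phase + delta) % 3
        prev = pos
    if length > prev:
        frags.append((prev, length, phase))
    return frags


def locus_from_truth(record: PlantRecord, score: float = 100.0):
    """Build the idealized Locus for a planted element from its truth record.

    Fragments follow the element's realized reading-frame segments (one
    per frameshift-delimited block), so the locus rules can be checked
    against ground truth independently of the screen's hit recovery.
    """
    from .locus_annotation import Fragment, Locus

    frags = []
    contig_len = record.flank5 + record.span + record.flank3
    for s, e, phase in truth_fragments(record):
        if record.strand == "+":
            a, b = record.nt_start + s, record.nt_start + e
            frame = ((record.nt_start + phase) % 3) + 1
        else:
            a, b = record.nt_end - e, record.nt_end - s
            frame = -(((contig_len - record.nt_end + phase) % 3) + 1)
        frags.append(Fragment(nt_start=a, nt_end=b, frame=frame, score=score))
    frags.sort(key=lambda f: f.nt_start)
    return Locus(
        species=record.species,
        contig_id=record.contig_id,
        nt_start=record.nt_start,
        nt_end=record.nt_end,
        strand=record.strand,
        fragments=frags,
        assigned_gene="rep",
        assigned_group="Circovirus",
    )


def validate_truth_table(
    truth: pd.DataFrame, assemblies: Mapping[str, Sequence[Contig]]
) -> pd.DataFrame:
    """Recompute status/intactness for every planted element via the locus rules.

    Returns the truth table with ``recomputed_status`` / ``recomputed_intact``
    columns appended; a generator bug would show up as disagreement with
    the recorded truth.
    """
    from .locus_annotation import call_intactness, call_status

    contigs = {
        sp: {c.id: c for c in clist} for sp, clist in assemblies.items()
    }
    statuses, intacts = [], []
    for row in truth.fillna({"shift_edits": "", "stop_codon_indices": ""}).itertuples(index=False):
        record = PlantRecord(**row._asdict())
        contig = contigs[record.species][record.contig_id]
        locus = locus_from_truth(record)
        statuses.append(call_status(locus, contig.length))
        intacts.append(call_intactness(locus, contig))
    out = truth.copy()
    out["recomputed_status"] = statuses
    out["recomputed_intact"] = intacts
    return out


# ---------------------------------------------------------------------------
# Genomes and peptides
# ---------------------------------------------------------------------------


def _random_seq(length: int, gc_content: float, rng: np.random.Generator) -> str:
    bases = np.array(list("ACGT"))
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    return "".join(rng.choice(bases, size=length, p=p))


def simulate_host_genome(
    n_contigs: int,
    mean_length: int,
    gc_content: float = 0.42,
    seed=0,
    id_prefix: str = "contig",
) -> list[Contig]:
    """I.i.d. nucleotide contigs at the stated GC content.

    Lengths are drawn uniformly from [0.5, 1.5] x mean_length.
    """
    if n_contigs <= 0 or mean_length <= 0:
        raise ValueError("n_contigs and mean_length must be positive")
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must be in [0, 1]")
    rng = _rng(seed)
    contigs = []
    for i in range(n_contigs):
        length = int(rng.integers(mean_length // 2, mean_length + mean_length // 2 + 1))
        seq = _random_seq(max(length, 3), gc_content, rng)
        contigs.append(Contig(id=f"{id_prefix}_{i + 1:03d}", seq=seq))
    return contigs


def random_peptide(length: int, seed=0, id: str = "pep") -> Polypeptide:
    rng = _rng(seed)
    return Polypeptide(id=id, seq="".join(rng.choice(list(AA20), size=length)))


def evolve_peptide(source: Polypeptide, proportion: float, seed=0, id: str | None = None) -> Polypeptide:
    """Replace round(proportion x length) positions with a different residue."""
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must be in [0, 1]")
    rng = _rng(seed)
    seq = list(source.seq)
    n = round(proportion * len(seq))
    positions = sorted(rng.choice(len(seq), size=n, replace=False))
    for pos in positions:
        choices = [a for a in AA20 if a != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    return Polypeptide(id=id or f"{source.id}_evo", seq="".join(seq), role=source.role)


def back_translate(peptide: Polypeptide, seed=0) -> str:
    """DNA encoding the peptide, codons chosen uniformly among synonyms."""
    rng = _rng(seed)
    codons = []
    for aa in peptide.seq:
        options = CODONS_FOR_AA[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Planting decayed elements
# ---------------------------------------------------------------------------


def _apply_decay(
    element: str, decay: DecayModel, rng: np.random.Generator
) -> tuple[str, int, int, int, str, str]:
    """Mutate a back-translated element; returns realized sequence + counts."""
    n_codons = len(element) // 3
    codons = [element[3 * i : 3 * i + 3] for i in range(n_codons)]
    tail = element[3 * n_codons :]

    n_subs = round(decay.aa_substitution_rate * n_codons)
    sub_idx = sorted(rng.choice(n_codons, size=n_subs, replace=False)) if n_subs else []
    for i in sub_idx:
        aa = CODON_TABLE.get(codons[i], "X")
        choices = [a for a in AA20 if a != aa]
        new_aa = choices[int(rng.integers(len(choices)))]
        options = CODONS_FOR_AA[new_aa]
        codons[i] = options[int(rng.integers(len(options)))]

    n_stops = round(decay.stop_rate)
    stop_idx: list[int] = []
    if n_stops:
        internal = np.arange(1, n_codons - 1)
        stop_idx = sorted(rng.choice(internal, size=n_stops, replace=False))
        for i in stop_idx:
            codons[i] = STOP_CODONS[int(rng.integers(3))]

    seq = "".join(codons) + tail
    n_shifts = round(decay.frameshift_rate)
    edits: list[tuple[int, int]] = []
    bases = "ACGT"
    for _ in range(n_shifts):
        # keep edit positions clear of the ends and of each other so each
        # frameshift produces a distinguishable frame segment
        while True:
            pos = int(rng.integers(6, len(seq) - 6))
            if all(abs(pos - p) >= 6 for p, _ in edits):
                break
        delta = int(rng.integers(1, 3))  # 1 or 2, not divisible by 3
        if rng.random() < 0.5:  # insertion
            ins = "".join(bases[int(rng.integers(4))] for _ in range(delta))
            seq = seq[:pos] + ins + seq[pos:]
            edits = [(p + delta if p > pos else p, d) for p, d in edits]
            edits.append((pos, delta))
        else:  # deletion
            seq = seq[:pos] + seq[pos + delta :]
            edits = [(p - delta if p > pos + delta else p, d) for p, d in edits]
            edits.append((pos, -delta))
    edits.sort()
    stop_str = ";".join(str(i) for i in stop_idx)
    edit_str = ";".join(f"{p}:{d}" for p, d in edits)
    return seq, n_subs, n_stops, n_shifts, stop_str, edit_str


def insert_eve(
    contig: Contig,
    source_peptide: Polypeptide,
    decay: DecayModel,
    position: int,
    strand: str,
    seed=0,
    species: str = "",
    source_ref_id: str | None = None,
    element_family: str = "viral",
    max_nt: int | None = None,
) -> tuple[Contig, PlantRecord]:
    """Splice a decayed back-translation of ``source_peptide`` into a contig.

    The element is back-translated (uniform codon choice), optionally
    truncated to ``max_nt``, decayed, reverse-complemented for '-' strand
    insertions, and inserted at ``position`` (host sequence is displaced,
    not overwritten).  The returned PlantRecord's status/intactness are
    computed from the *realized* mutations and flanks, not the requested
    rates.
    """
    rng = _rng(seed)
    if strand not in "+-":
        raise ValueError("strand must be + or -")
    if not 0 <= position <= contig.length:
        raise ValueError(f"position {position} outside contig {contig.id!r}")
    element = back_translate(source_peptide, rng)
    if max_nt is not None:
        element = element[:max_nt]
    if len(element) > contig.length:
        raise ValueError("element longer than contig")
    element, n_subs, n_stops, n_shifts, stop_str, edit_str = _apply_decay(
        element, decay, rng
    )
    planted = element if strand == "+" else reverse_complement(element)
    new_seq = contig.seq[:position] + planted + contig.seq[position:]
    flank5 = position
    flank3 = contig.length - position
    span = len(element)
    record = PlantRecord(
        species=species,
        contig_id=contig.id,
        nt_start=position,
        nt_end=position + span,
        strand=strand,
        source_ref_id=source_ref_id or source_peptide.id,
        element_family=element_family,
        n_subs=n_subs,
        n_stops=n_stops,
        n_shifts=n_shifts,
        flank5=flank5,
        flank3=flank3,
        true_status="confirmed_cve"
        if min(flank5, flank3) > FLANK_THRESHOLD
        else "unconfirmed",
        true_intact=span >= MIN_INTACT_LEN and n_stops == 0 and n_shifts == 0,
        stop_codon_indices=stop_str,
        shift_edits=edit_str,
    )
    return Contig(id=contig.id, seq=new_seq), record


# ---------------------------------------------------------------------------
# Reference library / probe generation
# ---------------------------------------------------------------------------

_HOSTS = {
    "Circovirus": ("birds", "mammals", "ray-finned fish"),
    "Cyclovirus": ("arthropods", "arthropods", "unknown"),
    "CRESS": ("unknown", "unknown", "unknown"),
}
_TIER_CYCLE = ("isolate", "cve", "metagenomic")


def make_reference_library(
    seed=0,
    rep_length: int = 220,
    cap_length: int = 230,
    n_per_group: int = 3,
    within_divergence: float = 0.08,
    between_divergence: float = 0.35,
) -> list[ReferenceEntry]:
    """A structured rep/cap reference set with three rep groups.

    Rep families for Circovirus, Cyclovirus and CRESS descend from one
    root peptide at ``between_divergence`` (CRESS further out), members at
    ``within_divergence`` from their group ancestor; the cap family is an
    unrelated root (the two genes share no homology).
    """
    rng = _rng(seed)
    rep_root = random_peptide(rep_length, rng, id="rep_root")
    cap_root = random_peptide(cap_length, rng, id="cap_root")
    entries: list[ReferenceEntry] = []
    for group in ("Circovirus", "Cyclovirus", "CRESS"):
        div = between_divergence * (1.3 if group == "CRESS" else 1.0)
        ancestor = evolve_peptide(rep_root, min(div, 1.0), rng)
        for i in range(n_per_group):
            rid = f"{group}_rep_{i + 1:02d}"
            pep = evolve_peptide(ancestor, within_divergence, rng, id=rid)
            entries.append(
                ReferenceEntry(
                    id=rid,
                    peptide=pep,
                    gene="rep",
                    group=group,
                    host_association=_HOSTS[group][i % 3],
                    evidence_tier=_TIER_CYCLE[i % 3],
                )
            )
    for group in ("Circovirus", "Cyclovirus"):
        ancestor = evolve_peptide(cap_root, between_divergence, rng)
        for i in range(max(1, n_per_group - 1)):
            rid = f"{group}_cap_{i + 1:02d}"
            pep = evolve_peptide(ancestor, within_divergence, rng, id=rid)
            entries.append(
                ReferenceEntry(
                    id=rid,
                    peptide=pep,
                    gene="cap",
                    group=group,
                    host_association=_HOSTS[group][i % 3],
                    evidence_tier=_TIER_CYCLE[i % 3],
                )
            )
    return entries


def make_probes(library: Sequence[ReferenceEntry]) -> list[Polypeptide]:
    """One rep probe per group plus one cap probe (the many-probe design)."""
    probes = []
    seen = set()
    for entry in library:
        key = (entry.gene, entry.group)
        if key in seen:
            continue
        if entry.gene == "cap" and any(g == "cap" for g, _ in seen):
            continue
        seen.add(key)
        probes.append(
            Polypeptide(id=f"probe_{entry.id}", seq=entry.peptide.seq, role="probe")
        )
    return probes


# ---------------------------------------------------------------------------
# Full screening dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for a simulated screen.

    Defaults give a small multi-species screen with moderately decayed
    rep elements: flanks straddle the 3 kb status threshold so both
    status classes occur, and one unrelated distractor element per
    species exercises specificity.
    """

    n_species: int = 3
    plants_per_species: int = 2
    aa_substitution_rate: float = 0.15
    stop_rate: float = 0.0
    frameshift_rate: float = 0.0
    flank_min: int = 2000
    flank_max: int = 8000
    distractors_per_species: int = 1
    n_background_contigs: int = 2
    background_contig_length: int = 20_000
    gc_content: float = 0.42
    rep_length: int = 220
    n_refs_per_group: int = 3


@dataclass
class ScreenDataset:
    """In-memory handle on a generated screening dataset."""

    assemblies: dict[str, list[Contig]]
    species_codes: dict[str, str]
    probes: list[Polypeptide]
    library: list[ReferenceEntry]
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_screen_dataset(
    config: ScreenSimConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ScreenDataset:
    """Generate a complete input set for the paired screen, plus ground truth.

    When ``out_dir`` is given, writes per-species FASTA, a manifest TSV
    (species, fasta_path, species_code; paths relative to the manifest),
    probe and reference FASTA, reference metadata TSV and the truth table.
    """
    config = config or ScreenSimConfig()
    rng = np.random.default_rng(seed)
    library = make_reference_library(
        rng, rep_length=config.rep_length, n_per_group=config.n_refs_per_group
    )
    probes = make_probes(library)
    rep_refs = [e for e in library if e.gene == "rep"]
    distractor_root = random_peptide(config.rep_length, rng, id="distractor_root")

    assemblies: dict[str, list[Contig]] = {}
    species_codes: dict[str, str] = {}
    records: list[PlantRecord] = []
    for si in range(config.n_species):
        species = f"species_{si + 1:02d}"
        species_codes[species] = f"Sp{si + 1:02d}"
        contigs: list[Contig] = []
        n_plant_contigs = config.plants_per_species + config.distractors_per_species
        for pi in range(n_plant_contigs):
            is_distractor = pi >= config.plants_per_species
            flank5 = int(rng.integers(config.flank_min, config.flank_max + 1))
            flank3 = int(rng.integers(config.flank_min, config.flank_max + 1))
            base = Contig(
                id=f"{species}_ctg{pi + 1:02d}",
                seq=_random_seq(flank5 + flank3, config.gc_content, rng),
            )
            strand = "+" if rng.random() < 0.5 else "-"
            if is_distractor:
                source = evolve_peptide(
                    distractor_root, 0.1, rng, id=f"distractor_{si + 1:02d}"
                )
                family = "distractor"
            else:
                source = rep_refs[int(rng.integers(len(rep_refs)))].peptide
                family = "viral"
            decay = DecayModel(
                aa_substitution_rate=config.aa_substitution_rate,
                stop_rate=config.stop_rate,
                frameshift_rate=config.frameshift_rate,
            )
            planted, record = insert_eve(
                base,
                source,
                decay,
                position=flank5,
                strand=strand,
                seed=rng,
                species=species,
                element_family=family,
            )
            contigs.append(planted)
            records.append(record)
        contigs.extend(
            simulate_host_genome(
                config.n_background_contigs,
                config.background_contig_length,
                config.gc_content,
                rng,
                id_prefix=f"{species}_bg",
            )
        )
        assemblies[species] = contigs

    truth = pd.DataFrame([asdict(r) for r in records], columns=TRUTH_COLUMNS)
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for species, contigs in assemblies.items():
            fasta = out / f"{species}.fasta"
            write_fasta(contigs, fasta)
            manifest_rows.append(
                {
                    "species": species,
                    "fasta_path": fasta.name,
                    "species_code": species_codes[species],
                }
            )
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
        write_fasta(probes, out / "probes.faa")
        write_fasta([e.peptide for e in library], out / "reflib.faa")
        pd.DataFrame(
            [
                {
                    "id": e.id,
                    "gene": e.gene,
                    "group": e.group,
                    "host_association": e.host_association,
                    "evidence_tier": e.evidence_tier,
                }
                for e in library
            ]
        ).to_csv(out / "reflib.tsv", sep="\t", index=False)
        with open(out / "truth.tsv", "w") as fh:
            fh.write(f"# seed: {seed}\n")
            truth.to_csv(fh, sep="\t", index=False)
        paths = {
            "manifest": out / "manifest.tsv",
            "probes": out / "probes.faa",
            "reflib_fasta": out / "reflib.faa",
            "reflib_meta": out / "reflib.tsv",
            "truth": out / "truth.tsv",
        }
    return ScreenDataset(
        assemblies=assemblies,
        species_codes=species_codes,
        probes=probes,
        library=library,
        truth=truth,
        paths=paths,
    )


# ---------------------------------------------------------------------------
# Labeled trees with planted transitions and contaminants
# ---------------------------------------------------------------------------


@dataclass
class LabeledTreeTruth:
    """A simulated host-labeled tree plus its planted ground truth."""

    atree: AnnotatedTree
    planted_transition_count: int
    contaminant_ids: list[str]
    clean_metagenomic_ids: list[str]


def simulate_labeled_tree(
    n_tips: int,
    host_groups: Sequence[str],
    planted_transitions: int = 0,
    contamination_rate: float = 0.0,
    seed=0,
    clean_metagenomic_rate: float = 0.1,
    support_range: tuple[int, int] = (75, 100),
) -> LabeledTreeTruth:
    """Random rooted binary tree with planted host-state transitions.

    Host labels change on exactly ``planted_transitions`` distinct edges
    (each switch moves to a different group), so the realized labeling
    implies exactly that many changes.  A fraction ``contamination_rate``
    of tips gain a metagenomic sibling carrying a *wrong* group label
    (planted contaminant); ``clean_metagenomic_rate`` of tips gain a
    correctly labeled metagenomic sibling.  Internal-node supports are
    drawn from ``support_range``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if planted_transitions > n_tips - 1:
        raise ValueError("planted_transitions must be <= n_tips - 1")
    if len(host_groups) < 2 and (planted_transitions or contamination_rate):
        raise ValueError("need >= 2 host groups to plant transitions/contaminants")
    rng = _rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node(edge_length=round(float(rng.exponential(0.1)), 4))
        node.taxon = taxa.new_taxon(label=f"t{i + 1:03d}")
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node(edge_length=round(float(rng.exponential(0.1)), 4))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.is_rooted = True

    # plant label switches on distinct edges
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    switch_nodes = set()
    if planted_transitions:
        idx = rng.choice(len(edges), size=planted_transitions, replace=False)
        switch_nodes = {id(edges[int(i)]) for i in idx}
    tree.seed_node.state = host_groups[0]
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        state = node.parent_node.state
        if id(node) in switch_nodes:
            others = [g for g in host_groups if g != state]
            state = others[int(rng.integers(len(others)))]
        node.state = state

    host_group: dict[str, str] = {}
    tier: dict[str, str] = {}
    leaves = [lf for lf in tree.leaf_node_iter()]
    for leaf in leaves:
        host_group[leaf.taxon.label] = leaf.state
        tier[leaf.taxon.label] = "cve" if rng.random() < 0.5 else "isolate"

    def add_sibling(leaf, label_suffix, state):
        new_leaf = dendropy.Node(edge_length=0.01)
        new_leaf.taxon = taxa.new_taxon(label=leaf.taxon.label + label_suffix)
        parent = leaf.parent_node
        joint = dendropy.Node(edge_length=leaf.edge_length)
        if parent is None:
            tree.seed_node = joint
        else:
            parent.remove_child(leaf)
            parent.add_child(joint)
        leaf.edge_length = 0.01
        joint.add_child(leaf)
        joint.add_child(new_leaf)
        host_group[new_leaf.taxon.label] = state
        tier[new_leaf.taxon.label] = "metagenomic"
        return new_leaf.taxon.label

    n_cont = round(contamination_rate * n_tips)
    n_clean = round(clean_metagenomic_rate * n_tips)
    chosen = rng.choice(len(leaves), size=min(n_cont + n_clean, len(leaves)), replace=False)
    contaminant_ids: list[str] = []
    clean_ids: list[str] = []
    for rank, li in enumerate(chosen):
        leaf = leaves[int(li)]
        if rank < n_cont:
            wrong = [g for g in host_groups if g != leaf.state]
            state = wrong[int(rng.integers(len(wrong)))]
            contaminant_ids.append(add_sibling(leaf, "_mg", state))
        else:
            clean_ids.append(add_sibling(leaf, "_mgc", leaf.state))

    lo, hi = support_range
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.parent_node is not None:
            node.label = str(int(rng.integers(lo, hi + 1)))

    atree = AnnotatedTree(tree=tree, host_group=host_group, evidence_tier=tier)
    return LabeledTreeTruth(
        atree=atree,
        planted_transition_count=planted_transitions,
        contaminant_ids=sorted(contaminant_ids),
        clean_metagenomic_ids=sorted(clean_ids),
    )
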