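"""From classified hits to annotated CVe loci.

Fragmentary hits on a contig are merged into discrete loci; each locus is
then judged on two independent axes used throughout paleovirology:

* **status** — ``confirmed_cve`` when the region of viral homology is
  flanked on both sides by more than a threshold (default 3 kb) of host
  genomic sequence, evidence of genuine germline integration; otherwise
  ``unconfirmed`` (potentially derived from contaminating virus, e.g. a
  short viral contig co-assembled with the genome).
* **intactness** — whether uninterrupted protein-coding potential is
  preserved across the whole region of homology: a minimum length, a
  single reading frame across all fragments (no frameshift), and no
  internal stop codon.

Confirmed loci receive stable identifiers ``CVe-<Group>.<n>-<SpeciesCode>``
where orthologous insertions in different species share the number ``n``.
Orthology between loci is established from flanking host sequence: two
insertions sitting in homologous genomic context descend from a single
ancestral integration event.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import pandas as pd

from .sequence_core import Contig, read_dna_fasta, reverse_complement, translate_dna

GFF3_SOURCE = "cvescreen"
GFF3_FEATURE_TYPE = "endogenous_viral_element"

_CVE_ID_RE = re.compile(r"^CVe-(?P<group>[^.]+)\.(?P<num>\d+)-(?P<code>.+)$")

LOCUS_TSV_COLUMNS = [
    "species",
    "contig",
    "start",
    "end",
    "strand",
    "assigned_gene",
    "assigned_group",
    "flank5",
    "flank3",
    "status",
    "intact",
    "cve_id",
    "fragments",
]


@dataclass(frozen=True)
class Fragment:
    """One member hit of a locus (frame sign encodes the strand)."""

    nt_start: int
    nt_end: int
    frame: int
    score: float


@dataclass
class Locus:
    """A putative endogenous viral element: merged hits plus annotation."""

    species: str
    contig_id: str
    nt_start: int
    nt_end: int
    strand: str
    fragments: list[Fragment]
    assigned_gene: str
    assigned_group: str
    flank5: int = 0
    flank3: int = 0
    status: str = "unconfirmed"
    intact: bool = False
    cve_id: str = "unassigned"

    @property
    def span(self) -> int:
        return self.nt_end - self.nt_start


@dataclass
class OrthologGroup:
    """Loci in one or more species descending from one integration event."""

    members: list[Locus]
    numeric_id: int | None = None

    def __post_init__(self) -> None:
        genes = {m.assigned_gene for m in self.members}
        groups = {m.assigned_group for m in self.members}
        if len(genes) > 1 or len(groups) > 1:
            raise ValueError("ortholog group members must share gene and group")


# ---------------------------------------------------------------------------
# Merging hits into loci
# ---------------------------------------------------------------------------


def merge_hits_to_loci(
    hits: pd.DataFrame | Sequence, species: str, contig_id: str, max_gap: int = 100
) -> list[Locus]:
    """Merge same-strand hits on one contig into loci.

    Hits whose nucleotide gap is at most ``max_gap`` (overlap counts) and
    that lie on the same strand fuse into one locus; different strands
    never merge.  Within a cluster, a hit overlapping a higher-scoring
    retained hit is dropped (redundant probes covering the same region).
    A locus inherits gene/group from its highest-scoring fragment.  The
    operation is idempotent: re-merging the resulting loci changes nothing.

    ``hits`` is a DataFrame with columns start, end, strand, frame, score,
    assigned_gene, assigned_group (the screen results table restricted to
    one species+contig), or any sequence of records with those attributes.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if isinstance(hits, pd.DataFrame):
        records = list(hits.itertuples(index=False))
    else:
        records = list(hits)
    if not records:
        return []

    def _get(r, name):
        return getattr(r, name)

    loci: list[Locus] = []
    for strand in "+-":
        strand_hits = sorted(
            (r for r in records if _get(r, "strand") == strand),
            key=lambda r: (_get(r, "start"), _get(r, "end")),
        )
        cluster: list = []
        clusters: list[list] = []
        for r in strand_hits:
            if cluster and _get(r, "start") - max(_get(c, "end") for c in cluster) > max_gap:
                clusters.append(cluster)
                cluster = []
            cluster.append(r)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            # drop hits overlapping a higher-scoring retained hit
            kept: list = []
            for r in sorted(cl, key=lambda r: (-_get(r, "score"), _get(r, "start"))):
                if all(
                    _get(r, "end") <= _get(k, "start") or _get(r, "start") >= _get(k, "end")
                    for k in kept
                ):
                    kept.append(r)
            kept.sort(key=lambda r: _get(r, "start"))
            best = min(kept, key=lambda r: (-_get(r, "score"), _get(r, "start")))
            loci.append(
                Locus(
                    species=species,
                    contig_id=contig_id,
                    nt_start=min(_get(r, "start") for r in kept),
                    nt_end=max(_get(r, "end") for r in kept),
                    strand=strand,
                    fragments=[
                        Fragment(
                            nt_start=int(_get(r, "start")),
                            nt_end=int(_get(r, "end")),
                            frame=int(_get(r, "frame")),
                            score=float(_get(r, "score")),
                        )
                        for r in kept
                    ],
                    assigned_gene=str(_get(best, "assigned_gene")),
                    assigned_group=str(_get(best, "assigned_group")),
                )
            )
    loci.sort(key=lambda l: (l.nt_start, l.nt_end, l.strand))
    return loci


# ---------------------------------------------------------------------------
# Status and intactness calls
# ---------------------------------------------------------------------------


def call_status(locus: Locus, contig_length: int, flank_threshold: int = 3000) -> str:
    """Call CVe status from flank lengths.

    ``confirmed_cve`` requires *both* flanks to strictly exceed
    ``flank_threshold`` nucleotides of host sequence (the conservative
    reading: a locus near either contig end, or spanning a short contig,
    could be assembly contamination rather than a germline insertion).
    """
    if locus.nt_end > contig_length or locus.nt_start < 0:
        raise ValueError(
            f"locus {locus.nt_start}-{locus.nt_end} exceeds contig length {contig_length}"
        )
    flank5 = locus.nt_start
    flank3 = contig_length - locus.nt_end
    locus.flank5 = flank5
    locus.flank3 = flank3
    locus.status = (
        "confirmed_cve" if min(flank5, flank3) > flank_threshold else "unconfirmed"
    )
    return locus.status


def call_intactness(locus: Locus, contig: Contig, min_len: int = 200) -> bool:
    """Judge whether coding potential is preserved across the locus.

    True iff the locus spans at least ``min_len`` nucleotides, all
    fragments lie in one reading frame (fragments in different frames
    imply a frameshifting indel between them), and the translation of the
    full locus span in that frame carries no internal stop codon (the
    final codon may be a stop).
    """
    if locus.nt_end > contig.length:
        raise ValueError("locus exceeds contig bounds")
    locus.intact = False
    if locus.span < min_len:
        return False
    frames = {f.frame for f in locus.fragments}
    if len(frames) != 1:
        return False
    frame = frames.pop()
    seq = contig.seq
    L = contig.length
    phase = abs(frame) - 1
    if frame > 0:
        lo, hi = locus.nt_start, locus.nt_end
    else:
        seq = reverse_complement(seq)
        lo, hi = L - locus.nt_end, L - locus.nt_start
    s0 = lo + ((phase - lo) % 3)
    sub = seq[s0 : s0 + 3 * ((hi - s0) // 3)]
    pep = translate_dna(sub)
    locus.intact = "*" not in pep[:-1]
    return locus.intact


# ---------------------------------------------------------------------------
# Orthology from flanking host sequence
# ---------------------------------------------------------------------------


def _oriented_flanks(locus: Locus, contig: Contig, window: int) -> tuple[str, str]:
    """Up/downstream flank windows in the locus's own orientation.

    Returns (upstream, downstream); either may be shorter than ``window``
    when the locus sits near a contig end.
    """
    before = contig.seq[max(0, locus.nt_start - window) : locus.nt_start]
    after = contig.seq[locus.nt_end : locus.nt_end + window]
    if locus.strand == "+":
        return before, after
    return reverse_complement(after), reverse_complement(before)


def flank_identity(a: str, b: str) -> float:
    """Global-alignment nucleotide identity of two flank windows."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def group_orthologs(
    loci: Sequence[Locus],
    contigs: Mapping[str, Mapping[str, Contig]],
    flank_window: int = 500,
    min_flank_identity: float = 0.7,
) -> list[OrthologGroup]:
    """Group loci descending from a single ancestral integration.

    Two loci are directly orthologous when they share gene and group and a
    same-side flank comparison (upstream-vs-upstream or
    downstream-vs-downstream, in locus orientation, over windows of
    ``flank_window`` nt) reaches ``min_flank_identity`` nucleotide
    identity.  Groups are the connected components of this relation; loci
    without a full flank window on either side become singletons.

    ``contigs`` maps species -> contig_id -> Contig.
    """
    flanks: list[tuple[str, str]] = []
    for locus in loci:
        contig = contigs[locus.species][locus.contig_id]
        flanks.append(_oriented_flanks(locus, contig, flank_window))
    g = nx.Graph()
    g.add_nodes_from(range(len(loci)))
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            if (a.assigned_gene, a.assigned_group) != (b.assigned_gene, b.assigned_group):
                continue
            linked = False
            for side in (0, 1):
                fa, fb = flanks[i][side], flanks[j][side]
                if len(fa) >= flank_window and len(fb) >= flank_window:
                    if flank_identity(fa, fb) >= min_flank_identity:
                        linked = True
                        break
            if linked:
                g.add_edge(i, j)
    groups = []
    for comp in nx.connected_components(g):
        members = [loci[i] for i in sorted(comp)]
        groups.append(OrthologGroup(members=members))
    groups.sort(
        key=lambda og: min(
            (m.species, m.contig_id, m.nt_start) for m in og.members
        )
    )
    return groups


# ---------------------------------------------------------------------------
# ID assignment
# ---------------------------------------------------------------------------


def _parse_registry(registry: pd.DataFrame | None) -> pd.DataFrame:
    if registry is None:
        return pd.DataFrame(columns=["cve_id", "species", "contig", "start", "end"])
    required = {"cve_id", "species", "contig", "start", "end"}
    missing = required - set(registry.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    return registry


def assign_cve_ids(
    groups: Sequence[OrthologGroup],
    species_codes: Mapping[str, str],
    registry: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign ``CVe-<Group>.<n>-<SpeciesCode>`` identifiers to loci.

    All members of an ortholog group share the numeric component ``n``.
    Numbers already present in ``registry`` (a table of previously issued
    ids, keyed by species/contig/start/end) are reused for matching loci;
    new numbers continue from the maximum already issued within the CVe
    group name, allocated in deterministic group order.  Returns the
    updated registry.  An id colliding with a registry entry for a
    different locus is an error.
    """
    reg = _parse_registry(registry)
    issued: dict[str, tuple[str, str, int, int]] = {}
    max_num: dict[str, int] = {}
    loc_to_id: dict[tuple[str, str, int, int], str] = {}
    for row in reg.itertuples(index=False):
        m = _CVE_ID_RE.match(row.cve_id)
        if not m:
            raise ValueError(f"malformed cve_id in registry: {row.cve_id!r}")
        key = (row.species, row.contig, int(row.start), int(row.end))
        issued[row.cve_id] = key
        loc_to_id[key] = row.cve_id
        gname = m.group("group")
        max_num[gname] = max(max_num.get(gname, 0), int(m.group("num")))

    new_rows = []
    for og in groups:
        gname = og.members[0].assigned_group
        # number reused from any member already in the registry
        nums = set()
        for m_ in og.members:
            key = (m_.species, m_.contig_id, m_.nt_start, m_.nt_end)
            if key in loc_to_id:
                parsed = _CVE_ID_RE.match(loc_to_id[key])
                nums.add(int(parsed.group("num")))
        if len(nums) > 1:
            raise ValueError(
                f"ortholog group spans registry numbers {sorted(nums)}"
            )
        if nums:
            num = nums.pop()
        else:
            num = max_num.get(gname, 0) + 1
            max_num[gname] = num
        for m_ in og.members:
            code = species_codes[m_.species]
            cve_id = f"CVe-{gname}.{num}-{code}"
            key = (m_.species, m_.contig_id, m_.nt_start, m_.nt_end)
            if cve_id in issued and issued[cve_id] != key:
                raise ValueError(
                    f"id collision: {cve_id} already issued to {issued[cve_id]}"
                )
            if cve_id in {r["cve_id"] for r in new_rows}:
                raise ValueError(
                    f"id collision within run: {cve_id} (two loci of one group "
                    f"in species {m_.species})"
                )
            m_.cve_id = cve_id
            if issued.get(cve_id) != key:
                new_rows.append(
                    {
                        "cve_id": cve_id,
                        "species": m_.species,
                        "contig": m_.contig_id,
                        "start": m_.nt_start,
                        "end": m_.nt_end,
                    }
                )
        og.numeric_id = num
    out = pd.concat([reg, pd.DataFrame(new_rows, columns=reg.columns)], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_GFF3_ESCAPE = {";": "%3B", "=": "%3D", "%": "%25", "&": "%26", ",": "%2C", "\t": "%09"}


def _gff3_escape(value: str) -> str:
    return "".join(_GFF3_ESCAPE.get(c, c) for c in str(value))


def _fragments_to_str(fragments: Sequence[Fragment]) -> str:
    return ",".join(
        f"{f.nt_start}-{f.nt_end}/{f.frame}/{f.score:g}" for f in fragments
    )


def _fragments_from_str(s: str) -> list[Fragment]:
    out = []
    for part in s.split(","):
        span, frame, score = part.split("/")
        a, b = span.split("-")
        out.append(Fragment(int(a), int(b), int(frame), float(score)))
    return out


def loci_to_table(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = [
        {
            "species": l.species,
            "contig": l.contig_id,
            "start": l.nt_start,
            "end": l.nt_end,
            "strand": l.strand,
            "assigned_gene": l.assigned_gene,
            "assigned_group": l.assigned_group,
            "flank5": l.flank5,
            "flank3": l.flank3,
            "status": l.status,
            "intact": l.intact,
            "cve_id": l.cve_id,
            "fragments": _fragments_to_str(l.fragments),
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=LOCUS_TSV_COLUMNS)


def read_loci_tsv(path: str | Path) -> list[Locus]:
    df = pd.read_csv(path, sep="\t", dtype={"cve_id": str})
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            Locus(
                species=row.species,
                contig_id=row.contig,
                nt_start=int(row.start),
                nt_end=int(row.end),
                strand=row.strand,
                fragments=_fragments_from_str(row.fragments),
                assigned_gene=row.assigned_gene,
                assigned_group=row.assigned_group,
                flank5=int(row.flank5),
                flank3=int(row.flank3),
                status=row.status,
                intact=bool(row.intact),
                cve_id=row.cve_id,
            )
        )
    return loci


def export_loci(loci: Sequence[Locus], path: str | Path, format: str = "tsv") -> None:
    """Write annotated loci as TSV (mirrors the internal table; round-trips
    through :func:`read_loci_tsv`) or GFF3 (1-based inclusive coordinates,
    feature type ``endogenous_viral_element``)."""
    path = Path(path)
    if format == "tsv":
        loci_to_table(loci).to_csv(path, sep="\t", index=False)
        return
    if format == "gff3":
        lines = ["##gff-version 3"]
        for l in loci:
            best_score = max(f.score for f in l.fragments)
            attrs = ";".join(
                f"{k}={_gff3_escape(v)}"
                for k, v in [
                    ("ID", l.cve_id if l.cve_id != "unassigned" else
                     f"{l.species}:{l.contig_id}:{l.nt_start}-{l.nt_end}"),
                    ("species", l.species),
                    ("gene", l.assigned_gene),
                    ("group", l.assigned_group),
                    ("status", l.status),
                    ("intact", str(l.intact)),
                ]
            )
            lines.append(
                "\t".join(
                    [
                        l.contig_id,
                        GFF3_SOURCE,
                        GFF3_FEATURE_TYPE,
                        str(l.nt_start + 1),
                        str(l.nt_end),
                        f"{best_score:g}",
                        l.strand,
                        ".",
                        attrs,
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Pipeline: screen results -> annotated loci
# ---------------------------------------------------------------------------


def annotate_loci(
    results: pd.DataFrame,
    assemblies: Mapping[str, str | Path | Sequence[Contig]],
    species_codes: Mapping[str, str],
    max_gap: int = 100,
    flank_threshold: int = 3000,
    min_intact_len: int = 200,
    flank_window: int = 500,
    min_flank_identity: float = 0.7,
    registry: pd.DataFrame | None = None,
) -> tuple[list[Locus], pd.DataFrame]:
    """Full annotation pass over a screen results table.

    Merges hits per (species, contig), calls status and intactness against
    the assembly sequence, groups confirmed loci into ortholog groups via
    flank identity, and assigns CVe ids.  Returns (loci, updated registry).
    """
    contigs: dict[str, dict[str, Contig]] = {}
    for species, source in assemblies.items():
        clist = (
            read_dna_fasta(source) if isinstance(source, (str, Path)) else list(source)
        )
        contigs[species] = {c.id: c for c in clist}

    loci: list[Locus] = []
    for (species, contig_id), sub in results.groupby(["species", "contig"], sort=True):
        merged = merge_hits_to_loci(sub, species=species, contig_id=contig_id, max_gap=max_gap)
        contig = contigs[species][contig_id]
        for locus in merged:
            call_status(locus, contig.length, flank_threshold)
            call_intactness(locus, contig, min_intact_len)
        loci.extend(merged)

    confirmed = [l for l in loci if l.status == "confirmed_cve"]
    groups = group_orthologs(
        confirmed, contigs, flank_window=flank_window, min_flank_identity=min_flank_identity
    )
    registry_out = assign_cve_ids(groups, species_codes, registry)
    return loci, registry_out
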