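"""Aligned multi-gene protein database.

The species database is a gene-wise multiple sequence alignment: for each of a
configured set of bone-proteome genes, every species contributes one aligned
protein sequence (over the 20 amino acids plus ``-`` for gaps).  Concatenating
the per-gene alignments in alphabetical gene order defines a single 1-based
"global site" coordinate system that is shared by all species, so that peptide
evidence from any species can be compared at homologous positions.

This module parses the database from FASTA (UniProt or pseudo-UniProt headers
carrying ``OS=``/``OX=``/``GN=`` tags), collapses isoforms, filters species
with too many missing genes, and builds the global site index, per-residue
site maps, and the site-specific species difference matrix that downstream
species competition is scored on.
"""

from __future__ import annotations

import io
import logging
import re
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

GAP = "-"
GAP_CODE = ord(GAP)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DECOY_PREFIX = "DECOY_"

#: Default gene panel: the most abundant protein-coding genes of the bone
#: proteome (collagens plus major non-collagenous bone proteins).  The panel
#: is configurable; any ``GN=`` value outside it is rejected at parse time.
BONE_GENES: tuple[str, ...] = (
    "AHSG", "ALB", "APOA1", "BGN", "CHAD", "COL1A1", "COL1A2", "COL3A1",
    "COL5A1", "COL5A2", "COL11A1", "DCN", "FN1", "IBSP", "LUM", "OMD",
    "PCOLCE", "SERPINC1", "SPP1", "VIM",
)

_VALID_CHARS = set(AMINO_ACIDS) | {GAP}

_OS_RE = re.compile(r"\bOS\s*=\s*(.*?)\s*(?=\b(?:OX|GN|PE|SV)\s*=|$)")
_OX_RE = re.compile(r"\bOX\s*=\s*(\d+)")
_GN_RE = re.compile(r"\bGN\s*=\s*(\S+)")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: an aligned protein sequence for (species, gene)."""

    accession: str
    gene: str
    species: str
    taxon_id: int | None
    source: str  # uniprot | ncbi | uniref-annotated | manual
    aligned_seq: str


def parse_header(description: str) -> dict:
    """Extract accession/species/taxon/gene/source from a FASTA description.

    Understands UniProt headers (``sp|P02453|CO1A1_BOVIN ... OS=Bos taurus
    OX=9913 GN=COL1A1``) and the pipe-separated pseudo-UniProt dialect
    (``NCBI | XP_1 | XP_1_COL1A1 ... OS = Bos taurus OX = 9913 GN = COL1A1``).
    """
    os_m = _OS_RE.search(description)
    ox_m = _OX_RE.search(description)
    gn_m = _GN_RE.search(description)
    head = description.split("OS")[0]
    if "|" in head:
        parts = [p.strip() for p in head.split("|")]
        accession = parts[1] if len(parts) > 1 and parts[1] else parts[0]
        tag = parts[0].strip().lower()
        if tag == "ncbi":
            source = "ncbi"
        elif tag in ("sp", "tr"):
            source = "uniprot"
        elif "uniref" in tag:
            source = "uniref-annotated"
        else:
            source = "manual"
    else:
        accession = head.split()[0] if head.split() else description
        source = "manual"
    return {
        "accession": accession,
        "species": os_m.group(1).strip() if os_m else None,
        "taxon_id": int(ox_m.group(1)) if ox_m else None,
        "gene": gn_m.group(1).strip() if gn_m else None,
        "source": source,
    }


@dataclass
class SpeciesDatabase:
    """Gene-wise aligned sequences, one representative per (gene, species).

    ``gene_alignments`` maps gene -> species -> aligned sequence.  Species
    whose name starts with ``decoy_prefix`` are chimeric decoys; they behave
    exactly like targets in coordinate mapping, the difference matrix, and
    competition, and are exempt from the gene-count filter.
    """

    gene_alignments: dict[str, dict[str, str]]
    gene_set: tuple[str, ...] = BONE_GENES
    taxon_ids: dict[str, int | None] = field(default_factory=dict)
    decoy_prefix: str = DECOY_PREFIX

    @property
    def gene_order(self) -> list[str]:
        return sorted(self.gene_alignments)

    def species(self) -> list[str]:
        roster: set[str] = set()
        for seqs in self.gene_alignments.values():
            roster.update(seqs)
        return sorted(roster)

    def target_species(self) -> list[str]:
        return [s for s in self.species() if not self.is_decoy(s)]

    def decoy_species(self) -> list[str]:
        return [s for s in self.species() if self.is_decoy(s)]

    def is_decoy(self, species: str) -> bool:
        return species.startswith(self.decoy_prefix)

    def alignment_length(self, gene: str) -> int:
        seqs = self.gene_alignments[gene]
        return len(next(iter(seqs.values())))

    def gene_count(self, species: str) -> int:
        return sum(1 for seqs in self.gene_alignments.values() if species in seqs)

    def concat(self, species: str) -> str:
        """Full-length aligned concatenation over genes in alphabetical order.

        Genes missing for the species are filled with gaps, so every species
        yields a string of the same total length.
        """
        parts = []
        for gene in self.gene_order:
            seqs = self.gene_alignments[gene]
            parts.append(seqs.get(species, GAP * self.alignment_length(gene)))
        return "".join(parts)

    def validate(self) -> None:
        for gene, seqs in self.gene_alignments.items():
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                raise ValueError(
                    f"unequal aligned lengths within gene {gene}: {sorted(lengths)}"
                )
            if not seqs:
                raise ValueError(f"gene {gene} has no sequences")

    def copy(self) -> "SpeciesDatabase":
        return SpeciesDatabase(
            gene_alignments={g: dict(s) for g, s in self.gene_alignments.items()},
            gene_set=self.gene_set,
            taxon_ids=dict(self.taxon_ids),
            decoy_prefix=self.decoy_prefix,
        )


def _sanitize(seq: str) -> tuple[str, int]:
    """Upper-case and map characters outside the 20 amino acids + '-' to gaps."""
    seq = seq.upper()
    bad = sum(1 for c in seq if c not in _VALID_CHARS)
    if bad:
        seq = "".join(c if c in _VALID_CHARS else GAP for c in seq)
    return seq, bad


def _collapse_isoforms(seqs: list[str]) -> str:
    """Per-column majority consensus over isoforms.

    A column becomes a gap when more than half of the isoforms have a gap
    there; otherwise the most frequent amino acid wins, ties broken
    alphabetically.
    """
    if len(seqs) == 1:
        return seqs[0]
    arr = np.array([list(s) for s in seqs])
    out = []
    n = len(seqs)
    for col in arr.T:
        counts = Counter(col)
        if counts.get(GAP, 0) * 2 > n:
            out.append(GAP)
            continue
        aa_counts = {aa: c for aa, c in counts.items() if aa != GAP}
        if not aa_counts:
            out.append(GAP)
            continue
        out.append(min(aa_counts, key=lambda a: (-aa_counts[a], a)))
    return "".join(out)


def parse_database(
    fasta,
    gene_set: tuple[str, ...] = BONE_GENES,
    decoy_prefix: str = DECOY_PREFIX,
) -> SpeciesDatabase:
    """Parse an aligned multi-FASTA into a :class:`SpeciesDatabase`.

    ``fasta`` may be a path, raw FASTA text, or an open handle.  Records
    lacking ``OS=`` or ``GN=`` tags, or with a gene outside ``gene_set``, are
    rejected with a logged warning.  Multiple records per (species, gene) are
    collapsed to a per-column majority consensus.  Unequal aligned lengths
    within a gene raise ``ValueError``.
    """
    if hasattr(fasta, "read"):
        handle = fasta
    else:
        text = str(fasta)
        if not text or text.lstrip().startswith(">") or "\n" in text:
            handle = io.StringIO(text)
        else:
            handle = open(text)

    gene_names = set(gene_set)
    raw: dict[tuple[str, str], list[str]] = {}
    taxon_ids: dict[str, int | None] = {}
    rejected = 0
    sanitized = 0
    for rec in SeqIO.parse(handle, "fasta"):
        meta = parse_header(rec.description)
        if not meta["species"] or not meta["gene"]:
            log.warning("rejecting record %r: missing OS= or GN= tag", rec.id)
            rejected += 1
            continue
        if meta["gene"] not in gene_names:
            log.warning(
                "rejecting record %r: unknown gene %r", rec.id, meta["gene"]
            )
            rejected += 1
            continue
        seq, bad = _sanitize(str(rec.seq))
        sanitized += bad
        if not seq:
            rejected += 1
            continue
        raw.setdefault((meta["species"], meta["gene"]), []).append(seq)
        if meta["taxon_id"] is not None:
            taxon_ids[meta["species"]] = meta["taxon_id"]
    if not hasattr(fasta, "read"):
        handle.close()
    if sanitized:
        log.warning("converted %d non-standard residues to gaps", sanitized)
    if rejected:
        log.warning("rejected %d records during parsing", rejected)

    gene_alignments: dict[str, dict[str, str]] = {}
    for (species, gene), seqs in raw.items():
        if len({len(s) for s in seqs}) > 1:
            raise ValueError(
                f"unequal aligned lengths within gene {gene} for species {species}"
            )
        gene_alignments.setdefault(gene, {})[species] = _collapse_isoforms(seqs)

    db = SpeciesDatabase(
        gene_alignments=gene_alignments,
        gene_set=tuple(gene_set),
        taxon_ids=taxon_ids,
        decoy_prefix=decoy_prefix,
    )
    db.validate()
    return db


def normalize_il(obj):
    """Replace every isoleucine by leucine (I and L are isobaric in MS).

    Accepts a string or a :class:`SpeciesDatabase` and returns the same type.
    """
    if isinstance(obj, SpeciesDatabase):
        out = obj.copy()
        for gene, seqs in out.gene_alignments.items():
            out.gene_alignments[gene] = {
                sp: s.replace("I", "L") for sp, s in seqs.items()
            }
        return out
    return str(obj).replace("I", "L")


def filter_by_gene_count(
    db: SpeciesDatabase, max_missing: int = 5
) -> tuple[SpeciesDatabase, pd.DataFrame]:
    """Remove target species lacking more than ``max_missing`` genes.

    Presence is counted against the genes the database actually covers (the
    full 20-gene panel in the reference configuration), so a species needs
    at least ``n_genes - max_missing`` of them to survive.  Decoy species
    are exempt (they are generated after filtering).  Returns the filtered
    database and a removal report.
    """
    n_genes = len(db.gene_alignments)
    rows = []
    removed: set[str] = set()
    for sp in db.species():
        n = db.gene_count(sp)
        missing = n_genes - n
        drop = missing > max_missing and not db.is_decoy(sp)
        rows.append(
            {"species": sp, "genes_present": n, "genes_missing": missing,
             "removed": drop}
        )
        if drop:
            removed.add(sp)
    out = db.copy()
    for gene in list(out.gene_alignments):
        out.gene_alignments[gene] = {
            sp: s for sp, s in out.gene_alignments[gene].items() if sp not in removed
        }
        if not out.gene_alignments[gene]:
            del out.gene_alignments[gene]
    report = pd.DataFrame(rows, columns=["species", "genes_present",
                                         "genes_missing", "removed"])
    return out, report


@dataclass
class GlobalSiteIndex:
    """1-based global coordinates over the alphabetical gene concatenation."""

    gene_order: tuple[str, ...]
    gene_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.offsets: dict[str, int] = {}
        off = 0
        for g in self.gene_order:
            self.offsets[g] = off
            off += self.gene_lengths[g]
        self.total_length = off
        self._bounds = np.cumsum([self.gene_lengths[g] for g in self.gene_order])

    def site(self, gene: str, column: int) -> int:
        """Global site of a 1-based alignment column within ``gene``."""
        if not 1 <= column <= self.gene_lengths[gene]:
            raise IndexError(f"column {column} outside gene {gene}")
        return self.offsets[gene] + column

    def locate(self, site: int) -> tuple[str, int]:
        """Inverse map: global site -> (gene, 1-based column)."""
        if not 1 <= site <= self.total_length:
            raise IndexError(f"site {site} outside 1..{self.total_length}")
        gi = bisect_right(self._bounds.tolist(), site - 1)
        gene = self.gene_order[gi]
        return gene, site - self.offsets[gene]


def build_global_index(db: SpeciesDatabase) -> GlobalSiteIndex:
    """Number every alignment column 1..L, genes in alphabetical order."""
    return GlobalSiteIndex(
        gene_order=tuple(db.gene_order),
        gene_lengths={g: db.alignment_length(g) for g in db.gene_order},
    )


def build_residue_maps(
    db: SpeciesDatabase, index: GlobalSiteIndex
) -> dict[tuple[str, str], np.ndarray]:
    """For each (species, gene): gapless residue index -> global site.

    Entry k (0-based) of the array is the global site of the (k+1)-th non-gap
    character of the species' aligned sequence for that gene.
    """
    maps: dict[tuple[str, str], np.ndarray] = {}
    for gene in db.gene_order:
        off = index.offsets[gene]
        for sp, seq in db.gene_alignments[gene].items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            maps[(sp, gene)] = np.flatnonzero(arr != GAP_CODE) + off + 1
    return maps


def gapless_sequences(db: SpeciesDatabase) -> dict[tuple[str, str], str]:
    """Aligned sequences with gaps stripped, keyed by (species, gene)."""
    out = {}
    for gene in db.gene_order:
        for sp, seq in db.gene_alignments[gene].items():
            g = seq.replace(GAP, "")
            if g:
                out[(sp, gene)] = g
    return out


class SiteDifferenceMatrix:
    """Per unordered species pair, the discriminating global sites.

    For each pair {A, B} the matrix lists (site, aa_A, aa_B) at every global
    site where the two species carry different amino acids and neither has a
    gap.  Stored internally as numpy arrays keyed by the alphabetically
    sorted pair.
    """

    def __init__(
        self,
        species: list[str],
        entries: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]],
    ):
        self.species = list(species)
        self._entries = entries

    def pairs(self):
        return self._entries.keys()

    def diff(self, a: str, b: str) -> list[tuple[int, str, str]]:
        """Differences oriented as (site, aa of ``a``, aa of ``b``)."""
        key = (a, b) if a <= b else (b, a)
        sites, ca, cb = self._entries[key]
        if key != (a, b):
            ca, cb = cb, ca
        return [
            (int(s), chr(x), chr(y)) for s, x, y in zip(sites, ca, cb)
        ]

    def arrays(self, a: str, b: str):
        """(sites, aa codes of a, aa codes of b) as numpy arrays (ASCII codes)."""
        key = (a, b) if a <= b else (b, a)
        sites, ca, cb = self._entries[key]
        if key != (a, b):
            ca, cb = cb, ca
        return sites, ca, cb

    def n_diff(self, a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        return len(self._entries[key][0])

    def summary(self) -> pd.DataFrame:
        rows = [
            {"species_a": a, "species_b": b, "n_differences": len(v[0])}
            for (a, b), v in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["species_a", "species_b", "n_differences"])


def build_difference_matrix(
    db: SpeciesDatabase, index: GlobalSiteIndex
) -> SiteDifferenceMatrix:
    """Compare every unordered species pair column by column.

    Sites where either species has a gap (including missing genes, which are
    gap-filled) are ignored.
    """
    species = db.species()
    mats = {
        sp: np.frombuffer(db.concat(sp).encode("ascii"), dtype=np.uint8)
        for sp in species
    }
    entries = {}
    for i, a in enumerate(species):
        va = mats[a]
        a_ok = va != GAP_CODE
        for b in species[i + 1:]:
            vb = mats[b]
            mask = (va != vb) & a_ok & (vb != GAP_CODE)
            idx = np.flatnonzero(mask)
            entries[(a, b)] = (idx + 1, va[idx].copy(), vb[idx].copy())
    return SiteDifferenceMatrix(species, entries)


def _fasta_header(db: SpeciesDatabase, species: str, gene: str) -> str:
    ox = db.taxon_ids.get(species)
    ox_part = f" OX = {ox}" if ox is not None else ""
    return (
        f"TAXOPEP | {species}_{gene} | {species}_{gene} {gene} protein"
        f" OS = {species}{ox_part} GN = {gene}"
    )


def write_aligned_fasta(db: SpeciesDatabase, path) -> None:
    """Write the gene-wise aligned database (gap characters preserved)."""
    with open(path, "w") as fh:
        for gene in db.gene_order:
            for sp in sorted(db.gene_alignments[gene]):
                fh.write(f">{_fasta_header(db, sp, gene)}\n")
                fh.write(db.gene_alignments[gene][sp] + "\n")


def write_gapless_fasta(db: SpeciesDatabase, path) -> None:
    """Write the gap-stripped database for use in search engines."""
    with open(path, "w") as fh:
        for gene in db.gene_order:
            for sp in sorted(db.gene_alignments[gene]):
                seq = db.gene_alignments[gene][sp].replace(GAP, "")
                if seq:
                    fh.write(f">{_fasta_header(db, sp, gene)}\n")
                    fh.write(seq + "\n")
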