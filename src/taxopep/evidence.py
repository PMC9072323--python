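"""Reading and annotating peptide-precursor evidence tables.

Two search-engine dialects are supported: MaxQuant ``evidence.txt`` (DDA,
already filtered to 1% precursor FDR by the search engine, no q-value
column) and a Spectronaut-style report (DIA, with an explicit precursor
q-value column).  Both are reduced to one logical schema; a precursor is a
unique (raw file, modified sequence, charge) and a peptide is the unique
stripped sequence.

Precursors are annotated against the combined target+decoy database by exact
substring matching of the I->L-normalized stripped sequence in every species'
gapless gene sequences; matches are translated to covered global sites via
the residue maps.  Protease (trypsin/LysC autolysis) and other contaminant
precursors are flagged: they never contribute to site observations but are
kept in the table because they count toward total intensity — the protease
signal is treated as a spike-in standard downstream.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .db import GAP, SpeciesDatabase, gapless_sequences

log = logging.getLogger(__name__)

LOGICAL_COLUMNS = [
    "raw_file", "stripped_seq", "modified_seq", "charge",
    "intensity", "score", "precursor_q",
]


@dataclass(frozen=True)
class EvidenceDialect:
    """Column-name mapping from a search-engine table to the logical schema."""

    name: str
    raw_file: str
    sequence: str
    modified_sequence: str
    charge: str
    intensity: str
    score: str
    q_value: str | None = None
    proteins: str | None = None

    def required(self) -> list[str]:
        cols = [self.raw_file, self.sequence, self.modified_sequence,
                self.charge, self.intensity, self.score]
        if self.q_value:
            cols.append(self.q_value)
        return cols


MAXQUANT_EVIDENCE = EvidenceDialect(
    name="maxquant_evidence",
    raw_file="Raw file",
    sequence="Sequence",
    modified_sequence="Modified sequence",
    charge="Charge",
    intensity="Intensity",
    score="Score",
    q_value=None,
    proteins="Proteins",
)

SPECTRONAUT_REPORT = EvidenceDialect(
    name="spectronaut_report",
    raw_file="R.FileName",
    sequence="PEP.StrippedSequence",
    modified_sequence="EG.ModifiedSequence",
    charge="FG.Charge",
    intensity="FG.Quantity",
    score="EG.Cscore",
    q_value="EG.Qvalue",
    proteins="PG.ProteinAccessions",
)

DIALECTS = {d.name: d for d in (MAXQUANT_EVIDENCE, SPECTRONAUT_REPORT)}


def read_evidence(table, dialect="maxquant_evidence", sep: str = "\t") -> pd.DataFrame:
    """Read a precursor table into the logical schema.

    ``dialect`` is a dialect name or an :class:`EvidenceDialect`.  Duplicate
    precursor identities (raw file, modified sequence, charge) are merged by
    summing intensity and taking the maximum score.  Missing intensities
    become 0; rows with unparsable charge are dropped with a warning count.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown evidence dialect: {dialect!r}") from None
    df = pd.read_csv(table, sep=sep, dtype=str)
    missing = [c for c in dialect.required() if c not in df.columns]
    if missing:
        raise ValueError(
            f"evidence table lacks required column(s) {missing} "
            f"for dialect {dialect.name}"
        )
    out = pd.DataFrame(
        {
            "raw_file": df[dialect.raw_file].astype(str),
            "stripped_seq": df[dialect.sequence].astype(str).str.upper()
            .str.replace("I", "L", regex=False),
            "modified_seq": df[dialect.modified_sequence].astype(str),
            "charge": pd.to_numeric(df[dialect.charge], errors="coerce"),
            "intensity": pd.to_numeric(df[dialect.intensity], errors="coerce"),
            "score": pd.to_numeric(df[dialect.score], errors="coerce"),
            "precursor_q": (
                pd.to_numeric(df[dialect.q_value], errors="coerce")
                if dialect.q_value
                else np.nan
            ),
        }
    )
    n0 = len(out)
    out = out[out["charge"].notna() & (out["stripped_seq"].str.len() > 0)]
    skipped = n0 - len(out)
    if skipped:
        log.warning("skipped %d unparsable evidence rows", skipped)
    out["charge"] = out["charge"].astype(int)
    out["intensity"] = out["intensity"].fillna(0.0).clip(lower=0.0)
    out["score"] = out["score"].fillna(0.0)
    merged = (
        out.groupby(["raw_file", "modified_seq", "charge"], as_index=False, sort=True)
        .agg(
            stripped_seq=("stripped_seq", "first"),
            intensity=("intensity", "sum"),
            score=("score", "max"),
            precursor_q=("precursor_q", "min"),
        )
    )
    return merged[LOGICAL_COLUMNS]


def filter_precursor_fdr(records: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Drop precursors with q-value above ``alpha``; absent q passes."""
    q = records["precursor_q"]
    return records[q.isna() | (q <= alpha)].reset_index(drop=True)


@dataclass
class ContaminantSet:
    """I->L-normalized contaminant sequences split into protease and other."""

    protease: list[tuple[str, str]] = field(default_factory=list)  # (name, seq)
    other: list[tuple[str, str]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.protease or self.other)


PROTEASE_KEYWORDS = ("trypsin", "lys-c", "lysc", "protease")


def load_contaminants(fasta) -> ContaminantSet:
    """Read a contaminant FASTA; entries whose header mentions trypsin/LysC
    (or an explicit 'protease' tag) are classed as protease."""
    if hasattr(fasta, "read"):
        handle = fasta
    else:
        text = str(fasta)
        handle = io.StringIO(text) if text.lstrip().startswith(">") else open(text)
    cs = ContaminantSet()
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper().replace("I", "L").replace(GAP, "")
        desc = rec.description.lower()
        if any(k in desc for k in PROTEASE_KEYWORDS):
            cs.protease.append((rec.id, seq))
        else:
            cs.other.append((rec.id, seq))
    if not hasattr(fasta, "read"):
        handle.close()
    return cs


def flag_contaminants(records: pd.DataFrame, contaminants: ContaminantSet) -> pd.DataFrame:
    """Add ``is_protease`` / ``is_contaminant`` flags by substring matching."""
    out = records.copy()
    if not contaminants:
        log.warning("empty contaminant database: no precursors flagged")
        out["is_protease"] = False
        out["is_contaminant"] = False
        return out
    prot_seqs = [s for _, s in contaminants.protease]
    other_seqs = [s for _, s in contaminants.other]
    cache_p: dict[str, bool] = {}
    cache_c: dict[str, bool] = {}
    for pep in out["stripped_seq"].unique():
        cache_p[pep] = any(pep in s for s in prot_seqs)
        cache_c[pep] = cache_p[pep] or any(pep in s for s in other_seqs)
    out["is_protease"] = out["stripped_seq"].map(cache_p)
    out["is_contaminant"] = out["stripped_seq"].map(cache_c)
    return out


@dataclass
class PeptideAnnotation:
    """Database matches of one stripped peptide sequence.

    ``sites``/``aas`` are parallel arrays of the distinct (global site,
    amino acid) pairs covered by the peptide, unioned over all matching
    species (a site covered via several species counts once).
    """

    species: frozenset
    genes: frozenset
    sites: np.ndarray  # int64 global sites
    aas: np.ndarray    # uint8 ASCII codes


class _SpeciesText:
    """Concatenated gapless gene sequences of one species with '|' separators,
    plus the parallel global-site array, for fast multi-gene substring scans."""

    def __init__(self, species, genes, seqs, maps):
        self.species = species
        parts, sites, gene_of = [], [], []
        for gene in genes:
            seq = seqs.get((species, gene))
            if not seq:
                continue
            parts.append(seq)
            sites.append(maps[(species, gene)])
            gene_of.append((gene, len(seq)))
            parts.append("|")
            sites.append(np.zeros(1, dtype=np.int64))
            gene_of.append((None, 1))
        self.text = "".join(parts)
        self.sites = (
            np.concatenate(sites) if sites else np.zeros(0, dtype=np.int64)
        )
        # gene label per character position
        labels = []
        for gene, n in gene_of:
            labels.extend([gene] * n)
        self.gene_at = labels

    def find_all(self, pep: str):
        start = self.text.find(pep)
        while start != -1:
            yield start
            start = self.text.find(pep, start + 1)


def annotate_precursors(
    records: pd.DataFrame,
    db: SpeciesDatabase,
    residue_maps: dict[tuple[str, str], np.ndarray],
) -> tuple[pd.DataFrame, dict[str, PeptideAnnotation]]:
    """Match every non-contaminant stripped sequence against the database.

    Returns the records with ``matched_species``/``matched_genes``/
    ``n_matched_species`` columns added, and a per-peptide annotation map
    carrying the covered (site, amino acid) pairs.  Records with zero matches
    keep empty annotation but remain in the table.  The database must be
    I->L normalized, as the reader already normalizes peptide sequences.
    """
    seqs = gapless_sequences(db)
    genes = db.gene_order
    texts = [
        _SpeciesText(sp, genes, seqs, residue_maps) for sp in db.species()
    ]

    if "is_contaminant" in records.columns:
        contaminant = dict(
            records.groupby("stripped_seq")["is_contaminant"].any()
        )
    else:
        contaminant = {}

    annotations: dict[str, PeptideAnnotation] = {}
    empty = PeptideAnnotation(
        frozenset(), frozenset(),
        np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.uint8),
    )
    for pep in sorted(set(records["stripped_seq"])):
        if contaminant.get(pep, False):
            annotations[pep] = empty
            continue
        pep_codes = np.frombuffer(pep.encode("ascii"), dtype=np.uint8)
        sp_hits, gene_hits = set(), set()
        site_chunks, aa_chunks = [], []
        for st in texts:
            for start in st.find_all(pep):
                sp_hits.add(st.species)
                gene_hits.add(st.gene_at[start])
                site_chunks.append(st.sites[start: start + len(pep)])
                aa_chunks.append(pep_codes)
        if not sp_hits:
            annotations[pep] = empty
            continue
        sites = np.concatenate(site_chunks)
        aas = np.concatenate(aa_chunks)
        pairs = np.unique(np.stack([sites, aas.astype(np.int64)]), axis=1)
        annotations[pep] = PeptideAnnotation(
            species=frozenset(sp_hits),
            genes=frozenset(gene_hits),
            sites=pairs[0],
            aas=pairs[1].astype(np.uint8),
        )

    out = records.copy()
    out["matched_species"] = out["stripped_seq"].map(
        lambda p: ";".join(sorted(annotations[p].species))
    )
    out["matched_genes"] = out["stripped_seq"].map(
        lambda p: ";".join(sorted(annotations[p].genes))
    )
    out["n_matched_species"] = out["stripped_seq"].map(
        lambda p: len(annotations[p].species)
    )
    return out, annotations
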