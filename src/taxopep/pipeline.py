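"""End-to-end species inference over a study cohort.

All raw files of a study are processed together — the decoy q-value is a
cohort-level quantity, so adding or removing files changes every file's q.
The pipeline: normalize the database (I->L), drop species with too many
missing genes, extend with chimeric decoys, build the global site index and
difference matrix, read/filter/annotate the evidence, aggregate to site
level and compute J-scores, run the species competition per file, refine by
fine-grouping, and apply the two confidence thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import qc as _qc
from .compete import (
    COMPETITION_COLUMNS,
    PairScorer,
    best_match as _best_match,
    fine_group as _fine_group,
    load_marker_table as _load_marker_table,
)
from .db import (
    BONE_GENES,
    SpeciesDatabase,
    build_difference_matrix,
    build_global_index,
    build_residue_maps,
    filter_by_gene_count,
    normalize_il,
)
from .decoys import generate_decoys
from .evidence import (
    ContaminantSet,
    annotate_precursors,
    filter_precursor_fdr,
    flag_contaminants,
    load_contaminants,
)
from .sites import aggregate_sites, score_sites

log = logging.getLogger(__name__)

FLAG_BLANK = "blank"
FLAG_SIGNAL = "signal_too_low"
FLAG_FDR = "above_fdr_threshold"


@dataclass
class PipelineParams:
    """Tunable parameters of a study run (defaults follow the method)."""

    gene_set: tuple[str, ...] = BONE_GENES
    max_missing_genes: int = 5
    slice_len: int = 500
    n_decoys: int | None = None  # None -> one decoy per target species
    fdr_alpha: float = 0.01      # precursor-level q-value threshold
    q_threshold: float = 0.01    # species-level (decoy) q-value threshold
    seed: int = 0
    manual_protease_cutoff: float | None = None
    decoy_prefix: str = "DECOY_"


@dataclass
class StudyResult:
    """All artifacts of one cohort run."""

    results: pd.DataFrame
    site_scores: pd.DataFrame
    competition: pd.DataFrame
    consensus: dict[str, pd.Series]
    protease_cutoff: float
    db: SpeciesDatabase          # filtered targets + decoys, I->L normalized
    index: object
    decoy_provenance: pd.DataFrame
    removal_report: pd.DataFrame


def run_study(
    db: SpeciesDatabase,
    evidence: pd.DataFrame,
    contaminants: ContaminantSet | str | None = None,
    sample_annotations: pd.DataFrame | None = None,
    marker_table: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
) -> StudyResult:
    """Run the full species-inference pipeline on a cohort.

    ``evidence`` is a logical-schema precursor table spanning all raw files
    (see :mod:`taxopep.evidence`); ``sample_annotations`` marks laboratory
    blanks (columns ``raw_file``, ``is_blank``).  ``contaminants`` is a
    :class:`ContaminantSet` or a FASTA path/text.
    """
    params = params or PipelineParams()

    # --- database side ---------------------------------------------------
    db = normalize_il(db)
    db, removal_report = filter_by_gene_count(db, params.max_missing_genes)
    if not db.target_species():
        raise ValueError("no target species left after gene-count filtering")
    index = build_global_index(db)
    db, decoy_provenance = generate_decoys(
        db, index,
        slice_len=params.slice_len,
        n_decoys=params.n_decoys,
        seed=params.seed,
        prefix=params.decoy_prefix,
    )
    residue_maps = build_residue_maps(db, index)
    diff = build_difference_matrix(db, index)
    scorer = PairScorer(diff)
    concat = {sp: db.concat(sp) for sp in db.species()}

    # --- evidence side ---------------------------------------------------
    if contaminants is None:
        contaminants = ContaminantSet()
    elif not isinstance(contaminants, ContaminantSet):
        contaminants = load_contaminants(contaminants)
    records = filter_precursor_fdr(evidence, params.fdr_alpha)
    records = flag_contaminants(records, contaminants)
    records, annotations = annotate_precursors(records, db, residue_maps)
    site_scores = score_sites(aggregate_sites(records, annotations))

    if marker_table is not None:
        marker_table = _load_marker_table(marker_table, db=db)

    blanks: set[str] = set()
    if sample_annotations is not None:
        ann = sample_annotations
        blanks = set(ann.loc[ann["is_blank"].astype(bool), "raw_file"])

    raw_files = sorted(set(evidence["raw_file"]))

    # --- per-file inference ----------------------------------------------
    comp_frames = []
    consensus: dict[str, pd.Series] = {}
    rows = []
    site_by_file = dict(tuple(site_scores.groupby("raw_file", sort=False)))
    empty_sites = site_scores.iloc[0:0]
    for rf in raw_files:
        fs = site_by_file.get(rf, empty_sites)
        comp = scorer.score_file(rf, fs)
        comp_frames.append(comp)
        best = _best_match(comp)
        frecs = records[records["raw_file"] == rf]
        fine = _fine_group(frecs, marker_table, best)
        final = fine if fine else best
        sc = _qc.site_count(fs, final, concat)
        rel_prot = _qc.relative_protease_intensity(frecs)
        deam = _qc.deamidation_fractions(frecs)
        consensus[rf] = _qc.consensus_sequence(fs)
        decoy_only = bool(final) and all(db.is_decoy(sp) for sp in final)
        rows.append(
            {
                "raw_file": rf,
                "species": ";".join(sorted(final)),
                "best_match": ";".join(sorted(best)),
                "fine_group": ";".join(sorted(fine)) if fine != best else "",
                "n_species": len(final),
                "is_decoy_only": decoy_only,
                "site_count": sc,
                "rel_protease_intensity": rel_prot,
                "n_precursors": int(len(frecs)),
                "total_intensity": float(frecs["intensity"].sum()),
                "deamidation_N": deam["N"],
                "deamidation_Q": deam["Q"],
                "is_blank": rf in blanks,
            }
        )
    results = pd.DataFrame(rows)

    # --- confidence thresholds -------------------------------------------
    if blanks:
        cutoff = _qc.protease_cutoff(
            results.loc[results["is_blank"], "rel_protease_intensity"]
        )
    elif params.manual_protease_cutoff is not None:
        cutoff = float(params.manual_protease_cutoff)
    else:
        raise ValueError(
            "no laboratory blanks annotated and no manual protease cutoff "
            "configured: cannot calibrate the signal threshold"
        )
    # tolerance guards against summation-order jitter between files whose
    # ratios are identical by construction (e.g. pure-protease blanks)
    results["signal_too_low"] = (
        results["rel_protease_intensity"] >= cutoff - 1e-9
    )
    results = _qc.compute_qvalues(results, alpha=params.q_threshold)

    def _flags(row) -> str:
        f = []
        if row["is_blank"]:
            f.append(FLAG_BLANK)
        if row["signal_too_low"]:
            f.append(FLAG_SIGNAL)
        if row["above_fdr_threshold"]:
            f.append(FLAG_FDR)
        return ",".join(f)

    results["flags"] = results.apply(_flags, axis=1)
    columns = [
        "raw_file", "species", "best_match", "fine_group", "n_species",
        "is_decoy_only", "site_count", "q_value", "q_value_raw",
        "rel_protease_intensity", "signal_too_low", "above_fdr_threshold",
        "is_blank", "flags", "n_precursors", "total_intensity",
        "deamidation_N", "deamidation_Q",
    ]
    results = results[columns]
    competition = (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(columns=COMPETITION_COLUMNS)
    )
    return StudyResult(
        results=results,
        site_scores=site_scores,
        competition=competition,
        consensus=consensus,
        protease_cutoff=cutoff,
        db=db,
        index=index,
        decoy_provenance=decoy_provenance,
        removal_report=removal_report,
    )


def write_consensus_fasta(result: StudyResult, path) -> None:
    """Write per-file consensus sequences as a full-length aligned FASTA."""
    L = result.index.total_length
    with open(path, "w") as fh:
        for rf in sorted(result.consensus):
            fh.write(f">{rf} consensus OS = {rf}\n")
            fh.write(_qc.consensus_string(result.consensus[rf], L) + "\n")
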