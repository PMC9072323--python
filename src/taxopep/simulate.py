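"""Synthetic databases and synthetic precursor evidence.

The simulator makes the whole inference pipeline testable without any mass
spectrometry: it evolves a gene-wise aligned protein database along a random
bifurcating tree, digests a chosen "true" species in silico (tryptic with
missed cleavages and optional semi-tryptic truncation, as in degraded bone),
and emits precursor tables in both supported search-engine dialects with
log-normal intensities, search-engine-like scores, deamidation annotations,
protease autolysis contamination at a controllable relative intensity, and
protease-dominated laboratory blanks.

What it emulates — and what it does not: peptides carry realistic counts,
intensities and scores, but there is no spectrum-level physics (no m/z,
retention time, interference or chromatographic effects), the substitution
model is uniform per site without rate heterogeneity, and simulated
alignments contain no insertions, so gaps arise only from missing genes.

Every draw comes from one seeded generator; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .db import AMINO_ACIDS, GAP, SpeciesDatabase, build_global_index, build_residue_maps

log = logging.getLogger(__name__)

#: cleave after K or R, not before P
TRYPSIN_RULE = r"[KR](?!P)"

_SYNTH_GENES = ("ALB", "BGN", "COL1A1", "COL1A2", "COL3A1", "LUM", "SPP1", "VIM")


@dataclass
class SimulationConfig:
    """Everything the simulator needs; the seed fully determines the output."""

    seed: int = 0
    n_species: int = 30
    gene_names: tuple[str, ...] = _SYNTH_GENES
    gene_lengths: tuple[int, ...] = (375,) * 8
    divergence: float = 0.04          # mean per-site substitution prob per branch
    missing_gene_rate: float = 0.03   # per (species, gene) drop probability
    true_species: str | None = None   # None -> drawn per file; "novel" -> held out
    target_site_coverage: int = 1000  # distinct sites of the true species to cover
    p_semitryptic: float = 0.3
    peptide_length: tuple[int, int] = (7, 30)
    max_missed_cleavages: int = 2
    intensity_meanlog: float = math.log(1e6)
    intensity_sdlog: float = 1.2
    score_mean: float = 100.0
    score_sd: float = 30.0
    score_min: float = 40.0           # MaxQuant-like minimum identification score
    deamidation_prob: float = 0.1     # per N/Q residue per precursor
    second_charge_prob: float = 0.2   # chance of observing charge 3 alongside 2
    protease_relative_intensity: float = 0.1
    n_noise_peptides: int = 20
    n_fdr_fail: int = 5               # precursors with q above the 1% threshold

    def validate(self) -> None:
        for name in ("missing_gene_rate", "p_semitryptic", "deamidation_prob",
                     "second_charge_prob", "protease_relative_intensity",
                     "second_charge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if len(self.gene_names) != len(self.gene_lengths):
            raise ValueError("gene_names and gene_lengths differ in length")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# database simulation

def _evolve(root: np.ndarray, n_leaves: int, divergence: float,
            rng: np.random.Generator) -> list[np.ndarray]:
    """Recursively bifurcate; each branch substitutes sites independently."""
    if n_leaves == 1:
        return [root]
    n_left = int(rng.integers(1, n_leaves))
    leaves = []
    for n_child in (n_left, n_leaves - n_left):
        p = float(rng.uniform(0.5, 1.5)) * divergence
        child = root.copy()
        mask = rng.random(len(root)) < p
        # uniform replacement by one of the other 19 amino acids
        shift = rng.integers(1, 20, size=int(mask.sum()))
        child[mask] = (child[mask] + shift) % 20
        leaves.extend(_evolve(child, n_child, divergence, rng))
    return leaves


def simulate_database(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    heldout: bool = False,
):
    """Evolve an aligned database of ``n_species`` along a random tree.

    With ``heldout=True`` one extra species is evolved in the same alignment
    but returned separately (and omitted from the database) — the "novel"
    species scenario for FDR calibration.  Returns a
    :class:`SpeciesDatabase`, or ``(db, novel_db)`` when ``heldout``.
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    n_leaves = config.n_species + (1 if heldout else 0)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    names = [f"Species_{i + 1:03d}" for i in range(config.n_species)]
    gene_alignments: dict[str, dict[str, str]] = {g: {} for g in config.gene_names}
    novel_alignments: dict[str, dict[str, str]] = {g: {} for g in config.gene_names}
    novel_name = "Novelis_heldout"

    for gene, length in zip(config.gene_names, config.gene_lengths):
        root = rng.integers(0, 20, size=length).astype(np.int64)
        leaves = _evolve(root, n_leaves, config.divergence, rng)
        novel_seq = leaves[-1] if heldout else None
        for name, codes in zip(names, leaves):
            gene_alignments[gene][name] = aa[codes].tobytes().decode("ascii")
        if heldout:
            novel_alignments[gene][novel_name] = (
                aa[novel_seq].tobytes().decode("ascii")
            )

    # drop genes at random, but keep every species in at least one gene
    for name in names:
        droppable = [g for g in config.gene_names]
        drops = [g for g in droppable if rng.random() < config.missing_gene_rate]
        if len(drops) == len(droppable):
            drops = drops[:-1]
        for g in drops:
            del gene_alignments[g][name]

    db = SpeciesDatabase(
        gene_alignments={g: s for g, s in gene_alignments.items() if s},
        gene_set=tuple(config.gene_names),
    )
    db.validate()
    if not heldout:
        return db
    novel_db = SpeciesDatabase(
        gene_alignments=novel_alignments, gene_set=tuple(config.gene_names)
    )
    return db, novel_db


def add_sister_species(
    db: SpeciesDatabase,
    species: str,
    n_diff_sites: int,
    rng: np.random.Generator,
    sister_name: str | None = None,
) -> str:
    """Add a near-identical sister of ``species`` differing at exactly
    ``n_diff_sites`` non-gap positions (drawn uniformly over its genes)."""
    sister = sister_name or f"{species}_sister"
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    lookup = {c: i for i, c in enumerate(aa)}
    genes = [g for g in db.gene_order if species in db.gene_alignments[g]]
    arrs = {
        g: np.frombuffer(db.gene_alignments[g][species].encode(), dtype=np.uint8).copy()
        for g in genes
    }
    positions = [
        (g, i) for g in genes for i in np.flatnonzero(arrs[g] != ord(GAP))
    ]
    if len(positions) < n_diff_sites:
        raise ValueError("species too short for the requested number of differences")
    chosen = rng.choice(len(positions), size=n_diff_sites, replace=False)
    for k in chosen:
        g, i = positions[int(k)]
        shift = int(rng.integers(1, 20))
        arrs[g][i] = aa[(lookup[arrs[g][i]] + shift) % 20]
    for g in genes:
        db.gene_alignments[g][sister] = arrs[g].tobytes().decode("ascii")
    return sister


# ---------------------------------------------------------------------------
# in-silico digestion

def digest_in_silico(
    species: str,
    db: SpeciesDatabase,
    p_semitryptic: float = 0.0,
    length_range: tuple[int, int] = (7, 30),
    max_missed_cleavages: int = 2,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Tryptic digest of every gene of ``species`` (cleave after K/R, not
    before P, up to ``max_missed_cleavages``); with probability
    ``p_semitryptic`` a peptide loses one terminus at a random internal
    position.  Length-filtered, deterministic under a seeded ``rng``."""
    rng = _rng(0 if rng is None else rng)
    lo, hi = length_range
    peptides: list[str] = []
    for gene in db.gene_order:
        seq = db.gene_alignments[gene].get(species, "").replace(GAP, "")
        if not seq:
            continue
        for pep in sorted(
            _pyt_parser.cleave(seq, TRYPSIN_RULE,
                               missed_cleavages=max_missed_cleavages)
        ):
            if p_semitryptic > 0 and rng.random() < p_semitryptic and len(pep) > lo:
                new_len = int(rng.integers(lo, len(pep)))
                if rng.random() < 0.5:
                    pep = pep[:new_len]      # non-tryptic C-terminus
                else:
                    pep = pep[-new_len:]     # non-tryptic N-terminus
            if lo <= len(pep) <= hi:
                peptides.append(pep)
    return sorted(set(peptides))


def _random_peptides(
    n: int, rng: np.random.Generator, forbidden_texts: list[str],
    length_range=(8, 20), max_tries: int = 1000,
) -> list[str]:
    """Random amino-acid strings guaranteed absent from the database."""
    out = []
    aa = list(AMINO_ACIDS)
    while len(out) < n:
        for _ in range(max_tries):
            k = int(rng.integers(length_range[0], length_range[1] + 1))
            pep = "".join(rng.choice(aa, size=k))
            probe = pep.replace("I", "L")
            if not any(probe in t for t in forbidden_texts):
                out.append(pep)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a non-matching noise peptide")
    return out


def make_protease_fasta(
    db: SpeciesDatabase, rng: np.random.Generator,
    lengths=(231, 269),
) -> str:
    """Synthetic protease (trypsin/LysC stand-in) contaminant FASTA.

    The sequences are random, rejection-checked so that none of their tryptic
    peptides occurs in the database — autolysis peptides must never map to a
    species.
    """
    texts = [db.concat(sp).replace(GAP, "").replace("I", "L") for sp in db.species()]
    names = ["CON_TRYPSIN synthetic trypsin autolysis entry",
             "CON_LYSC synthetic Lys-C protease autolysis entry"]
    entries = []
    for name, length in zip(names, lengths):
        for _ in range(100):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            peps = _pyt_parser.cleave(seq, TRYPSIN_RULE, missed_cleavages=2)
            probes = [p.replace("I", "L") for p in peps if len(p) >= 6]
            if not any(any(p in t for t in texts) for p in probes):
                entries.append((name, seq))
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate a non-matching protease sequence")
    return "".join(f">{n}\n{s}\n" for n, s in entries)


# ---------------------------------------------------------------------------
# evidence simulation

def _protease_peptide_pool(contaminant_fasta: str) -> list[str]:
    pool = []
    for block in contaminant_fasta.split(">"):
        if not block.strip():
            continue
        lines = block.splitlines()
        seq = "".join(lines[1:])
        pool.extend(
            p for p in sorted(
                _pyt_parser.cleave(seq, TRYPSIN_RULE, missed_cleavages=2)
            )
            if 7 <= len(p) <= 30
        )
    return sorted(set(pool))


def _modify(pep: str, deam_prob: float, rng: np.random.Generator) -> str:
    out = []
    for c in pep:
        out.append(c)
        if c in "NQ" and rng.random() < deam_prob:
            out.append("(de)")
    return "".join(out)


def simulate_evidence(
    db: SpeciesDatabase,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    raw_file: str = "sample_01",
    true_db: SpeciesDatabase | None = None,
    contaminant_fasta: str | None = None,
    is_blank: bool = False,
    target_site_coverage: int | None = None,
) -> pd.DataFrame:
    """Simulate one raw file's precursor table (logical schema).

    The true species' digest pool is sampled until ``target_site_coverage``
    distinct sites of that species are covered (a warning is logged when the
    pool cannot reach the target).  ``true_db`` defaults to ``db``; pass the
    held-out database for the "novel species" scenario.  Blanks contain only
    protease autolysis precursors (with intensity) and spurious unmatched
    identifications (intensity 0, identified but unquantified).
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    true_db = true_db if true_db is not None else db
    coverage_target = (
        config.target_site_coverage
        if target_site_coverage is None
        else target_site_coverage
    )
    forbidden = [db.concat(sp).replace(GAP, "").replace("I", "L")
                 for sp in db.species()]

    rows = []

    def add_precursor(pep, intensity, q=None):
        mod = _modify(pep, config.deamidation_prob, rng)
        score = max(config.score_min,
                    float(rng.normal(config.score_mean, config.score_sd)))
        charge = int(rng.choice([2, 3]))
        rows.append((raw_file, pep, mod, charge, intensity, score,
                     float(rng.uniform(0, 0.0099)) if q is None else q))
        if rng.random() < config.second_charge_prob:
            score2 = max(config.score_min,
                         float(rng.normal(config.score_mean, config.score_sd)))
            rows.append((raw_file, pep, mod, 5 - charge,
                         intensity * float(rng.uniform(0.1, 0.5)), score2,
                         float(rng.uniform(0, 0.0099)) if q is None else q))

    n_signal = 0
    if not is_blank and coverage_target > 0:
        true_species = config.true_species or true_db.species()[0]
        if true_species == "novel":
            true_species = true_db.species()[0]
        pool = digest_in_silico(
            true_species, true_db,
            p_semitryptic=config.p_semitryptic,
            length_range=config.peptide_length,
            max_missed_cleavages=config.max_missed_cleavages,
            rng=rng,
        )
        index = build_global_index(true_db)
        maps = build_residue_maps(true_db, index)
        texts = {}
        for gene in true_db.gene_order:
            seq = true_db.gene_alignments[gene].get(true_species, "")
            g = seq.replace(GAP, "")
            if g:
                texts[gene] = (g, maps[(true_species, gene)])
        covered: set[int] = set()
        order = rng.permutation(len(pool))
        for k in order:
            if len(covered) >= coverage_target:
                break
            pep = pool[int(k)]
            hit_sites = []
            for gene, (g, m) in texts.items():
                start = g.find(pep)
                while start != -1:
                    hit_sites.extend(m[start: start + len(pep)].tolist())
                    start = g.find(pep, start + 1)
            if not hit_sites:
                continue
            new = set(hit_sites) - covered
            if not new:
                continue
            covered |= set(hit_sites)
            n_signal += 1
            add_precursor(
                pep,
                float(rng.lognormal(config.intensity_meanlog,
                                    config.intensity_sdlog)),
            )
        if len(covered) < coverage_target:
            log.warning(
                "%s: coverage target %d unreachable, achieved %d",
                raw_file, coverage_target, len(covered),
            )

    # spurious identifications absent from the database; blanks carry them
    # as identified-but-unquantified rows (intensity 0)
    noise = _random_peptides(config.n_noise_peptides, rng, forbidden)
    for pep in noise:
        intensity = 0.0 if is_blank else float(
            rng.lognormal(config.intensity_meanlog - 4.0, config.intensity_sdlog)
        )
        add_precursor(pep, intensity)

    # a few precursors that fail the 1% precursor FDR filter
    for pep in _random_peptides(config.n_fdr_fail, rng, forbidden):
        add_precursor(
            pep,
            float(rng.lognormal(config.intensity_meanlog - 4.0,
                                config.intensity_sdlog)),
            q=float(rng.uniform(0.02, 0.5)),
        )

    df = pd.DataFrame(
        rows,
        columns=["raw_file", "stripped_seq", "modified_seq", "charge",
                 "intensity", "score", "precursor_q"],
    )

    # protease autolysis: scaled so the realized relative protease intensity
    # equals the configured value (or dominates entirely in blanks)
    p = config.protease_relative_intensity
    if contaminant_fasta and (p > 0 or is_blank):
        prot_pool = _protease_peptide_pool(contaminant_fasta)
        n_prot = min(len(prot_pool), int(rng.integers(8, 16)))
        chosen = rng.choice(len(prot_pool), size=n_prot, replace=False)
        raw_int = rng.lognormal(config.intensity_meanlog,
                                config.intensity_sdlog, size=n_prot)
        # only precursors that survive the 1% FDR filter count toward the
        # realized ratio downstream
        signal_total = float(
            df.loc[df["precursor_q"] <= 0.01, "intensity"].sum()
        )
        if is_blank or signal_total == 0 or n_signal == 0:
            # no endogenous signal: autolysis dominates, as in empty wells
            scale = 1.0
        else:
            scale = (p / (1.0 - p)) * signal_total / raw_int.sum()
        prot_rows = []
        for k, intensity in zip(chosen, raw_int * scale):
            pep = prot_pool[int(k)]
            score = max(config.score_min,
                        float(rng.normal(config.score_mean, config.score_sd)))
            prot_rows.append((raw_file, pep, pep, int(rng.choice([2, 3])),
                              float(intensity), score,
                              float(rng.uniform(0, 0.0099))))
        df = pd.concat([df, pd.DataFrame(prot_rows, columns=df.columns)],
                       ignore_index=True)

    # normalize like the readers do: I->L, merged precursor identities
    df["stripped_seq"] = df["stripped_seq"].str.replace("I", "L", regex=False)
    df = (
        df.groupby(["raw_file", "modified_seq", "charge"], as_index=False, sort=True)
        .agg(stripped_seq=("stripped_seq", "first"),
             intensity=("intensity", "sum"),
             score=("score", "max"),
             precursor_q=("precursor_q", "min"))
    )
    return df[["raw_file", "stripped_seq", "modified_seq", "charge",
               "intensity", "score", "precursor_q"]]


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class SyntheticStudy:
    """A complete simulated cohort ready for the inference pipeline."""

    db: SpeciesDatabase               # target species only
    evidence: pd.DataFrame
    sample_annotations: pd.DataFrame  # raw_file, is_blank
    truth: pd.DataFrame               # raw_file, true_species, is_novel, is_blank
    contaminant_fasta: str
    config: SimulationConfig


def simulate_cohort(
    config: SimulationConfig,
    n_samples: int = 150,
    n_novel: int = 30,
    n_blanks: int = 20,
    coverage_range: tuple[int, int] = (400, 2500),
) -> SyntheticStudy:
    """Simulate a study: samples from database species, samples from one
    held-out novel species, and protease-dominated laboratory blanks.

    Per-file coverage targets are drawn log-uniformly from
    ``coverage_range`` to create a realistic preservation gradient.
    """
    rng = np.random.default_rng(config.seed)
    db, novel_db = simulate_database(config, rng=rng, heldout=True)
    contaminant_fasta = make_protease_fasta(db, rng)
    targets = db.target_species()

    frames, truth_rows, ann_rows = [], [], []

    def draw_coverage() -> int:
        lo, hi = np.log10(coverage_range[0]), np.log10(coverage_range[1])
        return int(round(10 ** rng.uniform(lo, hi)))

    for i in range(n_samples):
        rf = f"sample_{i + 1:03d}"
        true_sp = (
            config.true_species
            if config.true_species and config.true_species != "novel"
            else targets[int(rng.integers(0, len(targets)))]
        )
        cov = draw_coverage()
        cfg = _with_true(config, true_sp)
        frames.append(
            simulate_evidence(
                db, cfg, rng=rng, raw_file=rf,
                contaminant_fasta=contaminant_fasta,
                target_site_coverage=cov,
            )
        )
        truth_rows.append({"raw_file": rf, "true_species": true_sp,
                           "is_novel": False, "is_blank": False,
                           "coverage_target": cov})
        ann_rows.append({"raw_file": rf, "is_blank": False})

    for i in range(n_novel):
        rf = f"novel_{i + 1:03d}"
        cov = draw_coverage()
        cfg = _with_true(config, novel_db.species()[0])
        frames.append(
            simulate_evidence(
                db, cfg, rng=rng, raw_file=rf, true_db=novel_db,
                contaminant_fasta=contaminant_fasta,
                target_site_coverage=cov,
            )
        )
        truth_rows.append({"raw_file": rf,
                           "true_species": novel_db.species()[0],
                           "is_novel": True, "is_blank": False,
                           "coverage_target": cov})
        ann_rows.append({"raw_file": rf, "is_blank": False})

    for i in range(n_blanks):
        rf = f"blank_{i + 1:03d}"
        frames.append(
            simulate_evidence(
                db, config, rng=rng, raw_file=rf,
                contaminant_fasta=contaminant_fasta, is_blank=True,
            )
        )
        truth_rows.append({"raw_file": rf, "true_species": "",
                           "is_novel": False, "is_blank": True,
                           "coverage_target": 0})
        ann_rows.append({"raw_file": rf, "is_blank": True})

    return SyntheticStudy(
        db=db,
        evidence=pd.concat(frames, ignore_index=True),
        sample_annotations=pd.DataFrame(ann_rows),
        truth=pd.DataFrame(truth_rows),
        contaminant_fasta=contaminant_fasta,
        config=config,
    )


def _with_true(config: SimulationConfig, true_species: str) -> SimulationConfig:
    cfg = SimulationConfig(**asdict(config))
    cfg.true_species = true_species
    return cfg


# ---------------------------------------------------------------------------
# dialect writers (bit-compatible with the evidence readers)

def write_maxquant_evidence(evidence: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "Raw file": evidence["raw_file"],
            "Sequence": evidence["stripped_seq"],
            "Modified sequence": evidence["modified_seq"],
            "Charge": evidence["charge"],
            "Intensity": evidence["intensity"],
            "Score": evidence["score"],
            "Proteins": "",
        }
    )
    # MaxQuant evidence is already 1% FDR filtered and carries no q column
    out = out[~(evidence["precursor_q"] > 0.01).to_numpy()]
    out.to_csv(path, sep="\t", index=False)


def write_spectronaut_report(evidence: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "R.FileName": evidence["raw_file"],
            "PEP.StrippedSequence": evidence["stripped_seq"],
            "EG.ModifiedSequence": evidence["modified_seq"],
            "FG.Charge": evidence["charge"],
            "FG.Quantity": evidence["intensity"],
            "EG.Cscore": evidence["score"],
            "EG.Qvalue": evidence["precursor_q"],
            "PG.ProteinAccessions": "",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_sample_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)
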