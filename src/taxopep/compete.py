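"""Species-to-species competition and marker-peptide fine-grouping.

Every unordered pair of species (targets and decoys alike) is compared over
its discriminating sites: for each site where the pair differs, the J-score
of species A's variant (if observed in the file) is added to A's sum and
likewise for B.  The species with the larger sum wins the comparison; equal
sums — including the no-data 0 vs 0 case — make both species winners.  The
best match for a file is the set of species winning the most comparisons,
which may contain several indistinguishable species.

Fine-grouping refines a best match within a genus using hand-picked marker
peptides: each candidate species is scored by the summed precursor intensity
of its detected markers, and the top-scoring candidate(s) replace the best
match.  Fine-grouping never widens the taxonomy — it only applies when the
best match intersects a marker group, and its output is restricted to that
group's candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .db import SiteDifferenceMatrix

COMPETITION_COLUMNS = [
    "raw_file", "species_a", "species_b",
    "sum_j_a", "sum_j_b", "n_discriminating_sites_observed", "outcome",
]


class PairScorer:
    """Flattened difference-matrix arrays for vectorized per-file scoring.

    Building the scorer once and reusing it across raw files avoids
    re-walking the pair dictionary 200 times in a cohort run.
    """

    def __init__(self, diff_matrix: SiteDifferenceMatrix):
        self.species = list(diff_matrix.species)
        self.pairs = sorted(diff_matrix.pairs())
        sites, codes_a, codes_b, pair_ids = [], [], [], []
        for k, (a, b) in enumerate(self.pairs):
            s, ca, cb = diff_matrix.arrays(a, b)
            sites.append(s)
            codes_a.append(ca)
            codes_b.append(cb)
            pair_ids.append(np.full(len(s), k, dtype=np.int64))
        self.sites = np.concatenate(sites) if sites else np.zeros(0, dtype=np.int64)
        self.codes_a = np.concatenate(codes_a) if codes_a else np.zeros(0, np.uint8)
        self.codes_b = np.concatenate(codes_b) if codes_b else np.zeros(0, np.uint8)
        self.pair_ids = (
            np.concatenate(pair_ids) if pair_ids else np.zeros(0, dtype=np.int64)
        )
        self.max_site = int(self.sites.max()) if len(self.sites) else 0

    def dense_scores(self, file_sites: pd.DataFrame):
        """Dense (site, aa) -> J-score and presence lookups for one file."""
        L = max(self.max_site, int(file_sites["site"].max()) if len(file_sites) else 0)
        j = np.zeros((L + 1, 128), dtype=np.float64)
        present = np.zeros((L + 1, 128), dtype=bool)
        if len(file_sites):
            s = file_sites["site"].to_numpy(dtype=np.int64)
            a = file_sites["aa"].map(ord).to_numpy(dtype=np.int64)
            j[s, a] = file_sites["j_score"].to_numpy(dtype=np.float64)
            present[s, a] = True
        return j, present

    def score_file(self, raw_file: str, file_sites: pd.DataFrame) -> pd.DataFrame:
        j, present = self.dense_scores(file_sites)
        n_pairs = len(self.pairs)
        va = j[self.sites, self.codes_a]
        vb = j[self.sites, self.codes_b]
        obs = present[self.sites, self.codes_a] | present[self.sites, self.codes_b]
        sum_a = np.bincount(self.pair_ids, weights=va, minlength=n_pairs)
        sum_b = np.bincount(self.pair_ids, weights=vb, minlength=n_pairs)
        n_obs = np.bincount(self.pair_ids, weights=obs, minlength=n_pairs).astype(int)
        outcome = np.where(
            sum_a > sum_b, "a_wins", np.where(sum_b > sum_a, "b_wins", "tie")
        )
        return pd.DataFrame(
            {
                "raw_file": raw_file,
                "species_a": [p[0] for p in self.pairs],
                "species_b": [p[1] for p in self.pairs],
                "sum_j_a": sum_a,
                "sum_j_b": sum_b,
                "n_discriminating_sites_observed": n_obs,
                "outcome": outcome,
            },
            columns=COMPETITION_COLUMNS,
        )


def compete(
    site_scores: pd.DataFrame,
    diff_matrix: SiteDifferenceMatrix,
    raw_file: str,
    scorer: PairScorer | None = None,
) -> pd.DataFrame:
    """Score every species pair for one raw file.

    ``site_scores`` is the scored site table (possibly spanning many files);
    only rows of ``raw_file`` are used.  Pass a prebuilt :class:`PairScorer`
    to amortize setup across files.
    """
    scorer = scorer or PairScorer(diff_matrix)
    file_sites = site_scores[site_scores["raw_file"] == raw_file]
    return scorer.score_file(raw_file, file_sites)


def best_match(matrix: pd.DataFrame) -> frozenset:
    """Species winning the most comparisons; a tie is a win for both sides."""
    if len(matrix) == 0:
        raise ValueError("empty competition matrix: no species to rank")
    wins: dict[str, int] = {}
    for sp in pd.unique(matrix[["species_a", "species_b"]].to_numpy().ravel()):
        wins[sp] = 0
    a = matrix["species_a"].to_numpy()
    b = matrix["species_b"].to_numpy()
    out = matrix["outcome"].to_numpy()
    for sa, sb, o in zip(a, b, out):
        if o == "a_wins":
            wins[sa] += 1
        elif o == "b_wins":
            wins[sb] += 1
        else:
            wins[sa] += 1
            wins[sb] += 1
    top = max(wins.values())
    return frozenset(sp for sp, w in wins.items() if w == top)


def load_marker_table(table, db=None, sep: str = "\t") -> pd.DataFrame:
    """Load the fine-grouping marker table (group, species, peptide).

    Marker peptides must already be I->L normalized (an 'I' raises), and with
    ``db`` given every candidate species must exist in the database.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep=sep)
    required = {"group", "species", "peptide"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    df = df.copy()
    df["peptide"] = df["peptide"].astype(str).str.upper()
    if df["peptide"].str.contains("I").any():
        raise ValueError("marker peptides must be I->L normalized (found 'I')")
    if db is not None:
        unknown = set(df["species"]) - set(db.species())
        if unknown:
            raise ValueError(f"marker species not in database: {sorted(unknown)}")
    return df


def fine_group(
    records: pd.DataFrame,
    marker_table: pd.DataFrame | None,
    best_match_set: frozenset,
) -> frozenset:
    """Refine ``best_match_set`` with marker-peptide intensities for one file.

    ``records`` must contain only the file's precursors.  Candidate species
    are those of marker groups intersecting the best match; each candidate is
    scored by the summed intensity of its detected marker peptides.  With no
    detected marker the best match is returned unchanged.
    """
    if marker_table is None or len(marker_table) == 0:
        return best_match_set
    groups = marker_table.groupby("group")["species"].agg(set)
    active = [g for g, sps in groups.items() if sps & best_match_set]
    if not active:
        return best_match_set
    candidates = marker_table[marker_table["group"].isin(active)]
    pep_intensity = records.groupby("stripped_seq")["intensity"].sum()
    scores = {}
    for sp, sub in candidates.groupby("species"):
        detected = [p for p in sub["peptide"] if p in pep_intensity.index]
        if detected:
            scores[sp] = float(pep_intensity.loc[detected].sum())
    if not scores:
        return best_match_set
    top = max(scores.values())
    return frozenset(sp for sp, v in scores.items() if v == top)
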