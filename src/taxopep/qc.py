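"""Per-file QC metrics, blank-calibrated signal threshold, and decoy FDR.

Two independent confidence controls gate the final species calls:

* Relative protease intensity — autolysis peptides of the digestion
  proteases (trypsin/LysC) behave like a spike-in standard.  Their summed
  intensity divided by the file's total intensity approaches 1 in empty
  runs, so files at or above the upper quartile of the laboratory blanks are
  flagged ``signal_too_low``.

* Decoy-species q-value — files are ranked by site count (absolute sequence
  coverage of the assigned species); at each site-count cutoff the fraction
  of decoy-only identifications among the files above it estimates the
  species-level FDR.  After monotonization, files with q > 1% are flagged
  ``above_fdr_threshold``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def relative_protease_intensity(records: pd.DataFrame, raw_file: str | None = None) -> float:
    """Summed protease precursor intensity over total intensity (0 if empty)."""
    df = records if raw_file is None else records[records["raw_file"] == raw_file]
    total = float(df["intensity"].sum())
    if total <= 0:
        return 0.0
    prot = float(df.loc[df["is_protease"], "intensity"].sum())
    # summation order can push the quotient epsilon past 1
    return min(1.0, max(0.0, prot / total))


def protease_cutoff(blank_ratios) -> float:
    """Upper quartile (linear-interpolation) of blank protease ratios."""
    ratios = np.asarray(list(blank_ratios), dtype=float)
    if len(ratios) == 0:
        raise ValueError(
            "no laboratory blanks: supply a manual protease-intensity cutoff "
            "via configuration"
        )
    return float(np.percentile(ratios, 75))


def site_count(
    file_sites: pd.DataFrame,
    assigned_species,
    species_concat: dict[str, str],
) -> int:
    """Distinct global sites where an observed amino acid matches the
    assigned species (any member of an indistinguishable set)."""
    if len(file_sites) == 0 or not assigned_species:
        return 0
    sites = file_sites["site"].to_numpy(dtype=np.int64)
    aas = file_sites["aa"].to_numpy()
    matched = np.zeros(len(file_sites), dtype=bool)
    for sp in assigned_species:
        seq = species_concat[sp]
        residues = np.array([seq[s - 1] for s in sites])
        matched |= residues == aas
    return int(pd.unique(sites[matched]).size)


def compute_qvalues(
    results: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Rank files by decreasing site count and compute decoy q-values.

    ``results`` needs columns ``raw_file``, ``site_count`` and
    ``is_decoy_only`` (True when the final species set consists only of
    decoys; a set mixing targets and decoys counts as a target
    identification).  The raw q at a site-count cutoff is the decoy fraction
    among all files at or above it; q-values are then monotonized by a
    cumulative minimum from the lowest-coverage rank upward so that the flag
    corresponds to a single site-count cutoff.  Adds ``q_value_raw``,
    ``q_value`` and ``above_fdr_threshold``.

    When a ``signal_too_low`` column is present, files failing the signal
    threshold are excluded from the ranking (they are already excluded
    from the results) and receive q = NaN: only then does the cutoff
    guarantee a <=alpha decoy fraction among the unflagged files, since
    signal-failed blanks would otherwise pad the low-coverage tail of the
    ranking and dilute the decoy fraction there.
    """
    df = results.sort_values(
        ["site_count", "raw_file"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if "signal_too_low" in df.columns and df["signal_too_low"].any():
        ranked = compute_qvalues(
            df[~df["signal_too_low"]].drop(columns=["signal_too_low"]),
            alpha=alpha,
        )
        ranked["signal_too_low"] = False
        rest = df[df["signal_too_low"]].copy()
        rest["q_value_raw"] = float("nan")
        rest["q_value"] = float("nan")
        rest["above_fdr_threshold"] = False
        return pd.concat([ranked, rest], ignore_index=True)[
            list(df.columns) + ["q_value_raw", "q_value", "above_fdr_threshold"]
        ]
    n = len(df)
    if n == 0:
        for col in ("q_value_raw", "q_value"):
            df[col] = pd.Series(dtype=float)
        df["above_fdr_threshold"] = pd.Series(dtype=bool)
        return df
    cum_decoy = np.cumsum(df["is_decoy_only"].to_numpy(dtype=float))
    ranks = np.arange(1, n + 1, dtype=float)
    raw = cum_decoy / ranks
    # all files sharing a site count stand or fall together: use the value at
    # the last (worst) rank of each tie group
    sc = df["site_count"].to_numpy()
    last_of_group = np.r_[sc[1:] != sc[:-1], True]
    group_value = raw[last_of_group]
    group_idx = np.cumsum(last_of_group) - 1  # index of own group
    raw_tied = group_value[group_idx]
    q = np.minimum.accumulate(raw_tied[::-1])[::-1]
    df["q_value_raw"] = raw_tied
    df["q_value"] = q
    df["above_fdr_threshold"] = df["q_value"] > alpha
    return df


def consensus_sequence(file_sites: pd.DataFrame) -> pd.Series:
    """Per covered global site, the amino acid with maximal J-score.

    Ties break alphabetically; uncovered sites are absent.  Returns a Series
    indexed by global site.
    """
    if len(file_sites) == 0:
        return pd.Series(dtype=object, name="aa")
    ordered = file_sites.sort_values(
        ["site", "j_score", "aa"], ascending=[True, False, True], kind="mergesort"
    )
    top = ordered.drop_duplicates("site")
    return pd.Series(top["aa"].to_numpy(), index=top["site"].to_numpy(), name="aa")


def consensus_string(consensus: pd.Series, total_length: int, gap: str = "-") -> str:
    """Render a consensus as a full-length string with gaps at uncovered sites."""
    chars = [gap] * total_length
    for site, aa in consensus.items():
        chars[int(site) - 1] = aa
    return "".join(chars)


_DEAM_TOKENS = ("de",)  # short MaxQuant notation "(de)"


def _is_deamidation(token: str) -> bool:
    t = token.strip().strip("()[]").lower()
    return t.startswith("deam") or t in _DEAM_TOKENS


def _tokenize_modified(mseq: str):
    """Yield ('res', aa) and ('mod', token) items; mod tokens may nest
    parentheses, as in the long MaxQuant notation "(Deamidation (NQ))"."""
    i, n = 0, len(mseq)
    while i < n:
        c = mseq[i]
        if c in "([":
            depth = 0
            j = i
            while j < n:
                if mseq[j] in "([":
                    depth += 1
                elif mseq[j] in ")]":
                    depth -= 1
                    if depth == 0:
                        break
                j += 1
            yield ("mod", mseq[i: j + 1])
            i = j + 1
        else:
            yield ("res", c)
            i += 1


def deamidation_fractions(records: pd.DataFrame, raw_file: str | None = None) -> dict:
    """Fraction of deamidated N and Q residue occurrences across precursors.

    Modification notation: a parenthesized or bracketed token directly after
    the residue whose text starts with "deam" (or the MaxQuant shorthand
    "(de)").  Residue types with no occurrences yield NaN.
    """
    df = records if raw_file is None else records[records["raw_file"] == raw_file]
    totals = {"N": 0, "Q": 0}
    deam = {"N": 0, "Q": 0}
    for mseq in df["modified_seq"]:
        last_residue = None
        for kind, token in _tokenize_modified(str(mseq).strip("_")):
            if kind == "res":
                last_residue = token if token in "NQ" else None
                if last_residue:
                    totals[last_residue] += 1
            elif last_residue and _is_deamidation(token):
                deam[last_residue] += 1
    return {
        r: (deam[r] / totals[r] if totals[r] else float("nan")) for r in ("N", "Q")
    }
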