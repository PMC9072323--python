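"""Site-level aggregation and the normalized joint score (J-score).

Peptide identifications are split into amino-acid identifications: every
annotated precursor deposits its residues on the global sites it covers.
Per (raw file, global site, amino acid), four metrics are accumulated —
precursor count, peptide count, summed intensity, and maximum search score.
Summed intensities above 1 are log10-transformed; each metric is scaled by
its maximum over the amino acids observed at that site in that file; the
four scaled metrics are multiplied and the product re-scaled by the per-site
maximum, giving a J-score in [0, 1].  The J-score is not an amino-acid
probability — it weights amino acids by the strength of their underlying
evidence, and at least one amino acid per covered site scores 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RAW_COLUMNS = [
    "raw_file", "site", "aa",
    "n_precursors", "n_peptides", "sum_intensity", "max_score",
]


def aggregate_sites(
    records: pd.DataFrame,
    annotations: dict,
) -> pd.DataFrame:
    """One row per (raw file, global site, amino acid) observed.

    Only annotated, non-contaminant precursors contribute (protease and
    contaminant flags exclude a precursor from site observations entirely).
    A precursor matched to several species deposits on the union of its
    covered (site, aa) pairs once, not once per species.
    """
    df = records
    if "is_contaminant" in df.columns:
        df = df[~df["is_contaminant"]]
    peps = df["stripped_seq"].to_numpy()
    lengths = np.array([len(annotations[p].sites) for p in peps])
    keep = lengths > 0
    df = df[keep]
    lengths = lengths[keep]
    if len(df) == 0:
        return pd.DataFrame(columns=RAW_COLUMNS)

    idx = np.repeat(np.arange(len(df)), lengths)
    sites = np.concatenate([annotations[p].sites for p in df["stripped_seq"]])
    aas = np.concatenate([annotations[p].aas for p in df["stripped_seq"]])
    long = pd.DataFrame(
        {
            "raw_file": df["raw_file"].to_numpy()[idx],
            "site": sites,
            "aa": aas,
            "stripped_seq": df["stripped_seq"].to_numpy()[idx],
            "intensity": df["intensity"].to_numpy()[idx],
            "score": df["score"].to_numpy()[idx],
        }
    )
    agg = (
        long.groupby(["raw_file", "site", "aa"], as_index=False, sort=True)
        .agg(
            n_precursors=("stripped_seq", "size"),
            n_peptides=("stripped_seq", "nunique"),
            sum_intensity=("intensity", "sum"),
            max_score=("score", "max"),
        )
    )
    agg["aa"] = agg["aa"].map(chr)
    return agg[RAW_COLUMNS]


def _scaled(values: np.ndarray, gmax: np.ndarray) -> np.ndarray:
    # a metric whose per-site maximum is 0 carries no ranking information at
    # that site and is treated as neutral (factor 1) rather than 0/0
    return np.where(gmax > 0, values / np.where(gmax > 0, gmax, 1.0), 1.0)


def score_sites(site_table: pd.DataFrame) -> pd.DataFrame:
    """Compute scaled metrics and the J-score per (raw file, site)."""
    df = site_table.copy()
    if len(df) == 0:
        for col in ("log_intensity", "scaled_n_precursors", "scaled_n_peptides",
                    "scaled_log_intensity", "scaled_max_score", "j_score"):
            df[col] = pd.Series(dtype=float)
        return df
    sum_int = df["sum_intensity"].to_numpy(dtype=float)
    df["log_intensity"] = np.where(sum_int > 1.0, np.log10(np.maximum(sum_int, 1.0)), 0.0)
    # negative search scores carry no evidence; clamp before scaling
    clamped_score = df["max_score"].clip(lower=0.0).to_numpy(dtype=float)

    metrics = {
        "scaled_n_precursors": df["n_precursors"].to_numpy(dtype=float),
        "scaled_n_peptides": df["n_peptides"].to_numpy(dtype=float),
        "scaled_log_intensity": df["log_intensity"].to_numpy(dtype=float),
        "scaled_max_score": clamped_score,
    }
    raw_j = np.ones(len(df))
    for name, values in metrics.items():
        df["_tmp"] = values
        gmax = df.groupby(["raw_file", "site"], sort=False)["_tmp"].transform("max")
        df[name] = _scaled(values, gmax.to_numpy())
        raw_j = raw_j * df[name].to_numpy()
    del df["_tmp"]
    df["_raw_j"] = raw_j
    jmax = df.groupby(["raw_file", "site"], sort=False)["_raw_j"].transform("max").to_numpy()
    df["j_score"] = np.where(jmax > 0, raw_j / np.where(jmax > 0, jmax, 1.0), 0.0)
    del df["_raw_j"]
    return df
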