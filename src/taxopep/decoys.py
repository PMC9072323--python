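"""Chimeric decoy species.

Species-level FDR is estimated by extending the target database with an
equally sized set of decoy species.  Each decoy is a chimera: the global
alignment (1..L) is cut into fixed-length slices (500 columns by default) and
every slice is copied verbatim — gaps included — from a target species drawn
uniformly at random, with replacement across slices.  A decoy therefore looks
locally like a real species everywhere but corresponds to no coherent taxon,
so a sample whose evidence is too sparse or too ambiguous to pin down a real
species is as likely to best-match a decoy as a target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .db import GAP, DECOY_PREFIX, GlobalSiteIndex, SpeciesDatabase


def generate_decoys(
    db: SpeciesDatabase,
    index: GlobalSiteIndex,
    slice_len: int = 500,
    n_decoys: int | None = None,
    seed: int | np.random.Generator | None = None,
    prefix: str | None = None,
    max_attempts: int = 100,
) -> tuple[SpeciesDatabase, pd.DataFrame]:
    """Extend ``db`` with chimeric decoy species.

    Returns the combined target+decoy database and a provenance table with
    one row per (decoy, slice) recording the source species, for audit.
    The final partial slice (when L is not a multiple of ``slice_len``) is
    kept.  A decoy whose aligned concatenation is identical to a target is
    regenerated.  Fixed ``seed`` gives byte-identical output.
    """
    if slice_len < 1:
        raise ValueError("slice_len must be >= 1")
    targets = db.target_species()
    if not targets:
        raise ValueError("empty target roster: nothing to build decoys from")
    prefix = prefix if prefix is not None else db.decoy_prefix or DECOY_PREFIX
    n_decoys = len(targets) if n_decoys is None else n_decoys
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    L = index.total_length
    concat = {sp: db.concat(sp) for sp in targets}
    target_strings = set(concat.values())
    starts = list(range(0, L, slice_len))

    out = db.copy()
    out.decoy_prefix = prefix
    provenance_rows = []
    for i in range(n_decoys):
        name = f"{prefix}{i + 1:03d}"
        for attempt in range(max_attempts):
            src_idx = rng.integers(0, len(targets), size=len(starts))
            chimera = "".join(
                concat[targets[j]][s: s + slice_len]
                for j, s in zip(src_idx, starts)
            )
            if chimera not in target_strings:
                break
        else:
            raise RuntimeError(
                f"could not generate a decoy distinct from all targets after "
                f"{max_attempts} attempts; database may be degenerate"
            )
        for j, s in zip(src_idx, starts):
            provenance_rows.append(
                {
                    "decoy": name,
                    "slice_start": s + 1,
                    "slice_end": min(s + slice_len, L),
                    "source_species": targets[j],
                }
            )
        # re-derive per-gene sequences from the global chimera; genes that
        # come out all-gap are treated as missing for the decoy
        for gene in index.gene_order:
            off = index.offsets[gene]
            part = chimera[off: off + index.gene_lengths[gene]]
            if set(part) != {GAP}:
                out.gene_alignments[gene][name] = part
    provenance = pd.DataFrame(
        provenance_rows,
        columns=["decoy", "slice_start", "slice_end", "source_species"],
    )
    return out, provenance
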