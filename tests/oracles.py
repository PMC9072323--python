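"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: concatenation, substring
search, and pair scoring are done with naive Python loops so that agreement
with the vectorized implementations is meaningful.
"""

from __future__ import annotations


def concat_aligned(db, species: str) -> str:
    """Alphabetical gene concatenation with gap fill, by plain loops."""
    out = []
    for gene in sorted(db.gene_alignments):
        seqs = db.gene_alignments[gene]
        length = len(next(iter(seqs.values())))
        out.append(seqs.get(species, "-" * length))
    return "".join(out)


def brute_difference_matrix(db) -> dict:
    """pair (a, b) sorted -> list of (1-based site, aa_a, aa_b)."""
    species = sorted({sp for seqs in db.gene_alignments.values() for sp in seqs})
    full = {sp: concat_aligned(db, sp) for sp in species}
    out = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            diffs = []
            for pos, (x, y) in enumerate(zip(full[a], full[b]), start=1):
                if x != y and x != "-" and y != "-":
                    diffs.append((pos, x, y))
            out[(a, b)] = diffs
    return out


def brute_annotate(peptide: str, db) -> dict:
    """All matches of a peptide: species -> set of (site, aa) pairs.

    Scans every (species, gene) aligned sequence position by position,
    skipping gaps, and compares slices of the gapless sequence.
    """
    hits: dict[str, set] = {}
    for gene in sorted(db.gene_alignments):
        offset = sum(
            len(next(iter(db.gene_alignments[g].values())))
            for g in sorted(db.gene_alignments)
            if g < gene
        )
        for sp, aligned in db.gene_alignments[gene].items():
            gapless = []
            sites = []
            for col, c in enumerate(aligned, start=1):
                if c != "-":
                    gapless.append(c)
                    sites.append(offset + col)
            gapless = "".join(gapless)
            for start in range(len(gapless) - len(peptide) + 1):
                if gapless[start: start + len(peptide)] == peptide:
                    pairs = {
                        (sites[start + k], peptide[k]) for k in range(len(peptide))
                    }
                    hits.setdefault(sp, set()).update(pairs)
    return hits


def brute_compete(j_scores: dict, diff: dict) -> dict:
    """pair -> (sum_a, sum_b, outcome) from a {(site, aa): j} lookup."""
    out = {}
    for (a, b), entries in diff.items():
        sum_a = sum(j_scores.get((s, x), 0.0) for s, x, _ in entries)
        sum_b = sum(j_scores.get((s, y), 0.0) for s, _, y in entries)
        if sum_a > sum_b:
            outcome = "a_wins"
        elif sum_b > sum_a:
            outcome = "b_wins"
        else:
            outcome = "tie"
        out[(a, b)] = (sum_a, sum_b, outcome)
    return out


def brute_best_match(compete_results: dict) -> set:
    wins: dict[str, int] = {}
    for (a, b), (_, _, outcome) in compete_results.items():
        wins.setdefault(a, 0)
        wins.setdefault(b, 0)
        if outcome in ("a_wins", "tie"):
            wins[a] += 1
        if outcome in ("b_wins", "tie"):
            wins[b] += 1
    top = max(wins.values())
    return {sp for sp, w in wins.items() if w == top}


def brute_site_count(observed_pairs, assigned, full_seqs) -> int:
    """Distinct sites where an observed aa equals any assigned species' residue."""
    matched = set()
    for site, aa in observed_pairs:
        for sp in assigned:
            if full_seqs[sp][site - 1] == aa:
                matched.add(site)
    return len(matched)


def random_toy_db(rng, n_species=None, n_genes=None):
    """A small random aligned database (with gaps) for oracle comparisons."""
    from taxopep.db import SpeciesDatabase

    n_species = n_species or int(rng.integers(2, 7))
    n_genes = n_genes or int(rng.integers(1, 4))
    genes = [f"G{k}" for k in range(n_genes)]
    alphabet = list("ACDEFGHKLMNPQRSTVWY")  # I excluded: databases are I->L
    alignments = {}
    for g in genes:
        length = int(rng.integers(10, 101))
        alignments[g] = {}
        for i in range(n_species):
            chars = [
                "-" if rng.random() < 0.1
                else alphabet[int(rng.integers(0, len(alphabet)))]
                for _ in range(length)
            ]
            if rng.random() < 0.15 and n_species > 1:
                continue  # species misses this gene
            alignments[g][f"Sp{i}"] = "".join(chars)
    # every species must appear in at least one gene
    for i in range(n_species):
        if not any(f"Sp{i}" in alignments[g] for g in genes):
            length = len(next(iter(alignments[genes[0]].values())))
            alignments[genes[0]][f"Sp{i}"] = "".join(
                alphabet[int(rng.integers(0, len(alphabet)))] for _ in range(length)
            )
    return SpeciesDatabase(
        gene_alignments=alignments, gene_set=tuple(genes)
    )
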