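import numpy as np
import pandas as pd
import pytest

from taxopep.db import SpeciesDatabase

TOY_FASTA = """\
>NCBI | XP_1 | XP_1_COL1A1 collagen alpha-1 OS = Bos taurus OX = 9913 GN = COL1A1
GPAGPKGELGPVG-
>sp|P02465|CO1A2_BOVIN Collagen alpha-2(I) OS=Bos taurus OX=9913 GN=COL1A2
MLSFVDTR--
>NCBI | XP_2 | XP_2_COL1A1 collagen alpha-1 OS = Ovis aries OX = 9940 GN = COL1A1
GPAGPKGESGPVG-
>NCBI | XP_3 | XP_3_COL1A2 collagen alpha-2 OS = Ovis aries OX = 9940 GN = COL1A2
MLSFVDSR--
>NCBI | XP_4 | XP_4_COL1A1 collagen alpha-1 OS = Capra hircus OX = 9925 GN = COL1A1
GPAGPKGESGPVG-
"""


@pytest.fixture
def toy_fasta() -> str:
    """Three species, two genes; sheep and goat identical on COL1A1."""
    return TOY_FASTA


@pytest.fixture
def toy_db(toy_fasta) -> SpeciesDatabase:
    from taxopep.db import parse_database

    return parse_database(toy_fasta)


def make_evidence(rows) -> pd.DataFrame:
    """Logical-schema evidence table from (raw_file, seq, charge, intensity,
    score[, q]) tuples; modified sequence defaults to the stripped one."""
    recs = []
    for row in rows:
        rf, seq, charge, intensity, score = row[:5]
        q = row[5] if len(row) > 5 else np.nan
        recs.append(
            {
                "raw_file": rf,
                "stripped_seq": seq.replace("I", "L"),
                "modified_seq": row[6] if len(row) > 6 else seq,
                "charge": charge,
                "intensity": float(intensity),
                "score": float(score),
                "precursor_q": q,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20_220_505)
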