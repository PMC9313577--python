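import numpy as np
import pandas as pd
import pytest

from repsubsets import (ClonotypeRecord, Frame, RepLabel, Repertoire)


def make_repertoire(counts, label=RepLabel(donor_id="t"), frame=Frame.productive):
    """A repertoire with the given template counts and distinct CDR3s."""
    bases = "ACGT"
    recs = []
    for i, c in enumerate(counts):
        # distinct, in-frame, stop-free sequences: GCT = Ala
        nt = "TGT" + "".join(bases[(i >> (2 * j)) & 3] * 3 for j in range(4)) + "GCT"
        recs.append(ClonotypeRecord(cdr3_nt=nt, templates=int(c),
                                    v_gene=f"TRAV{i + 1}", j_gene="TRAJ4",
                                    frame=frame))
    return Repertoire.from_records(recs, label=label)


def make_keyed_repertoire(keys, label=RepLabel(donor_id="k"),
                          counts=None, frame=Frame.productive):
    """A repertoire whose identity keys are derived from the given tokens."""
    recs = []
    counts = counts or [1] * len(keys)
    for tok, c in zip(keys, counts):
        nt = "".join("ACGT"[ord(ch) % 4] for ch in f"{tok:>6}") * 2
        recs.append(ClonotypeRecord(cdr3_nt=nt + "GCT", templates=int(c),
                                    v_gene=f"TRAV{tok}", j_gene="TRAJ1",
                                    frame=frame))
    return Repertoire.from_records(recs, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cell_row(donor="D1", age=30.0, tissue="blood", comp="CD4",
             cmv="negative", **markers):
    base = {"CD45RA": True, "CCR7": True, "CD27": True, "CD28": True,
            "CD95": False, "CD31": True, "CD21": False, "CD62L": True,
            "Ki67": False}
    base.update(markers)
    return {"donor_id": donor, "age_years": age, "tissue": tissue,
            "cmv_status": cmv, "compartment": comp, **base}


def cells_frame(rows):
    return pd.DataFrame(rows)
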