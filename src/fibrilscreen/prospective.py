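"""A bundled 30-compound prospective screening outcome table.

This fixture represents a completed prospective campaign: each compound
carries the label the model predicted before measurement and the
subsequently measured binding outcome (a fitted Ki in nM, or a censored
"no binding" call). It exercises the full prospective-evaluation path —
threshold labeling, classification report, hit lists — without external
data. Structures are decorated scaffold SMILES from the synthetic
templates; outcome counts follow the documented campaign summary:
13 predicted binders, 7 of them confirmed (5 with Ki below 10 nM,
3 false positives still under 50 nM), and 2 binders missed among the 17
predicted non-binders.
"""

from __future__ import annotations

from fibrilscreen.labeling import BINDER, NON_BINDER, CompoundRecord
from fibrilscreen.io import read_compound_table
from fibrilscreen.simulate import SCAFFOLD_TEMPLATES, SUBSTITUENTS


def _smiles(chemotype: str, t: int, i: int, j: int) -> str:
    return SCAFFOLD_TEMPLATES[chemotype][t].format(
        R0=SUBSTITUENTS[i], R1=SUBSTITUENTS[j]
    )


# (id, chemotype, template, sub_i, sub_j, predicted, ki_nM or None=censored)
_ROWS: tuple[tuple, ...] = (
    # predicted binders confirmed by measurement (7; five below 10 nM)
    ("P01", "V", 0, 12, 7, BINDER, 2.1),
    ("P02", "V", 1, 12, 8, BINDER, 3.4),
    ("P03", "M", 0, 12, 7, BINDER, 5.6),
    ("P04", "Z", 0, 12, 7, BINDER, 7.9),
    ("P05", "A", 0, 0, 1, BINDER, 9.2),
    ("P06", "M", 1, 11, 7, BINDER, 14.0),
    ("P07", "Z", 2, 11, 8, BINDER, 21.0),
    # predicted binders not confirmed (6; three potent but above threshold)
    ("P08", "V", 0, 10, 4, BINDER, 31.0),
    ("P09", "M", 0, 10, 5, BINDER, 38.0),
    ("P10", "Z", 0, 10, 6, BINDER, 47.0),
    ("P11", "V", 2, 1, 4, BINDER, 220.0),
    ("P12", "A", 1, 2, 3, BINDER, None),
    ("P13", "A", 2, 4, 5, BINDER, None),
    # measured binders the model missed (2)
    ("P14", "V", 1, 13, 9, NON_BINDER, 12.0),
    ("P15", "M", 2, 13, 9, NON_BINDER, 18.5),
    # correctly predicted non-binders (15)
    ("P16", "V", 0, 4, 4, NON_BINDER, 140.0),
    ("P17", "V", 1, 5, 5, NON_BINDER, 300.0),
    ("P18", "M", 0, 6, 6, NON_BINDER, 560.0),
    ("P19", "M", 1, 3, 3, NON_BINDER, 750.0),
    ("P20", "Z", 1, 2, 2, NON_BINDER, 980.0),
    ("P21", "V", 2, 0, 2, NON_BINDER, None),
    ("P22", "V", 0, 1, 3, NON_BINDER, None),
    ("P23", "M", 2, 0, 2, NON_BINDER, None),
    ("P24", "M", 0, 2, 0, NON_BINDER, None),
    ("P25", "Z", 0, 3, 1, NON_BINDER, None),
    ("P26", "Z", 2, 0, 0, NON_BINDER, None),
    ("P27", "A", 0, 2, 2, NON_BINDER, None),
    ("P28", "A", 1, 0, 1, NON_BINDER, None),
    ("P29", "A", 2, 1, 1, NON_BINDER, None),
    ("P30", "A", 3, 0, 0, NON_BINDER, None),
)


def example_prospective_table() -> list[dict]:
    """Rows of the bundled prospective campaign as plain dicts."""
    rows = []
    for cid, chemotype, t, i, j, predicted, ki in _ROWS:
        rows.append(
            {
                "id": cid,
                "smiles": _smiles(chemotype, t, i, j),
                "ki_nM": ki,
                "no_binding": int(ki is None),
                "chemotype": chemotype,
                "predicted": predicted,
            }
        )
    return rows


def write_example_prospective_table(path) -> None:
    """Write the measured outcomes (CSV) and predictions side by side."""
    rows = example_prospective_table()
    with open(path, "w") as fh:
        fh.write("id,smiles,ki_nM,no_binding,chemotype,predicted\n")
        for r in rows:
            ki = "" if r["ki_nM"] is None else r["ki_nM"]
            fh.write(
                f"{r['id']},{r['smiles']},{ki},{r['no_binding']},"
                f"{r['chemotype']},{r['predicted']}\n"
            )


def load_example_prospective(path=None) -> tuple[list[tuple[str, str]], list[CompoundRecord]]:
    """Return (predictions, measured records) for the bundled campaign.

    If ``path`` is given the table is round-tripped through the standard
    compound-table reader; otherwise it is built in memory.
    """
    rows = example_prospective_table()
    predictions = [(r["id"], r["predicted"]) for r in rows]
    if path is not None:
        write_example_prospective_table(path)
        measured, _ = read_compound_table(path)
        return predictions, measured
    import os
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        tmp = fh.name
    try:
        write_example_prospective_table(tmp)
        measured, _ = read_compound_table(tmp)
    finally:
        os.unlink(tmp)
    return predictions, measured
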